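"""Inter-scaffold gap DNA estimation.

The DNA content of a gap is estimated from the axis distance between the
two FISH foci flanking it: the gap-facing border focus of the left scaffold
and of the right scaffold.  That distance, converted to Mb with the linear
density of the chromatin involved, overestimates the gap because each focus
sits at its BAC's center, inside its scaffold; the scaffold DNA from each
anchor center out to the gap-facing scaffold end (the *overhang*) is
subtracted.  Negative corrected values mean the gap is at or below FISH
resolution and are clamped to 0 kb.  Foci too close to measure reliably
(closer than ``resolution_threshold_um``) get an assigned default distance
of 0.1 µm, just below light-microscope resolution.

By default the µm→Mb conversion integrates piecewise over the chromatin
segments the inter-focus interval crosses; a strict single-class mode using
the class at the gap midpoint is available (``class_mode='midpoint'``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .arrangement import Arrangement, PlacedScaffold, _side_extension_mb
from .bac_anchoring import BorderSet
from .chromosome_model import ChromatinClass, ChromosomeModel, models_by_chrom
from .density import um_to_mb
from .util import percent_of

__all__ = ["GapParams", "GapRecord", "estimate_gap", "estimate_all_gaps", "total_gap_content", "GapTotals"]

DEFAULT_DISTANCE_UM = 0.1


@dataclass(frozen=True)
class GapParams:
    #: measured inter-focus distances below this are considered unresolvable
    resolution_threshold_um: float = 0.2
    #: distance assigned when foci are unresolvable
    default_distance_um: float = DEFAULT_DISTANCE_UM
    #: 'piecewise' integrates densities across segments; 'midpoint' uses the
    #: single class at the gap midpoint
    class_mode: str = "piecewise"


@dataclass(frozen=True)
class GapRecord:
    chrom: object
    left_scaffold: object
    right_scaffold: object
    measured_distance_um: float
    default_distance_used: bool
    chromatin: ChromatinClass
    overhang_left_mb: float
    overhang_right_mb: float
    gap_mb: float
    clamped: bool
    unmeasurable: bool = False

    def __post_init__(self) -> None:
        if not self.unmeasurable and self.gap_mb < 0:
            raise ValueError("gap_mb must be non-negative")


def _piecewise_mb(model: ChromosomeModel, lo: float, hi: float, densities) -> float:
    total = 0.0
    for seg in model.segments:
        a, b = max(seg.start_um, lo), min(seg.end_um, hi)
        if b > a:
            total += um_to_mb(b - a, seg.chromatin, densities)
    return total


def estimate_gap(
    *,
    chrom,
    left_scaffold,
    right_scaffold,
    left_focus_um: float,
    right_focus_um: float,
    overhang_left_mb: float,
    overhang_right_mb: float,
    model: ChromosomeModel,
    densities,
    params: GapParams | None = None,
    unresolvable: bool = False,
) -> GapRecord:
    """Estimate the DNA (Mb) in one gap from its flanking foci.

    ``left_focus_um``/``right_focus_um`` are the axis positions of the two
    gap-facing border foci; the overhangs are the scaffold DNA from each
    flanking anchor center to the scaffold end facing the gap.  Negative
    corrected values are recorded as 0 with ``clamped`` set.
    """
    params = params or GapParams()
    d = right_focus_um - left_focus_um
    default_used = False
    if unresolvable or d < params.resolution_threshold_um:
        d = params.default_distance_um
        default_used = True

    mid = (left_focus_um + right_focus_um) / 2.0
    mid = min(max(mid, 0.0), model.total_length_um)
    mid_class = model.classify(mid)
    if default_used or params.class_mode == "midpoint":
        between_mb = um_to_mb(d, mid_class, densities)
    elif params.class_mode == "piecewise":
        between_mb = _piecewise_mb(model, left_focus_um, right_focus_um, densities)
    else:
        raise ValueError(f"unknown class_mode {params.class_mode!r}")

    raw = between_mb - overhang_left_mb - overhang_right_mb
    return GapRecord(
        chrom=chrom,
        left_scaffold=left_scaffold,
        right_scaffold=right_scaffold,
        measured_distance_um=d,
        default_distance_used=default_used,
        chromatin=mid_class,
        overhang_left_mb=overhang_left_mb,
        overhang_right_mb=overhang_right_mb,
        gap_mb=max(raw, 0.0),
        clamped=raw < 0,
    )


def estimate_all_gaps(
    arrangement: Arrangement,
    border_bacs: Mapping[object, BorderSet],
    scaffolds: pd.DataFrame,
    densities,
    models,
    params: GapParams | None = None,
) -> list[GapRecord]:
    """Estimate every junction gap of an inferred arrangement.

    For each adjacent scaffold pair the left scaffold's higher-axis focus
    and the right scaffold's lower-axis focus flank the gap; the overhangs
    are computed orientation-aware (a reversed scaffold presents its
    physical head to the gap).  Junctions missing a flanking focus yield an
    ``unmeasurable`` record with ``gap_mb`` NaN, excluded from totals.
    """
    params = params or GapParams()
    by_chrom = models_by_chrom(models)
    lengths = scaffolds.set_index("scaffold")["length_bp"].to_dict()

    records: list[GapRecord] = []
    for chrom, placed in arrangement.chromosomes.items():
        model = by_chrom[chrom]
        for left, right in zip(placed, placed[1:]):
            lf, rf = left.hi_um, right.lo_um
            if lf is None or rf is None:
                records.append(
                    GapRecord(
                        chrom, left.scaffold, right.scaffold,
                        measured_distance_um=float("nan"),
                        default_distance_used=False,
                        chromatin=model.classify(model.kinetochore_center_um),
                        overhang_left_mb=float("nan"),
                        overhang_right_mb=float("nan"),
                        gap_mb=float("nan"),
                        clamped=False,
                        unmeasurable=True,
                    )
                )
                continue
            ov_l = _side_extension_mb(
                left, border_bacs[left.scaffold], int(lengths[left.scaffold]), "hi"
            )
            ov_r = _side_extension_mb(
                right, border_bacs[right.scaffold], int(lengths[right.scaffold]), "lo"
            )
            records.append(
                estimate_gap(
                    chrom=chrom,
                    left_scaffold=left.scaffold,
                    right_scaffold=right.scaffold,
                    left_focus_um=lf,
                    right_focus_um=rf,
                    overhang_left_mb=ov_l,
                    overhang_right_mb=ov_r,
                    model=model,
                    densities=densities,
                    params=params,
                )
            )
    return records


@dataclass
class GapTotals:
    per_class_mb: dict[ChromatinClass, float]
    total_mb: float
    n_gaps: int
    n_unmeasurable: int
    genome_size_mb: float | None = None
    genome_percent: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chromatin": cls.value, "gap_mb": mb}
            for cls, mb in sorted(self.per_class_mb.items(), key=lambda kv: kv[0].value)
        ]
        rows.append({"chromatin": "total", "gap_mb": self.total_mb})
        return pd.DataFrame(rows)


def total_gap_content(
    gap_records: Iterable[GapRecord], genome_size_mb: float | None = None
) -> GapTotals:
    """Sum gap DNA by chromatin class, optionally as a percent of the genome.

    The genome fraction is reported as a whole-number percent (total gap Mb
    over total genome Mb, rounded to the nearest integer), matching the
    convention of assembly gap-content summaries.
    """
    per_class: dict[ChromatinClass, float] = {}
    total = 0.0
    n = n_un = 0
    for rec in gap_records:
        if rec.unmeasurable:
            n_un += 1
            continue
        n += 1
        per_class[rec.chromatin] = per_class.get(rec.chromatin, 0.0) + rec.gap_mb
        total += rec.gap_mb
    pct = percent_of(total, genome_size_mb) if genome_size_mb else None
    return GapTotals(per_class, total, n, n_un, genome_size_mb, pct)


def gaps_to_frame(gap_records: Iterable[GapRecord]) -> pd.DataFrame:
    rows = []
    for r in gap_records:
        rows.append(
            {
                "chrom": r.chrom,
                "left": r.left_scaffold,
                "right": r.right_scaffold,
                "distance_um": r.measured_distance_um,
                "chromatin": r.chromatin.value,
                "gap_kb": r.gap_mb * 1000 if not r.unmeasurable else float("nan"),
                "default_distance": r.default_distance_used,
                "clamped": r.clamped,
                "unmeasurable": r.unmeasurable,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "left", "right", "distance_um", "chromatin",
            "gap_kb", "default_distance", "clamped", "unmeasurable",
        ],
    )
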