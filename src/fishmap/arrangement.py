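"""Inference of scaffold order and orientation from probe placements.

Scaffolds are ordered along each chromosome axis by the midpoint of their
border-BAC foci (for single-BAC scaffolds, by their lone focus), which is
robust to scaffold length and to a missing focus.  Orientation is called
``forward`` when the head focus lies at a lower axis coordinate than the
tail focus and ``reverse`` when the opposite holds; when the two foci are
closer than a resolvability margin (by default twice the larger of their
measurement SDs) or only one focus exists, the orientation is left
``unknown`` rather than guessed.

The kinetochore, whose center defines the arm junction, is located either
inside a scaffold (when its center falls within the scaffold's focus
interval extended by the DNA beyond each focus) or in the gap between two
scaffolds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import pandas as pd

from .bac_anchoring import BorderSet
from .chromosome_model import ChromosomeModel, models_by_chrom
from .cytomeasure import placement_to_axis

__all__ = [
    "PlacedScaffold",
    "Arrangement",
    "KinetochoreLocation",
    "infer_arrangement",
    "locate_kinetochore",
    "extended_intervals",
]

ORIENTATIONS = ("forward", "reverse", "unknown")


@dataclass(frozen=True)
class PlacedScaffold:
    """One scaffold's position along an SC axis.

    ``head_axis_um``/``tail_axis_um`` are the axis positions of the foci of
    the head and tail border BACs (equal for a single-BAC scaffold; None
    when missing).
    """

    scaffold: object
    rank: int
    orientation: str = "unknown"
    head_axis_um: float | None = None
    tail_axis_um: float | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def known_foci(self) -> list[float]:
        return [x for x in (self.head_axis_um, self.tail_axis_um) if x is not None]

    @property
    def midpoint_um(self) -> float | None:
        foci = self.known_foci
        return sum(foci) / len(foci) if foci else None

    @property
    def lo_um(self) -> float | None:
        foci = self.known_foci
        return min(foci) if foci else None

    @property
    def hi_um(self) -> float | None:
        foci = self.known_foci
        return max(foci) if foci else None


@dataclass(frozen=True)
class KinetochoreLocation:
    kind: str  # 'in_scaffold' | 'in_gap'
    scaffold: object = None
    left: object = None
    right: object = None
    ambiguous: bool = False


@dataclass
class Arrangement:
    """Per-chromosome ordered, oriented scaffold lists."""

    chromosomes: dict[object, list[PlacedScaffold]] = field(default_factory=dict)
    kinetochore_location: dict[object, KinetochoreLocation] = field(default_factory=dict)
    issues: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, placed in self.chromosomes.items():
            ranks = sorted(p.rank for p in placed)
            if ranks != list(range(len(placed))):
                raise ValueError(f"ranks on chrom {chrom} are not a permutation of 0..n-1")
            ids = [p.scaffold for p in placed]
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate scaffold in arrangement of chrom {chrom}")
            self.chromosomes[chrom] = sorted(placed, key=lambda p: p.rank)

    @classmethod
    def from_orders(
        cls,
        orders: Mapping[object, list],
    ) -> "Arrangement":
        """Build from ``{chrom: [scaffold | (scaffold, orientation), ...]}``."""
        chroms = {}
        for chrom, entries in orders.items():
            placed = []
            for rank, entry in enumerate(entries):
                if isinstance(entry, tuple):
                    sid, orient = entry
                else:
                    sid, orient = entry, "forward"
                placed.append(PlacedScaffold(sid, rank, orient))
            chroms[chrom] = placed
        return cls(chroms)

    def scaffold_ids(self, chrom) -> list:
        return [p.scaffold for p in self.chromosomes[chrom]]

    def find(self, chrom, scaffold) -> PlacedScaffold:
        for p in self.chromosomes[chrom]:
            if p.scaffold == scaffold:
                return p
        raise KeyError(f"scaffold {scaffold!r} not on chrom {chrom!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.chromosomes, key=str):
            for p in self.chromosomes[chrom]:
                rows.append(
                    {
                        "chrom": chrom,
                        "rank": p.rank,
                        "scaffold": p.scaffold,
                        "orientation": p.orientation,
                        "head_um": p.head_axis_um,
                        "tail_um": p.tail_axis_um,
                        "flags": ";".join(sorted(p.flags)),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["chrom", "rank", "scaffold", "orientation", "head_um", "tail_um", "flags"],
        )


class MultiChromosomeError(ValueError):
    """A scaffold's probes place it on more than one chromosome."""


def infer_arrangement(
    placements: pd.DataFrame,
    border_bacs: Mapping[object, BorderSet],
    scaffolds: pd.DataFrame,
    models,
    orientation_margin_um: float | None = None,
) -> Arrangement:
    """Order and orient scaffolds from averaged probe placements.

    Parameters
    ----------
    placements
        Averaged probe placements (``cytomeasure.PLACEMENT_COLUMNS``).
    border_bacs
        Per-scaffold border anchors from ``select_border_bacs``.
    scaffolds
        Table with ``scaffold`` and ``chrom`` columns; chromosome assignment
        is nevertheless taken from the placements (conflicts are reported).
    orientation_margin_um
        Foci closer than this are considered unresolvable and the
        orientation left unknown.  Default: per scaffold, twice the larger
        of the two focus SDs.

    Deterministic: no randomness is involved; ordering ties are broken by
    scaffold id and flagged.
    """
    by_chrom = models_by_chrom(models)
    pl = placements.set_index("probe")

    per_chrom: dict[object, list[dict]] = {}
    issues: list[dict] = []
    for sid, borders in border_bacs.items():
        foci: dict[str, tuple[float, float]] = {}  # role -> (axis, sd)
        chroms = set()
        for role, anchor in (("head", borders.head), ("tail", borders.tail)):
            if anchor is None or anchor.bac not in pl.index:
                continue
            p = pl.loc[anchor.bac]
            model = by_chrom[p["chrom"]]
            foci[role] = (placement_to_axis(p, model), float(p["sd_um"]))
            chroms.add(p["chrom"])
        if not foci:
            issues.append({"scaffold": sid, "issue": "no placed border BAC"})
            continue
        if len(chroms) > 1:
            raise MultiChromosomeError(
                f"scaffold {sid!r} has border BACs placed on chromosomes {sorted(map(str, chroms))}"
            )
        chrom = chroms.pop()
        flags = set()
        single = borders.single is not None
        if single:
            flags.add("single_anchor")
        head = foci.get("head")
        tail = foci.get("tail")
        if not single and (head is None or tail is None):
            flags.add("missing_focus")
        if single:
            axis = head[0] if head else tail[0]
            head_ax = tail_ax = axis
            orientation = "unknown"
        else:
            head_ax = head[0] if head else None
            tail_ax = tail[0] if tail else None
            if head is None or tail is None:
                orientation = "unknown"
            else:
                margin = (
                    orientation_margin_um
                    if orientation_margin_um is not None
                    else 2.0 * max(head[1], tail[1])
                )
                if abs(head_ax - tail_ax) < margin:
                    orientation = "unknown"
                    flags.add("ambiguous_orientation")
                elif head_ax < tail_ax:
                    orientation = "forward"
                else:
                    orientation = "reverse"
        low = False
        for role in ("head", "tail"):
            a = getattr(borders, role)
            if a is not None and a.bac in pl.index and bool(pl.loc[a.bac]["low_support"]):
                low = True
        if low:
            flags.add("low_support")
        per_chrom.setdefault(chrom, []).append(
            {
                "scaffold": sid,
                "orientation": orientation,
                "head": head_ax,
                "tail": tail_ax,
                "flags": flags,
                "mid": (
                    (head_ax if head_ax is not None else tail_ax)
                    if head_ax is None or tail_ax is None
                    else (head_ax + tail_ax) / 2.0
                ),
            }
        )

    chromosomes: dict[object, list[PlacedScaffold]] = {}
    for chrom in sorted(per_chrom, key=str):
        entries = sorted(per_chrom[chrom], key=lambda e: (e["mid"], str(e["scaffold"])))
        for a, b in zip(entries, entries[1:]):
            if a["mid"] == b["mid"]:
                a["flags"].add("order_tie")
                b["flags"].add("order_tie")
                warnings.warn(
                    f"ordering tie between scaffolds {a['scaffold']!r} and "
                    f"{b['scaffold']!r} on chrom {chrom!r}; broken by id"
                )
        chromosomes[chrom] = [
            PlacedScaffold(
                e["scaffold"],
                rank,
                e["orientation"],
                e["head"],
                e["tail"],
                frozenset(e["flags"]),
            )
            for rank, e in enumerate(entries)
        ]
    return Arrangement(chromosomes, issues=issues)


def _side_extension_mb(ps: PlacedScaffold, borders: BorderSet, length_bp: int, side: str) -> float:
    """DNA (Mb) beyond the scaffold's ``side`` ('lo'|'hi') focus, toward that side.

    The lo-side focus is whichever border focus has the lower axis
    coordinate; the DNA beyond it runs from the corresponding anchor center
    to the physical scaffold end it marks.  For single-anchor scaffolds the
    orientation is unknown, so half the scaffold is assumed on each side.
    """
    if borders.single is not None or ps.head_axis_um is None or ps.tail_axis_um is None:
        return length_bp / 2.0 / 1e6
    head_is_lo = ps.head_axis_um <= ps.tail_axis_um
    lo_role = "head" if head_is_lo else "tail"
    role = lo_role if side == "lo" else ("tail" if head_is_lo else "head")
    anchor = getattr(borders, role)
    if anchor is None:
        return length_bp / 2.0 / 1e6
    if role == "head":
        return anchor.center_bp / 1e6
    return (length_bp - anchor.center_bp) / 1e6


def extended_intervals(
    placed: list[PlacedScaffold],
    model: ChromosomeModel,
    scaffold_lengths: Mapping[object, int] | None = None,
    border_bacs: Mapping[object, BorderSet] | None = None,
    densities=None,
) -> list[tuple[object, float, float]]:
    """Axis interval of each scaffold, extended by its overhang DNA in µm.

    Without anchors/densities the raw focus intervals are returned.  The
    overhang Mb is converted to µm with the density of the chromatin class
    at the corresponding focus.
    """
    from .density import um_to_mb  # local import to avoid cycle

    out = []
    for ps in placed:
        lo, hi = ps.lo_um, ps.hi_um
        if lo is None:
            continue
        if scaffold_lengths is not None and border_bacs is not None and densities is not None:
            borders = border_bacs[ps.scaffold]
            length = int(scaffold_lengths[ps.scaffold])
            for side, focus in (("lo", lo), ("hi", hi)):
                ext_mb = _side_extension_mb(ps, borders, length, side)
                cls = model.classify(min(max(focus, 0.0), model.total_length_um))
                dens = um_to_mb(1.0, cls, densities)  # Mb per µm for this class
                ext_um = ext_mb / dens
                if side == "lo":
                    lo = max(0.0, lo - ext_um)
                else:
                    hi = min(model.total_length_um, hi + ext_um)
        out.append((ps.scaffold, lo, hi))
    return out


def locate_kinetochore(
    arrangement: Arrangement,
    models,
    scaffolds: pd.DataFrame | None = None,
    border_bacs: Mapping[object, BorderSet] | None = None,
    densities=None,
) -> dict[object, KinetochoreLocation]:
    """Place each chromosome's kinetochore center in a scaffold or a gap.

    The center is compared against scaffold focus intervals extended by
    their overhang DNA (when anchors and densities are supplied).  Results
    are stored on ``arrangement.kinetochore_location`` and returned.
    """
    by_chrom = models_by_chrom(models)
    lengths = None
    if scaffolds is not None:
        lengths = scaffolds.set_index("scaffold")["length_bp"].to_dict()

    result: dict[object, KinetochoreLocation] = {}
    for chrom, placed in arrangement.chromosomes.items():
        model = by_chrom[chrom]
        center = model.kinetochore_center_um
        intervals = extended_intervals(placed, model, lengths, border_bacs, densities)
        hits = [sid for sid, lo, hi in intervals if lo <= center <= hi]
        if hits:
            result[chrom] = KinetochoreLocation(
                "in_scaffold", scaffold=hits[0], ambiguous=len(hits) > 1
            )
            continue
        left = right = None
        for sid, lo, hi in intervals:
            if hi < center:
                left = sid
            if lo > center and right is None:
                right = sid
        result[chrom] = KinetochoreLocation("in_gap", left=left, right=right)
    arrangement.kinetochore_location = result
    return result


def reverse_axis(arrangement: Arrangement, models) -> Arrangement:
    """Relabel arms (flip the axis): ranks reverse and orientations flip."""
    by_chrom = models_by_chrom(models)
    chroms = {}
    flip = {"forward": "reverse", "reverse": "forward", "unknown": "unknown"}
    for chrom, placed in arrangement.chromosomes.items():
        L = by_chrom[chrom].total_length_um
        n = len(placed)
        chroms[chrom] = [
            replace(
                p,
                rank=n - 1 - p.rank,
                orientation=flip[p.orientation],
                head_axis_um=None if p.head_axis_um is None else L - p.head_axis_um,
                tail_axis_um=None if p.tail_axis_um is None else L - p.tail_axis_um,
            )
            for p in placed
        ]
    return Arrangement(chroms)
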