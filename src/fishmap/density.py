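"""Linear DNA density (Mb per µm of SC) per chromatin class.

A scaffold whose two border BACs have been placed on the axis gives one
density observation: the DNA between the two FISH signals divided by the
micrometers between them.  Because a FISH signal marks the *center* of its
BAC, the DNA between two signals on one scaffold is the distance between
the anchor centers — which equals the scaffold size minus half of each
border BAC for true border BACs, and automatically subtracts all DNA
distal to the signal when a more internal BAC had to be used.

Per class, observations are pooled as total Mb over total µm (µm-weighted)
rather than averaging per-scaffold ratios, so long intervals carry
proportionally more weight and the estimate is scale-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .bac_anchoring import BacAnchor
from .chromosome_model import (
    DEFAULT_DENSITIES,
    ChromatinClass,
    ChromosomeModel,
    models_by_chrom,
)
from .cytomeasure import placement_to_axis

__all__ = [
    "DensityTable",
    "intersignal_dna",
    "estimate_density",
    "um_to_mb",
]


@dataclass
class DensityTable:
    """Mb/µm per chromatin class with the supporting interval observations.

    ``defaults_used`` lists classes for which no observation was available
    and the configured default density was kept.
    """

    mb_per_um: dict[ChromatinClass, float] = field(
        default_factory=lambda: dict(DEFAULT_DENSITIES)
    )
    observations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["scaffold", "chromatin", "intersignal_mb", "intersignal_um"]
        )
    )
    defaults_used: list[ChromatinClass] = field(default_factory=list)
    excluded: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cls, d in self.mb_per_um.items():
            if d <= 0:
                raise ValueError(f"non-positive density for {cls}")

    def __getitem__(self, chromatin: ChromatinClass) -> float:
        return self.mb_per_um[ChromatinClass(chromatin)]

    def to_frame(self) -> pd.DataFrame:
        obs = self.observations
        rows = []
        for cls, d in self.mb_per_um.items():
            sub = obs[obs["chromatin"] == cls]
            rows.append(
                {
                    "chromatin": cls.value,
                    "mb_per_um": d,
                    "n_obs": int(len(sub)),
                    "total_um": float(sub["intersignal_um"].sum()),
                    "default_used": cls in self.defaults_used,
                }
            )
        return pd.DataFrame(rows)


def intersignal_dna(
    scaffold_length_bp: int, left_anchor: BacAnchor, right_anchor: BacAnchor
) -> float:
    """DNA (Mb) between two FISH signals on the same scaffold.

    The signal sits at the BAC center, so the DNA between two signals is
    the distance between anchor centers.  For border BACs this equals the
    scaffold length minus half of each BAC; for internal anchors it
    likewise excludes all DNA distal to each signal.
    """
    if left_anchor.scaffold != right_anchor.scaffold:
        raise ValueError(
            f"anchors on different scaffolds: {left_anchor.scaffold} vs "
            f"{right_anchor.scaffold}"
        )
    if left_anchor.center_bp > right_anchor.center_bp:
        raise ValueError("left anchor center must not exceed right anchor center")
    if not (0 <= left_anchor.center_bp <= scaffold_length_bp):
        raise ValueError("anchor center outside scaffold")
    return (right_anchor.center_bp - left_anchor.center_bp) / 1e6


def _axis_span_class(model: ChromosomeModel, lo: float, hi: float):
    """Chromatin class of [lo, hi] if it lies wholly in one class, else None."""
    classes = {seg.chromatin for seg in model.segments if seg.start_um < hi and seg.end_um > lo}
    if len(classes) == 1:
        return classes.pop()
    return None


def estimate_density(
    placements: pd.DataFrame,
    border_bacs: Mapping[object, "BorderSet"],
    scaffolds: pd.DataFrame,
    models,
    class_filter: Sequence[ChromatinClass] | None = None,
    defaults: Mapping[ChromatinClass, float] | None = None,
) -> DensityTable:
    """Estimate Mb/µm per chromatin class from two-anchor scaffolds.

    For every scaffold with placed head and tail anchors whose axis span
    lies wholly within one chromatin class, record (intersignal Mb,
    intersignal µm) and pool per class as total Mb / total µm.  Scaffolds
    spanning a class boundary are excluded and listed in ``excluded``.
    Classes without observations (or excluded by ``class_filter``) keep the
    default density and are recorded in ``defaults_used``.
    """
    by_chrom = models_by_chrom(models)
    lengths = scaffolds.set_index("scaffold")["length_bp"]
    pl = placements.set_index("probe")

    keep = None if class_filter is None else {ChromatinClass(c) for c in class_filter}
    obs_rows: list[dict] = []
    excluded: list[dict] = []
    for scaffold, borders in border_bacs.items():
        head, tail = borders.head, borders.tail
        if head is None or tail is None or head.bac == tail.bac:
            continue
        if head.bac not in pl.index or tail.bac not in pl.index:
            continue
        p_head, p_tail = pl.loc[head.bac], pl.loc[tail.bac]
        if p_head["chrom"] != p_tail["chrom"]:
            excluded.append({"scaffold": scaffold, "reason": "anchors on two chromosomes"})
            continue
        model = by_chrom[p_head["chrom"]]
        ax_head = placement_to_axis(p_head, model)
        ax_tail = placement_to_axis(p_tail, model)
        lo, hi = sorted((ax_head, ax_tail))
        chromatin = _axis_span_class(model, lo, hi)
        if chromatin is None:
            excluded.append({"scaffold": scaffold, "reason": "spans class boundary"})
            continue
        if keep is not None and chromatin not in keep:
            continue
        left, right = sorted((head, tail), key=lambda a: a.center_bp)
        mb = intersignal_dna(int(lengths.loc[scaffold]), left, right)
        um = hi - lo
        if um <= 0:
            excluded.append({"scaffold": scaffold, "reason": "coincident foci"})
            continue
        obs_rows.append(
            {
                "scaffold": scaffold,
                "chromatin": chromatin,
                "intersignal_mb": mb,
                "intersignal_um": um,
            }
        )

    obs = pd.DataFrame(
        obs_rows, columns=["scaffold", "chromatin", "intersignal_mb", "intersignal_um"]
    )
    densities = dict(DEFAULT_DENSITIES if defaults is None else defaults)
    defaults_used = []
    for cls in ChromatinClass:
        sub = obs[obs["chromatin"] == cls]
        if len(sub):
            densities[cls] = float(
                sub["intersignal_mb"].sum() / sub["intersignal_um"].sum()
            )
        else:
            defaults_used.append(cls)
    return DensityTable(densities, obs, defaults_used, excluded)


def um_to_mb(length_um: float, chromatin, densities) -> float:
    """Convert micrometers of SC to megabases for one chromatin class."""
    if length_um < 0:
        raise ValueError("length must be non-negative")
    cls = ChromatinClass(chromatin)
    table = densities.mb_per_um if isinstance(densities, DensityTable) else densities
    if cls not in table:
        raise KeyError(f"no density configured for class {cls}")
    return length_um * table[cls]
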