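"""Aggregation of per-spread FISH focus measurements into probe placements.

Each BAC probe is measured on many independent SC spreads as a distance
from the kinetochore center along one arm, together with that spread's arm
length.  Because spreads vary in absolute length, measurements are first
normalised to a fraction of arm length, the fractions are averaged, and
only then is the mean fraction rescaled by the chromosome model's mean arm
length to give a position in micrometers.  The per-probe SD is computed in
micrometer space (per-spread fraction times mean arm length), matching the
convention under which a well-measured BAC has an SD of about 0.1 µm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chromosome_model import ChromosomeModel, arm_to_axis, models_by_chrom

__all__ = [
    "OBSERVATION_COLUMNS",
    "PLACEMENT_COLUMNS",
    "average_positions",
    "placement_to_axis",
    "MultiSiteError",
]

#: Schema of the per-spread observation table (one row per spread x probe).
OBSERVATION_COLUMNS = [
    "spread",
    "probe",
    "chrom",
    "arm",
    "distance_um",
    "arm_length_um",
]

#: Schema of the averaged placement table (one row per probe).
PLACEMENT_COLUMNS = [
    "probe",
    "chrom",
    "arm",
    "mean_fraction",
    "position_um",
    "sd_um",
    "n_spreads",
    "low_support",
]


class MultiSiteError(ValueError):
    """A probe was observed on more than one chromosome/arm site."""


@dataclass
class PlacementResult:
    """Averaged placements plus the probes excluded as multi-site."""

    placements: pd.DataFrame
    multi_site: pd.DataFrame  # columns: probe, sites (list of (chrom, arm))

    def __iter__(self):  # allow tuple-unpacking
        return iter((self.placements, self.multi_site))


def _validate_observations(obs: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in OBSERVATION_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    obs = obs.copy()
    if (obs["distance_um"] < 0).any():
        raise ValueError("negative distance_um in observations")
    if (obs["arm_length_um"] <= 0).any():
        raise ValueError("non-positive arm_length_um in observations")
    bad = obs["distance_um"] > obs["arm_length_um"] * (1 + 1e-9)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} observations have distance > arm length"
        )
    return obs


def average_positions(
    observations: pd.DataFrame,
    models,
    min_spreads: int = 10,
    mad_filter: float | None = None,
) -> PlacementResult:
    """Average per-spread measurements into one placement per probe.

    Parameters
    ----------
    observations
        Table with :data:`OBSERVATION_COLUMNS`.
    models
        Chromosome models (mapping or iterable); supplies the mean arm
        length used to rescale fractions.
    min_spreads
        Probes measured on fewer spreads are flagged ``low_support`` but
        kept (downstream stages may still use them).
    mad_filter
        If set, per-probe observations whose fraction deviates from the
        median by more than ``mad_filter`` times the median absolute
        deviation are dropped before averaging.  Off by default: routine
        practice is to average all spreads.

    Returns
    -------
    PlacementResult
        ``placements`` with :data:`PLACEMENT_COLUMNS` (sorted by probe id)
        and ``multi_site`` listing probes observed at more than one
        chromosome/arm site, which are excluded from the placements.
    """
    obs = _validate_observations(observations)
    by_chrom = models_by_chrom(models)

    placements: list[dict] = []
    multi: list[dict] = []
    for probe, grp in obs.groupby("probe", sort=True):
        sites = sorted(set(zip(grp["chrom"], grp["arm"])))
        if len(sites) > 1:
            multi.append({"probe": probe, "sites": sites})
            continue
        chrom, arm = sites[0]
        if chrom not in by_chrom:
            raise KeyError(f"no chromosome model for chrom {chrom!r} (probe {probe})")
        model = by_chrom[chrom]
        mean_arm = model.arm_length_um(arm)
        frac = (grp["distance_um"] / grp["arm_length_um"]).to_numpy(float)
        if mad_filter is not None and len(frac) >= 3:
            med = np.median(frac)
            mad = np.median(np.abs(frac - med))
            if mad > 0:
                frac = frac[np.abs(frac - med) <= mad_filter * mad]
        p = float(np.mean(frac))
        um = frac * mean_arm
        sd_um = float(np.std(um, ddof=1)) if len(um) > 1 else 0.0
        placements.append(
            {
                "probe": probe,
                "chrom": chrom,
                "arm": arm,
                "mean_fraction": p,
                "position_um": p * mean_arm,
                "sd_um": sd_um,
                "n_spreads": int(len(frac)),
                "low_support": len(frac) < min_spreads,
            }
        )

    pl = pd.DataFrame(placements, columns=PLACEMENT_COLUMNS)
    ms = pd.DataFrame(multi, columns=["probe", "sites"])
    return PlacementResult(pl, ms)


def placement_to_axis(placement, model: ChromosomeModel) -> float:
    """Axis position (µm) of an averaged placement.

    ``placement`` is a row (mapping-like) with ``arm`` and ``position_um``.
    """
    return arm_to_axis(placement["arm"], placement["position_um"], model)
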