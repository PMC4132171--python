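"""Cytological coordinate system for pachytene chromosomes (SC axes).

A chromosome is represented by its synaptonemal-complex (SC) axis, a 1-D
coordinate in micrometers running from the short-arm telomere (axis 0)
through the kinetochore center (axis = short-arm length) to the long-arm
telomere (axis = short + long arm length).  The axis is tiled by chromatin
segments (euchromatin, pericentric heterochromatin, the kinetochore itself,
and optionally NOR / chromomere / border segments), each carrying a linear
DNA density so that micrometers of SC can be converted to megabases.

Positions measured on spreads are reported per arm as a distance from the
kinetochore center; :func:`arm_to_axis` and :func:`axis_to_arm` convert
between that convention and the axis coordinate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ChromatinClass",
    "Segment",
    "ChromosomeModel",
    "classify_chromatin",
    "arm_to_axis",
    "axis_to_arm",
    "standard_model",
    "DEFAULT_DENSITIES",
]


class ChromatinClass(str, enum.Enum):
    """Closed set of chromatin classes distinguishable on SC spreads."""

    EUCHROMATIN = "euchromatin"
    HETEROCHROMATIN = "heterochromatin"
    KINETOCHORE = "kinetochore"
    NOR = "NOR"
    CHROMOMERE = "chromomere"
    BORDER = "border"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Default linear DNA densities in Mb per µm of SC, per chromatin class.
#: Euchromatin / heterochromatin / kinetochore values are the tomato
#: SC-spread estimates; NOR, chromomere and border segments are
#: heterochromatin-like and default to the heterochromatin value.
DEFAULT_DENSITIES: dict[ChromatinClass, float] = {
    ChromatinClass.EUCHROMATIN: 1.5,
    ChromatinClass.HETEROCHROMATIN: 8.8,
    ChromatinClass.KINETOCHORE: 3.3,
    ChromatinClass.NOR: 8.8,
    ChromatinClass.CHROMOMERE: 8.8,
    ChromatinClass.BORDER: 8.8,
}


class AxisRangeError(ValueError):
    """An axis or arm position falls outside the chromosome model."""


@dataclass(frozen=True)
class Segment:
    """Half-open axis interval [start_um, end_um) of one chromatin class."""

    start_um: float
    end_um: float
    chromatin: ChromatinClass

    @property
    def length_um(self) -> float:
        return self.end_um - self.start_um

    def __post_init__(self) -> None:
        if not self.end_um > self.start_um:
            raise ValueError(
                f"empty or inverted segment [{self.start_um}, {self.end_um})"
            )


@dataclass
class ChromosomeModel:
    """SC axis model: arm lengths, kinetochore extent and chromatin tiling.

    Parameters
    ----------
    chrom
        Chromosome identifier (1..12 for tomato, any hashable id for
        synthetic chromosomes).
    arm_short_um, arm_long_um
        Mean SC arm lengths in micrometers.  The kinetochore center sits at
        axis position ``arm_short_um``.
    segments
        Ordered chromatin segments tiling ``[0, arm_short_um + arm_long_um]``
        without overlap or holes.  Segment intervals are half-open; a
        position on a boundary belongs to the segment starting there.  The
        final segment is closed at the long-arm telomere so classification
        is total on the axis.
    """

    chrom: object
    arm_short_um: float
    arm_long_um: float
    segments: list[Segment] = field(default_factory=list)

    _TOL = 1e-9

    def __post_init__(self) -> None:
        if self.arm_short_um <= 0 or self.arm_long_um <= 0:
            raise ValueError("arm lengths must be positive")
        if not self.segments:
            raise ValueError("segments must tile the axis")
        self.segments = sorted(self.segments, key=lambda s: s.start_um)
        if abs(self.segments[0].start_um) > self._TOL:
            raise ValueError("first segment must start at axis 0")
        for a, b in zip(self.segments, self.segments[1:]):
            if abs(a.end_um - b.start_um) > self._TOL:
                raise ValueError(
                    f"segments do not tile: gap/overlap at {a.end_um} vs {b.start_um}"
                )
        if abs(self.segments[-1].end_um - self.total_length_um) > 1e-6:
            raise ValueError("segments must end at the long-arm telomere")

    # -- geometry -------------------------------------------------------

    @property
    def total_length_um(self) -> float:
        return self.arm_short_um + self.arm_long_um

    @property
    def kinetochore_center_um(self) -> float:
        return self.arm_short_um

    @property
    def kinetochore_interval_um(self) -> tuple[float, float]:
        """Axis interval of the kinetochore segment (must exist)."""
        for seg in self.segments:
            if seg.chromatin is ChromatinClass.KINETOCHORE:
                return (seg.start_um, seg.end_um)
        raise ValueError(f"model for chrom {self.chrom} has no kinetochore segment")

    def arm_length_um(self, arm: str) -> float:
        if arm == "short":
            return self.arm_short_um
        if arm == "long":
            return self.arm_long_um
        raise ValueError(f"arm must be 'short' or 'long', got {arm!r}")

    # -- classification -------------------------------------------------

    def classify(self, axis_pos_um: float) -> ChromatinClass:
        return classify_chromatin(axis_pos_um, self)

    def dna_content_mb(self, densities: Mapping[ChromatinClass, float]) -> float:
        """Total DNA per chromatid implied by the tiling and a density table."""
        return sum(seg.length_um * densities[seg.chromatin] for seg in self.segments)


def classify_chromatin(axis_pos_um: float, model: ChromosomeModel) -> ChromatinClass:
    """Chromatin class of an axis position.

    Segments are half-open ``[start, end)``, so a boundary position belongs
    to the segment that starts there; the long-arm telomere belongs to the
    last segment.
    """
    if axis_pos_um < -model._TOL or axis_pos_um > model.total_length_um + model._TOL:
        raise AxisRangeError(
            f"axis position {axis_pos_um} outside [0, {model.total_length_um}] "
            f"for chrom {model.chrom}"
        )
    for seg in model.segments:
        if seg.start_um <= axis_pos_um < seg.end_um:
            return seg.chromatin
    return model.segments[-1].chromatin


def arm_to_axis(arm: str, distance_from_kinetochore_um: float, model: ChromosomeModel) -> float:
    """Convert an arm-relative distance (µm from the kinetochore center) to axis µm."""
    arm_len = model.arm_length_um(arm)
    d = distance_from_kinetochore_um
    if d < -model._TOL or d > arm_len + model._TOL:
        raise AxisRangeError(
            f"distance {d} µm exceeds {arm} arm length {arm_len} µm on chrom {model.chrom}"
        )
    d = min(max(d, 0.0), arm_len)
    if arm == "short":
        return model.arm_short_um - d
    return model.arm_short_um + d


def axis_to_arm(axis_pos_um: float, model: ChromosomeModel) -> tuple[str, float]:
    """Inverse of :func:`arm_to_axis`.

    Positions short of the kinetochore center map to the short arm; the
    center itself and everything beyond map to the long arm (distance 0 at
    the center).
    """
    if axis_pos_um < -model._TOL or axis_pos_um > model.total_length_um + model._TOL:
        raise AxisRangeError(
            f"axis position {axis_pos_um} outside model for chrom {model.chrom}"
        )
    if axis_pos_um < model.arm_short_um:
        return ("short", model.arm_short_um - axis_pos_um)
    return ("long", axis_pos_um - model.arm_short_um)


def standard_model(
    chrom: object,
    arm_short_um: float,
    arm_long_um: float,
    het_arm_fraction: float = 0.36,
    kinetochore_width_um: float = 1.0,
) -> ChromosomeModel:
    """Build a model with the canonical pachytene chromatin layout.

    Distal euchromatin on both arms flanks a block of pericentric
    heterochromatin, with the ~1 µm kinetochore centered on the
    euchromatin-free junction of the two arms:

    ``eu | het | kinetochore | het | eu``

    ``het_arm_fraction`` is the fraction of each arm's axis (outside the
    kinetochore half-width) occupied by pericentric heterochromatin; the
    default approximates the tomato situation where most of the genome's
    DNA, though not most of its SC length, lies in heterochromatin.
    """
    if not 0.0 <= het_arm_fraction <= 1.0:
        raise ValueError("het_arm_fraction must be in [0, 1]")
    half_k = kinetochore_width_um / 2.0
    if half_k >= min(arm_short_um, arm_long_um):
        raise ValueError("kinetochore wider than an arm")
    L = arm_short_um + arm_long_um
    het_s = het_arm_fraction * (arm_short_um - half_k)
    het_l = het_arm_fraction * (arm_long_um - half_k)
    k0 = arm_short_um - half_k
    k1 = arm_short_um + half_k
    segments = []
    eu = ChromatinClass.EUCHROMATIN
    het = ChromatinClass.HETEROCHROMATIN
    if k0 - het_s > 1e-12:
        segments.append(Segment(0.0, k0 - het_s, eu))
    if het_s > 1e-12:
        segments.append(Segment(k0 - het_s, k0, het))
    segments.append(Segment(k0, k1, ChromatinClass.KINETOCHORE))
    if het_l > 1e-12:
        segments.append(Segment(k1, k1 + het_l, het))
    if L - (k1 + het_l) > 1e-12:
        segments.append(Segment(k1 + het_l, L, eu))
    return ChromosomeModel(chrom, arm_short_um, arm_long_um, segments)


def iter_models(models: Iterable[ChromosomeModel] | Mapping[object, ChromosomeModel]):
    """Yield models from either a mapping or an iterable (helper)."""
    if isinstance(models, Mapping):
        yield from models.values()
    else:
        yield from models


def models_by_chrom(
    models: Iterable[ChromosomeModel] | Mapping[object, ChromosomeModel],
) -> dict[object, ChromosomeModel]:
    if isinstance(models, Mapping):
        return dict(models)
    return {m.chrom: m for m in models}
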