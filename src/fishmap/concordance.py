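"""Concordance analysis between scaffold arrangements and evidence sources.

Compares two arrangements of the same scaffolds (e.g. linkage-map-based
versus FISH-based pseudomolecules) scaffold by scaffold, checks optical-map
superscaffolds for compatibility with an arrangement, compares gap-size
estimates between evidence sources, and classifies where unassigned
("chromosome 0") probes fall relative to scaffolds and gaps.

Order discordance uses positional-index mismatch: a scaffold is
order-discordant when its rank differs between the two arrangements, so
both members of a swapped pair count.  An LCS-based alternative (scaffolds
outside a longest common subsequence count) is available for sensitivity
analysis.  Orientation discordance requires the orientation to be *known*
in both arrangements; a scaffold with unknown orientation can therefore be
classified ``same`` or ``order_only`` but never ``orientation_only`` or
``both``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .arrangement import Arrangement
from .chromosome_model import models_by_chrom
from .gaps import GapRecord
from .util import percent_of

__all__ = [
    "DiscordanceReport",
    "SuperScaffold",
    "compare_arrangements",
    "check_superscaffold_compatibility",
    "compare_gap_estimates",
    "classify_unassigned",
]

CLASSES = ("same", "order_only", "orientation_only", "both", "unknown")


@dataclass
class DiscordanceReport:
    """Per-scaffold discordance classes plus Mb aggregates."""

    per_scaffold: pd.DataFrame  # chrom, scaffold, class
    counts: dict[str, int]
    concordant_mb: float = 0.0
    discordant_mb: float = 0.0
    unknown_mb: float = 0.0

    @property
    def n_discordant(self) -> int:
        return (
            self.counts.get("order_only", 0)
            + self.counts.get("orientation_only", 0)
            + self.counts.get("both", 0)
        )

    @property
    def assembled_mb(self) -> float:
        return self.concordant_mb + self.discordant_mb + self.unknown_mb

    def fractions(self) -> dict[str, int]:
        total = self.assembled_mb
        if total <= 0:
            return {}
        return {
            "concordant_percent": percent_of(self.concordant_mb, total),
            "discordant_percent": percent_of(self.discordant_mb, total),
        }


def _lcs_same_set(order_a: list, order_b: list) -> set:
    """Scaffolds on a longest common subsequence of the two orders."""
    n, m = len(order_a), len(order_b)
    pos_b = {s: i for i, s in enumerate(order_b)}
    # classic LCS DP over the rank sequence
    seq = [pos_b[s] for s in order_a if s in pos_b]
    L = [[0] * (m + 1) for _ in range(len(seq) + 1)]
    for i in range(len(seq) - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if seq[i] == j:
                L[i][j] = 1 + L[i + 1][j + 1]
            else:
                L[i][j] = max(L[i + 1][j], L[i][j + 1])
    keep, i, j = set(), 0, 0
    order_a_shared = [s for s in order_a if s in pos_b]
    while i < len(seq) and j < m:
        if seq[i] == j:
            keep.add(order_a_shared[i])
            i += 1
            j += 1
        elif L[i + 1][j] >= L[i][j + 1]:
            i += 1
        else:
            j += 1
    return keep


def compare_arrangements(
    a: Arrangement,
    b: Arrangement,
    scaffold_lengths: Mapping[object, int] | pd.DataFrame | None = None,
    order_rule: str = "positional",
) -> DiscordanceReport:
    """Classify per-scaffold discordance between two arrangements.

    Scaffolds present in only one arrangement are classified ``unknown``.
    ``order_rule`` is ``'positional'`` (rank mismatch; default) or
    ``'lcs'`` (scaffolds off a longest common subsequence).
    """
    lengths: Mapping[object, float] = {}
    if scaffold_lengths is not None:
        if hasattr(scaffold_lengths, "set_index"):
            lengths = scaffold_lengths.set_index("scaffold")["length_bp"].to_dict()
        else:
            lengths = dict(scaffold_lengths)

    rows = []
    chroms = sorted(set(a.chromosomes) | set(b.chromosomes), key=str)
    for chrom in chroms:
        pa = {p.scaffold: p for p in a.chromosomes.get(chrom, [])}
        pb = {p.scaffold: p for p in b.chromosomes.get(chrom, [])}
        for sid in sorted(set(pa) | set(pb), key=str):
            if sid not in pa or sid not in pb:
                rows.append({"chrom": chrom, "scaffold": sid, "class": "unknown"})
                continue
            if order_rule == "positional":
                order_diff = pa[sid].rank != pb[sid].rank
            elif order_rule == "lcs":
                keep = _lcs_same_set(
                    [p.scaffold for p in a.chromosomes[chrom]],
                    [p.scaffold for p in b.chromosomes[chrom]],
                )
                order_diff = sid not in keep
            else:
                raise ValueError(f"unknown order_rule {order_rule!r}")
            oa, ob = pa[sid].orientation, pb[sid].orientation
            orient_diff = oa != ob and "unknown" not in (oa, ob)
            cls = {
                (False, False): "same",
                (True, False): "order_only",
                (False, True): "orientation_only",
                (True, True): "both",
            }[(order_diff, orient_diff)]
            rows.append({"chrom": chrom, "scaffold": sid, "class": cls})

    per = pd.DataFrame(rows, columns=["chrom", "scaffold", "class"])
    counts = {c: int((per["class"] == c).sum()) for c in CLASSES}
    conc = disc = unk = 0.0
    for _, row in per.iterrows():
        mb = lengths.get(row["scaffold"], 0) / 1e6
        if row["class"] == "same":
            conc += mb
        elif row["class"] == "unknown":
            unk += mb
        else:
            disc += mb
    return DiscordanceReport(per, counts, conc, disc, unk)


@dataclass(frozen=True)
class SuperScaffold:
    """An ordered, oriented run of scaffolds bridged by optical mapping."""

    id: object
    members: tuple  # ((scaffold, orientation), ...)
    junction_gaps_mb: tuple = ()
    chrom: object = None

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a superscaffold bridges at least two scaffolds")
        ids = [m[0] for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate scaffold within a superscaffold")
        if self.junction_gaps_mb and len(self.junction_gaps_mb) != len(self.members) - 1:
            raise ValueError("need one junction gap per adjacent pair")


def _orientations_match(ss_orient: str, arr_orient: str) -> bool:
    return arr_orient == "unknown" or ss_orient == "unknown" or ss_orient == arr_orient


_FLIP = {"forward": "reverse", "reverse": "forward", "unknown": "unknown"}


def check_superscaffold_compatibility(
    ss: SuperScaffold, arr: Arrangement
) -> tuple[str, dict]:
    """Is a superscaffold's order/orientation consistent with an arrangement?

    Compatible iff its scaffolds occupy consecutive ranks in the same order
    with matching orientations, or its full reversal (order reversed, every
    orientation flipped) does.  Unknown orientations in the arrangement
    match anything.
    """
    chrom = None
    for c, placed in arr.chromosomes.items():
        ids = {p.scaffold for p in placed}
        if all(m[0] in ids for m in ss.members):
            chrom = c
            break
    if chrom is None:
        return "incompatible", {"reason": "scaffolds not all on one chromosome"}
    placed = {p.scaffold: p for p in arr.chromosomes[chrom]}
    ranks = [placed[m[0]].rank for m in ss.members]

    def consecutive(rs):
        return all(b - a == 1 for a, b in zip(rs, rs[1:]))

    if consecutive(ranks):
        ok = all(
            _orientations_match(o, placed[s].orientation) for s, o in ss.members
        )
        if ok:
            return "compatible", {"chrom": chrom, "direction": "forward"}
        return "incompatible", {"chrom": chrom, "reason": "orientation mismatch"}
    rev = list(reversed(ranks))
    if consecutive(rev):
        ok = all(
            _orientations_match(_FLIP[o], placed[s].orientation) for s, o in ss.members
        )
        if ok:
            return "compatible", {"chrom": chrom, "direction": "reversed"}
        return "incompatible", {"chrom": chrom, "reason": "orientation mismatch"}
    return "incompatible", {"chrom": chrom, "reason": "ranks not consecutive", "ranks": ranks}


@dataclass
class GapComparison:
    matched: pd.DataFrame  # chrom, left, right, chromatin, a_mb, b_mb, abs_diff_mb
    unmatched_a: pd.DataFrame
    unmatched_b: pd.DataFrame

    @property
    def min_diff_mb(self) -> float:
        return float(self.matched["abs_diff_mb"].min()) if len(self.matched) else float("nan")

    @property
    def max_diff_mb(self) -> float:
        return float(self.matched["abs_diff_mb"].max()) if len(self.matched) else float("nan")

    def by_class(self) -> pd.DataFrame:
        return (
            self.matched.groupby("chromatin")["abs_diff_mb"]
            .agg(["count", "mean", "max"])
            .reset_index()
        )


def _gap_key(rec: GapRecord):
    return (rec.left_scaffold, rec.right_scaffold)


def compare_gap_estimates(
    gaps_a: Iterable[GapRecord], gaps_b: Iterable[GapRecord]
) -> GapComparison:
    """Absolute differences between two sets of gap estimates.

    Gaps are matched by their (left, right) scaffold pair, in either
    junction direction; unmatched gaps from each side are listed separately.
    """
    a_list = [g for g in gaps_a if not g.unmeasurable]
    b_by_key: dict = {}
    for g in gaps_b:
        if not g.unmeasurable:
            b_by_key[_gap_key(g)] = g
            b_by_key[(_gap_key(g)[1], _gap_key(g)[0])] = g
    rows, used = [], set()
    unmatched_a = []
    for g in a_list:
        other = b_by_key.get(_gap_key(g))
        if other is None:
            unmatched_a.append(g)
            continue
        used.add(_gap_key(other))
        rows.append(
            {
                "chrom": g.chrom,
                "left": g.left_scaffold,
                "right": g.right_scaffold,
                "chromatin": g.chromatin.value,
                "a_mb": g.gap_mb,
                "b_mb": other.gap_mb,
                "abs_diff_mb": abs(g.gap_mb - other.gap_mb),
            }
        )
    from .gaps import gaps_to_frame

    unmatched_b = [g for g in gaps_b if not g.unmeasurable and _gap_key(g) not in used]
    return GapComparison(
        pd.DataFrame(rows, columns=["chrom", "left", "right", "chromatin", "a_mb", "b_mb", "abs_diff_mb"]),
        gaps_to_frame(unmatched_a),
        gaps_to_frame(unmatched_b),
    )


def classify_unassigned(
    placements: pd.DataFrame,
    arrangement: Arrangement,
    models,
    scaffolds: pd.DataFrame | None = None,
    border_bacs=None,
    densities=None,
) -> tuple[pd.DataFrame, dict]:
    """Classify unassigned-probe placements as in-gap, in-scaffold or unlocalized.

    Each probe's axis position is compared against the extended scaffold
    intervals of its chromosome (as for kinetochore location).  Probes
    falling between two scaffolds' extended intervals are ``in_gap``;
    probes distal to the terminal scaffold are ``unlocalized``.  The
    summary reports the in-gap percentage over all single-site probes,
    rounded to the nearest integer.
    """
    from .arrangement import extended_intervals
    from .cytomeasure import placement_to_axis

    by_chrom = models_by_chrom(models)
    lengths = (
        scaffolds.set_index("scaffold")["length_bp"].to_dict()
        if scaffolds is not None
        else None
    )
    rows = []
    for _, p in placements.iterrows():
        chrom = p["chrom"]
        model = by_chrom[chrom]
        axis = placement_to_axis(p, model)
        intervals = extended_intervals(
            arrangement.chromosomes.get(chrom, []), model, lengths, border_bacs, densities
        )
        hit = next((sid for sid, lo, hi in intervals if lo <= axis <= hi), None)
        if hit is not None:
            rows.append(
                {"probe": p["probe"], "chrom": chrom, "location": "in_scaffold",
                 "scaffold": hit, "left": None, "right": None}
            )
            continue
        left = right = None
        for sid, lo, hi in intervals:
            if hi < axis:
                left = sid
            if lo > axis and right is None:
                right = sid
        if left is not None and right is not None:
            rows.append(
                {"probe": p["probe"], "chrom": chrom, "location": "in_gap",
                 "scaffold": None, "left": left, "right": right}
            )
        else:
            rows.append(
                {"probe": p["probe"], "chrom": chrom, "location": "unlocalized",
                 "scaffold": None, "left": left, "right": right}
            )
    table = pd.DataFrame(
        rows, columns=["probe", "chrom", "location", "scaffold", "left", "right"]
    )
    n = len(table)
    n_gap = int((table["location"] == "in_gap").sum()) if n else 0
    summary = {
        "n_single_site": n,
        "n_in_gap": n_gap,
        "n_in_scaffold": int((table["location"] == "in_scaffold").sum()) if n else 0,
        "n_unlocalized": int((table["location"] == "unlocalized").sum()) if n else 0,
        "percent_in_gap": percent_of(n_gap, n) if n else None,
    }
    return table, summary
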