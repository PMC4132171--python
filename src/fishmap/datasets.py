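"""Bundled example data: the tomato SL2.40 linkage-vs-FISH comparison.

The tomato genome's 91 scaffolds were first arranged into 12
pseudomolecules by the EXPEN 2000 linkage map; BAC-FISH on SC spreads then
re-determined order and head-tail orientation chromosome by chromosome.
This module encodes both arrangements: the linkage arrangement is the
identity order 1..N per chromosome (scaffold numbering follows the linkage
map) with nominal forward orientations, and the FISH arrangement applies
the published per-chromosome changes — the scaffolds observed at changed
positions are given changed ranks, orientation flips are applied, and the
small single-BAC scaffolds whose orientation FISH could not determine
(chr1 s7, chr8 s7, chr9 s2) are marked orientation-unknown.

Scaffold ids are ``c<chrom>s<number>`` with numbers from the linkage-based
pseudomolecules.
"""

from __future__ import annotations

from .arrangement import Arrangement

__all__ = ["tomato_linkage_vs_fish", "TOMATO_N_SCAFFOLDS"]

#: scaffolds per tomato chromosome (SL2.40 build)
TOMATO_N_SCAFFOLDS = {1: 9, 2: 7, 3: 13, 4: 6, 5: 3, 6: 8, 7: 4, 8: 9, 9: 10, 10: 6, 11: 6, 12: 10}

# FISH scaffold order per chromosome, in linkage numbering.  Every scaffold
# reported at a changed position has a changed rank; all others keep theirs.
_FISH_ORDER = {
    1: [1, 3, 2, 4, 5, 6, 8, 7, 9],
    2: [2, 1, 4, 3, 6, 5, 7],
    3: [1, 4, 5, 6, 9, 7, 8, 12, 2, 10, 11, 3, 13],
    4: [1, 3, 2, 4, 5, 6],
    5: [1, 2, 3],
    6: [1, 3, 2, 4, 5, 6, 7, 8],
    7: [1, 2, 3, 4],
    8: [1, 2, 7, 3, 4, 5, 6, 8, 9],
    9: [1, 3, 4, 2, 5, 6, 7, 8, 9, 10],
    10: [1, 2, 4, 3, 5, 6],
    11: [1, 3, 4, 2, 5, 6],
    12: [1, 3, 4, 5, 6, 7, 8, 2, 9, 10],
}

# scaffolds whose head-tail orientation differs by FISH
_FLIPPED = {
    1: {2}, 2: {4, 6}, 3: {2, 3}, 4: {2, 3}, 5: {2}, 6: {3, 5},
    7: set(), 8: {3, 4, 5, 6}, 9: {3}, 10: set(), 11: {3}, 12: {7},
}

# single-BAC scaffolds: FISH gives position but not orientation
_ORIENTATION_UNKNOWN = {1: {7}, 8: {7}, 9: {2}}


def _sid(chrom: int, num: int) -> str:
    return f"c{chrom}s{num}"


def tomato_linkage_vs_fish() -> tuple[Arrangement, Arrangement]:
    """The linkage-map-based and FISH-based tomato scaffold arrangements.

    Returns
    -------
    (linkage, fish)
        Two :class:`~fishmap.arrangement.Arrangement` objects over the same
        91 scaffolds.  Comparing them with
        :func:`~fishmap.concordance.compare_arrangements` under the
        positional-index order rule reproduces the published discordance
        tally: 45 scaffolds differ, 28 of them in order only.
    """
    linkage = Arrangement.from_orders(
        {
            chrom: [(_sid(chrom, k), "forward") for k in range(1, n + 1)]
            for chrom, n in TOMATO_N_SCAFFOLDS.items()
        }
    )
    fish_orders = {}
    for chrom, order in _FISH_ORDER.items():
        entries = []
        for num in order:
            if num in _ORIENTATION_UNKNOWN.get(chrom, set()):
                orient = "unknown"
            elif num in _FLIPPED[chrom]:
                orient = "reverse"
            else:
                orient = "forward"
            entries.append((_sid(chrom, num), orient))
        fish_orders[chrom] = entries
    return linkage, Arrangement.from_orders(fish_orders)
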