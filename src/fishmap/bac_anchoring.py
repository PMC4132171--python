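"""Anchoring BAC clones into scaffolds from their end sequences.

Each BAC contributes up to two end reads (T7/SP6 or short sequence tags).
An end read is *anchored* when it has a unique maximal exact match of at
least ``min_match`` bases somewhere in the scaffold set (both strands are
searched).  Two anchored ends of the same BAC on the same scaffold, on
opposite strands and pointing toward each other with a plausible insert
span, define a ``paired_unique`` insert interval; a lone anchored end gives
a ``single_unique`` point at the hit midpoint.  Matching is exact: the end
tags are taken verbatim from the clone library, so mismatch tolerance buys
nothing on curated or simulated input, and a precomputed hit table can be
supplied to bypass sequence search entirely.

Border selection then picks, per scaffold, the reliable anchor closest to
each scaffold end (head = lowest coordinate, tail = highest); scaffolds
below the single-BAC threshold carry one centrally chosen anchor that gives
position but not orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from Bio.Seq import reverse_complement

__all__ = [
    "BacAnchor",
    "BorderSet",
    "AnchorParams",
    "anchor_clone_ends",
    "select_border_bacs",
]

RELIABILITIES = ("paired_unique", "single_unique", "ambiguous", "unmapped")
ROLES = ("head", "tail", "single", "internal", "none")


@dataclass(frozen=True)
class BacAnchor:
    """A BAC's inferred location within one scaffold.

    ``start_bp``/``end_bp`` are the 0-based half-open insert interval for
    paired anchors; for single-end anchors they delimit the end-read hit
    and ``center_bp`` is the hit midpoint.  ``strand`` is '+' when the
    insert runs head-to-tail along the scaffold's forward strand.
    """

    bac: str
    scaffold: object
    start_bp: int
    end_bp: int
    reliability: str
    role: str = "none"
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.reliability not in RELIABILITIES:
            raise ValueError(f"unknown reliability {self.reliability!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.reliability in ("paired_unique", "single_unique"):
            if not 0 <= self.start_bp < self.end_bp:
                raise ValueError(f"invalid interval for {self.bac}")

    @property
    def center_bp(self) -> float:
        return (self.start_bp + self.end_bp) / 2.0

    @property
    def insert_length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def reliable(self) -> bool:
        return self.reliability in ("paired_unique", "single_unique")


@dataclass
class BorderSet:
    """Reliable anchors chosen to mark a scaffold's ends."""

    scaffold: object
    head: BacAnchor | None = None
    tail: BacAnchor | None = None
    internal: tuple[BacAnchor, ...] = ()

    @property
    def single(self) -> BacAnchor | None:
        """The lone anchor of a single-BAC scaffold, if that is the case."""
        if self.head is not None and self.head.role == "single":
            return self.head
        return None

    def anchors(self) -> list[BacAnchor]:
        out = [a for a in (self.head, self.tail) if a is not None]
        if self.head is self.tail and len(out) == 2:
            out = out[:1]
        return out


@dataclass(frozen=True)
class AnchorParams:
    min_match: int = 26
    insert_min_bp: int = 30_000
    insert_max_bp: int = 250_000


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def _end_hits(seq: str, scaffolds: Mapping[object, str], min_match: int):
    """All exact placements of an end read across scaffolds and strands.

    Returns (scaffold, start, end, strand) tuples; strand is the scaffold
    strand the read matches ('+' = read as given, '-' = reverse complement).
    """
    if len(seq) < min_match:
        return []
    seq = seq.upper()
    rc = reverse_complement(seq)
    hits = []
    for sid, ssq in scaffolds.items():
        for strand, query in (("+", seq), ("-", rc)):
            for pos in _find_all(ssq, query):
                hits.append((sid, pos, pos + len(query), strand))
    return hits


def anchor_clone_ends(
    end_seqs: Mapping[str, Sequence[str]] | Iterable[tuple[str, Sequence[str]]],
    scaffolds: Mapping[object, str],
    params: AnchorParams | None = None,
) -> list[BacAnchor]:
    """Anchor BACs into scaffolds by exact search of their end reads.

    Parameters
    ----------
    end_seqs
        Mapping of BAC id to its 1 or 2 end-read sequences.
    scaffolds
        Mapping of scaffold id to (upper-case) sequence.
    params
        Matching parameters (minimum exact-match length, insert bounds).

    Returns
    -------
    list of BacAnchor, one per BAC, sorted by BAC id.  Reliability is
    ``paired_unique`` (both ends unique, same scaffold, opposite strands,
    facing each other, span within insert bounds), ``single_unique``,
    ``ambiguous`` (multiple equal-quality placements or inconsistent
    pairing), or ``unmapped``.
    """
    params = params or AnchorParams()
    if hasattr(end_seqs, "items"):
        items = list(end_seqs.items())
    else:
        items = list(end_seqs)
    seen = set()
    for bac, _ in items:
        if bac in seen:
            raise ValueError(f"duplicate BAC id {bac!r}")
        seen.add(bac)
    scaffolds = {sid: str(s).upper() for sid, s in scaffolds.items()}

    anchors = []
    for bac, seqs in sorted(items):
        seqs = [s for s in seqs if s]
        if not 1 <= len(seqs) <= 2:
            raise ValueError(f"BAC {bac!r} must have 1 or 2 end sequences")
        per_end = [_end_hits(s, scaffolds, params.min_match) for s in seqs]
        unique = [h[0] if len(h) == 1 else None for h in per_end]
        n_mapped = sum(1 for h in per_end if h)
        n_unique = sum(1 for u in unique if u is not None)

        if n_mapped == 0:
            anchors.append(BacAnchor(bac, None, 0, 1, "unmapped"))
            continue
        if len(seqs) == 2 and n_unique == 2:
            (s1, a1, b1, st1), (s2, a2, b2, st2) = unique
            if s1 == s2 and {st1, st2} == {"+", "-"}:
                # head-to-head: the forward-strand read must precede the
                # reverse-strand read so the two point toward each other.
                fwd, rev = ((a1, b1), (a2, b2)) if st1 == "+" else ((a2, b2), (a1, b1))
                span = rev[1] - fwd[0]
                if fwd[0] < rev[0] and params.insert_min_bp <= span <= params.insert_max_bp:
                    anchors.append(
                        BacAnchor(bac, s1, fwd[0], rev[1], "paired_unique")
                    )
                    continue
            anchors.append(BacAnchor(bac, None, 0, 1, "ambiguous"))
            continue
        if n_unique >= 1 and n_mapped == n_unique:
            # one usable unique end (other end absent or unmapped)
            sid, a, b, _ = next(u for u in unique if u is not None)
            anchors.append(BacAnchor(bac, sid, a, b, "single_unique"))
            continue
        anchors.append(BacAnchor(bac, None, 0, 1, "ambiguous"))
    return anchors


def select_border_bacs(
    anchors: Iterable[BacAnchor],
    scaffolds,
    single_bac_threshold_bp: int = 400_000,
) -> tuple[dict[object, BorderSet], list[object]]:
    """Choose head/tail border anchors for every scaffold.

    ``scaffolds`` is a DataFrame with ``scaffold`` and ``length_bp`` columns
    (or a mapping of scaffold id to length).  Among reliable anchors the one
    with the smallest center becomes the head and the largest the tail;
    anchors in between are kept with role ``internal``.  Scaffolds shorter
    than ``single_bac_threshold_bp``, or with a single reliable anchor and
    short length, get one anchor with role ``single`` (position without
    orientation).  A longer scaffold with one anchor keeps it as head with
    the tail missing.  Scaffolds with no reliable anchor are returned in the
    second element and excluded from the border map.
    """
    if hasattr(scaffolds, "set_index"):
        lengths = scaffolds.set_index("scaffold")["length_bp"].to_dict()
    else:
        lengths = dict(scaffolds)

    per_scaffold: dict[object, list[BacAnchor]] = {sid: [] for sid in lengths}
    for a in anchors:
        if a.reliable and a.scaffold in per_scaffold:
            per_scaffold[a.scaffold].append(a)

    borders: dict[object, BorderSet] = {}
    unanchored: list[object] = []
    for sid in lengths:
        alist = sorted(per_scaffold[sid], key=lambda a: (a.center_bp, a.bac))
        if not alist:
            unanchored.append(sid)
            continue
        if lengths[sid] < single_bac_threshold_bp or len(alist) == 1:
            if lengths[sid] < single_bac_threshold_bp:
                # pick the most central anchor as the single marker
                mid = lengths[sid] / 2.0
                best = min(alist, key=lambda a: (abs(a.center_bp - mid), a.bac))
                one = replace(best, role="single")
                borders[sid] = BorderSet(sid, head=one, tail=one)
            else:
                borders[sid] = BorderSet(sid, head=replace(alist[0], role="head"))
            continue
        head = replace(alist[0], role="head")
        tail = replace(alist[-1], role="tail")
        internal = tuple(replace(a, role="internal") for a in alist[1:-1])
        borders[sid] = BorderSet(sid, head=head, tail=tail, internal=internal)
    return borders, unanchored
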