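"""Ground-truth genome and SC-spread measurement simulator.

Generates everything the pipeline consumes, with the statistical structure
of a pachytene BAC-FISH curation study: chromosomes with distal euchromatin
and pericentric heterochromatin tiled at class-specific DNA densities
(1.5 / 8.8 / 3.3 Mb/µm for euchromatin / heterochromatin / kinetochore),
scaffolds partitioning each chromosome's DNA with gaps of 0–3.2 Mb,
~100-kb BAC inserts marking both ends of every scaffold (one central BAC
for scaffolds under 400 kb), per-spread focus measurements with 0.1 µm
noise on at least 10 spreads, a scrambled "linkage-map" arrangement whose
errors concentrate in heterochromatin, and optical-map-style superscaffold
evidence.

All randomness flows from one master seed; each operation draws from its
own substream (``default_rng([seed, op_tag])``) so stages can be re-run
independently and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .arrangement import Arrangement, PlacedScaffold
from .bac_anchoring import BacAnchor, BorderSet
from .chromosome_model import (
    DEFAULT_DENSITIES,
    ChromatinClass,
    ChromosomeModel,
    axis_to_arm,
    standard_model,
)
from .concordance import SuperScaffold
from .cytomeasure import OBSERVATION_COLUMNS

__all__ = [
    "SimConfig",
    "TruthGenome",
    "ScrambleResult",
    "simulate_genome",
    "simulate_spreads",
    "scramble_arrangement",
    "simulate_superscaffolds",
    "simulate_sequences",
]

_SUB_GENOME, _SUB_SPREADS, _SUB_SCRAMBLE, _SUB_SUPER, _SUB_SEQ = range(5)


class ConfigError(ValueError):
    """The simulation configuration is internally infeasible."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults reproduce the conditions of a tomato-scale study: 12
    chromosomes of roughly 90 scaffolds total, 0.1 µm focus noise, 10
    spreads per probe, ~100-kb BAC inserts, gaps up to 3.2 Mb, and scaffold
    scrambling concentrated in heterochromatin.
    """

    seed: int
    n_chromosomes: int = 12
    scaffolds_per_chromosome: int = 8
    arm_short_um: float = 8.0
    arm_long_um: float = 12.0
    arm_jitter_cv: float = 0.15  # chromosome-to-chromosome arm length spread
    het_arm_fraction: float = 0.36
    kinetochore_width_um: float = 1.0
    density_truth: Mapping[ChromatinClass, float] = field(
        default_factory=lambda: dict(DEFAULT_DENSITIES)
    )
    gap_range_mb: tuple[float, float] = (0.0, 3.2)
    min_scaffold_bp: int = 600_000
    small_scaffold_rate: float = 0.3  # per-chromosome chance of one <400 kb scaffold
    single_bac_threshold_bp: int = 400_000
    bac_insert_mean_bp: int = 100_000
    bac_insert_sd_bp: int = 10_000
    bac_insert_bounds_bp: tuple[int, int] = (30_000, 250_000)
    unassigned_per_chromosome: int = 1
    unassigned_in_scaffold_rate: float = 0.0
    # spread measurement
    n_spreads: int = 10
    focus_noise_sd_um: float = 0.1
    arm_length_cv: float = 0.1
    dropout_rate: float = 0.0
    # linkage-style scrambling (order swaps / orientation flips per scaffold)
    scramble_order_rate_eu: float = 0.05
    scramble_order_rate_het: float = 0.5
    scramble_flip_rate_eu: float = 0.03
    scramble_flip_rate_het: float = 0.3
    # superscaffold evidence
    superscaffold_coverage: float = 0.5
    superscaffold_gap_noise_mb: float = 0.1
    # sequence emission (only used by simulate_sequences)
    clone_end_length_bp: int = 200

    def __post_init__(self) -> None:
        for name in (
            "small_scaffold_rate", "unassigned_in_scaffold_rate", "dropout_rate",
            "scramble_order_rate_eu", "scramble_order_rate_het",
            "scramble_flip_rate_eu", "scramble_flip_rate_het",
            "superscaffold_coverage",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_spreads < 1:
            raise ConfigError("n_spreads must be >= 1")
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.gap_range_mb[0] < 0 or self.gap_range_mb[1] < self.gap_range_mb[0]:
            raise ConfigError("invalid gap range")

    @classmethod
    def nano(cls, seed: int, **overrides) -> "SimConfig":
        """Tiny sequence-scale preset (~400 kb chromosomes).

        Used when actual nucleotide sequence must be emitted (BAC-anchoring
        round trips); all bp-scale parameters are shrunk accordingly while
        keeping the class densities and measurement-noise structure.
        """
        defaults = dict(
            n_chromosomes=2,
            scaffolds_per_chromosome=3,
            arm_short_um=0.04,
            arm_long_um=0.06,
            arm_jitter_cv=0.0,
            kinetochore_width_um=0.01,
            gap_range_mb=(0.002, 0.012),
            min_scaffold_bp=60_000,
            small_scaffold_rate=0.0,
            single_bac_threshold_bp=80_000,
            bac_insert_mean_bp=20_000,
            bac_insert_sd_bp=2_000,
            bac_insert_bounds_bp=(5_000, 40_000),
            unassigned_per_chromosome=1,
            clone_end_length_bp=100,
        )
        defaults.update(overrides)
        return cls(seed=seed, **defaults)


def _bp_um_breakpoints(model: ChromosomeModel, densities) -> tuple[np.ndarray, np.ndarray]:
    """Monotone breakpoints (bp, µm) of the piecewise-linear axis/DNA map."""
    um = [0.0]
    bp = [0.0]
    for seg in model.segments:
        um.append(seg.end_um)
        bp.append(bp[-1] + seg.length_um * densities[seg.chromatin] * 1e6)
    return np.array(bp), np.array(um)


@dataclass
class TruthGenome:
    """Simulated ground truth for every pipeline stage.

    Tables
    ------
    scaffolds : DataFrame
        scaffold, chrom, true_rank, start_bp (chromosome coordinate),
        length_bp, orientation.
    gaps : DataFrame
        chrom, left, right, gap_bp (the truth each estimator is judged
        against).
    bacs : DataFrame
        bac, chrom, scaffold (NA for unassigned probes), role
        (head/tail/single/unassigned), start_bp/end_bp (scaffold-local),
        chrom_start_bp/chrom_end_bp, axis_um, arm, distance_um, fraction.
    """

    config: SimConfig
    models: dict[object, ChromosomeModel]
    density_truth: dict[ChromatinClass, float]
    scaffolds: pd.DataFrame
    gaps: pd.DataFrame
    bacs: pd.DataFrame
    dna_content_bp: dict[object, int]

    # -- coordinate maps ------------------------------------------------

    def bp_to_um(self, chrom, bp) -> float:
        b, u = _bp_um_breakpoints(self.models[chrom], self.density_truth)
        return float(np.interp(bp, b, u))

    def um_to_bp(self, chrom, um) -> float:
        b, u = _bp_um_breakpoints(self.models[chrom], self.density_truth)
        return float(np.interp(um, u, b))

    # -- derived pipeline inputs ---------------------------------------

    def scaffold_table(self) -> pd.DataFrame:
        return self.scaffolds[["scaffold", "chrom", "length_bp"]].copy()

    def border_bacs(self) -> dict[object, BorderSet]:
        """Truth border-anchor map (bypasses sequence anchoring)."""
        out: dict[object, BorderSet] = {}
        assigned = self.bacs[self.bacs["role"] != "unassigned"]
        for sid, grp in assigned.groupby("scaffold", sort=True):
            anchors = {
                row["role"]: BacAnchor(
                    row["bac"], sid, int(row["start_bp"]), int(row["end_bp"]),
                    "paired_unique", role=row["role"],
                )
                for _, row in grp.iterrows()
            }
            if "single" in anchors:
                out[sid] = BorderSet(sid, head=anchors["single"], tail=anchors["single"])
            else:
                out[sid] = BorderSet(sid, head=anchors.get("head"), tail=anchors.get("tail"))
        return out

    def arrangement(self) -> Arrangement:
        """The true arrangement, with foci at the true BAC axis positions."""
        chroms: dict[object, list[PlacedScaffold]] = {}
        bacs = self.bacs.set_index("bac")
        borders = self.border_bacs()
        for chrom, grp in self.scaffolds.groupby("chrom", sort=True):
            placed = []
            for _, row in grp.sort_values("true_rank").iterrows():
                b = borders[row["scaffold"]]
                if b.single is not None:
                    ax = float(bacs.loc[b.single.bac, "axis_um"])
                    placed.append(
                        PlacedScaffold(
                            row["scaffold"], int(row["true_rank"]), "unknown",
                            ax, ax, frozenset({"single_anchor"}),
                        )
                    )
                else:
                    head_ax = float(bacs.loc[b.head.bac, "axis_um"])
                    tail_ax = float(bacs.loc[b.tail.bac, "axis_um"])
                    placed.append(
                        PlacedScaffold(
                            row["scaffold"], int(row["true_rank"]),
                            row["orientation"], head_ax, tail_ax,
                        )
                    )
            chroms[chrom] = placed
        return Arrangement(chroms)

    def validate(self) -> None:
        """DNA conservation: scaffolds + gaps tile each chromosome's DNA."""
        for chrom, grp in self.scaffolds.groupby("chrom"):
            total = int(grp["length_bp"].sum())
            total += int(self.gaps.loc[self.gaps["chrom"] == chrom, "gap_bp"].sum())
            if abs(total - self.dna_content_bp[chrom]) > 1:
                raise AssertionError(
                    f"DNA not conserved on chrom {chrom}: {total} vs "
                    f"{self.dna_content_bp[chrom]}"
                )

    def checksum_text(self) -> str:
        """Deterministic text rendering (for reproducibility checks)."""
        parts = [self.scaffolds.to_csv(index=False), self.gaps.to_csv(index=False),
                 self.bacs.to_csv(index=False)]
        for chrom in sorted(self.models, key=str):
            m = self.models[chrom]
            parts.append(
                f"{chrom}\t{m.arm_short_um:.9f}\t{m.arm_long_um:.9f}\t"
                + ";".join(f"{s.start_um:.9f}-{s.end_um:.9f}:{s.chromatin}" for s in m.segments)
            )
        return "\n".join(parts)


def _partition_chromosome(rng: np.random.Generator, cfg: SimConfig, d_bp: int):
    """Split a chromosome's DNA into scaffold lengths and gaps (bp)."""
    n = cfg.scaffolds_per_chromosome
    if n < 1:
        raise ConfigError("need at least one scaffold per chromosome")
    lo, hi = cfg.gap_range_mb
    for _ in range(200):
        gaps = rng.uniform(lo, hi, size=n - 1) * 1e6
        gaps = gaps.astype(np.int64)
        small = None
        if cfg.small_scaffold_rate > 0 and rng.random() < cfg.small_scaffold_rate:
            small = int(rng.integers(150_000, cfg.single_bac_threshold_bp))
        n_big = n - (1 if small is not None else 0)
        remaining = d_bp - int(gaps.sum()) - (small or 0)
        if remaining < n_big * cfg.min_scaffold_bp:
            continue
        shares = rng.dirichlet(np.full(n_big, 3.0))
        big = np.floor(shares * remaining).astype(np.int64)
        big[-1] = remaining - int(big[:-1].sum())
        if (big < cfg.min_scaffold_bp).any():
            continue
        lengths = list(big)
        if small is not None:
            lengths.insert(int(rng.integers(0, n)), small)
        return [int(x) for x in lengths], [int(g) for g in gaps]
    raise ConfigError(
        f"cannot partition {d_bp} bp into {n} scaffolds with gaps in {cfg.gap_range_mb} Mb"
    )


def _draw_insert(rng: np.random.Generator, cfg: SimConfig, max_bp: int) -> int:
    lo, hi = cfg.bac_insert_bounds_bp
    ins = int(np.clip(rng.normal(cfg.bac_insert_mean_bp, cfg.bac_insert_sd_bp), lo, hi))
    return min(ins, max_bp)


def simulate_genome(config: SimConfig) -> TruthGenome:
    """Generate a ground-truth genome (deterministic for a fixed seed)."""
    rng = np.random.default_rng([config.seed, _SUB_GENOME])
    densities = {ChromatinClass(k): float(v) for k, v in config.density_truth.items()}

    models: dict[object, ChromosomeModel] = {}
    scaffold_rows, gap_rows, bac_rows = [], [], []
    dna_content: dict[object, int] = {}
    for c in range(1, config.n_chromosomes + 1):
        jit_s = max(0.3, 1.0 + config.arm_jitter_cv * rng.standard_normal())
        jit_l = max(0.3, 1.0 + config.arm_jitter_cv * rng.standard_normal())
        model = standard_model(
            c,
            config.arm_short_um * jit_s,
            config.arm_long_um * jit_l,
            config.het_arm_fraction,
            config.kinetochore_width_um,
        )
        models[c] = model
        d_bp = int(round(model.dna_content_mb(densities) * 1e6))
        dna_content[c] = d_bp
        lengths, gaps = _partition_chromosome(rng, config, d_bp)

        bp_breaks, um_breaks = _bp_um_breakpoints(model, densities)

        def to_axis(bp: float) -> float:
            return float(np.interp(bp, bp_breaks, um_breaks))

        start = 0
        scaffold_ids = []
        for rank, length in enumerate(lengths):
            sid = f"c{c}s{rank + 1}"
            scaffold_ids.append(sid)
            scaffold_rows.append(
                {
                    "scaffold": sid, "chrom": c, "true_rank": rank,
                    "start_bp": start, "length_bp": length, "orientation": "forward",
                }
            )
            # plant BACs
            def add_bac(name: str, role: str, s_lo: int, s_hi: int) -> None:
                center = start + (s_lo + s_hi) / 2.0
                axis = to_axis(center)
                arm, dist = axis_to_arm(axis, model)
                bac_rows.append(
                    {
                        "bac": name, "chrom": c, "scaffold": sid, "role": role,
                        "start_bp": s_lo, "end_bp": s_hi,
                        "chrom_start_bp": start + s_lo, "chrom_end_bp": start + s_hi,
                        "axis_um": axis, "arm": arm, "distance_um": dist,
                        "fraction": dist / model.arm_length_um(arm),
                    }
                )

            if length < config.single_bac_threshold_bp:
                ins = _draw_insert(rng, config, length)
                if (length - ins) % 2:  # center the insert exactly
                    ins -= 1
                lo = (length - ins) // 2
                add_bac(f"{sid}_S", "single", lo, lo + ins)
            else:
                ins_h = _draw_insert(rng, config, length // 2)
                ins_t = _draw_insert(rng, config, length // 2)
                add_bac(f"{sid}_H", "head", 0, ins_h)
                add_bac(f"{sid}_T", "tail", length - ins_t, length)
            start += length
            if rank < len(gaps):
                gap_rows.append(
                    {
                        "chrom": c, "left": sid, "right": f"c{c}s{rank + 2}",
                        "gap_bp": gaps[rank], "start_bp": start,
                        "end_bp": start + gaps[rank],
                    }
                )
                start += gaps[rank]

        # unassigned ("chromosome 0") probes dropped into gaps
        open_gaps = [g for g in gap_rows if g["chrom"] == c and g["gap_bp"] > 0]
        for k in range(config.unassigned_per_chromosome):
            name = f"c{c}u{k + 1}"
            in_scaffold = (
                config.unassigned_in_scaffold_rate > 0
                and rng.random() < config.unassigned_in_scaffold_rate
            )
            if in_scaffold or not open_gaps:
                row = scaffold_rows[int(rng.integers(len(scaffold_rows) - len(lengths), len(scaffold_rows)))]
                center = row["start_bp"] + rng.uniform(0.2, 0.8) * row["length_bp"]
            else:
                g = open_gaps[int(rng.integers(len(open_gaps)))]
                center = g["start_bp"] + rng.uniform(0.05, 0.95) * g["gap_bp"]
            ins = _draw_insert(rng, config, config.bac_insert_bounds_bp[1])
            axis = to_axis(center)
            arm, dist = axis_to_arm(axis, model)
            bac_rows.append(
                {
                    "bac": name, "chrom": c, "scaffold": None, "role": "unassigned",
                    "start_bp": np.nan, "end_bp": np.nan,
                    "chrom_start_bp": center - ins / 2, "chrom_end_bp": center + ins / 2,
                    "axis_um": axis, "arm": arm, "distance_um": dist,
                    "fraction": dist / model.arm_length_um(arm),
                }
            )

    truth = TruthGenome(
        config=config,
        models=models,
        density_truth=densities,
        scaffolds=pd.DataFrame(scaffold_rows),
        gaps=pd.DataFrame(gap_rows, columns=["chrom", "left", "right", "gap_bp", "start_bp", "end_bp"]),
        bacs=pd.DataFrame(bac_rows),
        dna_content_bp=dna_content,
    )
    truth.validate()
    return truth


def simulate_spreads(truth: TruthGenome, config: SimConfig | None = None) -> pd.DataFrame:
    """Per-spread focus observations for every probe.

    Per spread and chromosome, an arm length is drawn around the model mean
    (multiplicative, CV = ``arm_length_cv``); each probe's observed distance
    is its true arm fraction times that spread's arm length plus Normal
    focus noise (SD ``focus_noise_sd_um``), truncated to the arm.
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, _SUB_SPREADS])
    rows = []
    bacs = truth.bacs.sort_values("bac")
    for s in range(1, config.n_spreads + 1):
        spread_id = f"spread{s:03d}"
        factors = {
            (chrom, arm): max(0.05, 1.0 + config.arm_length_cv * rng.standard_normal())
            for chrom in truth.models
            for arm in ("short", "long")
        }
        for _, b in bacs.iterrows():
            if config.dropout_rate > 0 and rng.random() < config.dropout_rate:
                continue
            model = truth.models[b["chrom"]]
            arm = b["arm"]
            arm_len = model.arm_length_um(arm) * factors[(b["chrom"], arm)]
            obs = b["fraction"] * arm_len
            if config.focus_noise_sd_um > 0:
                obs += config.focus_noise_sd_um * rng.standard_normal()
            obs = min(max(obs, 0.0), arm_len)
            rows.append(
                {
                    "spread": spread_id, "probe": b["bac"], "chrom": b["chrom"],
                    "arm": arm, "distance_um": obs, "arm_length_um": arm_len,
                }
            )
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


@dataclass
class ScrambleResult:
    """A scrambled (linkage-map-style) arrangement plus its change log."""

    arrangement: Arrangement
    changed_order: dict[object, set]
    changed_orientation: dict[object, set]

    def changed(self, chrom) -> set:
        return self.changed_order.get(chrom, set()) | self.changed_orientation.get(chrom, set())


_HET_LIKE = {
    ChromatinClass.HETEROCHROMATIN,
    ChromatinClass.KINETOCHORE,
    ChromatinClass.NOR,
    ChromatinClass.CHROMOMERE,
}


def scramble_arrangement(truth: TruthGenome, config: SimConfig | None = None) -> ScrambleResult:
    """Corrupt the true arrangement the way an unreliable linkage map would.

    Scaffolds are marked for an adjacent transposition and/or an
    orientation flip at class-dependent rates: scaffolds resident in
    heterochromatin-like chromatin (where crossing over, hence linkage
    resolution, is suppressed) are scrambled at the heterochromatin rates.
    The change log records which scaffolds ended up with a different rank
    or orientation than the truth.
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, _SUB_SCRAMBLE])
    true_arr = truth.arrangement()

    chroms: dict[object, list[PlacedScaffold]] = {}
    changed_order: dict[object, set] = {}
    changed_orient: dict[object, set] = {}
    for chrom in sorted(true_arr.chromosomes, key=str):
        placed = true_arr.chromosomes[chrom]
        model = truth.models[chrom]
        order = [p.scaffold for p in placed]
        resident_het = {}
        for p in placed:
            mid = p.midpoint_um if p.midpoint_um is not None else model.kinetochore_center_um
            resident_het[p.scaffold] = model.classify(mid) in _HET_LIKE
        # adjacent transpositions
        for sid in list(order):
            rate = (
                config.scramble_order_rate_het
                if resident_het[sid]
                else config.scramble_order_rate_eu
            )
            if rng.random() < rate and len(order) > 1:
                i = order.index(sid)
                j = i + 1 if (i == 0 or (i < len(order) - 1 and rng.random() < 0.5)) else i - 1
                order[i], order[j] = order[j], order[i]
        # orientation flips (the scrambled map claims an orientation for all)
        orient = {}
        flipped = set()
        for p in placed:
            rate = (
                config.scramble_flip_rate_het
                if resident_het[p.scaffold]
                else config.scramble_flip_rate_eu
            )
            base = p.orientation if p.orientation != "unknown" else "forward"
            if rng.random() < rate:
                orient[p.scaffold] = "reverse" if base == "forward" else "forward"
                flipped.add(p.scaffold)
            else:
                orient[p.scaffold] = base
        chroms[chrom] = [
            PlacedScaffold(sid, rank, orient[sid]) for rank, sid in enumerate(order)
        ]
        true_rank = {p.scaffold: p.rank for p in placed}
        changed_order[chrom] = {sid for rank, sid in enumerate(order) if true_rank[sid] != rank}
        changed_orient[chrom] = flipped
    return ScrambleResult(Arrangement(chroms), changed_order, changed_orient)


def simulate_superscaffolds(
    truth: TruthGenome, config: SimConfig | None = None
) -> list[SuperScaffold]:
    """Optical-map-style evidence: runs of truly adjacent scaffolds.

    Each adjacency is bridged independently with probability
    ``superscaffold_coverage``; maximal runs of bridged adjacencies become
    superscaffolds carrying the true relative order/orientation and noisy
    junction gap estimates (truth gap plus Normal noise, floored at 0).
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, _SUB_SUPER])
    gap_bp = {
        (r["left"], r["right"]): int(r["gap_bp"]) for _, r in truth.gaps.iterrows()
    }
    out: list[SuperScaffold] = []
    counter = 0
    for chrom, grp in truth.scaffolds.groupby("chrom", sort=True):
        ordered = grp.sort_values("true_rank")
        sids = list(ordered["scaffold"])
        orients = dict(zip(ordered["scaffold"], ordered["orientation"]))
        bridged = [rng.random() < config.superscaffold_coverage for _ in sids[:-1]]
        i = 0
        while i < len(bridged):
            if not bridged[i]:
                i += 1
                continue
            j = i
            while j < len(bridged) and bridged[j]:
                j += 1
            members = tuple((sid, orients[sid]) for sid in sids[i : j + 1])
            gaps_mb = []
            for a, b in zip(sids[i : j], sids[i + 1 : j + 1]):
                g = gap_bp[(a, b)] / 1e6
                if config.superscaffold_gap_noise_mb > 0:
                    g += config.superscaffold_gap_noise_mb * rng.standard_normal()
                gaps_mb.append(max(g, 0.0))
            counter += 1
            out.append(
                SuperScaffold(f"ss{counter}", members, tuple(gaps_mb), chrom=chrom)
            )
            i = j + 1
    return out


_BASES = np.array(list("ACGT"))


def simulate_sequences(
    truth: TruthGenome, config: SimConfig | None = None
) -> tuple[dict[object, str], dict[str, list[str]]]:
    """Emit scaffold sequences and clone-end reads (sequence-scale configs only).

    Scaffold sequences are random nucleotides; each BAC's end reads are cut
    verbatim from its insert ends (forward strand at the insert start,
    reverse complement at the insert end, i.e. head-to-head).  Unassigned
    probes get random reads that match no scaffold.  Intended for ``nano``
    scale configurations — emitting megabase chromosomes this way is
    possible but slow.
    """
    from Bio.Seq import reverse_complement

    config = config or truth.config
    rng = np.random.default_rng([config.seed, _SUB_SEQ])
    seqs: dict[object, str] = {}
    for _, row in truth.scaffolds.iterrows():
        seqs[row["scaffold"]] = "".join(
            _BASES[rng.integers(0, 4, size=int(row["length_bp"]))]
        )
    ends: dict[str, list[str]] = {}
    L = config.clone_end_length_bp
    for _, b in truth.bacs.iterrows():
        if b["role"] == "unassigned":
            ends[b["bac"]] = [
                "".join(_BASES[rng.integers(0, 4, size=L)]),
                "".join(_BASES[rng.integers(0, 4, size=L)]),
            ]
            continue
        s = seqs[b["scaffold"]]
        lo, hi = int(b["start_bp"]), int(b["end_bp"])
        if b["role"] == "single":
            ends[b["bac"]] = [s[lo : lo + L]]
        else:
            ends[b["bac"]] = [s[lo : lo + L], reverse_complement(s[hi - L : hi])]
    return seqs, ends
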