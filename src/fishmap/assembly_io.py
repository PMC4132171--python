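"""File formats, configuration and the pipeline driver.

Formats
-------
* AGP 2.0 (1.1 accepted on read) for pseudomolecule builds; coordinates
  are 1-based inclusive as the format requires, while everything internal
  is 0-based half-open.
* BED6 for BAC anchors (0-based half-open; score encodes reliability).
* Versioned TSV schemas for chromosome models, observations, placements,
  arrangements, gap records, density tables and superscaffolds.  Every
  writer puts a ``# fishmap <name> v1`` header comment; readers skip
  comment lines.

The pipeline driver chains anchor -> measure -> density -> arrange ->
gaps -> compare -> build-agp from a single YAML/flat-key configuration and
writes all tables plus a machine-readable JSON summary.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .arrangement import Arrangement, PlacedScaffold, infer_arrangement, locate_kinetochore
from .bac_anchoring import AnchorParams, BacAnchor, anchor_clone_ends, select_border_bacs
from .chromosome_model import ChromatinClass, ChromosomeModel, Segment, models_by_chrom
from .concordance import (
    SuperScaffold,
    check_superscaffold_compatibility,
    classify_unassigned,
    compare_arrangements,
)
from .cytomeasure import average_positions
from .density import DensityTable, estimate_density
from .gaps import GapParams, GapRecord, estimate_all_gaps, gaps_to_frame, total_gap_content
from .util import round_half_up

__all__ = [
    "PseudomoleculeBuild",
    "write_agp",
    "read_agp",
    "run_pipeline",
    "write_models",
    "read_models",
    "write_table",
    "read_table",
    "anchors_to_bed",
    "write_superscaffolds",
    "read_superscaffolds",
]

_ORIENT_TO_AGP = {"forward": "+", "reverse": "-", "unknown": "?"}
_AGP_TO_ORIENT = {"+": "forward", "-": "reverse", "?": "unknown", "0": "unknown", "na": "unknown"}

_BUILD_COLUMNS = [
    "object", "object_beg", "object_end", "part_number", "kind",
    "component", "component_beg", "component_end", "orientation",
    "gap_length", "gap_type", "linkage", "evidence",
]


class AgpError(ValueError):
    """Malformed AGP content."""


@dataclass
class PseudomoleculeBuild:
    """Parsed AGP document: per-object component and gap records."""

    components: pd.DataFrame  # _BUILD_COLUMNS
    version: str = "2.0"

    def objects(self) -> list[str]:
        return list(dict.fromkeys(self.components["object"]))

    def to_arrangement(self) -> Arrangement:
        chroms: dict[object, list[PlacedScaffold]] = {}
        for obj in self.objects():
            sub = self.components[
                (self.components["object"] == obj) & (self.components["kind"] == "W")
            ]
            chroms[obj] = [
                PlacedScaffold(row["component"], rank, _AGP_TO_ORIENT[row["orientation"]])
                for rank, (_, row) in enumerate(sub.iterrows())
            ]
        return Arrangement(chroms)


def write_agp(
    arrangement: Arrangement,
    gap_records: Iterable[GapRecord],
    scaffolds: pd.DataFrame,
    evidence: str = "map",
    min_gap_bp: int = 100,
    densities: DensityTable | None = None,
    object_prefix: str = "chr",
) -> str:
    """Serialize an arrangement and its gap estimates as AGP 2.0 text.

    Gap Mb values are rounded half-up to bp; clamped (0 kb) and sub-minimum
    gaps are written with ``min_gap_bp`` so the build stays valid AGP (the
    true 0-kb calls live in the gap table).  Junctions without a measurable
    gap become U (unknown-size) gap lines.  Scaffold orientation is written
    ``+``/``-``/``?``.
    """
    by_pair = {}
    for g in gap_records:
        by_pair[(g.chrom, g.left_scaffold, g.right_scaffold)] = g
    lengths = scaffolds.set_index("scaffold")["length_bp"].to_dict()

    out = io.StringIO()
    out.write("##agp-version\t2.0\n")
    out.write("# generated by fishmap (FISH-derived joins tagged as 'map' evidence: fish)\n")
    if densities is not None:
        dens = ", ".join(
            f"{cls.value}={mb:.4g}" for cls, mb in sorted(densities.mb_per_um.items(), key=lambda kv: kv[0].value)
        )
        out.write(f"# linear DNA densities (Mb/um): {dens}\n")
    for chrom in sorted(arrangement.chromosomes, key=str):
        obj = f"{object_prefix}{chrom}"
        pos = 1
        part = 1
        placed = arrangement.chromosomes[chrom]
        for i, ps in enumerate(placed):
            if ps.scaffold not in lengths:
                raise AgpError(f"unknown scaffold length for {ps.scaffold!r}")
            length = int(lengths[ps.scaffold])
            out.write(
                "\t".join(
                    [
                        obj, str(pos), str(pos + length - 1), str(part), "W",
                        str(ps.scaffold), "1", str(length), _ORIENT_TO_AGP[ps.orientation],
                    ]
                )
                + "\n"
            )
            pos += length
            part += 1
            if i == len(placed) - 1:
                continue
            g = by_pair.get((chrom, ps.scaffold, placed[i + 1].scaffold))
            if g is None or g.unmeasurable:
                kind, gap_bp = "U", 100
            else:
                kind = "N"
                gap_bp = max(round_half_up(g.gap_mb * 1e6), min_gap_bp)
            out.write(
                "\t".join(
                    [
                        obj, str(pos), str(pos + gap_bp - 1), str(part), kind,
                        str(gap_bp), "scaffold", "yes", evidence,
                    ]
                )
                + "\n"
            )
            pos += gap_bp
            part += 1
    return out.getvalue()


def read_agp(source) -> PseudomoleculeBuild:
    """Parse AGP 1.1 or 2.0 text (path, file object or string)."""
    if isinstance(source, (str, Path)) and "\n" not in str(source) and "\t" not in str(source):
        text = Path(source).read_text()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)

    rows = []
    version = "2.0"
    expected_pos: dict[str, int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            if "agp-version" in line and "1.1" in line:
                version = "1.1"
            continue
        f = line.split("\t")
        if len(f) < 8:
            raise AgpError(f"line {lineno}: expected >=8 tab-separated fields")
        try:
            obj, beg, end, part, kind = f[0], int(f[1]), int(f[2]), int(f[3]), f[4]
        except ValueError as exc:
            raise AgpError(f"line {lineno}: bad coordinates ({exc})") from None
        if beg > end:
            raise AgpError(f"line {lineno}: object_beg > object_end")
        want = expected_pos.get(obj, 1)
        if beg != want:
            raise AgpError(
                f"line {lineno}: non-contiguous coordinates for {obj} (got {beg}, expected {want})"
            )
        expected_pos[obj] = end + 1
        row = dict.fromkeys(_BUILD_COLUMNS)
        row.update(object=obj, object_beg=beg, object_end=end, part_number=part, kind=kind)
        if kind == "W":
            if len(f) < 9:
                raise AgpError(f"line {lineno}: W line needs 9 fields")
            row.update(
                component=f[5], component_beg=int(f[6]), component_end=int(f[7]),
                orientation=f[8],
            )
            if f[8] not in _AGP_TO_ORIENT:
                raise AgpError(f"line {lineno}: bad orientation {f[8]!r}")
            if end - beg != int(f[7]) - int(f[6]):
                raise AgpError(f"line {lineno}: component span != object span")
        elif kind in ("N", "U"):
            gap_len = int(f[5])
            if kind == "N" and gap_len != end - beg + 1:
                raise AgpError(f"line {lineno}: gap length != object span")
            row.update(gap_length=gap_len, gap_type=f[6], linkage=f[7])
            if len(f) >= 9:
                row.update(evidence=f[8])
            else:
                version = "1.1"
        else:
            raise AgpError(f"line {lineno}: unsupported component type {kind!r}")
        rows.append(row)
    return PseudomoleculeBuild(pd.DataFrame(rows, columns=_BUILD_COLUMNS), version)


# ---------------------------------------------------------------------------
# TSV schemas


def write_table(df: pd.DataFrame, path, name: str) -> None:
    """Write a schema-versioned TSV (deterministic byte output)."""
    with open(path, "w") as fh:
        fh.write(f"# fishmap {name} v1\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_models(models, arms_path, segments_path) -> None:
    by_chrom = models_by_chrom(models)
    arms = pd.DataFrame(
        [
            {"chrom": c, "arm_short_um": m.arm_short_um, "arm_long_um": m.arm_long_um}
            for c, m in sorted(by_chrom.items(), key=lambda kv: str(kv[0]))
        ]
    )
    segs = pd.DataFrame(
        [
            {"chrom": c, "start_um": s.start_um, "end_um": s.end_um, "class": s.chromatin.value}
            for c, m in sorted(by_chrom.items(), key=lambda kv: str(kv[0]))
            for s in m.segments
        ]
    )
    write_table(arms, arms_path, "chromosome-models")
    write_table(segs, segments_path, "chromatin-segments")


def read_models(arms_path, segments_path) -> dict[object, ChromosomeModel]:
    arms = read_table(arms_path)
    segs = read_table(segments_path)
    models = {}
    for _, a in arms.iterrows():
        sub = segs[segs["chrom"] == a["chrom"]]
        segments = [
            Segment(r["start_um"], r["end_um"], ChromatinClass(r["class"]))
            for _, r in sub.iterrows()
        ]
        models[a["chrom"]] = ChromosomeModel(
            a["chrom"], a["arm_short_um"], a["arm_long_um"], segments
        )
    return models


_RELIABILITY_SCORE = {"paired_unique": 1000, "single_unique": 500, "ambiguous": 100, "unmapped": 0}


def anchors_to_bed(anchors: Iterable[BacAnchor]) -> str:
    """BED6 rendering of anchors (0-based half-open, scaffold as chrom)."""
    lines = []
    for a in anchors:
        if a.scaffold is None:
            continue
        lines.append(
            "\t".join(
                [
                    str(a.scaffold), str(a.start_bp), str(a.end_bp), a.bac,
                    str(_RELIABILITY_SCORE[a.reliability]), a.strand,
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def anchors_to_frame(anchors: Iterable[BacAnchor]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "bac": a.bac, "scaffold": a.scaffold, "start_bp": a.start_bp,
                "end_bp": a.end_bp, "reliability": a.reliability, "role": a.role,
                "strand": a.strand,
            }
            for a in anchors
        ],
        columns=["bac", "scaffold", "start_bp", "end_bp", "reliability", "role", "strand"],
    )


def write_superscaffolds(sss: Iterable[SuperScaffold], path) -> None:
    rows = []
    for ss in sss:
        for i, (sid, orient) in enumerate(ss.members):
            gap = ss.junction_gaps_mb[i] if i < len(ss.junction_gaps_mb) else ""
            rows.append(
                {
                    "superscaffold": ss.id, "chrom": ss.chrom, "position": i,
                    "scaffold": sid, "orientation": orient, "gap_after_mb": gap,
                }
            )
    write_table(
        pd.DataFrame(rows, columns=["superscaffold", "chrom", "position", "scaffold", "orientation", "gap_after_mb"]),
        path,
        "superscaffolds",
    )


def read_superscaffolds(path) -> list[SuperScaffold]:
    df = read_table(path)
    out = []
    for ssid, grp in df.groupby("superscaffold", sort=True):
        grp = grp.sort_values("position")
        members = tuple(zip(grp["scaffold"], grp["orientation"]))
        gaps = tuple(float(g) for g in grp["gap_after_mb"][:-1] if pd.notna(g))
        chrom = grp["chrom"].iloc[0]
        out.append(SuperScaffold(ssid, members, gaps, chrom=chrom))
    return out


# ---------------------------------------------------------------------------
# Pipeline driver


def _load_config(config) -> dict:
    if isinstance(config, Mapping):
        return dict(config)
    with open(config) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config, outdir) -> dict:
    """Run the full curation pipeline from a configuration.

    Two input modes:

    * ``simulate:`` section — generate a synthetic study (genome, spreads,
      scrambled linkage arrangement, superscaffolds) and curate it.
    * file inputs — ``observations``, ``models_arms``/``models_segments``,
      ``scaffolds`` TSVs, plus either ``anchors`` (precomputed TSV) or
      ``scaffold_fasta``+``clone_end_fasta``; optional ``linkage_agp`` and
      ``superscaffolds`` evidence for concordance checks.

    Writes every stage's table under ``outdir`` plus ``summary.json`` and
    the corrected-pseudomolecule AGP; returns the summary dict.  Outputs
    are byte-deterministic given config (seeded simulation, no other RNG).
    """
    from . import synthetic_data as sd

    cfg = _load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": _jsonable(cfg)}

    linkage_arr = None
    superscaffolds = []
    if "simulate" in cfg:
        sim = sd.SimConfig(**cfg["simulate"])
        truth = sd.simulate_genome(sim)
        observations = sd.simulate_spreads(truth)
        models = truth.models
        scaffolds = truth.scaffold_table()
        border_bacs = truth.border_bacs()
        linkage_arr = sd.scramble_arrangement(truth).arrangement
        superscaffolds = sd.simulate_superscaffolds(truth)
        unassigned_probes = set(truth.bacs.loc[truth.bacs["role"] == "unassigned", "bac"])
        write_models(models, outdir / "models_arms.tsv", outdir / "models_segments.tsv")
        write_table(scaffolds, outdir / "scaffolds.tsv", "scaffolds")
        write_table(observations, outdir / "observations.tsv", "observations")
        summary["simulated"] = {"seed": sim.seed, "n_chromosomes": sim.n_chromosomes}
    else:
        models = read_models(cfg["models_arms"], cfg["models_segments"])
        scaffolds = read_table(cfg["scaffolds"])
        observations = read_table(cfg["observations"])
        if "anchors" in cfg:
            adf = read_table(cfg["anchors"])
            anchors = [
                BacAnchor(r["bac"], r["scaffold"], int(r["start_bp"]), int(r["end_bp"]),
                          r["reliability"], strand=r.get("strand", "+"))
                for _, r in adf.iterrows()
            ]
        else:
            from Bio import SeqIO

            seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(cfg["scaffold_fasta"], "fasta")}
            ends: dict[str, list[str]] = {}
            for rec in SeqIO.parse(cfg["clone_end_fasta"], "fasta"):
                bac = rec.id.rsplit("_", 1)[0]
                ends.setdefault(bac, []).append(str(rec.seq))
            anchors = anchor_clone_ends(ends, seqs, AnchorParams(**cfg.get("anchor_params", {})))
            write_table(anchors_to_frame(anchors), outdir / "anchors.tsv", "anchors")
            (outdir / "anchors.bed").write_text(anchors_to_bed(anchors))
        border_bacs, unanchored = select_border_bacs(
            anchors, scaffolds, cfg.get("single_bac_threshold_bp", 400_000)
        )
        summary["unanchored_scaffolds"] = [str(s) for s in unanchored]
        unassigned_probes = set(cfg.get("unassigned_probes", []))
        if "linkage_agp" in cfg:
            linkage_arr = read_agp(cfg["linkage_agp"]).to_arrangement()
        if "superscaffolds" in cfg:
            superscaffolds = read_superscaffolds(cfg["superscaffolds"])

    # measure
    result = average_positions(
        observations, models, min_spreads=cfg.get("min_spreads", 10)
    )
    placements = result.placements
    write_table(placements, outdir / "placements.tsv", "placements")
    summary["n_probes"] = int(len(placements))
    summary["multi_site_probes"] = [str(p) for p in result.multi_site["probe"]]

    assigned = placements[~placements["probe"].isin(unassigned_probes)]

    # density
    densities = estimate_density(assigned, border_bacs, scaffolds, models)
    write_table(densities.to_frame(), outdir / "density.tsv", "density")
    summary["densities_mb_per_um"] = {
        cls.value: densities.mb_per_um[cls] for cls in ChromatinClass
    }

    # arrange
    arr = infer_arrangement(assigned, border_bacs, scaffolds, models,
                            orientation_margin_um=cfg.get("orientation_margin_um"))
    kin = locate_kinetochore(arr, models, scaffolds, border_bacs, densities)
    write_table(arr.to_frame(), outdir / "arrangement.tsv", "arrangement")
    summary["kinetochore"] = {
        str(c): (loc.kind, str(loc.scaffold) if loc.scaffold is not None else f"{loc.left}|{loc.right}")
        for c, loc in kin.items()
    }

    # gaps
    gap_params = GapParams(**cfg.get("gap_params", {}))
    gap_records = estimate_all_gaps(arr, border_bacs, scaffolds, densities, models, gap_params)
    write_table(gaps_to_frame(gap_records), outdir / "gaps.tsv", "gaps")
    totals = total_gap_content(gap_records, cfg.get("genome_size_mb"))
    summary["gap_totals_mb"] = {cls.value: mb for cls, mb in totals.per_class_mb.items()}
    summary["gap_total_mb"] = totals.total_mb
    summary["gap_genome_percent"] = totals.genome_percent

    # concordance
    if linkage_arr is not None:
        report = compare_arrangements(linkage_arr, arr, scaffolds)
        write_table(report.per_scaffold, outdir / "discordance.tsv", "discordance")
        summary["discordance_counts"] = report.counts
        summary["discordant_mb"] = report.discordant_mb
    if superscaffolds:
        verdicts = {
            str(ss.id): check_superscaffold_compatibility(ss, arr)[0] for ss in superscaffolds
        }
        summary["superscaffold_compatibility"] = verdicts
    if unassigned_probes:
        un = placements[placements["probe"].isin(unassigned_probes)]
        table, un_summary = classify_unassigned(
            un, arr, models, scaffolds, border_bacs, densities
        )
        write_table(table, outdir / "unassigned.tsv", "unassigned")
        summary["unassigned"] = un_summary

    # build
    agp = write_agp(arr, gap_records, scaffolds, densities=densities,
                    min_gap_bp=cfg.get("min_gap_bp", 100))
    (outdir / "pseudomolecules.agp").write_text(agp)

    (outdir / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2, sort_keys=True))
    return summary


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)
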