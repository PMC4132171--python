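import pandas as pd
import pytest

from fishmap import read_agp, write_agp
from fishmap.arrangement import Arrangement, PlacedScaffold
from fishmap.assembly_io import (
    AgpError,
    anchors_to_bed,
    read_models,
    read_superscaffolds,
    read_table,
    run_pipeline,
    write_models,
    write_superscaffolds,
    write_table,
)
from fishmap.bac_anchoring import BacAnchor
from fishmap.chromosome_model import ChromatinClass
from fishmap.concordance import SuperScaffold
from fishmap.gaps import GapRecord


def _scaffolds(lengths):
    return pd.DataFrame(
        [{"scaffold": s, "chrom": "c", "length_bp": n} for s, n in lengths.items()]
    )


def _gap(left, right, mb):
    return GapRecord("c", left, right, 0.5, False, ChromatinClass.EUCHROMATIN,
                     0.0, 0.0, mb, clamped=mb == 0.0)


def test_agp_coordinates():
    arr = Arrangement({"c": [PlacedScaffold("s1", 0, "forward"),
                             PlacedScaffold("s2", 1, "unknown")]})
    text = write_agp(arr, [_gap("s1", "s2", 0.5)], _scaffolds({"s1": 3_000_000, "s2": 2_000_000}))
    lines = [l.split("\t") for l in text.splitlines() if not l.startswith("#")]
    assert lines[0][:5] == ["chrc", "1", "3000000", "1", "W"]
    assert lines[1][:6] == ["chrc", "3000001", "3500000", "2", "N", "500000"]
    assert lines[2][1:3] == ["3500001", "5500000"]
    assert lines[2][8] == "?"  # unknown orientation


def test_agp_round_trip():
    arr = Arrangement({"c": [PlacedScaffold("s1", 0, "forward"),
                             PlacedScaffold("s2", 1, "reverse"),
                             PlacedScaffold("s3", 2, "unknown")]})
    gaps = [_gap("s1", "s2", 1.2345), _gap("s2", "s3", 0.0)]
    sc = _scaffolds({"s1": 3_000_000, "s2": 2_000_000, "s3": 400_000})
    text = write_agp(arr, gaps, sc)
    build = read_agp(text)
    arr2 = build.to_arrangement()
    assert [(p.scaffold, p.orientation) for p in arr2.chromosomes["chrc"]] == [
        ("s1", "forward"), ("s2", "reverse"), ("s3", "unknown")
    ]
    # a second pass preserves the component list
    again = read_agp(write_agp(arr2, [], sc.assign(chrom="chrc"))).components
    assert again.loc[again["kind"] == "W", "component"].tolist() == ["s1", "s2", "s3"]


def test_agp_clamped_gap_gets_minimum_length():
    arr = Arrangement({"c": [PlacedScaffold("s1", 0, "forward"),
                             PlacedScaffold("s2", 1, "forward")]})
    text = write_agp(arr, [_gap("s1", "s2", 0.0)], _scaffolds({"s1": 1_000_000, "s2": 1_000_000}))
    gap_line = [l for l in text.splitlines() if "\tN\t" in l][0].split("\t")
    assert gap_line[5] == "100"


def test_agp_unmeasurable_gap_becomes_U():
    arr = Arrangement({"c": [PlacedScaffold("s1", 0, "forward"),
                             PlacedScaffold("s2", 1, "forward")]})
    text = write_agp(arr, [], _scaffolds({"s1": 1_000_000, "s2": 1_000_000}))
    build = read_agp(text)
    u = build.components[build.components["kind"] == "U"]
    assert len(u) == 1 and int(u.iloc[0]["gap_length"]) == 100


def test_agp_malformed_and_non_monotone():
    with pytest.raises(AgpError, match="line 1"):
        read_agp("chr1\t1\tnope\t1\tW\ts\t1\t10\t+")
    bad = "chr1\t1\t10\t1\tW\ts1\t1\t10\t+\nchr1\t12\t20\t2\tW\ts2\t1\t9\t+"
    with pytest.raises(AgpError, match="non-contiguous"):
        read_agp(bad)


def test_agp_11_dialect_detected():
    text = "chr1\t1\t10\t1\tW\ts1\t1\t10\t+\nchr1\t11\t110\t2\tN\t100\tscaffold\tyes\n" \
           "chr1\t111\t120\t3\tW\ts2\t1\t10\t-\n"
    build = read_agp(text)
    assert build.version == "1.1"
    assert build.to_arrangement().chromosomes["chr1"][1].orientation == "reverse"


def test_models_tsv_round_trip(toy_model, tmp_path):
    write_models([toy_model], tmp_path / "arms.tsv", tmp_path / "segs.tsv")
    models = read_models(tmp_path / "arms.tsv", tmp_path / "segs.tsv")
    m = models["toy"]
    assert m.arm_short_um == toy_model.arm_short_um
    assert [(s.start_um, s.end_um, s.chromatin) for s in m.segments] == [
        (s.start_um, s.end_um, s.chromatin) for s in toy_model.segments
    ]


def test_table_round_trip_and_header(tmp_path):
    df = pd.DataFrame({"a": [1, 2], "b": ["x", "y"]})
    write_table(df, tmp_path / "t.tsv", "demo")
    assert (tmp_path / "t.tsv").read_text().startswith("# fishmap demo v1\n")
    pd.testing.assert_frame_equal(read_table(tmp_path / "t.tsv"), df)


def test_superscaffold_tsv_round_trip(tmp_path):
    ss = [SuperScaffold("ss1", (("a", "forward"), ("b", "reverse")), (0.5,), chrom="c")]
    write_superscaffolds(ss, tmp_path / "ss.tsv")
    back = read_superscaffolds(tmp_path / "ss.tsv")
    assert back[0].members == ss[0].members
    assert back[0].junction_gaps_mb == pytest.approx(ss[0].junction_gaps_mb)


def test_bed_output_zero_based():
    bed = anchors_to_bed([BacAnchor("b1", "s1", 0, 100_000, "paired_unique")])
    assert bed == "s1\t0\t100000\tb1\t1000\t+\n"


def test_run_pipeline_end_to_end_zero_noise(tmp_path):
    cfg = {
        "simulate": dict(seed=7, n_chromosomes=2, scaffolds_per_chromosome=5,
                         focus_noise_sd_um=0.0, arm_length_cv=0.0, n_spreads=10,
                         small_scaffold_rate=0.5),
        "gap_params": {"resolution_threshold_um": 0.0},
        "genome_size_mb": 919.0,
    }
    summary = run_pipeline(cfg, tmp_path / "out")
    # inferred arrangement equals the simulated truth
    from fishmap.synthetic_data import SimConfig, simulate_genome

    truth = simulate_genome(SimConfig(**cfg["simulate"]))
    arr = read_table(tmp_path / "out" / "arrangement.tsv")
    for chrom, grp in truth.scaffolds.groupby("chrom"):
        got = arr[arr["chrom"] == chrom].sort_values("rank")["scaffold"].tolist()
        assert got == grp.sort_values("true_rank")["scaffold"].tolist()
    # gap table matches simulated gaps within 1 kb
    gaps = read_table(tmp_path / "out" / "gaps.tsv").set_index(["left", "right"])
    for _, row in truth.gaps.iterrows():
        est_kb = gaps.loc[(row["left"], row["right"]), "gap_kb"]
        assert est_kb == pytest.approx(row["gap_bp"] / 1000, abs=1.0)
    # all written artifacts exist
    for name in ("placements.tsv", "density.tsv", "gaps.tsv", "arrangement.tsv",
                 "pseudomolecules.agp", "summary.json"):
        assert (tmp_path / "out" / name).exists()
    assert summary["unassigned"]["percent_in_gap"] == 100


def test_run_pipeline_rerun_identical(tmp_path):
    cfg = {"simulate": dict(seed=9, n_chromosomes=1, scaffolds_per_chromosome=4,
                            focus_noise_sd_um=0.05, n_spreads=10)}
    run_pipeline(cfg, tmp_path / "a")
    run_pipeline(cfg, tmp_path / "b")
    for name in ("placements.tsv", "arrangement.tsv", "gaps.tsv", "pseudomolecules.agp"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_run_pipeline_missing_input_clear_error(tmp_path):
    with pytest.raises((FileNotFoundError, KeyError)):
        run_pipeline({"observations": str(tmp_path / "missing.tsv"),
                      "models_arms": str(tmp_path / "none.tsv"),
                      "models_segments": str(tmp_path / "none2.tsv"),
                      "scaffolds": str(tmp_path / "none3.tsv")}, tmp_path / "out")


def test_run_pipeline_file_mode_with_anchor_table(tmp_path):
    """File-input mode: tables written by the simulator feed back in."""
    from fishmap.assembly_io import anchors_to_frame, write_models
    from fishmap.synthetic_data import SimConfig, simulate_genome, simulate_spreads

    sim = SimConfig(seed=21, n_chromosomes=1, scaffolds_per_chromosome=4,
                    focus_noise_sd_um=0.0, arm_length_cv=0.0, n_spreads=10,
                    small_scaffold_rate=0.0)
    truth = simulate_genome(sim)
    d = tmp_path
    write_models(truth.models, d / "arms.tsv", d / "segs.tsv")
    write_table(truth.scaffold_table(), d / "scaffolds.tsv", "scaffolds")
    write_table(simulate_spreads(truth), d / "obs.tsv", "observations")
    anchors = [a for bs in truth.border_bacs().values() for a in bs.anchors()]
    write_table(anchors_to_frame(anchors), d / "anchors.tsv", "anchors")
    summary = run_pipeline(
        {"observations": str(d / "obs.tsv"), "models_arms": str(d / "arms.tsv"),
         "models_segments": str(d / "segs.tsv"), "scaffolds": str(d / "scaffolds.tsv"),
         "anchors": str(d / "anchors.tsv"),
         "gap_params": {"resolution_threshold_um": 0.0}},
        d / "out",
    )
    assert (d / "out" / "pseudomolecules.agp").exists()
    assert summary["unanchored_scaffolds"] == []
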