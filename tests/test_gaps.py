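import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fishmap import (
    ChromatinClass,
    GapParams,
    SimConfig,
    average_positions,
    estimate_density,
    estimate_gap,
    infer_arrangement,
    simulate_genome,
    simulate_spreads,
    total_gap_content,
)
from fishmap.chromosome_model import Segment, ChromosomeModel
from fishmap.gaps import estimate_all_gaps
from tests.conftest import zero_noise_config

EU = ChromatinClass.EUCHROMATIN
HET = ChromatinClass.HETEROCHROMATIN
DENS = {EU: 1.5, HET: 8.8, ChromatinClass.KINETOCHORE: 3.3}


def _uniform_model(cls, length=20.0, arm=10.0):
    kin = ChromatinClass.KINETOCHORE
    return ChromosomeModel(
        "u", arm, arm,
        [Segment(0.0, arm - 0.5, cls), Segment(arm - 0.5, arm + 0.5, kin),
         Segment(arm + 0.5, length, cls)],
    )


def _gap(model, lf, rf, ov_l, ov_r, **kw):
    return estimate_gap(
        chrom="u", left_scaffold="L", right_scaffold="R",
        left_focus_um=lf, right_focus_um=rf,
        overhang_left_mb=ov_l, overhang_right_mb=ov_r,
        model=model, densities=DENS, **kw,
    )


def test_gap_arithmetic_heterochromatin():
    # 0.5 µm at 8.8 Mb/µm minus 0.1 Mb of overhangs = 4.3 Mb
    rec = _gap(_uniform_model(HET), 1.0, 1.5, 0.05, 0.05)
    assert rec.gap_mb == pytest.approx(4.3)
    assert not rec.default_distance_used and not rec.clamped
    assert rec.chromatin is HET


def test_gap_default_distance_for_unresolvable_foci():
    # foci closer than the resolution threshold get the 0.1 µm default
    rec = _gap(_uniform_model(EU), 1.0, 1.05, 0.0, 0.0)
    assert rec.default_distance_used
    assert rec.measured_distance_um == pytest.approx(0.1)
    assert rec.gap_mb == pytest.approx(0.15)


def test_gap_clamped_to_zero():
    # overhang DNA exceeding the inter-focus DNA: 0.1x1.5 - 0.2 -> 0, clamped
    rec = _gap(_uniform_model(EU), 1.0, 1.05, 0.1, 0.1, unresolvable=True)
    assert rec.gap_mb == 0.0
    assert rec.clamped and rec.default_distance_used


def test_gap_piecewise_across_boundary():
    eu, het = EU, HET
    kin = ChromatinClass.KINETOCHORE
    model = ChromosomeModel(
        "m", 5.0, 5.0,
        [Segment(0.0, 2.0, eu), Segment(2.0, 4.5, het), Segment(4.5, 5.5, kin),
         Segment(5.5, 10.0, eu)],
    )
    rec = estimate_gap(
        chrom="m", left_scaffold="L", right_scaffold="R",
        left_focus_um=1.0, right_focus_um=3.0,
        overhang_left_mb=0.0, overhang_right_mb=0.0,
        model=model, densities=DENS,
        params=GapParams(resolution_threshold_um=0.0),
    )
    # 1 µm euchromatin + 1 µm heterochromatin
    assert rec.gap_mb == pytest.approx(1.5 + 8.8)
    # strict single-class mode uses the midpoint class (het at axis 2.0 boundary)
    rec2 = estimate_gap(
        chrom="m", left_scaffold="L", right_scaffold="R",
        left_focus_um=1.0, right_focus_um=3.0,
        overhang_left_mb=0.0, overhang_right_mb=0.0,
        model=model, densities=DENS,
        params=GapParams(resolution_threshold_um=0.0, class_mode="midpoint"),
    )
    assert rec2.gap_mb == pytest.approx(2.0 * 8.8)


@given(
    d=st.floats(0.25, 3.0),
    ov=st.floats(0.0, 5.0),
    extra=st.floats(0.0, 2.0),
)
@settings(max_examples=100, derandomize=True)
def test_clamping_monotone_and_nonnegative(d, ov, extra):
    """gap_mb >= 0 always; increasing overhangs never increases the gap."""
    model = _uniform_model(HET)
    a = _gap(model, 1.0, 1.0 + d, ov, 0.0)
    b = _gap(model, 1.0, 1.0 + d, ov + extra, 0.0)
    assert a.gap_mb >= 0 and b.gap_mb >= 0
    assert b.gap_mb <= a.gap_mb + 1e-12


def _pipeline_gaps(truth, params):
    pl = average_positions(simulate_spreads(truth), truth.models, 10).placements
    borders = truth.border_bacs()
    sc = truth.scaffold_table()
    dens = estimate_density(pl, borders, sc, truth.models)
    arr = infer_arrangement(pl, borders, sc, truth.models)
    return estimate_all_gaps(arr, borders, sc, dens, truth.models, params)


def test_zero_noise_gap_identity(zero_noise_truth):
    """Noise-free estimates reproduce every simulated gap within 1 kb."""
    recs = _pipeline_gaps(zero_noise_truth, GapParams(resolution_threshold_um=0.0))
    truth_gaps = zero_noise_truth.gaps.set_index(["left", "right"])["gap_bp"]
    assert len(recs) == len(truth_gaps)
    for r in recs:
        assert not r.unmeasurable
        expected = truth_gaps.loc[(r.left_scaffold, r.right_scaffold)]
        assert r.gap_mb * 1e6 == pytest.approx(expected, abs=1000)


def test_brute_force_oracle_equivalence(zero_noise_truth):
    """Independent recomputation from true bp coordinates matches
    estimate_gap to 1e-9 Mb at zero noise."""
    truth = zero_noise_truth
    recs = _pipeline_gaps(truth, GapParams(resolution_threshold_um=0.0))
    bacs = truth.bacs
    sc = truth.scaffolds.set_index("scaffold")

    def oracle(left, right):
        # DNA between the two flanking signals, directly in bp space
        tail = bacs[(bacs["scaffold"] == left) & (bacs["role"].isin(["tail", "single"]))]
        head = bacs[(bacs["scaffold"] == right) & (bacs["role"].isin(["head", "single"]))]
        c_l = (tail["chrom_start_bp"].iloc[0] + tail["chrom_end_bp"].iloc[0]) / 2
        c_r = (head["chrom_start_bp"].iloc[0] + head["chrom_end_bp"].iloc[0]) / 2
        between = (c_r - c_l) / 1e6
        ov_l = (sc.loc[left, "start_bp"] + sc.loc[left, "length_bp"] - c_l) / 1e6
        ov_r = (c_r - sc.loc[right, "start_bp"]) / 1e6
        return max(between - ov_l - ov_r, 0.0)

    for r in recs:
        assert r.gap_mb == pytest.approx(oracle(r.left_scaffold, r.right_scaffold), abs=1e-9)


def test_noisy_gap_estimates_unbiased():
    """Mean signed error ~ 0 for gaps at least 0.5 µm wide, over 20 seeds."""
    errors = []
    for seed in range(1, 21):
        cfg = SimConfig(seed=seed, n_chromosomes=2, scaffolds_per_chromosome=6,
                        het_arm_fraction=0.05, gap_range_mb=(1.0, 3.2),
                        focus_noise_sd_um=0.1, arm_length_cv=0.0, n_spreads=15,
                        small_scaffold_rate=0.0)
        truth = simulate_genome(cfg)
        truth_gaps = truth.gaps.set_index(["left", "right"])
        recs = _pipeline_gaps(truth, GapParams())
        for r in recs:
            if r.unmeasurable or r.default_distance_used:
                continue
            row = truth_gaps.loc[(r.left_scaffold, r.right_scaffold)]
            true_um = truth.bp_to_um(r.chrom, row["end_bp"]) - truth.bp_to_um(r.chrom, row["start_bp"])
            if true_um >= 0.5:
                errors.append(r.gap_mb - row["gap_bp"] / 1e6)
    assert len(errors) >= 50
    assert abs(np.mean(errors)) < 0.1


def test_total_gap_content_percent_and_grouping():
    model = _uniform_model(HET)
    recs = [
        _gap(model, 1.0, 1.5, 0.05, 0.05),  # 4.3 Mb het
        _gap(_uniform_model(EU), 1.0, 2.0, 0.0, 0.0),  # 1.5 Mb eu
    ]
    totals = total_gap_content(recs, genome_size_mb=919.0)
    assert totals.per_class_mb[HET] == pytest.approx(4.3)
    assert totals.per_class_mb[EU] == pytest.approx(1.5)
    assert totals.total_mb == pytest.approx(5.8)
    assert totals.genome_percent == 1


def test_total_gap_content_empty():
    totals = total_gap_content([])
    assert totals.total_mb == 0.0 and totals.per_class_mb == {} and totals.n_gaps == 0
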