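import itertools

import pandas as pd
import pytest

from fishmap import (
    SuperScaffold,
    average_positions,
    check_superscaffold_compatibility,
    compare_arrangements,
    compare_gap_estimates,
    estimate_density,
    infer_arrangement,
    scramble_arrangement,
    simulate_genome,
    simulate_spreads,
)
from fishmap.arrangement import Arrangement
from fishmap.concordance import classify_unassigned
from fishmap.gaps import GapRecord
from fishmap.chromosome_model import ChromatinClass
from tests.conftest import zero_noise_config


def _arr(order, orients=None):
    orients = orients or {}
    return Arrangement.from_orders(
        {"c": [(s, orients.get(s, "forward")) for s in order]}
    )


def test_identity_comparison():
    a = _arr(["x", "y", "z"])
    rep = compare_arrangements(a, a, {"x": 1_000_000, "y": 2_000_000, "z": 3_000_000})
    assert rep.counts["same"] == 3 and rep.n_discordant == 0
    assert rep.discordant_mb == 0.0 and rep.concordant_mb == pytest.approx(6.0)


def test_positional_rule_on_all_length3_permutations():
    """Exhaustive oracle: a scaffold is order-discordant iff its positional
    index changed; an adjacent swap marks both members."""
    base = ["x", "y", "z"]
    for perm in itertools.permutations(base):
        rep = compare_arrangements(_arr(base), _arr(list(perm)))
        expected = {s for i, s in enumerate(base) if perm[i] != s}
        got = set(rep.per_scaffold.loc[rep.per_scaffold["class"] == "order_only", "scaffold"])
        assert got == expected
    swap = _arr(["y", "x", "z"])
    rep = compare_arrangements(_arr(base), swap)
    assert rep.counts["order_only"] == 2 and rep.counts["same"] == 1


def test_orientation_classes_and_unknowns():
    a = _arr(["x", "y", "z"])
    b = _arr(["y", "x", "z"], {"x": "reverse", "z": "unknown"})
    rep = compare_arrangements(a, b)
    cls = rep.per_scaffold.set_index("scaffold")["class"]
    assert cls["x"] == "both"
    assert cls["y"] == "order_only"
    assert cls["z"] == "same"  # unknown orientation can never be orientation-discordant


def test_comparison_symmetric():
    a = _arr(["x", "y", "z", "w"], {"y": "reverse"})
    b = _arr(["y", "x", "z", "w"], {"w": "reverse"})
    ra = compare_arrangements(a, b).per_scaffold
    rb = compare_arrangements(b, a).per_scaffold
    pd.testing.assert_frame_equal(ra, rb)


def test_set_differences_reported_as_unknown():
    a = _arr(["x", "y"])
    b = _arr(["x", "y", "z"])
    rep = compare_arrangements(a, b, {"x": 1e6, "y": 1e6, "z": 5e6})
    assert rep.counts["unknown"] == 1
    assert rep.unknown_mb == pytest.approx(5.0)
    assert rep.assembled_mb == pytest.approx(7.0)


def test_duplicate_scaffold_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        Arrangement.from_orders({"c": ["x", "x"]})


def test_discordant_set_matches_scramble_log():
    """Scramble, re-infer from zero-noise spreads, compare: the discordant
    set equals the scramble change log exactly."""
    cfg = zero_noise_config(seed=17, small_scaffold_rate=0.0,
                            scramble_order_rate_het=0.6, scramble_order_rate_eu=0.2,
                            scramble_flip_rate_het=0.4, scramble_flip_rate_eu=0.1)
    truth = simulate_genome(cfg)
    pl = average_positions(simulate_spreads(truth), truth.models, 10).placements
    fish = infer_arrangement(pl, truth.border_bacs(), truth.scaffold_table(), truth.models)
    res = scramble_arrangement(truth)
    rep = compare_arrangements(res.arrangement, fish)
    per = rep.per_scaffold
    discordant = set(per.loc[per["class"] != "same", "scaffold"])
    expected = set().union(*(res.changed(c) for c in truth.models))
    assert discordant == expected


def test_superscaffold_run_copied_from_arrangement():
    arr = _arr(["a", "b", "c", "d"], {"b": "reverse"})
    ss = SuperScaffold("ss1", (("b", "reverse"), ("c", "forward")))
    verdict, detail = check_superscaffold_compatibility(ss, arr)
    assert verdict == "compatible" and detail["direction"] == "forward"


def test_superscaffold_reversal_symmetry():
    arr = _arr(["a", "b", "c", "d"], {"b": "reverse"})
    ss = SuperScaffold("ss1", (("c", "reverse"), ("b", "forward")))  # reversed + flipped
    verdict, detail = check_superscaffold_compatibility(ss, arr)
    assert verdict == "compatible" and detail["direction"] == "reversed"


def test_superscaffold_order_swap_incompatible():
    arr = _arr(["a", "b", "c", "d"])
    ss = SuperScaffold("ss1", (("c", "forward"), ("b", "forward"), ("d", "forward")))
    verdict, _ = check_superscaffold_compatibility(ss, arr)
    assert verdict == "incompatible"


def test_superscaffold_unknown_orientation_matches_anything():
    arr = _arr(["a", "b", "c"], {"b": "unknown"})
    ss = SuperScaffold("ss1", (("a", "forward"), ("b", "reverse")))
    assert check_superscaffold_compatibility(ss, arr)[0] == "compatible"


def _gap_rec(left, right, mb, cls=ChromatinClass.EUCHROMATIN):
    return GapRecord("c", left, right, 0.5, False, cls, 0.0, 0.0, mb, False)


def test_compare_gap_estimates_identity_and_offset():
    a = [_gap_rec("x", "y", 1.0), _gap_rec("y", "z", 2.0)]
    cmp0 = compare_gap_estimates(a, a)
    assert (cmp0.matched["abs_diff_mb"] == 0).all()
    b = [_gap_rec("x", "y", 1.2), _gap_rec("y", "z", 2.0)]
    cmp1 = compare_gap_estimates(a, b)
    assert cmp1.max_diff_mb == pytest.approx(0.2)
    assert cmp1.min_diff_mb == pytest.approx(0.0)


def test_compare_gap_estimates_unmatched_listed():
    a = [_gap_rec("x", "y", 1.0)]
    b = [_gap_rec("p", "q", 1.0)]
    cmp0 = compare_gap_estimates(a, b)
    assert len(cmp0.matched) == 0
    assert len(cmp0.unmatched_a) == 1 and len(cmp0.unmatched_b) == 1


def test_fish_vs_superscaffold_gap_differences_centered():
    """Synthetic FISH and superscaffold gap estimates agree on average."""
    import numpy as np

    from fishmap import GapParams
    from fishmap.gaps import estimate_all_gaps
    from fishmap.synthetic_data import simulate_superscaffolds

    diffs = []
    for seed in range(1, 11):
        cfg = zero_noise_config(seed=seed, small_scaffold_rate=0.0,
                                superscaffold_coverage=1.0,
                                superscaffold_gap_noise_mb=0.2)
        truth = simulate_genome(cfg)
        pl = average_positions(simulate_spreads(truth), truth.models, 10).placements
        borders, sc = truth.border_bacs(), truth.scaffold_table()
        dens = estimate_density(pl, borders, sc, truth.models)
        arr = infer_arrangement(pl, borders, sc, truth.models)
        fish_gaps = estimate_all_gaps(arr, borders, sc, dens, truth.models,
                                      GapParams(resolution_threshold_um=0.0))
        ss_gaps = []
        for ss in simulate_superscaffolds(truth):
            members = [m[0] for m in ss.members]
            for (l, r), mb in zip(zip(members, members[1:]), ss.junction_gaps_mb):
                ss_gaps.append(_gap_rec(l, r, mb))
        cmp0 = compare_gap_estimates(fish_gaps, ss_gaps)
        diffs.extend(cmp0.matched["a_mb"] - cmp0.matched["b_mb"])
    assert len(diffs) >= 30
    assert abs(np.mean(diffs)) < 0.1


def test_classify_unassigned_gap_and_scaffold(zero_noise_truth):
    truth = zero_noise_truth
    pl = average_positions(simulate_spreads(truth), truth.models, 10).placements
    borders, sc = truth.border_bacs(), truth.scaffold_table()
    dens = estimate_density(pl, borders, sc, truth.models)
    arr = infer_arrangement(pl[~pl["probe"].str.contains("u")], borders, sc, truth.models)
    unassigned = pl[pl["probe"].str.contains("u")]
    table, summary = classify_unassigned(unassigned, arr, truth.models, sc, borders, dens)
    # the generator dropped every unassigned probe into a gap
    truth_unassigned = truth.bacs[truth.bacs["role"] == "unassigned"]
    assert summary["n_single_site"] == len(truth_unassigned)
    assert summary["n_in_gap"] == len(truth_unassigned)
    assert summary["percent_in_gap"] == 100
    # cross-check the flanking scaffolds against the simulated gap intervals
    gaps = truth.gaps
    for _, row in table.iterrows():
        center = (truth_unassigned.set_index("bac").loc[row["probe"], "chrom_start_bp"]
                  + truth_unassigned.set_index("bac").loc[row["probe"], "chrom_end_bp"]) / 2
        g = gaps[(gaps["chrom"] == row["chrom"]) & (gaps["start_bp"] <= center) & (center < gaps["end_bp"])]
        assert row["left"] == g.iloc[0]["left"] and row["right"] == g.iloc[0]["right"]


def test_classify_unassigned_in_scaffold(toy_model):
    from fishmap.arrangement import PlacedScaffold

    arr = Arrangement({"toy": [PlacedScaffold("a", 0, "forward", 1.0, 3.0),
                               PlacedScaffold("b", 1, "forward", 7.0, 9.0)]})
    pl = pd.DataFrame([
        {"probe": "u1", "chrom": "toy", "arm": "short", "mean_fraction": 0.6,
         "position_um": 3.0, "sd_um": 0.0, "n_spreads": 10, "low_support": False},  # axis 2.0 -> in a
        {"probe": "u2", "chrom": "toy", "arm": "short", "mean_fraction": 0.0,
         "position_um": 0.0, "sd_um": 0.0, "n_spreads": 10, "low_support": False},  # axis 5.0 -> gap
    ])
    table, summary = classify_unassigned(pl, arr, [toy_model])
    by_probe = table.set_index("probe")
    assert by_probe.loc["u1", "location"] == "in_scaffold" and by_probe.loc["u1", "scaffold"] == "a"
    assert by_probe.loc["u2", "location"] == "in_gap"
    assert summary["percent_in_gap"] == 50
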