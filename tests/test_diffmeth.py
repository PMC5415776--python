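import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methpanel import diffmeth, synthetic_data as sd
from methpanel.data_model import DegenerateInputError, ParameterError


def _textbook_t(diffs):
    """Independent oracle: plain-Python textbook formula."""
    n = len(diffs)
    mean = sum(diffs) / n
    var = sum((d - mean) ** 2 for d in diffs) / (n - 1)
    t = mean / math.sqrt(var / n)
    p = 2 * stats.t.sf(abs(t), n - 1)
    return t, n - 1, p


class TestPairedTTest:
    def test_hand_computed_example(self):
        t, df, p = diffmeth.paired_t_test([0.2, 0.1, 0.3, 0.2])
        assert t == pytest.approx(4.898979, abs=1e-5)
        assert df == 3

    def test_constant_differences_degenerate(self):
        with pytest.raises(DegenerateInputError):
            diffmeth.paired_t_test([1.0, 1.0, 1.0])

    def test_too_few_values(self):
        with pytest.raises(DegenerateInputError):
            diffmeth.paired_t_test([0.4])

    def test_antisymmetry(self, rng):
        d = rng.normal(0.1, 0.3, 8)
        t1, _, p1 = diffmeth.paired_t_test(d)
        t2, _, p2 = diffmeth.paired_t_test(-d)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_matches_textbook_oracle(self, rng):
        for _ in range(25):
            d = rng.normal(0, 1, rng.integers(3, 20))
            if np.std(d, ddof=1) == 0:
                continue
            got = diffmeth.paired_t_test(d)
            want = _textbook_t(list(d))
            assert got[0] == pytest.approx(want[0], abs=1e-10)
            assert got[2] == pytest.approx(want[2], abs=1e-10)

    def test_matches_scipy_ttest_rel(self, rng):
        a = rng.random(12)
        b = rng.random(12)
        t, _, p = diffmeth.paired_t_test(a - b)
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestBonferroni:
    def test_simple(self):
        assert diffmeth.bonferroni_adjust(0.01, 5) == pytest.approx(0.05)

    def test_cap_at_one(self):
        assert diffmeth.bonferroni_adjust(0.5, 10) == 1.0

    def test_inverse_of_table_scale(self):
        # adjusted value of 2.32e-4 over 473864 tests implies this raw p
        raw = 2.32e-4 / 473864
        assert diffmeth.bonferroni_adjust(raw, 473864) == pytest.approx(2.32e-4)

    def test_bad_inputs(self):
        with pytest.raises(ParameterError):
            diffmeth.bonferroni_adjust(1.5, 10)
        with pytest.raises(ParameterError):
            diffmeth.bonferroni_adjust(0.5, 0)


class TestDeltaBeta:
    @pytest.mark.parametrize(
        "ab,om,expected",
        [(0.53, 0.96, -0.43), (0.45, 0.04, 0.41), (0.3, 0.3, 0.0)],
    )
    def test_values(self, ab, om, expected):
        assert diffmeth.delta_beta(ab, om) == pytest.approx(expected)

    def test_antisymmetric_under_class_swap(self, rng):
        a, b = rng.random(2)
        assert diffmeth.delta_beta(a, b) == pytest.approx(-diffmeth.delta_beta(b, a))


@pytest.fixture(scope="module")
def planted_sim():
    """50 planted delta=0.4 probes over 5000 nulls, n = 15 pairs."""
    cfg = sd.SimConfig(
        n_individuals=15, n_probes=5050, n_discriminating=50,
        delta_levels=(0.4,), precision=200.0, individual_sd=0.2, seed=23,
    )
    return sd.simulate_cohort(cfg)


class TestSignificantSites:
    def test_all_insignificant_gives_empty(self):
        records = pd.DataFrame(
            {"probe_id": ["a", "b"], "p_adjusted": [1.0, 1.0],
             "delta_beta": [0.1, 0.2]}
        )
        assert diffmeth.significant_sites(records).empty

    def test_recovery_with_no_false_positives(self, planted_sim):
        cohort = planted_sim
        records = diffmeth.diffmeth_table(cohort.beta, cohort.sheet, "before")
        sig = diffmeth.significant_sites(records, alpha_adjusted=1e-7)
        planted = set(cohort.truth.loc[cohort.truth["discriminating"], "probe_id"])
        found = set(sig["probe_id"])
        assert found == planted  # all 50 recovered, zero false positives

    def test_injected_marker_ranks_first_by_delta(self, planted_sim):
        cohort = planted_sim
        marker = cohort.truth.loc[~cohort.truth["discriminating"], "probe_id"].iloc[0]
        beta = sd.inject_perfect_marker(
            cohort.beta, cohort.sheet, marker, low=0.05, high=0.95, rng=3
        )
        records = diffmeth.diffmeth_table(beta, cohort.sheet, "before")
        sig = diffmeth.significant_sites(records, alpha_adjusted=1e-7)
        top = sig.loc[sig["rank_delta"] == 1, "probe_id"].iloc[0]
        assert top == marker

    def test_rankings_are_permutations(self, planted_sim):
        records = diffmeth.diffmeth_table(planted_sim.beta, planted_sim.sheet, "before")
        sig = diffmeth.significant_sites(records, alpha_adjusted=1e-7)
        k = len(sig)
        assert sorted(sig["rank_p"]) == list(range(1, k + 1))
        assert sorted(sig["rank_delta"]) == list(range(1, k + 1))


class TestBinByDelta:
    def test_worked_example(self):
        records = pd.DataFrame({"delta_beta": [0.06, -0.12, 0.3]})
        bins = diffmeth.bin_by_delta(records).set_index("threshold")
        assert (bins.loc[0.05, ["n_positive", "n_negative"]] == [2, 1]).all()
        assert (bins.loc[0.10, ["n_positive", "n_negative"]] == [1, 1]).all()
        assert (bins.loc[0.20, ["n_positive", "n_negative"]] == [1, 0]).all()
        assert (bins.loc[0.50, ["n_positive", "n_negative"]] == [0, 0]).all()

    def test_empty_input(self):
        bins = diffmeth.bin_by_delta(pd.DataFrame({"delta_beta": []}))
        assert (bins[["n_positive", "n_negative", "n_total"]] == 0).all().all()

    def test_counts_nested_across_thresholds(self, rng):
        records = pd.DataFrame({"delta_beta": rng.uniform(-1, 1, 200)})
        bins = diffmeth.bin_by_delta(records)
        for col in ("n_positive", "n_negative", "n_total"):
            assert (np.diff(bins[col]) <= 0).all()
        at5 = bins.set_index("threshold").loc[0.05]
        assert at5["n_positive"] + at5["n_negative"] <= len(records)


class TestOverlapTimepoints:
    def test_disjoint_lists_empty(self):
        before = pd.DataFrame({"probe_id": ["a"], "delta_beta": [0.2]})
        after = pd.DataFrame({"probe_id": ["b"], "delta_beta": [0.2]})
        assert diffmeth.overlap_timepoints(before, after).empty

    def test_widened_probe_flagged(self):
        before = pd.DataFrame({"probe_id": ["cg1"], "delta_beta": [-0.43]})
        after = pd.DataFrame({"probe_id": ["cg1"], "delta_beta": [-0.64]})
        overlap = diffmeth.overlap_timepoints(before, after, widen_min=0.05)
        assert overlap.loc[0, "widened"]
        assert overlap.loc[0, "widening"] == pytest.approx(0.21)

    def test_flagged_subset_of_overlap(self, rng):
        probes = [f"cg{i}" for i in range(50)]
        before = pd.DataFrame({"probe_id": probes,
                               "delta_beta": rng.uniform(-0.5, 0.5, 50)})
        after = pd.DataFrame({"probe_id": probes[20:],
                              "delta_beta": rng.uniform(-0.5, 0.5, 30)})
        overlap = diffmeth.overlap_timepoints(before, after)
        assert overlap["widened"].sum() <= len(overlap) == 30
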