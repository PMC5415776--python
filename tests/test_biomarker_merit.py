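from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methpanel import biomarker_merit as bm
from methpanel.data_model import DegenerateInputError


def brute_force_wilcoxon(diffs):
    """Independent oracle: enumerate all 2^n sign assignments."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    if n == 0:
        return 1.0
    # midranks of |d|
    abs_sorted = sorted(abs(x) for x in d)
    ranks = []
    for x in d:
        same = [i for i, v in enumerate(abs_sorted) if v == abs(x)]
        ranks.append(sum(i + 1 for i in same) / len(same))
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    le = ge = 0
    for signs in product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    total = 2**n
    return min(1.0, 2.0 * min(le / total, ge / total))


class TestMeritScore:
    def test_identical_constant_classes(self):
        assert bm.merit_score([0.4, 0.4, 0.4], [0.4, 0.4, 0.4]) == pytest.approx(0.0)

    def test_hand_computed(self):
        # medians 0.2 / 0.8, each sample SD exactly 0.1
        score = bm.merit_score([0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
        assert score == pytest.approx(0.4)

    def test_symmetry(self, rng):
        a, b = rng.random(5), rng.random(7)
        assert bm.merit_score(a, b) == pytest.approx(bm.merit_score(b, a))

    def test_degenerate_class(self):
        with pytest.raises(DegenerateInputError):
            bm.merit_score([0.5], [0.1, 0.2])

    @given(
        st.lists(st.floats(0, 1), min_size=3, max_size=8),
        st.lists(st.floats(0, 1), min_size=3, max_size=8),
        st.floats(-5, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_translation_invariance(self, a, b, c):
        base = bm.merit_score(a, b)
        shifted = bm.merit_score([x + c for x in a], [x + c for x in b])
        assert shifted == pytest.approx(base, abs=1e-8)

    @given(
        st.lists(st.floats(0, 1), min_size=3, max_size=8),
        st.lists(st.floats(0, 1), min_size=3, max_size=8),
        st.floats(0.01, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_positive_scaling(self, a, b, c):
        base = bm.merit_score(a, b)
        scaled = bm.merit_score([x * c for x in a], [x * c for x in b])
        assert scaled == pytest.approx(c * base, abs=max(1e-8, 1e-8 * c))

    def test_positive_when_supports_well_separated(self, rng):
        a = rng.uniform(0.1, 0.2, 10)
        b = rng.uniform(0.7, 0.8, 10)
        assert bm.merit_score(a, b) > 0


class TestWilcoxonSignedRank:
    def test_unanimous_n15(self):
        p = bm.wilcoxon_signed_rank(np.full(15, 0.1))
        assert p == pytest.approx(2.0 * 2.0**-15)
        assert p == pytest.approx(6.10e-5, abs=1e-7)

    def test_all_zero_differences(self):
        assert bm.wilcoxon_signed_rank([0.0, 0.0, 0.0]) == 1.0

    def test_empty_raises(self):
        with pytest.raises(DegenerateInputError):
            bm.wilcoxon_signed_rank([])

    def test_unanimous_n5_floor(self):
        # smallest attainable p at n=5 is 2/32 -- cannot pass p < 0.001
        assert bm.wilcoxon_signed_rank([1, 2, 3, 4, 5]) == pytest.approx(0.0625)

    def test_floor_unattainable_below_n11(self):
        for n in range(1, 11):
            assert bm.wilcoxon_signed_rank(np.arange(1, n + 1)) > 0.001
        assert bm.wilcoxon_signed_rank(np.arange(1, 16)) < 0.001

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 13))
            d = rng.normal(0, 1, n)
            if rng.random() < 0.4:  # force ties and zeros sometimes
                d = np.round(d, 1)
            got = bm.wilcoxon_signed_rank(d)
            want = brute_force_wilcoxon(list(d))
            assert got == pytest.approx(want, abs=1e-12)

    def test_normal_approximation_close_to_exact(self, rng):
        # compare both code paths on the same n=24 data
        d = rng.normal(0.2, 1.0, 24)
        exact = bm.wilcoxon_signed_rank(d, exact_max_n=25)
        approx = bm.wilcoxon_signed_rank(d, exact_max_n=10)
        assert approx == pytest.approx(exact, abs=0.02)


class TestCandidateFilter:
    def test_perfect_marker_ranks_first(self, marker_cohort):
        beta, sheet, marker = marker_cohort
        table = bm.candidate_filter(beta, sheet, "after")
        assert table.iloc[0]["probe_id"] == marker
        assert (table["merit"] > 0).all()
        assert (table["wilcoxon_p"] < 0.001).all()
        assert sorted(table["rank"]) == list(range(1, len(table) + 1))

    def test_zero_threshold_gives_empty(self, cohort):
        table = bm.candidate_filter(cohort.beta, cohort.sheet, "after", p_threshold=0.0)
        assert table.empty

    def test_sample_permutation_invariance(self, cohort):
        table = bm.candidate_filter(cohort.beta, cohort.sheet, "before")
        shuffled = cohort.beta.data.sample(frac=1.0, axis=1, random_state=1)
        from methpanel.data_model import BetaMatrix

        table2 = bm.candidate_filter(BetaMatrix(shuffled), cohort.sheet, "before")
        assert table.equals(table2)

    def test_matches_per_probe_brute_force(self, rng):
        """Oracle equivalence: vectorized filter vs naive per-probe loop."""
        import pandas as pd

        from conftest import make_matrix, make_sheet
        from methpanel.data_model import pair_samples

        n_probes, n_ind = 150, 8
        sheet = make_sheet(n_ind, timepoints=("before",))
        values = rng.random((n_probes, 2 * n_ind))
        matrix = make_matrix(values, sample_ids=list(sheet.data["sample_id"]))
        table = bm.candidate_filter(matrix, sheet, "before", p_threshold=0.05)

        rows = []
        for probe in matrix.probe_ids:
            pairs = pair_samples(sheet, "before")
            a = matrix.data.loc[probe, [p.ab for p in pairs]].to_numpy()
            b = matrix.data.loc[probe, [p.om for p in pairs]].to_numpy()
            merit = bm.merit_score(a, b)
            p = brute_force_wilcoxon(list(a - b))
            if merit > 0 and p < 0.05:
                rows.append((probe, merit, p))
        expected = pd.DataFrame(rows, columns=["probe_id", "merit", "wilcoxon_p"])
        expected = expected.sort_values(
            ["merit", "probe_id"], ascending=[False, True]
        ).reset_index(drop=True)
        assert list(table["probe_id"]) == list(expected["probe_id"])
        assert np.allclose(table["merit"], expected["merit"], atol=1e-12)
        assert np.allclose(table["wilcoxon_p"], expected["wilcoxon_p"], atol=1e-12)
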