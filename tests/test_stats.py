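"""Contingency battery, Holm step-down, normality and rank tests."""

import numpy as np
import pytest
from scipy import stats as sps

from pplnet import stats as st
from pplnet.ppl_finder import PathwayResult

# the published occurrence matrices for the two mirSVR thresholds
MATRIX_03 = st.ContingencyMatrix(
    groups=("metabolic", "non_metabolic", "random"),
    loops=(10, 28, 25),
    no_loops=(97, 23, 75),
)
MATRIX_06 = st.ContingencyMatrix(
    groups=("metabolic", "non_metabolic", "random"),
    loops=(7, 24, 19),
    no_loops=(100, 27, 81),
)


def holm_oracle(p_values):
    """Independent step-down implementation: sort ascending, multiply the
    i-th smallest by (m - i + 1), running max, cap at 1."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    out = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p_values[idx]))
        out[idx] = running
    return out


class TestBuildContingency:
    def test_group_counts_and_order(self):
        results = (
            [PathwayResult(f"m{i}", "metabolic", 1) for i in range(10)]
            + [PathwayResult(f"M{i}", "metabolic", 0) for i in range(97)]
            + [PathwayResult(f"n{i}", "non_metabolic", 2) for i in range(28)]
            + [PathwayResult(f"N{i}", "non_metabolic", 0) for i in range(23)]
            + [PathwayResult(f"r{i}", "random", 5) for i in range(25)]
            + [PathwayResult(f"R{i}", "random", 0) for i in range(75)]
        )
        matrix = st.build_contingency(results)
        assert matrix == MATRIX_03

    def test_all_loop_free(self):
        results = [PathwayResult(f"p{i}", "metabolic", 0) for i in range(5)]
        matrix = st.build_contingency(results)
        assert matrix.loops == (0,) and matrix.no_loops == (5,)

    def test_single_group(self):
        matrix = st.build_contingency([PathwayResult("p", "random", 3)])
        assert matrix.groups == ("random",)
        with pytest.raises(ValueError):
            st.pairwise_chi_square_holm(matrix)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            st.build_contingency([])

    def test_render_row_and_column_percentages(self):
        text = MATRIX_03.render()
        assert "10 (9.3), [15.9]" in text or "10 (9.3), [15.8]" in text
        assert "107" in text


class TestChiSquare:
    def test_omnibus_uncorrected_reproduces_published_value(self):
        res = st.chi_square(MATRIX_03, continuity_corrected=False)
        assert res.statistic == pytest.approx(38.8678, abs=5e-5)
        assert res.df == 2

    def test_pairwise_corrected_reproduces_published_value(self):
        res = st.chi_square(MATRIX_03.pair(0, 1), continuity_corrected=True)
        assert res.statistic == pytest.approx(36.7867, abs=5e-5)
        assert res.df == 1 and res.continuity_corrected

    def test_proportional_rows_give_zero(self):
        matrix = st.ContingencyMatrix(
            groups=("a", "b"), loops=(10, 20), no_loops=(30, 60)
        )
        assert st.chi_square(matrix).statistic == pytest.approx(0.0, abs=1e-12)

    def test_zero_marginal_rejected(self):
        matrix = st.ContingencyMatrix(
            groups=("a", "b"), loops=(0, 0), no_loops=(5, 5)
        )
        with pytest.raises(ValueError):
            st.chi_square(matrix)

    @pytest.mark.parametrize("seed", range(20))
    def test_correction_never_increases_statistic(self, seed):
        rng = np.random.default_rng(seed)
        matrix = st.ContingencyMatrix(
            groups=("a", "b"),
            loops=tuple(int(v) for v in rng.integers(1, 50, 2)),
            no_loops=tuple(int(v) for v in rng.integers(1, 50, 2)),
        )
        corrected = st.chi_square(matrix, continuity_corrected=True).statistic
        uncorrected = st.chi_square(matrix, continuity_corrected=False).statistic
        assert corrected <= uncorrected + 1e-12


class TestHolm:
    def test_single_value_identity(self):
        assert st.holm_adjust([0.01]) == [0.01]

    def test_step_down_example(self):
        assert st.holm_adjust([0.01, 0.04, 0.03]) == pytest.approx(
            [0.03, 0.06, 0.06]
        )

    def test_monotone_enforcement_and_cap(self):
        # sorted [0.5, 0.6]: 0.5*2 = 1.0, then max(1.0, 0.6*1) = 1.0
        assert st.holm_adjust([0.5, 0.6]) == [1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            st.holm_adjust([0.5, 1.5])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_independent_oracle_and_invariants(self, seed):
        rng = np.random.default_rng(seed)
        p = [float(v) for v in rng.uniform(0, 1, int(rng.integers(1, 8)))]
        adjusted = st.holm_adjust(p)
        assert adjusted == pytest.approx(holm_oracle(p))
        assert all(a >= raw for a, raw in zip(adjusted, p))
        # order-preserving under permutation of inputs
        perm = list(rng.permutation(len(p)))
        permuted = st.holm_adjust([p[i] for i in perm])
        assert permuted == pytest.approx([adjusted[i] for i in perm])


class TestPairwiseChiSquare:
    def test_published_pairwise_battery_threshold_03(self):
        out = st.pairwise_chi_square_holm(MATRIX_03)
        stats = {round(r.statistic, 4) for r in out.values()}
        assert stats == {36.7867, 7.9363, 11.9768}
        met_nonmet = out[("metabolic", "non_metabolic")]
        assert met_nonmet.p_adjusted == pytest.approx(3.953649e-09, rel=1e-6)

    def test_published_pairwise_battery_threshold_06(self):
        out = st.pairwise_chi_square_holm(MATRIX_06)
        stats = {round(r.statistic, 4) for r in out.values()}
        assert stats == {33.4281, 6.2143, 11.7142}

    def test_identical_groups_capped_at_one(self):
        matrix = st.ContingencyMatrix(
            groups=("a", "b"), loops=(10, 10), no_loops=(30, 30)
        )
        out = st.pairwise_chi_square_holm(matrix)
        r = out[("a", "b")]
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_adjusted == 1.0


class TestLilliefors:
    def test_spike_mixture_rejected_as_normal(self):
        """A zero-inflated mixture like per-pathway loop counts is far from
        Normal: D large, p far below 0.01."""
        rng = np.random.default_rng(0)
        x = np.where(rng.random(300) < 0.7, 0.0, rng.uniform(1, 10, 300))
        res = st.lilliefors(x, method="mc", n_reps=2000, seed=1)
        assert res.statistic > 0.3
        assert res.p_value < 0.01

    def test_normal_sample_usually_not_rejected(self):
        rejections = 0
        for seed in range(10):
            x = np.random.default_rng(seed).normal(5, 2, 200)
            res = st.lilliefors(x, method="mc", n_reps=1000, seed=seed)
            rejections += res.p_value <= 0.05
        assert rejections <= 1  # >= 90% of runs keep normality

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            st.lilliefors([1.0, 2.0, 3.0])

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            st.lilliefors([2.0] * 10)

    def test_mc_agrees_with_table_approximation(self):
        x = np.random.default_rng(7).gamma(2.0, 1.0, 150)
        mc = st.lilliefors(x, method="mc", n_reps=5000, seed=3)
        approx = st.lilliefors(x, method="approx")
        assert mc.statistic == pytest.approx(approx.statistic)
        # both methods agree on the reject/keep call at alpha = 0.05
        assert (mc.p_value < 0.05) == (approx.p_value < 0.05)


class TestKruskalWallis:
    def test_tie_free_closed_form(self):
        # ranks {1,2} vs {3,4}: H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1)
        samples = st.GroupSamples(
            samples={"a": np.array([1.0, 2.0]), "b": np.array([3.0, 4.0])}
        )
        res = st.kruskal_wallis(samples)
        assert res.statistic == pytest.approx(2.4)
        assert res.df == 1

    def test_identical_groups_zero(self):
        samples = st.GroupSamples(
            samples={"a": np.array([5.0, 5.0]), "b": np.array([5.0, 5.0])}
        )
        assert st.kruskal_wallis(samples).statistic == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_closed_form_on_tie_free_data(self, seed):
        rng = np.random.default_rng(seed)
        pooled = rng.permutation(rng.uniform(0, 100, 15))
        groups = {"a": pooled[:5], "b": pooled[5:9], "c": pooled[9:]}
        res = st.kruskal_wallis(st.GroupSamples(samples=groups))
        n = 15
        ranks = sps.rankdata(np.concatenate([groups["a"], groups["b"], groups["c"]]))
        r_a, r_b, r_c = ranks[:5].sum(), ranks[5:9].sum(), ranks[9:].sum()
        h = 12 / (n * (n + 1)) * (r_a**2 / 5 + r_b**2 / 4 + r_c**2 / 6) - 3 * (n + 1)
        assert res.statistic == pytest.approx(h)


class TestMannWhitney:
    def test_exact_enumeration_small_sample(self):
        res = st.mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 6)
        assert res.method == "mann-whitney-exact"

    def test_identical_groups_p_one(self):
        out = st.pairwise_mann_whitney_holm(
            st.GroupSamples(
                samples={"a": np.array([1.0, 2.0, 3.0]), "b": np.array([1.0, 2.0, 3.0])}
            )
        )
        assert out[("a", "b")].p_adjusted == 1.0

    def test_shifted_group_has_smallest_adjusted_p(self):
        rng = np.random.default_rng(2)
        samples = st.GroupSamples(
            samples={
                "a": rng.normal(0, 1, 30),
                "b": rng.normal(0.2, 1, 30),
                "c": rng.normal(8, 1, 30),
            }
        )
        out = st.pairwise_mann_whitney_holm(samples)
        best = min(out, key=lambda k: out[k].p_adjusted)
        assert "c" in best
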