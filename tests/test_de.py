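"""Differential expression: filters, TMM, dispersion, exact test, BH, calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import binom

from binsplice import (
    CountMatrix,
    NBExactTest,
    bh_adjust,
    call_deg,
    estimate_common_dispersion,
    filter_low_expression,
    nb_exact_test,
    tmm_norm_factors,
)


def make_cm(cols, lib=None):
    df = pd.DataFrame(cols)
    return CountMatrix(
        counts=df,
        condition_of={s: s.rsplit("_", 1)[0] for s in df.columns},
        lib_size=lib or {},
    )


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def exact_test_oracle(sum_a, sum_b, n_a, n_b, phi):
    """Brute-force conditional two-sided p by scalar enumeration.

    Computes the group-sum NB pmf with explicit log-gamma arithmetic,
    normalizes over all splits of the total, and sums every split at most
    as probable as the observed one.
    """

    def logpmf(y, n, mu):
        m = n * mu
        if m == 0:
            return 0.0 if y == 0 else -math.inf
        if phi == 0:
            return y * math.log(m) - m - math.lgamma(y + 1)
        r = n / phi
        return (
            math.lgamma(y + r)
            - math.lgamma(r)
            - math.lgamma(y + 1)
            + r * math.log(r / (r + m))
            + y * math.log(m / (r + m))
        )

    total = sum_a + sum_b
    mu = total / (n_a + n_b)
    probs = [
        math.exp(logpmf(s, n_a, mu) + logpmf(total - s, n_b, mu))
        for s in range(total + 1)
    ]
    z = sum(probs)
    obs = probs[sum_a]
    return sum(p for p in probs if p <= obs * (1 + 1e-9)) / z


def bh_oracle(pvals):
    """Naive O(m^2) Benjamini-Hochberg step-up."""
    m = len(pvals)
    out = []
    for p in pvals:
        adj = min(q * m / sum(1 for r in pvals if r <= q) for q in pvals if q >= p)
        out.append(min(adj, 1.0))
    return out


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


class TestFilter:
    def test_low_mean_in_one_condition_removed(self):
        cm = make_cm({"wt_1": [12, 10, 0], "mut_1": [9, 10, 0]})
        kept = filter_low_expression(cm, min_mean=10)
        # gene 0 has means (12, 9.7<10) -> out; boundary mean 10 kept; zeros out
        assert list(kept.features) == [1]

    def test_boundary_mean_exactly_ten_is_kept(self):
        cm = make_cm({"wt_1": [10], "mut_1": [10]})
        assert len(filter_low_expression(cm, min_mean=10).features) == 1

    def test_single_condition_rejected(self):
        cm = make_cm({"wt_1": [5], "wt_2": [5]})
        with pytest.raises(ValueError):
            filter_low_expression(cm)


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(50, 100)
        cm = make_cm({"wt_1": col, "mut_1": col.copy()})
        factors = tmm_norm_factors(cm)
        assert all(abs(f - 1) < 1e-12 for f in factors.values())

    def test_doubled_column_yields_effective_size_ratio_two(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(60, 200) + 1
        cm = make_cm({"wt_1": a, "mut_1": 2 * a})
        factors = tmm_norm_factors(cm)
        eff_a = cm.lib_size["wt_1"] * factors["wt_1"]
        eff_b = cm.lib_size["mut_1"] * factors["mut_1"]
        assert eff_b / eff_a == pytest.approx(2.0, abs=1e-6)
        assert factors["wt_1"] * factors["mut_1"] == pytest.approx(1.0, abs=1e-9)

    def test_factors_multiply_to_one(self):
        rng = np.random.default_rng(2)
        cm = make_cm({f"s_{j}": rng.poisson(40, 150) for j in range(5)})
        factors = np.array(list(tmm_norm_factors(cm).values()))
        assert np.prod(factors) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_sample_rejected(self):
        cm = make_cm({"wt_1": [0, 0], "mut_1": [5, 5]}, lib={"wt_1": 10.0, "mut_1": 10.0})
        with pytest.raises(ValueError, match="all-zero"):
            tmm_norm_factors(cm)


# ---------------------------------------------------------------------------
# Common dispersion
# ---------------------------------------------------------------------------


class TestDispersion:
    def test_poisson_counts_give_near_zero_phi(self):
        rng = np.random.default_rng(1)
        cm = make_cm({f"wt_{j}": rng.poisson(100, 300) for j in range(1, 7)})
        cm.condition_of = {s: "wt" for s in cm.samples}
        assert estimate_common_dispersion(cm) < 0.02

    def test_recovers_planted_dispersion(self):
        rng = np.random.default_rng(1)
        phi, r = 0.2, 5.0
        mu = 100.0
        cols = {
            f"{c}_{j}": rng.negative_binomial(r, r / (r + mu), 200)
            for c in ("wt", "mut")
            for j in range(1, 4)
        }
        cm = make_cm(cols)
        assert 0.1 <= estimate_common_dispersion(cm) <= 0.3

    def test_duplicate_columns_drive_phi_to_zero(self):
        col = np.arange(10, 110, 10)
        cm = make_cm({"wt_1": col, "wt_2": col.copy()})
        cm.condition_of = {s: "wt" for s in cm.samples}
        assert estimate_common_dispersion(cm) == 0.0

    def test_all_singleton_groups_warn_and_return_zero(self):
        cm = make_cm({"wt_1": [50, 60], "mut_1": [55, 65]})
        with pytest.warns(UserWarning, match="no replicated group"):
            assert estimate_common_dispersion(cm) == 0.0


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------


class TestExactTest:
    def test_binomial_special_case(self):
        # phi=0, singletons: conditional Binomial(2, 1/2), pmf {.25,.5,.25};
        # outcomes at most as probable as the observed extreme: {0,2} -> 0.5
        p, _ = nb_exact_test([2], [0], phi=0.0)
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_perfect_symmetry_gives_p_one(self):
        for phi in (0.0, 0.2):
            p, lfc = nb_exact_test([5], [5], phi=phi)
            assert p == pytest.approx(1.0)
            assert lfc == 0.0

    def test_matches_conditional_binomial_tail(self):
        # independent closed-form oracle for the Poisson limit
        p, _ = nb_exact_test([10, 12], [30, 28], phi=0.0)
        pmf = binom.pmf(np.arange(81), 80, 0.5)
        expected = pmf[pmf <= pmf[22] * (1 + 1e-12)].sum()
        assert p == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.4])
    @pytest.mark.parametrize(
        "a,b", [([3, 7], [20, 15]), ([0, 0, 1], [4, 5, 6]), ([40], [41, 39])]
    )
    def test_matches_enumeration_oracle(self, a, b, phi):
        p, _ = nb_exact_test(a, b, phi=phi)
        expected = exact_test_oracle(int(sum(a)), int(sum(b)), len(a), len(b), phi)
        assert p == pytest.approx(expected, abs=1e-12)

    @given(
        st.lists(st.integers(0, 40), min_size=1, max_size=4),
        st.lists(st.integers(0, 40), min_size=1, max_size=4),
        st.sampled_from([0.0, 0.1, 0.5]),
    )
    def test_group_swap_negates_log2fc_and_keeps_p(self, a, b, phi):
        p1, l1 = nb_exact_test(a, b, phi)
        p2, l2 = nb_exact_test(b, a, phi)
        assert p1 == pytest.approx(p2, rel=1e-9)
        assert l1 == pytest.approx(-l2, abs=1e-12)

    def test_zero_total_convention(self):
        assert nb_exact_test([0, 0], [0, 0], phi=0.1) == (1.0, 0.0)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test([1], [2], phi=-0.1)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


class TestBH:
    def test_stepup_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_tied_pvalues_unchanged(self):
        assert bh_adjust([0.2]).tolist() == [0.2]
        assert np.allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_empty_input(self):
        assert bh_adjust([]).size == 0

    def test_matches_naive_oracle_and_permutation_invariant(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            got = bh_adjust(p)
            assert np.allclose(got, bh_oracle(list(p)), atol=1e-12)
            perm = rng.permutation(len(p))
            assert np.allclose(bh_adjust(p[perm]), got[perm], atol=1e-12)


# ---------------------------------------------------------------------------
# DEG calling
# ---------------------------------------------------------------------------


class TestCallDeg:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["log2fc", "fdr"])

    def test_threshold_boundaries_are_strict(self):
        t, s = call_deg(self.table([(0.59, 0.049), (0.50, 0.049), (0.59, 0.05)]))
        assert t["significant"].tolist() == [True, False, False]
        assert s["n_up"] == 1

    def test_up_down_percentages(self):
        # the printed split of a 869-gene DEG set: 642 up, 227 down
        rows = [(1.0, 0.01)] * 642 + [(-1.0, 0.01)] * 227
        _, s = call_deg(self.table(rows))
        assert (s["n_up"], s["n_down"]) == (642, 227)
        assert (s["pct_up"], s["pct_down"]) == (73.9, 26.1)


# ---------------------------------------------------------------------------
# Model / Results integration
# ---------------------------------------------------------------------------


class TestNBExactTestModel:
    def test_recovers_planted_fold_change_direction(self):
        rng = np.random.default_rng(21)
        mu = np.full(300, 80.0)
        mu_mut = mu.copy()
        mu_mut[:10] *= 4  # strong planted up-regulation
        r = 1 / 0.05
        cols = {f"wt_{j}": rng.negative_binomial(r, r / (r + mu)) for j in range(1, 4)}
        cols |= {f"mut_{j}": rng.negative_binomial(r, r / (r + mu_mut)) for j in range(1, 4)}
        cm = make_cm(cols)
        res = NBExactTest(cm, reference="wt", alternative="mut").fit()
        called = set(int(g) for g in res.significant_genes)
        assert called >= set(range(10))
        assert all(res.table.loc[g, "log2fc"] > 0 for g in called if g < 10)
        assert "DEG" in res.summary()

    def test_requires_two_conditions(self):
        cm = make_cm({"wt_1": [5], "wt_2": [5]})
        with pytest.raises(ValueError, match="2 conditions"):
            NBExactTest(cm)
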