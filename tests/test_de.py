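"""Differential-expression engine: TMM, dispersion, exact test, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from invasig import de, simulate


def _brute_tmm_log_factor(y, n, y_ref, n_ref, trim_m=0.3, trim_a=0.05):
    """Straight-line re-statement of the trim rule: enumerate kept genes."""
    kept_m, kept_a, kept_w = [], [], []
    for yi, ri in zip(y, y_ref):
        if yi > 0 and ri > 0:
            p, pr = yi / n, ri / n_ref
            kept_m.append(np.log2(p / pr))
            kept_a.append(0.5 * np.log2(p * pr))
            kept_w.append((n - yi) / (n * yi) + (n_ref - ri) / (n_ref * ri))
    m, a, w = map(np.array, (kept_m, kept_a, kept_w))
    lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
    sel = [i for i in range(len(m)) if lo_m <= m[i] <= hi_m and lo_a <= a[i] <= hi_a]
    return np.sum([m[i] / w[i] for i in sel]) / np.sum([1 / w[i] for i in sel])


class TestTMM:
    def test_identical_columns_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        nf = de.tmm_factors(counts)
        np.testing.assert_allclose(nf.factors, [1.0, 1.0])

    def test_pure_depth_difference(self):
        base = np.array([13, 25, 8, 40, 100, 7, 55, 19, 3, 62])
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        nf = de.tmm_factors(counts)
        np.testing.assert_allclose(nf.factors, [1.0, 1.0], atol=1e-12)
        assert nf.effective_sizes["b"] / nf.effective_sizes["a"] == pytest.approx(2.0)

    def test_matches_brute_force_trim(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.poisson([100] * 50, size=(2, 50)).T, columns=["s1", "s2"]
        )
        counts["s2"] = (counts["s2"] * 1.6).astype(int) + 1
        nf = de.tmm_factors(counts)
        ref = counts.sum().idxmax()
        other = [c for c in counts.columns if c != ref][0]
        lf = _brute_tmm_log_factor(
            counts[other].to_numpy(), counts[other].sum(),
            counts[ref].to_numpy(), counts[ref].sum(),
        )
        # rescaling to geometric mean 1 splits lf evenly between the two columns
        assert np.log2(nf.factors[other]) == pytest.approx(lf / 2, abs=1e-10)
        assert np.log2(nf.factors[ref]) == pytest.approx(-lf / 2, abs=1e-10)

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError):
            de.tmm_factors(pd.DataFrame({"a": [1, 2], "b": [0, 0]}))


class TestDispersion:
    @pytest.mark.parametrize("phi_true, lo, hi", [(0.0, 0.0, 0.05), (0.2, 0.15, 0.25)])
    def test_recovers_simulated_dispersion(self, phi_true, lo, hi):
        cfg = simulate.BulkSimConfig(
            n_genes=500, n_reps_per_group=5, baseline_mean=100.0,
            dispersion=phi_true, lib_size_range=(1.0, 1.0), seed=42,
        )
        mats, _ = simulate.gen_bulk(cfg)
        counts = pd.concat([mats[("INV+", "none")], mats[("INV+", "ici")]], axis=1)
        groups = pd.Series(["A"] * 5 + ["B"] * 5, index=counts.columns)
        nf = de.tmm_factors(counts)
        phi = de.estimate_common_dispersion(counts, groups, nf).phi
        assert lo <= phi <= hi

    def test_equal_counts_yield_zero(self):
        counts = pd.DataFrame([[7, 7, 7, 7]], index=["g"], columns=list("abcd"))
        groups = pd.Series(["A", "A", "B", "B"], index=counts.columns)
        nf = de.tmm_factors(counts)
        assert de.estimate_common_dispersion(counts, groups, nf).phi == 0.0
        # likelihood is monotone decreasing in phi when there is no spread
        lls = [de._conditional_loglik(np.array([[7, 7]]), p) for p in (0.0, 0.1, 1.0)]
        assert lls[0] > lls[1] > lls[2]

    def test_single_replicate_group_rejected(self):
        counts = pd.DataFrame(np.ones((3, 3), int), columns=list("abc"))
        nf = de.tmm_factors(counts)
        with pytest.raises(ValueError):
            de.estimate_common_dispersion(counts, ["A", "A", "B"], nf)


def brute_binomial_pvalue(sum_a: int, sum_b: int) -> float:
    """Poisson-limit oracle for 2v2 equal libraries: A | total ~ Bin(total, 1/2)."""
    total = sum_a + sum_b
    probs = np.array([comb(total, a, exact=True) for a in range(total + 1)], dtype=float)
    probs /= probs.sum()
    obs = probs[sum_a]
    return min(1.0, probs[probs <= obs * (1 + 1e-12)].sum())


class TestExactTest:
    def test_identical_counts_give_p_one(self):
        counts = pd.DataFrame([[9, 9, 9, 9]], index=["g"], columns=list("abcd"))
        nf = de.tmm_factors(counts)
        tab = de.nb_exact_test(counts, ["a", "b"], ["c", "d"], nf, phi=0.1)
        assert tab.loc["g", "p"] == pytest.approx(1.0)
        assert tab.loc["g", "log2fc"] == pytest.approx(0.0)

    def test_matches_binomial_enumeration_at_zero_dispersion(self):
        for total in range(1, 31):
            for a in range(total + 1):
                got = de.exact_nb_pvalue(a, total - a, 2, 2, phi=0.0)
                want = brute_binomial_pvalue(a, total - a)
                assert got == pytest.approx(want, abs=1e-9), (a, total - a)

    def test_group_swap_negates_lfc_keeps_p(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(80, size=(40, 4)), columns=list("abcd"))
        nf = de.tmm_factors(counts)
        fwd = de.nb_exact_test(counts, ["a", "b"], ["c", "d"], nf, 0.1)
        rev = de.nb_exact_test(counts, ["c", "d"], ["a", "b"], nf, 0.1)
        np.testing.assert_allclose(fwd["p"], rev["p"], rtol=1e-12)
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], rtol=1e-12)

    def test_negative_phi_rejected(self):
        counts = pd.DataFrame(np.ones((2, 4), int), columns=list("abcd"))
        nf = de.tmm_factors(counts)
        with pytest.raises(ValueError):
            de.nb_exact_test(counts, ["a", "b"], ["c", "d"], nf, -0.1)


def brute_bh(p: np.ndarray) -> np.ndarray:
    """Min-over-tail step-up definition, evaluated literally."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_pos, idx in enumerate(order):
        tail = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
        adj[idx] = min(1.0, min(tail))
    return adj


class TestBH:
    def test_single_p_identity(self):
        np.testing.assert_allclose(de.bh_adjust([0.05]), [0.05])

    def test_stepup_formula_example(self):
        got = de.bh_adjust([0.002, 0.01, 0.03, 0.04])
        np.testing.assert_allclose(got, [0.008, 0.02, 0.04, 0.04], atol=1e-12)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(de.bh_adjust(p), brute_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_in_rank_and_permutation_invariant(self, pvals):
        p = np.array(pvals)
        adj = de.bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(de.bh_adjust(p[perm]), adj[perm], atol=1e-12)
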