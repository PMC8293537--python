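"""The iterative negative-binomial caller, step by step and end to end."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mccnv import (
    SimulationConfig,
    adjusted_counts,
    bh_adjust,
    diploid_pvalue,
    mom_dispersion,
    nb_loglik,
    run_mccnv,
    shrink_dispersion,
    simulate_pool,
    size_factors,
    update_states,
)
from mccnv.core import CNVCaller, STATE_GRID, grid_search_xi


class TestAdjustedCounts:
    def test_diploid_identity(self):
        c = np.array([[10, 20], [30, 40]])
        np.testing.assert_array_equal(adjusted_counts(c, np.ones_like(c)), c)

    def test_halved_state_doubles_count(self):
        assert adjusted_counts(np.array([[100.0]]), np.array([[0.5]]))[0, 0] == 200

    def test_zero_state_masked(self):
        out = adjusted_counts(np.array([[100.0]]), np.array([[0.0]]))
        assert np.isnan(out[0, 0])


class TestSizeFactors:
    def test_identical_subjects_give_unit_factors(self):
        c = np.tile([100.0, 200, 300], (4, 1))
        np.testing.assert_allclose(size_factors(c), 1.0)

    def test_doubled_subject_hand_derivation(self):
        """Subject 2 = 2x subject 1 everywhere: g_j = c_1j*sqrt(2), so
        f = (1/sqrt2, sqrt2)."""
        c1 = np.array([100.0, 200, 300, 400])
        c = np.vstack([c1, 2 * c1])
        np.testing.assert_allclose(size_factors(c), [1 / np.sqrt(2), np.sqrt(2)])

    def test_target_permutation_invariance(self, rng):
        c = rng.poisson(200, size=(5, 40)).astype(float)
        perm = rng.permutation(40)
        np.testing.assert_allclose(size_factors(c), size_factors(c[:, perm]))

    def test_subject_below_threshold_everywhere_errors(self):
        c = np.array([[5.0, 6, 7], [100, 200, 300]])
        with pytest.raises(ValueError, match="subject index 0"):
            size_factors(c)


class TestMomDispersion:
    def test_balanced_values_floor_at_zero(self):
        """{90,100,110}: sample variance 100 equals the mean, phi = 0."""
        mu, phi = mom_dispersion(np.array([[90.0], [100], [110]]), np.ones(3))
        assert mu[0] == 100 and phi[0] == 0

    def test_overdispersed_values_hand_arithmetic(self):
        """{50,100,150}: variance 2500, phi = (2500-100)/100^2 = 0.24."""
        mu, phi = mom_dispersion(np.array([[50.0], [100], [150]]), np.ones(3))
        assert mu[0] == 100
        assert phi[0] == pytest.approx(0.24)

    def test_constant_values_zero_dispersion(self):
        mu, phi = mom_dispersion(np.full((4, 2), 123.0), np.ones(4))
        assert (phi == 0).all()


class TestShrinkDispersion:
    def test_no_shrinkage_limit(self):
        phi = np.array([0.1, 0.2, 0.3])
        out, d, _ = shrink_dispersion(phi, delta=0.0)
        np.testing.assert_array_equal(out, phi)

    def test_full_shrinkage_limit(self):
        phi = np.array([0.1, 0.2, 0.3])
        out, d, xi = shrink_dispersion(phi, delta=1.0)
        np.testing.assert_allclose(out, xi)

    def test_identical_raw_values_noop(self):
        phi = np.full(5, 0.07)
        out, d, _ = shrink_dispersion(phi)
        assert d == 1.0
        np.testing.assert_allclose(out, phi)

    def test_grid_minimizer_agrees_with_mean(self, rng):
        phi = rng.gamma(2, 0.05, size=500)
        _, _, xi = shrink_dispersion(phi)
        assert xi == pytest.approx(grid_search_xi(phi), abs=(phi.max() - phi.min()) / 1000)

    def test_shrinkage_dominates_raw_under_common_dispersion(self, rng):
        """With a shared true phi, shrunken estimates beat raw on average."""
        true_phi, m, wins = 0.05, 100.0, 0
        r = 1 / true_phi
        p = r / (r + m)
        raw_err, shr_err = [], []
        for _ in range(100):
            counts = rng.negative_binomial(r, p, size=(8, 200)).astype(float)
            _, phi_hat = mom_dispersion(counts, np.ones(8))
            phi_tilde, _, _ = shrink_dispersion(phi_hat)
            raw_err.append(np.abs(phi_hat - true_phi).mean())
            shr_err.append(np.abs(phi_tilde - true_phi).mean())
        assert np.mean(shr_err) <= np.mean(raw_err)


class TestNbLoglik:
    def test_poisson_limit_exact(self):
        c = np.arange(0, 30)
        np.testing.assert_allclose(
            nb_loglik(c, 5.0, 0.0), stats.poisson.logpmf(c, 5.0), atol=1e-9
        )

    def test_pmf_normalizes(self):
        c = np.arange(0, 5000)
        total = np.exp(nb_loglik(c, 100.0, 0.1)).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_variance_parameterization(self, rng):
        """Sampled variance matches m + phi m^2 (m=100, phi=0.1 -> 1100)."""
        m, phi = 100.0, 0.1
        r = 1 / phi
        draws = rng.negative_binomial(r, r / (r + m), size=1_000_000)
        assert draws.var() == pytest.approx(m + phi * m**2, rel=0.01)


class TestUpdateStates:
    def test_diploid_consistent_count(self):
        f = np.array([0.9, 1.1])
        mu = np.array([200.0, 300.0])
        c = np.rint(f[:, None] * mu[None, :]).astype(int)
        s, valid = update_states(c, f, mu, np.full(2, 1e-3))
        assert (s == 1.0).all() and valid.all()

    def test_half_count_calls_het_deletion(self):
        """c=100 against f*mu=200 with tiny dispersion: argmax is 0.5."""
        s, _ = update_states(np.array([[100]]), np.ones(1), np.array([200.0]),
                             np.array([0.001]))
        assert s[0, 0] == 0.5

    def test_zero_mean_target_reported_missing(self):
        s, valid = update_states(np.array([[5, 5]]), np.ones(1),
                                 np.array([0.0, 10.0]), np.array([0.0, 0.0]))
        assert np.isnan(s[0, 0]) and s[0, 1] == 0.5
        assert not valid[0, 0]

    def test_matches_brute_force_oracle(self, rng):
        """Vectorized argmax equals an independent per-cell likelihood loop
        on 1000 random instances, exactly."""
        n = 1000
        f = rng.uniform(0.5, 2.0, n)
        mu = rng.uniform(5, 500, n)
        phi = rng.uniform(0, 0.3, n)
        c = rng.integers(0, 1200, n)
        states, _ = update_states(c[None, :], np.ones(1), f * mu, phi)
        # oracle: plain python loop over the grid, scipy pmfs directly
        order = sorted(STATE_GRID, key=lambda s: (abs(s - 1), s))
        for k in range(n):
            best, best_ll = None, -np.inf
            for sv in order:
                m = sv * f[k] * mu[k]
                d = phi[k]
                if d <= 1e-12:
                    ll = stats.poisson.logpmf(c[k], m)
                else:
                    r = 1 / d
                    ll = stats.nbinom.logpmf(c[k], r, r / (r + m))
                if ll > best_ll:
                    best, best_ll = sv, ll
            assert states[0, k] == best, k


class TestDiploidPvalue:
    def test_central_value_capped_at_one(self):
        m = 200.0
        med = stats.poisson.ppf(0.5, m)
        p = diploid_pvalue(np.array([med]), 1.0, m, 0.0)
        assert p[0] > 0.95

    def test_extreme_count_tiny_pvalue(self):
        p = diploid_pvalue(np.array([0]), 1.0, 1000.0, 1e-4)
        assert p[0] < 1e-10

    def test_tail_monotonicity(self):
        m = 100.0
        c = np.arange(0, 300)
        p = diploid_pvalue(c, 1.0, m, 0.05)
        mode = int(np.argmax(p))
        assert (np.diff(p[mode:]) <= 1e-12).all()
        assert (np.diff(p[:mode]) >= -1e-12).all()


class TestBHAdjust:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4
        )

    def test_single_pvalue_unchanged(self):
        assert bh_adjust(np.array([0.3]))[0] == 0.3

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=500)
        assert (bh_adjust(p) >= p).all()

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    def test_matches_statsmodels_reference(self, pvals):
        from statsmodels.stats.multitest import multipletests

        p = np.asarray(pvals)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    def test_order_invariance(self, rng):
        p = rng.uniform(size=100)
        perm = rng.permutation(100)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))


class TestCaller:
    def test_null_pool_converges_all_diploid(self):
        """Variant-free pools settle at the all-diploid fixed point with
        essentially no flagged exons."""
        flagged = []
        for seed in range(5):
            cfg = SimulationConfig(n_subjects=16, n_targets=500, depth=225 * 500,
                                   variant_prob=0.0, seed=seed)
            pool = simulate_pool(cfg)
            caller = CNVCaller().fit(pool.counts)
            assert caller.converged_
            flagged.append(int(caller.called_.sum()))
        assert sum(n <= 1 for n in flagged) == 5

    def test_injected_homozygous_deletion_recovered(self):
        """A zeroed-out exon at ~225 molecules/target is flagged with state < 1."""
        cfg = SimulationConfig(n_subjects=16, n_targets=500, depth=225 * 500,
                               variant_prob=0.0, seed=7)
        pool = simulate_pool(cfg)
        counts = pool.counts.counts.copy()
        j = int(np.argsort(pool.simplex)[len(pool.simplex) // 2])  # median-coverage exon
        counts.iloc[0, j] = 0
        caller = CNVCaller().fit(counts)
        assert caller.called_[0, j]
        assert caller.states_[0, j] < 1

    def test_injected_het_deletion_recovered(self):
        cfg = SimulationConfig(n_subjects=16, n_targets=500, depth=225 * 500,
                               variant_prob=0.0, seed=8)
        pool = simulate_pool(cfg)
        counts = pool.counts.counts.copy()
        j = int(np.argmax(pool.simplex))
        counts.iloc[2, j] = int(counts.iloc[2, j] * 0.5)
        caller = CNVCaller().fit(counts)
        assert caller.called_[2, j]
        assert caller.states_[2, j] == 0.5

    def test_deterministic_refit(self, medium_pool):
        a = CNVCaller().fit(medium_pool.counts)
        b = CNVCaller().fit(medium_pool.counts)
        np.testing.assert_array_equal(a.states_, b.states_, strict=True)
        np.testing.assert_array_equal(a.pvalues_adjusted_, b.pvalues_adjusted_)
        assert a.n_iter_ == b.n_iter_

    def test_callset_table_and_merged_variants(self, medium_pool):
        cs, caller = run_mccnv(medium_pool.counts)
        t = cs.table
        assert list(t.columns) == ["subject", "chrom", "start", "end", "target_id",
                                   "state", "p", "p_adj", "called"]
        assert len(t) == medium_pool.counts.shape[0] * medium_pool.counts.shape[1]
        called = t[t["called"]]
        assert (called["state"] != 1).all()
        ok = t.dropna(subset=["p"])
        assert (ok["p_adj"] >= ok["p"] - 1e-12).all()
        # merged records never mix directions and cover >= 1 exon
        if len(cs.variants):
            assert set(cs.variants["direction"]) <= {"dup", "del"}
            assert (cs.variants["n_exons"] >= 1).all()

    def test_sklearn_estimator_contract(self):
        from sklearn.base import clone

        est = CNVCaller(alpha=0.01, max_iter=10)
        cloned = clone(est)
        assert cloned.get_params()["alpha"] == 0.01
        assert cloned.get_params()["max_iter"] == 10

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="subject"):
            CNVCaller().fit(np.array([[10, 20, 30]]))

    def test_all_zero_targets_dropped_with_warning(self):
        rng = np.random.default_rng(0)
        c = rng.poisson(200, (4, 50))
        c[:, 10] = 0
        with pytest.warns(UserWarning, match="all-zero"):
            caller = CNVCaller().fit(c)
        assert np.isnan(caller.states_[:, 10]).all()
        assert not caller.called_[:, 10].any()

    def test_pvalue_methods_agree_on_strong_signals(self, medium_pool):
        tail = CNVCaller(pvalue_method="tail").fit(medium_pool.counts)
        lik = CNVCaller(pvalue_method="likelihood").fit(medium_pool.counts)
        np.testing.assert_array_equal(tail.states_, lik.states_)
        strong = tail.pvalues_ < 1e-12
        assert (lik.pvalues_[strong] < 1e-3).all()
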