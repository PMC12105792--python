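"""OADA likelihood, fitting, model comparison, profile CIs, pST, Fisher test."""

import numpy as np
import pytest
from scipy import stats

from feederdiff import (
    DiffusionDesign,
    OadaFit,
    OadaModelSpec,
    compare_models,
    compute_pst,
    event_rates,
    fisher_exact_2xk,
    fit_oada,
    oada_loglik,
    profile_ci_s,
    pst_with_ci,
)
from feederdiff.oada import aicc, simulate_pst

from helpers import random_designs


def two_linked():
    """Two individuals, unit edge, order (a, b)."""
    return DiffusionDesign(np.array([[0.0, 1.0], [1.0, 0.0]]), [0, 1])


def star_network(n_leaves):
    A = np.zeros((n_leaves + 1, n_leaves + 1))
    A[0, 1:] = A[1:, 0] = 1.0
    return A


class TestEventRates:
    def test_null_model_rates_all_one(self):
        r = event_rates(["a", "b", "c"], [], np.zeros((3, 3)), s=0, beta=0)
        np.testing.assert_array_equal(r, 1.0)

    def test_social_term_adds_exposure(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        r = event_rates(["a", "b"], ["b"], A, s=1, beta=0)
        np.testing.assert_allclose(r, [2.0, 1.0])

    def test_ilv_scales_asocial_rate(self):
        r = event_rates(["a"], [], np.zeros((1, 1)), s=0, beta=np.log(2), ilv=[1.0])
        assert r[0] == pytest.approx(2.0)

    def test_informed_outside_risk_set_errors(self):
        with pytest.raises(ValueError, match="informed"):
            event_rates(["a"], ["z"], np.zeros((1, 1)), s=0, beta=0)

    def test_negative_s_errors(self):
        with pytest.raises(ValueError, match="s must be"):
            event_rates(["a"], [], np.zeros((1, 1)), s=-1, beta=0)

    def test_star_conditional_probabilities(self):
        # center informed -> all leaves equally exposed (uniform continuation);
        # one leaf informed -> center next with prob (1+s)/((1+s) + (N-2))
        s = 1000.0
        A = star_network(4)
        ids = list(range(5))
        r_center_first = event_rates(ids, [0], A, s=s, beta=0)
        np.testing.assert_allclose(r_center_first[1:], r_center_first[1])
        r_leaf_first = event_rates(ids, [1], A, s=s, beta=0)
        naive = [0, 2, 3, 4]
        p_center = r_leaf_first[0] / r_leaf_first[naive].sum()
        assert p_center == pytest.approx((1 + s) / ((1 + s) + 3), rel=1e-12)


class TestOadaLoglik:
    def test_asocial_full_diffusion_is_log_factorial(self):
        d = DiffusionDesign(np.zeros((3, 3)), [0, 1, 2])
        assert oada_loglik(d) == pytest.approx(-np.log(6), abs=1e-12)

    def test_two_individual_social_hand_trace(self):
        assert oada_loglik(two_linked(), s=1) == pytest.approx(
            np.log(0.5), abs=1e-12
        )

    def test_censored_individuals_stay_in_denominator(self):
        # 3 at risk, only one acquires: the event competes against all 3
        d = DiffusionDesign(np.zeros((3, 3)), [0])
        assert oada_loglik(d) == pytest.approx(np.log(1 / 3), abs=1e-12)

    def test_pooling_is_additive(self, rng):
        designs = random_designs(rng, 3, 8, s=2.0)
        total = oada_loglik(designs, s=1.5, beta=0.3)
        parts = sum(oada_loglik(d, s=1.5, beta=0.3) for d in designs)
        assert total == pytest.approx(parts, abs=1e-12)

    @staticmethod
    def _asocial_oracle(d, beta):
        # independent sequential-multinomial implementation
        ll, naive = 0.0, list(range(d.N))
        w = np.exp(beta * d.x)
        for i in d.order:
            ll += np.log(w[i] / w[naive].sum())
            naive.remove(i)
        return ll

    def test_social_at_zero_equals_asocial(self, rng):
        for _ in range(25):
            d = random_designs(rng, 1, 10, s=float(rng.random() * 3))[0]
            beta = float(rng.normal())
            assert oada_loglik(d, s=0.0, beta=beta) == pytest.approx(
                self._asocial_oracle(d, beta), abs=1e-12
            )


class TestFitOada:
    def test_social_loglik_dominates_nested_asocial(self, rng):
        designs = random_designs(rng, 5, 10, s=3.0)
        social = fit_oada(designs, spec=OadaModelSpec("social", seed=0))
        asocial = fit_oada(designs, spec=OadaModelSpec("asocial", seed=0))
        assert social.loglik >= asocial.loglik - 1e-9
        assert social.k == 2 and asocial.k == 1

    def test_pooled_recovery_smoke(self, rng):
        designs = random_designs(rng, 25, 12, s=4.0)
        fit = fit_oada(designs, spec=OadaModelSpec("social", seed=1))
        assert 1.0 < fit.s_hat < 16.0
        assert fit.converged

    def test_aicc_undefined_with_too_few_events(self):
        with pytest.raises(ValueError, match="pool"):
            aicc(-1.0, k=2, n_events=3)


class TestCompareModels:
    def _fit(self, model, loglik, k, n=10, converged=True):
        return OadaFit(
            model_type=model, s_hat=1.0 if model == "social" else None,
            beta_hat=0.0, loglik=loglik, k=k, n_events=n,
            aicc=aicc(loglik, k, n), converged=converged,
        )

    def test_hand_computed_aicc_selects_asocial(self):
        social = self._fit("social", -10.0, 2)
        asocial = self._fit("asocial", -11.0, 1)
        assert social.aicc == pytest.approx(20 + 4 + 12 / 7, abs=1e-12)
        assert asocial.aicc == pytest.approx(24.5, abs=1e-12)
        assert compare_models(social, asocial).winner == "asocial"

    def test_exact_tie_goes_to_asocial(self):
        social = self._fit("social", -10.0, 2)
        # choose asocial loglik so the AICc values coincide exactly
        target = social.aicc
        ll = -(target - 2 - 0.5) / 2
        asocial = self._fit("asocial", ll, 1)
        assert asocial.aicc == pytest.approx(social.aicc, abs=1e-12)
        sel = compare_models(social, asocial)
        assert sel.winner == "asocial" and not sel.replaced

    def test_nonconverged_social_winner_replaced(self):
        social = self._fit("social", -5.0, 2, converged=False)
        asocial = self._fit("asocial", -11.0, 1)
        assert social.aicc < asocial.aicc
        sel = compare_models(social, asocial)
        assert sel.winner == "asocial" and sel.replaced

    def test_differing_event_counts_error(self):
        with pytest.raises(ValueError, match="different"):
            compare_models(self._fit("social", -5, 2, 10), self._fit("asocial", -5, 1, 12))


class TestProfileCi:
    def test_boundary_lower_limit_is_zero(self, rng):
        # weak data: profile at s=0 within the chi-square band
        designs = random_designs(rng, 1, 6, s=0.0)
        fit = fit_oada(designs, spec=OadaModelSpec("social", seed=0))
        ci = profile_ci_s(designs, fit=fit)
        assert ci.s_lower == 0.0

    def test_grid_search_oracle_brackets_same_bounds(self, rng):
        designs = random_designs(rng, 10, 8, s=2.0, ilv_scale=0.0)
        fit = fit_oada(designs, spec=OadaModelSpec("social", seed=0))
        ci = profile_ci_s(designs, fit=fit)
        assert not ci.unbounded_upper
        # beta is irrelevant here (ilv = 0), so the profile is 1-D in s
        grid = np.arange(0.0, max(4 * fit.s_hat, 10.0), 1e-3)
        ll = np.array([oada_loglik(designs, s=s, beta=0.0) for s in grid])
        crit = stats.chi2.ppf(0.95, 1) / 2
        inside = grid[ll >= ll.max() - crit]
        assert ci.s_lower == pytest.approx(inside.min(), abs=1e-2)
        assert ci.s_upper == pytest.approx(inside.max(), abs=1e-2)

    def test_network_following_diffusion_unbounded_upper(self):
        # chain diffusion: each acquirer is the unique maximally exposed naive
        n = 10
        A = np.zeros((n, n))
        for i in range(n - 1):
            A[i, i + 1] = A[i + 1, i] = 1.0
        d = DiffusionDesign(A, list(range(n)))
        fit = fit_oada(d, spec=OadaModelSpec("social", seed=0))
        ci = profile_ci_s(d, fit=fit)
        assert ci.unbounded_upper
        est = pst_with_ci(fit, ci, d)
        assert est.pst_upper == 0.99999


class TestComputePst:
    def test_zero_s_gives_zero(self, rng):
        designs = random_designs(rng, 3, 8, s=2.0)
        assert compute_pst(designs, s=0.0, beta=0.7) == 0.0

    def test_two_individual_hand_trace(self):
        assert compute_pst(two_linked(), s=1.0) == pytest.approx(0.25, abs=1e-12)

    def test_large_s_saturates(self):
        assert compute_pst(two_linked(), s=1000.0) == pytest.approx(
            (0 + 1000 / 1001) / 2, abs=1e-12
        )

    def test_monotone_in_s(self, rng):
        for _ in range(50):
            d = random_designs(rng, 1, 8, s=float(rng.random() * 4))[0]
            beta = float(rng.normal() * 0.5)
            svals = np.sort(rng.random(5) * 50)
            psts = [compute_pst(d, s=s, beta=beta) for s in svals]
            assert all(b >= a - 1e-12 for a, b in zip(psts, psts[1:]))

    def test_simulation_estimator_agrees_on_toy(self):
        # every order of the 2-individual dyad has attribution (0 + 1/2)/2
        sim = simulate_pst(two_linked(), s=1.0, n_rep=200, seed=3)
        assert sim == pytest.approx(0.25, abs=1e-12)


class TestFisherExact:
    def test_no_association_table_is_one(self):
        assert fisher_exact_2xk([[2, 2], [2, 2]]) == pytest.approx(1.0, abs=1e-12)

    def test_perfect_separation_closed_form(self):
        assert fisher_exact_2xk([[0, 5], [5, 0]]) == pytest.approx(
            2 / 252, abs=1e-12
        )

    def test_matches_closed_form_hypergeometric_2x2(self, rng):
        for _ in range(30):
            t = rng.integers(1, 12, (2, 2))
            p = fisher_exact_2xk(t)
            # closed form: sum hypergeometric pmf over tables no more probable
            r1, c1, n = t[0].sum(), t[:, 0].sum(), t.sum()
            ks = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
            pmf = stats.hypergeom.pmf(ks, n, r1, c1)
            p_obs = stats.hypergeom.pmf(t[0, 0], n, r1, c1)
            expected = pmf[pmf <= p_obs + 1e-12].sum()
            assert p == pytest.approx(expected, abs=1e-12)
            assert p == pytest.approx(stats.fisher_exact(t)[1], abs=1e-9)

    def test_2xk_reduces_sensibly_and_mc_agrees(self):
        t = [[3, 7, 2], [8, 2, 5]]
        p_exact = fisher_exact_2xk(t)
        p_mc = fisher_exact_2xk(t, max_exact_total=5, n_mc=40_000, seed=1)
        assert 0.0 < p_exact < 1.0
        assert p_mc == pytest.approx(p_exact, abs=0.02)

    def test_zero_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_2xk([[0, 0], [3, 4]]) == 1.0
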