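"""Maximum-entropy reweighting: restraint classification, optimizer
correctness against brute-force oracles, L-curve selection, and the
iterative tethered-chain protocol."""

import numpy as np
import pandas as pd
import pytest

from prefold.observables import radius_of_gyration
from prefold.reweight import (ISOLATED_BOUNDS, Restraint, _model_matrix,
                              iterative_reweight_rnc, kl_divergence,
                              negative_log_posterior, optimize_weights,
                              restraints_from_ratios, reweight_isolated,
                              theta_scan)


def _gauss(value, sigma, residue=1, site=10):
    return [Restraint(residue, site, value, sigma, "gaussian")]


class TestClassification:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["site", "residue", "ratio",
                                           "ratio_err"])

    def test_mid_range_ratio_becomes_gaussian(self):
        rs = restraints_from_ratios(
            self._table([(740, 700, 0.5, 0.05)]))
        assert rs[0].kind == "gaussian"
        assert rs[0].value > 0
        assert rs[0].sigma > 0

    def test_undetected_peak_becomes_lower_bound(self):
        rs = restraints_from_ratios(
            self._table([(740, 700, np.nan, 0.1)]))
        assert rs[0].kind == "lower_bound"
        assert rs[0].value == ISOLATED_BOUNDS["lower"] == 64.5

    def test_unattenuated_peak_becomes_upper_bound(self):
        rs = restraints_from_ratios(
            self._table([(740, 700, 1.00, 0.03)]))
        assert rs[0].kind == "upper_bound"
        assert rs[0].value == ISOLATED_BOUNDS["upper"] == 2.2

    def test_missing_r2_entry_skips_with_warning(self):
        with pytest.warns(UserWarning, match="no R2"):
            rs = restraints_from_ratios(
                self._table([(740, 700, 0.5, 0.05), (740, 701, 0.6, 0.05)]),
                R2_H={701: 90.0})
        assert len(rs) == 1 and rs[0].residue == 701

    def test_gaussian_sigma_tracks_the_local_derivative(self):
        # flat region of the ratio curve -> larger Gamma2 uncertainty
        steep = restraints_from_ratios(self._table([(1, 2, 0.5, 0.02)]))[0]
        flat = restraints_from_ratios(self._table([(1, 2, 0.1, 0.02)]))[0]
        assert flat.sigma > steep.sigma


class TestNegativeLogPosterior:
    def test_satisfied_restraints_at_prior_give_zero(self):
        w0 = np.array([0.5, 0.5])
        y = np.array([[1.0, 3.0]])
        rs = _gauss(2.0, 0.1)
        assert negative_log_posterior(w0, y, rs, 7.0, w0) == \
            pytest.approx(0.0, abs=1e-12)

    def test_satisfied_lower_bound_contributes_nothing(self):
        w = np.array([0.5, 0.5])
        y = np.array([[12.0, 12.0]])
        rs = [Restraint(1, 10, 10.0, 1.0, "lower_bound")]
        assert negative_log_posterior(w, y, rs, 0.0, w) == 0.0

    def test_violated_lower_bound_quadratic_penalty(self):
        # <y> = 8 against bound 10 with sigma 1: L = (8-10)^2 / 2 = 2
        w = np.array([0.5, 0.5])
        y = np.array([[8.0, 8.0]])
        rs = [Restraint(1, 10, 10.0, 1.0, "lower_bound")]
        assert negative_log_posterior(w, y, rs, 0.0, w) == pytest.approx(2.0)

    def test_zero_prior_weight_with_mass_is_infinite(self):
        w = np.array([0.5, 0.5])
        w0 = np.array([1.0, 0.0])
        y = np.array([[1.0, 2.0]])
        assert negative_log_posterior(w, y, _gauss(1.5, 0.1), 1.0, w0) \
            == np.inf


class TestOptimizer:
    def test_huge_theta_returns_prior(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(0, 10, size=(1, 6))
        res = optimize_weights(y, _gauss(3.0, 0.1), theta=1e9)
        assert np.allclose(res.weights, 1 / 6, atol=1e-6)
        assert res.S_KL == pytest.approx(0.0, abs=1e-9)
        assert res.N_eff == pytest.approx(1.0, abs=1e-9)

    def test_two_conformer_solution_matches_grid_oracle(self):
        # oracle: 1D grid search over w1 for y = (0, 1), Y = 0.5
        y = np.array([[0.0, 1.0]])
        rs = _gauss(0.5, 0.01)
        res = optimize_weights(y, rs, theta=1e-6)
        grid = np.linspace(1e-6, 1 - 1e-6, 100001)
        w0 = np.full(2, 0.5)
        L = 1e-6 * (grid * np.log(grid / 0.5)
                    + (1 - grid) * np.log((1 - grid) / 0.5)) \
            + ((1 - grid) - 0.5) ** 2 / (2 * 0.01 ** 2)
        best = grid[np.argmin(L)]
        assert res.weights[0] == pytest.approx(best, abs=1e-3)
        assert np.allclose(res.weights, 0.5, atol=1e-3)

    @pytest.mark.parametrize("with_bound", [False, True])
    def test_three_conformer_simplex_grid_agreement(self, with_bound):
        # brute-force simplex grid (step 1e-3) must agree with the
        # optimizer in L within 1e-4
        rng = np.random.default_rng(1)
        y = rng.uniform(0, 10, size=(3, 3))
        rs = [Restraint(1, 10, 4.0, 0.5, "gaussian"),
              Restraint(2, 10, 6.0, 0.8, "gaussian"),
              Restraint(3, 10, 5.0, 0.6,
                        "lower_bound" if with_bound else "gaussian")]
        theta = 0.5
        res = optimize_weights(y, rs, theta)
        step = 1e-3
        w1 = np.arange(0, 1 + step / 2, step)
        best = np.inf
        w0 = np.full(3, 1 / 3)
        for a in w1:
            b = np.arange(0, 1 - a + step / 2, step)
            c = 1 - a - b
            ws = np.stack([np.full_like(b, a), b, c], axis=1)
            ws = np.clip(ws, 1e-12, None)
            ws /= ws.sum(axis=1, keepdims=True)
            skl = np.sum(ws * np.log(ws / w0), axis=1)
            avg = ws @ y.T
            pen = np.zeros(len(ws))
            for i, r in enumerate(rs):
                resid = (avg[:, i] - r.value) / r.sigma
                if r.kind == "lower_bound":
                    resid = np.where(avg[:, i] < r.value, resid, 0.0)
                pen += 0.5 * resid ** 2
            best = min(best, float(np.min(theta * skl + pen)))
        L_opt = negative_log_posterior(res.weights, y, rs, theta, w0)
        assert abs(L_opt - best) < 1e-4

    def test_chi2_non_increasing_as_theta_decreases(self, noise_free_pre):
        rs, model = noise_free_pre
        y = np.nan_to_num(_model_matrix(model, rs, {}))
        thetas = np.logspace(3, -2, 6)
        chi2 = [optimize_weights(y, rs, t).chi2_red for t in thetas]
        for a, b in zip(chi2[:-1], chi2[1:]):
            assert b <= a + 1e-6

    def test_kl_divergence_nonnegative_iff_prior(self):
        w0 = np.array([0.4, 0.6])
        assert kl_divergence(w0, w0) == pytest.approx(0.0, abs=1e-15)
        assert kl_divergence(np.array([0.7, 0.3]), w0) > 0


class TestThetaScan:
    def test_prior_that_fits_selects_largest_theta(self):
        y = np.array([[1.0, 1.02], [2.0, 2.02]])
        rs = [Restraint(1, 10, 1.01, 0.5, "gaussian"),
              Restraint(2, 10, 2.01, 0.5, "gaussian")]
        results, sel = theta_scan(y, rs, np.logspace(2, -2, 5))
        assert sel == pytest.approx(100.0)

    def test_neff_decreases_with_theta(self, noise_free_pre):
        rs, model = noise_free_pre
        y = np.nan_to_num(_model_matrix(model, rs, {}))
        results, _ = theta_scan(y, rs, np.logspace(2, -2, 6))
        neff = [r.N_eff for r in results]  # results ordered large -> small
        for a, b in zip(neff[:-1], neff[1:]):
            assert b <= a + 1e-6

    def test_two_population_recovery_selects_intermediate_theta(self):
        # synthetic truth: two populations with 80/20 split; prior biased
        # 50/50; restraints generated from the truth
        rng = np.random.default_rng(2)
        n = 40
        y = np.concatenate([rng.normal(10, 0.5, size=(20, n // 2)),
                            rng.normal(20, 0.5, size=(20, n // 2))], axis=1)
        truth = np.concatenate([np.full(n // 2, 0.8 / (n // 2)),
                                np.full(n // 2, 0.2 / (n // 2))])
        targets = y @ truth
        rs = [Restraint(i, 10, targets[i], 0.3, "gaussian")
              for i in range(20)]
        results, sel = theta_scan(y, rs, np.logspace(3, -3, 9))
        chosen = next(r for r in results if r.theta == sel)
        neffs = [r.N_eff for r in results]
        assert min(neffs) < chosen.N_eff < max(neffs)
        assert chosen.chi2_red <= 1.5


class TestRecoveryAndIteration:
    def test_noise_free_weight_recovery_within_one_percent(
            self, noise_free_pre, small_coil):
        # restraints generated from known non-uniform truth weights with no
        # noise: the reweighted observable must match the truth observable
        rs, model = noise_free_pre
        truth_w = model.ensemble.weights
        rg = np.array([radius_of_gyration(x, model.ensemble.topology)
                       for x in model.ensemble.coordinates])
        res = reweight_isolated(model, rs, theta=1.0)
        truth_obs = float(np.dot(truth_w, rg))
        post_obs = float(np.dot(res.weights, rg))
        assert abs(post_obs - truth_obs) / truth_obs < 0.01
        # and the restrained quantities themselves fit closely
        assert res.chi2_red < 0.1

    def _tethered_truth_problem(self, small_tethered, pre_params, conc=5.0):
        from prefold.pre import PREEnsembleModel
        model = PREEnsembleModel(small_tethered, [20], pre_params)
        n = model.ensemble.n_conformers
        truth_w = np.random.default_rng(5).dirichlet(np.full(n, conc))
        tau = model.tethered_tau(20, weights=truth_w)[1]
        g = model.conformer_gamma2(20, tau_c=tau)
        targets = g.T @ truth_w
        rs = [Restraint(int(rid), 20, float(t), max(0.05 * abs(t), 0.5),
                        "gaussian")
              for rid, t in zip(model.residue_ids, targets)
              if np.isfinite(t) and rid != 20]
        return model, truth_w, rs

    def test_iterative_rnc_truth_is_a_fixed_point(self, small_tethered,
                                                  pre_params):
        # noise-free restraints generated with the tethering-aware forward
        # model at the truth weights: starting the self-consistent cycle
        # from the truth prior must reproduce the truth exactly
        model, truth_w, rs = self._tethered_truth_problem(small_tethered,
                                                          pre_params)
        final = iterative_reweight_rnc(model, rs, theta=1.0, n_rounds=10,
                                       prior_weights=truth_w)
        assert np.abs(final.weights - truth_w).sum() < 1e-6
        assert final.chi2_red < 0.01

    def test_iterative_rnc_weight_changes_shrink(self, small_tethered,
                                                 pre_params):
        # from a uniform prior the per-round weight change must shrink by
        # the final round (the protocol stops on |dw| or the round budget)
        model, truth_w, rs = self._tethered_truth_problem(small_tethered,
                                                          pre_params)
        final = iterative_reweight_rnc(model, rs, theta=1.0, n_rounds=12)
        trace = final.history["l1_weight_change"]
        assert trace[-1] < trace[0]
        assert len(final.history["chi2_red"]) <= 12
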