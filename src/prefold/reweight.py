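"""Bayesian maximum-entropy ensemble reweighting against PRE restraints.

Posterior conformer weights minimize the negative log-posterior

    L(w) = theta * S_KL(w | w0) + sum_i (sum_a w_a y_i^a - Y_i)^2 / (2 sigma_i^2)

where S_KL = sum_a w_a ln(w_a / w0_a) and theta expresses confidence in the
prior ensemble. Restraints come in three kinds: ``gaussian`` (always
counted), ``lower_bound`` (penalized only while the back-calculated average
sits below the bound) and ``upper_bound`` (only while above). The optimal
theta is chosen by L-curve analysis of (S_KL, reduced chi^2); the reduced
chi^2 is computed against intensity ratios for restraints that carry them,
with the effective Gamma2 mapped through the intensity-ratio equation.

For ribosome-tethered chains the conformer-level PREs depend on the
weights through tau_C,eff, so reweighting is iterated: each round receives
the weights and correlation times of the previous one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .pre import PREEnsembleModel, gamma2_from_ratio, intensity_ratio

__all__ = [
    "Restraint",
    "RestraintSet",
    "ReweightResult",
    "restraints_from_ratios",
    "kl_divergence",
    "negative_log_posterior",
    "optimize_weights",
    "theta_scan",
    "iterative_reweight_rnc",
]

# default Gamma2 bounds (s^-1) for broadened-out / unattenuated peaks
ISOLATED_BOUNDS = {"lower": 64.5, "upper": 2.2}
RNC_BOUNDS = {"lower": 96.0, "upper": 3.7}


@dataclass
class Restraint:
    """One per-residue PRE restraint in Gamma2 space.

    ``ratio``/``ratio_err`` carry the underlying intensity-ratio datum when
    it exists, so goodness of fit can be evaluated in ratio space.
    """

    residue: int
    site: int
    value: float          # target Gamma2, s^-1 (bound value for inequalities)
    sigma: float          # uncertainty, s^-1
    kind: str = "gaussian"  # gaussian | lower_bound | upper_bound
    ratio: float | None = None
    ratio_err: float | None = None
    R2_H: float = 100.0
    R2_MQ: float = 100.0
    delta: float = 5.43e-3

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.kind not in ("gaussian", "lower_bound", "upper_bound"):
            raise ValueError(f"unknown restraint kind {self.kind!r}")
        if self.kind == "lower_bound" and self.value < 0:
            raise ValueError("lower bound must be >= 0")


@dataclass
class RestraintSet:
    restraints: list[Restraint] = field(default_factory=list)

    def __len__(self):
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    def __getitem__(self, i):
        return self.restraints[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "site_residue": r.site, "observed_residue": r.residue,
            "gamma2": r.value, "gamma2_err": r.sigma, "kind": r.kind,
            "ratio": r.ratio, "ratio_err": r.ratio_err} for r in self])

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RestraintSet":
        df = pd.read_csv(path)
        rs = [Restraint(residue=int(row.observed_residue),
                        site=int(row.site_residue), value=float(row.gamma2),
                        sigma=float(row.gamma2_err), kind=str(row.kind),
                        ratio=None if pd.isna(row.get("ratio", np.nan)) else float(row.ratio),
                        ratio_err=None if pd.isna(row.get("ratio_err", np.nan)) else float(row.ratio_err))
              for row in df.itertuples()]
        return cls(rs)


def restraints_from_ratios(ratio_table: pd.DataFrame, R2_H=100.0, R2_MQ=100.0,
                           delta: float = 5.43e-3,
                           bounds: dict | None = None) -> RestraintSet:
    """Classify measured intensity ratios into Gamma2 restraints.

    ``ratio_table`` columns: site, residue, ratio, ratio_err. A NaN ratio
    marks a peak broadened beyond detection (-> lower-bound restraint at
    the stated threshold, with ratio_err read as a relative error). Ratios
    indistinguishable from 1 (|1 - ratio| <= ratio_err) become upper
    bounds. Everything else becomes a Gaussian restraint with Gamma2 from
    numerical inversion and sigma propagated through the local derivative.
    ``R2_H``/``R2_MQ`` may be scalars or ``{residue: rate}`` mappings;
    residues missing from a mapping are skipped with a warning.
    """
    import warnings
    if bounds is None:
        bounds = ISOLATED_BOUNDS
    out = []
    for row in ratio_table.itertuples():
        residue, site = int(row.residue), int(row.site)
        if isinstance(R2_H, dict):
            if residue not in R2_H:
                warnings.warn(f"no R2 for residue {residue}; skipped")
                continue
            r2h = float(R2_H[residue])
        else:
            r2h = float(R2_H)
        r2mq = float(R2_MQ[residue]) if isinstance(R2_MQ, dict) else float(R2_MQ)
        ratio, err = float(row.ratio), float(row.ratio_err)
        if np.isnan(ratio) or ratio <= err:
            # missing or indistinguishable from zero: broadened beyond
            # detection
            bound = bounds["lower"]
            out.append(Restraint(residue, site, bound, max(bound * err, 1e-9),
                                 "lower_bound", ratio=None, ratio_err=err,
                                 R2_H=r2h, R2_MQ=r2mq, delta=delta))
        elif ratio >= 1.0 or (1.0 - ratio) <= err:
            bound = bounds["upper"]
            rel = err / min(ratio, 1.0)
            out.append(Restraint(residue, site, bound, max(bound * rel, 1e-9),
                                 "upper_bound", ratio=min(ratio, 1.0),
                                 ratio_err=err, R2_H=r2h, R2_MQ=r2mq,
                                 delta=delta))
        else:
            g = gamma2_from_ratio(ratio, r2h, r2mq, delta)
            # sigma via the local derivative d(ratio)/d(Gamma2)
            h = max(1e-3, 1e-4 * max(g, 1.0))
            dr = (intensity_ratio(g + h, r2h, r2mq, delta)
                  - intensity_ratio(max(g - h, 0.0), r2h, r2mq, delta)) \
                / (h + min(h, g))
            sigma = err / abs(dr)
            out.append(Restraint(residue, site, g, sigma, "gaussian",
                                 ratio=ratio, ratio_err=err, R2_H=r2h,
                                 R2_MQ=r2mq, delta=delta))
    return RestraintSet(out)


@dataclass
class ReweightResult:
    weights: np.ndarray
    theta: float
    S_KL: float
    chi2_red: float
    N_eff: float
    converged: bool = True
    flags: list[str] = field(default_factory=list)
    n_active_bounds: int = 0
    history: dict = field(default_factory=dict)


def kl_divergence(weights, prior_weights) -> float:
    w = np.asarray(weights, float)
    w0 = np.asarray(prior_weights, float)
    mask = w > 0
    if np.any(w0[mask] <= 0):
        return float("inf")
    return float(np.sum(w[mask] * np.log(w[mask] / w0[mask])))


def _residual_terms(avg, restraints):
    """Per-restraint (residual/sigma, active) given back-calculated averages."""
    res = np.zeros(len(restraints))
    active = np.zeros(len(restraints), dtype=bool)
    for i, r in enumerate(restraints):
        if r.kind == "gaussian":
            res[i] = (avg[i] - r.value) / r.sigma
            active[i] = True
        elif r.kind == "lower_bound":
            if avg[i] < r.value:
                res[i] = (avg[i] - r.value) / r.sigma
                active[i] = True
        else:  # upper_bound
            if avg[i] > r.value:
                res[i] = (avg[i] - r.value) / r.sigma
                active[i] = True
    return res, active


def negative_log_posterior(weights, model_values, restraints, theta,
                           prior_weights) -> float:
    """L = theta * S_KL + sum over counted restraints of residual^2 / 2.

    ``model_values``: (M, N) back-calculated values y_i^alpha.
    Bound restraints contribute only while violated. Zero prior weight with
    nonzero posterior weight yields +inf.
    """
    w = np.asarray(weights, float)
    skl = kl_divergence(w, prior_weights)
    if not np.isfinite(skl):
        return float("inf")
    avg = np.asarray(model_values) @ w
    res, _ = _residual_terms(avg, restraints)
    return float(theta * skl + 0.5 * np.sum(res ** 2))


def chi2_reduced(weights, model_values, restraints) -> tuple[float, int]:
    """Reduced chi^2 against the experimental intensity ratios.

    Gaussian restraints carrying a ratio are scored in ratio space (the
    ensemble-average Gamma2 mapped through the intensity-ratio equation);
    restraints without one, and bound restraints while active, are scored
    in Gamma2 space. Degrees of freedom = number of counted restraints
    (bounds only while active).
    """
    w = np.asarray(weights, float)
    avg = np.asarray(model_values) @ w
    total, counted = 0.0, 0
    for i, r in enumerate(restraints):
        if r.kind == "gaussian":
            if r.ratio is not None and r.ratio_err:
                pred = intensity_ratio(avg[i], r.R2_H, r.R2_MQ, r.delta)
                total += ((pred - r.ratio) / r.ratio_err) ** 2
            else:
                total += ((avg[i] - r.value) / r.sigma) ** 2
            counted += 1
        elif r.kind == "lower_bound" and avg[i] < r.value:
            total += ((avg[i] - r.value) / r.sigma) ** 2
            counted += 1
        elif r.kind == "upper_bound" and avg[i] > r.value:
            total += ((avg[i] - r.value) / r.sigma) ** 2
            counted += 1
    if counted == 0:
        return 0.0, 0
    return total / counted, counted


def _optimize_from(v0, y, restraints, theta, w0, log_w0):
    """L-BFGS on free log-weights (last coordinate pinned at 0)."""
    n = len(w0)
    targets = np.array([r.value for r in restraints])
    sigmas = np.array([r.sigma for r in restraints])
    kinds = np.array([{"gaussian": 0, "lower_bound": 1,
                       "upper_bound": 2}[r.kind] for r in restraints])

    def softmax(v_free):
        v = np.concatenate([v_free, [0.0]])
        v = v - v.max()
        e = np.exp(v)
        return e / e.sum()

    def fun_grad(v_free):
        w = softmax(v_free)
        lw = np.log(np.maximum(w, 1e-300))
        skl = float(np.sum(w * (lw - log_w0)))
        avg = y @ w
        res = (avg - targets) / sigmas
        active = np.ones(len(restraints), dtype=bool)
        active[(kinds == 1) & (avg >= targets)] = False
        active[(kinds == 2) & (avg <= targets)] = False
        res = np.where(active, res, 0.0)
        f = theta * skl + 0.5 * np.sum(res ** 2)
        dl_dw = theta * (lw - log_w0 + 1.0) + (res / sigmas) @ y
        grad_full = w * (dl_dw - np.dot(w, dl_dw))
        return f, grad_full[:n - 1]

    out = minimize(fun_grad, v0[:n - 1], jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-9})
    w = softmax(out.x)
    return w, float(out.fun), bool(out.success)


def optimize_weights(model_values, restraints, theta,
                     prior_weights=None, n_starts: int = 3) -> ReweightResult:
    """Minimize the negative log-posterior over the weight simplex.

    Log-weight (softmax) parameterization with a quasi-Newton optimizer and
    multi-start (prior, uniform, data-greedy) to hedge the mild
    non-convexity introduced by bound restraints.
    """
    y = np.asarray(model_values, dtype=float)
    m, n = y.shape
    if m != len(restraints):
        raise ValueError("model_values rows must match the restraint count")
    if n < 2:
        raise ValueError("need at least 2 conformers")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    w0 = np.full(n, 1.0 / n) if prior_weights is None \
        else np.asarray(prior_weights, float) / np.sum(prior_weights)
    log_w0 = np.log(np.maximum(w0, 1e-300))

    starts = [log_w0 - log_w0[-1]]
    if n_starts >= 2:
        starts.append(np.zeros(n))
    if n_starts >= 3:
        # data-greedy: upweight conformers that individually fit best
        targets = np.array([r.value for r in restraints])
        sigmas = np.array([r.sigma for r in restraints])
        per_conf = 0.5 * np.sum(((y - targets[:, None]) / sigmas[:, None]) ** 2,
                                axis=0)
        v = -per_conf / max(per_conf.std(), 1e-12)
        starts.append(v - v[-1])

    best = None
    for v0 in starts:
        w, f, ok = _optimize_from(v0, y, restraints, theta, w0, log_w0)
        if best is None or f < best[1]:
            best = (w, f, ok)
    w, f, ok = best
    skl = kl_divergence(w, w0)
    chi2, counted = chi2_reduced(w, y, restraints)
    avg = y @ w
    _, active = _residual_terms(avg, restraints)
    n_active = int(sum(1 for r, a in zip(restraints, active)
                       if a and r.kind != "gaussian"))
    flags = [] if ok else ["optimizer did not report convergence"]
    return ReweightResult(weights=w, theta=theta, S_KL=skl, chi2_red=chi2,
                          N_eff=float(np.exp(-skl)), converged=ok,
                          flags=flags, n_active_bounds=n_active)


def _curvature(x, y):
    """Discrete curvature by 3-point finite differences (parametric)."""
    kappa = np.full(len(x), -np.inf)
    for i in range(1, len(x) - 1):
        dx1, dy1 = x[i] - x[i - 1], y[i] - y[i - 1]
        dx2, dy2 = x[i + 1] - x[i], y[i + 1] - y[i]
        dt1 = np.hypot(dx1, dy1)
        dt2 = np.hypot(dx2, dy2)
        if dt1 < 1e-12 or dt2 < 1e-12:
            continue
        xp = (dx1 / dt1 + dx2 / dt2) / 2
        yp = (dy1 / dt1 + dy2 / dt2) / 2
        xpp = (dx2 / dt2 - dx1 / dt1) / ((dt1 + dt2) / 2)
        ypp = (dy2 / dt2 - dy1 / dt1) / ((dt1 + dt2) / 2)
        denom = (xp ** 2 + yp ** 2) ** 1.5
        if denom > 1e-12:
            kappa[i] = (xp * ypp - yp * xpp) / denom
    return kappa


def theta_scan(model_values, restraints, theta_grid,
               prior_weights=None) -> tuple[list[ReweightResult], float]:
    """Reweight across a log-spaced theta grid and pick the L-curve elbow.

    The elbow is the point of maximum discrete curvature of the
    (S_KL, chi2_red) curve on log-scaled axes; a flat (degenerate) curve
    falls back to the largest theta whose chi2_red lies within 5% of the
    minimum, flagged.
    """
    grid = np.sort(np.asarray(theta_grid, float))[::-1]  # large -> small
    if len(grid) < 5:
        raise ValueError("theta grid needs >= 5 points")
    results = [optimize_weights(model_values, restraints, t, prior_weights)
               for t in grid]
    skl = np.array([r.S_KL for r in results])
    chi2 = np.array([r.chi2_red for r in results])
    # prior already fits: keep the strongest regularization
    if chi2[0] <= 1.0:
        return results, float(grid[0])
    x = np.log10(np.maximum(skl, 1e-12))
    y = np.log10(np.maximum(chi2, 1e-12))
    span_x = x.max() - x.min()
    span_y = y.max() - y.min()
    if span_x < 1e-6 or span_y < 1e-6:
        sel = _flat_fallback(grid, chi2, results)
        return results, sel
    kappa = _curvature((x - x.min()) / span_x, (y - y.min()) / span_y)
    if not np.any(np.isfinite(kappa) & (kappa > -np.inf)):
        sel = _flat_fallback(grid, chi2, results)
        return results, sel
    return results, float(grid[int(np.argmax(kappa))])


def _flat_fallback(grid, chi2, results):
    ok = chi2 <= 1.05 * chi2.min()
    idx = int(np.nonzero(ok)[0][0])  # grid is sorted large -> small
    results[idx].flags.append("degenerate L-curve; largest theta within 5% "
                              "of minimum chi2 selected")
    return float(grid[idx])


def _model_matrix(model: PREEnsembleModel, restraints, tau_by_site):
    """(M, N) conformer-level Gamma2 values for each restraint."""
    rid = model.residue_ids
    cache = {s: model.conformer_gamma2(s, tau_by_site.get(s))
             for s in {r.site for r in restraints}}
    rows = []
    for r in restraints:
        slot = int(np.searchsorted(rid, r.residue))
        if slot >= len(rid) or rid[slot] != r.residue:
            raise KeyError(f"restraint residue {r.residue} not in topology")
        rows.append(cache[r.site][:, slot])
    return np.array(rows)


def reweight_isolated(model: PREEnsembleModel, restraints, theta,
                      prior_weights=None) -> ReweightResult:
    """Single-round reweighting at fixed tau_C (isolated chain)."""
    y = _model_matrix(model, restraints, {})
    return optimize_weights(np.nan_to_num(y), restraints, theta, prior_weights)


def iterative_reweight_rnc(model: PREEnsembleModel, restraints, theta,
                           n_rounds: int = 20, tol: float = 1e-6,
                           prior_weights=None,
                           tau_damping: float = 0.5) -> ReweightResult:
    """Self-consistent reweighting for ribosome-tethered ensembles.

    Each round recomputes the per-residue tau_C,eff (which depends on the
    current weights through S2_NC), rebuilds the conformer-level Gamma2
    matrix, and re-optimizes the weights. The tau update is damped
    (``tau_damping`` of the previous round retained) because the
    weights -> S2_NC -> tau -> Gamma2 feedback can overshoot on small
    ensembles. Stops after ``n_rounds`` or when max |dw| < ``tol``. A
    non-monotone ||dw||_1 trace over the last five rounds is flagged and
    the best-chi2 round returned.
    """
    n = model.ensemble.n_conformers
    w0 = np.full(n, 1.0 / n) if prior_weights is None \
        else np.asarray(prior_weights, float)
    w = w0.copy()
    trace, results = [], []
    sites = {r.site for r in restraints}
    tau_by_site = {s: model.tethered_tau(s, weights=w)[1] for s in sites}
    for round_k in range(n_rounds):
        if round_k > 0:
            for s in sites:
                new = model.tethered_tau(s, weights=w)[1]
                tau_by_site[s] = tau_damping * tau_by_site[s] \
                    + (1.0 - tau_damping) * new
        y = np.nan_to_num(_model_matrix(model, restraints, tau_by_site))
        res = optimize_weights(y, restraints, theta, prior_weights=w0)
        dw = float(np.abs(res.weights - w).max())
        trace.append(float(np.abs(res.weights - w).sum()))
        w = res.weights
        results.append(res)
        if dw < tol:
            break
    final = results[-1]
    if len(trace) >= 5:
        tail = trace[-5:]
        if any(tail[i + 1] > tail[i] * 1.5 for i in range(4)):
            best = int(np.argmin([r.chi2_red for r in results]))
            final = results[best]
            final.flags.append("weight oscillation; best-chi2 round returned")
    final.history = {"l1_weight_change": trace,
                     "chi2_red": [r.chi2_red for r in results]}
    return final
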