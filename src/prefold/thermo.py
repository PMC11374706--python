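"""Folding-equilibrium thermodynamics and 1D spectral fitting.

Temperature series of the folding equilibrium constant are fit to the
constant-heat-capacity Gibbs-Helmholtz form

    ln K(T) = -(dH_T0 + dCp (T - T0)) / (R T) + (dS_T0 + dCp ln(T/T0)) / R

(the van't Hoff line being the dCp = 0 special case), with parameter
uncertainties from the covariance diagonal. State populations come from
sums of Lorentzians fit to 1D spectra with residual-resampling bootstrap
errors; translational diffusion comes from the Stejskal-Tanner decay and
the Stokes-Einstein relation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import constants as c

__all__ = [
    "ThermoFit",
    "gibbs_helmholtz_fit",
    "vant_hoff_fit",
    "LorentzianPeak",
    "SpectrumPeaks",
    "lorentzian_fit",
    "dG_from_populations",
    "wildtype_dg_estimate",
    "stejskal_tanner_fit",
    "stokes_einstein",
    "r2_from_decay",
]


@dataclass
class ThermoFit:
    """Folding thermodynamic parameters at a reference temperature.

    dH_T0 in kcal/mol; dS_T0 and dCp in kcal/mol/K; covariance over
    (dH, dS, dCp), with zero rows/columns for fixed parameters.
    """

    dH_T0: float
    dS_T0: float
    dCp: float
    T0: float = 298.0
    covariance: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))

    def __post_init__(self):
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (3, 3):
            raise ValueError("covariance must be 3x3")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")

    @property
    def sds(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    @property
    def correlations(self) -> np.ndarray:
        sd = self.sds
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = self.covariance / np.outer(sd, sd)
        corr[~np.isfinite(corr)] = 0.0
        np.fill_diagonal(corr, 1.0)
        return corr

    def dH(self, T):
        return self.dH_T0 + self.dCp * (np.asarray(T, float) - self.T0)

    def dS(self, T):
        return self.dS_T0 + self.dCp * np.log(np.asarray(T, float) / self.T0)

    def dG(self, T):
        T = np.asarray(T, dtype=float)
        return self.dH(T) - T * self.dS(T)

    def minus_TdS(self, T):
        return -np.asarray(T, float) * self.dS(T)

    def lnK(self, T):
        T = np.asarray(T, dtype=float)
        return -self.dG(T) / (c.R_KCAL * T)

    def at_reference(self, T0_new: float) -> "ThermoFit":
        """Re-express the same fit at another reference temperature."""
        j = np.array([
            [1.0, 0.0, T0_new - self.T0],
            [0.0, 1.0, np.log(T0_new / self.T0)],
            [0.0, 0.0, 1.0]])
        cov = j @ self.covariance @ j.T
        return ThermoFit(float(self.dH(T0_new)), float(self.dS(T0_new)),
                         self.dCp, T0_new, cov)


def _lnk_model(T, dh, ds, dcp, T0):
    return (-(dh + dcp * (T - T0)) / (c.R_KCAL * T)
            + (ds + dcp * np.log(T / T0)) / c.R_KCAL)


def gibbs_helmholtz_fit(table: pd.DataFrame, T0: float = 298.0,
                        fix_dCp: float | None = None) -> ThermoFit:
    """Weighted nonlinear fit of ln K(T); columns T_K, lnK and optional sd.

    ``fix_dCp`` pins the heat capacity (0 gives the van't Hoff line).
    Warns when a free dCp is requested over a temperature span below 20 K,
    where the three parameters are nearly collinear.
    """
    T = np.asarray(table["T_K"], dtype=float)
    y = np.asarray(table["lnK"], dtype=float)
    sd = np.asarray(table["sd"], dtype=float) if "sd" in table else None
    free = 2 if fix_dCp is not None else 3
    if len(T) < free + 1:
        raise ValueError(f"need at least {free + 1} temperature points")
    if np.ptp(T) <= 0:
        raise ValueError("all temperatures identical: singular design")
    if fix_dCp is None and np.ptp(T) < 20.0:
        warnings.warn("temperature span < 20 K with free dCp: parameters "
                      "will be strongly correlated")
    sigma = None
    if sd is not None and np.all(sd > 0):
        sigma = sd
    if fix_dCp is not None:
        def model(T, dh, ds):
            return _lnk_model(T, dh, ds, fix_dCp, T0)
        p0 = (-10.0, -0.03)
        popt, pcov = curve_fit(model, T, y, p0=p0, sigma=sigma,
                               absolute_sigma=sigma is not None,
                               maxfev=20000)
        cov = np.zeros((3, 3))
        cov[:2, :2] = pcov
        return ThermoFit(popt[0], popt[1], fix_dCp, T0, cov)

    def model(T, dh, ds, dcp):
        return _lnk_model(T, dh, ds, dcp, T0)
    popt, pcov = curve_fit(model, T, y, p0=(-10.0, -0.03, -1.0), sigma=sigma,
                           absolute_sigma=sigma is not None, maxfev=20000)
    return ThermoFit(popt[0], popt[1], popt[2], T0, pcov)


def vant_hoff_fit(table: pd.DataFrame, T0: float = 298.0) -> ThermoFit:
    """Linear van't Hoff fit (dCp = 0)."""
    return gibbs_helmholtz_fit(table, T0=T0, fix_dCp=0.0)


@dataclass
class LorentzianPeak:
    center: float        # x units (e.g. ppm)
    half_width: float    # x units, half width at half maximum
    amplitude: float     # peak height
    integral: float      # amplitude * pi * half_width
    integral_sd: float = 0.0
    label: str = ""


@dataclass
class SpectrumPeaks:
    peaks: list[LorentzianPeak]
    populations: np.ndarray
    population_sds: np.ndarray
    residual_norm: float
    converged: bool = True

    def population(self, label: str) -> float:
        for p, pop in zip(self.peaks, self.populations):
            if p.label == label:
                return float(pop)
        raise KeyError(label)


def _lorentz_sum(x, *params):
    y = np.zeros_like(x)
    for k in range(len(params) // 3):
        x0, hw, a = params[3 * k: 3 * k + 3]
        y = y + a * hw ** 2 / ((x - x0) ** 2 + hw ** 2)
    return y


def lorentzian_fit(x, y, init, n_bootstrap: int = 200, seed: int = 0,
                   labels=None, noise_sd: float | None = None) -> SpectrumPeaks:
    """Fit a sum of Lorentzians to a 1D spectrum.

    ``init``: list of (center, half_width, amplitude) triples. Integrals
    are analytic (amplitude * pi * half_width); integral errors come from
    residual-resampling bootstrap; populations are normalized integrals.
    An undetectable state can be represented by passing ``noise_sd`` and a
    peak whose fitted amplitude falls below 3x the noise floor — its
    population is then reported as the corresponding upper limit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly monotone increasing")
    n_peaks = len(init)
    if n_peaks < 1:
        raise ValueError("need at least one peak")
    p0 = np.concatenate([np.asarray(t, float) for t in init])
    lo = np.tile([-np.inf, 1e-12, 0.0], n_peaks)
    hi = np.tile([np.inf, np.inf, np.inf], n_peaks)
    try:
        popt, _ = curve_fit(_lorentz_sum, x, y, p0=p0, bounds=(lo, hi),
                            maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    resid = y - _lorentz_sum(x, *popt)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_bootstrap, n_peaks))
    for b in range(n_bootstrap):
        yb = _lorentz_sum(x, *popt) + rng.choice(resid, size=len(x),
                                                 replace=True)
        try:
            pb, _ = curve_fit(_lorentz_sum, x, yb, p0=popt,
                              bounds=(lo, hi), maxfev=5000)
        except RuntimeError:
            pb = popt
        boot[b] = [pb[3 * k + 2] * np.pi * pb[3 * k + 1]
                   for k in range(n_peaks)]
    integrals = np.array([popt[3 * k + 2] * np.pi * popt[3 * k + 1]
                          for k in range(n_peaks)])
    integral_sds = boot.std(axis=0, ddof=1) / np.sqrt(1.0)
    if noise_sd is not None:
        # undetectable states: upper-limit integral from the noise floor
        for k in range(n_peaks):
            if popt[3 * k + 2] < 3.0 * noise_sd:
                integrals[k] = 3.0 * noise_sd * np.pi * popt[3 * k + 1]
    pops = integrals / integrals.sum()
    pop_sds = integral_sds / integrals.sum()
    labels = labels or [""] * n_peaks
    peaks = [LorentzianPeak(popt[3 * k], popt[3 * k + 1], popt[3 * k + 2],
                            integrals[k], integral_sds[k], labels[k])
             for k in range(n_peaks)]
    return SpectrumPeaks(peaks, pops, pop_sds,
                         float(np.linalg.norm(resid)), converged)


def dG_from_populations(p_folded: float, p_unfolded: float,
                        T: float = 298.0) -> float:
    """Folding free energy dG = -RT ln(p_folded / p_unfolded), kcal/mol."""
    if p_folded <= 0 or p_unfolded <= 0:
        raise ValueError("populations must be positive; use a bound for an "
                         "undetected state")
    return float(-c.R_KCAL * T * np.log(p_folded / p_unfolded))


def wildtype_dg_estimate(mutant_dgs_rnc, mutant_ddgs_iso):
    """Wild-type RNC folding free energy from destabilized mutants.

    dG_WT = mean over mutants of (dG_mut,RNC - ddG_mut-WT,iso); the spread
    (half-range) is reported alongside.
    """
    rnc = np.asarray(mutant_dgs_rnc, dtype=float)
    iso = np.asarray(mutant_ddgs_iso, dtype=float)
    if rnc.shape != iso.shape or rnc.size == 0:
        raise ValueError("need matching, non-empty mutant value lists")
    estimates = rnc - iso
    return float(estimates.mean()), float(np.ptp(estimates) / 2.0)


def stejskal_tanner_fit(gradient_strengths, intensities, delta: float,
                        Delta: float, gamma: float = c.GAMMA_H):
    """Translational diffusion coefficient from a pulsed-field-gradient decay.

    I(g) = I0 exp(-D (gamma delta g)^2 (Delta - delta/3)); returns (D, sd)
    in m^2/s. ``delta``/``Delta`` are the gradient pulse length and
    diffusion delay in s, g in T/m. Non-monotone decays beyond noise are
    flagged with a warning.
    """
    g = np.asarray(gradient_strengths, dtype=float)
    I = np.asarray(intensities, dtype=float)
    if len(g) < 4:
        raise ValueError("need at least 4 gradient points")
    if np.any(I <= 0):
        raise ValueError("intensities must be positive")
    order = np.argsort(g)
    if np.any(np.diff(I[order]) > 0.05 * I.max()):
        warnings.warn("non-monotone intensity decay beyond noise")
    b = (gamma * delta * g) ** 2 * (Delta - delta / 3.0)
    coeffs, cov = np.polyfit(b, np.log(I), 1, cov=True)
    return float(-coeffs[0]), float(np.sqrt(cov[0, 0]))


def stokes_einstein(D: float, viscosity: float, T: float) -> float:
    """Hydrodynamic radius (Å) from a diffusion coefficient (m^2/s)
    and viscosity (Pa s): R_h = k_B T / (6 pi eta D)."""
    if D <= 0 or viscosity <= 0 or T <= 0:
        raise ValueError("D, viscosity and T must be positive")
    return float(c.KB_SI * T / (6.0 * np.pi * viscosity * D) / c.ANGSTROM)


def r2_from_decay(delays, integrals, sigma=None):
    """Transverse relaxation rate from a Hahn-echo decay.

    Single-exponential weighted fit I(t) = I0 exp(-R2 t); returns
    (R2, sd) in s^-1. Negative fitted rates are flagged with a warning.
    """
    t = np.asarray(delays, dtype=float)
    I = np.asarray(integrals, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 delays")

    def model(t, i0, r2):
        return i0 * np.exp(-r2 * t)

    popt, pcov = curve_fit(model, t, I, p0=(I.max(), 1.0 / max(t.mean(), 1e-9)),
                           sigma=sigma, absolute_sigma=sigma is not None,
                           maxfev=20000)
    r2 = float(popt[1])
    if r2 < 0:
        warnings.warn("negative fitted relaxation rate")
    return r2, float(np.sqrt(pcov[1, 1]))
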