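"""Ground-truth synthetic datasets for recovery tests.

Forward-generated PRE restraint tables (from a known truth ensemble and
known weights) and folding-equilibrium temperature series (from known
thermodynamic parameters) let every downstream estimator be tested for
parameter/weight recovery without any external data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import constants as c
from .ensemble import Ensemble
from .pre import PREEnsembleModel, PREParameters, intensity_ratio
from .reweight import ISOLATED_BOUNDS, RestraintSet, restraints_from_ratios

__all__ = ["synth_pre_dataset", "synth_keq_series", "gibbs_helmholtz_lnK"]


def synth_pre_dataset(truth: Ensemble, sites, pre_params: PREParameters,
                      noise_sd: float, seed: int,
                      bounds: dict | None = None,
                      library=None) -> tuple[RestraintSet, PREEnsembleModel]:
    """Noisy PRE intensity-ratio restraints from a known truth ensemble.

    Forward-calculates ratios via the full rotamer PRE model under the
    truth weights, adds Gaussian noise (sd ``noise_sd``), clips to
    [0, 1.2], and classifies restraints by the standard bound rules.
    Returns the restraint set and the forward model (which the caller can
    reuse with different weights). Deterministic for a given seed.
    """
    if bounds is None:
        bounds = ISOLATED_BOUNDS
    rng = np.random.default_rng(seed)
    model = PREEnsembleModel(truth, sites, pre_params, library)
    rows = []
    for s in model.sites:
        g = model.mean_gamma2(s)
        ratio = intensity_ratio(g, pre_params.R2_H, pre_params.R2_MQ,
                                pre_params.delta_HMQC)
        for rid, rat in zip(model.residue_ids, ratio):
            if not np.isfinite(rat) or rid == s:
                continue
            noisy = rat + rng.normal(0.0, noise_sd) if noise_sd > 0 else rat
            noisy = float(np.clip(noisy, 0.0, 1.2))
            # noise-free datasets still carry a realistic uncertainty so
            # downstream chi^2 scales stay well conditioned
            rows.append({"site": s, "residue": int(rid), "ratio": noisy,
                         "ratio_err": noise_sd if noise_sd > 0 else 0.01})
    table = pd.DataFrame(rows)
    restraints = restraints_from_ratios(
        table, R2_H=pre_params.R2_H, R2_MQ=pre_params.R2_MQ,
        delta=pre_params.delta_HMQC, bounds=bounds)
    return restraints, model


def gibbs_helmholtz_lnK(T, dH0: float, dS0: float, dCp: float,
                        T0: float = 298.0) -> np.ndarray:
    """ln K_eq(T) for constant-dCp folding thermodynamics.

    ln K = -(dH0 + dCp (T - T0)) / (R T) + (dS0 + dCp ln(T/T0)) / R,
    with dH0 in kcal/mol, dS0 and dCp in kcal/mol/K, T in K.
    """
    T = np.asarray(T, dtype=float)
    return (-(dH0 + dCp * (T - T0)) / (c.R_KCAL * T)
            + (dS0 + dCp * np.log(T / T0)) / c.R_KCAL)


def synth_keq_series(dH0: float, dS0: float, dCp: float, T0: float,
                     temperatures, noise_sd: float = 0.0,
                     seed: int = 0) -> pd.DataFrame:
    """Noisy ln K_eq(T) table from known (dH, dS, dCp) at T0.

    Returns a DataFrame with columns T_K, lnK, sd. Temperatures in K.
    """
    T = np.asarray(temperatures, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive (Kelvin)")
    lnk = gibbs_helmholtz_lnK(T, dH0, dS0, dCp, T0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        lnk = lnk + rng.normal(0.0, noise_sd, size=len(T))
    return pd.DataFrame({"T_K": T, "lnK": lnk,
                         "sd": np.full(len(T), max(noise_sd, 1e-12))})
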