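"""Conformational-entropy and solvation-thermodynamics estimators, and the
ribosome-binding free-energy model.

Conformational entropy follows the torsion-histogram scheme: per-residue
entropies S = -k_B sum p ln p over joint torsion-angle histograms, with the
residue-class rules

    Pro/Gly/Ala            S[P(phi, psi)]
    residues with <= 2 chi S[P(phi, psi, chi1, chi2)]
    residues with  > 2 chi S[P(phi, psi, chi1)] + sum_n S[P(chi_n)] - S[P(chi1)]

Solvation thermodynamics come from empirical surface-area relations:

    dC            = alpha * dASA_apolar + beta * dASA_polar
    dH_solv(333K) = gamma * dASA_apolar + delta * dASA_polar
    dS_solv(T)    = dC_apolar ln(T/385) - dC_polar ln(T/335)   (as printed)
    dG_solv       = dH_solv - T dS_solv

The minus sign on the polar entropy term is implemented as printed in the
source relation, with a ``polar_sign="standard"`` toggle for the all-plus
convention; results report which convention produced them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as c
from .ensemble import Ensemble
from .geometry import dihedral

__all__ = [
    "TorsionEntropyScheme",
    "SolvationParams",
    "BindingModelParams",
    "histogram_entropy",
    "conformational_entropy",
    "entropy_difference",
    "solvation_thermo",
    "binding_dG",
    "p_bound_from_tau",
    "ensemble_energetic_summary",
]

# number of sidechain chi torsions per residue type
N_CHI = {
    "ALA": 0, "GLY": 0, "SER": 1, "CYS": 1, "THR": 1, "VAL": 1,
    "ASP": 2, "ASN": 2, "PHE": 2, "TYR": 2, "TRP": 2, "HIS": 2,
    "ILE": 2, "LEU": 2, "PRO": 2, "MET": 3, "GLU": 3, "GLN": 3,
    "LYS": 4, "ARG": 4,
}

# chi1..chi4 atom quadruples (names along the sidechain)
_CHI_ATOMS = [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
              ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")]


@dataclass
class TorsionEntropyScheme:
    """Histogram resolution for the torsion-entropy estimator.

    50 bins/dimension for 2D backbone histograms; joint histograms in three
    or more dimensions default to 12 bins/dimension because a 50-bin joint
    grid is unpopulatable at any realistic ensemble size.
    """

    bins_2d: int = 50
    bins_joint: int = 12

    def __post_init__(self):
        if self.bins_2d < 2 or self.bins_joint < 2:
            raise ValueError("need at least 2 bins per dimension")


def histogram_entropy(samples: np.ndarray, bins: int,
                      weights=None) -> float:
    """-k_B sum p ln p (cal/mol/K) of a joint torsion histogram.

    ``samples``: (n, d) angles in radians, binned on [-pi, pi] per
    dimension.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    d = x.shape[1]
    edges = [np.linspace(-np.pi, np.pi, bins + 1)] * d
    hist, _ = np.histogramdd(x, bins=edges, weights=weights)
    p = hist.ravel()
    total = p.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    p = p / total
    p = p[p > 0]
    return float(-c.KB_CAL * np.sum(p * np.log(p)))


def _backbone_dihedrals(ensemble: Ensemble):
    """(phi, psi) arrays of shape (n_conf, n_res), NaN where undefined."""
    top = ensemble.topology
    ids = top.residue_ids
    n_conf, n_res = ensemble.n_conformers, top.n_residues
    phi = np.full((n_conf, n_res), np.nan)
    psi = np.full((n_conf, n_res), np.nan)
    idx = {}
    for r, rid in enumerate(ids):
        for nm in ("N", "CA", "C"):
            if top.has_atom(rid, nm):
                idx[(r, nm)] = top.atom_index(rid, nm)
    for a, x in enumerate(ensemble.coordinates):
        for r in range(n_res):
            if r > 0 and all(k in idx for k in
                             [(r - 1, "C"), (r, "N"), (r, "CA"), (r, "C")]):
                phi[a, r] = dihedral(x[idx[(r - 1, "C")]], x[idx[(r, "N")]],
                                     x[idx[(r, "CA")]], x[idx[(r, "C")]])
            if r < n_res - 1 and all(k in idx for k in
                                     [(r, "N"), (r, "CA"), (r, "C"),
                                      (r + 1, "N")]):
                psi[a, r] = dihedral(x[idx[(r, "N")]], x[idx[(r, "CA")]],
                                     x[idx[(r, "C")]], x[idx[(r + 1, "N")]])
    return phi, psi


def _chi_angles(ensemble: Ensemble, residue_id: int, n_chi: int):
    """Available chi torsions (n_conf, n_avail); fewer when atoms missing."""
    top = ensemble.topology
    cols = []
    for k in range(n_chi):
        names = _CHI_ATOMS[k]
        if not all(top.has_atom(residue_id, nm) for nm in names):
            break
        idx = [top.atom_index(residue_id, nm) for nm in names]
        col = np.array([dihedral(*(x[i] for i in idx))
                        for x in ensemble.coordinates])
        cols.append(col)
    if not cols:
        return np.empty((ensemble.n_conformers, 0))
    return np.stack(cols, axis=1)


def conformational_entropy(ensemble: Ensemble,
                           scheme: TorsionEntropyScheme | None = None,
                           weights=None):
    """Per-residue and total conformational entropy (cal/mol/K).

    Residues whose class requires chi torsions but whose sidechain atoms
    are absent (e.g. Cα- or backbone-only models) fall back to the
    backbone (phi, psi) histogram with a warning.
    """
    import warnings
    if scheme is None:
        scheme = TorsionEntropyScheme()
    top = ensemble.topology
    w = ensemble.weights if weights is None else np.asarray(weights, float)
    phi, psi = _backbone_dihedrals(ensemble)
    per_res = np.full(top.n_residues, np.nan)
    warned = False
    for r, rid in enumerate(top.residue_ids):
        ok = np.isfinite(phi[:, r]) & np.isfinite(psi[:, r])
        if not ok.any():
            continue
        bb = np.stack([phi[ok, r], psi[ok, r]], axis=1)
        ww = w[ok] / w[ok].sum()
        resname = top.residue_names[r]
        n_chi = N_CHI.get(resname, 0)
        chi = _chi_angles(ensemble, rid, n_chi)[ok]
        if n_chi > 0 and chi.shape[1] < n_chi and not warned:
            warnings.warn("missing sidechain atoms: backbone-only entropy "
                          "for some residues")
            warned = True
        if resname in ("PRO", "GLY", "ALA") or chi.shape[1] == 0:
            per_res[r] = histogram_entropy(bb, scheme.bins_2d, ww)
        elif n_chi <= 2:
            joint = np.concatenate([bb, chi[:, :2]], axis=1)
            per_res[r] = histogram_entropy(joint, scheme.bins_joint, ww)
        else:
            s = histogram_entropy(np.concatenate([bb, chi[:, :1]], axis=1),
                                  scheme.bins_joint, ww)
            s1 = histogram_entropy(chi[:, :1], scheme.bins_2d, ww)
            for k in range(chi.shape[1]):
                s += histogram_entropy(chi[:, k:k + 1], scheme.bins_2d, ww)
            per_res[r] = s - s1
    total = float(np.nansum(per_res))
    return top.residue_ids, per_res, total


def entropy_difference(ensemble_a: Ensemble, ensemble_b: Ensemble,
                       scheme: TorsionEntropyScheme | None = None,
                       T: float = 298.0):
    """dS (a - b) per residue and total, with -T dS in kcal/mol."""
    ids_a, per_a, tot_a = conformational_entropy(ensemble_a, scheme)
    ids_b, per_b, tot_b = conformational_entropy(ensemble_b, scheme)
    if not np.array_equal(ids_a, ids_b):
        raise ValueError("ensembles do not share a residue numbering")
    d_per = per_a - per_b
    d_tot = tot_a - tot_b
    return ids_a, d_per, d_tot, -T * d_tot / 1000.0


@dataclass
class SolvationParams:
    """Empirical surface-area coefficients (cal mol^-1 [K^-1] Å^-2)."""

    alpha: float = 0.34
    alpha_sd: float = 0.11
    beta: float = -0.12
    beta_sd: float = 0.12
    gamma: float = -8.44
    delta: float = 31.4
    gamma_delta_rel_sd: float = 0.50
    T_apolar: float = 385.0
    T_polar: float = 335.0
    T_ref: float = 333.0

    def __post_init__(self):
        if min(self.T_apolar, self.T_polar, self.T_ref) <= 0:
            raise ValueError("temperatures must be positive")


def solvation_thermo(dasa_apolar: float, dasa_polar: float, T: float = 298.0,
                     params: SolvationParams | None = None,
                     polar_sign: str = "printed") -> dict:
    """Solvation heat capacity, enthalpy, entropy and free energy.

    Inputs in Å²; outputs in kcal/mol (dC in kcal/mol/K) with first-order
    propagated parameter uncertainties. ``polar_sign``: "printed" keeps the
    minus sign on the polar entropy term of the source relation;
    "standard" uses the all-plus convention.
    """
    if T <= 0:
        raise ValueError("T must be positive (Kelvin)")
    if polar_sign not in ("printed", "standard"):
        raise ValueError("polar_sign must be 'printed' or 'standard'")
    p = params or SolvationParams()
    sign = -1.0 if polar_sign == "printed" else 1.0
    ap, po = float(dasa_apolar), float(dasa_polar)

    dc_ap = p.alpha * ap / 1000.0            # kcal/mol/K
    dc_po = p.beta * po / 1000.0
    dc = dc_ap + dc_po
    dh_ref = (p.gamma * ap + p.delta * po) / 1000.0
    dh = dh_ref + dc * (T - p.T_ref)
    ds = dc_ap * np.log(T / p.T_apolar) + sign * dc_po * np.log(T / p.T_polar)
    dg = dh - T * ds

    # first-order propagation over (alpha, beta, gamma, delta)
    s_al, s_be = p.alpha_sd, p.beta_sd
    s_ga = abs(p.gamma) * p.gamma_delta_rel_sd
    s_de = abs(p.delta) * p.gamma_delta_rel_sd
    dc_sd = np.hypot(s_al * ap, s_be * po) / 1000.0
    dh_sd = np.sqrt((s_ga * ap) ** 2 + (s_de * po) ** 2
                    + ((T - p.T_ref) * 1000.0 * dc_sd) ** 2) / 1000.0
    ds_sd = np.hypot(s_al * ap / 1000.0 * np.log(T / p.T_apolar),
                     s_be * po / 1000.0 * np.log(T / p.T_polar))
    dg_dal = ap / 1000.0 * ((T - p.T_ref) - T * np.log(T / p.T_apolar))
    dg_dbe = po / 1000.0 * ((T - p.T_ref) - sign * T * np.log(T / p.T_polar))
    dg_sd = np.sqrt((s_al * dg_dal) ** 2 + (s_be * dg_dbe) ** 2
                    + (s_ga * ap / 1000.0) ** 2 + (s_de * po / 1000.0) ** 2)

    return {
        "dC": dc, "dC_sd": float(dc_sd),
        "dH_solv": float(dh), "dH_solv_sd": float(dh_sd),
        "dS_solv": float(ds), "dS_solv_sd": float(ds_sd),
        "minus_T_dS_solv": float(-T * ds),
        "minus_T_dS_solv_sd": float(T * ds_sd),
        "dG_solv": float(dg), "dG_solv_sd": float(dg_sd),
        "T": T, "polar_sign": polar_sign,
    }


@dataclass
class BindingModelParams:
    """Rotational-correlation-time interpolation for the bound population."""

    tau_c_iso: float = 7.7       # ns, free protein at 298 K
    tau_c_bound: float = 3003.0  # ns, ribosome tumbling
    S2_bound: float = 1.0        # rigidity of the bound state

    def __post_init__(self):
        if not (0 < self.S2_bound <= 1):
            raise ValueError("S2_bound must be in (0, 1]")
        if self.S2_bound * self.tau_c_bound <= self.tau_c_iso:
            raise ValueError("scaled tau_c_bound must exceed tau_c_iso")


def p_bound_from_tau(tau_exp: float,
                     params: BindingModelParams | None = None) -> float:
    """Fraction bound from a measured rotational correlation time (ns).

    p_B = (tau_exp - tau_iso) / (S2_bound * tau_bound - tau_iso).
    """
    p = params or BindingModelParams()
    hi = p.S2_bound * p.tau_c_bound
    if not (p.tau_c_iso <= tau_exp <= hi):
        raise ValueError("tau_exp outside [tau_iso, scaled tau_bound]")
    return float((tau_exp - p.tau_c_iso) / (hi - p.tau_c_iso))


def binding_dG(p_bound: float, T: float = 298.0) -> float:
    """Stabilization from surface binding: ddG = RT ln(1 - p_B), kcal/mol.

    Negative (the bound species is stabilized); its magnitude is the
    unfolded-state destabilization of folding.
    """
    if not (0 <= p_bound < 1):
        raise ValueError("p_bound must be in [0, 1)")
    return float(c.R_KCAL * T * np.log(1.0 - p_bound))


def ensemble_energetic_summary(ensemble_rnc: Ensemble, ensemble_iso: Ensemble,
                               T: float = 298.0,
                               scheme: TorsionEntropyScheme | None = None,
                               solvation: SolvationParams | None = None,
                               n_blocks: int = 2,
                               binding_dg: float | None = None,
                               sasa_points: int = 240) -> dict:
    """Energetic changes of the unfolded state on vs off the ribosome.

    Combines the conformational-entropy difference, the polar/apolar
    surface-area differences (protein atoms only; context atoms excluded)
    and the surface-area solvation model into the component table
    (-T dS_conf, dASA, dC, dH_solv, -T dS_solv, dG contributions), with
    errors combined from half-data block SEMs and the empirical parameter
    uncertainties. Sign convention: positive dASA = more exposed on the
    ribosome.
    """
    from .observables import ensemble_sasa
    top_r, top_i = ensemble_rnc.topology, ensemble_iso.topology
    if list(top_r.residue_names) != list(top_i.residue_names):
        raise ValueError("ensembles do not share a sequence/topology")

    def _blocks(ens):
        n = ens.n_conformers
        size = n // n_blocks
        return [ens.subset(np.arange(k * size, (k + 1) * size))
                for k in range(n_blocks)]

    def _block_sem(vals):
        v = np.asarray(vals, float)
        return float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0

    # conformational entropy difference with half-data block error
    _, _, d_tot, minus_tds_conf = entropy_difference(
        ensemble_rnc, ensemble_iso, scheme, T)
    block_tds = []
    for br, bi in zip(_blocks(ensemble_rnc), _blocks(ensemble_iso)):
        block_tds.append(entropy_difference(br, bi, scheme, T)[3])
    tds_conf_sem = _block_sem(block_tds)

    # surface areas (weighted means) with per-conformer block error
    sas_r = ensemble_sasa(ensemble_rnc, n_points=sasa_points)
    sas_i = ensemble_sasa(ensemble_iso, n_points=sasa_points)
    d_ap = sas_r["apolar"] - sas_i["apolar"]
    d_po = sas_r["polar"] - sas_i["polar"]
    d_tot_asa = sas_r["total"] - sas_i["total"]
    from .ensemble import block_sem as _bs
    sem_r = _bs(sas_r["per_conformer_total"], ensemble_rnc.weights,
                n_blocks).sem
    sem_i = _bs(sas_i["per_conformer_total"], ensemble_iso.weights,
                n_blocks).sem
    dasa_sem = float(np.hypot(sem_r, sem_i))

    sol = solvation_thermo(d_ap, d_po, T, solvation)
    total_tds = minus_tds_conf + sol["minus_T_dS_solv"]
    out = {
        "T": T,
        "minus_T_dS_conf": minus_tds_conf,
        "minus_T_dS_conf_sem": tds_conf_sem,
        "dASA_total": d_tot_asa, "dASA_apolar": d_ap, "dASA_polar": d_po,
        "dASA_sem": dasa_sem,
        "dC": sol["dC"], "dC_sd": sol["dC_sd"],
        "dH_solv": sol["dH_solv"], "dH_solv_sd": sol["dH_solv_sd"],
        "minus_T_dS_solv": sol["minus_T_dS_solv"],
        "minus_T_dS_solv_sd": sol["minus_T_dS_solv_sd"],
        "minus_T_dS_total": total_tds,
        "dG_solv": sol["dG_solv"], "dG_solv_sd": sol["dG_solv_sd"],
        "polar_sign": sol["polar_sign"],
    }
    if binding_dg is not None:
        out["ribosome_binding_dG"] = float(binding_dg)
        out["dG_total"] = total_tds + sol["dH_solv"] + float(binding_dg)
    else:
        out["dG_total"] = total_tds + sol["dH_solv"]
    return out
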