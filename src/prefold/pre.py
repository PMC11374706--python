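"""Forward calculation of paramagnetic relaxation enhancements.

Transverse PRE rates of backbone amide protons are computed with the
Solomon-Bloembergen equation using a model-free spectral density for a
flexible label:

    Gamma2 = (1/15) (mu0/4pi)^2 gammaH^2 ge^2 muB^2 S(S+1) [4 J(0) + 3 J(wH)]
    J(w)   = <r^-6> [ S2 tau_c / (1 + (w tau_c)^2) + (1 - S2) tau_t / (1 + (w tau_t)^2) ]
    tau_t  = (tau_c^-1 + tau_i^-1)^-1

where r is the electron-proton distance over the rotamer ensemble at a
labelling site and S2 = S2_angular * S2_radial is the order parameter of
the electron-proton vector (radial part <r^-6>^-1 <r^-3>^2; angular part
from second-order spherical harmonics). The electron spin relaxation time
is neglected (tau_c ~ tau_r).

The literature form of the prefactor uses S(S+1) with electron spin
S = 1/2; a variant with S(S-1) exists in print and is available behind the
``printed_spin_prefactor`` toggle — it is not the default because it
vanishes for S = 1/2.

For ribosome-tethered chains the tumbling of each electron-amide vector is
slowed according to its nascent-chain order parameter S2_NC over the whole
ensemble, interpolating between free-chain and ribosome correlation times:
tau_C,eff = S2_NC * tau_r,70S + (1 - S2_NC) * tau_C,iso.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from . import constants as c
from .ensemble import Ensemble
from .geometry import superpose
from .rotamers import RotamerLibrary, default_library

__all__ = [
    "PREParameters",
    "SiteAttachment",
    "attach_rotamers",
    "gamma2_single_conformer",
    "ensemble_gamma2",
    "PREEnsembleModel",
    "tethered_correlation_time",
    "intensity_ratio",
    "gamma2_from_ratio",
    "reference_profile",
]

_BACKBONE_CLASH_ATOMS = ("N", "CA", "C", "O", "CB")


@dataclass
class PREParameters:
    """Physical parameters of the PRE forward model (SI units for times)."""

    field_MHz: float = 800.0          # 1H Larmor frequency
    tau_i: float = 500e-12            # label internal correlation time, s
    tau_c: float = 5e-9               # chain rotational correlation time, s
    tau_r_70S: float = 4.3e-6         # ribosome tumbling at 283 K in water, s
    tau_c_iso: float = 3e-9           # free-chain tau_C for tethering interpolation
    delta_HMQC: float = 5.43e-3       # PRE evolution delay, s
    R2_H: float = 100.0               # 1H linewidth rate, s^-1
    R2_MQ: float = 100.0              # multiple-quantum linewidth rate, s^-1
    S_spin: float = 0.5               # electron spin quantum number
    printed_spin_prefactor: bool = False  # use S(S-1) instead of S(S+1)
    clash_cutoff: float = 2.5         # Å, strict < is a clash

    @property
    def omega_H(self) -> float:
        return 2.0 * np.pi * self.field_MHz * 1e6

    @property
    def prefactor(self) -> float:
        """(1/15)(mu0/4pi)^2 gammaH^2 ge^2 muB^2 S(S+1), SI (m^6 s^-2)."""
        spin = self.S_spin * (self.S_spin - 1.0) if self.printed_spin_prefactor \
            else self.S_spin * (self.S_spin + 1.0)
        k = (c.MU_0 / (4.0 * np.pi)) ** 2 * c.GAMMA_H ** 2 * c.G_E ** 2 * c.MU_B ** 2
        return k * spin / 15.0


@dataclass
class SiteAttachment:
    """Rotamers surviving the steric clash filter at one labelling site."""

    site_residue: int
    allowed: np.ndarray            # surviving rotamer indices
    electron_positions: np.ndarray  # (n_allowed, 3), Å, conformer frame
    rotamer_weights: np.ndarray    # normalized over the surviving set
    clash_cutoff: float = 2.5

    @property
    def n_allowed(self) -> int:
        return len(self.allowed)


def attach_rotamers(conformer_coords: np.ndarray, topology,
                    site_residue: int,
                    library: RotamerLibrary | None = None,
                    clash_cutoff: float = 2.5) -> SiteAttachment:
    """Superpose the rotamer library onto a labelling site and clash-filter.

    The library backbone frame (N, CA, C and CB when the site has one) is
    least-squares superposed onto the site; rotamers with any heavy atom
    strictly within ``clash_cutoff`` of any protein backbone/CB atom outside
    the site residue are discarded. An empty surviving set is a valid
    result — the caller discards such conformers.
    """
    if library is None:
        library = default_library()
    x = np.asarray(conformer_coords)
    frame_names = ["N", "CA", "C", "CB"]
    if not topology.has_atom(site_residue, "CB"):
        frame_names = ["N", "CA", "C"]
    site_idx = [topology.atom_index(site_residue, nm) for nm in frame_names]
    target = x[site_idx]
    mobile = library.backbone_frame[:len(frame_names)]
    n_rot, n_atoms, _ = library.sidechain.shape
    stacked = np.concatenate(
        [library.sidechain.reshape(-1, 3), library.electron], axis=0)
    moved = superpose(mobile, target, apply_to=stacked)
    side = moved[:n_rot * n_atoms].reshape(n_rot, n_atoms, 3)
    electrons = moved[n_rot * n_atoms:]

    clash_idx = [i for i, nm in enumerate(topology.atom_names)
                 if nm in _BACKBONE_CLASH_ATOMS]
    site_res_slot = int(np.searchsorted(topology.residue_ids, site_residue))
    clash_idx = [i for i in clash_idx
                 if topology.atom_resindex[i] != site_res_slot]
    if clash_idx:
        prot = x[clash_idx]
        d = np.linalg.norm(side[:, :, None, :] - prot[None, None, :, :], axis=-1)
        min_d = d.min(axis=(1, 2))
        allowed = np.nonzero(min_d >= clash_cutoff)[0]
    else:
        allowed = np.arange(n_rot)
    w = library.weights[allowed]
    if w.sum() > 0:
        w = w / w.sum()
    return SiteAttachment(site_residue, allowed, electrons[allowed], w,
                          clash_cutoff)


def _vector_moments(vectors: np.ndarray, weights: np.ndarray):
    """Weighted <r^-6>, <r^-3> (Å^-6, Å^-3) and angular S2 of a vector set.

    ``vectors``: (..., k, 3); ``weights``: (k,). Returns arrays of the
    leading shape.
    """
    r = np.linalg.norm(vectors, axis=-1)
    r6 = np.einsum("k,...k->...", weights, r ** -6.0)
    r3 = np.einsum("k,...k->...", weights, r ** -3.0)
    u = vectors / r[..., None]
    m = np.einsum("k,...ki,...kj->...ij", weights, u, u)
    tr_m2 = np.einsum("...ij,...ji->...", m, m)
    s2_ang = np.clip((3.0 * tr_m2 - 1.0) / 2.0, 0.0, 1.0)
    return r6, r3, s2_ang


def _gamma2_from_moments(r6_A, r3_A, s2_ang, tau_c, params: PREParameters):
    """Gamma2 (s^-1) from Å-unit radial moments and the angular S2."""
    r6 = np.asarray(r6_A, dtype=float) / c.ANGSTROM ** 6
    r3 = np.asarray(r3_A, dtype=float) / c.ANGSTROM ** 3
    s2_rad = np.where(r6 > 0, r3 ** 2 / np.where(r6 > 0, r6, 1.0), 0.0)
    s2 = np.clip(np.asarray(s2_ang) * s2_rad, 0.0, 1.0)
    tau_c = np.asarray(tau_c, dtype=float)
    tau_t = 1.0 / (1.0 / tau_c + 1.0 / params.tau_i)
    w = params.omega_H

    def j(omega):
        return r6 * (s2 * tau_c / (1.0 + (omega * tau_c) ** 2)
                     + (1.0 - s2) * tau_t / (1.0 + (omega * tau_t) ** 2))

    return params.prefactor * (4.0 * j(0.0) + 3.0 * j(w))


def _amide_h_indices(topology):
    """Per-residue flat index of the amide H, or -1 where absent."""
    out = np.full(topology.n_residues, -1, dtype=int)
    for slot, rid in enumerate(topology.residue_ids):
        if topology.has_atom(rid, "H"):
            out[slot] = topology.atom_index(rid, "H")
    return out


def gamma2_single_conformer(conformer_coords: np.ndarray, topology,
                            attachment: SiteAttachment, residue: int,
                            params: PREParameters,
                            tau_c: float | None = None) -> float:
    """Rotamer-averaged Gamma2 (s^-1) at one residue of one conformer.

    Returns NaN (with no error) for residues lacking an amide proton
    (proline, chain start).
    """
    if attachment.n_allowed == 0:
        raise ValueError("attachment has no surviving rotamers")
    if not topology.has_atom(residue, "H"):
        return float("nan")
    h = np.asarray(conformer_coords)[topology.atom_index(residue, "H")]
    vec = h[None, :] - attachment.electron_positions
    r6, r3, s2a = _vector_moments(vec[None, ...], attachment.rotamer_weights)
    tau = params.tau_c if tau_c is None else tau_c
    return float(_gamma2_from_moments(r6, r3, s2a, tau, params)[0])


class PREEnsembleModel:
    """Cached per-conformer PRE moments for an ensemble and a set of sites.

    Rotamer attachment and the radial/angular moments are computed once;
    Gamma2 profiles for any correlation-time assignment (and hence any
    reweighting round) are then cheap. Conformers for which at least one
    site admits no rotamer are discarded and the weights renormalized.
    """

    def __init__(self, ensemble: Ensemble, sites, params: PREParameters,
                 library: RotamerLibrary | None = None):
        if library is None:
            library = default_library()
        self.params = params
        self.sites = list(sites)
        top = ensemble.topology
        h_idx = _amide_h_indices(top)
        self.observable = h_idx >= 0            # per-residue mask
        kept, per_site_electrons = [], {s: [] for s in self.sites}
        per_site_weights = {s: [] for s in self.sites}
        for a in range(ensemble.n_conformers):
            atts = [attach_rotamers(ensemble.coordinates[a], top, s, library,
                                    params.clash_cutoff) for s in self.sites]
            if any(att.n_allowed == 0 for att in atts):
                continue
            kept.append(a)
            for s, att in zip(self.sites, atts):
                per_site_electrons[s].append(att.electron_positions)
                per_site_weights[s].append(att.rotamer_weights)
        if not kept:
            raise ValueError("every conformer was discarded by the clash filter")
        self.ensemble = ensemble.subset(np.asarray(kept))
        n_conf = self.ensemble.n_conformers
        n_res = top.n_residues
        self.residue_ids = top.residue_ids
        # per site: (n_conf, n_res) moment arrays
        self.moments = {}
        h_pos = np.array([
            [self.ensemble.coordinates[a][h_idx[r]] if h_idx[r] >= 0
             else np.full(3, np.nan) for r in range(n_res)]
            for a in range(n_conf)])
        for s in self.sites:
            r6 = np.empty((n_conf, n_res))
            r3 = np.empty((n_conf, n_res))
            s2a = np.empty((n_conf, n_res))
            for a in range(n_conf):
                vec = h_pos[a][:, None, :] - per_site_electrons[s][a][None, :, :]
                r6[a], r3[a], s2a[a] = _vector_moments(
                    vec, per_site_weights[s][a])
            self.moments[s] = (r6, r3, s2a)
        # site CA positions, for the tethered-vector order parameter
        self.site_ca = {
            s: self.ensemble.coordinates[:, top.atom_index(s, "CA"), :]
            for s in self.sites}
        self.h_pos = h_pos

    def conformer_gamma2(self, site, tau_c=None) -> np.ndarray:
        """(n_conf, n_res) Gamma2 matrix; NaN where no amide H.

        ``tau_c``: scalar or per-residue array of correlation times (s).
        """
        r6, r3, s2a = self.moments[site]
        tau = self.params.tau_c if tau_c is None else np.asarray(tau_c)
        g = _gamma2_from_moments(r6, r3, s2a, tau, self.params)
        g[:, ~self.observable] = np.nan
        return g

    def mean_gamma2(self, site, weights=None, tau_c=None) -> np.ndarray:
        """Weighted ensemble-average Gamma2 per residue."""
        w = self.ensemble.weights if weights is None else np.asarray(weights)
        return np.einsum("a,ar->r", w, self.conformer_gamma2(site, tau_c))

    def tethered_tau(self, site, weights=None):
        """(S2_NC, tau_C,eff) per residue for a ribosome-tethered ensemble.

        The electron is approximated by the Cα of the labelling site; the
        order parameter is taken over the weighted conformer ensemble and
        interpolates tau between ribosome and free-chain tumbling.
        """
        w = self.ensemble.weights if weights is None else np.asarray(weights)
        vec = self.h_pos - self.site_ca[site][:, None, :]   # (conf, res, 3)
        with np.errstate(invalid="ignore"):
            r6, r3, s2a = _vector_moments(
                np.moveaxis(vec, 0, 1), w)                  # (res,)
            s2_rad = np.where(r6 > 0, r3 ** 2 / np.where(r6 > 0, r6, 1.0), 0.0)
        s2_nc = np.clip(s2a * s2_rad, 0.0, 1.0)
        if self.ensemble.n_conformers == 1:
            s2_nc = np.ones_like(s2_nc)
        tau_eff = s2_nc * self.params.tau_r_70S + \
            (1.0 - s2_nc) * self.params.tau_c_iso
        return s2_nc, tau_eff


def ensemble_gamma2(ensemble: Ensemble, site: int, params: PREParameters,
                    library: RotamerLibrary | None = None,
                    tau_c=None):
    """Weight-averaged Gamma2 per residue over an ensemble at one site.

    Conformers with no sterically allowed rotamer are excluded and the
    weights renormalized. Returns ``(residue_ids, mean_gamma2)``.
    """
    model = PREEnsembleModel(ensemble, [site], params, library)
    return model.residue_ids, model.mean_gamma2(site, tau_c=tau_c)


def tethered_correlation_time(ensemble: Ensemble, site: int,
                              params: PREParameters,
                              library: RotamerLibrary | None = None):
    """Per-residue (S2_NC, tau_C,eff) for a tethered (RNC-mode) ensemble."""
    import warnings
    if ensemble.n_conformers == 1:
        warnings.warn("single conformer: S2_NC = 1 (rigid limit)")
    model = PREEnsembleModel(ensemble, [site], params, library)
    return model.tethered_tau(site)


def intensity_ratio(gamma2, R2_H=100.0, R2_MQ=100.0, delta=5.43e-3):
    """Paramagnetic/diamagnetic peak intensity ratio from <Gamma2>.

    I_para/I_dia = R2 exp(-2 delta G) / (R2 + G) * R2MQ / (R2MQ + G).
    """
    g = np.asarray(gamma2, dtype=float)
    return (R2_H * np.exp(-2.0 * delta * g) / (R2_H + g)
            * R2_MQ / (R2_MQ + g))


def gamma2_from_ratio(ratio, R2_H=100.0, R2_MQ=100.0, delta=5.43e-3,
                      tol=1e-6):
    """Invert the intensity-ratio equation for Gamma2 by bracketed root
    finding (the ratio is strictly decreasing in Gamma2).

    Ratios above 1 cannot be inverted; classify them as upper-bound
    restraints instead.
    """
    def _invert(rat):
        if rat > 1.0:
            raise ValueError("ratio > 1 is not invertible; use an "
                             "upper-bound restraint")
        if rat == 1.0:
            return 0.0
        if rat <= 0.0:
            raise ValueError("ratio must be positive")
        hi = 10.0
        while intensity_ratio(hi, R2_H, R2_MQ, delta) > rat:
            hi *= 10.0
            if hi > 1e9:
                raise RuntimeError("failed to bracket Gamma2")
        return brentq(
            lambda g: intensity_ratio(g, R2_H, R2_MQ, delta) - rat,
            0.0, hi, xtol=tol)

    if np.isscalar(ratio):
        return _invert(float(ratio))
    return np.array([_invert(float(r)) for r in np.asarray(ratio)])


def reference_profile(n_residues: int, site_index: int,
                      params: PREParameters | None = None) -> np.ndarray:
    """Reference intensity-ratio profile of a fully extended polyalanine
    chain labelled at ``site_index`` (0-based), computed with tau_C = 5 ns
    and R2_H = R2_MQ = 100 s^-1. This is the 'no structure' baseline a
    measured PRE profile is compared against."""
    from .chains import build_extended_chain
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if params is None:
        params = PREParameters(tau_c=5e-9, R2_H=100.0, R2_MQ=100.0)
    seq = "A" * n_residues
    ens = build_extended_chain(seq)
    site = int(ens.topology.residue_ids[site_index])
    _, g = ensemble_gamma2(ens, site, params)
    return intensity_ratio(g, params.R2_H, params.R2_MQ, params.delta_HMQC)
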