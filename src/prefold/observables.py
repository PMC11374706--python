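"""Structural observables over weighted conformer ensembles.

All ensemble-level quantities respect the conformer weights; per-residue
profiles are reported against author residue numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .ensemble import Ensemble
from .geometry import rmsd_after_superposition

__all__ = [
    "ContactDefinition",
    "NativeContactParams",
    "RhRelationParams",
    "radius_of_gyration",
    "local_rg",
    "hydration_radius",
    "ensemble_rh",
    "asphericity",
    "fraction_native_contacts",
    "contact_map",
    "long_range_profile",
    "sasa",
    "ensemble_sasa",
    "cluster_gromos",
    "BONDI_RADII",
    "ATOM_CHARGES",
]


@dataclass
class ContactDefinition:
    cutoff: float = 10.0                 # Å, Cα-Cα
    long_range_min_separation: int = 10  # residues

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass
class NativeContactParams:
    """Smooth native-contact fraction Q = (1/N) sum 1/(1+exp(beta(r - lambda r0)))."""

    reference_pairs: np.ndarray        # (n_pairs, 2) flat atom indices
    reference_distances: np.ndarray    # (n_pairs,) r0 in Å
    beta_smooth: float = 5.0           # Å^-1
    lambda_fluct: float = 1.8

    def __post_init__(self):
        if self.beta_smooth <= 0 or self.lambda_fluct <= 0:
            raise ValueError("beta and lambda must be > 0")
        if len(self.reference_pairs) == 0:
            raise ValueError("reference pair list is empty")


@dataclass
class RhRelationParams:
    """Empirical Rg -> Rh map for disordered chains of N residues."""

    alpha1: float = 0.216   # Å^-1
    alpha2: float = 4.06    # Å
    alpha3: float = 0.821
    N: int = 114

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("N must be >= 2")


def _ca_coords(conformer: np.ndarray, topology, residue_range=None):
    ids = topology.residue_ids
    sel = topology.select("CA")
    if residue_range is not None:
        lo, hi = residue_range
        keep = [i for i in sel if lo <= ids[topology.atom_resindex[i]] <= hi]
        sel = np.asarray(keep, dtype=int)
    if len(sel) < 2:
        raise ValueError("fewer than 2 CA atoms in selection")
    return conformer[sel]


def radius_of_gyration(conformer: np.ndarray, topology,
                       residue_range=None) -> float:
    """Unweighted Cα radius of gyration (Å) of one conformer."""
    x = _ca_coords(conformer, topology, residue_range)
    return float(np.sqrt(((x - x.mean(axis=0)) ** 2).sum() / len(x)))


def local_rg(ensemble: Ensemble, window: int = 21):
    """Weighted mean Cα R_g of a sliding window centred on each residue.

    Windows are truncated at the termini. Returns (residue_ids, values).
    """
    ids = ensemble.topology.residue_ids
    ca = ensemble.atom_positions("CA")         # (n_conf, n_res, 3)
    half = window // 2
    n_res = ca.shape[1]
    out = np.empty(n_res)
    w = ensemble.weights
    for r in range(n_res):
        lo, hi = max(0, r - half), min(n_res, r + half + 1)
        seg = ca[:, lo:hi, :]
        cen = seg - seg.mean(axis=1, keepdims=True)
        rg = np.sqrt((cen ** 2).sum(axis=(1, 2)) / seg.shape[1])
        out[r] = float(np.dot(w, rg))
    return ids, out


def hydration_radius(rg: float, params: RhRelationParams) -> float:
    """Empirical hydrodynamic radius (Å) from a Cα R_g.

    R_h = R_g / [ alpha1 (R_g - alpha2 N^0.33) / (N^0.60 - N^0.33) + alpha3 ].
    Carries a documented ±5% systematic uncertainty.
    """
    if rg <= 0:
        raise ValueError("R_g must be > 0")
    n = params.N
    denom = params.alpha1 * (rg - params.alpha2 * n ** 0.33) \
        / (n ** 0.60 - n ** 0.33) + params.alpha3
    if denom <= 0:
        raise ValueError("R_g outside the validity range of the relation")
    return float(rg / denom)


def ensemble_rh(ensemble: Ensemble, params: RhRelationParams | None = None,
                residue_range=None) -> float:
    """Ensemble-average R_h via <R_h> = 1 / ln(<exp(-1/R_h)>)^... i.e. the
    exponential-of-inverse average appropriate for diffusion-weighted data:
    <R_h> = -1 / ln(<exp(-1/R_h)>)."""
    if params is None:
        params = RhRelationParams(N=ensemble.topology.n_residues)
    top = ensemble.topology
    rhs = np.array([hydration_radius(
        radius_of_gyration(x, top, residue_range), params)
        for x in ensemble.coordinates])
    avg = float(np.dot(ensemble.weights, np.exp(-1.0 / rhs)))
    return float(-1.0 / np.log(avg))


def asphericity(points: np.ndarray) -> float:
    """Gyration-tensor asphericity Delta in [0, 1] (0 sphere, 1 rod).

    Delta = (3/2) sum_i (lambda_i - mean)^2 / (tr T)^2.
    """
    x = np.asarray(points, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    cen = x - x.mean(axis=0)
    t = cen.T @ cen / len(x)
    lam = np.linalg.eigvalsh(t)
    tr = lam.sum()
    if tr <= 0:
        raise ValueError("degenerate point set (zero gyration tensor)")
    return float(1.5 * np.sum((lam - tr / 3.0) ** 2) / tr ** 2)


def fraction_native_contacts(conformer: np.ndarray,
                             params: NativeContactParams) -> float:
    """Smooth fraction of native contacts Q of one conformer."""
    i, j = params.reference_pairs.T
    r = np.linalg.norm(conformer[i] - conformer[j], axis=1)
    q = 1.0 / (1.0 + np.exp(params.beta_smooth
                            * (r - params.lambda_fluct
                               * params.reference_distances)))
    return float(q.mean())


def native_pairs_from_reference(reference: np.ndarray, topology,
                                cutoff: float = 10.0,
                                min_separation: int = 3) -> NativeContactParams:
    """Build the native Cα pair list from a reference conformer."""
    sel = topology.select("CA")
    resindex = topology.atom_resindex[sel]
    x = reference[sel]
    pairs, dists = [], []
    for a in range(len(sel)):
        for b in range(a + 1, len(sel)):
            if resindex[b] - resindex[a] < min_separation:
                continue
            d = float(np.linalg.norm(x[a] - x[b]))
            if d < cutoff:
                pairs.append((sel[a], sel[b]))
                dists.append(d)
    return NativeContactParams(np.asarray(pairs), np.asarray(dists))


def contact_map(ensemble: Ensemble,
                definition: ContactDefinition | None = None) -> np.ndarray:
    """Weighted Cα-Cα contact probability matrix (n_res, n_res)."""
    if definition is None:
        definition = ContactDefinition()
    ca = ensemble.atom_positions("CA")
    d = np.linalg.norm(ca[:, :, None, :] - ca[:, None, :, :], axis=-1)
    contacts = (d < definition.cutoff).astype(float)
    p = np.einsum("a,aij->ij", ensemble.weights, contacts)
    np.fill_diagonal(p, 0.0)
    return p


def long_range_profile(ensemble: Ensemble,
                       definition: ContactDefinition | None = None):
    """Per-residue mean long-range contact probability (|i-j| >= 10)."""
    if definition is None:
        definition = ContactDefinition()
    p = contact_map(ensemble, definition)
    n = p.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    mask = np.abs(i - j) >= definition.long_range_min_separation
    prof = np.where(mask, p, 0.0).sum(axis=1) / np.maximum(mask.sum(axis=1), 1)
    return ensemble.topology.residue_ids, prof


# ---- solvent-accessible surface area ------------------------------------

BONDI_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.10}

# per-atom-name partial charges approximating protein force-field backbone
# charges; atoms with |q| <= 0.3 count as apolar for solvation energetics
ATOM_CHARGES = {
    "N": -0.47, "H": 0.31, "CA": 0.07, "C": 0.51, "O": -0.51,
    "CB": -0.18, "SG": -0.08, "SD": -0.08, "CE": -0.05,
    "C3": 0.0, "C4": 0.0, "C5": 0.0, "N1": -0.10, "O1": -0.30,
}


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def sasa(conformer: np.ndarray, topology, probe: float = 1.4,
         n_points: int = 960, include_hydrogens: bool = False):
    """Shrake-Rupley solvent-accessible surface area.

    Returns (per_atom, per_residue, total) in Å². Heavy atoms only by
    default, Bondi radii; unknown elements get the carbon radius with a
    warning.
    """
    import warnings
    names = topology.atom_names
    heavy = [i for i, nm in enumerate(names)
             if include_hydrogens or not nm.startswith("H")]
    radii = np.empty(len(heavy))
    for k, i in enumerate(heavy):
        el = names[i][0]
        if el not in BONDI_RADII:
            warnings.warn(f"unknown element for atom {names[i]}; carbon "
                          "radius used")
            el = "C"
        radii[k] = BONDI_RADII[el] + probe
    x = np.asarray(conformer)[heavy]
    pts = _sphere_points(n_points)
    tree = cKDTree(x)
    per_atom_heavy = np.zeros(len(heavy))
    rmax = radii.max()
    for k in range(len(heavy)):
        surface = x[k] + radii[k] * pts
        neighbors = tree.query_ball_point(x[k], radii[k] + rmax)
        coincident = [n for n in neighbors if n != k
                      and np.linalg.norm(x[n] - x[k]) < 1e-9]
        if any(n < k for n in coincident):
            continue  # degenerate duplicate: counted once, for the first
        neighbors = [n for n in neighbors if n != k and n not in coincident]
        if neighbors:
            d = np.linalg.norm(surface[:, None, :] - x[neighbors][None, :, :],
                               axis=-1)
            exposed = np.all(d >= radii[neighbors][None, :], axis=1)
        else:
            exposed = np.ones(n_points, dtype=bool)
        per_atom_heavy[k] = 4.0 * np.pi * radii[k] ** 2 \
            * exposed.sum() / n_points
    per_atom = np.zeros(len(names))
    per_atom[heavy] = per_atom_heavy
    per_res = np.zeros(topology.n_residues)
    np.add.at(per_res, topology.atom_resindex, per_atom)
    return per_atom, per_res, float(per_atom.sum())


def polar_apolar_split(per_atom: np.ndarray, topology,
                       charge_cut: float = 0.3):
    """Split a per-atom SASA into (apolar, polar) totals by |partial charge|.

    Atoms with |q| <= ``charge_cut`` are apolar. The split is exact:
    apolar + polar equals the total.
    """
    apolar = polar = 0.0
    for i, nm in enumerate(topology.atom_names):
        q = ATOM_CHARGES.get(nm, 0.0)
        if abs(q) <= charge_cut:
            apolar += per_atom[i]
        else:
            polar += per_atom[i]
    return float(apolar), float(polar)


def ensemble_sasa(ensemble: Ensemble, probe: float = 1.4,
                  n_points: int = 960, per_frame_max: bool = False):
    """Weighted ensemble SASA.

    Returns a dict with total/apolar/polar means and the per-residue
    profile. ``per_frame_max=True`` reports, per residue, the maximum
    per-frame SASA over the ensemble instead of the weighted mean (the
    'maximum theoretical surface' reading of an unfolded ensemble).
    """
    top = ensemble.topology
    totals, apolars, polars, residue_rows = [], [], [], []
    for x in ensemble.coordinates:
        per_atom, per_res, total = sasa(x, top, probe, n_points)
        ap, po = polar_apolar_split(per_atom, top)
        totals.append(total)
        apolars.append(ap)
        polars.append(po)
        residue_rows.append(per_res)
    residue_rows = np.array(residue_rows)
    w = ensemble.weights
    per_res = residue_rows.max(axis=0) if per_frame_max \
        else np.einsum("a,ar->r", w, residue_rows)
    return {
        "total": float(np.dot(w, totals)),
        "apolar": float(np.dot(w, apolars)),
        "polar": float(np.dot(w, polars)),
        "per_residue": per_res,
        "residue_ids": top.residue_ids,
        "per_conformer_total": np.asarray(totals),
    }


# ---- clustering ----------------------------------------------------------

@dataclass
class Cluster:
    centroid: int              # frame index of the cluster centre
    members: np.ndarray        # frame indices
    population: float          # summed weights


def cluster_gromos(ensemble: Ensemble, rmsd_cutoff: float = 15.0,
                   max_clusters: int | None = None) -> list[Cluster]:
    """GROMOS conformational clustering on best-fit Cα RMSD.

    Iteratively takes the conformer with the largest weighted neighbour
    count within ``rmsd_cutoff`` as a cluster centre, removes the cluster,
    and repeats. Populations are summed conformer weights.
    """
    if ensemble.n_conformers < 2:
        raise ValueError("need at least 2 conformers")
    ca = ensemble.atom_positions("CA")
    n = ensemble.n_conformers
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d[a, b] = d[b, a] = rmsd_after_superposition(ca[a], ca[b])
    neighbors = d <= rmsd_cutoff
    w = ensemble.weights.copy()
    remaining = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while remaining.any():
        counts = (neighbors & remaining[None, :]) @ (w * remaining)
        counts[~remaining] = -np.inf
        centre = int(np.argmax(counts))
        members = np.nonzero(neighbors[centre] & remaining)[0]
        clusters.append(Cluster(centroid=centre, members=members,
                                population=float(w[members].sum())))
        remaining[members] = False
        if max_clusters is not None and len(clusters) >= max_clusters:
            leftovers = np.nonzero(remaining)[0]
            if len(leftovers):
                clusters.append(Cluster(centroid=int(leftovers[0]),
                                        members=leftovers,
                                        population=float(w[leftovers].sum())))
            break
    return clusters
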