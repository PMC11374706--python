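"""Coarse-grained Cα chain model: 10-12 Lennard-Jones stickiness plus
Debye-Hückel screened electrostatics, sampled by Metropolis Monte Carlo.

The pair potential is

    u(r) = lambda * [5 (sigma/r)^12 - 6 (sigma/r)^10] + A q_i q_j exp(-kappa r)/r

summed over bead pairs separated by at least ``exclusion_separation``
residues in sequence. ``lambda`` and ``sigma`` per pair are arithmetic
means of per-residue values. The 10-12 form has its minimum -lambda at
r = sigma. Energies are in units of the reduced temperature (kT).

The shipped per-residue stickiness scale is an approximation: it ranks
residues by hydrophobicity on [0, 1] and is not the published
hydrophobicity-optimized parameter set, which is cited by reference only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import Ensemble, Topology
from .geometry import rotation_about_axis

__all__ = ["CGPotentialParams", "cg_energy", "mc_sample_cg", "ca_trace_ensemble"]

# approximate per-residue stickiness (hydrophobicity-ranked, 0..1)
DEFAULT_LAMBDA = {
    "F": 0.95, "W": 1.00, "Y": 0.85, "L": 0.80, "I": 0.78, "M": 0.76,
    "V": 0.70, "C": 0.68, "A": 0.50, "T": 0.40, "S": 0.38, "G": 0.45,
    "P": 0.40, "H": 0.45, "N": 0.35, "Q": 0.35, "D": 0.20, "E": 0.20,
    "K": 0.20, "R": 0.35,
}
DEFAULT_SIGMA = 6.0  # Å, Cα-Cα contact distance
DEFAULT_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1}


@dataclass
class CGPotentialParams:
    """Pairwise parameters of the Cα model.

    ``debye_kappa`` defaults to aqueous screening at roughly 12 mM MgCl2
    ionic strength (Debye length ~16 Å); ``dielectric_prefactor`` is the
    Coulomb constant in kT·Å per unit charge pair at that condition. Both
    are configurable because the reference parameterization is not printed.
    """

    lambda_res: dict = field(default_factory=lambda: dict(DEFAULT_LAMBDA))
    sigma_res: dict = field(default_factory=dict)
    charges: dict = field(default_factory=lambda: dict(DEFAULT_CHARGE))
    debye_kappa: float = 1.0 / 16.0        # Å^-1
    dielectric_prefactor: float = 7.0      # kT Å (Bjerrum length in water)
    reduced_temperature: float = 1.0
    exclusion_separation: int = 4
    lambda_scale: float = 1.0

    def pair_tables(self, sequence: str):
        lam = np.array([self.lambda_res.get(a, 0.5) for a in sequence])
        sig = np.array([self.sigma_res.get(a, DEFAULT_SIGMA) for a in sequence])
        q = np.array([self.charges.get(a, 0.0) for a in sequence])
        lam_ij = self.lambda_scale * 0.5 * (lam[:, None] + lam[None, :])
        sig_ij = 0.5 * (sig[:, None] + sig[None, :])
        return lam_ij, sig_ij, q


def _pair_mask(n: int, min_sep: int) -> tuple[np.ndarray, np.ndarray]:
    i, j = np.triu_indices(n, k=min_sep)
    return i, j


def cg_energy(ca_coordinates: np.ndarray, sequence: str,
              params: CGPotentialParams) -> float:
    """Total nonbonded energy (kT units) of a Cα trace.

    Sums the 10-12 LJ and screened-Coulomb terms over all pairs separated
    by at least ``exclusion_separation`` residues.
    """
    x = np.asarray(ca_coordinates, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 beads")
    lam_ij, sig_ij, q = params.pair_tables(sequence)
    i, j = _pair_mask(n, params.exclusion_separation)
    r = np.linalg.norm(x[i] - x[j], axis=1)
    sr = sig_ij[i, j] / r
    lj = lam_ij[i, j] * (5.0 * sr ** 12 - 6.0 * sr ** 10)
    qq = q[i] * q[j]
    coul = params.dielectric_prefactor * qq * np.exp(-params.debye_kappa * r) / r
    return float(np.sum(lj) + np.sum(coul))


def _move(x: np.ndarray, rng: np.random.Generator, max_angle: float) -> np.ndarray:
    """Symmetric crankshaft or pivot proposal preserving bond lengths."""
    n = len(x)
    y = x.copy()
    angle = rng.uniform(-max_angle, max_angle)
    if rng.random() < 0.5 or n < 4:
        # pivot: rotate the tail about a random axis through bead k
        k = int(rng.integers(1, n - 1))
        axis = rng.normal(size=3)
        rot = rotation_about_axis(axis, angle)
        y[k + 1:] = (y[k + 1:] - y[k]) @ rot.T + y[k]
    else:
        # crankshaft: rotate interior beads about the chord i..j
        i = int(rng.integers(0, n - 3))
        j = int(rng.integers(i + 2, min(i + 8, n)))
        axis = y[j] - y[i]
        if np.linalg.norm(axis) < 1e-9:
            return y
        rot = rotation_about_axis(axis, angle)
        y[i + 1:j] = (y[i + 1:j] - y[i]) @ rot.T + y[i]
    return y


def mc_sample_cg(initial_ca: np.ndarray, sequence: str,
                 params: CGPotentialParams, n_steps: int, seed: int,
                 sample_every: int = 50,
                 max_angle: float = np.pi / 3) -> Ensemble:
    """Metropolis Monte Carlo on a Cα trace.

    Crankshaft and pivot proposals are symmetric (uniform angle about a
    uniformly chosen axis/segment), so Metropolis acceptance
    min(1, exp(-dU/T)) satisfies detailed balance with respect to
    exp(-U/T) on the fixed-bond-length configuration space. Returns the
    retained frames (including the initial trace) as a Cα-only ensemble.
    Deterministic for a given seed.
    """
    x = np.asarray(initial_ca, dtype=float).copy()
    rng = np.random.default_rng(seed)
    temp = params.reduced_temperature
    energy = cg_energy(x, sequence, params)
    frames = [x.copy()]
    for step in range(n_steps):
        y = _move(x, rng, max_angle)
        e_new = cg_energy(y, sequence, params)
        if e_new <= energy or rng.random() < np.exp(-(e_new - energy) / temp):
            x, energy = y, e_new
        if (step + 1) % sample_every == 0:
            frames.append(x.copy())
    return ca_trace_ensemble(np.array(frames), sequence)


def ca_trace_ensemble(frames: np.ndarray, sequence: str,
                      first_residue_id: int = 1) -> Ensemble:
    """Wrap Cα-only frames (n_frames, n_res, 3) as an Ensemble."""
    from .chains import AA_1TO3
    n = len(sequence)
    top = Topology(
        residue_ids=np.arange(first_residue_id, first_residue_id + n),
        residue_names=[AA_1TO3[a] for a in sequence],
        atom_names=["CA"] * n,
        atom_resindex=np.arange(n))
    return Ensemble(top, np.asarray(frames, dtype=float))
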