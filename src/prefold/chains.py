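"""Synthetic unfolded-chain ensembles.

This module generates heterogeneous unfolded-state ensembles that stand in
for cluster-scale MD sampling: self-avoiding backbone chains drawn from a
coil (phi, psi) distribution, optionally biased toward a target radius of
gyration, and optionally tethered by one terminus next to a flat repulsive
wall that emulates steric exclusion by the ribosome surface.

Chains carry full backbones (N, H, CA, CB, C, O) in ideal peptide geometry,
which is all that the PRE forward model, secondary-structure assignment and
surface-area estimators downstream require. Sidechains beyond CB are not
built.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import Ensemble, Topology
from .geometry import dihedral, place_atom, rotation_about_axis

__all__ = [
    "ChainModelParams",
    "CoilLibrary",
    "build_extended_chain",
    "build_chain",
    "sample_coil_ensemble",
    "isolated_like_ensemble",
    "tethered_like_ensemble",
    "SYNTHETIC_IG_SEQUENCE",
    "AA_1TO3",
]

# one- to three-letter codes
AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# Synthetic 114-residue sequence with an immunoglobulin-like composition
# (beta-rich domains are threonine/valine/glycine heavy with sparse aromatics).
# This is a stand-in sequence, not any natural protein; numbering 637-750 is
# applied by the study-condition helpers below. Residue 104 (author id 740)
# is a cysteine so the conventional C740 labelling site exists.
SYNTHETIC_IG_SEQUENCE = (
    "MAEKTGVSLNPDAGFTVKSYTGDALESKVTVPGQAEGTVKADNGNGTYSVEYTPKEAGDY"
    "TVSIKYGGDPVKGSPFTVKASTPGNADKVTASGPGLEKSGVELNKPTHFTVC"  # 740 = C
    "AG"
)
assert len(SYNTHETIC_IG_SEQUENCE) == 114

# ideal backbone geometry (Engh-Huber-like), Å and degrees
_B = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
      "CA-CB": 1.530, "N-H": 1.010}
_A = {"N-CA-C": 111.0, "CA-C-N": 116.6, "C-N-CA": 121.9,
      "CA-C-O": 120.5, "C-CA-CB": 110.1}
_CB_IMPROPER = 122.6  # dihedral N-C-CA-CB, fixes L chirality


def _rad(x):
    return np.deg2rad(x)


@dataclass
class CoilLibrary:
    """Mixture of Gaussian basins in the Ramachandran plane for coil sampling.

    Defaults: broad beta basin, polyproline-II basin, and a minor (10%)
    alpha basin — a generic statistical-coil picture appropriate for chains
    with ~1-3% residual strand and negligible helix.
    """

    centers: np.ndarray = field(default_factory=lambda: np.array(
        [[-120.0, 135.0], [-75.0, 150.0], [-63.0, -43.0]]))
    sigmas: np.ndarray = field(default_factory=lambda: np.array(
        [[30.0, 25.0], [20.0, 20.0], [10.0, 10.0]]))
    fractions: np.ndarray = field(default_factory=lambda: np.array(
        [0.50, 0.40, 0.10]))

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        comp = rng.choice(len(self.fractions), size=n, p=self.fractions)
        phi_psi = rng.normal(self.centers[comp], self.sigmas[comp])
        return np.deg2rad(phi_psi)


@dataclass
class ChainModelParams:
    """Conditions for synthetic coil-ensemble generation.

    compaction_bias: optional ``(target_rg_A, strength_kT_per_A2)`` harmonic
    restraint on the Cα radius of gyration.
    tether: optional ``(terminus, wall_offset_A)`` — ``terminus`` is "N" or
    "C"; the tethered Cα is pinned at the origin and every atom must satisfy
    z >= wall_offset (a flat repulsive wall; offset is negative, placing the
    wall just below the tether point).
    """

    sequence: str = SYNTHETIC_IG_SEQUENCE
    n_conformers: int = 100
    seed: int = 0
    compaction_bias: tuple[float, float] | None = None
    tether: tuple[str, float] | None = None
    first_residue_id: int = 1
    ca_clash_A: float = 4.0
    burn_in_sweeps: int = 100
    stride_sweeps: int = 4
    coil: CoilLibrary = field(default_factory=CoilLibrary)

    def __post_init__(self):
        if self.n_conformers < 1:
            raise ValueError("n_conformers must be >= 1")
        if self.compaction_bias is not None and self.compaction_bias[0] <= 0:
            raise ValueError("target R_g must be > 0")
        for aa in self.sequence:
            if aa not in AA_1TO3:
                raise ValueError(f"unknown residue code {aa!r}")


class BackboneChain:
    """Mutable full-backbone chain supporting dihedral pivot moves.

    Internal helper for the coil sampler; the public products are
    :class:`~prefold.ensemble.Ensemble` objects.
    """

    def __init__(self, sequence: str, phi: np.ndarray, psi: np.ndarray,
                 first_residue_id: int = 1):
        self.sequence = sequence
        n = len(sequence)
        names, resindex, res_names = [], [], []
        self.index = []  # per-residue dict atom name -> flat index
        flat = 0
        for i, aa in enumerate(sequence):
            res_names.append(AA_1TO3[aa])
            per = {}
            atoms = ["N"]
            if aa != "P" and i > 0:
                atoms.append("H")
            atoms.append("CA")
            if aa != "G":
                atoms.append("CB")
            atoms += ["C", "O"]
            for nm in atoms:
                per[nm] = flat
                names.append(nm)
                resindex.append(i)
                flat += 1
            self.index.append(per)
        self.topology = Topology(
            residue_ids=np.arange(first_residue_id, first_residue_id + n),
            residue_names=res_names, atom_names=names,
            atom_resindex=np.array(resindex))
        self.coords = np.zeros((flat, 3))
        self._build(phi, psi)
        self.ca_idx = self.topology.select("CA")

    def _build(self, phi, psi):
        x = self.coords
        idx = self.index
        n = len(self.sequence)
        # residue 0 seed frame
        x[idx[0]["N"]] = [0.0, 0.0, 0.0]
        x[idx[0]["CA"]] = [_B["N-CA"], 0.0, 0.0]
        ang = np.pi - _rad(_A["N-CA-C"])
        x[idx[0]["C"]] = x[idx[0]["CA"]] + _B["CA-C"] * np.array(
            [np.cos(ang), np.sin(ang), 0.0])
        for i in range(n):
            N, CA, C = (x[idx[i][k]] for k in ("N", "CA", "C"))
            if i > 0:
                prevC = x[idx[i - 1]["C"]]
                if "H" in idx[i]:
                    u = prevC - N
                    v = CA - N
                    b = -(u / np.linalg.norm(u) + v / np.linalg.norm(v))
                    x[idx[i]["H"]] = N + _B["N-H"] * b / np.linalg.norm(b)
            if "CB" in idx[i]:
                x[idx[i]["CB"]] = place_atom(
                    N, C, CA, _B["CA-CB"], _rad(_A["C-CA-CB"]),
                    _rad(_CB_IMPROPER))
            if i < n - 1:
                nextN = place_atom(N, CA, C, _B["C-N"],
                                   _rad(_A["CA-C-N"]), psi[i])
                x[idx[i + 1]["N"]] = nextN
                x[idx[i + 1]["CA"]] = place_atom(
                    CA, C, nextN, _B["N-CA"], _rad(_A["C-N-CA"]), np.pi)
                x[idx[i + 1]["C"]] = place_atom(
                    C, nextN, x[idx[i + 1]["CA"]], _B["CA-C"],
                    _rad(_A["N-CA-C"]), phi[i + 1])
            # carbonyl O anti to the next amide N (trans peptide plane)
            x[idx[i]["O"]] = place_atom(
                N, CA, C, _B["C-O"], _rad(_A["CA-C-O"]), psi[i] + np.pi)

    # ---- pivot machinery -------------------------------------------------
    def _downstream(self, i: int, which: str) -> np.ndarray:
        """Flat indices moved by a phi/psi rotation at residue i."""
        start_next = self.index[i + 1]["N"] if i + 1 < len(self.index) else self.coords.shape[0]
        moved = list(range(start_next, self.coords.shape[0]))
        if which == "phi":
            moved = [self.index[i][k] for k in ("C", "O", "CB") if k in self.index[i]] + moved
        else:  # psi
            moved = [self.index[i]["O"]] + moved
        return np.asarray(moved, dtype=int)

    def rotate(self, i: int, which: str, delta: float,
               coords: np.ndarray | None = None) -> np.ndarray:
        """Return a coordinate copy with phi_i or psi_i changed by ``delta``."""
        x = (self.coords if coords is None else coords).copy()
        if which == "phi":
            a0 = x[self.index[i]["N"]]
            a1 = x[self.index[i]["CA"]]
        else:
            a0 = x[self.index[i]["CA"]]
            a1 = x[self.index[i]["C"]]
        rot = rotation_about_axis(a1 - a0, delta)
        moved = self._downstream(i, which)
        x[moved] = (x[moved] - a0) @ rot.T + a0
        return x

    def get_phi_psi(self, i: int) -> tuple[float, float]:
        x, idx = self.coords, self.index
        phi = np.nan
        if i > 0:
            phi = dihedral(x[idx[i - 1]["C"]], x[idx[i]["N"]],
                           x[idx[i]["CA"]], x[idx[i]["C"]])
        psi = np.nan
        if i < len(idx) - 1:
            psi = dihedral(x[idx[i]["N"]], x[idx[i]["CA"]],
                           x[idx[i]["C"]], x[idx[i + 1]["N"]])
        return phi, psi


def build_chain(sequence: str, phi=None, psi=None,
                first_residue_id: int = 1) -> BackboneChain:
    """Full-backbone chain at the given dihedrals (default: fully extended)."""
    if not sequence:
        raise ValueError("empty sequence")
    for aa in sequence:
        if aa not in AA_1TO3:
            raise ValueError(f"unknown residue code {aa!r}")
    n = len(sequence)
    phi = np.full(n, -np.pi) if phi is None else np.asarray(phi, float)
    psi = np.full(n, np.pi) if psi is None else np.asarray(psi, float)
    return BackboneChain(sequence, phi, psi, first_residue_id)


def build_extended_chain(sequence: str, first_residue_id: int = 1) -> Ensemble:
    """Fully extended chain (phi = -180°, psi = 180°, omega = 180°) as a
    single-conformer ensemble. Used for reference PRE profiles."""
    chain = build_chain(sequence, first_residue_id=first_residue_id)
    return Ensemble(chain.topology, chain.coords[None, :, :])


def _ca_rg(ca: np.ndarray) -> float:
    c = ca - ca.mean(axis=0)
    return float(np.sqrt((c ** 2).sum() / len(ca)))


def _self_avoiding(ca: np.ndarray, cutoff: float) -> bool:
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    i, j = np.triu_indices(len(ca), k=3)
    return bool(np.all(d[i, j] >= cutoff))


def sample_coil_ensemble(params: ChainModelParams) -> Ensemble:
    """Metropolis-sampled coil ensemble under the stated constraints.

    Single-residue (phi, psi) pivot proposals drawn from the coil library
    (an independence proposal, hence symmetric in the sampled basin
    measure); hard-sphere Cα self-avoidance and the optional wall are
    enforced by rejection; an optional harmonic R_g restraint enters the
    acceptance probability. Deterministic for a given seed.
    """
    rng = np.random.default_rng(params.seed)
    n = len(params.sequence)
    chain = build_chain(params.sequence, first_residue_id=params.first_residue_id)

    tether_flat = None
    wall = None
    if params.tether is not None:
        terminus, wall = params.tether
        res = 0 if terminus.upper() == "N" else n - 1
        tether_flat = chain.index[res]["CA"]
        # start pointing away from the wall
        chain.coords = chain.coords @ rotation_about_axis([0, 1, 0], -np.pi / 2).T
        chain.coords -= chain.coords[tether_flat]

    def bias_energy(ca):
        if params.compaction_bias is None:
            return 0.0
        target, k = params.compaction_bias
        return k * (_ca_rg(ca) - target) ** 2

    ca_idx = chain.ca_idx
    energy = bias_energy(chain.coords[ca_idx])
    conformers = []
    total_sweeps = params.burn_in_sweeps + params.stride_sweeps * params.n_conformers
    collected = 0
    failures = 0
    for sweep in range(total_sweeps):
        for _ in range(n):
            i = int(rng.integers(0, n))
            phi_new, psi_new = params.coil.sample(rng)[0]
            phi_old, psi_old = chain.get_phi_psi(i)
            x = chain.coords
            if i > 0 and np.isfinite(phi_old):
                x = chain.rotate(i, "phi", phi_new - phi_old, coords=x)
            if i < n - 1 and np.isfinite(psi_old):
                x = chain.rotate(i, "psi", psi_new - psi_old, coords=x)
            if tether_flat is not None:
                x = x - x[tether_flat]
            ca = x[ca_idx]
            if not _self_avoiding(ca, params.ca_clash_A):
                failures += 1
                continue
            if wall is not None and np.min(x[:, 2]) < wall:
                failures += 1
                continue
            e_new = bias_energy(ca)
            if e_new <= energy or rng.random() < np.exp(energy - e_new):
                chain.coords = x
                energy = e_new
        if sweep >= params.burn_in_sweeps and \
                (sweep - params.burn_in_sweeps) % params.stride_sweeps == 0:
            conformers.append(chain.coords.copy())
            collected += 1
            if collected == params.n_conformers:
                break
    if collected < params.n_conformers:
        raise RuntimeError(
            f"could not collect {params.n_conformers} conformers "
            f"(got {collected}); constraints (self-avoidance/wall) may be "
            f"unsatisfiable for this sequence")
    return Ensemble(chain.topology, np.array(conformers))


# ---- study conditions ----------------------------------------------------

def isolated_like_ensemble(n_conformers: int = 100, seed: int = 0,
                           target_rg: float = 34.9) -> Ensemble:
    """Compact isolated-protein-like unfolded ensemble of the synthetic
    114-residue domain (author numbering 637-750), biased to the study's
    isolated-state compactness (R_g = 34.9 Å by default)."""
    params = ChainModelParams(
        sequence=SYNTHETIC_IG_SEQUENCE, n_conformers=n_conformers, seed=seed,
        compaction_bias=(target_rg, 0.5), first_residue_id=637)
    return sample_coil_ensemble(params)


def tethered_like_ensemble(n_conformers: int = 100, seed: int = 0,
                           target_rg: float = 44.1,
                           wall_offset: float = -3.0) -> Ensemble:
    """Expanded ribosome-tethered-like unfolded ensemble: C terminus pinned
    at the origin, flat repulsive wall just below it, biased to the study's
    tethered-state compactness (R_g = 44.1 Å by default)."""
    params = ChainModelParams(
        sequence=SYNTHETIC_IG_SEQUENCE, n_conformers=n_conformers, seed=seed,
        compaction_bias=(target_rg, 0.5), tether=("C", wall_offset),
        first_residue_id=637)
    return sample_coil_ensemble(params)
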