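"""Ensemble data model and I/O.

The central object of the package is the :class:`Ensemble`: a topology, an
ordered set of conformers and a normalized per-conformer weight vector
``w_alpha``. Every downstream stage (PRE forward model, reweighting,
observables, energetics) consumes and/or produces ensembles.

Coordinates are in Å. Residue numbering follows the author numbering of the
construct (e.g. 637-750 for a domain excised from a larger protein);
internal 0-based indices are
never part of the public surface.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Topology",
    "Ensemble",
    "BlockStats",
    "read_ensemble",
    "write_ensemble",
    "read_weights",
    "weighted_mean",
    "block_sem",
]

_WEIGHT_SUM_TOL = 1e-3


@dataclass
class Topology:
    """Residue/atom bookkeeping for a conformer ensemble.

    ``residue_ids`` carry author numbering and must be strictly increasing.
    ``atom_resindex`` maps each atom to its (0-based, internal) residue slot.
    ``chain_tags`` flags atoms as ``"protein"`` or ``"context"`` (e.g. static
    ribosome-surface atoms carried along for clash/contact tests).
    """

    residue_ids: np.ndarray
    residue_names: list[str]
    atom_names: list[str]
    atom_resindex: np.ndarray
    chain_tags: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.atom_resindex = np.asarray(self.atom_resindex, dtype=int)
        if not self.chain_tags:
            self.chain_tags = ["protein"] * len(self.atom_names)
        if np.any(np.diff(self.residue_ids) <= 0):
            raise ValueError("residue_ids must be strictly increasing")
        if len(self.atom_names) != len(self.atom_resindex):
            raise ValueError("atom_names and atom_resindex length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def atom_index(self, residue_id: int, atom_name: str) -> int:
        """Flat index of ``atom_name`` in the residue with author id ``residue_id``."""
        res_slot = int(np.searchsorted(self.residue_ids, residue_id))
        if res_slot >= self.n_residues or self.residue_ids[res_slot] != residue_id:
            raise KeyError(f"no residue {residue_id}")
        for i in np.nonzero(self.atom_resindex == res_slot)[0]:
            if self.atom_names[i] == atom_name:
                return int(i)
        raise KeyError(f"residue {residue_id} has no atom {atom_name}")

    def has_atom(self, residue_id: int, atom_name: str) -> bool:
        try:
            self.atom_index(residue_id, atom_name)
            return True
        except KeyError:
            return False

    def select(self, atom_name: str, protein_only: bool = True) -> np.ndarray:
        """Flat indices of all atoms named ``atom_name`` (in residue order)."""
        idx = [i for i, nm in enumerate(self.atom_names)
               if nm == atom_name and (not protein_only or self.chain_tags[i] == "protein")]
        return np.asarray(idx, dtype=int)

    def residue_name(self, residue_id: int) -> str:
        res_slot = int(np.searchsorted(self.residue_ids, residue_id))
        if res_slot >= self.n_residues or self.residue_ids[res_slot] != residue_id:
            raise KeyError(f"no residue {residue_id}")
        return self.residue_names[res_slot]


@dataclass
class Ensemble:
    """Set of conformers sharing a topology, with normalized weights."""

    topology: Topology
    coordinates: np.ndarray   # (n_conformers, n_atoms, 3) in Å
    weights: np.ndarray | None = None
    frame_ids: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_conformers, n_atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError("coordinate array does not match topology atom count")
        n = self.coordinates.shape[0]
        if self.weights is None:
            self.weights = np.full(n, 1.0 / n)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != n:
                raise ValueError("weight count does not match conformer count")
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")
            s = self.weights.sum()
            if abs(s - 1.0) > _WEIGHT_SUM_TOL:
                raise ValueError(f"weights sum to {s:.6f}, not 1")
            self.weights = self.weights / s
        if self.frame_ids is None:
            self.frame_ids = np.arange(n)

    @property
    def n_conformers(self) -> int:
        return self.coordinates.shape[0]

    def with_weights(self, weights: np.ndarray) -> "Ensemble":
        return Ensemble(self.topology, self.coordinates, np.asarray(weights, float),
                        frame_ids=self.frame_ids)

    def subset(self, keep: np.ndarray) -> "Ensemble":
        """Ensemble restricted to conformers ``keep``; weights renormalized."""
        keep = np.asarray(keep)
        w = self.weights[keep]
        if w.sum() <= 0:
            raise ValueError("subset has zero total weight")
        return Ensemble(self.topology, self.coordinates[keep], w / w.sum(),
                        frame_ids=self.frame_ids[keep])

    def atom_positions(self, atom_name: str) -> np.ndarray:
        """(n_conformers, n_matching_atoms, 3) positions of all atoms named ``atom_name``."""
        return self.coordinates[:, self.topology.select(atom_name), :]


@dataclass
class BlockStats:
    """Weighted mean with a block-averaging standard error."""

    mean: float
    sem: float
    n_blocks: int

    def __post_init__(self):
        if self.sem < 0:
            raise ValueError("sem must be >= 0")
        if self.n_blocks < 2:
            raise ValueError("need at least 2 blocks")


def weighted_mean(ensemble_or_weights, values) -> float:
    """Weighted ensemble average  sum_alpha w_alpha y_alpha."""
    w = ensemble_or_weights.weights if isinstance(ensemble_or_weights, Ensemble) \
        else np.asarray(ensemble_or_weights, float)
    y = np.asarray(values, dtype=float)
    if len(y) != len(w):
        raise ValueError("value count does not match conformer count")
    return float(np.dot(w, y))


def block_sem(values, weights=None, n_blocks: int = 10) -> BlockStats:
    """Standard error of a (weighted) ensemble mean from contiguous blocks.

    The series is split into ``n_blocks`` contiguous equal-size blocks
    (remainder truncated). Block means are weighted by their summed conformer
    weights, so reweighted ensembles propagate posterior weights into the
    error estimate.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if n < n_blocks:
        raise ValueError("fewer values than blocks")
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, dtype=float)
    size = n // n_blocks
    used = size * n_blocks
    yb = y[:used].reshape(n_blocks, size)
    wb = w[:used].reshape(n_blocks, size)
    block_w = wb.sum(axis=1)
    if np.any(block_w <= 0):
        raise ValueError("a block has zero total weight")
    block_means = (wb * yb).sum(axis=1) / block_w
    wnorm = block_w / block_w.sum()
    mean = float(np.dot(wnorm, block_means))
    var_between = float(np.dot(wnorm, (block_means - mean) ** 2))
    # unbiased scaling, reduces to sd/sqrt(n_blocks) for uniform weights
    sem = float(np.sqrt(var_between * n_blocks / (n_blocks - 1) / n_blocks))
    return BlockStats(mean=mean, sem=sem, n_blocks=n_blocks)


def read_weights(path) -> np.ndarray:
    """Whitespace/newline-delimited conformer weights.

    Renormalized if the sum deviates from 1 by <= 1e-3; an error otherwise
    (tolerates rounding, catches corruption).
    """
    text = open(path).read() if not hasattr(path, "read") else path.read()
    w = np.array([float(tok) for tok in text.split()], dtype=float)
    if np.any(w < 0):
        raise ValueError("negative weight in weights file")
    s = w.sum()
    if abs(s - 1.0) > _WEIGHT_SUM_TOL:
        raise ValueError(f"weights sum to {s:.6f}; refusing to renormalize")
    return w / s


def read_ensemble(path, weights_path=None) -> Ensemble:
    """Read a multi-model PDB (MODEL/ENDMDL records) into an :class:`Ensemble`.

    Uniform weights are assigned when no weights file is given. A topology
    PDB plus trajectory pair is also accepted by passing a tuple
    ``(topology_path, trajectory_path)`` — both go through MDAnalysis.
    """
    import MDAnalysis as mda
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if isinstance(path, tuple):
            u = mda.Universe(*path)
        else:
            u = mda.Universe(str(path))
        atoms = u.atoms
        residue_ids = atoms.residues.resids
        residue_names = [str(r) for r in atoms.residues.resnames]
        atom_names = [str(a) for a in atoms.names]
        atom_resindex = atoms.resindices
        try:
            segids = [str(s) for s in atoms.segids]
        except Exception:
            segids = [""] * len(atom_names)
        chain_tags = ["context" if s.upper() in {"RIBO", "CTX"} else "protein"
                      for s in segids]
        top = Topology(residue_ids, residue_names, atom_names, atom_resindex,
                       chain_tags)
        coords = np.array([atoms.positions.copy() for _ in u.trajectory])
    if weights_path is not None:
        w = read_weights(weights_path)
        if len(w) != coords.shape[0]:
            raise ValueError(
                f"{len(w)} weights for {coords.shape[0]} models")
    else:
        w = None
    return Ensemble(top, coords, w)


def write_ensemble(ensemble: Ensemble, path, weights_path=None) -> None:
    """Write a multi-model PDB (and optionally a plain-text weights file)."""
    top = ensemble.topology
    buf = io.StringIO()
    for m, frame in enumerate(ensemble.coordinates, start=1):
        buf.write(f"MODEL     {m:4d}\n")
        serial = 1
        for i in range(top.n_atoms):
            ri = top.atom_resindex[i]
            name = top.atom_names[i]
            pdb_name = f" {name:<3s}" if len(name) < 4 else name
            chain = "A" if top.chain_tags[i] == "protein" else "R"
            x, y, z = frame[i]
            element = name.strip()[0]
            buf.write(
                f"ATOM  {serial:5d} {pdb_name:<4s} {top.residue_names[ri]:<3s} "
                f"{chain}{top.residue_ids[ri]:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{element:>2s}\n")
            serial += 1
        buf.write("ENDMDL\n")
    buf.write("END\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
    if weights_path is not None:
        with open(weights_path, "w") as fh:
            fh.write("\n".join(f"{w:.12g}" for w in ensemble.weights) + "\n")


def profile_to_csv(residue_ids, values, sems, path) -> None:
    """Emit a per-residue statistic as CSV (residue_id, value, sem)."""
    pd.DataFrame({"residue_id": residue_ids, "value": values,
                  "sem": sems}).to_csv(path, index=False)
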