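"""Nitroxide spin-label rotamer library.

The PRE forward model places an explicit ensemble of spin-label sidechain
rotamers at each labelling site. The default library shipped here is a
synthetic one: a dihedral-enumerated set of 216 MTSL-like sidechain
conformers (chi1 x chi2 x chi3 x chi4 x chi5 over standard staggered /
perpendicular wells) built in ideal geometry, with the unpaired electron at
the midpoint of the nitroxide N-O bond. It reproduces the reach (~7-12 Å
from CB) and angular spread of the published 216-rotamer MTSL library but
is not that library; ``load_library`` accepts an external library in a
documented CSV + multi-model PDB format so a published one can be swapped
in.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .geometry import place_atom

__all__ = ["RotamerLibrary", "default_library", "load_library"]

_DEG = np.pi / 180.0

# template backbone frame (matches the chain builder's ideal geometry)
_TEMPLATE_N = np.array([0.0, 0.0, 0.0])
_TEMPLATE_CA = np.array([1.458, 0.0, 0.0])


@dataclass
class RotamerLibrary:
    """Spin-label rotamers in a local backbone frame.

    ``backbone_frame``: (4, 3) template N, CA, C, CB positions used for
    superposition onto a labelling site. ``sidechain``: (n_rotamers,
    n_atoms, 3) heavy atoms beyond CB. ``electron``: (n_rotamers, 3)
    point-electron position per rotamer (N-O bond midpoint).
    ``weights``: prior rotamer populations (normalized).
    """

    backbone_frame: np.ndarray
    sidechain: np.ndarray
    electron: np.ndarray
    weights: np.ndarray
    atom_names: list[str]

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.weights = self.weights / self.weights.sum()
        if len(self.weights) != len(self.sidechain) or \
                len(self.electron) != len(self.sidechain):
            raise ValueError("inconsistent rotamer library arrays")

    @property
    def n_rotamers(self) -> int:
        return len(self.sidechain)


def _build_template_backbone() -> np.ndarray:
    """Ideal N, CA, C, CB of a cysteine-like residue in the local frame."""
    n, ca = _TEMPLATE_N, _TEMPLATE_CA
    ang = np.pi - 111.0 * _DEG
    c = ca + 1.525 * np.array([np.cos(ang), np.sin(ang), 0.0])
    cb = place_atom(n, c, ca, 1.530, 110.1 * _DEG, 122.6 * _DEG)
    return np.array([n, ca, c, cb])


def _build_rotamer(backbone: np.ndarray, chi: tuple) -> np.ndarray:
    """MTSL-like sidechain beyond CB from five dihedrals, ideal geometry."""
    n, ca, c, cb = backbone
    chi1, chi2, chi3, chi4, chi5 = (x * _DEG for x in chi)
    sg = place_atom(n, ca, cb, 1.81, 114.0 * _DEG, chi1)
    sd = place_atom(ca, cb, sg, 2.03, 104.0 * _DEG, chi2)
    ce = place_atom(cb, sg, sd, 1.81, 104.0 * _DEG, chi3)
    c3 = place_atom(sg, sd, ce, 1.51, 114.0 * _DEG, chi4)
    # rigid 5-membered nitroxide ring hung off C3, oriented by chi5
    c4 = place_atom(sd, ce, c3, 1.34, 125.0 * _DEG, chi5)
    c5 = place_atom(ce, c3, c4, 1.51, 112.0 * _DEG, 180.0 * _DEG)
    n1 = place_atom(c3, c4, c5, 1.47, 105.0 * _DEG, 0.0)
    o1 = place_atom(c4, c5, n1, 1.28, 123.0 * _DEG, 180.0 * _DEG)
    return np.array([sg, sd, ce, c3, c4, c5, n1, o1])


_ATOM_NAMES = ["SG", "SD", "CE", "C3", "C4", "C5", "N1", "O1"]

_CHI1 = (-60.0, 60.0, 180.0)
_CHI2 = (-60.0, 60.0, 180.0)
_CHI3 = (-60.0, 60.0, 180.0)
_CHI4 = (-90.0, 90.0)
_CHI5 = (-120.0, -60.0, 60.0, 120.0)


def default_library() -> RotamerLibrary:
    """The synthetic dihedral-enumerated 216-rotamer nitroxide library."""
    backbone = _build_template_backbone()
    rotamers, electrons = [], []
    for chi in product(_CHI1, _CHI2, _CHI3, _CHI4, _CHI5):
        atoms = _build_rotamer(backbone, chi)
        rotamers.append(atoms)
        electrons.append(0.5 * (atoms[-2] + atoms[-1]))  # N1-O1 midpoint
    rotamers = np.array(rotamers)
    assert len(rotamers) == 216
    return RotamerLibrary(
        backbone_frame=backbone,
        sidechain=rotamers,
        electron=np.array(electrons),
        weights=np.full(len(rotamers), 1.0),
        atom_names=list(_ATOM_NAMES))


def load_library(pdb_path, index_csv=None) -> RotamerLibrary:
    """Load an external rotamer library.

    ``pdb_path``: multi-model PDB, one rotamer per MODEL, containing the
    backbone atoms N, CA, C, CB plus the label sidechain with nitroxide
    atoms named N1 and O1. ``index_csv``: optional CSV with columns
    ``rotamer_id, weight`` giving prior populations (uniform if absent).
    """
    import pandas as pd

    from .ensemble import read_ensemble

    ens = read_ensemble(pdb_path)
    top = ens.topology
    names = top.atom_names
    def _one(name):
        idx = [i for i, nm in enumerate(names) if nm == name]
        if len(idx) != 1:
            raise ValueError(f"library must contain exactly one atom {name}")
        return idx[0]
    backbone_idx = [_one(n) for n in ("N", "CA", "C", "CB")]
    side_idx = [i for i in range(len(names))
                if i not in backbone_idx and names[i] not in ("H", "O")]
    n1, o1 = _one("N1"), _one("O1")
    frames = ens.coordinates
    backbone = frames[0][backbone_idx]
    sidechain = frames[:, side_idx, :]
    electron = 0.5 * (frames[:, n1, :] + frames[:, o1, :])
    if index_csv is not None:
        table = pd.read_csv(index_csv)
        weights = table.sort_values("rotamer_id")["weight"].to_numpy(float)
    else:
        weights = np.full(len(frames), 1.0)
    return RotamerLibrary(backbone, sidechain, electron, weights,
                          [names[i] for i in side_idx])
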