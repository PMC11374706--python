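"""Kabsch-Sander secondary-structure assignment ({H, E, coil} subset).

Backbone hydrogen bonds are detected with the Kabsch-Sander electrostatic
model,

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol,

a bond being assigned when E < -0.5 kcal/mol. Alpha-helix (H) comes from
consecutive i -> i+4 turns and extended strand (E) from parallel or
antiparallel bridges, exactly the subset needed for strand/helix content
of unfolded-state ensembles; the full eight-state alphabet (3-10 and pi
helices, turns, bends) is deliberately not reproduced.
"""

from __future__ import annotations

import numpy as np

from .ensemble import Ensemble

__all__ = ["kabsch_sander_hbonds", "assign_secondary_structure",
           "secondary_structure_fractions"]

_Q1Q2_F = 0.084 * 332.0  # kcal/mol when distances are in Å
_E_CUT = -0.5


def kabsch_sander_hbonds(conformer: np.ndarray, topology) -> np.ndarray:
    """Boolean matrix hb[i, j]: backbone N-H of residue i donates to C=O of j."""
    n_res = topology.n_residues
    ids = topology.residue_ids

    def _pos(rid, name):
        return conformer[topology.atom_index(rid, name)] \
            if topology.has_atom(rid, name) else None

    hb = np.zeros((n_res, n_res), dtype=bool)
    for i, rid_i in enumerate(ids):
        n = _pos(rid_i, "N")
        h = _pos(rid_i, "H")
        if n is None or h is None:
            continue
        for j, rid_j in enumerate(ids):
            if abs(i - j) < 2:
                continue
            cc = _pos(rid_j, "C")
            o = _pos(rid_j, "O")
            if cc is None or o is None:
                continue
            r_on = np.linalg.norm(o - n)
            if r_on > 5.2:   # cheap distance gate
                continue
            r_ch = np.linalg.norm(cc - h)
            r_oh = np.linalg.norm(o - h)
            r_cn = np.linalg.norm(cc - n)
            e = _Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if e < _E_CUT:
                hb[i, j] = True
    return hb


def assign_secondary_structure(conformer: np.ndarray, topology) -> np.ndarray:
    """Per-residue assignment: 'H' (alpha helix), 'E' (strand) or 'C' (coil)."""
    n_res = topology.n_residues
    hb = kabsch_sander_hbonds(conformer, topology)
    ss = np.full(n_res, "C", dtype="<U1")

    # alpha helix: two consecutive i -> i+4 turns cover residues i+1..i+4
    turn4 = np.zeros(n_res, dtype=bool)
    for i in range(n_res - 4):
        if hb[i + 4, i]:
            turn4[i] = True
    for i in range(1, n_res - 4):
        if turn4[i - 1] and turn4[i]:
            ss[i:i + 4] = "H"

    # bridges (strand)
    for i in range(1, n_res - 1):
        for j in range(i + 2, n_res - 1):
            antiparallel = (hb[i, j] and hb[j, i]) or \
                (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            parallel = (hb[i - 1, j] and hb[j, i + 1]) or \
                (hb[j - 1, i] and hb[i, j + 1])
            if antiparallel or parallel:
                if ss[i] != "H":
                    ss[i] = "E"
                if ss[j] != "H":
                    ss[j] = "E"
    return ss


def secondary_structure_fractions(ensemble: Ensemble):
    """Weighted per-residue and total strand/helix/coil fractions.

    Returns (residue_ids, per_residue DataFrame-like dict, totals dict).
    Residues missing backbone atoms stay coil and are excluded from totals.
    """
    top = ensemble.topology
    n_res = top.n_residues
    frac = {"H": np.zeros(n_res), "E": np.zeros(n_res), "C": np.zeros(n_res)}
    for w, x in zip(ensemble.weights, ensemble.coordinates):
        ss = assign_secondary_structure(x, top)
        for key in frac:
            frac[key] += w * (ss == key)
    totals = {key: float(frac[key].mean()) for key in frac}
    return top.residue_ids, frac, totals
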