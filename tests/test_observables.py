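"""Structural observables: gyration measures, hydrodynamic radius, shape,
contacts, surface area and clustering."""

import numpy as np
import pytest

from prefold.chains import build_extended_chain
from prefold.ensemble import Ensemble, Topology
from prefold.observables import (ContactDefinition, NativeContactParams,
                                 RhRelationParams, asphericity, cluster_gromos,
                                 contact_map, ensemble_rh, ensemble_sasa,
                                 fraction_native_contacts, hydration_radius,
                                 local_rg, long_range_profile,
                                 native_pairs_from_reference,
                                 polar_apolar_split, radius_of_gyration, sasa)


def _point_ensemble(points_list, weights=None):
    n_atoms = len(points_list[0])
    top = Topology(np.arange(1, n_atoms + 1), ["ALA"] * n_atoms,
                   ["CA"] * n_atoms, np.arange(n_atoms))
    return Ensemble(top, np.asarray(points_list, float), weights)


class TestGyration:
    def test_two_points_two_angstroms_apart(self):
        ens = _point_ensemble([[[0, 0, 0], [2, 0, 0]]])
        assert radius_of_gyration(ens.coordinates[0], ens.topology) == \
            pytest.approx(1.0)

    def test_regular_tetrahedron_matches_hand_computed_value(self):
        # oracle: all vertices at distance d from the centroid -> R_g = d
        verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                         float)
        ens = _point_ensemble([verts])
        assert radius_of_gyration(ens.coordinates[0], ens.topology) == \
            pytest.approx(np.sqrt(3.0), rel=1e-12)

    def test_rigid_rotation_invariance(self):
        from prefold.geometry import rotation_about_axis
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        rot = rotation_about_axis([1.0, 1.0, 0.2], 0.8)
        ens = _point_ensemble([pts])
        a = radius_of_gyration(pts, ens.topology)
        b = radius_of_gyration(pts @ rot.T + 3.0, ens.topology)
        assert a == pytest.approx(b, rel=1e-12)

    def test_uniform_scaling_scales_linearly(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        top = _point_ensemble([pts]).topology
        assert radius_of_gyration(2.5 * pts, top) == \
            pytest.approx(2.5 * radius_of_gyration(pts, top), rel=1e-12)

    def test_residue_range_selection(self):
        pts = np.array([[0, 0, 0], [2, 0, 0], [100, 0, 0]], float)
        top = _point_ensemble([pts]).topology
        assert radius_of_gyration(pts, top, residue_range=(1, 2)) == \
            pytest.approx(1.0)

    def test_local_rg_window_truncates_at_termini(self, small_coil):
        ids, vals = local_rg(small_coil, window=21)
        assert len(vals) == small_coil.topology.n_residues
        assert np.all(np.isfinite(vals))
        # interior windows average more residues -> larger local R_g
        assert vals[len(vals) // 2] > vals[0] * 0.5


class TestHydrationRadius:
    def test_printed_constants_worked_value(self):
        # direct evaluation of the empirical map at N = 114, R_g = 34.9 Å
        params = RhRelationParams(N=114)
        assert hydration_radius(34.9, params) == pytest.approx(31.96,
                                                               abs=0.02)

    def test_identical_conformers_reduce_to_single_value(self):
        ens = build_extended_chain("AKTVEGSL")
        stacked = Ensemble(ens.topology,
                           np.repeat(ens.coordinates, 4, axis=0))
        single = hydration_radius(
            radius_of_gyration(ens.coordinates[0], ens.topology),
            RhRelationParams(N=8))
        assert ensemble_rh(stacked, RhRelationParams(N=8)) == \
            pytest.approx(single, rel=1e-12)

    def test_diffusion_average_below_arithmetic_mean(self, small_coil):
        # Jensen: the exp(-1/Rh) average weights small radii more strongly
        params = RhRelationParams(N=small_coil.topology.n_residues)
        rhs = [hydration_radius(radius_of_gyration(x, small_coil.topology),
                                params) for x in small_coil.coordinates]
        assert ensemble_rh(small_coil, params) <= np.mean(rhs) + 1e-9

    def test_out_of_validity_range_errors(self):
        # short chains push the empirical denominator negative
        with pytest.raises(ValueError):
            hydration_radius(2.0, RhRelationParams(N=2))


class TestAsphericity:
    def test_sphere_surface_tends_to_zero(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(20000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        assert asphericity(v) < 0.01

    def test_collinear_points_give_one(self):
        pts = np.outer(np.linspace(0, 10, 7), [1.0, 2.0, -1.0])
        assert asphericity(pts) == pytest.approx(1.0, rel=1e-12)

    def test_matches_eigenvalue_oracle(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(50, 3)) * np.array([3.0, 1.0, 0.5])
        cen = pts - pts.mean(axis=0)
        lam = np.linalg.eigvalsh(cen.T @ cen / len(pts))
        expected = 1.5 * np.sum((lam - lam.mean()) ** 2) / lam.sum() ** 2
        assert asphericity(pts) == pytest.approx(expected, abs=1e-12)


class TestNativeContacts:
    def _reference(self):
        rng = np.random.default_rng(4)
        # compact reference cloud with CA topology
        pts = rng.normal(size=(20, 3)) * 4.0
        ens = _point_ensemble([pts])
        params = native_pairs_from_reference(pts, ens.topology)
        return pts, ens.topology, params

    def test_native_conformer_scores_near_one(self):
        pts, top, params = self._reference()
        q = fraction_native_contacts(pts, params)
        assert 0.95 <= q <= 1.0

    def test_sigmoid_midpoint_at_lambda_r0(self):
        pts, top, params = self._reference()
        # place every pair exactly at lambda * r0 via uniform scaling
        q = fraction_native_contacts(pts * params.lambda_fluct, params)
        assert q == pytest.approx(0.5, abs=0.05)

    def test_extended_chain_scores_low(self):
        pts, top, params = self._reference()
        stretched = pts * 10.0
        assert fraction_native_contacts(stretched, params) < 0.1


class TestContacts:
    def test_sequence_neighbours_always_in_contact(self, small_coil):
        p = contact_map(small_coil)
        first_off = np.array([p[i, i + 1]
                              for i in range(p.shape[0] - 1)])
        assert np.allclose(first_off, 1.0)

    def test_extended_chain_has_no_long_range_contacts(self):
        ens = build_extended_chain("A" * 40)
        _, prof = long_range_profile(ens)
        assert np.allclose(prof, 0.0)

    def test_map_is_symmetric(self, small_coil):
        p = contact_map(small_coil)
        assert np.allclose(p, p.T)

    def test_permutation_of_conformers_and_weights_is_invariant(
            self, small_coil):
        rng = np.random.default_rng(5)
        w = rng.dirichlet(np.ones(small_coil.n_conformers))
        ens = small_coil.with_weights(w)
        perm = rng.permutation(small_coil.n_conformers)
        permuted = Ensemble(small_coil.topology,
                            small_coil.coordinates[perm], w[perm])
        assert np.allclose(contact_map(ens), contact_map(permuted))


class TestSasa:
    def test_single_atom_closed_form(self):
        top = Topology([1], ["ALA"], ["CA"], [0])
        _, _, total = sasa(np.zeros((1, 3)), top)
        assert total == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2,
                                      rel=1e-12)

    def test_coincident_atoms_count_once(self):
        top = Topology([1, 2], ["ALA", "ALA"], ["CA", "CA"], [0, 1])
        _, _, total = sasa(np.zeros((2, 3)), top)
        assert total == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2,
                                      rel=1e-12)

    def test_enclosed_atom_is_buried(self):
        # central atom caged by 26 close neighbours
        grid = np.array([[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1)
                         for k in (-1, 0, 1)], float) * 1.6
        n = len(grid)
        top = Topology(np.arange(1, n + 1), ["ALA"] * n, ["CA"] * n,
                       np.arange(n))
        per_atom, _, _ = sasa(grid, top)
        centre = np.flatnonzero((grid == 0).all(axis=1))[0]
        assert per_atom[centre] == 0.0

    def test_polar_apolar_split_is_exact(self):
        ens = build_extended_chain("AKTVEG")
        per_atom, _, total = sasa(ens.coordinates[0], ens.topology)
        ap, po = polar_apolar_split(per_atom, ens.topology)
        assert ap + po == pytest.approx(total, rel=1e-12)

    def test_agrees_with_mdtraj_shrake_rupley(self):
        md = pytest.importorskip("mdtraj")
        from mdtraj.core import element as elem
        ens = build_extended_chain("AKTVEGSL")
        top = ens.topology
        heavy = [i for i, nm in enumerate(top.atom_names)
                 if not nm.startswith("H")]
        t = md.Topology()
        chain = t.add_chain()
        el = {"N": elem.nitrogen, "C": elem.carbon, "O": elem.oxygen,
              "S": elem.sulfur}
        res_handles = {}
        for i in heavy:
            r = top.atom_resindex[i]
            if r not in res_handles:
                res_handles[r] = t.add_residue(top.residue_names[r], chain,
                                               resSeq=int(top.residue_ids[r]))
            t.add_atom(top.atom_names[i], el[top.atom_names[i][0]],
                       res_handles[r])
        traj = md.Trajectory(ens.coordinates[0][heavy][None] / 10.0, t)
        ref = float(md.shrake_rupley(traj, n_sphere_points=960)[0].sum()) * 100.0
        _, _, ours = sasa(ens.coordinates[0], top)
        assert ours == pytest.approx(ref, rel=0.02)


class TestClustering:
    def test_identical_conformers_form_one_full_cluster(self):
        pts = np.random.default_rng(6).normal(size=(12, 3)) * 5.0
        ens = _point_ensemble([pts] * 5)
        clusters = cluster_gromos(ens, rmsd_cutoff=1.0)
        assert len(clusters) == 1
        assert clusters[0].population == pytest.approx(1.0)

    def test_two_separated_shapes_give_two_clusters(self):
        rng = np.random.default_rng(7)
        compact = rng.normal(size=(15, 3)) * 2.0
        rod = np.outer(np.linspace(0, 80, 15), [1.0, 0, 0])
        frames = [compact + rng.normal(0, 0.1, size=(15, 3))
                  for _ in range(4)]
        frames += [rod + rng.normal(0, 0.1, size=(15, 3)) for _ in range(2)]
        ens = _point_ensemble(frames)
        clusters = cluster_gromos(ens, rmsd_cutoff=5.0)
        assert len(clusters) == 2
        pops = sorted(c.population for c in clusters)
        assert pops == pytest.approx([2 / 6, 4 / 6])

    def test_populations_sum_to_one(self, small_coil):
        clusters = cluster_gromos(small_coil, rmsd_cutoff=6.0)
        assert sum(c.population for c in clusters) == pytest.approx(1.0)
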