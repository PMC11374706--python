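"""PRE forward model: rotamer attachment, Solomon-Bloembergen rates,
intensity ratios and tethering-corrected correlation times."""

import numpy as np
import pytest
from scipy.integrate import quad

from prefold import (PREEnsembleModel, PREParameters, attach_rotamers,
                     gamma2_from_ratio, intensity_ratio, reference_profile)
from prefold.chains import build_chain, build_extended_chain
from prefold.pre import _gamma2_from_moments, _vector_moments
from prefold.rotamers import RotamerLibrary, default_library


def _single_rotamer_library(offset=(10.0, 0.0, 0.0)):
    lib = default_library()
    pos = lib.backbone_frame[3] + np.asarray(offset)
    return RotamerLibrary(
        backbone_frame=lib.backbone_frame,
        sidechain=pos[None, None, :],
        electron=pos[None, :],
        weights=np.array([1.0]),
        atom_names=["X1"])


class TestAttachment:
    def test_isolated_residue_keeps_all_216_rotamers(self):
        ens = build_extended_chain("A")
        att = attach_rotamers(ens.coordinates[0], ens.topology, 1)
        assert att.n_allowed == 216

    def test_blocking_wall_removes_every_rotamer(self):
        # surround the site with a dense far-side-independent grid of
        # pseudo-backbone atoms so every rotamer position is within 2.5 Å
        ens = build_extended_chain("AA")
        top = ens.topology
        x = ens.coordinates[0].copy()
        att0 = attach_rotamers(x, top, 1)
        lib = default_library()
        # move residue 2's CA onto each rotamer in turn: cheap check that a
        # 2.0 Å contact kills a rotamer
        killed = 0
        for k in range(0, 216, 36):
            y = x.copy()
            # electron position of rotamer k after attachment at residue 1
            e = att0.electron_positions[list(att0.allowed).index(k)] \
                if k in att0.allowed else None
            if e is None:
                continue
            y[top.atom_index(2, "CA")] = e + np.array([2.0, 0.0, 0.0])
            att = attach_rotamers(y, top, 1, lib)
            assert k not in att.allowed
            killed += 1
        assert killed > 0

    def test_clash_boundary_is_strict_less_than(self):
        # a contact at exactly the cutoff is retained; just inside is not
        lib = _single_rotamer_library()
        ens = build_extended_chain("AA")
        top = ens.topology
        x = ens.coordinates[0].copy()
        att = attach_rotamers(x, top, 1, lib)
        assert att.n_allowed == 1
        rot_atom = att.electron_positions[0]
        blocker = top.atom_index(2, "CA")
        y = x.copy()
        y[blocker] = rot_atom + np.array([2.5, 0.0, 0.0])
        assert attach_rotamers(y, top, 1, lib).n_allowed == 1
        y[blocker] = rot_atom + np.array([2.4999, 0.0, 0.0])
        assert attach_rotamers(y, top, 1, lib).n_allowed == 0


class TestGamma2:
    def test_worked_value_at_20_angstrom(self):
        # independent oracle: direct evaluation of the Solomon-Bloembergen
        # prefactor and spectral density with CODATA constants, S(S+1)
        mu0_4pi = 1e-7
        gh, ge, mub = 2.6752218744e8, 2.00231930436, 9.2740100783e-24
        k = (mu0_4pi ** 2) * gh ** 2 * ge ** 2 * mub ** 2 * 0.75 / 15.0
        r6 = (20e-10) ** -6.0
        tau_c, tau_i = 5e-9, 500e-12
        tau_t = 1.0 / (1.0 / tau_c + 1.0 / tau_i)
        w = 2 * np.pi * 800e6
        # S2 = 1 for a single electron position
        j0 = r6 * tau_c
        jw = r6 * tau_c / (1 + (w * tau_c) ** 2)
        expected = k * (4 * j0 + 3 * jw)
        params = PREParameters(tau_c=5e-9)
        got = _gamma2_from_moments(20.0 ** -6, 20.0 ** -3, 1.0, 5e-9, params)
        # exact mu0 differs from 4 pi x 1e-7 in the 10th digit
        assert got == pytest.approx(expected, rel=1e-6)
        assert got == pytest.approx(3.86, rel=2e-3)

    def test_printed_spin_prefactor_toggle(self):
        # the as-printed S(S-1) form gives -1/3 of the standard S(S+1)
        # prefactor for S = 1/2 (and hence unphysical negative rates),
        # which is why it is a toggle rather than the default
        printed = PREParameters(printed_spin_prefactor=True).prefactor
        standard = PREParameters().prefactor
        assert printed == pytest.approx(-standard / 3.0, rel=1e-12)

    def test_r_to_the_minus_six_scaling(self):
        params = PREParameters(tau_c=5e-9)
        g1 = _gamma2_from_moments(10.0 ** -6, 10.0 ** -3, 1.0, 5e-9, params)
        g2 = _gamma2_from_moments(20.0 ** -6, 20.0 ** -3, 1.0, 5e-9, params)
        assert g1 / g2 == pytest.approx(64.0, rel=1e-12)

    def test_single_rotamer_order_parameter_is_one(self):
        vec = np.array([[3.0, 4.0, 12.0]])
        r6, r3, s2a = _vector_moments(vec[None, ...], np.array([1.0]))
        assert s2a[0] == pytest.approx(1.0, abs=1e-12)
        assert (r3[0] ** 2 / r6[0]) == pytest.approx(1.0, rel=1e-12)

    def test_isotropic_rotamers_have_vanishing_angular_s2(self):
        # Monte-Carlo oracle: |<Y2m>|^2 -> 0 for isotropic unit vectors
        rng = np.random.default_rng(0)
        v = rng.normal(size=(4000, 3))
        v = 15.0 * v / np.linalg.norm(v, axis=1, keepdims=True)
        _, _, s2a = _vector_moments(v[None, ...], np.full(4000, 1 / 4000))
        assert s2a[0] < 0.01

    def test_fixed_direction_radial_s2_matches_quadrature(self):
        # lengths uniform in [10, 20] Å along a fixed direction:
        # angular S2 = 1, radial S2 = <r^-6>^-1 <r^-3>^2 by 1D integrals
        lengths = np.linspace(10.0, 20.0, 2001)
        v = np.outer(lengths, np.array([1.0, 0.0, 0.0]))
        w = np.full(len(lengths), 1.0 / len(lengths))
        r6, r3, s2a = _vector_moments(v[None, ...], w)
        assert s2a[0] == pytest.approx(1.0, abs=1e-12)
        i6 = quad(lambda r: r ** -6 / 10.0, 10, 20)[0]
        i3 = quad(lambda r: r ** -3 / 10.0, 10, 20)[0]
        assert (r3[0] ** 2 / r6[0]) == pytest.approx(i3 ** 2 / i6, rel=1e-3)

    def test_rotation_translation_invariance(self, pre_params):
        from prefold.geometry import rotation_about_axis
        ens = build_extended_chain("AKTVEG")
        model = PREEnsembleModel(ens, [3], pre_params)
        g0 = model.mean_gamma2(3)
        rot = rotation_about_axis([1.0, 2.0, 0.5], 1.1)
        moved = ens.coordinates[0] @ rot.T + np.array([5.0, -3.0, 8.0])
        from prefold.ensemble import Ensemble
        model2 = PREEnsembleModel(Ensemble(ens.topology, moved[None]),
                                  [3], pre_params)
        ok = np.isfinite(g0)
        assert np.allclose(model2.mean_gamma2(3)[ok], g0[ok], rtol=1e-9)

    def test_ensemble_average_is_linear_in_weights(self, small_coil,
                                                   pre_params):
        model = PREEnsembleModel(small_coil, [10], pre_params)
        n = model.ensemble.n_conformers
        rng = np.random.default_rng(3)
        w1 = rng.dirichlet(np.ones(n))
        w2 = rng.dirichlet(np.ones(n))
        alpha = 0.3
        g_mix = model.mean_gamma2(10, weights=alpha * w1 + (1 - alpha) * w2)
        g_lin = alpha * model.mean_gamma2(10, weights=w1) \
            + (1 - alpha) * model.mean_gamma2(10, weights=w2)
        ok = np.isfinite(g_mix)
        assert np.allclose(g_mix[ok], g_lin[ok], rtol=1e-12)

    def test_order_parameter_never_exceeds_one(self, small_coil, pre_params):
        model = PREEnsembleModel(small_coil, [10], pre_params)
        r6, r3, s2a = model.moments[10]
        s2 = s2a * r3 ** 2 / r6
        assert np.all(s2[np.isfinite(s2)] <= 1.0 + 1e-9)


class TestIntensityRatio:
    def test_limits_and_worked_value(self):
        assert intensity_ratio(0.0) == pytest.approx(1.0)
        assert intensity_ratio(50.0, 100.0, 100.0, 5.43e-3) == \
            pytest.approx((2 / 3) * np.exp(-0.543) * (2 / 3), rel=1e-12)
        assert intensity_ratio(1e7) < 1e-12

    def test_inversion_round_trips(self):
        assert gamma2_from_ratio(1.0) == 0.0
        g = gamma2_from_ratio(0.2582233899393786, 100.0, 100.0, 5.43e-3)
        assert g == pytest.approx(50.0, abs=1e-3)
        rng = np.random.default_rng(7)
        ratios = rng.uniform(0.01, 0.999, size=100)
        back = intensity_ratio(gamma2_from_ratio(ratios))
        assert np.allclose(back, ratios, atol=1e-6)

    def test_ratio_above_one_rejected(self):
        with pytest.raises(ValueError):
            gamma2_from_ratio(1.05)


class TestReferenceProfile:
    def test_extended_polyalanine_profile_shape(self):
        prof = reference_profile(60, 30)
        # immediate neighbours of the site are fully broadened
        assert prof[29] < 0.01 and prof[31] < 0.01
        # monotone non-decreasing with separation beyond 2 residues
        right = prof[33:]
        assert np.all(np.diff(right) >= -1e-9)
        left = prof[1:28][::-1]   # residue 0 has no amide H
        assert np.all(np.diff(left) >= -1e-9)
        assert prof[-1] > 0.99


class TestTetheredTau:
    def test_single_conformer_is_rigid_limit(self, pre_params):
        ens = build_extended_chain("AKTVEG")
        model = PREEnsembleModel(ens, [3], pre_params)
        s2, tau = model.tethered_tau(3)
        ok = np.isfinite(ens.coordinates[0][:, 0])
        assert np.allclose(s2, 1.0)
        assert np.allclose(tau, pre_params.tau_r_70S)

    def test_heterogeneous_ensemble_interpolates_between_limits(
            self, small_tethered, pre_params):
        model = PREEnsembleModel(small_tethered, [20], pre_params)
        s2, tau = model.tethered_tau(20)
        ok = np.isfinite(s2)
        assert np.all((s2[ok] >= 0.0) & (s2[ok] <= 1.0))
        assert np.all(tau[ok] >= pre_params.tau_c_iso - 1e-15)
        assert np.all(tau[ok] <= pre_params.tau_r_70S + 1e-15)

    def test_tau_eff_stays_below_300ns_on_defaults(self, small_tethered,
                                                   pre_params):
        model = PREEnsembleModel(small_tethered, [20], pre_params)
        _, tau = model.tethered_tau(20)
        far = (np.abs(model.residue_ids - 20) > 3) & np.isfinite(tau)
        assert np.all(tau[far] < 300e-9)
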