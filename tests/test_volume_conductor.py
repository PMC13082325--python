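"""Volume-conductor solver: maximum principle, linearity,
superposition, the point-source law, current conservation and fiber
potential sampling."""

import numpy as np
import pytest

from clss.volume_conductor import (
    ArmModel,
    ElectrodePatch,
    PotentialField,
    current_density,
    sample_fiber_potential,
    solve_potential,
)
from tests.conftest import bipolar_pair


class TestGeometry:
    def test_radial_grid_resolves_every_layer(self):
        arm = ArmModel()
        edges = arm.radial_edges()
        for lo, hi in [(0, 10), (10, 35), (35, 38.5), (38.5, 40)]:
            inside = (edges > lo) & (edges <= hi)
            assert inside.sum() >= 2, f"layer ({lo}, {hi}] under-resolved"

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            ArmModel(radius_muscle_mm=9.0)

    def test_nonpositive_conductivity_rejected(self):
        with pytest.raises(ValueError, match="sigma_fat"):
            ArmModel(sigma_fat=0.0)

    def test_electrode_nominal_areas_equal_for_shape_set(self):
        d = 30.0
        circ = ElectrodePatch(shape="circle", size_mm=d)
        sq = ElectrodePatch(shape="square", size_mm=d * np.sqrt(np.pi) / 2)
        tri = ElectrodePatch(shape="triangle",
                             size_mm=d * np.sqrt(np.pi / np.sqrt(3)))
        assert sq.area_mm2() == pytest.approx(circ.area_mm2(), rel=1e-9)
        assert tri.area_mm2() == pytest.approx(circ.area_mm2(), rel=1e-9)


class TestSolver:
    def test_discrete_maximum_principle(self, coarse_field):
        applied = max(abs(e.potential_v) for e in coarse_field.electrodes)
        assert np.abs(coarse_field.potential).max() <= applied + 1e-12

    def test_antisymmetric_pair_gives_antisymmetric_field(self, coarse_field):
        v = coarse_field.potential
        np.testing.assert_allclose(v, -v[:, :, ::-1], atol=1e-6)

    def test_scaling_linearity(self, coarse_arm, coarse_field):
        f2 = solve_potential(coarse_arm, bipolar_pair(coarse_arm, voltage=3.0))
        np.testing.assert_allclose(f2.potential, 3.0 * coarse_field.potential,
                                   rtol=1e-9, atol=1e-9)

    def test_superposition_of_monopoles(self, coarse_arm, coarse_field):
        """Bipolar solution equals the sum of the two single-driven
        solutions (the silent patch held at 0 V)."""
        es = bipolar_pair(coarse_arm)
        e_cat = [ElectrodePatch(**{**es[0].__dict__}),
                 ElectrodePatch(**{**es[1].__dict__, "potential_v": 0.0})]
        e_an = [ElectrodePatch(**{**es[0].__dict__, "potential_v": 0.0}),
                ElectrodePatch(**{**es[1].__dict__})]
        v_sum = solve_potential(coarse_arm, e_cat).potential \
            + solve_potential(coarse_arm, e_an).potential
        np.testing.assert_allclose(v_sum, coarse_field.potential,
                                   atol=5e-8)

    def test_point_source_inverse_distance_law(self):
        """A small surface patch in a homogeneous cylinder approximates
        a point source on a half-space: V ~ I / (2 pi sigma r) (image
        doubling at the insulating surface), within 10% for
        r in [3, 10] mm.

        Compared in potential-difference form against a 25 mm
        reference depth on the same radial line: the finite cylinder
        adds a series channel-resistance offset to every sample, which
        the difference cancels while leaving the 1/r structure intact.
        """
        sigma = 0.3
        arm = ArmModel(sigma_bone=sigma, sigma_muscle=sigma, sigma_fat=sigma,
                       sigma_skin=sigma, dr_target_mm=0.75, dtheta_deg=3.0,
                       dz_mm=1.5, length_mm=240.0)
        src = ElectrodePatch(shape="circle", size_mm=3.0, center_z_mm=60.0,
                             potential_v=1.0, polarity="anode",
                             contact_impedance_kohm_cm2=0.0)
        ret = ElectrodePatch(shape="circle", size_mm=60.0, center_z_mm=200.0,
                             potential_v=0.0, contact_impedance_kohm_cm2=0.0)
        field = solve_potential(arm, [src, ret])
        current_a = field.surface_flux_ma[0] * 1e-3
        ref_mm = 25.0
        _, v_ref = sample_fiber_potential(field, ref_mm, 0.0,
                                          np.array([60.0]))
        for r in (3.0, 5.0, 7.0, 10.0):
            _, ve = sample_fiber_potential(field, r, 0.0, np.array([60.0]))
            got = ve[0] - v_ref[0]
            expected = current_a / (2 * np.pi * sigma) \
                * (1.0 / (r * 1e-3) - 1.0 / (ref_mm * 1e-3))
            assert got == pytest.approx(expected, rel=0.10)

    def test_missing_return_rejected(self, coarse_arm):
        with pytest.raises(ValueError, match="return"):
            solve_potential(coarse_arm, [ElectrodePatch(potential_v=1.0,
                                                        polarity="anode")])

    def test_overlapping_electrodes_rejected(self, coarse_arm):
        es = bipolar_pair(coarse_arm, spacing=10.0)
        with pytest.raises(ValueError, match="overlap"):
            solve_potential(coarse_arm, es)

    def test_grid_refinement_convergence(self):
        """Halving the default azimuthal/axial spacing changes the
        sampled fiber potential by < 5%."""
        base = ArmModel()
        halved = ArmModel(dtheta_deg=base.dtheta_deg / 2,
                          dz_mm=base.dz_mm / 2)
        z = np.linspace(80, 220, 57)
        f1 = solve_potential(base, bipolar_pair(base))
        f2 = solve_potential(halved, bipolar_pair(halved))
        _, v1 = sample_fiber_potential(f1, 5.0, 0.0, z)
        _, v2 = sample_fiber_potential(f2, 5.0, 0.0, z)
        scale = np.max(np.abs(v2))
        assert np.max(np.abs(v1 - v2)) < 0.05 * scale


class TestCurrentDensity:
    def test_uniform_axial_gradient_gives_constant_jz(self, coarse_arm):
        arm = ArmModel(sigma_bone=0.2, sigma_muscle=0.2, sigma_fat=0.2,
                       sigma_skin=0.2, dr_target_mm=2.0, dtheta_deg=10.0,
                       dz_mm=5.0)
        edges = arm.radial_edges()
        r_cent = 0.5 * (edges[:-1] + edges[1:])
        th = np.arange(0, 360, 10.0) + 5.0
        z = np.arange(0, 300, 5.0) + 2.5
        v = np.broadcast_to(0.01 * z, (r_cent.size, th.size, z.size))
        field = PotentialField(potential=np.array(v), r_centers_mm=r_cent,
                               theta_centers_deg=th, z_centers_mm=z,
                               arm=arm, residual=0.0)
        j_r, j_th, j_z = current_density(field)
        np.testing.assert_allclose(j_z, j_z.flat[0], rtol=1e-9)
        np.testing.assert_allclose(j_r, 0.0, atol=1e-12)
        assert j_z.flat[0] == pytest.approx(-0.2 * 0.01 * 1e3)

    def test_charge_conservation_between_electrodes(self, coarse_field):
        """Net current leaving the anode equals the current entering
        the cathode within 2% (surface-flux integration)."""
        i_cat = coarse_field.surface_flux_ma[0]
        i_an = coarse_field.surface_flux_ma[1]
        assert abs(i_cat + i_an) <= 0.02 * abs(i_an)

    def test_current_density_peaks_near_electrode(self, coarse_field):
        j_r, j_th, j_z = current_density(coarse_field)
        mag = np.sqrt(j_r**2 + j_th**2 + j_z**2)
        i_max, j_max, k_max = np.unravel_index(mag.argmax(), mag.shape)
        # in conductive tissue beneath the patch (not in the bone core),
        # axially adjacent to an electrode and at the electrode azimuth
        assert coarse_field.r_centers_mm[i_max] > \
            coarse_field.arm.radius_bone_mm
        e_z = [e.center_z_mm for e in coarse_field.electrodes]
        z_peak = coarse_field.z_centers_mm[k_max]
        assert min(abs(z_peak - ez) for ez in e_z) <= 20.0
        az = coarse_field.theta_centers_deg[j_max]
        assert min(az, 360.0 - az) <= 30.0


class TestFiberPotential:
    def test_peak_to_peak_decreases_with_depth(self, coarse_field):
        _, v1 = sample_fiber_potential(coarse_field, 1.0, 0.0)
        _, v16 = sample_fiber_potential(coarse_field, 16.0, 0.0)
        assert np.ptp(v1) > np.ptp(v16)

    def test_extremum_under_cathode(self, coarse_field):
        """V_e dips to a local minimum beneath the cathode patch."""
        z, ve = sample_fiber_potential(coarse_field, 2.0, 0.0)
        cathode_z = coarse_field.electrodes[0].center_z_mm
        k = np.argmin(np.abs(z - cathode_z))
        assert ve[k] == np.min(ve[max(0, k - 10):k + 10])
        # curvature flips sign around the trough
        curv = np.diff(ve, 2)
        assert curv[max(0, k - 10):k + 10].max() > 0

    def test_zero_applied_potential_gives_zero_ve(self, coarse_arm):
        es = bipolar_pair(coarse_arm, voltage=0.0)
        field = solve_potential(coarse_arm, es)
        _, ve = sample_fiber_potential(field, 5.0, 0.0)
        np.testing.assert_allclose(ve, 0.0, atol=1e-12)

    def test_depth_outside_tissue_rejected(self, coarse_field):
        with pytest.raises(ValueError, match="depth"):
            sample_fiber_potential(coarse_field, 45.0, 0.0)
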