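"""Cable-model fiber activation: activating function, thresholds,
population structure, counting and screen/confirm consistency."""

import numpy as np
import pytest

from clss.fiber_activation import (
    Fiber,
    FiberPopulation,
    activating_function,
    af_screen,
    build_population,
    count_activated,
    find_threshold,
    run_sweep,
    simulate_fiber,
)
from clss.stimulation import make_biphasic
from clss.volume_conductor import sample_fiber_potential

FS_STIM = 2e6


def pulse(amplitude, pw=200.0):
    return make_biphasic(amplitude, pw, 0.0, 50.0, 1.0 / 50.0, FS_STIM)


class TestActivatingFunction:
    def test_linear_profile_gives_zero(self):
        f = activating_function(np.linspace(0.0, 5.0, 21))
        np.testing.assert_allclose(f, 0.0, atol=1e-12)

    def test_quadratic_profile_gives_constant_two(self):
        x = np.arange(15.0)
        f = activating_function(x**2)
        np.testing.assert_allclose(f[1:-1], 2.0, rtol=1e-12)

    def test_point_source_polarity_structure(self):
        """1/r potential of a point cathode over the fiber: central
        positive AF peak flanked by negative lobes; anode flips it."""
        x = np.linspace(-20, 20, 41)
        h = 5.0
        v_cathode = -1.0 / np.sqrt(x**2 + h**2)
        f_cat = activating_function(v_cathode)
        center = len(x) // 2
        assert f_cat[center] > 0
        assert f_cat[1:-1].min() < 0
        interior = f_cat[1:-1]
        assert np.argmax(interior) == center - 1
        f_an = activating_function(-v_cathode)
        np.testing.assert_allclose(f_an, -f_cat, rtol=1e-12)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            activating_function(np.array([1.0, 2.0]))


class TestFiberGeometry:
    def test_node_spacing_is_100_diameters(self):
        fib = Fiber(diameter_um=12.0)
        assert fib.node_spacing_mm == pytest.approx(1.2)
        z = fib.node_z_mm()
        np.testing.assert_allclose(np.diff(z), 1.2)

    def test_default_population_structure(self):
        pop = build_population()
        assert pop.depths_mm.max() == 16.0
        assert pop.depths_mm.min() == 1.0
        assert len(pop) == 16 * 72
        # all fibers parallel to the axis: same node-z grid everywhere
        z0 = pop.fibers[0].node_z_mm()
        np.testing.assert_array_equal(pop.fibers[-1].node_z_mm(), z0)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_population(depth_range_mm=(10.0, 5.0))

    def test_depth_outside_tissue_rejected(self):
        with pytest.raises(ValueError, match="tissue"):
            build_population(depth_range_mm=(1.0, 45.0))


@pytest.fixture(scope="module")
def ve_at(coarse_field):
    def _get(depth, diameter=10.0):
        fib = Fiber(depth_mm=depth, diameter_um=diameter)
        _, ve = sample_fiber_potential(coarse_field, depth, 0.0,
                                       fib.node_z_mm())
        return fib, ve
    return _get


class TestSingleFiber:

    def test_zero_amplitude_stays_at_rest(self, ve_at):
        fib, ve = ve_at(5.0)
        activated, peak = simulate_fiber(fib, ve, pulse(0.0), 0.5)
        assert not activated
        assert np.max(np.abs(peak)) < 0.1

    def test_threshold_monotone_in_depth(self, ve_at):
        thr = []
        for depth in (2.0, 8.0, 14.0):
            fib, ve = ve_at(depth)
            thr.append(find_threshold(fib, ve, 0.5, n_bisect=10))
        assert thr[0] < thr[1] < thr[2]

    def test_inverse_recruitment_threshold_falls_with_diameter(self, ve_at):
        thr = []
        for diameter in (5.0, 10.0, 15.0):
            fib, ve = ve_at(6.0, diameter)
            thr.append(find_threshold(fib, ve, 0.5, n_bisect=10))
        assert thr[0] > thr[1] > thr[2]

    def test_strength_duration_monotone(self, ve_at):
        """Threshold amplitude decreases with phase width, 50-500 us."""
        fib, ve = ve_at(5.0)
        thr = [find_threshold(fib, ve, 0.5, phase_width_us=pw, n_bisect=12)
               for pw in (50.0, 125.0, 250.0, 500.0)]
        assert all(a >= b for a, b in zip(thr, thr[1:]))
        assert thr[0] > thr[-1]

    def test_coarse_time_step_rejected(self, ve_at):
        fib, ve = ve_at(5.0)
        with pytest.raises(ValueError, match="time step"):
            simulate_fiber(fib, ve, pulse(1.0), 0.5, dt_ms=0.1)


@pytest.fixture(scope="module")
def small_population(coarse_arm):
    return build_population(depth_step_mm=2.0, azimuth_step_deg=15.0,
                            arm=coarse_arm)


class TestCounting:
    def test_zero_voltage_activates_nothing(self, small_population,
                                            coarse_field):
        res = count_activated(small_population, coarse_field, pulse(0.0))
        assert res.count == 0

    def test_count_monotone_in_amplitude(self, small_population,
                                         coarse_field):
        lo = count_activated(small_population, coarse_field, pulse(10.0))
        hi = count_activated(small_population, coarse_field, pulse(20.0))
        assert hi.count >= lo.count
        assert hi.count > 0

    def test_activation_clusters_beneath_electrodes(self, small_population,
                                                    coarse_field):
        """Activated fibers concentrate at the electrode azimuth."""
        res = count_activated(small_population, coarse_field, pulse(15.0))
        az = small_population.azimuths_deg[res.activated]
        assert az.size > 0
        # electrode azimuth is 0 deg; fold to [-180, 180)
        folded = (az + 180.0) % 360.0 - 180.0
        assert np.median(np.abs(folded)) <= 45.0

    def test_determinism(self, small_population, coarse_field):
        r1 = count_activated(small_population, coarse_field, pulse(15.0))
        r2 = count_activated(small_population, coarse_field, pulse(15.0))
        np.testing.assert_array_equal(r1.activated, r2.activated)

    def test_screen_agrees_with_cable_model_off_boundary(
            self, small_population, coarse_field):
        """The activating-function screen matches the full cable model
        for fibers away (>2x) from the calibrated threshold."""
        wf = pulse(15.0)
        full = count_activated(small_population, coarse_field, wf)
        flags, peaks, af_star = af_screen(small_population, coarse_field, wf,
                                          return_details=True)
        assert np.isfinite(af_star)
        far = (peaks > 2.0 * af_star) | (peaks < 0.5 * af_star)
        agree = flags[far] == full.activated[far]
        assert far.sum() > 0
        assert agree.mean() >= 0.95


class TestSweeps:
    def test_invalid_axis_rejected(self, coarse_arm, small_population):
        with pytest.raises(ValueError, match="axis"):
            run_sweep("thickness", [1, 2], arm=coarse_arm,
                      population=small_population)

    def test_voltage_sweep_positive_correlation(self, coarse_arm,
                                                small_population):
        df = run_sweep("voltage", [10.0, 30.0, 50.0], arm=coarse_arm,
                       population=small_population)
        counts = df["activated_count"].to_numpy()
        assert np.all(np.diff(counts) >= 0)
        assert counts[-1] > counts[0]

    def test_table_carries_provenance_hash(self, coarse_arm,
                                           small_population):
        df = run_sweep("voltage", [20.0], arm=coarse_arm,
                       population=small_population)
        assert df["config_hash"].nunique() == 1
        assert len(df["config_hash"].iloc[0]) == 12


def test_population_requires_fibers():
    with pytest.raises(ValueError, match="empty"):
        FiberPopulation([])
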