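"""Myelinated nerve-fiber activation under transcutaneous stimulation.

Step two of the two-step simulation.  Fibers run parallel to the arm
axis at depths 1–16 mm beneath the skin.  Each fiber is a chain of
nodes of Ranvier (spacing 100x the fiber diameter) coupled by
internodal axoplasm; the myelin is treated as a perfect insulator, so
the membrane dynamics live at the nodes only.  Nodal kinetics follow
the CRRSS mammalian formulation (sodium + leak, 37 deg C).  The
extracellular potential enters through its second spatial difference
along the fiber — the activating function — via the classical cable
source term, and the quasi-static factorization V_e(x, t) =
V_e(x) * s(t) couples the (linear) volume-conductor solution to the
stimulus waveform.  A fiber counts as activated when any node's
membrane potential crosses 0 mV absolute (80 mV depolarization from
the -80 mV rest).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimulation import StimWaveform, make_biphasic
from .volume_conductor import (
    ArmModel,
    ElectrodePatch,
    PotentialField,
    sample_fiber_potential,
    solve_potential,
)

__all__ = [
    "Fiber", "FiberPopulation", "ActivationResult",
    "activating_function", "simulate_fiber", "find_threshold",
    "build_population", "count_activated", "run_sweep",
]

# --- CRRSS nodal membrane constants (37 deg C) -----------------------------
G_NA = 1445.0      # sodium conductance, mS/cm^2
G_L = 128.0        # leak conductance, mS/cm^2
E_NA = 115.0       # sodium reversal, mV above rest
E_L = 0.0          # leak reversal at rest
C_M = 2.5          # membrane capacitance, uF/cm^2
RHO_AXIAL = 54.7   # axoplasmic resistivity, Ohm*cm
NODE_LENGTH_UM = 1.5
AXON_RATIO = 0.7   # axon diameter / fiber diameter
V_REST_MV = -80.0
DEPOL_THRESHOLD_MV = 80.0   # deviation giving 0 mV absolute


def _rates(v: np.ndarray):
    """CRRSS gating rate constants (1/ms); v is mV above rest.

    The argument is clamped to [-120, 180] mV: outside that range the
    exponentials overflow while the rates are already saturated, and
    transient excursions beyond it occur only under supra-threshold
    stimuli whose outcome the clamp does not change.
    """
    v = np.clip(v, -120.0, 180.0)
    am = (126.0 + 0.363 * v) / (1.0 + np.exp(-(v - 49.0) / 5.3))
    bm = am / np.exp((v - 56.2) / 4.17)
    bh = 15.6 / (1.0 + np.exp(-(v - 56.0) / 10.0))
    ah = bh / np.exp((v - 74.5) / 5.0)
    return am, bm, ah, bh


@dataclass
class Fiber:
    """An axial myelinated fiber: diameter, position, node geometry.

    When ``n_nodes`` is not given it is derived from ``span_mm`` so
    that fibers of any diameter cover the same axial extent (they run
    the length of the forearm segment and pass beneath the
    electrodes); node spacing is always 100 x diameter.
    """

    diameter_um: float = 10.0
    depth_mm: float = 5.0
    azimuth_deg: float = 0.0
    n_nodes: int | None = None
    center_z_mm: float = 150.0
    span_mm: float = 200.0

    def __post_init__(self):
        if self.diameter_um <= 0:
            raise ValueError("fiber diameter must be positive")
        if self.n_nodes is None:
            self.n_nodes = int(round(self.span_mm / self.node_spacing_mm)) + 1
        if self.n_nodes < 3:
            raise ValueError("need at least 3 nodes")

    @property
    def node_spacing_mm(self) -> float:
        """Internodal spacing L = 100 x diameter."""
        return 100.0 * self.diameter_um * 1e-3

    def node_z_mm(self) -> np.ndarray:
        L = self.node_spacing_mm
        offsets = (np.arange(self.n_nodes) - (self.n_nodes - 1) / 2) * L
        return self.center_z_mm + offsets

    # electrical parameters in (mS, uF, mV, ms, uA) units
    def axial_conductance_ms(self) -> float:
        d_cm = AXON_RATIO * self.diameter_um * 1e-4
        L_cm = self.node_spacing_mm * 0.1
        return 1e3 * np.pi * d_cm**2 / (4.0 * RHO_AXIAL * L_cm)  # mS

    def node_area_cm2(self) -> float:
        d_cm = AXON_RATIO * self.diameter_um * 1e-4
        return np.pi * d_cm * NODE_LENGTH_UM * 1e-4


@dataclass
class FiberPopulation:
    fibers: list

    def __post_init__(self):
        if not self.fibers:
            raise ValueError("empty fiber population")

    def __len__(self):
        return len(self.fibers)

    @property
    def depths_mm(self) -> np.ndarray:
        return np.array([f.depth_mm for f in self.fibers])

    @property
    def azimuths_deg(self) -> np.ndarray:
        return np.array([f.azimuth_deg for f in self.fibers])


@dataclass
class ActivationResult:
    activated: np.ndarray          # per-fiber boolean flags
    sweep_meta: dict = field(default_factory=dict)

    @property
    def count(self) -> int:
        return int(np.count_nonzero(self.activated))


def activating_function(ve: np.ndarray) -> np.ndarray:
    """Second difference of the extracellular potential along the fiber.

    ``f_n = ve[n-1] - 2 ve[n] + ve[n+1]`` for interior nodes; the two
    terminal nodes get 0 (sealed ends contribute no axial drive
    beyond the chain).  Positive peaks mark candidate depolarization
    sites.
    """
    ve = np.asarray(ve, dtype=float)
    if ve.shape[-1] < 3:
        raise ValueError("need at least 3 nodes")
    f = np.zeros_like(ve)
    f[..., 1:-1] = ve[..., :-2] - 2.0 * ve[..., 1:-1] + ve[..., 2:]
    return f


def _waveform_scale(waveform: StimWaveform, field_ref_v: float,
                    dt_ms: float, extra_ms: float = 1.0,
                    monophasic: bool = False) -> np.ndarray:
    """Per-timestep multiplier s(t) of the solved field for one pulse.

    The volume conductor was solved at electrode potentials of
    magnitude ``field_ref_v``; the waveform rescales them sample by
    sample (quasi-static linearity).  The leading phase reproduces the
    solved polarity at amplitude/ref scaling.  ``monophasic=True``
    drops the reversal phase — used for electrode-polarity studies,
    where a symmetric biphasic pulse would deliver both polarities and
    mask the asymmetry.
    """
    pw_ms = waveform.phase_width_us * 1e-3
    gap_ms = waveform.gap_us * 1e-3
    total_ms = 2 * pw_ms + gap_ms + extra_ms
    t = np.arange(0.0, total_ms, dt_ms)
    s = np.zeros_like(t)
    a = waveform.amplitude_v / field_ref_v
    s[t < pw_ms] = a
    if not monophasic:
        s[(t >= pw_ms + gap_ms) & (t < 2 * pw_ms + gap_ms)] = -a
    return s


def _simulate_batch(ve_nodes_mv: np.ndarray, ga_ms: np.ndarray,
                    area_cm2: np.ndarray, scale: np.ndarray,
                    dt_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Semi-implicit cable integration for a batch of fibers.

    ``ve_nodes_mv``: (F, N) extracellular potential at nodes for the
    reference solve, in mV.  Returns (activated flags, peak V trace
    (F, N) maximal deviation over time).
    """
    n_f, n_n = ve_nodes_mv.shape
    v = np.zeros((n_f, n_n))                 # deviation from rest, mV
    am, bm, ah, bh = _rates(v)
    m = am / (am + bm)
    h = ah / (ah + bh)
    c = C_M * area_cm2                        # uF, (F, 1)
    ga = ga_ms                                # mS, (F, 1)
    peak = np.zeros_like(v)

    # tridiagonal structure: -ga on off-diagonals, sealed ends
    lower = np.full(n_n, -1.0); lower[0] = 0.0
    upper = np.full(n_n, -1.0); upper[-1] = 0.0
    lap_diag = np.full(n_n, 2.0); lap_diag[0] = lap_diag[-1] = 1.0

    for s_t in scale:
        ve = ve_nodes_mv * s_t
        # gating (exponential Euler at current voltage)
        am, bm, ah, bh = _rates(v)
        m = m + dt_ms * (am * (1 - m) - bm * m)
        h = h + dt_ms * (ah * (1 - h) - bh * h)
        np.clip(m, 0.0, 1.0, out=m)
        np.clip(h, 0.0, 1.0, out=h)
        g_na = G_NA * m**2 * h                # mS/cm^2, (F, N)
        g_tot = (g_na + G_L) * area_cm2       # mS
        # axial drive from the extracellular field (activating function)
        f_ve = np.zeros_like(ve)
        f_ve[:, 1:-1] = ve[:, :-2] - 2 * ve[:, 1:-1] + ve[:, 2:]
        f_ve[:, 0] = ve[:, 1] - ve[:, 0]
        f_ve[:, -1] = ve[:, -2] - ve[:, -1]
        rhs = (c / dt_ms) * v + ga * f_ve \
            + (g_na * E_NA + G_L * E_L) * area_cm2
        # (C/dt + g_tot) v_new + ga * Lap v_new = rhs  (backward Euler,
        # ionic conductances frozen over the step)
        diag = (c / dt_ms) + g_tot + ga * lap_diag[None, :]
        lo = ga * lower[None, :]
        up = ga * upper[None, :]
        v = _thomas(lo, diag, up, rhs)
        np.maximum(peak, v, out=peak)
    activated = peak.max(axis=1) >= DEPOL_THRESHOLD_MV
    return activated, peak


def _thomas(lower: np.ndarray, diag: np.ndarray, upper: np.ndarray,
            rhs: np.ndarray) -> np.ndarray:
    """Vectorized Thomas solve of (F) tridiagonal systems of size N.

    ``lower[:, i]`` couples node i to i-1, ``upper[:, i]`` to i+1.
    """
    n = diag.shape[1]
    cp = np.empty_like(diag)
    dp = np.empty_like(rhs)
    cp[:, 0] = upper[:, 0] / diag[:, 0]
    dp[:, 0] = rhs[:, 0] / diag[:, 0]
    for i in range(1, n):
        denom = diag[:, i] - lower[:, i] * cp[:, i - 1]
        cp[:, i] = upper[:, i] / denom
        dp[:, i] = (rhs[:, i] - lower[:, i] * dp[:, i - 1]) / denom
    x = np.empty_like(rhs)
    x[:, -1] = dp[:, -1]
    for i in range(n - 2, -1, -1):
        x[:, i] = dp[:, i] - cp[:, i] * x[:, i + 1]
    return x


def simulate_fiber(fiber: Fiber, ve_profile_v: np.ndarray,
                   waveform: StimWaveform, field_ref_v: float = 1.0,
                   dt_ms: float = 0.005, extra_ms: float = 1.0):
    """Integrate one fiber over a single stimulus pulse plus 1 ms.

    ``ve_profile_v`` is the extracellular potential at the fiber's
    nodes (volts) from a volume-conductor solve at reference electrode
    magnitude ``field_ref_v``.  Returns ``(activated, peak_mv)`` where
    ``peak_mv`` is each node's maximal depolarization.
    """
    if dt_ms > 0.025:
        raise ValueError("time step too coarse for stable gating integration")
    ve_mv = np.asarray(ve_profile_v, dtype=float)[None, :] * 1e3
    if ve_mv.shape[1] != fiber.n_nodes:
        raise ValueError("potential profile length must equal node count")
    scale = _waveform_scale(waveform, field_ref_v, dt_ms, extra_ms)
    act, peak = _simulate_batch(
        ve_mv,
        np.array([[fiber.axial_conductance_ms()]]),
        np.array([[fiber.node_area_cm2()]]),
        scale, dt_ms)
    return bool(act[0]), peak[0]


def find_threshold(fiber: Fiber, ve_profile_v: np.ndarray,
                   field_ref_v: float = 1.0,
                   phase_width_us: float = 200.0,
                   lo_v: float = 0.01, hi_v: float = 500.0,
                   n_bisect: int = 14, dt_ms: float = 0.005) -> float:
    """Threshold stimulus amplitude (volts) by bisection.

    Returns inf when even ``hi_v`` fails to activate.
    """
    def fires(a: float) -> bool:
        wf = make_biphasic(a, phase_width_us, 0.0, 50.0, 1.0 / 50.0, 2e6)
        act, _ = simulate_fiber(fiber, ve_profile_v, wf, field_ref_v, dt_ms)
        return act

    if not fires(hi_v):
        return np.inf
    if fires(lo_v):
        return lo_v
    for _ in range(n_bisect):
        mid = np.sqrt(lo_v * hi_v)
        if fires(mid):
            hi_v = mid
        else:
            lo_v = mid
    return hi_v


def build_population(depth_range_mm: tuple = (1.0, 16.0),
                     depth_step_mm: float = 1.0,
                     azimuth_step_deg: float = 5.0,
                     diameter_um: float = 10.0,
                     n_nodes: int | None = None,
                     center_z_mm: float = 150.0,
                     span_mm: float = 200.0,
                     arm: ArmModel | None = None) -> FiberPopulation:
    """The default deterministic fiber grid: depths 1..16 mm (1 mm
    step) x azimuths every 5 degrees, all parallel to the arm axis."""
    lo, hi = depth_range_mm
    if hi < lo:
        raise ValueError("empty depth range")
    arm = arm or ArmModel()
    if lo <= 0 or hi >= arm.radius_skin_mm:
        raise ValueError("depth range extends outside the tissue")
    depths = np.arange(lo, hi + 0.5 * depth_step_mm, depth_step_mm)
    azimuths = np.arange(0.0, 360.0, azimuth_step_deg)
    fibers = [
        Fiber(diameter_um=diameter_um, depth_mm=float(d),
              azimuth_deg=float(a), n_nodes=n_nodes, center_z_mm=center_z_mm,
              span_mm=span_mm)
        for d in depths for a in azimuths
    ]
    return FiberPopulation(fibers)


def count_activated(population: FiberPopulation, field: PotentialField,
                    waveform: StimWaveform, dt_ms: float = 0.005,
                    meta: dict | None = None,
                    monophasic: bool = False) -> ActivationResult:
    """Run the cable model over the whole population and count fibers.

    All fibers are integrated in one vectorized batch; deterministic
    (no randomness anywhere in this module).
    """
    ref = max(abs(e.potential_v) for e in field.electrodes)
    if ref == 0:
        return ActivationResult(
            activated=np.zeros(len(population), dtype=bool),
            sweep_meta=meta or {})
    interp = field.interpolator()
    outer = field.arm.radius_skin_mm
    ve = np.empty((len(population), population.fibers[0].n_nodes))
    ga = np.empty((len(population), 1))
    area = np.empty((len(population), 1))
    for i, f in enumerate(population.fibers):
        z = f.node_z_mm()
        pts = np.column_stack([
            np.full(z.size, outer - f.depth_mm),
            np.full(z.size, f.azimuth_deg % 360.0), z])
        ve[i] = interp(pts) * 1e3      # volts -> mV
        ga[i, 0] = f.axial_conductance_ms()
        area[i, 0] = f.node_area_cm2()
    scale = _waveform_scale(waveform, ref, dt_ms, monophasic=monophasic)
    activated, _ = _simulate_batch(ve, ga, area, scale, dt_ms)
    return ActivationResult(activated=activated, sweep_meta=meta or {})


def af_screen(population: FiberPopulation, field: PotentialField,
              waveform: StimWaveform, threshold_fiber_index: int | None = None,
              dt_ms: float = 0.005, return_details: bool = False):
    """Fast activating-function screen of the population.

    A reference fiber (default: the population's median-AF fiber) is
    taken through the full cable model by amplitude bisection to
    calibrate the AF peak that corresponds to threshold; every fiber
    is then classified by comparing its own AF peak (scaled by the
    waveform amplitude) against that calibrated value.
    """
    ref = max(abs(e.potential_v) for e in field.electrodes)
    interp = field.interpolator()
    outer = field.arm.radius_skin_mm
    peaks = np.empty(len(population))
    ves = []
    for i, f in enumerate(population.fibers):
        z = f.node_z_mm()
        pts = np.column_stack([
            np.full(z.size, outer - f.depth_mm),
            np.full(z.size, f.azimuth_deg % 360.0), z])
        ve = interp(pts)
        ves.append(ve)
        # solved field already carries its own sign; drive scales +A/ref
        peaks[i] = np.max(activating_function(ve)) * waveform.amplitude_v / ref
    if threshold_fiber_index is None:
        # calibrate on a strongly driven fiber (one that can actually
        # be brought to threshold); walk down the AF ranking if needed
        order = np.argsort(peaks)[::-1]
        candidates = [int(order[min(len(order) - 1, int(q * len(order)))])
                      for q in (0.2, 0.1, 0.05, 0.0)]
    else:
        candidates = [threshold_fiber_index]
    thr_amp, idx_used = np.inf, candidates[-1]
    for idx in candidates:
        thr_amp = find_threshold(population.fibers[idx], ves[idx], ref,
                                 waveform.phase_width_us, dt_ms=dt_ms)
        if np.isfinite(thr_amp):
            idx_used = idx
            break
    if not np.isfinite(thr_amp):
        flags = np.zeros(len(population), dtype=bool)
        return (flags, peaks, np.inf) if return_details else flags
    af_star = np.max(activating_function(ves[idx_used])) * thr_amp / ref
    flags = peaks >= af_star
    return (flags, peaks, af_star) if return_details else flags


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_sweep(axis: str, values, arm: ArmModel | None = None,
              population: FiberPopulation | None = None,
              voltage_v: float = 30.0, spacing_mm: float = 75.0,
              electrode_diameter_mm: float = 30.0,
              phase_width_us: float = 200.0,
              return_diameter_mm: float | None = None,
              dt_ms: float = 0.005) -> pd.DataFrame:
    """Electrode-design sweep: one field solve + count per grid point.

    ``axis`` is one of voltage, spacing, diameter, shape, orientation,
    polarity.  The base configuration is a bipolar pair of equal-area
    circular electrodes at +/- V/2 along the arm axis.  A voltage
    sweep reuses a single solve (the problem is linear in the applied
    potentials).  Returns a table with the swept value, activated
    count and a config hash for provenance.
    """
    valid = {"voltage", "spacing", "diameter", "shape", "orientation", "polarity"}
    if axis not in valid:
        raise ValueError(f"axis must be one of {sorted(valid)}")
    arm = arm or ArmModel()
    population = population or build_population(arm=arm)
    z_mid = arm.length_mm / 2.0

    def electrodes(spacing=spacing_mm, diam=electrode_diameter_mm,
                   shape="circle", orientation="circumferential",
                   volt=voltage_v, active_polarity=None):
        size: float | tuple = diam
        if shape == "square":
            size = diam * np.sqrt(np.pi) / 2.0          # equal area
        elif shape == "triangle":
            size = diam * np.sqrt(np.pi / np.sqrt(3.0))  # equal area
        elif shape == "rectangle":
            area = np.pi * diam**2 / 4.0
            size = (2.0 * np.sqrt(area / 2.0), np.sqrt(area / 2.0))  # 2:1
        if active_polarity is None:
            return [
                ElectrodePatch(shape=shape, size_mm=size,
                               center_z_mm=z_mid - spacing / 2,
                               orientation=orientation,
                               polarity="cathode", potential_v=-volt / 2),
                ElectrodePatch(shape=shape, size_mm=size,
                               center_z_mm=z_mid + spacing / 2,
                               orientation=orientation,
                               polarity="anode", potential_v=+volt / 2),
            ]
        # polarity axis: one active electrode, larger indifferent return
        sign = -1.0 if active_polarity == "cathode" else 1.0
        ret_d = return_diameter_mm or 2.0 * diam
        return [
            ElectrodePatch(shape=shape, size_mm=size,
                           center_z_mm=z_mid - spacing / 2,
                           polarity=active_polarity, potential_v=sign * volt),
            ElectrodePatch(shape="circle", size_mm=ret_d,
                           center_z_mm=z_mid + spacing / 2,
                           polarity="anode" if active_polarity == "cathode" else "cathode",
                           potential_v=0.0),
        ]

    rows = []
    meta = {"axis": axis, "voltage_v": voltage_v, "spacing_mm": spacing_mm,
            "electrode_diameter_mm": electrode_diameter_mm,
            "phase_width_us": phase_width_us}
    chash = _config_hash(meta)

    def wf(volt):
        return make_biphasic(volt, phase_width_us, 0.0, 50.0, 1.0 / 50.0, 2e6)

    if axis == "voltage":
        fld = solve_potential(arm, electrodes(volt=1.0))
        for v in values:
            res = count_activated(population, fld, wf(v / 2.0), dt_ms)
            rows.append((v, res.count))
    elif axis == "spacing":
        for s in values:
            fld = solve_potential(arm, electrodes(spacing=s))
            res = count_activated(population, fld, wf(voltage_v / 2.0), dt_ms)
            rows.append((s, res.count))
    elif axis == "diameter":
        for d in values:
            fld = solve_potential(arm, electrodes(diam=d))
            res = count_activated(population, fld, wf(voltage_v / 2.0), dt_ms)
            rows.append((d, res.count))
    elif axis == "shape":
        for shape in values:
            fld = solve_potential(arm, electrodes(shape=shape))
            res = count_activated(population, fld, wf(voltage_v / 2.0), dt_ms)
            rows.append((shape, res.count))
    elif axis == "orientation":
        for orient in values:
            fld = solve_potential(arm, electrodes(shape="rectangle",
                                                  orientation=orient))
            res = count_activated(population, fld, wf(voltage_v / 2.0), dt_ms)
            rows.append((orient, res.count))
    else:  # polarity
        # monophasic test pulse: a symmetric biphasic pulse contains
        # both polarities, which would mask the cathode/anode asymmetry
        for pol in values:
            fld = solve_potential(arm, electrodes(active_polarity=pol))
            res = count_activated(population, fld, wf(voltage_v), dt_ms,
                                  monophasic=True)
            rows.append((pol, res.count))
    df = pd.DataFrame(rows, columns=[axis, "activated_count"])
    df["config_hash"] = chash
    return df
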