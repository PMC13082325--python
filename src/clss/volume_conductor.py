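"""Quasi-static volume-conductor model of the forearm.

Transcutaneous stimulation is modelled as the first step of the
classical two-step approach: solve the quasi-static potential
``div(sigma grad V) = 0`` in a concentric-cylinder forearm (bone,
muscle, fat, skin) with Dirichlet patches where surface electrodes
impose a potential and zero normal current elsewhere, then sample the
extracellular potential along axial nerve-fiber paths for the cable
model (second step, :mod:`clss.fiber_activation`).

Discretization: cell-centered finite volumes on a cylindrical grid
(radial cells sized per layer so every layer is resolved by at least
two cells, uniform azimuthal and axial spacing), harmonic averaging of
conductivity at cell faces, sparse direct or conjugate-gradient solve.
The scheme yields an M-matrix, so the discrete maximum principle holds
and the potential never exceeds the applied electrode potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "ArmModel",
    "ElectrodePatch",
    "PotentialField",
    "solve_potential",
    "current_density",
    "sample_fiber_potential",
]


@dataclass
class ArmModel:
    """Concentric-layer forearm geometry and conductivities.

    Radii are outer radii of each layer (mm), conductivities in S/m.
    Defaults are literature-typical values for a 40 mm radius forearm;
    the muscle layer may be anisotropic (longitudinal/transverse).
    """

    radius_bone_mm: float = 10.0
    radius_muscle_mm: float = 35.0
    radius_fat_mm: float = 38.5
    radius_skin_mm: float = 40.0
    sigma_bone: float = 0.02
    sigma_muscle: float = 0.35
    sigma_muscle_transverse: float | None = None  # None -> isotropic
    sigma_fat: float = 0.04
    sigma_skin: float = 0.1
    length_mm: float = 300.0
    dr_target_mm: float = 1.0
    dtheta_deg: float = 5.0
    dz_mm: float = 2.5

    def __post_init__(self):
        radii = [self.radius_bone_mm, self.radius_muscle_mm,
                 self.radius_fat_mm, self.radius_skin_mm]
        if not all(b > a > 0 for a, b in zip(radii, radii[1:])):
            raise ValueError("layer radii must be strictly increasing and positive")
        for name in ("sigma_bone", "sigma_muscle", "sigma_fat", "sigma_skin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma_muscle_transverse is not None and self.sigma_muscle_transverse <= 0:
            raise ValueError("sigma_muscle_transverse must be positive")

    # --- grid construction -------------------------------------------------
    def radial_edges(self) -> np.ndarray:
        """Radial cell edges: each layer split into >= 2 cells of about
        ``dr_target_mm``."""
        bounds = [0.0, self.radius_bone_mm, self.radius_muscle_mm,
                  self.radius_fat_mm, self.radius_skin_mm]
        edges = [0.0]
        for a, b in zip(bounds, bounds[1:]):
            n = max(2, int(round((b - a) / self.dr_target_mm)))
            edges.extend(np.linspace(a, b, n + 1)[1:])
        return np.asarray(edges)

    def conductivity_at(self, r_mm: np.ndarray) -> np.ndarray:
        """Longitudinal (axial) conductivity by radius."""
        sig = np.empty_like(r_mm, dtype=float)
        sig[...] = self.sigma_skin
        sig[r_mm <= self.radius_fat_mm] = self.sigma_fat
        sig[r_mm <= self.radius_muscle_mm] = self.sigma_muscle
        sig[r_mm <= self.radius_bone_mm] = self.sigma_bone
        return sig

    def conductivity_transverse_at(self, r_mm: np.ndarray) -> np.ndarray:
        sig = self.conductivity_at(r_mm)
        if self.sigma_muscle_transverse is not None:
            in_muscle = (r_mm > self.radius_bone_mm) & (r_mm <= self.radius_muscle_mm)
            sig[in_muscle] = self.sigma_muscle_transverse
        return sig


@dataclass
class ElectrodePatch:
    """A skin-surface electrode: shape, size, position, polarity, volts.

    ``center_z_mm`` / ``center_azimuth_deg`` locate the patch center on
    the outer skin surface; ``size_mm`` is the diameter (circle), side
    (square/triangle) or (length, width) pair (rectangle).  Rectangle
    orientation is ``"circumferential"`` (long edge around the arm) or
    ``"axial"``.
    """

    shape: str = "circle"
    size_mm: float | tuple = 30.0
    center_z_mm: float = 100.0
    center_azimuth_deg: float = 0.0
    orientation: str = "circumferential"
    polarity: str = "cathode"
    potential_v: float = -1.0
    #: electrode-skin contact impedance (complete-electrode-model style
    #: Robin coupling), kOhm*cm^2.  The stratum corneum dominates the
    #: interface in transcutaneous stimulation; it also makes the
    #: delivered current scale with electrode area rather than
    #: perimeter, which is what renders equal-area shapes comparable.
    contact_impedance_kohm_cm2: float = 2.0

    def __post_init__(self):
        if self.shape not in ("circle", "square", "triangle", "rectangle"):
            raise ValueError(f"unknown electrode shape {self.shape!r}")
        if self.orientation not in ("circumferential", "axial"):
            raise ValueError("orientation must be circumferential or axial")
        if self.polarity not in ("anode", "cathode"):
            raise ValueError("polarity must be anode or cathode")

    def area_mm2(self) -> float:
        """Analytic electrode area (independent of grid rasterization)."""
        if self.shape == "circle":
            d = float(np.atleast_1d(self.size_mm)[0])
            return np.pi * d**2 / 4.0
        if self.shape == "square":
            s = float(np.atleast_1d(self.size_mm)[0])
            return s**2
        if self.shape == "triangle":
            s = float(np.atleast_1d(self.size_mm)[0])
            return np.sqrt(3.0) / 4.0 * s**2
        length, width = self.size_mm
        return float(length) * float(width)

    def footprint(self, z_mm: np.ndarray, arc_mm: np.ndarray) -> np.ndarray:
        """Boolean mask of surface points covered by the patch.

        ``arc_mm`` is the circumferential arc distance from the patch
        center (signed, wrapped); the skin surface is treated as
        locally unrolled, which is accurate for patches small relative
        to the circumference.
        """
        dz = z_mm - self.center_z_mm
        if self.shape == "circle":
            r = float(np.atleast_1d(self.size_mm)[0]) / 2.0
            return dz**2 + arc_mm**2 <= r**2
        if self.shape == "square":
            s = float(np.atleast_1d(self.size_mm)[0]) / 2.0
            return (np.abs(dz) <= s) & (np.abs(arc_mm) <= s)
        if self.shape == "triangle":
            # equilateral, apex toward +z, same nominal side length
            s = float(np.atleast_1d(self.size_mm)[0])
            h = s * np.sqrt(3) / 2
            y = dz + h / 3  # centroid at patch center
            return (y >= 0) & (y <= h) & (np.abs(arc_mm) <= (1 - y / h) * s / 2)
        # rectangle
        length, width = self.size_mm
        if self.orientation == "circumferential":
            half_arc, half_z = length / 2.0, width / 2.0
        else:
            half_arc, half_z = width / 2.0, length / 2.0
        return (np.abs(dz) <= half_z) & (np.abs(arc_mm) <= half_arc)


@dataclass
class PotentialField:
    """Solved potential on the cylindrical grid (volts)."""

    potential: np.ndarray          # (n_r, n_theta, n_z)
    r_centers_mm: np.ndarray
    theta_centers_deg: np.ndarray
    z_centers_mm: np.ndarray
    arm: ArmModel
    residual: float
    electrodes: list = field(default_factory=list)
    surface_flux_ma: dict = field(default_factory=dict)

    def interpolator(self) -> RegularGridInterpolator:
        """Trilinear interpolator with periodic azimuth padding."""
        theta = self.theta_centers_deg
        th_pad = np.concatenate([[theta[0] - (theta[1] - theta[0])], theta,
                                 [theta[-1] + (theta[1] - theta[0])]])
        v_pad = np.concatenate(
            [self.potential[:, -1:], self.potential, self.potential[:, :1]], axis=1)
        return RegularGridInterpolator(
            (self.r_centers_mm, th_pad, self.z_centers_mm), v_pad,
            bounds_error=False, fill_value=None)


def _wrap_arc(theta_deg: np.ndarray, center_deg: float, radius_mm: float) -> np.ndarray:
    d = (theta_deg - center_deg + 180.0) % 360.0 - 180.0
    return np.deg2rad(d) * radius_mm


def _assemble(arm: ArmModel, electrodes: list[ElectrodePatch]):
    """Build the finite-volume system.  Returns grid arrays, the sparse
    matrix, RHS and the Dirichlet bookkeeping."""
    r_edges = arm.radial_edges()
    r_cent = 0.5 * (r_edges[:-1] + r_edges[1:])
    n_r = r_cent.size
    n_t = max(4, int(round(360.0 / arm.dtheta_deg)))
    dth = 2 * np.pi / n_t
    th_cent = np.rad2deg(dth * (np.arange(n_t) + 0.5))
    n_z = max(2, int(round(arm.length_mm / arm.dz_mm)))
    dz = arm.length_mm / n_z
    z_cent = dz * (np.arange(n_z) + 0.5)

    # unit scale: mm and S/m give conductance in S*mm; consistent throughout
    sig_l = arm.conductivity_at(r_cent)        # axial (longitudinal)
    sig_t = arm.conductivity_transverse_at(r_cent)

    n_cells = n_r * n_t * n_z
    cell_index = np.arange(n_cells).reshape(n_r, n_t, n_z)
    rows_list, cols_list, vals_list = [], [], []
    diag = np.zeros(n_cells)
    rhs = np.zeros(n_cells)

    def couple(a_idx: np.ndarray, b_idx: np.ndarray, g: np.ndarray) -> None:
        a = a_idx.ravel(); b = b_idx.ravel(); gg = np.broadcast_to(g, a_idx.shape).ravel()
        rows_list.append(np.concatenate([a, b]))
        cols_list.append(np.concatenate([b, a]))
        vals_list.append(np.concatenate([-gg, -gg]))
        np.add.at(diag, a, gg)
        np.add.at(diag, b, gg)

    # radial faces between shells i and i+1: series (harmonic) sigma of
    # the two half-cells, transverse component
    r_face = r_edges[1:-1]
    dr1 = r_face - r_cent[:-1]
    dr2 = r_cent[1:] - r_face
    g_rad = (1.0 / (dr1 / sig_t[:-1] + dr2 / sig_t[1:])) * (r_face * dth * dz)
    couple(cell_index[:-1], cell_index[1:], g_rad[:, None, None])

    # azimuthal faces (periodic), transverse sigma within a shell
    dr_cell = r_edges[1:] - r_edges[:-1]
    g_th = sig_t * dr_cell * dz / (r_cent * dth)
    couple(cell_index, np.roll(cell_index, -1, axis=1), g_th[:, None, None])

    # axial faces, longitudinal sigma
    g_z = sig_l * r_cent * dth * dr_cell / dz
    couple(cell_index[:, :, :-1], cell_index[:, :, 1:], g_z[:, None, None])

    # electrode patches: Dirichlet through the outer half-cell resistance
    i_surf = n_r - 1
    dr_half = r_edges[-1] - r_cent[-1]
    g_surf = sig_t[i_surf] / dr_half * (r_edges[-1] * dth * dz)
    masks = []
    # supersampled rasterization: a surface cell belongs to a patch
    # when at least half of it is covered (4x4 subsampling); a binary
    # center test would admit slivers at sharp corners and create
    # grid-scale artifacts
    sub = (np.arange(4) + 0.5) / 4.0 - 0.5
    for e in electrodes:
        frac = np.zeros((n_z, n_t))
        for oz in sub:
            for ot in sub:
                zz, tt = np.meshgrid(z_cent + oz * dz,
                                     th_cent + ot * np.rad2deg(dth),
                                     indexing="ij")
                arc = _wrap_arc(tt, e.center_azimuth_deg, arm.radius_skin_mm)
                frac += e.footprint(zz, arc)
        frac /= len(sub)**2
        # half-coverage threshold, but never let a small patch vanish:
        # for sub-cell electrodes keep the best-covered cells
        mask = frac >= min(0.5, frac.max()) if frac.max() > 0 \
            else np.zeros_like(frac, dtype=bool)   # (n_z, n_t)
        if not mask.any():
            raise ValueError(
                f"electrode at z={e.center_z_mm} az={e.center_azimuth_deg} "
                "covers no surface cells; refine the grid or enlarge it")
        masks.append(mask)
    for a_i, ma in enumerate(masks):
        for b_i in range(a_i + 1, len(masks)):
            if (ma & masks[b_i]).any():
                raise ValueError("electrode patches overlap")
    cell_area_mm2 = r_edges[-1] * dth * dz
    g_effective = []
    for e, mask in zip(electrodes, masks):
        ks, js = np.nonzero(mask)
        a = cell_index[i_surf, js, ks]
        g_e = g_surf
        if e.contact_impedance_kohm_cm2 > 0:
            # series contact conductance per covered cell, in matrix
            # units (sigma[S/m]*mm = mS): g = area[cm^2]/z_c[kOhm*cm^2].
            # The electrode's analytic area is spread over its raster
            # cells so the total contact conductance matches the
            # physical electrode regardless of rasterization.
            per_cell_cm2 = (e.area_mm2() / 100.0) / len(ks)
            g_contact = per_cell_cm2 / e.contact_impedance_kohm_cm2
            g_e = 1.0 / (1.0 / g_surf + 1.0 / g_contact)
        np.add.at(diag, a, g_e)
        np.add.at(rhs, a, g_e * e.potential_v)
        g_effective.append(g_e)

    rows = np.concatenate(rows_list + [np.arange(n_cells)])
    cols = np.concatenate(cols_list + [np.arange(n_cells)])
    vals = np.concatenate(vals_list + [diag])
    mat = sp.csr_matrix((vals, (rows, cols)), shape=(n_cells, n_cells))
    grid = (r_cent, th_cent, z_cent, r_edges, dth, dz)
    return mat, rhs, grid, masks, g_effective


def solve_potential(arm: ArmModel, electrodes: list[ElectrodePatch],
                    tol: float = 1e-8, maxiter: int = 20000,
                    method: str = "auto") -> PotentialField:
    """Solve the volume-conduction problem for the given electrodes.

    Requires at least one anode and one cathode (or explicitly
    grounded patch at 0 V).  ``method`` is ``"direct"`` (sparse LU),
    ``"cg"`` (conjugate gradients, diagonal preconditioner) or
    ``"auto"`` (direct below 60k unknowns).
    """
    if not electrodes:
        raise ValueError("need at least one electrode")
    pots = [e.potential_v for e in electrodes]
    if len(electrodes) < 2 and not any(p == 0.0 for p in pots):
        raise ValueError("need a return electrode (anode+cathode or ground)")
    mat, rhs, grid, masks, g_effective = _assemble(arm, electrodes)
    n = mat.shape[0]
    if method == "auto":
        method = "direct" if n <= 20000 else "cg"
    if method == "direct":
        v = spla.spsolve(mat.tocsc(), rhs)
    else:
        ilu_pre = spla.LinearOperator((n, n), matvec=lambda x: x / mat.diagonal())
        v, info = spla.cg(mat, rhs, rtol=tol, maxiter=maxiter, M=ilu_pre)
        if info != 0:
            res = np.linalg.norm(mat @ v - rhs) / max(np.linalg.norm(rhs), 1e-300)
            raise RuntimeError(f"CG failed to converge (info={info}, residual={res:.2e})")
    scale = np.linalg.norm(rhs)
    residual = float(np.linalg.norm(mat @ v - rhs) / scale) if scale else 0.0

    r_cent, th_cent, z_cent, r_edges, dth, dz = grid
    n_r, n_t, n_z = r_cent.size, th_cent.size, z_cent.size
    pot = v.reshape(n_r, n_t, n_z)

    # net current through each electrode interface (mA: V * S*mm -> use
    # consistent mm units; sigma[S/m] * mm = 1e-3 S so result is in mA)
    flux = {}
    for ei, (e, mask) in enumerate(zip(electrodes, masks)):
        ks, js = np.nonzero(mask)
        i_cur = g_effective[ei] * (e.potential_v - pot[n_r - 1, js, ks]).sum()
        flux[ei] = float(i_cur)  # in V * S/m * mm = mA
    field_obj = PotentialField(
        potential=pot, r_centers_mm=r_cent, theta_centers_deg=th_cent,
        z_centers_mm=z_cent, arm=arm, residual=residual,
        electrodes=list(electrodes), surface_flux_ma=flux)
    return field_obj


def current_density(field: PotentialField):
    """J = -sigma grad V on the grid (central differences).

    Returns ``(j_r, j_theta, j_z)`` arrays in A/m^2 (with V in volts
    and lengths in mm the gradient is in V/mm = 1e3 V/m).
    """
    if field.potential is None:
        raise ValueError("field not solved")
    v = field.potential
    r = field.r_centers_mm
    th = np.deg2rad(field.theta_centers_deg)
    z = field.z_centers_mm
    dvdr = np.gradient(v, r, axis=0)
    dvdth = np.gradient(v, th, axis=1)
    dvdz = np.gradient(v, z, axis=2)
    sig_t = field.arm.conductivity_transverse_at(r)[:, None, None]
    sig_l = field.arm.conductivity_at(r)[:, None, None]
    mm_to_m = 1e3
    j_r = -sig_t * dvdr * mm_to_m
    j_th = -sig_t * (dvdth / r[:, None, None]) * mm_to_m
    j_z = -sig_l * dvdz * mm_to_m
    return j_r, j_th, j_z


def sample_fiber_potential(field: PotentialField, depth_mm: float,
                           azimuth_deg: float,
                           z_mm: np.ndarray | None = None):
    """Extracellular potential along an axial line at the given depth.

    The line runs parallel to the arm axis at radius
    ``skin_outer - depth`` and fixed azimuth.  Returns ``(z_mm, V_e)``.
    """
    outer = field.arm.radius_skin_mm
    if not (0 < depth_mm < outer):
        raise ValueError(f"depth {depth_mm} mm outside tissue (0, {outer})")
    if z_mm is None:
        z_mm = field.z_centers_mm
    z_mm = np.asarray(z_mm, dtype=float)
    radius = outer - depth_mm
    pts = np.column_stack([
        np.full(z_mm.size, radius),
        np.full(z_mm.size, azimuth_deg % 360.0),
        z_mm,
    ])
    ve = field.interpolator()(pts)
    return z_mm, ve
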