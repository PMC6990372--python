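"""Idealized truncated-ellipsoid LV meshes and sex-stratified synthetic cohorts.

The generator stands in for patient anatomy: the controlled variables are the
two size metrics the downstream analysis uses (LV mass and LVEDV), realized as
a prolate truncated-ellipsoid shell with uniform wall-thickness offset.  Cohort
statistics default to the CRT literature values for male and female patients
(mass 273 +/- 78 g vs 173 +/- 58 g, LVEDV 261 +/- 109 mL vs 165 +/- 67 mL).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm, truncnorm

from .geometry import SurfaceLabel, TetMesh, size_metrics

logger = logging.getLogger("qrscale")


class MeshingError(RuntimeError):
    pass


class FeasibilityError(ValueError):
    """Raised when a (mass, LVEDV) target pair admits no ellipsoid realization."""


@dataclass(frozen=True)
class EllipsoidParams:
    """Parameters of a truncated prolate-ellipsoid LV shell.

    ``endo_semi_axes`` are the cavity semi-axes (a, b, c) in mm with the long
    axis c along z and the apex at z = -c.  The wall is a uniform outward
    offset of the semi-axes by ``wall_thickness``.  ``truncation_fraction`` is
    the fraction of the apex-to-equator extent kept below the base plane
    (1.0 = full half-ellipsoid, base at the equator).
    """

    endo_semi_axes: tuple[float, float, float]
    wall_thickness: float
    truncation_fraction: float = 0.9
    target_edge_length: float = 3.5
    endo_layer_edge: float = 1.0  # transmural size of the first (endocardial) layer

    def __post_init__(self):
        a, b, c = self.endo_semi_axes
        if min(a, b, c) <= 0 or self.wall_thickness <= 0 or self.target_edge_length <= 0:
            raise ValueError("ellipsoid parameters must be positive")
        if not (0.5 < self.truncation_fraction <= 1.0):
            raise ValueError("truncation_fraction must lie in (0.5, 1.0]")
        if self.wall_thickness >= min(a, b):
            raise ValueError("wall_thickness must be smaller than min(a, b)")

    @property
    def base_z(self) -> float:
        """z of the truncation plane (0 at the equator, negative below)."""
        return -self.endo_semi_axes[2] * (1.0 - self.truncation_fraction)


@dataclass(frozen=True)
class CohortSpec:
    """Sex-stratified cohort sizes and (mass, LVEDV) distribution parameters."""

    n_male: int = 39
    n_female: int = 11
    male_mass: tuple[float, float] = (273.0, 78.0)  # g, mean +/- sd
    female_mass: tuple[float, float] = (173.0, 58.0)
    male_lvedv: tuple[float, float] = (261.0, 109.0)  # mL
    female_lvedv: tuple[float, float] = (165.0, 67.0)
    correlation: float = 0.7  # Gaussian-copula corr between mass and LVEDV
    truncate_sd: float = 2.5
    seed: int = 0
    target_edge_length: float = 3.5

    def __post_init__(self):
        if self.n_male < 1 or self.n_female < 1:
            raise ValueError("cohort sizes must be >= 1")
        for mean, sd in (self.male_mass, self.female_mass, self.male_lvedv, self.female_lvedv):
            if mean <= 0 or sd < 0:
                raise ValueError("distribution means must be > 0 and sds >= 0")


# ---------------------------------------------------------------------------
# analytic volumes of the truncated shell


def _ellipsoid_segment_volume(a: float, b: float, c: float, z_top: float) -> float:
    """Volume (mm^3) of the ellipsoid region with z in [-c, z_top]."""
    z = np.clip(z_top / c, -1.0, 1.0)
    return np.pi * a * b * c * (z - z**3 / 3.0 + 2.0 / 3.0)


def analytic_cavity_volume(p: EllipsoidParams) -> float:
    a, b, c = p.endo_semi_axes
    return _ellipsoid_segment_volume(a, b, c, p.base_z)


def analytic_wall_volume(p: EllipsoidParams) -> float:
    a, b, c = p.endo_semi_axes
    t = p.wall_thickness
    return _ellipsoid_segment_volume(a + t, b + t, c + t, p.base_z) - analytic_cavity_volume(p)


# ---------------------------------------------------------------------------
# structured shell mesher

# 6-tet decomposition of a hexahedron around the main diagonal v000-v111.
# Corner order: index bit 0 -> theta, bit 1 -> phi, bit 2 -> w, i.e.
# corners[b] = (d_theta, d_phi, d_w) = (b & 1, (b >> 1) & 1, (b >> 2) & 1).
_HEX_TETS = np.array(
    [
        [0b000, 0b001, 0b011, 0b111],
        [0b000, 0b011, 0b010, 0b111],
        [0b000, 0b010, 0b110, 0b111],
        [0b000, 0b110, 0b100, 0b111],
        [0b000, 0b100, 0b101, 0b111],
        [0b000, 0b101, 0b001, 0b111],
    ]
)


def _transmural_levels(t: float, first: float, step: float) -> np.ndarray:
    """Wall-depth levels [0 .. t]: a thin first layer to resolve the fast
    endocardial band, then roughly uniform steps of size <= ``step``."""
    if t <= 1.5 * first:
        n = max(2, int(np.ceil(t / first)))
        return np.linspace(0.0, t, n + 1)
    rest = t - first
    n = max(1, int(np.ceil(rest / step)))
    return np.concatenate([[0.0, first], first + np.cumsum(np.full(n, rest / n))])


def make_ellipsoid_lv(
    params: EllipsoidParams, mesh_id: str = "", sex: str = "UNSPECIFIED"
) -> TetMesh:
    """Mesh the truncated-ellipsoid LV wall as a conforming tet mesh.

    A structured (theta, phi, wall-depth) grid of hexahedra (degenerating to
    wedges at the apex) is split into tets with a translation-invariant
    template, so shared faces match exactly.  Surfaces come out labeled
    ENDO (inner shell), EPI (outer shell) and BASE (flat truncation annulus).
    """
    a, b, c = params.endo_semi_axes
    t = params.wall_thickness
    h = params.target_edge_length
    z_b = params.base_z

    levels = _transmural_levels(t, params.endo_layer_edge, max(h, 1.0))
    n_w = len(levels) - 1
    a_mid, c_mid = (a + b) / 2.0 + t / 2.0, c + t / 2.0
    n_theta = max(12, int(round(2.0 * np.pi * a_mid / h)))
    # meridian arc length (apex to base) of the mid-wall ellipse, sampled
    phis = np.linspace(np.arccos(np.clip(z_b / c_mid, -1, 1)), np.pi, 200)
    xs = a_mid * np.sin(phis)
    zs = c_mid * np.cos(phis)
    arc = float(np.sum(np.hypot(np.diff(xs), np.diff(zs))))
    n_phi = max(6, int(round(arc / h)))
    if n_theta * n_phi * n_w > 2_000_000:
        raise MeshingError(
            f"requested resolution gives {n_theta * n_phi * n_w} cells; "
            f"try a coarser target_edge_length (>= {h * 2:.1f} mm)"
        )

    # Node grid: rings j = 0..n_phi-1 (j=0 at base) plus one apex node per layer.
    nid = np.empty((n_w + 1, n_phi, n_theta), dtype=np.int64)
    coords = []
    apex_id = np.empty(n_w + 1, dtype=np.int64)
    theta = np.arange(n_theta) * (2.0 * np.pi / n_theta)
    ct, st = np.cos(theta), np.sin(theta)
    counter = 0
    for w in range(n_w + 1):
        d = levels[w]
        A, B, C = a + d, b + d, c + d
        phi_b = np.arccos(np.clip(z_b / C, -1.0, 1.0))
        phi = phi_b + (np.pi - phi_b) * np.arange(n_phi) / n_phi
        for j in range(n_phi):
            sp, cp = np.sin(phi[j]), np.cos(phi[j])
            ring = np.column_stack([A * sp * ct, B * sp * st, np.full(n_theta, C * cp)])
            if j == 0:
                ring[:, 2] = z_b  # exact planar base
            coords.append(ring)
            nid[w, j, :] = np.arange(counter, counter + n_theta)
            counter += n_theta
        coords.append(np.array([[0.0, 0.0, -C]]))
        apex_id[w] = counter
        counter += 1
    nodes = np.vstack(coords)

    # Hex cells away from the apex.
    w_idx, j_idx, k_idx = np.meshgrid(
        np.arange(n_w), np.arange(n_phi - 1), np.arange(n_theta), indexing="ij"
    )
    w_idx, j_idx, k_idx = w_idx.ravel(), j_idx.ravel(), k_idx.ravel()
    k1 = (k_idx + 1) % n_theta
    corner = np.empty((len(w_idx), 8), dtype=np.int64)
    for bcode in range(8):
        dth, dph, dw = bcode & 1, (bcode >> 1) & 1, (bcode >> 2) & 1
        kk = k1 if dth else k_idx
        corner[:, bcode] = nid[w_idx + dw, j_idx + dph, kk]
    hex_tets = corner[:, _HEX_TETS].reshape(-1, 4)

    # Apex wedges: ring j = n_phi-1 to the apex line.
    w_idx, k_idx = np.meshgrid(np.arange(n_w), np.arange(n_theta), indexing="ij")
    w_idx, k_idx = w_idx.ravel(), k_idx.ravel()
    k1 = (k_idx + 1) % n_theta
    r00 = nid[w_idx, n_phi - 1, k_idx]  # (theta_k, w)
    r10 = nid[w_idx, n_phi - 1, k1]  # (theta_k+1, w)
    r01 = nid[w_idx + 1, n_phi - 1, k_idx]
    r11 = nid[w_idx + 1, n_phi - 1, k1]
    a0 = apex_id[w_idx]
    a1 = apex_id[w_idx + 1]
    # 3-tet wedge split; quad diagonals r00-r11 (matches the hex template on
    # the shared phi-face), r00-a1 and r10-a1 (translation-invariant in theta).
    wedge_tets = np.concatenate(
        [
            np.column_stack([r00, r10, a0, a1]),
            np.column_stack([r00, r10, r11, a1]),
            np.column_stack([r00, r11, r01, a1]),
        ]
    )
    tets = np.vstack([hex_tets, wedge_tets])

    mesh = TetMesh.create(nodes, tets, mesh_id=mesh_id, sex=sex, validate=False)

    # Label boundary faces from the node grid structure.
    on_endo = np.zeros(len(nodes), dtype=bool)
    on_epi = np.zeros(len(nodes), dtype=bool)
    on_endo[nid[0].ravel()] = True
    on_endo[apex_id[0]] = True
    on_epi[nid[n_w].ravel()] = True
    on_epi[apex_id[n_w]] = True
    f = mesh.boundary_faces
    on_base_f = np.all(np.abs(nodes[f][:, :, 2] - z_b) < 1e-9, axis=1)
    on_endo_f = np.all(on_endo[f], axis=1) & ~on_base_f
    on_epi_f = np.all(on_epi[f], axis=1) & ~on_base_f
    labels = np.zeros(len(f), dtype=np.int64)
    labels[on_base_f] = int(SurfaceLabel.BASE)
    labels[on_endo_f] = int(SurfaceLabel.ENDO)
    labels[on_epi_f] = int(SurfaceLabel.EPI)
    if (labels == 0).any():
        raise MeshingError("mesher produced unclassifiable boundary faces")
    mesh.boundary_labels = labels
    mesh.validate()
    return mesh


def make_box(
    lengths: tuple[float, float, float], edge: float, origin=(0.0, 0.0, 0.0)
) -> TetMesh:
    """Structured tet mesh of a box (test fixture: slabs, bars).

    The x=0 plane is labeled ENDO, x=Lx EPI and the remaining sides BASE, so
    the box doubles as a two-electrode Laplace fixture.
    """
    lx, ly, lz = lengths
    nx, ny, nz = (max(1, int(round(l / edge))) for l in lengths)
    gx = np.linspace(0, lx, nx + 1) + origin[0]
    gy = np.linspace(0, ly, ny + 1) + origin[1]
    gz = np.linspace(0, lz, nz + 1) + origin[2]
    X, Y, Z = np.meshgrid(gx, gy, gz, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def gid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    corner = np.empty((len(i), 8), dtype=np.int64)
    for bcode in range(8):
        di, dj, dk = bcode & 1, (bcode >> 1) & 1, (bcode >> 2) & 1
        corner[:, bcode] = gid(i + di, j + dj, k + dk)
    tets = corner[:, _HEX_TETS].reshape(-1, 4)
    mesh = TetMesh.create(nodes, tets, validate=False)
    f = mesh.boundary_faces
    cx = nodes[f][:, :, 0]
    labels = np.full(len(f), int(SurfaceLabel.BASE), dtype=np.int64)
    labels[np.all(np.abs(cx - origin[0]) < 1e-9, axis=1)] = int(SurfaceLabel.ENDO)
    labels[np.all(np.abs(cx - origin[0] - lx) < 1e-9, axis=1)] = int(SurfaceLabel.EPI)
    mesh.boundary_labels = labels
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# inverse design: (mass, LVEDV) -> EllipsoidParams


_A_BOUNDS = (5.0, 80.0)
_T_BOUNDS = (1.0, 25.0)


def params_from_targets(
    mass: float,
    lvedv: float,
    long_axis_ratio: float = 3.0,
    truncation_fraction: float = 0.9,
    target_edge_length: float = 3.5,
    density: float = 1.05,
    tol: float = 0.01,
    max_correction: int = 6,
) -> EllipsoidParams:
    """Find ellipsoid parameters whose *meshed* size metrics hit the targets.

    With the aspect ratio fixed (a = b, c = long_axis_ratio * a) the cavity
    volume depends only on a and the wall volume only on (a, t), so the
    analytic inverse is two nested 1-D root finds.  A short fixed-point loop
    then corrects for the faceting bias of the discrete mesh so that
    ``size_metrics`` of the returned parameters' mesh lands within ``tol``
    (relative) of the targets.
    """
    if mass <= 0 or lvedv <= 0:
        raise FeasibilityError("mass and lvedv targets must be positive")
    wall_target = mass / density * 1000.0  # mm^3
    cav_target = lvedv * 1000.0

    def solve_analytic(cav_mm3, wall_mm3):
        def f_cav(a):
            p = _quick_params(a, _T_BOUNDS[0])
            return analytic_cavity_volume(p) - cav_mm3

        lo, hi = _A_BOUNDS
        if f_cav(lo) > 0 or f_cav(hi) < 0:
            raise FeasibilityError(
                f"LVEDV target {cav_mm3 / 1000:.1f} mL outside the admissible range "
                f"[{analytic_cavity_volume(_quick_params(lo, 1.0)) / 1000:.1f}, "
                f"{analytic_cavity_volume(_quick_params(hi, 1.0)) / 1000:.1f}] mL "
                f"at aspect ratio {long_axis_ratio}"
            )
        a = brentq(f_cav, lo, hi, xtol=1e-10)

        def f_wall(t):
            return analytic_wall_volume(_quick_params(a, t)) - wall_mm3

        t_lo, t_hi = _T_BOUNDS
        if a * 0.999 < t_hi:  # wall thinner than min semi-axis
            t_hi = min(t_hi, a * 0.999)
        if f_wall(t_lo) > 0 or f_wall(t_hi) < 0:
            raise FeasibilityError(
                f"LV mass target {wall_mm3 * density / 1000:.1f} g infeasible for "
                f"LVEDV {cav_mm3 / 1000:.1f} mL: admissible mass range "
                f"[{analytic_wall_volume(_quick_params(a, t_lo)) * density / 1000:.1f}, "
                f"{analytic_wall_volume(_quick_params(a, t_hi)) * density / 1000:.1f}] g"
            )
        t = brentq(f_wall, t_lo, t_hi, xtol=1e-10)
        return _quick_params(a, t)

    def _quick_params(a, t):
        return EllipsoidParams(
            endo_semi_axes=(a, a, long_axis_ratio * a),
            wall_thickness=t,
            truncation_fraction=truncation_fraction,
            target_edge_length=target_edge_length,
        )

    # Fixed-point correction of the analytic targets for mesh faceting bias.
    cav_goal, wall_goal = cav_target, wall_target
    params = solve_analytic(cav_goal, wall_goal)
    for _ in range(max_correction):
        m = size_metrics(make_ellipsoid_lv(params), density=density)
        err_c = m.lvedv * 1000.0 / cav_target
        err_w = m.wall_volume * 1000.0 / wall_target
        if abs(err_c - 1) < tol * 0.5 and abs(err_w - 1) < tol * 0.5:
            break
        cav_goal /= err_c
        wall_goal /= err_w
        params = solve_analytic(cav_goal, wall_goal)
    return params


# ---------------------------------------------------------------------------
# cohort sampling


@dataclass
class CohortCase:
    mesh_id: str
    sex: str
    mass: float
    lvedv: float
    params: EllipsoidParams


def _sample_truncated_pairs(rng, n, mass_ms, lvedv_ms, corr, k):
    """Correlated truncated-normal (mass, lvedv) draws via a Gaussian copula."""
    cov = np.array([[1.0, corr], [corr, 1.0]])
    L = np.linalg.cholesky(cov)
    z = rng.standard_normal((n, 2)) @ L.T
    u = norm.cdf(z)
    out = np.empty((n, 2))
    for col, (mean, sd) in enumerate((mass_ms, lvedv_ms)):
        if sd == 0:
            out[:, col] = mean
        else:
            lo = max(-k, (1e-6 - mean) / sd)  # also truncate at positivity
            out[:, col] = truncnorm.ppf(u[:, col], lo, k, loc=mean, scale=sd)
    return out


def sample_cohort(spec: CohortSpec) -> list[TetMesh]:
    """Draw a reproducible sex-stratified cohort of LV meshes.

    Each case's (mass, LVEDV) pair is a correlated truncated-normal draw
    realized through :func:`params_from_targets`; infeasible pairs are
    resampled (up to 100 times per case).  Meshes carry sex tags and ids.
    """
    rng = np.random.default_rng(spec.seed)
    meshes: list[TetMesh] = []
    for sex, n, mass_ms, lvedv_ms in (
        ("MALE", spec.n_male, spec.male_mass, spec.male_lvedv),
        ("FEMALE", spec.n_female, spec.female_mass, spec.female_lvedv),
    ):
        count = 0
        attempts = 0
        while count < n:
            if attempts > 100 * n:
                raise FeasibilityError(
                    f"could not realize {n} feasible {sex} cases after {attempts} draws"
                )
            draw = _sample_truncated_pairs(
                rng, 1, mass_ms, lvedv_ms, spec.correlation, spec.truncate_sd
            )[0]
            attempts += 1
            try:
                params = params_from_targets(
                    draw[0], draw[1], target_edge_length=spec.target_edge_length
                )
            except FeasibilityError:
                logger.info("resampling infeasible %s draw mass=%.1f lvedv=%.1f", sex, *draw)
                continue
            mesh_id = f"{sex.lower()}_{count:03d}"
            mesh = make_ellipsoid_lv(params, mesh_id=mesh_id, sex=sex)
            meshes.append(mesh)
            count += 1
    return meshes


def cohort_manifest(meshes: list[TetMesh]) -> "pandas.DataFrame":  # noqa: F821
    """Per-case table of ids, sex and measured size metrics."""
    import pandas as pd

    rows = []
    for m in meshes:
        sm = size_metrics(m)
        rows.append(
            {"mesh_id": m.mesh_id, "sex": m.sex, "lv_mass_g": sm.lv_mass, "lvedv_ml": sm.lvedv}
        )
    return pd.DataFrame(rows)
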