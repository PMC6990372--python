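"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own geometry kernels: volumes come
from voxel counting over analytic regions, and surface distances from dense
point sampling of the analytic surfaces.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def _ellipsoid_inside(x, y, z, a, b, c):
    return (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0


def voxel_cavity_volume_ml(a, b, c, z_base, pitch=0.2):
    """Voxel count of the truncated-ellipsoid cavity {inside, z <= z_base}."""
    xs = np.arange(-a + pitch / 2, a, pitch)
    ys = np.arange(-b + pitch / 2, b, pitch)
    zs = np.arange(-c + pitch / 2, z_base, pitch)
    count = 0
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    for z in zs:  # slice-wise to bound memory
        count += int(np.count_nonzero(_ellipsoid_inside(X, Y, z, a, b, c)))
    return count * pitch**3 / 1000.0


def voxel_wall_volume_ml(a, b, c, t, z_base, pitch=0.2):
    """Voxel count of the shell between inner (a,b,c) and outer (+t) below z_base."""
    A, B, C = a + t, b + t, c + t
    xs = np.arange(-A + pitch / 2, A, pitch)
    ys = np.arange(-B + pitch / 2, B, pitch)
    zs = np.arange(-C + pitch / 2, z_base, pitch)
    count = 0
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    for z in zs:
        outer = _ellipsoid_inside(X, Y, z, A, B, C)
        inner = _ellipsoid_inside(X, Y, z, a, b, c)
        count += int(np.count_nonzero(outer & ~inner))
    return count * pitch**3 / 1000.0


def _sample_ellipsoid_surface(a, b, c, z_base, n_theta=400, n_phi=400):
    phi_b = np.arccos(np.clip(z_base / c, -1, 1))
    phi = np.linspace(phi_b, np.pi, n_phi)
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    P, T = np.meshgrid(phi, theta, indexing="ij")
    return np.column_stack(
        [
            (a * np.sin(P) * np.cos(T)).ravel(),
            (b * np.sin(P) * np.sin(T)).ravel(),
            (c * np.cos(P)).ravel(),
        ]
    )


def voxel_endo_layer_fraction(a, b, c, t, z_base, thickness, pitch=0.5):
    """Fraction of wall voxels within ``thickness`` of the (analytic) endo surface."""
    surf = _sample_ellipsoid_surface(a, b, c, z_base)
    tree = cKDTree(surf)
    A, B, C = a + t, b + t, c + t
    xs = np.arange(-A + pitch / 2, A, pitch)
    ys = np.arange(-B + pitch / 2, B, pitch)
    zs = np.arange(-C + pitch / 2, z_base, pitch)
    n_wall = 0
    n_layer = 0
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    for z in zs:
        wall = _ellipsoid_inside(X, Y, z, A, B, C) & ~_ellipsoid_inside(X, Y, z, a, b, c)
        if not wall.any():
            continue
        pts = np.column_stack([X[wall], Y[wall], np.full(wall.sum(), z)])
        d, _ = tree.query(pts)
        n_wall += len(pts)
        n_layer += int(np.count_nonzero(d <= thickness))
    return n_layer / n_wall


def signed_wall_depth(mesh_nodes, a, b, c, t):
    """Normalized wall depth of nodes via dense sampling of both analytic surfaces."""
    endo = _sample_ellipsoid_surface(a, b, c, c, n_theta=500, n_phi=500)
    epi = _sample_ellipsoid_surface(a + t, b + t, c + t, c + t, n_theta=500, n_phi=500)
    d_endo, _ = cKDTree(endo).query(mesh_nodes)
    d_epi, _ = cKDTree(epi).query(mesh_nodes)
    return d_endo / np.maximum(d_endo + d_epi, 1e-12)
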