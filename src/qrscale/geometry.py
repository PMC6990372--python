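"""Tetrahedral LV mesh data model, file I/O, surface labeling and size metrics.

Units are fixed package-wide: coordinates in mm, time in ms, speed in m/s.
Because 1 m/s == 1 mm/ms, speeds are used directly in the mm/ms coordinate
system with no conversion factors anywhere else in the package.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger("qrscale")

#: Myocardial density used to convert wall volume to LV mass (g/mL).
MYOCARDIAL_DENSITY_G_PER_ML = 1.05

# Outward-oriented faces of a positively oriented tet (v0,v1,v2,v3).
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


class SurfaceLabel(IntEnum):
    """Labels for the three boundary surfaces of an LV wall mesh."""

    ENDO = 1
    EPI = 2
    BASE = 3


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be parsed."""


class UnsupportedElementError(MeshFormatError):
    """Raised when a mesh file contains non-tetrahedral volume cells."""


class LabelingError(RuntimeError):
    """Raised when boundary surfaces cannot be partitioned into ENDO/EPI/BASE."""


class CavityVolumeError(RuntimeError):
    """Raised when the endocardial surface cannot be closed with a single planar cap."""


@dataclass
class TetMesh:
    """Tetrahedral LV geometry with labeled boundary surfaces.

    Attributes
    ----------
    nodes : (N, 3) float array
        Node coordinates in mm.
    tets : (M, 4) int array
        Node indices of each tetrahedron, positively oriented.
    boundary_faces : (B, 3) int array
        Boundary triangles (faces belonging to exactly one tet), oriented
        outward with respect to the wall.
    boundary_labels : (B,) int array
        ``SurfaceLabel`` value per boundary triangle.
    fibers : (M, 3) float array or None
        Optional per-element unit fiber vectors (attached by the fields stage).
    """

    nodes: np.ndarray
    tets: np.ndarray
    boundary_faces: np.ndarray
    boundary_labels: np.ndarray
    mesh_id: str = ""
    sex: str = "UNSPECIFIED"
    fibers: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    # -- construction -----------------------------------------------------

    @classmethod
    def create(
        cls,
        nodes: np.ndarray,
        tets: np.ndarray,
        boundary_labels: np.ndarray | None = None,
        boundary_faces: np.ndarray | None = None,
        mesh_id: str = "",
        sex: str = "UNSPECIFIED",
        validate: bool = True,
    ) -> "TetMesh":
        """Build a mesh, normalizing tet orientation and extracting the boundary.

        Negative-volume tets are reordered (last two indices swapped) and the
        count logged.  If ``boundary_labels`` is None the mesh is returned
        unlabeled (all zeros); most pipeline stages then require
        :func:`label_surfaces` first.
        """
        nodes = np.ascontiguousarray(nodes, dtype=np.float64)
        tets = np.ascontiguousarray(tets, dtype=np.int64)
        if tets.ndim != 2 or tets.shape[1] != 4:
            raise MeshFormatError("tets must be an (M, 4) index array")
        vols = _tet_volumes(nodes, tets)
        neg = vols < 0
        if neg.any():
            logger.info("reoriented %d negative-volume tets", int(neg.sum()))
            tets = tets.copy()
            tets[neg, 2], tets[neg, 3] = tets[neg, 3], tets[neg, 2].copy()
        if boundary_faces is None:
            boundary_faces = _boundary_faces(tets)
        if boundary_labels is None:
            boundary_labels = np.zeros(len(boundary_faces), dtype=np.int64)
        mesh = cls(
            nodes=nodes,
            tets=tets,
            boundary_faces=np.ascontiguousarray(boundary_faces, dtype=np.int64),
            boundary_labels=np.ascontiguousarray(boundary_labels, dtype=np.int64),
            mesh_id=mesh_id,
            sex=sex,
        )
        if validate:
            mesh.validate(require_labels=boundary_labels is not None and boundary_labels.any())
        return mesh

    # -- basic properties --------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @property
    def is_labeled(self) -> bool:
        lab = self.boundary_labels
        return bool(
            (lab > 0).all()
            and (lab == SurfaceLabel.ENDO).any()
            and (lab == SurfaceLabel.EPI).any()
        )

    def tet_volumes(self) -> np.ndarray:
        """Signed volumes (mm^3) of all tets; positive after normalization."""
        return _tet_volumes(self.nodes, self.tets)

    def faces_with_label(self, label: SurfaceLabel) -> np.ndarray:
        return self.boundary_faces[self.boundary_labels == int(label)]

    def nodes_with_label(self, label: SurfaceLabel) -> np.ndarray:
        """Sorted unique node indices on a labeled boundary surface."""
        return np.unique(self.faces_with_label(label))

    def edges(self) -> np.ndarray:
        """Unique undirected edges of the tet mesh, as a sorted (E, 2) array."""
        if "edges" not in self._cache:
            pairs = self.tets[:, [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]]
            pairs = pairs.reshape(-1, 2)
            pairs = np.sort(pairs, axis=1)
            self._cache["edges"] = np.unique(pairs, axis=0)
        return self._cache["edges"]

    def mean_edge_length(self) -> float:
        e = self.edges()
        d = self.nodes[e[:, 0]] - self.nodes[e[:, 1]]
        return float(np.linalg.norm(d, axis=1).mean())

    def node_tet_adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR-style (offsets, tet-indices) mapping node -> incident tets."""
        if "adj" not in self._cache:
            flat = self.tets.ravel()
            tet_ids = np.repeat(np.arange(self.n_tets), 4)
            order = np.argsort(flat, kind="stable")
            counts = np.bincount(flat, minlength=self.n_nodes)
            offsets = np.zeros(self.n_nodes + 1, dtype=np.int64)
            np.cumsum(counts, out=offsets[1:])
            self._cache["adj"] = (offsets, tet_ids[order].astype(np.int64))
        return self._cache["adj"]

    def node_node_adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR-style (offsets, neighbor-indices) over mesh edges."""
        if "nbr" not in self._cache:
            e = self.edges()
            src = np.concatenate([e[:, 0], e[:, 1]])
            dst = np.concatenate([e[:, 1], e[:, 0]])
            order = np.argsort(src, kind="stable")
            counts = np.bincount(src, minlength=self.n_nodes)
            offsets = np.zeros(self.n_nodes + 1, dtype=np.int64)
            np.cumsum(counts, out=offsets[1:])
            self._cache["nbr"] = (offsets, dst[order].astype(np.int64))
        return self._cache["nbr"]

    # -- validation --------------------------------------------------------

    def validate(self, require_labels: bool = True) -> None:
        """Check the mesh invariants; raise ``MeshFormatError``/``LabelingError``."""
        if self.nodes.shape[1] != 3:
            raise MeshFormatError("nodes must be (N, 3)")
        if (self.tets < 0).any() or (self.tets >= self.n_nodes).any():
            raise MeshFormatError("tet index out of range")
        same = (
            (self.tets[:, 0] == self.tets[:, 1])
            | (self.tets[:, 0] == self.tets[:, 2])
            | (self.tets[:, 0] == self.tets[:, 3])
            | (self.tets[:, 1] == self.tets[:, 2])
            | (self.tets[:, 1] == self.tets[:, 3])
            | (self.tets[:, 2] == self.tets[:, 3])
        )
        if same.any():
            raise MeshFormatError(f"{int(same.sum())} tets with repeated node indices")
        vols = self.tet_volumes()
        if (vols <= 0).any():
            raise MeshFormatError(f"{int((vols <= 0).sum())} non-positive-volume tets")
        expected = _boundary_faces(self.tets)
        if len(expected) != len(self.boundary_faces):
            raise MeshFormatError(
                f"boundary has {len(expected)} faces but {len(self.boundary_faces)} are stored "
                "(non-conforming or mislabeled boundary)"
            )
        if not _same_face_set(expected, self.boundary_faces):
            raise MeshFormatError("stored boundary faces do not match the tet boundary")
        if require_labels:
            lab = self.boundary_labels
            valid = {int(s) for s in SurfaceLabel}
            if not set(np.unique(lab)).issubset(valid):
                raise LabelingError("boundary labels outside {ENDO, EPI, BASE}")
            if not (lab == SurfaceLabel.ENDO).any() or not (lab == SurfaceLabel.EPI).any():
                raise LabelingError("ENDO and EPI label sets must both be non-empty")


@dataclass(frozen=True)
class SizeMetrics:
    """LV size measures: mass (g), cavity volume (mL), wall volume (mL)."""

    lv_mass: float
    lvedv: float
    wall_volume: float
    density: float = MYOCARDIAL_DENSITY_G_PER_ML


# ---------------------------------------------------------------------------
# low-level helpers


def _tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a = nodes[tets[:, 1]] - nodes[tets[:, 0]]
    b = nodes[tets[:, 2]] - nodes[tets[:, 0]]
    c = nodes[tets[:, 3]] - nodes[tets[:, 0]]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def _boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Outward-oriented faces that belong to exactly one tet."""
    faces = tets[:, _TET_FACES].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    skey = key[order]
    new = np.ones(len(skey), dtype=bool)
    new[1:] = (skey[1:] != skey[:-1]).any(axis=1)
    group = np.cumsum(new) - 1
    counts = np.bincount(group)
    boundary = counts[group] == 1
    return faces[order[boundary]]


def _same_face_set(a: np.ndarray, b: np.ndarray) -> bool:
    ka = np.sort(a, axis=1)
    kb = np.sort(b, axis=1)
    ka = ka[np.lexsort((ka[:, 2], ka[:, 1], ka[:, 0]))]
    kb = kb[np.lexsort((kb[:, 2], kb[:, 1], kb[:, 0]))]
    return ka.shape == kb.shape and bool((ka == kb).all())


def _closed_surface_volume(nodes: np.ndarray, faces: np.ndarray) -> float:
    """Signed volume (mm^3) enclosed by a consistently oriented triangle surface."""
    x0 = nodes[faces[:, 0]]
    x1 = nodes[faces[:, 1]]
    x2 = nodes[faces[:, 2]]
    return float(np.einsum("ij,ij->i", x0, np.cross(x1, x2)).sum() / 6.0)


def _endo_cap_faces(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Flipped (cavity-outward) endo faces plus planar-cap fan triangles.

    The basal opening of the endocardial surface is closed with a fan from the
    centroid of its single boundary loop.  Raises ``CavityVolumeError`` if the
    opening is not a single loop.
    """
    endo = mesh.faces_with_label(SurfaceLabel.ENDO)
    if len(endo) == 0:
        raise CavityVolumeError("mesh has no ENDO faces")
    flipped = endo[:, [0, 2, 1]]
    # Directed edges of the flipped surface; boundary edges appear without
    # their reverse.
    e = np.concatenate([flipped[:, [0, 1]], flipped[:, [1, 2]], flipped[:, [2, 0]]])
    fwd = set(map(tuple, e))
    boundary = [(u, v) for (u, v) in fwd if (v, u) not in fwd]
    if not boundary:
        # Closed endo surface (no basal opening): nothing to cap.
        return flipped, np.empty((0, 3), dtype=np.int64)
    succ = {}
    for u, v in boundary:
        if u in succ:
            raise CavityVolumeError("endocardial opening is not a single simple loop")
        succ[u] = v
    start = boundary[0][0]
    loop = [start]
    while True:
        nxt = succ.get(loop[-1])
        if nxt is None:
            raise CavityVolumeError("endocardial opening loop is not closed")
        if nxt == start:
            break
        loop.append(nxt)
        if len(loop) > len(boundary):
            raise CavityVolumeError("endocardial opening contains multiple loops")
    if len(loop) != len(boundary):
        raise CavityVolumeError("endocardial opening contains multiple loops")
    centroid = mesh.nodes[loop].mean(axis=0)
    cidx = len(mesh.nodes)  # virtual node appended by the caller
    cap = np.array(
        [[cidx, v, u] for (u, v) in zip(loop, loop[1:] + [loop[0]])], dtype=np.int64
    )
    return flipped, cap, centroid


# ---------------------------------------------------------------------------
# size metrics


def size_metrics(mesh: TetMesh, density: float = MYOCARDIAL_DENSITY_G_PER_ML) -> SizeMetrics:
    """Compute LV mass, LVEDV and wall volume for a labeled mesh.

    Wall volume is the sum of tet volumes; LV mass multiplies it by the
    myocardial density (1.05 g/mL by default).  LVEDV is the volume enclosed
    by the endocardial surface closed with a planar cap across the basal
    opening (divergence theorem on the closed triangulation).
    """
    if not mesh.is_labeled:
        raise LabelingError("size_metrics requires a labeled mesh")
    wall_mm3 = float(mesh.tet_volumes().sum())
    flipped, cap, *rest = _endo_cap_faces(mesh)
    if len(cap):
        centroid = rest[0]
        nodes = np.vstack([mesh.nodes, centroid[None, :]])
        faces = np.vstack([flipped, cap])
    else:
        nodes, faces = mesh.nodes, flipped
    cavity_mm3 = abs(_closed_surface_volume(nodes, faces))
    return SizeMetrics(
        lv_mass=wall_mm3 / 1000.0 * density,
        lvedv=cavity_mm3 / 1000.0,
        wall_volume=wall_mm3 / 1000.0,
        density=density,
    )


# ---------------------------------------------------------------------------
# surface labeling


def _auto_long_axis(mesh: TetMesh) -> np.ndarray:
    """Principal axis of the node cloud, signed so that it points toward the
    flat (basal) end — the end with the larger area of axis-aligned boundary
    faces."""
    x = mesh.nodes - mesh.nodes.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    axis = vt[0]
    f = mesh.boundary_faces
    n = np.cross(
        mesh.nodes[f[:, 1]] - mesh.nodes[f[:, 0]],
        mesh.nodes[f[:, 2]] - mesh.nodes[f[:, 0]],
    )
    area = np.linalg.norm(n, axis=1) / 2.0
    with np.errstate(invalid="ignore"):
        align = n / np.linalg.norm(n, axis=1, keepdims=True)
    proj = mesh.nodes[f].mean(axis=1) @ axis
    flat = np.abs(align @ axis) > 0.95
    top = proj > np.median(proj)
    a_top = area[flat & top].sum()
    a_bot = area[flat & ~top].sum()
    return axis if a_top >= a_bot else -axis


def label_surfaces(
    mesh: TetMesh,
    long_axis: np.ndarray | None = None,
    base_fraction: float = 0.05,
    force: bool = False,
) -> TetMesh:
    """Partition boundary faces into ENDO / EPI / BASE.

    Faces whose centroid projects within ``base_fraction`` of the top of the
    long-axis extent become BASE; the remaining faces are split by connected
    component, the component enclosing the smaller volume (the cavity shell)
    becoming ENDO.  Already-labeled meshes pass through unchanged unless
    ``force`` is set.
    """
    if mesh.is_labeled and not force:
        return mesh
    if long_axis is None:
        axis = _auto_long_axis(mesh)
    else:
        axis = np.asarray(long_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
    faces = mesh.boundary_faces
    if len(faces) == 0:
        raise LabelingError("mesh has no boundary faces")
    cent = mesh.nodes[faces].mean(axis=1) @ axis
    proj = mesh.nodes @ axis
    lo, hi = float(proj.min()), float(proj.max())
    is_base = cent >= hi - base_fraction * (hi - lo)
    rest = np.where(~is_base)[0]
    if len(rest) == 0:
        raise LabelingError("all boundary faces classified as BASE")
    # Connected components of the remaining faces via shared edges.
    sub = faces[rest]
    e = np.sort(
        np.concatenate([sub[:, [0, 1]], sub[:, [1, 2]], sub[:, [2, 0]]]), axis=1
    )
    fid = np.tile(np.arange(len(sub)), 3)
    order = np.lexsort((e[:, 1], e[:, 0]))
    es, fs = e[order], fid[order]
    same = (es[1:] == es[:-1]).all(axis=1)
    rows = fs[:-1][same]
    cols = fs[1:][same]
    adj = coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(sub), len(sub))
    )
    ncomp, comp = connected_components(adj, directed=False)
    if ncomp < 2:
        raise LabelingError(
            f"expected >= 2 non-base surface components, found {ncomp}; "
            "manual labels required"
        )
    vols = np.empty(ncomp)
    for c in range(ncomp):
        vols[c] = abs(_closed_surface_volume(mesh.nodes, sub[comp == c]))
    endo_comp = int(np.argmin(vols))
    labels = np.empty(len(faces), dtype=np.int64)
    labels[is_base] = int(SurfaceLabel.BASE)
    labels[rest] = np.where(
        comp == endo_comp, int(SurfaceLabel.ENDO), int(SurfaceLabel.EPI)
    )
    out = TetMesh(
        nodes=mesh.nodes,
        tets=mesh.tets,
        boundary_faces=mesh.boundary_faces,
        boundary_labels=labels,
        mesh_id=mesh.mesh_id,
        sex=mesh.sex,
        fibers=mesh.fibers,
    )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# file I/O: VTK legacy ASCII


_LABEL_NAMES = {
    SurfaceLabel.ENDO: "endo",
    SurfaceLabel.EPI: "epi",
    SurfaceLabel.BASE: "base",
}


def write_mesh(
    mesh: TetMesh,
    path: str | Path,
    format: str = "vtk",
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a mesh as legacy ASCII VTK or as CARP .pts/.elem(/.lon/.surf).

    For VTK the tets are followed by the boundary triangles, with a
    ``surface_label`` cell-data array (0 on tets).  Extra per-node scalars
    (e.g. "activation_ms", "transmural") and per-tet scalars (e.g. "region")
    can be attached via ``point_data`` / ``cell_data``.  For CARP, ``path``
    is the basename; labeled surfaces are written as ``<base>_<name>.surf``
    and a ``.lon`` file is emitted when fibers are attached.
    """
    path = Path(path)
    if format == "vtk":
        _write_vtk(mesh, path, point_data=point_data, cell_data=cell_data)
    elif format == "carp":
        if point_data or cell_data:
            logger.warning("CARP writer ignores point/cell data arrays")
        _write_carp(mesh, path)
    else:
        raise ValueError(f"unknown mesh format {format!r}")


def read_mesh(path: str | Path, format: str | None = None) -> TetMesh:
    """Read a mesh written by :func:`write_mesh` (VTK legacy or CARP)."""
    path = Path(path)
    if format is None:
        format = "carp" if path.suffix in ("", ".pts", ".elem") else "vtk"
    if format == "vtk":
        return _read_vtk(path)
    if format == "carp":
        return _read_carp(path)
    raise ValueError(f"unknown mesh format {format!r}")


def _write_vtk(
    mesh: TetMesh,
    path: Path,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    nb = len(mesh.boundary_faces)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{mesh.mesh_id or 'qrscale mesh'} sex={mesh.sex}\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.17g")
        ncells = mesh.n_tets + nb
        size = 5 * mesh.n_tets + 4 * nb
        fh.write(f"CELLS {ncells} {size}\n")
        tet_rows = np.hstack([np.full((mesh.n_tets, 1), 4), mesh.tets])
        np.savetxt(fh, tet_rows, fmt="%d")
        if nb:
            tri_rows = np.hstack([np.full((nb, 1), 3), mesh.boundary_faces])
            np.savetxt(fh, tri_rows, fmt="%d")
        fh.write(f"CELL_TYPES {ncells}\n")
        np.savetxt(fh, np.concatenate([np.full(mesh.n_tets, 10), np.full(nb, 5)]), fmt="%d")
        fh.write(f"CELL_DATA {ncells}\n")
        fh.write("SCALARS surface_label int 1\nLOOKUP_TABLE default\n")
        np.savetxt(
            fh,
            np.concatenate([np.zeros(mesh.n_tets, dtype=int), mesh.boundary_labels]),
            fmt="%d",
        )
        if mesh.fibers is not None:
            fh.write("VECTORS fiber double\n")
            vecs = np.vstack([mesh.fibers, np.zeros((nb, 3))])
            np.savetxt(fh, vecs, fmt="%.17g")
        for name, arr in (cell_data or {}).items():
            if len(arr) != mesh.n_tets:
                raise ValueError(f"cell_data {name!r} must have one value per tet")
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, np.concatenate([np.asarray(arr, float), np.zeros(nb)]), fmt="%.17g")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                if len(arr) != mesh.n_nodes:
                    raise ValueError(f"point_data {name!r} must have one value per node")
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, np.asarray(arr, float), fmt="%.17g")


class _TokenStream:
    """Whitespace tokenizer that remembers line numbers for error messages."""

    def __init__(self, path: Path):
        self.path = path
        self.tokens: list[str] = []
        self.lines: list[int] = []
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                for tok in line.split():
                    self.tokens.append(tok)
                    self.lines.append(i)
        self.pos = 0

    def error(self, msg: str) -> MeshFormatError:
        line = self.lines[min(self.pos, len(self.lines) - 1)] if self.lines else 0
        return MeshFormatError(f"{self.path}:{line}: {msg}")

    def next(self) -> str:
        if self.pos >= len(self.tokens):
            raise self.error("unexpected end of file")
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def next_int(self) -> int:
        tok = self.next()
        try:
            return int(tok)
        except ValueError:
            self.pos -= 1
            raise self.error(f"expected integer, got {tok!r}")

    def next_float(self) -> float:
        tok = self.next()
        try:
            return float(tok)
        except ValueError:
            self.pos -= 1
            raise self.error(f"expected number, got {tok!r}")

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None


def _read_vtk(path: Path) -> TetMesh:
    # Line 1-2: header + title (title may carry sex=... metadata).
    with open(path) as fh:
        header = fh.readline()
        title = fh.readline().strip()
    if "vtk" not in header.lower():
        raise MeshFormatError(f"{path}:1: not a legacy VTK file")
    sex = "UNSPECIFIED"
    m = re.search(r"sex=(\w+)", title)
    if m:
        sex = m.group(1)
    ts = _TokenStream(path)
    # Skip the two header lines' tokens up to DATASET.
    while True:
        tok = ts.next().upper()
        if tok == "DATASET":
            kind = ts.next().upper()
            if kind != "UNSTRUCTURED_GRID":
                raise ts.error(f"unsupported dataset {kind}")
            break
    nodes = tets = None
    tris: list = []
    tri_rows = None
    cells = None
    types = None
    labels_all = None
    while ts.peek() is not None:
        section = ts.next().upper()
        if section == "POINTS":
            n = ts.next_int()
            ts.next()  # dtype
            nodes = np.array([ts.next_float() for _ in range(3 * n)]).reshape(n, 3)
        elif section == "CELLS":
            ncells = ts.next_int()
            ts.next_int()  # total size
            cells = []
            for _ in range(ncells):
                k = ts.next_int()
                cells.append([ts.next_int() for _ in range(k)])
        elif section == "CELL_TYPES":
            ncells = ts.next_int()
            types = np.array([ts.next_int() for _ in range(ncells)])
        elif section == "CELL_DATA":
            ncells = ts.next_int()
        elif section == "SCALARS":
            name = ts.next()
            ts.next()  # dtype
            nxt = ts.peek()
            if nxt is not None and nxt.isdigit():
                ts.next()
            lookup = ts.next().upper()
            if lookup != "LOOKUP_TABLE":
                raise ts.error("expected LOOKUP_TABLE after SCALARS")
            ts.next()
            vals = np.array([ts.next_float() for _ in range(ncells)])
            if name == "surface_label":
                labels_all = vals.astype(np.int64)
        elif section == "VECTORS":
            ts.next()
            ts.next()
            for _ in range(3 * ncells):
                ts.next_float()
        elif section == "POINT_DATA":
            ncells = ts.next_int()
        else:
            raise ts.error(f"unsupported VTK section {section!r}")
    if nodes is None or cells is None or types is None:
        raise MeshFormatError(f"{path}: missing POINTS/CELLS/CELL_TYPES sections")
    tets_list, tri_list, tri_pos = [], [], []
    for i, (cell, ctype) in enumerate(zip(cells, types)):
        if ctype == 10:
            tets_list.append(cell)
        elif ctype == 5:
            tri_list.append(cell)
            tri_pos.append(i)
        else:
            raise UnsupportedElementError(
                f"{path}: unsupported VTK cell type {ctype} at cell {i}"
            )
    tets = np.array(tets_list, dtype=np.int64)
    labels = None
    faces = None
    if tri_list:
        faces = np.array(tri_list, dtype=np.int64)
        if labels_all is not None:
            labels = labels_all[np.array(tri_pos)]
    mesh = TetMesh.create(
        nodes,
        tets,
        boundary_labels=None,
        mesh_id=path.stem,
        sex=sex,
        validate=False,
    )
    if faces is not None and labels is not None:
        mesh = _attach_labels(mesh, faces, labels)
    if not mesh.is_labeled:
        logger.info("%s: no surface labels found; geometric inference required", path)
    mesh.validate(require_labels=False)
    return mesh


def _attach_labels(mesh: TetMesh, faces: np.ndarray, labels: np.ndarray) -> TetMesh:
    """Map labels given on an arbitrary triangle list onto the mesh's own
    (outward-oriented) boundary faces, by sorted node-tuple lookup."""
    own = np.sort(mesh.boundary_faces, axis=1)
    given = np.sort(faces, axis=1)
    lut = {tuple(f): int(l) for f, l in zip(given, labels)}
    out = np.zeros(len(own), dtype=np.int64)
    for i, f in enumerate(map(tuple, own)):
        out[i] = lut.get(f, 0)
    return TetMesh(
        nodes=mesh.nodes,
        tets=mesh.tets,
        boundary_faces=mesh.boundary_faces,
        boundary_labels=out,
        mesh_id=mesh.mesh_id,
        sex=mesh.sex,
        fibers=mesh.fibers,
    )


# ---------------------------------------------------------------------------
# file I/O: CARP


def _write_carp(mesh: TetMesh, base: Path) -> None:
    base.parent.mkdir(parents=True, exist_ok=True)
    with open(base.with_suffix(".pts"), "w") as fh:
        fh.write(f"{mesh.n_nodes}\n")
        np.savetxt(fh, mesh.nodes, fmt="%.17g")
    with open(base.with_suffix(".elem"), "w") as fh:
        fh.write(f"{mesh.n_tets}\n")
        for row in mesh.tets:
            fh.write(f"Tt {row[0]} {row[1]} {row[2]} {row[3]} 1\n")
    if mesh.fibers is not None:
        with open(base.with_suffix(".lon"), "w") as fh:
            fh.write("1\n")
            np.savetxt(fh, mesh.fibers, fmt="%.17g")
    for label, name in _LABEL_NAMES.items():
        faces = mesh.faces_with_label(label)
        if len(faces) == 0:
            logger.warning("label %s empty; %s surf file not written", name, name)
            continue
        with open(base.parent / f"{base.stem}_{name}.surf", "w") as fh:
            fh.write(f"{len(faces)}\n")
            for row in faces:
                fh.write(f"Tr {row[0]} {row[1]} {row[2]}\n")


def _read_carp(path: Path) -> TetMesh:
    base = path.with_suffix("") if path.suffix in (".pts", ".elem") else path
    pts = base.with_suffix(".pts")
    elem = base.with_suffix(".elem")
    if not pts.exists() or not elem.exists():
        raise FileNotFoundError(f"CARP mesh requires {pts} and {elem}")
    with open(pts) as fh:
        try:
            n = int(fh.readline())
        except ValueError:
            raise MeshFormatError(f"{pts}:1: expected node count")
        nodes = np.loadtxt(fh, dtype=float, max_rows=n)
    if nodes.shape != (n, 3):
        raise MeshFormatError(f"{pts}: expected {n} x-y-z records")
    tets = []
    with open(elem) as fh:
        try:
            m = int(fh.readline())
        except ValueError:
            raise MeshFormatError(f"{elem}:1: expected element count")
        for i, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if parts[0] != "Tt":
                raise UnsupportedElementError(
                    f"{elem}:{i}: unsupported element type {parts[0]!r}"
                )
            if len(parts) < 5:
                raise MeshFormatError(f"{elem}:{i}: truncated element record")
            tets.append([int(p) for p in parts[1:5]])
    tets = np.array(tets, dtype=np.int64)
    if len(tets) != m:
        raise MeshFormatError(f"{elem}: expected {m} elements, found {len(tets)}")
    mesh = TetMesh.create(nodes, tets, mesh_id=base.stem, validate=False)
    # fibers
    lon = base.with_suffix(".lon")
    if lon.exists():
        with open(lon) as fh:
            try:
                nvec = int(fh.readline())
            except ValueError:
                raise MeshFormatError(f"{lon}:1: expected vector-count header")
            data = np.loadtxt(fh, dtype=float)
        data = np.atleast_2d(data)
        if data.shape[1] < 3:
            raise MeshFormatError(f"{lon}: expected >=3 columns")
        mesh.fibers = data[:, :3]
    # labeled surfaces
    faces_all, labels_all = [], []
    for label, name in _LABEL_NAMES.items():
        surf = base.parent / f"{base.stem}_{name}.surf"
        if not surf.exists():
            continue
        with open(surf) as fh:
            try:
                k = int(fh.readline())
            except ValueError:
                raise MeshFormatError(f"{surf}:1: expected triangle count")
            for i, line in enumerate(fh, start=2):
                parts = line.split()
                if not parts:
                    continue
                if parts[0] != "Tr" or len(parts) < 4:
                    raise MeshFormatError(f"{surf}:{i}: expected 'Tr n0 n1 n2'")
                faces_all.append([int(p) for p in parts[1:4]])
                labels_all.append(int(label))
    if faces_all:
        mesh = _attach_labels(
            mesh, np.array(faces_all, dtype=np.int64), np.array(labels_all, dtype=np.int64)
        )
    mesh.validate(require_labels=False)
    return mesh
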