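"""Synthetic ventricular geometries.

Two families of discretized myocardial domains are provided:

* 2D rectangular sheets ("slabs") of quadrilateral elements — fast fixtures
  on which the whole downstream pipeline (ischemia grading, pacing protocol,
  feature extraction) runs at desk scale;
* voxelized truncated prolate-ellipsoid left-ventricular shells — closed
  apex, open base — for demonstration runs on a 3D anatomy.

Element-centred labelling convention: ``region_label`` is 0 for healthy
myocardium and ``k >= 1`` for the k-th concentric ischemic layer (1 =
outermost); ``segment_id`` is 1..17 following AHA numbering, 0 for elements
outside the LV. Internal indices are 0-based.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VentricleGeometry",
    "IschemiaSpec",
    "GeometryError",
    "generate_slab",
    "generate_lv_shell",
    "assign_aha_segments",
    "assign_fibers",
]


class GeometryError(ValueError):
    """Raised for invalid geometry specifications."""


@dataclass
class IschemiaSpec:
    """Placement of the synthetic ischemic subdomain.

    Parameters
    ----------
    center : tuple of float, optional
        Centre of the ischemic disc/ball in mm. ``None`` places it at the
        domain centre (slab) or at a seeded mid-wall location (shell).
    radius : float
        Radius in mm. ``0`` yields a fully healthy domain. Ignored when
        ``target_ischemic_fraction`` is given.
    n_layers : int
        Number of concentric layers the region will later be divided into
        (patient-derived models carry between 10 and 27).
    target_ischemic_fraction : float, optional
        Desired ischemic volume as a percentage of total myocardial volume;
        when set, the radius is solved by bisection on element counts.
    """

    center: tuple | None = None
    radius: float = 0.0
    n_layers: int = 10
    target_ischemic_fraction: float | None = None

    def __post_init__(self):
        if self.n_layers < 1:
            raise GeometryError(f"n_layers must be >= 1, got {self.n_layers}")
        if self.radius < 0:
            raise GeometryError(f"radius must be >= 0, got {self.radius}")
        f = self.target_ischemic_fraction
        if f is not None and not (0 <= f < 100):
            raise GeometryError(
                f"target_ischemic_fraction must be in [0, 100), got {f}")


@dataclass
class VentricleGeometry:
    """Discretized myocardial domain with per-element labels.

    Attributes
    ----------
    nodes : (n_nodes, dim) float array, mm
    elements : (n_elem, 4|8) int array
        Quad (2D) or hexahedron (3D) corner-node connectivity.
    spacing : float
        Element edge length, mm.
    region_label : (n_elem,) int array
        0 = healthy, k >= 1 = ischemic layer k (1 outermost).
    fiber_angle : (n_elem,) float array, radians.
    segment_id : (n_elem,) int array
        AHA segment 1..17, or 0 outside the LV.
    element_volume : (n_elem,) float array
        mm^3 in 3D; mm^2 x unit thickness in 2D.
    centers : (n_elem, dim) float array, mm.
    shape : tuple or None
        Structured element-grid shape for slabs, ``None`` for voxel shells.
    metadata : dict
        Numeric provenance entries (seed, generator flags, axis lengths).
    """

    nodes: np.ndarray
    elements: np.ndarray
    spacing: float
    region_label: np.ndarray
    fiber_angle: np.ndarray
    segment_id: np.ndarray
    element_volume: np.ndarray
    centers: np.ndarray
    shape: tuple | None = None
    metadata: dict = field(default_factory=dict)
    extra_cell_data: dict = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return self.centers.shape[1]

    @property
    def n_elements(self) -> int:
        return self.region_label.size

    @property
    def ischemic_mask(self) -> np.ndarray:
        return self.region_label > 0

    @property
    def total_volume(self) -> float:
        return float(self.element_volume.sum())

    @property
    def ischemic_volume(self) -> float:
        return float(self.element_volume[self.ischemic_mask].sum())

    @property
    def ischemic_fraction(self) -> float:
        """Ischemic volume as a percentage of total myocardial volume."""
        return 100.0 * self.ischemic_volume / self.total_volume

    def copy(self) -> "VentricleGeometry":
        return dataclasses.replace(
            self,
            region_label=self.region_label.copy(),
            fiber_angle=self.fiber_angle.copy(),
            segment_id=self.segment_id.copy(),
            metadata=dict(self.metadata),
            extra_cell_data=dict(self.extra_cell_data),
        )

    def validate(self) -> None:
        n = self.n_elements
        for name in ("region_label", "fiber_angle", "segment_id",
                     "element_volume"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise GeometryError(f"{name} has shape {arr.shape}, "
                                    f"expected ({n},)")
        if np.any(self.element_volume <= 0):
            raise GeometryError("element volumes must be positive")
        lab = self.region_label
        layers = np.unique(lab[lab > 0])
        if layers.size and not np.array_equal(
                layers, np.arange(1, layers.size + 1)):
            raise GeometryError(
                f"ischemic layer indices must be contiguous from 1, "
                f"got {layers.tolist()}")


def _structured_nodes_2d(nx: int, ny: int, spacing: float):
    xs = np.arange(nx + 1) * spacing
    ys = np.arange(ny + 1) * spacing
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * (ny + 1) + j

    i, j = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    i, j = i.ravel(), j.ravel()
    elements = np.column_stack(
        [nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)])
    return nodes, elements.astype(np.int64)


def _solve_radius(centers, center, volumes, total, target_pct, r_max):
    """Bisect the radius so the labelled fraction matches target_pct."""
    lo, hi = 0.0, r_max
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        d2 = ((centers - center) ** 2).sum(axis=1)
        pct = 100.0 * volumes[d2 <= mid * mid].sum() / total
        if pct < target_pct:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_slab(nx: int, ny: int, spacing: float,
                  ischemia: IschemiaSpec | None = None,
                  seed: int = 0) -> VentricleGeometry:
    """Build a 2D myocardial sheet with an embedded ischemic disc.

    Parameters
    ----------
    nx, ny : int
        Element counts along x and y; both must be >= 10.
    spacing : float
        Element edge length in mm, within [0.1, 0.5].
    ischemia : IschemiaSpec, optional
        Disc placement; ``None`` or radius 0 gives a healthy sheet.
    seed : int
        Recorded in metadata; generation is fully deterministic.
    """
    if nx < 10 or ny < 10:
        raise GeometryError(f"nx, ny must be >= 10, got ({nx}, {ny})")
    if not (0.1 <= spacing <= 0.5):
        raise GeometryError(f"spacing must be in [0.1, 0.5] mm, got {spacing}")

    nodes, elements = _structured_nodes_2d(nx, ny, spacing)
    i, j = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    centers = np.column_stack([(i.ravel() + 0.5) * spacing,
                               (j.ravel() + 0.5) * spacing])
    n_elem = nx * ny
    region = np.zeros(n_elem, dtype=np.int64)
    Lx, Ly = nx * spacing, ny * spacing

    if ischemia is not None and (
            ischemia.radius > 0 or ischemia.target_ischemic_fraction):
        c = np.asarray(ischemia.center if ischemia.center is not None
                       else (0.5 * Lx, 0.5 * Ly), dtype=float)
        vol = np.full(n_elem, spacing * spacing)
        if ischemia.target_ischemic_fraction:
            r = _solve_radius(centers, c, vol, vol.sum(),
                              ischemia.target_ischemic_fraction,
                              r_max=max(Lx, Ly))
        else:
            r = float(ischemia.radius)
            if (c[0] - r < -spacing or c[0] + r > Lx + spacing
                    or c[1] - r < -spacing or c[1] + r > Ly + spacing):
                raise GeometryError(
                    f"ischemic disc (center {tuple(c)}, radius {r} mm) "
                    f"overflows the {Lx} x {Ly} mm domain")
        d2 = ((centers - c) ** 2).sum(axis=1)
        region[d2 <= r * r] = 1  # provisional single layer; see ischemia module

    geom = VentricleGeometry(
        nodes=nodes,
        elements=elements,
        spacing=spacing,
        region_label=region,
        fiber_angle=np.zeros(n_elem),
        segment_id=np.zeros(n_elem, dtype=np.int64),
        element_volume=np.full(n_elem, spacing * spacing),
        centers=centers,
        shape=(nx, ny),
        metadata={"seed": int(seed), "kind_slab": 1,
                  "n_layers": int(ischemia.n_layers) if ischemia else 1},
    )
    return geom


def generate_lv_shell(base_radius: float = 25.0, wall_thickness: float = 8.0,
                      apex_z: float = 45.0, spacing: float = 0.5,
                      ischemia: IschemiaSpec | None = None,
                      seed: int = 0) -> VentricleGeometry:
    """Voxelized truncated half-ellipsoid LV shell (closed apex, open base).

    The outer surface is the half-ellipsoid with equatorial semi-axes
    ``base_radius`` and long semi-axis ``apex_z`` (base plane at z=0, apex
    at z=-apex_z); the inner surface is offset by ``wall_thickness``.
    """
    if wall_thickness < 3 * spacing:
        raise GeometryError(
            f"degenerate shell: wall_thickness {wall_thickness} mm < "
            f"3 x spacing ({3 * spacing} mm)")
    if apex_z <= wall_thickness or base_radius <= wall_thickness:
        raise GeometryError("shell axes must exceed wall thickness")

    a_o, c_o = base_radius, apex_z
    a_i, c_i = a_o - wall_thickness, c_o - wall_thickness

    # Voxel lattice covering the bounding box.
    nxv = int(np.ceil(2 * a_o / spacing)) + 2
    nzv = int(np.ceil(c_o / spacing)) + 2
    x0 = -(nxv / 2) * spacing
    xs = x0 + (np.arange(nxv) + 0.5) * spacing
    zs = -((np.arange(nzv) + 0.5) * spacing)
    X, Y, Z = np.meshgrid(xs, xs, zs, indexing="ij")

    g_out = (X / a_o) ** 2 + (Y / a_o) ** 2 + (Z / c_o) ** 2
    g_in = (X / a_i) ** 2 + (Y / a_i) ** 2 + (Z / c_i) ** 2
    inside = (g_out <= 1.0) & (g_in >= 1.0) & (Z <= 0)
    idx = np.argwhere(inside)
    if idx.shape[0] == 0:
        raise GeometryError("shell specification produced no voxels")

    centers = np.column_stack([X[inside], Y[inside], Z[inside]])
    n_elem = centers.shape[0]

    # Hexahedral connectivity over the occupied voxels' corner lattice.
    corners_off = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                            [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]])
    corner_idx = idx[:, None, :] + corners_off[None, :, :]
    flat = (corner_idx[..., 0] * (nxv + 1) * (nzv + 1)
            + corner_idx[..., 1] * (nzv + 1) + corner_idx[..., 2])
    uniq, inv = np.unique(flat, return_inverse=True)
    elements = inv.reshape(n_elem, 8).astype(np.int64)
    ci = np.column_stack([uniq // ((nxv + 1) * (nzv + 1)),
                          (uniq // (nzv + 1)) % (nxv + 1),
                          uniq % (nzv + 1)])
    nodes = np.column_stack([x0 + ci[:, 0] * spacing,
                             x0 + ci[:, 1] * spacing,
                             -(ci[:, 2] * spacing)])

    region = np.zeros(n_elem, dtype=np.int64)
    vol = np.full(n_elem, spacing ** 3)

    if ischemia is not None and (
            ischemia.radius > 0 or ischemia.target_ischemic_fraction):
        if ischemia.center is not None:
            c = np.asarray(ischemia.center, dtype=float)
        else:
            rng = np.random.default_rng(seed)
            theta = rng.uniform(0, 2 * np.pi)
            r_mid = a_i + 0.5 * wall_thickness
            c = np.array([r_mid * np.cos(theta), r_mid * np.sin(theta),
                          -0.35 * c_o])
        if ischemia.target_ischemic_fraction:
            r = _solve_radius(centers, c, vol, vol.sum(),
                              ischemia.target_ischemic_fraction,
                              r_max=2 * (a_o + c_o))
        else:
            r = float(ischemia.radius)
        d2 = ((centers - c) ** 2).sum(axis=1)
        region[d2 <= r * r] = 1

    geom = VentricleGeometry(
        nodes=nodes,
        elements=elements,
        spacing=spacing,
        region_label=region,
        fiber_angle=np.zeros(n_elem),
        segment_id=np.zeros(n_elem, dtype=np.int64),
        element_volume=vol,
        centers=centers,
        shape=None,
        metadata={"seed": int(seed), "kind_slab": 0,
                  "base_radius": float(base_radius),
                  "wall_thickness": float(wall_thickness),
                  "apex_z": float(apex_z),
                  "n_layers": int(ischemia.n_layers) if ischemia else 1},
    )
    return geom


# ---------------------------------------------------------------------------
# AHA 17-segment assignment

def _aha_sector(phi, n_sectors, offset):
    """Bin circumferential angle phi (radians) into n_sectors starting at
    `offset` radians, counter-clockwise."""
    a = np.mod(phi - offset, 2 * np.pi)
    return np.minimum((a / (2 * np.pi / n_sectors)).astype(np.int64),
                      n_sectors - 1)


def assign_aha_segments(geom: VentricleGeometry) -> VentricleGeometry:
    """Assign the standard AHA 17-segment map to the LV.

    For LV shells the long axis (z) is divided into basal / mid / apical
    thirds; basal and mid rings each carry 6 circumferential sectors of 60
    degrees, the apical ring 4 sectors of 90 degrees (offset 45 degrees),
    and the apex cap is segment 17. For 2D slabs a deterministic 17-tile
    rectangular layout (3 rows x 6 columns, the last two tiles of the top
    row merged) substitutes for the polar map; this substitution is flagged
    in ``metadata['aha_slab_tiling']``.
    """
    out = geom.copy()
    if geom.metadata.get("kind_slab"):
        nx, ny = geom.shape
        i = (geom.centers[:, 0] / geom.spacing).astype(np.int64)
        j = (geom.centers[:, 1] / geom.spacing).astype(np.int64)
        col = np.minimum(i * 6 // nx, 5)
        row = np.minimum(j * 3 // ny, 2)
        tile = row * 6 + col  # 0..17
        tile[tile == 17] = 16  # merge the top row's last two tiles
        out.segment_id = (tile + 1).astype(np.int64)
        out.metadata["aha_slab_tiling"] = 1
    else:
        if "apex_z" not in geom.metadata:
            raise GeometryError("missing long-axis metadata (apex_z); "
                                "cannot orient the AHA map")
        z = geom.centers[:, 2]
        c_o = geom.metadata["apex_z"]
        # Normalized long-axis coordinate: 0 at apex tip, 1 at base.
        u = 1.0 + z / c_o
        phi = np.arctan2(geom.centers[:, 1], geom.centers[:, 0])
        seg = np.zeros(geom.n_elements, dtype=np.int64)

        cap = u < 1.0 / 12.0
        basal = u >= 2.0 / 3.0
        mid = (u >= 1.0 / 3.0) & ~basal
        apical = ~cap & ~basal & ~mid

        seg[basal] = 1 + _aha_sector(phi[basal], 6, 0.0)
        seg[mid] = 7 + _aha_sector(phi[mid], 6, 0.0)
        seg[apical] = 13 + _aha_sector(phi[apical], 4, np.pi / 4)
        seg[cap] = 17
        out.segment_id = seg
    present = np.unique(out.segment_id[out.segment_id > 0])
    if present.size != 17:
        raise GeometryError(
            f"AHA assignment produced {present.size} segments, expected 17")
    return out


# ---------------------------------------------------------------------------
# Rule-based fibers: linear rotation with transmural depth

def transmural_depth(geom: VentricleGeometry) -> np.ndarray:
    """Normalized transmural coordinate per element: 0 at endo, 1 at epi.

    Slabs use the y coordinate. Shells solve, per voxel, for the
    interpolation parameter t of the ellipsoid family between the inner
    (t=0) and outer (t=1) surfaces that passes through the voxel centre
    (bisection, vectorized)."""
    if geom.metadata.get("kind_slab"):
        ny = geom.shape[1]
        Ly = ny * geom.spacing
        d = geom.centers[:, 1] / Ly
        return np.clip(d, 0.0, 1.0)
    a_o = geom.metadata["base_radius"]
    c_o = geom.metadata["apex_z"]
    w = geom.metadata["wall_thickness"]
    a_i, c_i = a_o - w, c_o - w
    x2 = geom.centers[:, 0] ** 2 + geom.centers[:, 1] ** 2
    z2 = geom.centers[:, 2] ** 2
    lo = np.zeros(geom.n_elements)
    hi = np.ones(geom.n_elements)
    for _ in range(40):
        t = 0.5 * (lo + hi)
        a_t = a_i + (a_o - a_i) * t
        c_t = c_i + (c_o - c_i) * t
        g = x2 / a_t ** 2 + z2 / c_t ** 2
        outside = g > 1.0  # voxel beyond the t-surface -> need larger t
        lo = np.where(outside, t, lo)
        hi = np.where(outside, hi, t)
    # endo (inner surface, t=0) maps to depth 0.
    return 0.5 * (lo + hi)


def assign_fibers(geom: VentricleGeometry, endo_angle: float = 60.0,
                  epi_angle: float = -60.0) -> VentricleGeometry:
    """Linear transmural rotation of the fiber helix angle.

    ``endo_angle`` and ``epi_angle`` are in degrees; the stored
    ``fiber_angle`` is in radians and varies linearly with the normalized
    transmural depth (0 = endocardium, 1 = epicardium)."""
    out = geom.copy()
    d = transmural_depth(geom)
    ang = np.deg2rad(endo_angle) + d * (np.deg2rad(epi_angle)
                                        - np.deg2rad(endo_angle))
    out.fiber_angle = ang
    out.metadata["endo_angle_deg"] = float(endo_angle)
    out.metadata["epi_angle_deg"] = float(epi_angle)
    return out
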