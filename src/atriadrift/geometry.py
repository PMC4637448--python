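"""Voxelised idealised atrial geometries.

These builders generate the synthetic study domains: a 2D sheet, a 1D strand,
a wedge with linearly tapering wall thickness, a ridge (a thicker central
strip on the wall), and three pectinate-muscle (PM) bridge configurations:

* PM1 — flat 25x25x3 mm wall with a semicircular-arc bridge of diameter 2 mm
  and arc length 14 mm (along-wall junction distance is *shorter* than along
  the bridge);
* PM2 — hemispherical wall (outer diameter 30 mm, thickness 3 mm) with a
  straight 8 mm chord bridge on the concave (endocardial) side (the bridge is
  the *short cut* between its junctions);
* PM3 — PM2 plus a 2 mm ridge following the endocardial wall surface between
  the two junctions.

Grid convention: nodes are voxel centres with spacing ``dx``; an in-plane
extent of L mm maps to round(L/dx)+1 nodes, and a wall thickness of T mm maps
to round(T/dx) node layers.  A voxel is tissue iff its centre lies inside the
continuous solid.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConstructionError

__all__ = [
    "VoxelGeometry", "LABELS",
    "build_sheet2d", "build_strand1d", "build_wedge", "build_ridge",
    "build_pm1", "build_pm2", "build_pm3",
]

LABELS = {"none": 0, "wall": 1, "ridge": 2, "bridge": 3, "junction": 4}
_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class VoxelGeometry:
    """Labelled occupancy mask on a Cartesian grid.

    mask/labels/epi are (nx, ny, nz) arrays; ``dx`` in mm; ``origin`` is the
    physical position (mm) of node (0, 0, 0).
    """

    mask: np.ndarray
    dx: float = 0.33
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    labels: np.ndarray = None
    epi: np.ndarray = None
    name: str = "custom"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.labels is None:
            self.labels = np.where(self.mask, LABELS["wall"], 0).astype(np.uint8)
        else:
            self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.epi is None:
            self.epi = self.mask.copy()
        else:
            self.epi = np.asarray(self.epi, dtype=bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_tissue(self) -> int:
        return int(self.mask.sum())

    def voxel_centres(self) -> np.ndarray:
        """(n_tissue, 3) physical coordinates (mm) of tissue voxel centres."""
        idx = np.argwhere(self.mask)
        return idx * self.dx + np.asarray(self.origin)

    def n_components(self) -> int:
        _, n = ndimage.label(self.mask, structure=_STRUCT6)
        return int(n)

    def validate(self) -> None:
        if self.n_tissue == 0:
            raise ConstructionError("empty geometry")
        if self.n_components() != 1:
            raise ConstructionError(
                f"tissue is not 6-connected ({self.n_components()} components)"
            )

    def relabel_junctions(self) -> None:
        """Mark bridge voxels that are 6-adjacent to wall/ridge as junctions."""
        bridge = self.labels == LABELS["bridge"]
        wallish = (self.labels == LABELS["wall"]) | (self.labels == LABELS["ridge"])
        near_wall = ndimage.binary_dilation(wallish, structure=_STRUCT6)
        self.labels[bridge & near_wall] = LABELS["junction"]

    def junction_clusters(self) -> list[np.ndarray]:
        """Connected clusters of junction voxels, as (k, 3) index arrays."""
        lab, n = ndimage.label(self.labels == LABELS["junction"],
                               structure=ndimage.generate_binary_structure(3, 3))
        return [np.argwhere(lab == i + 1) for i in range(n)]


def _nodes(length: float, dx: float) -> int:
    return int(round(length / dx)) + 1


def _layers(thickness: float, dx: float) -> int:
    return int(round(thickness / dx))


def build_sheet2d(Lx: float = 25.0, Ly: float = 25.0, dx: float = 0.33) -> VoxelGeometry:
    """Single-voxel-thick homogeneous sheet; all voxels wall and epicardial."""
    if Lx <= 0 or Ly <= 0:
        raise ValueError("sheet dimensions must be positive")
    nx, ny = _nodes(Lx, dx), _nodes(Ly, dx)
    mask = np.ones((nx, ny, 1), dtype=bool)
    g = VoxelGeometry(mask, dx=dx, name="sheet2d",
                      meta={"Lx": Lx, "Ly": Ly})
    g.validate()
    return g


def build_strand1d(length: float, dx: float = 0.33) -> VoxelGeometry:
    """1 x 1 x N voxel strand along x (used for pacing/CV protocols)."""
    import warnings

    if length <= 0:
        raise ValueError("strand length must be positive")
    if length < 20.0:
        warnings.warn("strand shorter than 20 mm; propagation may not reach "
                      "a steady solitary-wave profile", stacklevel=2)
    n = _nodes(length, dx)
    mask = np.ones((n, 1, 1), dtype=bool)
    g = VoxelGeometry(mask, dx=dx, name="strand1d", meta={"length": length})
    g.validate()
    return g


def build_wedge(Lx: float = 25.0, Ly: float = 25.0, max_thickness: float = 3.0,
                dx: float = 0.33) -> VoxelGeometry:
    """Wall whose thickness tapers linearly from ``max_thickness`` at x=0 to
    zero at x=Lx; a monolayer is kept wherever the taper rounds to < 1 layer
    so the tissue stays connected.  Epicardium = flat bottom face (z=0)."""
    if max_thickness < 2 * dx:
        raise ValueError("max_thickness must be at least 2*dx")
    nx, ny = _nodes(Lx, dx), _nodes(Ly, dx)
    nz = _layers(max_thickness, dx)
    mask = np.zeros((nx, ny, nz), dtype=bool)
    x = np.arange(nx) * dx
    th = max_thickness * (1.0 - x / Lx)
    nlay = np.round(th / dx).astype(int)
    nlay = np.clip(nlay, 1, nz)  # keep a monolayer so tissue stays connected
    for i in range(nx):
        mask[i, :, : nlay[i]] = True
    epi = np.zeros_like(mask)
    epi[:, :, 0] = mask[:, :, 0]
    g = VoxelGeometry(mask, dx=dx, epi=epi, name="wedge",
                      meta={"Lx": Lx, "Ly": Ly, "max_thickness": max_thickness})
    g.validate()
    return g


def build_ridge(Lx: float = 25.0, Ly: float = 25.0, wall_thickness: float = 3.0,
                ridge_width: float = 2.0, ridge_height: float = 2.0,
                dx: float = 0.33) -> VoxelGeometry:
    """Uniform wall plus a centred strip (full Ly span) of extra thickness on
    the endocardial (top) face; strip voxels labelled ridge."""
    if ridge_width > Lx:
        raise ValueError("ridge wider than wall")
    nx, ny = _nodes(Lx, dx), _nodes(Ly, dx)
    nw = _layers(wall_thickness, dx)
    nr = _layers(ridge_height, dx)
    mask = np.zeros((nx, ny, nw + nr), dtype=bool)
    mask[:, :, :nw] = True
    labels = np.where(mask, LABELS["wall"], 0).astype(np.uint8)
    if nr > 0:
        wcols = _layers(ridge_width, dx)
        i0 = (nx - wcols) // 2
        mask[i0 : i0 + wcols, :, nw : nw + nr] = True
        labels[i0 : i0 + wcols, :, nw : nw + nr] = LABELS["ridge"]
    else:
        mask = mask[:, :, :nw]
        labels = labels[:, :, :nw]
    epi = np.zeros_like(mask)
    epi[:, :, 0] = True
    g = VoxelGeometry(mask, dx=dx, labels=labels, epi=epi, name="ridge",
                      meta={"Lx": Lx, "Ly": Ly, "wall_thickness": wall_thickness,
                            "ridge_width": ridge_width,
                            "ridge_height": ridge_height})
    g.validate()
    return g


def _tube_mask(centres: np.ndarray, points: np.ndarray, radius: float) -> np.ndarray:
    """Boolean mask of voxel centres within ``radius`` of a polyline's points.

    ``points`` must be sampled finely (spacing << radius)."""
    from scipy.spatial import cKDTree

    tree = cKDTree(points)
    d, _ = tree.query(centres, k=1)
    return d <= radius


def build_pm1(dx: float = 0.33, Lx: float = 25.0, Ly: float = 25.0,
              wall_thickness: float = 3.0, bridge_length: float = 14.0,
              bridge_diameter: float = 2.0) -> VoxelGeometry:
    """Flat wall with a semicircular-arc bridge (arc length 14 mm).

    The arc lies in the xz-plane through the wall centre, perpendicular to the
    wall, with both endpoints rooted in the wall top surface.  The chord
    (junction separation) of a semicircle of arc length L is 2L/pi ~ 8.9 mm,
    i.e. shorter than the bridge — the defining PM1 property.
    """
    arc_r = bridge_length / np.pi
    rad = bridge_diameter / 2.0
    nx, ny = _nodes(Lx, dx), _nodes(Ly, dx)
    nw = _layers(wall_thickness, dx)
    z_top = (nw - 1) * dx
    nz = _layers(z_top + arc_r + rad + dx, dx) + 1
    mask = np.zeros((nx, ny, nz), dtype=bool)
    mask[:, :, :nw] = True
    labels = np.where(mask, LABELS["wall"], 0).astype(np.uint8)

    xc, yc = (nx - 1) * dx / 2.0, (ny - 1) * dx / 2.0
    phi = np.linspace(0.0, np.pi, 400)
    # arc dips slightly (rad/2) into the wall so the tube roots at both ends
    arc = np.stack([xc + arc_r * np.cos(phi),
                    np.full_like(phi, yc),
                    z_top - rad / 2.0 + arc_r * np.sin(phi)], axis=1)
    ii, jj, kk = np.mgrid[0:nx, 0:ny, 0:nz]
    centres = np.stack([ii.ravel() * dx, jj.ravel() * dx, kk.ravel() * dx], axis=1)
    tube = _tube_mask(centres, arc, rad).reshape(nx, ny, nz)
    bridge = tube & ~mask
    mask |= bridge
    labels[bridge] = LABELS["bridge"]
    epi = np.zeros_like(mask)
    epi[:, :, 0] = True
    g = VoxelGeometry(mask, dx=dx, labels=labels, epi=epi, name="pm1",
                      meta={"Lx": Lx, "Ly": Ly, "wall_thickness": wall_thickness,
                            "bridge_length": bridge_length,
                            "bridge_diameter": bridge_diameter,
                            "arc_radius": arc_r,
                            "junctions": [(xc - arc_r, yc), (xc + arc_r, yc)]})
    g.relabel_junctions()
    g.validate()
    if len(g.junction_clusters()) < 2:
        raise ConstructionError("PM1 bridge failed to connect both junctions")
    return g


def _hemisphere_shell(dx: float, r_out: float, thickness: float):
    """Common scaffold for PM2/PM3: dome z >= 0, centred at origin."""
    r_in = r_out - thickness
    half = _nodes(r_out + dx, dx) - 1
    nxy = 2 * half + 1
    nz = _nodes(r_out + dx, dx)
    ax = (np.arange(nxy) - half) * dx
    az = np.arange(nz) * dx
    X, Y, Z = np.meshgrid(ax, ax, az, indexing="ij")
    r = np.sqrt(X ** 2 + Y ** 2 + Z ** 2)
    shell = (r <= r_out) & (r >= r_in) & (Z >= 0)
    origin = (-half * dx, -half * dx, 0.0)
    return shell, origin, (X, Y, Z, r)


def _pm23_geometry(dx: float, with_ridge: bool, r_out: float = 15.0,
                   thickness: float = 3.0, bridge_length: float = 8.0,
                   bridge_diameter: float = 2.0,
                   post_height: float = 2.0) -> VoxelGeometry:
    """PM2/PM3 scaffold.

    An 8 mm straight chord between two points of the 12 mm-radius endocardial
    sphere dips only c^2/(8 r) ~ 0.67 mm below the surface — less than the
    bridge radius — so a literal chord bridge would lie embedded in the wall.
    The bridge is therefore mounted on two short radial posts (height
    ``post_height``): the free straight span of ``bridge_length`` runs
    between the post tops, clear of the wall (and, in PM3, of the surface
    ridge) everywhere except at the junction feet.
    """
    r_in = r_out - thickness
    rad = bridge_diameter / 2.0
    shell, origin, (X, Y, Z, r) = _hemisphere_shell(dx, r_out, thickness)
    nx, ny, nz = shell.shape
    labels = np.where(shell, LABELS["wall"], 0).astype(np.uint8)
    mask = shell.copy()

    # junction feet: symmetric about the zenith in the xz-plane; the free
    # span between the post tops (radius r_in - post_height) is bridge_length
    r_ax = r_in - post_height
    alpha = np.arcsin(bridge_length / (2.0 * r_ax))
    d1 = np.array([-np.sin(alpha), 0.0, np.cos(alpha)])
    d2 = np.array([+np.sin(alpha), 0.0, np.cos(alpha)])
    top1, top2 = r_ax * d1, r_ax * d2
    centres = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    pieces = [np.linspace(top1, top2, 400)]                  # free span
    for d in (d1, d2):                                       # radial posts
        pieces.append(np.linspace(r_ax * d, (r_in + rad) * d, 120))
    seg = np.vstack(pieces)
    tube = _tube_mask(centres, seg, rad).reshape(nx, ny, nz)
    bridge = tube & ~mask & (Z >= 0)
    mask |= bridge
    labels[bridge] = LABELS["bridge"]

    name = "pm2"
    if with_ridge:
        # great-circle arc on the endocardial surface between the junctions
        th = np.linspace(-alpha, alpha, 400)
        arc = np.stack([r_in * np.sin(th), np.zeros_like(th),
                        r_in * np.cos(th)], axis=1)
        rtube = _tube_mask(centres, arc, rad).reshape(nx, ny, nz)
        ridge = rtube & ~mask & (Z >= 0)
        mask |= ridge
        labels[ridge] = LABELS["ridge"]
        name = "pm3"

    # epicardium: outermost layer of the convex face
    epi = mask & (r >= r_out - dx)
    g = VoxelGeometry(mask, dx=dx, origin=origin, labels=labels, epi=epi,
                      name=name,
                      meta={"r_out": r_out, "thickness": thickness,
                            "bridge_length": bridge_length,
                            "bridge_diameter": bridge_diameter,
                            "post_height": post_height,
                            "alpha": float(alpha),
                            "junctions": [tuple(r_in * d1), tuple(r_in * d2)],
                            "geodesic_j1j2": float(2.0 * r_in * alpha)})
    g.relabel_junctions()
    g.validate()
    if len(g.junction_clusters()) < 2:
        raise ConstructionError("bridge failed to connect both junctions")
    return g


def build_pm2(dx: float = 0.33, **kw) -> VoxelGeometry:
    """Hemispherical wall with a straight endocardial chord bridge."""
    return _pm23_geometry(dx, with_ridge=False, **kw)


def build_pm3(dx: float = 0.33, **kw) -> VoxelGeometry:
    """PM2 plus an endocardial ridge joining the junctions along the wall."""
    return _pm23_geometry(dx, with_ridge=True, **kw)


BUILDERS = {
    "sheet2d": build_sheet2d,
    "strand1d": build_strand1d,
    "wedge": build_wedge,
    "ridge": build_ridge,
    "pm1": build_pm1,
    "pm2": build_pm2,
    "pm3": build_pm3,
}
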