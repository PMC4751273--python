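"""Synthetic rasterized 2D brain-slice-like geometries.

The simulator does not ingest atlas imagery. Instead this module generates
parametric stand-ins for homogenized coronal and sagittal mouse-brain slices:
a rounded brain outline containing one homogenized gray-matter region and
parametric white-matter regions (bands/ellipses with a fibre axis), plus the
injection-needle rectangle (50 um wide) inserted from the top boundary down to
the needle tip. Simple homogeneous calibration rectangles for analytic
validation are generated here too.

Three quantitative anchors of the emulated coronal slice are hard
requirements and determine every targeted macroscopic number:

* bounding box 8.0 mm x 5.5 mm,
* needle tip at (5.7, 2.8) mm,
* brain boundary 2.46 mm from the tip in the drainage (+x) direction.

Together they force the brain box to span x in [0.16, 8.16] mm (the tip then
sits ~1.5 mm right of the brain midline). The downstream (right) boundary is
drawn as a circular arc whose farthest point from the tip is exactly the
2.46 mm clearance, so that tracer accumulating anywhere along that boundary
never exceeds the clearance distance -- the property that pins the
full-model detection distance at the boundary once the drainage front
arrives, regardless of how wide the accumulated band grows.

All coordinates are physical metres, origin at the lower-left of the grid,
y increasing upward ("top" = brain surface where the needle enters). Cells
are square; cell (i, j) has centre ``origin + (i, j) * dx``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import GeometryError
from .params import CaseSpec, Parameters

__all__ = [
    "EXTERIOR", "GRAY", "WHITE", "NEEDLE",
    "WhiteRegion", "SliceSpec", "GeometryGrid", "RegionFields",
    "coronal_like_spec", "sagittal_like_spec",
    "make_slice", "make_calibration_domain", "region_fields",
]

# region label codes (uint8)
EXTERIOR = 0
GRAY = 1
WHITE = 2
NEEDLE = 3

LABEL_NAMES = {EXTERIOR: "exterior", GRAY: "gray", WHITE: "white", NEEDLE: "needle"}

#: Distance from the needle tip to the downstream brain boundary, m.
CORONAL_BOUNDARY_CLEARANCE = 2.46e-3
#: Radius of the circular arc forming the downstream boundary, m.
CORONAL_CAP_RADIUS = 2.0e-3


@dataclass(frozen=True)
class WhiteRegion:
    """A homogenized white-matter region with a single fibre axis.

    ``shape`` is ``"ellipse"`` (centre + semi-axes) or ``"band"`` (an
    axis-aligned rectangle given by centre + half-sizes). ``fiber_axis``
    must be a unit 2-vector; diffusion is enhanced along it and hindered
    across it, and bulk flow follows it.
    """

    shape: Literal["ellipse", "band"]
    center: tuple[float, float]
    size: tuple[float, float]
    fiber_axis: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.shape not in ("ellipse", "band"):
            raise GeometryError(f"unknown white-region shape {self.shape!r}")
        if min(self.size) <= 0:
            raise GeometryError(f"white-region size must be positive, got {self.size!r}")
        norm = float(np.hypot(*self.fiber_axis))
        if abs(norm - 1.0) > 1e-8:
            raise GeometryError(
                f"fiber_axis must be a unit vector, got {self.fiber_axis!r} (|a|={norm:.6g})")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cx, cy = self.center
        sx, sy = self.size
        if self.shape == "ellipse":
            return ((x - cx) / sx) ** 2 + ((y - cy) / sy) ** 2 <= 1.0
        return (np.abs(x - cx) <= sx) & (np.abs(y - cy) <= sy)


@dataclass(frozen=True)
class SliceSpec:
    """Parametric description of a slice geometry prior to rasterization."""

    kind: Literal["coronal_like", "sagittal_like", "calibration"]
    width: float
    height: float
    dx: float
    needle_tip: tuple[float, float] | None = None
    needle_width: float = 50e-6
    white_regions: tuple[WhiteRegion, ...] = ()
    drainage_direction: tuple[float, float] = (1.0, 0.0)
    x_offset: float = 0.0          # physical x of the brain box's left edge
    corner_radius: float = 0.0
    cap_center: tuple[float, float] | None = None   # downstream arc boundary
    cap_radius: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.dx <= 0:
            raise GeometryError("width, height and dx must all be positive")
        norm = float(np.hypot(*self.drainage_direction))
        if abs(norm - 1.0) > 1e-8:
            raise GeometryError("drainage_direction must be a unit vector")


def _default_coronal_white() -> tuple[WhiteRegion, ...]:
    # A corpus-callosum-like band arcing above the injection site, fibres
    # along x. Placed high enough that the 0.1 % tracer contour of the
    # baseline diffusion case never touches it within the simulated 32 min.
    x0 = 5.7e-3 + CORONAL_BOUNDARY_CLEARANCE - 8.0e-3
    return (WhiteRegion("ellipse", (x0 + 4.0e-3, 4.6e-3), (3.0e-3, 0.2e-3), (1.0, 0.0)),)


def coronal_like_spec(dx: float = 25e-6,
                      white_regions: Sequence[WhiteRegion] | None = None) -> SliceSpec:
    """Default coronal-like slice: 8.0 x 5.5 mm, tip (5.7, 2.8) mm, drainage +x."""
    tip = (5.7e-3, 2.8e-3)
    width = 8.0e-3
    x_offset = tip[0] + CORONAL_BOUNDARY_CLEARANCE - width
    cap_cx = x_offset + width - CORONAL_CAP_RADIUS
    regions = tuple(white_regions) if white_regions is not None else _default_coronal_white()
    return SliceSpec(
        kind="coronal_like", width=width, height=5.5e-3, dx=dx,
        needle_tip=tip, white_regions=regions,
        drainage_direction=(1.0, 0.0), x_offset=x_offset,
        corner_radius=0.8e-3, cap_center=(cap_cx, tip[1]),
        cap_radius=CORONAL_CAP_RADIUS,
    )


def sagittal_like_spec(dx: float = 25e-6,
                       white_regions: Sequence[WhiteRegion] | None = None) -> SliceSpec:
    """Default sagittal-like slice: 13.7 x 5.5 mm, tip (6.1, 3.9) mm, drainage +y."""
    if white_regions is None:
        white_regions = (
            WhiteRegion("ellipse", (6.85e-3, 1.2e-3), (5.0e-3, 0.25e-3), (1.0, 0.0)),
        )
    return SliceSpec(
        kind="sagittal_like", width=13.7e-3, height=5.5e-3, dx=dx,
        needle_tip=(6.1e-3, 3.9e-3), white_regions=tuple(white_regions),
        drainage_direction=(0.0, 1.0), corner_radius=1.0e-3,
    )


@dataclass
class GeometryGrid:
    """A rasterized slice: uniform square cells with per-cell region labels.

    Arrays are indexed ``[i, j]`` with ``i`` along x and ``j`` along y.
    ``labels`` holds the codes EXTERIOR/GRAY/WHITE/NEEDLE; ``white_id`` maps
    white cells to an index into ``fiber_axes`` (and is -1 elsewhere).
    ``inflow`` is an index pair (arrays of i and of j) of the needle-tip
    cells where the injection concentration is prescribed.
    """

    dx: float
    nx: int
    ny: int
    origin: tuple[float, float]
    labels: np.ndarray
    white_id: np.ndarray
    fiber_axes: tuple[tuple[float, float], ...]
    needle_tip: tuple[float, float] | None
    inflow: tuple[np.ndarray, np.ndarray]
    drainage_direction: tuple[float, float] = (1.0, 0.0)
    spec: SliceSpec | None = field(default=None, repr=False)

    # -- coordinates -------------------------------------------------------
    @property
    def x_centers(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.nx) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.ny) * self.dx

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (indexing='ij') of physical cell-centre coordinates."""
        return np.meshgrid(self.x_centers, self.y_centers, indexing="ij")

    # -- masks -------------------------------------------------------------
    @property
    def gray_mask(self) -> np.ndarray:
        return self.labels == GRAY

    @property
    def white_mask(self) -> np.ndarray:
        return self.labels == WHITE

    @property
    def needle_mask(self) -> np.ndarray:
        return self.labels == NEEDLE

    @property
    def exterior_mask(self) -> np.ndarray:
        return self.labels == EXTERIOR

    @property
    def interior_mask(self) -> np.ndarray:
        """Brain tissue: gray or white (never needle or exterior)."""
        return (self.labels == GRAY) | (self.labels == WHITE)

    @property
    def inflow_mask(self) -> np.ndarray:
        m = np.zeros((self.nx, self.ny), dtype=bool)
        m[self.inflow] = True
        return m

    def region_areas(self) -> dict[str, float]:
        """Physical area per region label, m^2."""
        cell = self.dx**2
        return {name: float(np.count_nonzero(self.labels == code)) * cell
                for code, name in LABEL_NAMES.items()}

    def checksum(self) -> str:
        """Stable content hash of the rasterization (provenance tag)."""
        h = hashlib.sha256()
        h.update(np.asarray([self.dx, self.nx, self.ny, *self.origin]).tobytes())
        h.update(self.labels.tobytes())
        h.update(self.white_id.tobytes())
        return h.hexdigest()[:16]


def _rounded_box_mask(x: np.ndarray, y: np.ndarray, x0: float, y0: float,
                      x1: float, y1: float, r: float) -> np.ndarray:
    inside = (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
    if r <= 0:
        return inside
    for cx, cy in ((x0 + r, y0 + r), (x0 + r, y1 - r), (x1 - r, y0 + r), (x1 - r, y1 - r)):
        # beyond the corner-arc centre in both directions and outside the arc
        qx = (x - cx) * (1 if cx > (x0 + x1) / 2 else -1) > 0
        qy = (y - cy) * (1 if cy > (y0 + y1) / 2 else -1) > 0
        inside &= ~(qx & qy & ((x - cx) ** 2 + (y - cy) ** 2 > r**2))
    return inside


def _brain_mask(spec: SliceSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    x0, x1 = spec.x_offset, spec.x_offset + spec.width
    inside = _rounded_box_mask(x, y, x0, 0.0, x1, spec.height, spec.corner_radius)
    if spec.cap_center is not None and spec.cap_radius > 0:
        cx, cy = spec.cap_center
        beyond = x > cx
        inside &= ~beyond | ((x - cx) ** 2 + (y - cy) ** 2 <= spec.cap_radius**2)
    return inside


def make_slice(spec: SliceSpec) -> GeometryGrid:
    """Rasterize a :class:`SliceSpec` onto a uniform Cartesian grid.

    The grid covers exactly the brain bounding box (``width x height``); the
    brain outline, white regions and needle are labelled per cell centre,
    giving stair-step boundaries that converge with resolution.
    """
    dx = spec.dx
    nx = round(spec.width / dx)
    ny = round(spec.height / dx)
    if nx < 2 or ny < 2:
        raise GeometryError(f"dx={dx!r} too coarse for a {spec.width} x {spec.height} domain")
    if abs(nx * dx - spec.width) > 0.5 * dx or abs(ny * dx - spec.height) > 0.5 * dx:
        raise GeometryError(
            f"dx={dx!r} does not divide the domain within one cell "
            f"({spec.width} x {spec.height})")

    origin = (spec.x_offset + dx / 2, dx / 2)
    x = origin[0] + np.arange(nx) * dx
    y = origin[1] + np.arange(ny) * dx
    X, Y = np.meshgrid(x, y, indexing="ij")

    labels = np.zeros((nx, ny), dtype=np.uint8)
    labels[_brain_mask(spec, X, Y)] = GRAY

    white_id = np.full((nx, ny), -1, dtype=np.int16)
    fiber_axes: list[tuple[float, float]] = []
    for rid, region in enumerate(spec.white_regions):
        m = region.contains(X, Y) & (labels == GRAY)
        labels[m] = WHITE
        white_id[m] = rid
        fiber_axes.append(tuple(region.fiber_axis))

    inflow: tuple[np.ndarray, np.ndarray] = (np.array([], dtype=np.intp),) * 2
    if spec.needle_tip is not None:
        tip_x, tip_y = spec.needle_tip
        if not (x[0] - dx / 2 <= tip_x <= x[-1] + dx / 2 and
                y[0] - dx / 2 <= tip_y <= y[-1] + dx / 2):
            raise GeometryError(f"needle tip {spec.needle_tip!r} lies outside the domain")
        if dx > spec.needle_width + 1e-12:
            raise GeometryError(
                f"dx={dx!r} too coarse: needle width {spec.needle_width!r} < 1 cell")
        cols = np.abs(x - tip_x) <= spec.needle_width / 2 + 1e-12
        rows = y >= tip_y - 1e-12
        needle = np.outer(cols, rows) & (labels != EXTERIOR)
        if not needle.any():
            raise GeometryError("needle rasterized to zero cells")
        labels[needle] = NEEDLE
        white_id[needle] = -1
        ii, jj = np.nonzero(needle)
        j_tip = jj.min()
        sel = jj == j_tip
        inflow = (ii[sel], jj[sel])
        # each inflow cell must sit on gray tissue
        below = j_tip - 1
        if below < 0 or not np.all(labels[inflow[0], below] == GRAY):
            raise GeometryError("needle tip is not embedded in gray matter")
        tip_dist = np.hypot(x[inflow[0]] - tip_x, y[inflow[1]] - tip_y)
        if tip_dist.min() > dx * 0.75:
            raise GeometryError("no inflow cell within half a cell of the needle tip")

    return GeometryGrid(
        dx=dx, nx=nx, ny=ny, origin=origin, labels=labels, white_id=white_id,
        fiber_axes=tuple(fiber_axes), needle_tip=spec.needle_tip, inflow=inflow,
        drainage_direction=tuple(spec.drainage_direction), spec=spec,
    )


def make_calibration_domain(width: float, height: float, dx: float,
                            source: Literal["point", "none"] = "none") -> GeometryGrid:
    """Homogeneous all-gray rectangle for analytic validation.

    With ``source="point"`` the central cell is marked as the (sole) inflow
    cell, giving a point-like Dirichlet source; with ``"none"`` there is no
    prescribed cell and initial conditions supply any mass. ``needle_tip``
    is set to the domain centre in both variants so that detection distances
    are measured from the source location.
    """
    if width <= 0 or height <= 0 or dx <= 0:
        raise GeometryError("width, height and dx must all be positive")
    nx, ny = round(width / dx), round(height / dx)
    if nx < 2 or ny < 2:
        raise GeometryError("calibration domain must be at least 2 x 2 cells")
    labels = np.full((nx, ny), GRAY, dtype=np.uint8)
    center = (nx // 2, ny // 2)
    if source == "point":
        inflow = (np.array([center[0]], dtype=np.intp), np.array([center[1]], dtype=np.intp))
    elif source == "none":
        inflow = (np.array([], dtype=np.intp), np.array([], dtype=np.intp))
    else:
        raise GeometryError(f"unknown source mode {source!r}")
    origin = (dx / 2, dx / 2)
    tip = (origin[0] + center[0] * dx, origin[1] + center[1] * dx)
    return GeometryGrid(
        dx=dx, nx=nx, ny=ny, origin=origin, labels=labels,
        white_id=np.full((nx, ny), -1, dtype=np.int16), fiber_axes=(),
        needle_tip=tip, inflow=inflow, drainage_direction=(1.0, 0.0),
        spec=SliceSpec(kind="calibration", width=width, height=height, dx=dx),
    )


@dataclass
class RegionFields:
    """Per-cell transport coefficients derived from a grid, parameters, case.

    ``Dxx, Dyy, Dxy`` form the symmetric effective diffusion tensor (m^2/s)
    of the ECS field; ``ux, uy`` the ECS bulk-flow velocity (m/s). Gray cells
    carry the isotropic effective coefficient and zero velocity; white cells
    carry the anisotropic tensor ``D_free / lambda^2`` (rotated to the fibre
    axis) and bulk flow along the fibre; needle and exterior cells carry
    zeros.
    """

    Dxx: np.ndarray
    Dyy: np.ndarray
    Dxy: np.ndarray
    ux: np.ndarray
    uy: np.ndarray

    @property
    def max_eigenvalue(self) -> float:
        half_tr = 0.5 * (self.Dxx + self.Dyy)
        disc = np.sqrt((0.5 * (self.Dxx - self.Dyy)) ** 2 + self.Dxy**2)
        return float((half_tr + disc).max(initial=0.0))

    @property
    def max_speed_l1(self) -> float:
        """Max over cells of |ux| + |uy| (the 2D upwind CFL speed)."""
        return float((np.abs(self.ux) + np.abs(self.uy)).max(initial=0.0))


def region_fields(grid: GeometryGrid, params: Parameters, case: CaseSpec) -> RegionFields:
    """Build the per-cell diffusion tensor and ECS velocity for a case."""
    shape = (grid.nx, grid.ny)
    Dxx = np.zeros(shape)
    Dyy = np.zeros(shape)
    Dxy = np.zeros(shape)
    ux = np.zeros(shape)
    uy = np.zeros(shape)

    D_gray = case.diffusion_multiplier * params.D_star
    gray = grid.gray_mask
    Dxx[gray] = D_gray
    Dyy[gray] = D_gray

    D_free = case.diffusion_multiplier * params.D_free
    D_par = D_free / params.lambda_white_par**2
    D_perp = D_free / params.lambda_white_perp**2
    speed = case.bulkflow_multiplier * params.u_white
    for rid, axis in enumerate(grid.fiber_axes):
        ax, ay = axis
        norm = float(np.hypot(ax, ay))
        if abs(norm - 1.0) > 1e-8:
            raise GeometryError(f"fiber axis {axis!r} of white region {rid} is not unit length")
        m = grid.white_id == rid
        Dxx[m] = D_par * ax**2 + D_perp * ay**2
        Dyy[m] = D_par * ay**2 + D_perp * ax**2
        Dxy[m] = (D_par - D_perp) * ax * ay
        ux[m] = speed * ax
        uy[m] = speed * ay

    return RegionFields(Dxx=Dxx, Dyy=Dyy, Dxy=Dxy, ux=ux, uy=uy)
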