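"""Aperture geometry for on-line margin application.

Transforms a planned MLC segment into a machine-deliverable prescription:
the beam's-eye-view (BEV) polygon is shifted to the current target position,
rasterized on an isotropic grid, expanded by per-side/per-axis margins using
separable morphologic dilation, re-contoured, and finally fitted to the leaf
bank by sub-leaf averaging. Jaws (diaphragms) follow the polygon's extent
perpendicular to leaf travel plus the corresponding margins.

Conventions
-----------
Coordinates are isocenter-centered millimetres in BEV. ``x`` is the
leaf-travel axis, ``y`` the perpendicular (jaw) axis. Raster grids use
half-open cell intervals with cell-center sampling; ``occupancy[iy, ix]``
maps to position ``origin + (ix, iy) * resolution``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely.geometry import Polygon as _ShapelyPolygon

logger = logging.getLogger(__name__)

#: Isotropic raster resolution of the margin generator, mm.
DEFAULT_RESOLUTION = 0.25
#: Largest admissible margin per side, mm. Margins are clamped into
#: [0, MAX_MARGIN]; the generator only ever expands apertures.
MAX_MARGIN = 20.0


class GeometryError(ValueError):
    """Invalid geometric input."""


class ApertureVanishedError(GeometryError):
    """The aperture raster is empty; no deliverable segment exists."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def _signed_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class AperturePolygon:
    """Closed, simple BEV polygon (mm), normalized to counter-clockwise."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise GeometryError("polygon needs >= 3 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise GeometryError("polygon vertices must be finite")
        # drop an explicitly repeated closing vertex
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 3:
            raise GeometryError("polygon needs >= 3 distinct vertices")
        if _signed_area(v) < 0.0:
            v = v[::-1].copy()
        if abs(_signed_area(v)) > 0.0:
            if not _ShapelyPolygon(v).is_valid:
                raise GeometryError("polygon must be simple (non-self-intersecting)")
        else:
            # zero signed area: admit only truly degenerate (collinear) rings
            rel = v - v.mean(axis=0)
            if np.linalg.matrix_rank(rel, tol=1e-9 * max(1.0, np.abs(rel).max())) > 1:
                raise GeometryError("zero-area polygon must be collinear")
        object.__setattr__(self, "vertices", v)

    @property
    def area(self) -> float:
        return abs(_signed_area(self.vertices))

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in mm."""
        v = self.vertices
        return (v[:, 0].min(), v[:, 1].min(), v[:, 0].max(), v[:, 1].max())

    @property
    def centroid(self) -> tuple[float, float]:
        c = _ShapelyPolygon(self.vertices).centroid
        if c.is_empty:  # degenerate (zero area): fall back to vertex mean
            m = self.vertices.mean(axis=0)
            return float(m[0]), float(m[1])
        return float(c.x), float(c.y)

    def to_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)


def circle_aperture(diameter_mm: float, n_vertices: int = 256,
                    center: tuple[float, float] = (0.0, 0.0)) -> AperturePolygon:
    """Regular-polygon approximation of a circular aperture.

    Vertices are placed on the circle, so the polygon area is slightly below
    pi r^2 (relative deficit ~ (2 pi^2 / 3) / n^2, < 0.01% for n = 256).
    """
    if diameter_mm <= 0:
        raise GeometryError("diameter must be positive")
    ang = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r = diameter_mm / 2.0
    v = np.column_stack([center[0] + r * np.cos(ang), center[1] + r * np.sin(ang)])
    return AperturePolygon(v)


@dataclass(frozen=True)
class MarginSpec:
    """Per-side, per-axis tracking margins in mm.

    ``+``/``-`` refer to the side of the isocenter on which the margin is
    added along each axis.
    """

    x_plus: float = 0.0
    x_minus: float = 0.0
    y_plus: float = 0.0
    y_minus: float = 0.0

    def __post_init__(self) -> None:
        for name in ("x_plus", "x_minus", "y_plus", "y_minus"):
            val = getattr(self, name)
            if not np.isfinite(val):
                raise GeometryError(f"margin {name} must be finite")
            if val < 0.0 or val > MAX_MARGIN:
                raise GeometryError(
                    f"margin {name}={val} outside [0, {MAX_MARGIN}] mm; "
                    "use MarginSpec.clamped() to construct from raw values")

    @classmethod
    def clamped(cls, x_plus: float, x_minus: float, y_plus: float,
                y_minus: float, max_margin: float = MAX_MARGIN) -> "MarginSpec":
        """Clamp raw per-side values into [0, max_margin] (logged)."""
        out = []
        for name, val in (("x_plus", x_plus), ("x_minus", x_minus),
                          ("y_plus", y_plus), ("y_minus", y_minus)):
            c = min(max(float(val), 0.0), max_margin)
            if c != val:
                logger.warning("margin %s=%.3f mm clamped to %.3f mm", name, val, c)
            out.append(c)
        return cls(*out)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_plus, self.x_minus, self.y_plus, self.y_minus)


@dataclass
class RasterMask:
    """Binary occupancy grid at isotropic resolution.

    ``origin`` is the (x, y) position in mm of the center of cell
    ``occupancy[0, 0]``.
    """

    resolution: float
    origin: tuple[float, float]
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise GeometryError("resolution must be positive")
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 2:
            raise GeometryError("occupancy must be 2-D")

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    @property
    def area(self) -> float:
        """Occupied area in mm^2 (cell counting)."""
        return self.n_occupied * self.resolution ** 2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.occupancy.shape
        xs = self.origin[0] + np.arange(nx) * self.resolution
        ys = self.origin[1] + np.arange(ny) * self.resolution
        return xs, ys


@dataclass(frozen=True)
class BankGeometry:
    """Static description of the leaf bank: pair count, leaf width, origin.

    Leaf pair ``k`` covers ``y in [y0 + k*w, y0 + (k+1)*w)``. The default
    origin centers the bank on the isocenter.
    """

    n_pairs: int = 28
    leaf_width: float = 5.0
    y0: float | None = None

    def __post_init__(self) -> None:
        if self.n_pairs < 1 or self.leaf_width <= 0:
            raise GeometryError("invalid bank geometry")
        if self.y0 is None:
            object.__setattr__(self, "y0", -self.n_pairs * self.leaf_width / 2.0)

    def pair_edges(self, k: int) -> tuple[float, float]:
        lo = self.y0 + k * self.leaf_width
        return lo, lo + self.leaf_width


@dataclass
class LeafBank:
    """Deliverable prescription: per-pair leaf positions plus jaw positions.

    ``left[k] <= right[k]`` along the leaf-travel axis; a closed pair has
    ``left == right``. Leaf rows tile the y axis contiguously per
    ``geometry`` (a :class:`BankGeometry`).
    """

    geometry: BankGeometry
    left: np.ndarray
    right: np.ndarray
    jaw_y_minus: float
    jaw_y_plus: float

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != (self.geometry.n_pairs,) or \
                self.right.shape != (self.geometry.n_pairs,):
            raise GeometryError("leaf arrays must match n_pairs")
        if np.any(self.left > self.right + 1e-9):
            raise GeometryError("left leaf beyond right leaf")
        if self.jaw_y_minus > self.jaw_y_plus:
            raise GeometryError("jaws crossed")

    def translated(self, dx: float, dy: float) -> "LeafBank":
        """Rigid translation of the whole prescription (machine COG motion)."""
        geo = replace(self.geometry, y0=self.geometry.y0 + dy)
        return LeafBank(geo, self.left + dx, self.right + dx,
                        self.jaw_y_minus + dy, self.jaw_y_plus + dy)

    def cog(self) -> tuple[float, float]:
        """Area center of gravity of the open aperture (jaw-clipped)."""
        w = self.geometry.leaf_width
        ax = ay = area = 0.0
        for k in range(self.geometry.n_pairs):
            lo, hi = self.geometry.pair_edges(k)
            lo, hi = max(lo, self.jaw_y_minus), min(hi, self.jaw_y_plus)
            if hi <= lo:
                continue
            opening = self.right[k] - self.left[k]
            if opening <= 0:
                continue
            a = opening * (hi - lo)
            area += a
            ax += a * 0.5 * (self.left[k] + self.right[k])
            ay += a * 0.5 * (lo + hi)
        if area == 0.0:
            return 0.0, 0.0
        return ax / area, ay / area


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def shift_aperture(poly: AperturePolygon,
                   displacement: tuple[float, float]) -> AperturePolygon:
    """Translate the planned aperture to a new target position (isometry)."""
    d = np.asarray(displacement, dtype=float)
    if d.shape != (2,) or not np.all(np.isfinite(d)):
        raise GeometryError("displacement must be a finite (dx, dy)")
    return AperturePolygon(poly.vertices + d[None, :])


def build_dilation_kernel(margins_axis: tuple[float, float],
                          resolution: float = DEFAULT_RESOLUTION,
                          max_margin: float = MAX_MARGIN,
                          ) -> tuple[int, int, int]:
    """Structuring-element extents for one axis.

    ``margins_axis`` is ``(m_minus, m_plus)`` in mm. Returns
    ``(n_minus, n_center, n_plus)`` with ``n_center = 1`` and the side counts
    obtained by half-up rounding of ``m / resolution``; e.g. margins
    (4 mm, 2 mm) at 0.25 mm give (16, 1, 8), 25 elements in total.
    """
    if resolution <= 0:
        raise GeometryError("resolution must be positive")
    m_minus, m_plus = margins_axis
    if m_minus < 0 or m_plus < 0:
        raise GeometryError("margins must be >= 0")
    capped = []
    for m in (m_minus, m_plus):
        if m > max_margin:
            logger.warning("margin %.3f mm exceeds max %.3f mm; capped", m, max_margin)
            m = max_margin
        capped.append(m)
    # half-up rounding (not banker's): floor(m/res + 0.5)
    n_minus = int(np.floor(capped[0] / resolution + 0.5))
    n_plus = int(np.floor(capped[1] / resolution + 0.5))
    return n_minus, 1, n_plus


def rasterize(poly: AperturePolygon,
              resolution: float = DEFAULT_RESOLUTION,
              pad: float = MAX_MARGIN) -> RasterMask:
    """Rasterize the polygon: a cell is occupied iff its center lies inside.

    The grid is aligned so cell edges coincide with the polygon's bounding
    box and padded by ``pad`` on every side so that any admissible dilation
    stays on the grid.
    """
    if resolution <= 0:
        raise GeometryError("resolution must be positive")
    xmin, ymin, xmax, ymax = poly.bounds
    if poly.area == 0.0:
        logger.warning("zero-area polygon rasterizes to an empty mask")
    n_pad = int(np.ceil(pad / resolution))
    nx = 2 * n_pad + max(1, int(np.ceil((xmax - xmin) / resolution - 1e-9)))
    ny = 2 * n_pad + max(1, int(np.ceil((ymax - ymin) / resolution - 1e-9)))
    x0 = xmin + resolution / 2.0 - n_pad * resolution
    y0 = ymin + resolution / 2.0 - n_pad * resolution
    xs = x0 + np.arange(nx) * resolution
    ys = y0 + np.arange(ny) * resolution
    xx, yy = np.meshgrid(xs, ys)
    if poly.area == 0.0:
        occ = np.zeros((ny, nx), dtype=bool)
    else:
        geom = poly.to_shapely()
        shapely.prepare(geom)
        occ = shapely.contains_xy(geom, xx.ravel(), yy.ravel()).reshape(ny, nx)
    return RasterMask(resolution, (float(x0), float(y0)), occ)


def _dilate_1d(occ: np.ndarray, n_minus: int, n_plus: int, axis: int) -> np.ndarray:
    """out[j] = OR of in[j - n_plus .. j + n_minus] along `axis`."""
    if n_minus == 0 and n_plus == 0:
        return occ
    out = occ.copy()
    for shift in range(1, n_plus + 1):        # expand toward +axis
        sl_src = [slice(None)] * occ.ndim
        sl_dst = [slice(None)] * occ.ndim
        sl_src[axis] = slice(0, occ.shape[axis] - shift)
        sl_dst[axis] = slice(shift, None)
        out[tuple(sl_dst)] |= occ[tuple(sl_src)]
    for shift in range(1, n_minus + 1):       # expand toward -axis
        sl_src = [slice(None)] * occ.ndim
        sl_dst = [slice(None)] * occ.ndim
        sl_src[axis] = slice(shift, None)
        sl_dst[axis] = slice(0, occ.shape[axis] - shift)
        out[tuple(sl_dst)] |= occ[tuple(sl_src)]
    return out


def dilate(mask: RasterMask, margins: MarginSpec,
           max_margin: float = MAX_MARGIN) -> RasterMask:
    """Minkowski dilation by the separable asymmetric margin kernel.

    Applies the 1-D structuring elements from :func:`build_dilation_kernel`
    along x and y. The result is a superset of the input and monotone in
    every margin component. If the dilation would escape the padded grid the
    grid is extended (logged).
    """
    res = mask.resolution
    nxm, _, nxp = build_dilation_kernel((margins.x_minus, margins.x_plus), res, max_margin)
    nym, _, nyp = build_dilation_kernel((margins.y_minus, margins.y_plus), res, max_margin)

    occ = mask.occupancy
    origin = mask.origin
    # check head-room against the occupied bounding box
    rows, cols = np.nonzero(occ)
    if rows.size:
        pad_left = max(0, nxm - cols.min())
        pad_right = max(0, nxp - (occ.shape[1] - 1 - cols.max()))
        pad_bot = max(0, nym - rows.min())
        pad_top = max(0, nyp - (occ.shape[0] - 1 - rows.max()))
        if pad_left or pad_right or pad_bot or pad_top:
            logger.warning("dilation escapes grid; extending by (%d,%d,%d,%d) cells",
                           pad_left, pad_right, pad_bot, pad_top)
            occ = np.pad(occ, ((pad_bot, pad_top), (pad_left, pad_right)))
            origin = (origin[0] - pad_left * res, origin[1] - pad_bot * res)
    out = _dilate_1d(occ, nxm, nxp, axis=1)
    out = _dilate_1d(out, nym, nyp, axis=0)
    return RasterMask(res, origin, out)


def _trace_boundary(occ: np.ndarray) -> list[np.ndarray]:
    """Trace closed cell-edge loops around occupied cells, interior on the left.

    Vertices are cell-corner indices (row, col) on the corner grid; corner
    (i, j) is the lower-left corner of cell (i, j). Returns all loops (outer
    boundaries CCW, hole boundaries CW).
    """
    ny, nx = occ.shape
    padded = np.zeros((ny + 2, nx + 2), dtype=bool)
    padded[1:-1, 1:-1] = occ
    # directed boundary edges, keyed by start corner
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def add(a, b):
        edges.setdefault(a, []).append(b)

    rs, cs = np.nonzero(occ)
    for r, c in zip(rs.tolist(), cs.tolist()):
        if not padded[r, c + 1]:        # south neighbor empty
            add((r, c), (r, c + 1))
        if not padded[r + 1, c + 2]:    # east
            add((r, c + 1), (r + 1, c + 1))
        if not padded[r + 2, c + 1]:    # north
            add((r + 1, c + 1), (r + 1, c))
        if not padded[r + 1, c]:        # west
            add((r + 1, c), (r, c))

    loops: list[np.ndarray] = []
    while edges:
        start = next(iter(edges))
        loop = [start]
        prev_dir = None
        cur = start
        while True:
            cands = edges[cur]
            if len(cands) == 1 or prev_dir is None:
                nxt = cands.pop(0)
            else:
                # pinch corner: prefer the sharpest left turn to keep each
                # loop simple (keeps interior on the left)
                def turn_key(b):
                    d = (b[0] - cur[0], b[1] - cur[1])
                    cross = prev_dir[0] * d[1] - prev_dir[1] * d[0]
                    dot = prev_dir[0] * d[0] + prev_dir[1] * d[1]
                    return np.arctan2(cross, dot)
                cands.sort(key=turn_key)
                nxt = cands.pop(0)
            if not edges[cur]:
                del edges[cur]
            prev_dir = (nxt[0] - cur[0], nxt[1] - cur[1])
            cur = nxt
            if cur == start:
                break
            loop.append(cur)
        loops.append(np.array(loop, dtype=float))
    return loops


def _simplify_collinear(vertices: np.ndarray) -> np.ndarray:
    """Drop vertices lying on the segment between their neighbors."""
    n = len(vertices)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        a = vertices[i - 1]
        b = vertices[i]
        c = vertices[(i + 1) % n]
        cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(cross) < 1e-12:
            keep[i] = False
    return vertices[keep]


def mask_to_polygon(mask: RasterMask) -> AperturePolygon:
    """Outline of the occupied cells as a polygon (holes discarded).

    Takes the largest 4-connected component if several exist (logged). The
    polygon runs along cell edges, so re-rasterizing it reproduces the mask
    exactly away from pinch corners.
    """
    from scipy import ndimage

    occ = mask.occupancy
    if not occ.any():
        raise ApertureVanishedError("aperture raster is empty")
    labels, n_comp = ndimage.label(occ, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    if n_comp > 1:
        logger.warning("aperture raster has %d components; keeping largest", n_comp)
        sizes = ndimage.sum_labels(occ, labels, index=np.arange(1, n_comp + 1))
        occ = labels == (1 + int(np.argmax(sizes)))
    loops = _trace_boundary(occ)
    # outer boundaries are CCW (positive signed area); keep the largest
    best, best_area = None, 0.0
    for loop in loops:
        a = _signed_area(loop[:, ::-1])  # loops store (row, col) = (y, x)
        if a > best_area:
            best, best_area = loop, a
    if best is None:
        raise ApertureVanishedError("no outer boundary found")
    if len(loops) > 1:
        logger.debug("discarding %d inner/secondary boundary loops", len(loops) - 1)
    best = _simplify_collinear(best)
    res = mask.resolution
    # corner (i, j) -> mm: lower-left corner of cell (i, j)
    x = mask.origin[0] - res / 2.0 + best[:, 1] * res
    y = mask.origin[1] - res / 2.0 + best[:, 0] * res
    return AperturePolygon(np.column_stack([x, y]))


def polygon_row_extents(vertices: np.ndarray, ys: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Min/max x of a polygon's intersection with horizontal lines at ``ys``.

    Vectorized even-odd scanline. Rows that miss the polygon get NaN. Rows
    crossing the polygon more than twice take the global extents (the convex
    cover of the row).
    """
    v = np.asarray(vertices, dtype=float)
    x1, y1 = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    keep = y1 != y2
    x1, y1, x2, y2 = x1[keep], y1[keep], x2[keep], y2[keep]
    ys = np.asarray(ys, dtype=float)
    # half-open rule: edge spans [min(y1,y2), max(y1,y2))
    ylo, yhi = np.minimum(y1, y2), np.maximum(y1, y2)
    hits = (ys[:, None] >= ylo[None, :]) & (ys[:, None] < yhi[None, :])
    t = (ys[:, None] - y1[None, :]) / (y2 - y1)[None, :]
    xc = x1[None, :] + t * (x2 - x1)[None, :]
    lo = np.where(hits, xc, np.inf).min(axis=1)
    hi = np.where(hits, xc, -np.inf).max(axis=1)
    n_hits = hits.sum(axis=1)
    if np.any(n_hits > 2):
        logger.debug("rows with >2 polygon crossings: global extents taken")
    lo[n_hits == 0] = np.nan
    hi[n_hits == 0] = np.nan
    return lo, hi


def fit_leaves(poly: AperturePolygon, bank: BankGeometry,
               n_subleaves: int = 10) -> LeafBank:
    """Fit the polygon to the leaf bank by sub-leaf averaging.

    Each leaf width is subdivided into ``n_subleaves`` rows; every row whose
    center line intersects the polygon contributes the min/max x of the
    intersection, and the pair's left/right positions are the means over
    contributing rows. Pairs without intersection are parked closed at the
    aperture centroid's x. Jaws are initialized at the polygon's y extrema
    (apply :func:`set_jaws` for margins).
    """
    if n_subleaves < 1:
        raise GeometryError("n_subleaves must be >= 1")
    w = bank.leaf_width
    sub = (np.arange(n_subleaves) + 0.5) * w / n_subleaves
    left = np.empty(bank.n_pairs)
    right = np.empty(bank.n_pairs)
    cx, _ = poly.centroid
    any_open = False
    for k in range(bank.n_pairs):
        lo, _hi = bank.pair_edges(k)
        ys = lo + sub
        xlo, xhi = polygon_row_extents(poly.vertices, ys)
        good = ~np.isnan(xlo)
        if good.any():
            left[k] = xlo[good].mean()
            right[k] = xhi[good].mean()
            any_open = True
        else:
            left[k] = right[k] = cx
    if not any_open:
        logger.warning("polygon entirely outside leaf bank; all pairs closed")
    _, ymin, _, ymax = (poly.bounds[0], poly.bounds[1], poly.bounds[2], poly.bounds[3])
    return LeafBank(bank, left, right, jaw_y_minus=ymin, jaw_y_plus=ymax)


def set_jaws(bank: LeafBank, margins: MarginSpec,
             poly: AperturePolygon) -> LeafBank:
    """Set jaws to the polygon's y extrema offset by the y margins."""
    _, ymin, _, ymax = poly.bounds
    jp = ymax + margins.y_plus
    jm = ymin - margins.y_minus
    if jm > jp:
        raise GeometryError("jaw positions crossed")
    return LeafBank(bank.geometry, bank.left.copy(), bank.right.copy(),
                    jaw_y_minus=jm, jaw_y_plus=jp)
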