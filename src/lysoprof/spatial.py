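"""Radial quantification of organelle position along the perinuclear-
peripheral axis of a cell.

Given a fluorescence image, a manually traced convex cell boundary and a
nucleus boundary, the cytosol is segmented into R concentric shells: for a
pixel at parameter t along the ray from the nucleus centroid through the
pixel, with the ray crossing the nuclear boundary at t_n and exiting the
cell boundary at t_c, its fractional radial position is

    f = (t - t_n) / (t_c - t_n),   clamped to [0, 1),

and its shell is floor(f * R). Pixels before the nuclear crossing are
nucleus (-1), pixels past the cell exit are outside (-2). The assignment
is exact per pixel (a continuum of rays, not a discrete ray fan).

Two summaries are computed per cell: the mean intensity per shell divided
by the mean over all cytosolic pixels (robust to expression-level
differences between cells), and the cumulative intensity fraction from the
innermost shell outward. Shell means of two cell populations are compared
per shell with an unpaired two-tailed Student's t-test.

Coordinates are 0-based pixel centers, x rightward, y downward; polygons
live in the same frame. The cell polygon must be convex (unique ray exit);
the nucleus needs only to be simple and strictly inside the cell.

All ray geometry is computed from cross and dot products only (no trig),
which makes the shell labels exactly invariant under 90-degree rotations
of the pixel grid.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Polygon as _ShPolygon

OUTSIDE = -2
NUCLEUS = -1


def _as_vertices(polygon) -> np.ndarray:
    """(N, 2) float vertex array; a repeated closing vertex is dropped."""
    v = np.asarray(polygon, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValueError("polygon must be an (N, 2) array of vertices")
    if len(v) >= 2 and np.array_equal(v[0], v[-1]):
        v = v[:-1]
    return v


def check_convex(polygon) -> bool:
    """True iff all nonzero cross-products of consecutive edges share one
    sign (collinear runs tolerated). Fewer than 3 vertices is an error."""
    v = _as_vertices(polygon)
    if len(v) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    e = np.roll(v, -1, axis=0) - v
    cross = e[:, 0] * np.roll(e[:, 1], -1) - e[:, 1] * np.roll(e[:, 0], -1)
    return bool((cross >= 0).all() or (cross <= 0).all())


def polygon_centroid(polygon) -> tuple[float, float]:
    """Area centroid via the shoelace-weighted formula."""
    v = _as_vertices(polygon)
    if len(v) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    w = x * yn - xn * y
    area2 = w.sum()
    if area2 == 0:
        raise ValueError("polygon has zero area")
    cx = ((x + xn) * w).sum() / (3.0 * area2)
    cy = ((y + yn) * w).sum() / (3.0 * area2)
    return float(cx), float(cy)


def _point_in_polygon(v: np.ndarray, px: float, py: float) -> bool:
    """Even-odd crossing test (boundary points count as inside)."""
    inside = False
    n = len(v)
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            xi = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px <= xi:
                inside = not inside
    return inside


def _ray_ts(v: np.ndarray, ox: float, oy: float, dx, dy):
    """Parameters t > 0 where the ray origin + t*(dx, dy) crosses polygon
    edges. Vectorized over pixel direction arrays; edges use the half-open
    convention s in [0, 1) so a crossing at a shared vertex counts once.

    Returns the minimum positive t per direction (inf where no crossing).
    Implemented with cross products only, so 90-degree grid rotations
    produce bit-identical results.
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    tmin = np.full(dx.shape, np.inf)
    n = len(v)
    for i in range(n):
        ax, ay = v[i]
        bx, by = v[(i + 1) % n]
        ex, ey = bx - ax, by - ay
        wx, wy = ax - ox, ay - oy  # origin -> edge start (scalar per edge)
        denom = dx * ey - dy * ex  # cross(d, e)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (wx * ey - wy * ex) / denom  # cross(w, e) / cross(d, e)
            s = (wx * dy - wy * dx) / denom  # cross(w, d) / cross(d, e)
        hit = (denom != 0) & (t > 0) & (s >= 0) & (s < 1)
        tmin = np.where(hit & (t < tmin), t, tmin)
    return tmin


def ray_boundary_distance(polygon, origin, angle: float) -> float:
    """Euclidean distance from an interior origin to the nearest boundary
    crossing along direction (cos angle, sin angle)."""
    v = _as_vertices(polygon)
    ox, oy = float(origin[0]), float(origin[1])
    if not _point_in_polygon(v, ox, oy):
        raise ValueError(f"origin {origin} lies outside the polygon")
    t = _ray_ts(v, ox, oy, np.array(math.cos(angle)), np.array(math.sin(angle)))
    t = float(t)
    if math.isinf(t):  # pragma: no cover - grazing a vertex numerically
        raise ValueError("ray does not cross the polygon boundary")
    return t


@dataclass
class CellGeometry:
    """Traced cell and nucleus boundary polygons for one cell.

    Invariants (checked by :meth:`validate`): both polygons simple, the
    cell polygon convex, and the nucleus strictly inside the cell.
    """

    cell_polygon: np.ndarray
    nucleus_polygon: np.ndarray
    image_shape: tuple[int, int]  # (height, width)

    def __post_init__(self) -> None:
        self.cell_polygon = _as_vertices(self.cell_polygon)
        self.nucleus_polygon = _as_vertices(self.nucleus_polygon)
        self.validate()

    def validate(self) -> None:
        cell = _ShPolygon(self.cell_polygon)
        nuc = _ShPolygon(self.nucleus_polygon)
        if not cell.is_simple or not nuc.is_simple:
            raise ValueError("polygons must be simple (non-self-intersecting)")
        if not check_convex(self.cell_polygon):
            raise ValueError("cell polygon must be convex")
        import shapely

        if not shapely.contains_properly(cell, nuc):
            raise ValueError("nucleus must lie strictly inside the cell")


@dataclass
class RegionMap:
    """Per-pixel shell labels: -2 outside, -1 nucleus, 0..R-1 shells from
    most perinuclear to most peripheral."""

    labels: np.ndarray  # (H, W) int
    R: int

    def shell_mask(self, r: int) -> np.ndarray:
        return self.labels == r

    @property
    def cytosol_mask(self) -> np.ndarray:
        return self.labels >= 0


def assign_regions(geom: CellGeometry, R: int = 8) -> RegionMap:
    """Label every pixel of the image grid with its radial shell.

    The ray origin is the nucleus area centroid. R defaults to 8 shells.
    Raises if the cell exit does not lie strictly beyond the nuclear
    crossing for some cytosolic pixel (nucleus touching the membrane).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    h, w = geom.image_shape
    ox, oy = polygon_centroid(geom.nucleus_polygon)
    if not _point_in_polygon(geom.nucleus_polygon, ox, oy):
        raise ValueError("nucleus centroid lies outside the nucleus polygon")
    ys, xs = np.mgrid[0:h, 0:w]
    dx = xs - ox
    dy = ys - oy
    at_origin = (dx == 0) & (dy == 0)
    # avoid the degenerate zero direction; the pixel is relabeled below
    dx = np.where(at_origin, 1.0, dx)
    t_n = _ray_ts(geom.nucleus_polygon, ox, oy, dx, dy)
    t_c = _ray_ts(geom.cell_polygon, ox, oy, dx, dy)

    labels = np.full((h, w), OUTSIDE, dtype=np.int32)
    inside_cell = 1.0 <= t_c  # pixel parameter is t = 1 by construction
    in_nucleus = (1.0 < t_n) & inside_cell
    cytosol = inside_cell & ~in_nucleus
    if (t_c[cytosol] <= t_n[cytosol]).any():
        raise ValueError(
            "cell boundary not strictly beyond the nucleus along some ray "
            "(nucleus touching the cell membrane?)"
        )
    f = np.zeros((h, w))
    f[cytosol] = (1.0 - t_n[cytosol]) / (t_c[cytosol] - t_n[cytosol])
    shell = np.clip(np.floor(f * R).astype(np.int32), 0, R - 1)
    labels[cytosol] = shell[cytosol]
    labels[in_nucleus] = NUCLEUS
    labels[at_origin] = NUCLEUS
    return RegionMap(labels=labels, R=R)


@dataclass
class RadialProfile:
    """Per-shell normalized mean intensity and cumulative distribution."""

    R: int
    region_mean_norm: np.ndarray  # length R
    region_area_px: np.ndarray  # length R, int
    cumulative_norm: np.ndarray  # length R, nondecreasing, ends at 1

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "R": self.R,
                    "region_mean_norm": self.region_mean_norm.tolist(),
                    "region_area_px": self.region_area_px.tolist(),
                    "cumulative_norm": self.cumulative_norm.tolist(),
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "RadialProfile":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            R=int(d["R"]),
            region_mean_norm=np.asarray(d["region_mean_norm"], dtype=float),
            region_area_px=np.asarray(d["region_area_px"], dtype=np.int64),
            cumulative_norm=np.asarray(d["cumulative_norm"], dtype=float),
        )


def radial_profile(
    image: np.ndarray,
    regions: RegionMap,
    include_nucleus_in_norm: bool = False,
) -> RadialProfile:
    """Shell intensity summaries for one cell.

    The normalizing "whole cell" mean pools cytosolic pixels only by
    default (the quantified marker is cytoplasmic); set
    ``include_nucleus_in_norm`` to pool nuclear pixels too. The cumulative
    distribution always runs over cytosolic intensity.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != regions.labels.shape:
        raise ValueError(
            f"image shape {image.shape} != region map {regions.labels.shape}"
        )
    R = regions.R
    areas = np.zeros(R, dtype=np.int64)
    sums = np.zeros(R)
    for r in range(R):
        mask = regions.labels == r
        areas[r] = int(mask.sum())
        if areas[r] == 0:
            raise ValueError(
                f"shell {r} of {R} contains no pixels; use a lower region count"
            )
        sums[r] = image[mask].sum()
    total = sums.sum()
    if include_nucleus_in_norm:
        whole = regions.labels >= NUCLEUS
        whole_mean = image[whole].mean()
    else:
        whole_mean = total / areas.sum()
    if total <= 0 or whole_mean <= 0:
        warnings.warn(
            "total cytosolic intensity is 0; returning a zero profile",
            RuntimeWarning,
            stacklevel=2,
        )
        return RadialProfile(R, np.zeros(R), areas, np.zeros(R))
    mean_norm = (sums / areas) / whole_mean
    cumulative = np.cumsum(sums) / total
    return RadialProfile(R, mean_norm, areas, cumulative)


@dataclass
class ProfileComparison:
    """Per-shell two-group comparison of normalized shell means."""

    R: int
    mean_a: np.ndarray
    mean_b: np.ndarray
    p_values: np.ndarray
    direction: list[str]  # up/down (b vs a, at alpha) or none
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "shell": np.arange(self.R),
                "mean_a": self.mean_a,
                "mean_b": self.mean_b,
                "p_value": self.p_values,
                "direction": self.direction,
            }
        )


def compare_profiles(
    group_a: Sequence[RadialProfile],
    group_b: Sequence[RadialProfile],
    alpha: float = 0.05,
    welch: bool = False,
) -> ProfileComparison:
    """Unpaired two-tailed t-test on per-cell normalized shell means, one
    test per shell."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 cells per group")
    Rs = {p.R for p in group_a} | {p.R for p in group_b}
    if len(Rs) != 1:
        raise ValueError(f"profiles disagree on region count R: {sorted(Rs)}")
    R = Rs.pop()
    A = np.vstack([p.region_mean_norm for p in group_a])
    B = np.vstack([p.region_mean_norm for p in group_b])
    res = stats.ttest_ind(A, B, axis=0, equal_var=not welch)
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)  # both groups constant & equal
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    direction = [
        ("up" if mb[r] > ma[r] else "down") if p[r] < alpha else "none"
        for r in range(R)
    ]
    return ProfileComparison(R, ma, mb, p, direction, alpha)


# ---------------------------------------------------------------------------
# I/O: traced polygons (CSV) and single-channel images (TIFF/PNG)
# ---------------------------------------------------------------------------

def read_polygons_csv(path, image_shape: tuple[int, int]) -> CellGeometry:
    """Boundary CSV with columns role{cell,nucleus}, vertex_index, x, y."""
    df = pd.read_csv(path)
    need = {"role", "vertex_index", "x", "y"}
    if not need <= set(df.columns):
        raise ValueError(f"polygon CSV needs columns {sorted(need)}")
    polys = {}
    for role, grp in df.groupby("role"):
        grp = grp.sort_values("vertex_index")
        polys[role] = grp[["x", "y"]].values.astype(float)
    if set(polys) != {"cell", "nucleus"}:
        raise ValueError("polygon CSV must contain roles 'cell' and 'nucleus'")
    return CellGeometry(polys["cell"], polys["nucleus"], image_shape)


def write_polygons_csv(geom: CellGeometry, path) -> None:
    rows = []
    for role, poly in (("cell", geom.cell_polygon), ("nucleus", geom.nucleus_polygon)):
        for i, (x, y) in enumerate(poly):
            rows.append({"role": role, "vertex_index": i, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_image(path) -> np.ndarray:
    """Single-channel TIFF or PNG (8/16-bit or float) as a float array."""
    spath = str(path)
    if spath.lower().endswith((".tif", ".tiff")):
        import tifffile

        img = tifffile.imread(spath)
    else:
        import imageio.v3 as iio

        img = iio.imread(spath)
    img = np.asarray(img)
    if img.ndim == 3 and img.shape[2] == 1:
        img = img[:, :, 0]
    if img.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape {img.shape}")
    return img.astype(float)
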