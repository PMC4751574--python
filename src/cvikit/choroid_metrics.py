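"""Subfoveal choroid geometry and the vascularity metrics computed inside it.

The region of interest is the band of choroid between Bruch's membrane
(upper boundary) and the choroid–scleral interface (lower boundary),
restricted to a window of fixed physical width (default 1.5 mm) centred on
the fovea. Within that polygon:

* TCA — total choroidal area,
* LA  — luminal area, the dark pixels of the binarized scan,
* SA  — stromal area, SA = TCA - LA,
* CVI — 100 · LA / TCA (percent),
* LA/SA ratio,
* SFCT — subfoveal choroidal thickness, the boundary-to-boundary distance
  at the fovea column, in µm.

Areas are pixel-count areas: TCA and LA both count pixel *centers* inside
the polygon (even-odd rule) and multiply by the physical pixel area, so the
containment LA <= TCA and the closure SA + LA = TCA hold exactly, the way
they do for areas read off a binarized raster in ImageJ-style workflows.
The continuous shoelace area of the polygon is exposed separately.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path as FsPath

import numpy as np
from matplotlib.path import Path as MplPath
from shapely.geometry import Polygon as ShapelyPolygon

from .binarize import BinaryMask, BScan, PixelScale, ThresholdParams, binarize

__all__ = [
    "BoundaryTrace",
    "ROIPolygon",
    "ChoroidMetrics",
    "subfoveal_window",
    "polygon_area_mm2",
    "pixel_centers_in_polygon",
    "luminal_area_mm2",
    "sfct_um",
    "compute_metrics",
    "load_trace",
    "DEFAULT_WINDOW_MM",
]

DEFAULT_WINDOW_MM = 1.5


@dataclass(frozen=True)
class BoundaryTrace:
    """Choroid boundary annotation for one B-scan.

    ``upper`` and ``lower`` give the fractional row coordinate of Bruch's
    membrane and the choroid–scleral interface at each integer column
    ``cols[i]``; ``fovea_col`` marks the foveal center. Boundaries are
    inputs (manual annotation or synthetic ground truth) — no automatic
    layer segmentation is performed here.
    """

    cols: np.ndarray
    upper: np.ndarray
    lower: np.ndarray
    fovea_col: int

    def __post_init__(self) -> None:
        cols = np.asarray(self.cols, dtype=int)
        upper = np.asarray(self.upper, dtype=float)
        lower = np.asarray(self.lower, dtype=float)
        if not (cols.shape == upper.shape == lower.shape) or cols.ndim != 1 or cols.size < 2:
            raise ValueError("trace requires matched 1-D cols/upper/lower arrays of length >= 2")
        if not np.all(np.diff(cols) == 1):
            raise ValueError("trace columns must be consecutive integers")
        if not (np.all(np.isfinite(upper)) and np.all(np.isfinite(lower))):
            raise ValueError("boundary depths must be finite")
        if np.any(lower < upper):
            bad = cols[lower < upper]
            raise ValueError(f"lower boundary above upper boundary at columns {bad[:5]}...")
        if not (cols[0] <= self.fovea_col <= cols[-1]):
            raise ValueError(f"fovea column {self.fovea_col} outside trace domain [{cols[0]}, {cols[-1]}]")
        object.__setattr__(self, "cols", cols)
        object.__setattr__(self, "upper", upper)
        object.__setattr__(self, "lower", lower)

    def upper_at(self, col: float) -> float:
        return float(np.interp(col, self.cols, self.upper))

    def lower_at(self, col: float) -> float:
        return float(np.interp(col, self.cols, self.lower))


@dataclass(frozen=True)
class ROIPolygon:
    """Simple closed polygon in (row, col) fractional-pixel coordinates."""

    vertices: np.ndarray  # (n, 2) array of (row, col)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("polygon needs >= 3 (row, col) vertices")
        poly = ShapelyPolygon([(c, r) for r, c in v])
        if not poly.is_valid:
            raise ValueError("polygon is self-intersecting or otherwise invalid")
        if poly.area == 0.0:
            raise ValueError("polygon has zero area")
        object.__setattr__(self, "vertices", v)

    @property
    def shapely(self) -> ShapelyPolygon:
        return ShapelyPolygon([(c, r) for r, c in self.vertices])

    @property
    def area_px2(self) -> float:
        """Continuous (shoelace) area in px², orientation-independent."""
        return float(self.shapely.area)

    def bounds(self) -> tuple[float, float, float, float]:
        """(row_min, col_min, row_max, col_max)."""
        v = self.vertices
        return v[:, 0].min(), v[:, 1].min(), v[:, 0].max(), v[:, 1].max()


@dataclass(frozen=True)
class ChoroidMetrics:
    """CVI metrics for one eye. Closure SA + LA = TCA holds exactly."""

    tca_mm2: float
    la_mm2: float
    sa_mm2: float
    cvi_percent: float
    la_sa_ratio: float | None  # None when SA = 0 (undefined, not infinity)
    sfct_um: float

    @classmethod
    def from_areas(cls, tca_mm2: float, la_mm2: float, sfct_um: float = float("nan")) -> "ChoroidMetrics":
        """Build the full metric set from TCA and LA; SA, CVI, LA/SA derive."""
        if tca_mm2 <= 0:
            raise ValueError("TCA must be positive")
        if not (0 <= la_mm2 <= tca_mm2 * (1 + 1e-12)):
            raise ValueError(f"LA ({la_mm2}) must lie in [0, TCA] = [0, {tca_mm2}]")
        sa = tca_mm2 - la_mm2
        cvi = 100.0 * la_mm2 / tca_mm2
        ratio = la_mm2 / sa if sa > 0 else None
        return cls(tca_mm2=tca_mm2, la_mm2=la_mm2, sa_mm2=sa,
                   cvi_percent=cvi, la_sa_ratio=ratio, sfct_um=sfct_um)


def subfoveal_window(trace: BoundaryTrace, width_mm: float, scale: PixelScale) -> ROIPolygon:
    """Fovea-centred choroid window of physical width ``width_mm``.

    The polygon's left and right edges are vertical lines at
    ``fovea_col ± (width_mm / 2) / lateral scale``; the top edge follows the
    upper (Bruch's membrane) trace and the bottom edge the lower
    (choroid–scleral) trace. Vertices run counter-clockwise in image
    coordinates (row down). Windows that extend past the annotated trace
    domain raise rather than silently truncating.
    """
    if width_mm <= 0:
        raise ValueError("window width must be positive")
    half_px = (width_mm * 1000.0 / 2.0) / scale.lateral_um_per_px
    left = trace.fovea_col - half_px
    right = trace.fovea_col + half_px
    if left < trace.cols[0] or right > trace.cols[-1]:
        raise ValueError(
            f"subfoveal window [{left:.2f}, {right:.2f}] px exceeds trace domain "
            f"[{trace.cols[0]}, {trace.cols[-1]}]"
        )
    interior = trace.cols[(trace.cols > left) & (trace.cols < right)]
    top_cols = np.concatenate(([left], interior, [right]))
    # Top edge left->right along the upper trace, then bottom edge
    # right->left along the lower trace. With rows increasing downward this
    # ordering is counter-clockwise in (x=col, y=row) screen coordinates.
    top = [(trace.upper_at(c), c) for c in top_cols]
    bottom = [(trace.lower_at(c), c) for c in top_cols[::-1]]
    return ROIPolygon(vertices=np.array(top + bottom))


def polygon_area_mm2(roi: ROIPolygon, scale: PixelScale) -> float:
    """Continuous shoelace polygon area converted to mm²."""
    return roi.area_px2 * scale.pixel_area_mm2


def pixel_centers_in_polygon(roi: ROIPolygon, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Boolean grid of pixel centers strictly inside the polygon.

    Pixel (r, c) has its center at coordinates (r, c); membership uses the
    even-odd rule. If ``shape`` is omitted the grid covers the polygon's
    bounding box only (returned grid is offset — use the shaped form for
    mask intersection).
    """
    r0, c0, r1, c1 = roi.bounds()
    if shape is None:
        rows = np.arange(math.floor(r0), math.ceil(r1) + 1)
        cols = np.arange(math.floor(c0), math.ceil(c1) + 1)
    else:
        rows = np.arange(shape[0])
        cols = np.arange(shape[1])
    # Restrict the point-in-polygon test to the bounding box for speed.
    rsel = rows[(rows >= r0 - 1) & (rows <= r1 + 1)]
    csel = cols[(cols >= c0 - 1) & (cols <= c1 + 1)]
    inside = np.zeros((rows.size, cols.size), dtype=bool)
    if rsel.size and csel.size:
        rr, cc = np.meshgrid(rsel, csel, indexing="ij")
        pts = np.column_stack([cc.ravel(), rr.ravel()])  # (x=col, y=row)
        path = MplPath([(c, r) for r, c in roi.vertices])
        hit = path.contains_points(pts).reshape(rr.shape)
        inside[np.ix_(np.searchsorted(rows, rsel), np.searchsorted(cols, csel))] = hit
    return inside


def luminal_area_mm2(mask: BinaryMask, roi: ROIPolygon, scale: PixelScale) -> float:
    """Area of dark pixels whose centers fall inside the ROI, in mm²."""
    r0, c0, r1, c1 = roi.bounds()
    if r1 > mask.shape[0] - 1 + 1e-9 or c1 > mask.shape[1] - 1 + 1e-9 or r0 < -1e-9 or c0 < -1e-9:
        raise ValueError(f"ROI bounds {(r0, c0, r1, c1)} not covered by mask of shape {mask.shape}")
    inside = pixel_centers_in_polygon(roi, shape=mask.shape)
    if not inside.any():
        raise ValueError("ROI contains no pixel centers")
    return int(np.count_nonzero(mask.dark & inside)) * scale.pixel_area_mm2


def sfct_um(trace: BoundaryTrace, scale: PixelScale) -> float:
    """Subfoveal choroidal thickness: boundary separation at the fovea, µm."""
    up = trace.upper_at(trace.fovea_col)
    lo = trace.lower_at(trace.fovea_col)
    if lo < up:
        raise ValueError("choroid-scleral interface above Bruch's membrane at the fovea")
    return (lo - up) * scale.axial_um_per_px


def compute_metrics(image: BScan, trace: BoundaryTrace, params: ThresholdParams,
                    width_mm: float = DEFAULT_WINDOW_MM) -> ChoroidMetrics:
    """Full per-scan pipeline: binarize, select the subfoveal ROI, measure.

    The whole image is binarized *first* and the polygon applied afterwards,
    so boundary visibility never depends on ROI placement. TCA is the count
    of pixel centers inside the polygon times the pixel area — the same
    lattice used for LA — hence SA = TCA - LA is exact and non-negative.
    """
    mask = binarize(image, params)
    roi = subfoveal_window(trace, width_mm, image.scale)
    inside = pixel_centers_in_polygon(roi, shape=image.shape)
    n_inside = int(np.count_nonzero(inside))
    if n_inside == 0:
        raise ValueError("ROI contains no pixel centers; TCA would be zero")
    n_dark = int(np.count_nonzero(mask.dark & inside))
    px_area = image.scale.pixel_area_mm2
    metrics = ChoroidMetrics.from_areas(
        tca_mm2=n_inside * px_area,
        la_mm2=n_dark * px_area,
        sfct_um=sfct_um(trace, image.scale),
    )
    return metrics


# ---------------------------------------------------------------------------
# Annotation I/O

def load_trace(csv_path, sidecar_json=None) -> tuple[BoundaryTrace, PixelScale | None]:
    """Read a boundary annotation CSV (col, upper_row, lower_row).

    The JSON sidecar, when given, supplies ``fovea_col`` and the pixel
    scales: ``{"fovea_col": ..., "lateral_um_per_px": ..., "axial_um_per_px": ...}``.
    Without a sidecar the CSV must carry a ``fovea_col`` column (constant)
    and the returned scale is None.
    """
    cols, upper, lower = [], [], []
    fovea_from_csv = None
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            cols.append(int(row["col"]))
            upper.append(float(row["upper_row"]))
            lower.append(float(row["lower_row"]))
            if "fovea_col" in row:
                fovea_from_csv = int(row["fovea_col"])
    scale = None
    fovea = fovea_from_csv
    if sidecar_json is not None:
        meta = json.loads(FsPath(sidecar_json).read_text())
        fovea = int(meta["fovea_col"])
        if "lateral_um_per_px" in meta:
            scale = PixelScale(meta["lateral_um_per_px"], meta["axial_um_per_px"])
    if fovea is None:
        raise ValueError("fovea_col missing: provide a sidecar JSON or a fovea_col CSV column")
    trace = BoundaryTrace(cols=np.array(cols), upper=np.array(upper),
                          lower=np.array(lower), fovea_col=fovea)
    return trace, scale
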