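"""Transfer of classified 2D vegetation polygons onto the 3D point cloud.

Because the orthomosaic and the dense point cloud live in the same
georeferenced planimetric frame, the surface-to-point transfer reduces to a
vertical projection: a point belongs to the vegetation surface iff its (x, y)
falls inside (boundary included) a vegetation polygon. With M vegetation
polygons and N of them receiving at least one point, the mapping error is

    Q = N / M * 100  (percent)

After transfer, residual bare-soil points hiding inside vegetation polygons
can be purged by a per-point VDVI rule (explicit threshold, or automatic:
Otsu's split applied only when the within-polygon VDVI histogram is clearly
bimodal). Fractional vegetation cover is then the surviving vegetation point
count over the total cloud size, in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.strtree import STRtree
from skimage.filters import threshold_otsu

from .indices import IndexHistogram, bimodality, pointwise_index
from .raster import GeoTransform
from .scene import PointCloud
from .segmentation import SegmentationResult


@dataclass
class ClassifiedPolygons:
    """Planar polygons with class labels; vegetation ones drive the mapping."""

    polygons: list                      # shapely (Multi)Polygons
    labels: list
    vegetation_class: str = "vegetation"

    def __post_init__(self) -> None:
        if len(self.polygons) != len(self.labels):
            raise ValueError("polygons and labels must have the same length")
        for p in self.polygons:
            if not p.is_valid:
                raise ValueError("polygons must be simple (non-self-intersecting)")

    @property
    def vegetation_polygons(self) -> list:
        return [p for p, c in zip(self.polygons, self.labels) if c == self.vegetation_class]

    @property
    def m_vegetation(self) -> int:
        return len(self.vegetation_polygons)


def segments_to_polygons(
    seg: SegmentationResult,
    class_by_segment: dict,
    transform: GeoTransform,
) -> ClassifiedPolygons:
    """Dissolve each segment's pixels into one world-coordinate polygon."""
    labels = seg.label_raster
    ps = transform.pixel_size
    polys = []
    classes = []
    for sid in seg.segments.index:
        rows, cols = np.nonzero(labels == sid)
        x0 = transform.origin_x + cols * ps
        y1 = transform.origin_y - rows * ps
        boxes = shapely.box(x0, y1 - ps, x0 + ps, y1)
        polys.append(shapely.unary_union(boxes))
        classes.append(class_by_segment[sid])
    return ClassifiedPolygons(polys, classes)


@dataclass
class MappingResult:
    m_polygons: int                   # M: vegetation polygons offered
    n_mapped: int                     # N: vegetation polygons containing >= 1 point
    q_percent: float                  # mapping error Q = N/M * 100
    vegetation_mask: np.ndarray       # per-point bool: inside a vegetation polygon
    vegetation_point_count: int
    total_points: int
    fvc_percent: float | None = None
    purged_count: int = 0
    purge_threshold: float | None = None
    notes: list = field(default_factory=list)


def map_polygons(polys: ClassifiedPolygons, cloud: PointCloud) -> MappingResult:
    """Vertical surface-to-point transfer of the vegetation polygons.

    Boundary points count as inside. N counts the vegetation polygons that
    received at least one cloud point.
    """
    if cloud.total_count == 0:
        raise ValueError("point cloud is empty")
    veg = polys.vegetation_polygons
    m = len(veg)
    assigned = np.zeros(cloud.total_count, dtype=bool)
    n_mapped = 0
    if m > 0:
        points = shapely.points(cloud.xyz[:, 0], cloud.xyz[:, 1])
        tree = STRtree(points)
        hit_polys = set()
        for k, poly in enumerate(veg):
            idx = tree.query(poly, predicate="covers")
            if idx.size:
                hit_polys.add(k)
                assigned[idx] = True
        n_mapped = len(hit_polys)
    q = mapping_error(m, n_mapped) if m > 0 else 0.0
    return MappingResult(
        m_polygons=m,
        n_mapped=n_mapped,
        q_percent=q,
        vegetation_mask=assigned,
        vegetation_point_count=int(assigned.sum()),
        total_points=cloud.total_count,
    )


def mapping_error(m: int, n: int) -> float:
    """Q = N / M * 100 percent; the share of vegetation polygons actually mapped."""
    if m <= 0:
        raise ValueError("M must be positive")
    if not 0 <= n <= m:
        raise ValueError("N must satisfy 0 <= N <= M")
    return 100.0 * n / m


def purge_bare_points(
    result: MappingResult,
    cloud: PointCloud,
    vdvi_threshold="auto",
) -> MappingResult:
    """Drop vegetation-assigned points whose own VDVI says bare ground.

    With a float threshold, points with per-point VDVI below it are
    reassigned non-vegetation. With ``"auto"``, Otsu's threshold is applied
    only if the within-polygon VDVI distribution is bimodal; a unimodal
    distribution is taken as already clean and left untouched. Purging never
    adds vegetation points.
    """
    mask = result.vegetation_mask.copy()
    sel = np.nonzero(mask)[0]
    notes = list(result.notes)
    threshold: float | None = None
    if sel.size:
        vdvi = pointwise_index(cloud.rgb[sel], "VDVI")
        finite = np.isfinite(vdvi)
        if vdvi_threshold == "auto":
            vals = vdvi[finite]
            if vals.size >= 2 and np.ptp(vals) > 0:
                counts, edges = np.histogram(vals, bins=256, range=(-1.0, 1.0))
                bim = bimodality(IndexHistogram("VDVI", edges, counts))
                if bim.is_bimodal:
                    threshold = float(threshold_otsu(vals))
                    notes.append(f"auto purge: bimodal VDVI, Otsu threshold {threshold:.4f}")
                else:
                    notes.append("auto purge: VDVI unimodal, nothing removed")
            else:
                notes.append("auto purge: degenerate VDVI distribution, nothing removed")
        else:
            threshold = float(vdvi_threshold)
        if threshold is not None:
            drop = ~finite | (vdvi < threshold)
            mask[sel[drop]] = False
    remaining = int(mask.sum())
    purged = result.vegetation_point_count - remaining
    if result.vegetation_point_count > 0 and remaining == 0:
        warnings.warn("purge removed every vegetation point", RuntimeWarning, stacklevel=2)
    return MappingResult(
        m_polygons=result.m_polygons,
        n_mapped=result.n_mapped,
        q_percent=result.q_percent,
        vegetation_mask=mask,
        vegetation_point_count=remaining,
        total_points=result.total_points,
        purged_count=purged,
        purge_threshold=threshold,
        notes=notes,
    )


def fvc(vegetation_point_count: int, total_count: int) -> float:
    """Fractional vegetation cover in percent, rounded to 2 decimals."""
    if total_count <= 0:
        raise ValueError("total point count must be positive")
    if not 0 <= vegetation_point_count <= total_count:
        raise ValueError("vegetation count must lie in [0, total]")
    return round(100.0 * vegetation_point_count / total_count, 2)
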