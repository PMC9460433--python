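"""Multiresolution region-merging segmentation with LV-ROC scale selection.

Bottom-up object building: every pixel starts as its own segment; adjacent
segments merge while the *increase* in weighted heterogeneity their fusion
would cause stays below the squared scale parameter. The fusion cost of two
adjacent segments is

    C = w_color * dh_color + w_shape * dh_shape

    dh_color = sum_c w_c * [n_m * sigma_c(m) - (n_1 * sigma_c(1) + n_2 * sigma_c(2))]
    dh_shape = w_smooth * dh_smooth + w_compact * dh_compact
    dh_smooth  = n_m * l_m / b_m - (n_1 * l_1 / b_1 + n_2 * l_2 / b_2)
    dh_compact = l_m * sqrt(n_m) - (l_1 * sqrt(n_1) + l_2 * sqrt(n_2))

where, per segment, n is the pixel count, l the perimeter counted as exposed
unit pixel edges, b the shorter side of the axis-aligned bounding box, and
sigma_c the population standard deviation of image layer c. Merging proceeds
by local mutual best fitting: in each round every segment names its
cheapest neighbor (ties to the lowest id), and exactly the mutually-best,
admissible (cost < scale^2) pairs merge simultaneously. The round structure
plus fixed tie-breaking makes the result deterministic.

The optimal scale is estimated from the LV-ROC curve: LV(L) is the mean
per-segment (population) std of the spectral layers at scale L, and
ROC(L) = (LV(L) - LV(L_prev)) / LV(L_prev) * 100; the scale at the global ROC
peak marks the characteristic object size. Terrain layers (elevation, slope)
can be appended as extra weighted layers so object boundaries respect
topographic breaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SegWeights:
    """Criterion weights. Color/shape and smoothness/compactness each sum to 1."""

    w_color: float = 0.7
    w_shape: float = 0.3
    w_smoothness: float = 0.4
    w_compactness: float = 0.6
    layer_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.w_color < 0 or self.w_shape < 0:
            raise ValueError("color/shape weights must be nonnegative")
        if abs(self.w_color + self.w_shape - 1.0) > 1e-9:
            raise ValueError("w_color + w_shape must equal 1")
        if self.w_smoothness < 0 or self.w_compactness < 0:
            raise ValueError("smoothness/compactness weights must be nonnegative")
        if abs(self.w_smoothness + self.w_compactness - 1.0) > 1e-9:
            raise ValueError("w_smoothness + w_compactness must equal 1")
        if self.layer_weights is not None:
            if any(w < 0 for w in self.layer_weights):
                raise ValueError("layer weights must be nonnegative")

    def layer_weight_array(self, n_layers: int) -> np.ndarray:
        if self.layer_weights is None:
            return np.ones(n_layers)
        if len(self.layer_weights) != n_layers:
            raise ValueError(
                f"{len(self.layer_weights)} layer weights for {n_layers} layers"
            )
        return np.asarray(self.layer_weights, dtype=np.float64)


@dataclass
class SegmentStats:
    """Sufficient statistics of one segment for the fusion criterion."""

    id: int
    n: int                      # area in pixels
    perimeter: float            # exposed unit edges
    bbox: tuple[int, int, int, int]   # rmin, rmax, cmin, cmax (inclusive)
    layer_sums: np.ndarray
    layer_sumsqs: np.ndarray
    adjacency: dict[int, float] = field(default_factory=dict)  # neighbor -> shared edges

    @property
    def bbox_shortest_side(self) -> int:
        rmin, rmax, cmin, cmax = self.bbox
        return min(rmax - rmin + 1, cmax - cmin + 1)

    @property
    def means(self) -> np.ndarray:
        return self.layer_sums / self.n

    @property
    def stds(self) -> np.ndarray:
        var = self.layer_sumsqs / self.n - self.means**2
        return np.sqrt(np.maximum(var, 0.0))


def _pooled_std(a: SegmentStats, b: SegmentStats) -> np.ndarray:
    n = a.n + b.n
    s = a.layer_sums + b.layer_sums
    q = a.layer_sumsqs + b.layer_sumsqs
    var = q / n - (s / n) ** 2
    return np.sqrt(np.maximum(var, 0.0))


def fusion_cost(a: SegmentStats, b: SegmentStats, w: SegWeights) -> float:
    """Heterogeneity increase caused by merging two *adjacent* segments."""
    if b.id not in a.adjacency:
        raise ValueError(f"segments {a.id} and {b.id} are not adjacent")
    shared = a.adjacency[b.id]
    wc = w.layer_weight_array(len(a.layer_sums))
    n_m = a.n + b.n
    dh_color = float(
        np.sum(wc * (n_m * _pooled_std(a, b) - a.n * a.stds - b.n * b.stds))
    )
    l_m = a.perimeter + b.perimeter - 2.0 * shared
    rmin = min(a.bbox[0], b.bbox[0])
    rmax = max(a.bbox[1], b.bbox[1])
    cmin = min(a.bbox[2], b.bbox[2])
    cmax = max(a.bbox[3], b.bbox[3])
    b_m = min(rmax - rmin + 1, cmax - cmin + 1)
    dh_smooth = (
        n_m * l_m / b_m
        - a.n * a.perimeter / a.bbox_shortest_side
        - b.n * b.perimeter / b.bbox_shortest_side
    )
    dh_compact = (
        l_m * np.sqrt(n_m) - a.perimeter * np.sqrt(a.n) - b.perimeter * np.sqrt(b.n)
    )
    dh_shape = w.w_smoothness * dh_smooth + w.w_compactness * dh_compact
    return w.w_color * dh_color + w.w_shape * dh_shape


def _as_layer_stack(layers) -> np.ndarray:
    """Stack a list of 2-D layers into (C, H, W) float64."""
    if layers is None or len(layers) == 0:
        raise ValueError("at least one layer is required")
    stack = np.stack([np.asarray(l, dtype=np.float64) for l in layers])
    if stack.ndim != 3:
        raise ValueError("layers must be 2-D rasters")
    return stack


def segment_statistics(labels: np.ndarray, layers) -> dict[int, SegmentStats]:
    """Compute SegmentStats for every label of a label raster (from scratch)."""
    labels = np.asarray(labels)
    stack = _as_layer_stack(layers)
    if stack.shape[1:] != labels.shape:
        raise ValueError("layers must match the label grid")
    ids = np.unique(labels)
    k = int(labels.max()) + 1
    n = np.bincount(labels.ravel(), minlength=k)
    sums = np.stack([np.bincount(labels.ravel(), weights=l.ravel(), minlength=k) for l in stack], axis=1)
    sumsqs = np.stack(
        [np.bincount(labels.ravel(), weights=(l.ravel() ** 2), minlength=k) for l in stack], axis=1
    )
    rows, cols = np.indices(labels.shape)
    rmin = np.full(k, np.iinfo(np.int64).max)
    rmax = np.full(k, -1)
    cmin = np.full(k, np.iinfo(np.int64).max)
    cmax = np.full(k, -1)
    np.minimum.at(rmin, labels.ravel(), rows.ravel())
    np.maximum.at(rmax, labels.ravel(), rows.ravel())
    np.minimum.at(cmin, labels.ravel(), cols.ravel())
    np.maximum.at(cmax, labels.ravel(), cols.ravel())
    # perimeter = 4n - 2 * (same-label 4-adjacent pixel pairs)
    per = 4.0 * n
    shared: dict[tuple[int, int], float] = {}
    for aa, bb in (
        (labels[:, :-1].ravel(), labels[:, 1:].ravel()),
        (labels[:-1, :].ravel(), labels[1:, :].ravel()),
    ):
        same = aa == bb
        np.subtract.at(per, aa[same], 2.0)
        da, db = aa[~same], bb[~same]
        lo = np.minimum(da, db)
        hi = np.maximum(da, db)
        for key_lo, key_hi in zip(lo.tolist(), hi.tolist()):
            shared[(key_lo, key_hi)] = shared.get((key_lo, key_hi), 0.0) + 1.0
    stats = {
        int(i): SegmentStats(
            id=int(i),
            n=int(n[i]),
            perimeter=float(per[i]),
            bbox=(int(rmin[i]), int(rmax[i]), int(cmin[i]), int(cmax[i])),
            layer_sums=sums[i].copy(),
            layer_sumsqs=sumsqs[i].copy(),
        )
        for i in ids
    }
    for (i, j), s in shared.items():
        stats[int(i)].adjacency[int(j)] = s
        stats[int(j)].adjacency[int(i)] = s
    return stats


@dataclass
class SegmentationResult:
    """A partition of the raster into 4-connected segments."""

    label_raster: np.ndarray      # (rows, cols) consecutive ids, scan order
    segments: pd.DataFrame        # indexed by id: n, perimeter, bbox_b, mean_c, std_c
    scale: float
    weights: SegWeights
    adjacency: dict[int, dict[int, float]]

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def _build_result(labels, stack, scale, w) -> SegmentationResult:
    stats = segment_statistics(labels, stack)
    records = {}
    for i, st in stats.items():
        rec = {"n": st.n, "perimeter": st.perimeter, "bbox_b": st.bbox_shortest_side}
        for c, (m, s) in enumerate(zip(st.means, st.stds)):
            rec[f"mean_{c}"] = m
            rec[f"std_{c}"] = s
        records[i] = rec
    segments = pd.DataFrame.from_dict(records, orient="index").sort_index()
    segments.index.name = "id"
    adjacency = {i: dict(st.adjacency) for i, st in stats.items()}
    return SegmentationResult(labels, segments, scale, w, adjacency)


def segment(layers, w: SegWeights = SegWeights(), scale: float = 50.0) -> SegmentationResult:
    """Segment a stack of co-registered layers at one scale parameter."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    stack = _as_layer_stack(layers)
    n_layers, rows, cols = stack.shape
    wc = w.layer_weight_array(n_layers)
    npix = rows * cols
    threshold = float(scale) * float(scale)

    # per-segment running stats, indexed by (persistent) segment id = the
    # smallest original pixel index the segment contains
    n = np.ones(npix, dtype=np.float64)
    per = np.full(npix, 4.0)
    rmin = np.repeat(np.arange(rows), cols).astype(np.float64)
    rmax = rmin.copy()
    cmin = np.tile(np.arange(cols), rows).astype(np.float64)
    cmax = cmin.copy()
    flat = stack.reshape(n_layers, npix).T.copy()   # (npix, C)
    sums = flat.copy()
    sumsqs = flat**2

    cur = np.arange(npix, dtype=np.int64)           # pixel -> current segment id

    # initial 4-adjacency edges (each pixel pair shares 1 unit edge)
    idx = np.arange(npix).reshape(rows, cols)
    e_h = np.column_stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()])
    e_v = np.column_stack([idx[:-1, :].ravel(), idx[1:, :].ravel()])
    edges = np.vstack([e_h, e_v]).astype(np.int64)
    shared = np.ones(len(edges), dtype=np.float64)

    ws, wk = w.w_smoothness, w.w_compactness
    while len(edges) > 0:
        i, j = edges[:, 0], edges[:, 1]
        n_i, n_j = n[i], n[j]
        n_m = n_i + n_j
        s_m = sums[i] + sums[j]
        q_m = sumsqs[i] + sumsqs[j]
        var_m = q_m / n_m[:, None] - (s_m / n_m[:, None]) ** 2
        sig_m = np.sqrt(np.maximum(var_m, 0.0))
        var_i = sumsqs[i] / n_i[:, None] - (sums[i] / n_i[:, None]) ** 2
        var_j = sumsqs[j] / n_j[:, None] - (sums[j] / n_j[:, None]) ** 2
        sig_i = np.sqrt(np.maximum(var_i, 0.0))
        sig_j = np.sqrt(np.maximum(var_j, 0.0))
        dh_color = (
            (n_m[:, None] * sig_m - n_i[:, None] * sig_i - n_j[:, None] * sig_j) * wc
        ).sum(axis=1)

        l_m = per[i] + per[j] - 2.0 * shared
        rmin_m = np.minimum(rmin[i], rmin[j])
        rmax_m = np.maximum(rmax[i], rmax[j])
        cmin_m = np.minimum(cmin[i], cmin[j])
        cmax_m = np.maximum(cmax[i], cmax[j])
        b_m = np.minimum(rmax_m - rmin_m, cmax_m - cmin_m) + 1.0
        b_i = np.minimum(rmax[i] - rmin[i], cmax[i] - cmin[i]) + 1.0
        b_j = np.minimum(rmax[j] - rmin[j], cmax[j] - cmin[j]) + 1.0
        dh_smooth = n_m * l_m / b_m - n_i * per[i] / b_i - n_j * per[j] / b_j
        dh_compact = (
            l_m * np.sqrt(n_m) - per[i] * np.sqrt(n_i) - per[j] * np.sqrt(n_j)
        )
        cost = w.w_color * dh_color + w.w_shape * (ws * dh_smooth + wk * dh_compact)

        # best neighbor per segment: minimal (cost, neighbor id)
        seg_dir = np.concatenate([i, j])
        nb_dir = np.concatenate([j, i])
        cost_dir = np.concatenate([cost, cost])
        order = np.lexsort((nb_dir, cost_dir, seg_dir))
        seg_sorted = seg_dir[order]
        first = np.ones(len(seg_sorted), dtype=bool)
        first[1:] = seg_sorted[1:] != seg_sorted[:-1]
        best_nb = np.full(npix, -1, dtype=np.int64)
        best_nb[seg_sorted[first]] = nb_dir[order][first]

        mutual = (best_nb[i] == j) & (best_nb[j] == i) & (cost < threshold)
        if not mutual.any():
            break
        wi = np.minimum(i[mutual], j[mutual])
        lo = np.maximum(i[mutual], j[mutual])
        pair_shared = shared[mutual]
        # simultaneous merge of the (disjoint) mutually-best pairs
        n[wi] += n[lo]
        per[wi] = per[wi] + per[lo] - 2.0 * pair_shared
        rmin[wi] = np.minimum(rmin[wi], rmin[lo])
        rmax[wi] = np.maximum(rmax[wi], rmax[lo])
        cmin[wi] = np.minimum(cmin[wi], cmin[lo])
        cmax[wi] = np.maximum(cmax[wi], cmax[lo])
        sums[wi] += sums[lo]
        sumsqs[wi] += sumsqs[lo]

        remap = np.arange(npix, dtype=np.int64)
        remap[lo] = wi
        cur = remap[cur]
        edges = remap[edges]
        keep = edges[:, 0] != edges[:, 1]
        edges = edges[keep]
        shared = shared[keep]
        if len(edges) == 0:
            break
        lo_e = np.minimum(edges[:, 0], edges[:, 1])
        hi_e = np.maximum(edges[:, 0], edges[:, 1])
        key = lo_e * np.int64(npix) + hi_e
        uniq, inv = np.unique(key, return_inverse=True)
        agg = np.zeros(len(uniq))
        np.add.at(agg, inv, shared)
        edges = np.column_stack([uniq // npix, uniq % npix])
        shared = agg

    _, labels_flat = np.unique(cur, return_inverse=True)
    labels = labels_flat.reshape(rows, cols)
    return _build_result(labels, stack, float(scale), w)


def local_variance(seg: SegmentationResult, layer) -> float:
    """Mean over segments of the per-segment population std of one layer."""
    layer = np.asarray(layer, dtype=np.float64)
    labels = seg.label_raster
    if layer.shape != labels.shape:
        raise ValueError("layer must match the segmentation grid")
    k = int(labels.max()) + 1
    n = np.bincount(labels.ravel(), minlength=k).astype(np.float64)
    s = np.bincount(labels.ravel(), weights=layer.ravel(), minlength=k)
    q = np.bincount(labels.ravel(), weights=layer.ravel() ** 2, minlength=k)
    var = q / n - (s / n) ** 2
    return float(np.sqrt(np.maximum(var, 0.0)).mean())


@dataclass
class ScaleProfile:
    """LV and its rate of change across candidate scales."""

    scales: np.ndarray
    lv: np.ndarray
    roc: np.ndarray              # NaN where undefined (first scale, LV_prev = 0)
    optimal_scale: float
    segment_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scale": self.scales,
                "lv": self.lv,
                "roc": self.roc,
                "n_segments": self.segment_counts,
            }
        )


def lv_roc(
    layers,
    w: SegWeights = SegWeights(),
    scales=None,
    terrain_layers=None,
) -> ScaleProfile:
    """Estimate the optimal scale from the LV rate-of-change curve.

    LV is measured on the spectral ``layers`` only; ``terrain_layers`` are
    appended to the merge criterion so object boundaries also respect
    elevation/slope breaks. ``scales`` must be a strictly increasing sequence
    of at least 3 candidate scales (default 10, 20, ..., 100).
    """
    if scales is None:
        scales = np.arange(10.0, 101.0, 10.0)
    scales = np.asarray(scales, dtype=np.float64)
    if len(scales) < 3:
        raise ValueError("at least 3 candidate scales are required")
    if not (np.diff(scales) > 0).all():
        raise ValueError("scales must be strictly increasing")
    spectral = list(layers)
    all_layers = spectral + (list(terrain_layers) if terrain_layers is not None else [])
    lv = np.zeros(len(scales))
    counts = np.zeros(len(scales), dtype=np.int64)
    for k, sc in enumerate(scales):
        res = segment(all_layers, w, float(sc))
        lv[k] = float(np.mean([local_variance(res, lyr) for lyr in spectral]))
        counts[k] = res.n_segments
    roc = np.full(len(scales), np.nan)
    for k in range(1, len(scales)):
        if lv[k - 1] == 0:
            warnings.warn(
                f"LV is zero at scale {scales[k - 1]:g}; ROC undefined at {scales[k]:g}",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        roc[k] = (lv[k] - lv[k - 1]) / lv[k - 1] * 100.0
    finite = np.isfinite(roc)
    if not finite.any() or np.nanmax(np.abs(roc)) == 0:
        raise ValueError(
            "LV is flat across the candidate scales; no ROC peak exists "
            f"(LV = {lv.tolist()})"
        )
    best = int(np.nanargmax(roc))
    return ScaleProfile(scales, lv, roc, float(scales[best]), counts)
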