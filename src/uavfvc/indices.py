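"""Visible-band vegetation indices and index-selection diagnostics.

Nine indices computable from R, G, B alone (no near-infrared band needed):

====== ============================================ ==========
name   formula                                      range
====== ============================================ ==========
NGRDI  (G - R) / (G + R)                            [-1, 1]
NGBDI  (G - B) / (G + B)                            [-1, 1]
MRBVI  (R^2 - B^2) / (R^2 + B^2)                    [-1, 1]
MGRVI  (G^2 - R^2) / (G^2 + R^2)                    [-1, 1]
RGBVI  (G^2 - B*R) / (G^2 + B*R)                    [-1, 1]
ExG    2g - r - b                                   [-1, 2]
CIVE   0.44r - 0.88g + 0.385b + 18.78745            [17, 20]
VDVI   (2G - R - B) / (2G + R + B)                  [-1, 1]
EGRBDI ((2G)^2 - B*R) / ((2G)^2 + B*R)              [-1, 1]
====== ============================================ ==========

Lowercase r, g, b are the chromaticity-normalized bands, e.g.
``r = R / (R + G + B)``. Pixels where a formula's denominator vanishes are set
to NaN (nodata), never to 0 — zero is a meaningful index value.

The selection procedure mirrors common practice for picking a classification
index from an RGB-only sensor: discard indices with out-of-range pixels,
discard indices whose scene histogram is not clearly bimodal (vegetation vs
background), then rank the survivors by the mean of their per-class standard
deviations (smaller = cleaner class signatures).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .raster import RGBRaster

# fixed canonical order; also the deterministic tie-break order everywhere
INDEX_NAMES = (
    "NGRDI",
    "NGBDI",
    "MRBVI",
    "MGRVI",
    "RGBVI",
    "ExG",
    "CIVE",
    "VDVI",
    "EGRBDI",
)

#: theoretical closed range per index
INDEX_RANGES: dict[str, tuple[float, float]] = {
    "NGRDI": (-1.0, 1.0),
    "NGBDI": (-1.0, 1.0),
    "MRBVI": (-1.0, 1.0),
    "MGRVI": (-1.0, 1.0),
    "RGBVI": (-1.0, 1.0),
    "ExG": (-1.0, 2.0),
    "CIVE": (17.0, 20.0),
    "VDVI": (-1.0, 1.0),
    "EGRBDI": (-1.0, 1.0),
}


def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan, dtype=np.float64)
    ok = den != 0
    np.divide(num, den, out=out, where=ok)
    return out


def _index_values(name: str, R: np.ndarray, G: np.ndarray, B: np.ndarray) -> np.ndarray:
    if name == "NGRDI":
        return _ratio(G - R, G + R)
    if name == "NGBDI":
        return _ratio(G - B, G + B)
    if name == "MRBVI":
        return _ratio(R * R - B * B, R * R + B * B)
    if name == "MGRVI":
        return _ratio(G * G - R * R, G * G + R * R)
    if name == "RGBVI":
        return _ratio(G * G - B * R, G * G + B * R)
    if name in ("ExG", "CIVE"):
        total = R + G + B
        r = _ratio(R, total)
        g = _ratio(G, total)
        b = _ratio(B, total)
        if name == "ExG":
            return 2.0 * g - r - b
        return 0.44 * r - 0.88 * g + 0.385 * b + 18.78745
    if name == "VDVI":
        return _ratio(2.0 * G - R - B, 2.0 * G + R + B)
    if name == "EGRBDI":
        num = 4.0 * G * G
        return _ratio(num - B * R, num + B * R)
    raise ValueError(f"unknown index {name!r}; valid names: {', '.join(INDEX_NAMES)}")


@dataclass
class VIRaster:
    """Per-pixel values of one vegetation index (NaN = nodata)."""

    index_name: str
    values: np.ndarray
    theoretical_range: tuple[float, float]

    def finite_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


def compute_index(raster: RGBRaster, index_name: str) -> VIRaster:
    """Evaluate one index on every pixel of an 8-bit RGB raster.

    Bands are treated as real numbers; zero-denominator pixels and pixels under
    the raster's nodata mask come out as NaN.
    """
    if index_name not in INDEX_RANGES:
        raise ValueError(
            f"unknown index {index_name!r}; valid names: {', '.join(INDEX_NAMES)}"
        )
    values = _index_values(index_name, raster.r, raster.g, raster.b)
    if raster.nodata_mask is not None:
        values = np.where(raster.nodata_mask, np.nan, values)
    return VIRaster(index_name, values, INDEX_RANGES[index_name])


def compute_all_indices(raster: RGBRaster) -> dict[str, VIRaster]:
    return {name: compute_index(raster, name) for name in INDEX_NAMES}


def class_error_stats(vi: VIRaster, labels: np.ndarray, class_names=None) -> pd.DataFrame:
    """Per-class mean and population std of an index over labeled finite pixels.

    ``labels`` is a raster of class names (or any hashable codes) aligned with
    the index grid. Classes with no finite pixels are absent from the result,
    not reported as zeros.
    """
    labels = np.asarray(labels)
    if labels.shape != vi.values.shape:
        raise ValueError("labels grid does not match index grid")
    if class_names is None:
        class_names = pd.unique(labels.ravel())
    rows = {}
    finite = np.isfinite(vi.values)
    for cls in class_names:
        sel = (labels == cls) & finite
        if not sel.any():
            continue
        vals = vi.values[sel]
        rows[cls] = {"mean": float(vals.mean()), "std": float(vals.std())}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "class"
    return out


@dataclass
class IndexHistogram:
    """Gray histogram of an index over its theoretical range."""

    index_name: str
    bin_edges: np.ndarray
    counts: np.ndarray
    smoothing_window: int = 5
    peak_positions: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def span(self) -> float:
        return float(self.bin_edges[-1] - self.bin_edges[0])


def index_histogram(vi: VIRaster, bins: int = 256, smoothing_window: int = 5) -> IndexHistogram:
    """Histogram the finite pixels of an index over its theoretical range."""
    vals = vi.finite_values()
    counts, edges = np.histogram(vals, bins=bins, range=vi.theoretical_range)
    return IndexHistogram(vi.index_name, edges, counts, smoothing_window)


@dataclass
class BimodalityResult:
    n_major_peaks: int
    peak_positions: np.ndarray
    is_bimodal: bool


def bimodality(
    hist: IndexHistogram,
    prominence_frac: float = 0.05,
    min_separation_frac: float = 0.1,
) -> BimodalityResult:
    """Count well-separated major modes of a gray histogram.

    The histogram is smoothed with a moving average (``hist.smoothing_window``
    bins); a peak counts as major if its prominence is at least
    ``prominence_frac`` of the tallest smoothed count, and peaks closer than
    ``min_separation_frac`` of the histogram span are merged (the taller one
    survives). Exactly two major peaks means bimodal.
    """
    if hist.counts.size < 2:
        raise ValueError("histogram needs at least 2 bins")
    smoothed = uniform_filter1d(
        hist.counts.astype(np.float64), size=max(1, hist.smoothing_window), mode="nearest"
    )
    top = smoothed.max()
    if top <= 0 or np.ptp(smoothed) == 0:
        return BimodalityResult(0, np.empty(0), False)
    peaks, props = find_peaks(smoothed, prominence=prominence_frac * top)
    if peaks.size == 0:
        return BimodalityResult(0, np.empty(0), False)
    centers = hist.bin_centers[peaks]
    heights = smoothed[peaks]
    min_sep = min_separation_frac * hist.span
    # tallest-first greedy acceptance; ties by position for determinism
    order = np.lexsort((centers, -heights))
    accepted: list[float] = []
    for k in order:
        if all(abs(centers[k] - a) >= min_sep for a in accepted):
            accepted.append(float(centers[k]))
    accepted.sort()
    n = len(accepted)
    hist.peak_positions = np.asarray(accepted)
    return BimodalityResult(n, np.asarray(accepted), n == 2)


@dataclass
class IndexAudit:
    """Everything the selection procedure knows about one index."""

    name: str
    stats: pd.DataFrame
    histogram: IndexHistogram
    value_min: float
    value_max: float
    theoretical_range: tuple[float, float]
    bimodal: BimodalityResult | None = None

    @property
    def in_range(self) -> bool:
        lo, hi = self.theoretical_range
        return self.value_min >= lo and self.value_max <= hi

    @property
    def mean_std(self) -> float:
        return float(self.stats["std"].mean())


@dataclass
class SelectionReport:
    chosen: str
    ranking: list[str]
    eliminated: dict[str, str]
    mean_stds: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "chosen": self.chosen,
            "ranking": self.ranking,
            "eliminated": self.eliminated,
            "mean_stds": self.mean_stds,
        }


def select_index(
    audits: dict[str, IndexAudit],
    prominence_frac: float = 0.05,
    min_separation_frac: float = 0.1,
) -> SelectionReport:
    """Pick the classification index from per-index diagnostics.

    Procedure: (i) drop indices with any pixel outside the theoretical range,
    (ii) drop indices whose histogram is not bimodal, (iii) rank survivors by
    ascending mean per-class std; ties resolve in canonical index order.
    """
    missing = [n for n in INDEX_NAMES if n not in audits]
    if missing:
        raise ValueError(f"audits missing indices: {missing}")
    eliminated: dict[str, str] = {}
    survivors: list[IndexAudit] = []
    for name in INDEX_NAMES:
        audit = audits[name]
        if not audit.in_range:
            eliminated[name] = (
                f"pixels outside theoretical range {audit.theoretical_range}: "
                f"observed [{audit.value_min:.4g}, {audit.value_max:.4g}]"
            )
            continue
        bim = bimodality(audit.histogram, prominence_frac, min_separation_frac)
        audit.bimodal = bim
        if not bim.is_bimodal:
            eliminated[name] = f"not bimodal ({bim.n_major_peaks} major peak(s))"
            continue
        survivors.append(audit)
    if not survivors:
        raise ValueError(f"every index was eliminated: {eliminated}")
    order = {n: i for i, n in enumerate(INDEX_NAMES)}
    survivors.sort(key=lambda a: (a.mean_std, order[a.name]))
    ranking = [a.name for a in survivors]
    return SelectionReport(
        chosen=ranking[0],
        ranking=ranking,
        eliminated=eliminated,
        mean_stds={a.name: a.mean_std for a in survivors},
    )


def run_index_selection(
    raster: RGBRaster,
    labels: np.ndarray,
    class_names=None,
    bins: int = 256,
    smoothing_window: int = 5,
    prominence_frac: float = 0.05,
    min_separation_frac: float = 0.1,
) -> tuple[SelectionReport, dict[str, IndexAudit]]:
    """Compute all nine indices on a labeled scene and run the selection."""
    audits: dict[str, IndexAudit] = {}
    for name in INDEX_NAMES:
        vi = compute_index(raster, name)
        finite = vi.finite_values()
        audits[name] = IndexAudit(
            name=name,
            stats=class_error_stats(vi, labels, class_names),
            histogram=index_histogram(vi, bins, smoothing_window),
            value_min=float(finite.min()) if finite.size else np.nan,
            value_max=float(finite.max()) if finite.size else np.nan,
            theoretical_range=vi.theoretical_range,
        )
    report = select_index(audits, prominence_frac, min_separation_frac)
    return report, audits


def pointwise_index(rgb: np.ndarray, index_name: str = "VDVI") -> np.ndarray:
    """Index values for a flat (n, 3) array of RGB triples (e.g. cloud colors)."""
    rgb = np.asarray(rgb, dtype=np.float64)
    return _index_values(index_name, rgb[:, 0], rgb[:, 1], rgb[:, 2])
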