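"""Synthetic tailings-area scene generator.

Emulates the kind of site the pipeline targets: a four-class land cover
(vegetation, bare land, tailing sand, water) on a high-resolution RGB
orthomosaic (default 0.08 m/pixel), a stepped-terrace elevation field with
~140 m of relief, and an RGB-attributed dense point cloud (~214 points/m²)
whose colors are copied from the raster. Class regions come from quantile
thresholding of a smoothed Gaussian random field, which yields spatially
coherent blobs with smooth boundaries — the structure an object-based
segmentation stage assumes — while hitting requested areal fractions almost
exactly.

The per-class RGB distributions are a *calibration*, not ground truth: means
and covariances are chosen so that the per-class means/stds of the visible
indices computed downstream land near values reported for real tailings
scenes (vegetation weakly green, bare land bright reddish, tailing sand
bright gray, water dark blue). See docs/methods.md for the calibration
rationale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .raster import GeoTransform, RGBRaster, write_raster

CLASS_NAMES = ("vegetation", "bare_land", "tailing_sand", "water")

#: order along the random-field quantiles (low field value -> first entry);
#: water sits in the lowest blobs, vegetation next to it, then bare land and
#: the tailing sand heaps — mixed vegetation/bare-soil boundaries included.
_FIELD_ORDER = ("water", "vegetation", "bare_land", "tailing_sand")


@dataclass
class SpectralModel:
    """Per-class RGB mean vectors and 3x3 covariance matrices."""

    means: dict[str, np.ndarray]
    covs: dict[str, np.ndarray]


def _cov(chroma_sd: float, brightness_sd: float) -> np.ndarray:
    # common-brightness term (rank-1, cancels in ratio indices) + independent
    # chromatic noise per channel (drives index spread)
    return brightness_sd**2 * np.ones((3, 3)) + chroma_sd**2 * np.eye(3)


def default_spectral_model() -> SpectralModel:
    """Calibrated class signatures (see module docstring)."""
    means = {
        "vegetation": np.array([95.0, 100.0, 92.0]),   # VDVI mean ~ 0.034
        "bare_land": np.array([148.0, 152.0, 132.0]),  # VDVI mean ~ 0.041
        "tailing_sand": np.array([192.0, 198.0, 188.0]),  # VDVI mean ~ 0.021
        "water": np.array([80.0, 70.0, 150.0]),        # VDVI mean ~ -0.24
    }
    covs = {
        "vegetation": _cov(12.0, 18.0),
        "bare_land": _cov(2.5, 10.0),
        "tailing_sand": _cov(1.5, 8.0),
        "water": _cov(3.0, 10.0),
    }
    return SpectralModel(means, covs)


def default_class_fractions() -> dict[str, float]:
    return {"vegetation": 0.36, "bare_land": 0.34, "tailing_sand": 0.22, "water": 0.08}


@dataclass
class SceneConfig:
    rows: int = 256
    cols: int = 256
    pixel_size: float = 0.08            # m/pixel
    class_fractions: dict[str, float] = field(default_factory=default_class_fractions)
    relief: float = 140.0               # m of elevation range
    point_density: float = 214.36       # points/m^2
    spectral_model: SpectralModel = field(default_factory=default_spectral_model)
    noise_sd: float = 2.0               # extra iid pixel noise (DN)
    correlation_length: float = 2.0     # m; blob smoothness of the class field
    n_terraces: int = 7                 # steps in the terraced elevation ramp
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.point_density <= 0:
            raise ValueError("point_density must be positive")
        if self.rows * self.cols < 64:
            raise ValueError("scene must have at least 64 pixels")
        fr = self.class_fractions
        if set(fr) != set(CLASS_NAMES):
            raise ValueError(f"class_fractions must cover exactly {CLASS_NAMES}")
        vals = np.array([fr[c] for c in CLASS_NAMES], dtype=float)
        if (vals < 0).any():
            raise ValueError("class fractions must be nonnegative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if self.relief < 0 or self.noise_sd < 0:
            raise ValueError("relief and noise_sd must be nonnegative")
        if self.n_terraces < 1:
            raise ValueError("n_terraces must be >= 1")


@dataclass
class PointCloud:
    """xyz (meters, scene frame) plus per-point 8-bit RGB."""

    xyz: np.ndarray   # (n, 3) float64
    rgb: np.ndarray   # (n, 3) uint8

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64).reshape(-1, 3)
        self.rgb = np.asarray(self.rgb).reshape(-1, 3)
        if len(self.xyz) != len(self.rgb):
            raise ValueError("xyz and rgb must have the same length")
        if not np.isfinite(self.xyz).all():
            raise ValueError("point coordinates must be finite")

    @property
    def total_count(self) -> int:
        return len(self.xyz)

    def write_csv(self, path) -> None:
        data = np.column_stack([self.xyz, self.rgb.astype(np.float64)])
        np.savetxt(
            str(path),
            data,
            delimiter=",",
            header="x,y,z,r,g,b",
            comments="",
            fmt=["%.4f", "%.4f", "%.4f", "%d", "%d", "%d"],
        )

    @classmethod
    def read_csv(cls, path) -> "PointCloud":
        data = np.loadtxt(str(path), delimiter=",", skiprows=1, ndmin=2)
        return cls(data[:, :3], data[:, 3:6].astype(np.uint8))


@dataclass
class Scene:
    rgb: RGBRaster
    elevation: np.ndarray
    slope: np.ndarray
    truth_mask: np.ndarray       # (rows, cols) of class-name strings
    cloud: PointCloud
    truth_fvc: float             # percent
    config: SceneConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tr = self.rgb.transform
        write_raster(outdir / "rgb.tif", self.rgb.bands, tr)
        write_raster(outdir / "elevation.tif", self.elevation.astype(np.float32), tr)
        write_raster(outdir / "slope.tif", self.slope.astype(np.float32), tr)
        codes = class_codes(self.truth_mask)
        write_raster(
            outdir / "truth_mask.tif",
            codes.astype(np.uint8),
            tr,
            meta={"classes": list(CLASS_NAMES)},
        )
        self.cloud.write_csv(outdir / "cloud.csv")
        sidecar = {
            "truth_fvc_percent": self.truth_fvc,
            "config": {
                "rows": self.config.rows,
                "cols": self.config.cols,
                "pixel_size": self.config.pixel_size,
                "class_fractions": self.config.class_fractions,
                "relief": self.config.relief,
                "point_density": self.config.point_density,
                "noise_sd": self.config.noise_sd,
                "correlation_length": self.config.correlation_length,
                "n_terraces": self.config.n_terraces,
                "seed": self.config.seed,
            },
        }
        (outdir / "scene.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def class_codes(truth_mask: np.ndarray) -> np.ndarray:
    """Map a class-name raster to integer codes in CLASS_NAMES order."""
    codes = np.zeros(truth_mask.shape, dtype=np.int64)
    for i, name in enumerate(CLASS_NAMES):
        codes[truth_mask == name] = i
    return codes


def _class_field(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Blob-shaped class map via quantile thresholding of a smoothed GRF."""
    noise = rng.standard_normal((config.rows, config.cols))
    sigma_px = max(config.correlation_length / config.pixel_size, 1.0)
    fld = gaussian_filter(noise, sigma=sigma_px, mode="reflect")
    # tiny deterministic dither breaks exact ties so quantiles hit fractions
    fld = fld + 1e-9 * rng.standard_normal(fld.shape)
    fractions = np.array([config.class_fractions[c] for c in _FIELD_ORDER])
    cuts = np.quantile(fld, np.cumsum(fractions)[:-1])
    idx = np.searchsorted(cuts, fld, side="right")
    mask = np.empty(fld.shape, dtype=object)
    for i, name in enumerate(_FIELD_ORDER):
        mask[idx == i] = name
    return mask.astype("U12")


def _terraced_elevation(config: SceneConfig) -> np.ndarray:
    """Stepped ramp spanning exactly ``relief`` meters (flat treads, steep risers)."""
    rows, cols = config.rows, config.cols
    base = np.linspace(1.0, 0.0, rows)[:, None] * np.ones((1, cols))
    step = 1.0 / config.n_terraces
    tread = np.floor(base / step) * step
    residual = base - tread
    elev = tread + 0.15 * residual  # gently sloped treads, not perfectly flat
    elev = elev + 0.01 * np.linspace(0.0, 1.0, cols)[None, :]
    elev -= elev.min()
    peak = elev.max()
    if peak > 0:
        elev *= config.relief / peak
    return elev


def slope_degrees(elevation: np.ndarray, pixel_size: float) -> np.ndarray:
    """Slope in degrees: central differences inside, one-sided at borders."""
    dzdy, dzdx = np.gradient(elevation, pixel_size)
    return np.degrees(np.arctan(np.hypot(dzdx, dzdy)))


def rasterize_cloud(
    scene_rgb: RGBRaster,
    elevation: np.ndarray,
    density: float,
    seed: int | np.random.Generator = 0,
) -> PointCloud:
    """Sample a Poisson point cloud over the raster footprint.

    The expected count is footprint area (m²) × density; each point copies the
    RGB of its containing pixel and takes z from bilinear interpolation of the
    elevation grid at pixel centers.
    """
    if density <= 0:
        raise ValueError("point density must be positive")
    rows, cols = scene_rgb.shape
    if rows == 0 or cols == 0:
        raise ValueError("cannot rasterize an empty raster")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tr = scene_rgb.transform
    xmin, ymin, xmax, ymax = tr.bounds((rows, cols))
    area = (xmax - xmin) * (ymax - ymin)
    n = int(rng.poisson(area * density))
    x = rng.uniform(xmin, xmax, n)
    y = rng.uniform(ymin, ymax, n)
    row, col = tr.xy_to_rowcol(x, y)
    row = np.clip(row, 0, rows - 1)
    col = np.clip(col, 0, cols - 1)
    rgb = scene_rgb.bands[row, col]
    # fractional pixel-center coordinates for bilinear z
    u = (tr.origin_y - y) / tr.pixel_size - 0.5
    v = (x - tr.origin_x) / tr.pixel_size - 0.5
    z = map_coordinates(np.asarray(elevation, dtype=np.float64), [u, v], order=1, mode="nearest")
    return PointCloud(np.column_stack([x, y, z]), rgb)


def generate_scene(config: SceneConfig) -> Scene:
    """Generate a full synthetic scene; identical configs give identical scenes."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    truth_mask = _class_field(config, rng)
    elevation = _terraced_elevation(config)
    slope = slope_degrees(elevation, config.pixel_size)

    bands = np.zeros((config.rows, config.cols, 3), dtype=np.float64)
    model = config.spectral_model
    for name in CLASS_NAMES:
        sel = truth_mask == name
        k = int(sel.sum())
        if k == 0:
            continue
        draws = rng.multivariate_normal(model.means[name], model.covs[name], size=k,
                                        method="cholesky")
        bands[sel] = draws
    if config.noise_sd > 0:
        bands += rng.normal(0.0, config.noise_sd, bands.shape)
    bands = np.clip(np.rint(bands), 0, 255).astype(np.uint8)

    transform = GeoTransform(0.0, config.rows * config.pixel_size, config.pixel_size)
    rgb = RGBRaster(bands, transform)
    cloud = rasterize_cloud(rgb, elevation, config.point_density, rng)
    truth_fvc = 100.0 * float((truth_mask == "vegetation").mean())
    return Scene(rgb, elevation, slope, truth_mask, cloud, truth_fvc, config)


def with_vegetation_fraction(config: SceneConfig, fraction: float) -> SceneConfig:
    """Copy of a config with the vegetation fraction set and others rescaled."""
    if not 0 <= fraction <= 1:
        raise ValueError("vegetation fraction must lie in [0, 1]")
    others = {c: config.class_fractions[c] for c in CLASS_NAMES if c != "vegetation"}
    rest = sum(others.values())
    scale = (1.0 - fraction) / rest if rest > 0 else 0.0
    fr = {c: v * scale for c, v in others.items()}
    fr["vegetation"] = fraction
    if rest == 0:  # degenerate: everything was vegetation before
        fr = {c: (1.0 - fraction) / 3 for c in others}
        fr["vegetation"] = fraction
    return replace(config, class_fractions=fr)
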