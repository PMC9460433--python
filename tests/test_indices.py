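"""Visible-band indices: identities, ranges, diagnostics, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import uavfvc as uv
from uavfvc.indices import (
    INDEX_NAMES,
    INDEX_RANGES,
    IndexAudit,
    IndexHistogram,
    bimodality,
    index_histogram,
    pointwise_index,
    select_index,
)
from uavfvc.raster import RGBRaster


def _single_pixel(r, g, b):
    return RGBRaster(np.array([[[r, g, b]]], dtype=np.float64))


@pytest.mark.parametrize(
    "name,rgb,expected",
    [
        ("VDVI", (100, 100, 100), 0.0),
        ("VDVI", (0, 255, 0), 1.0),
        ("MRBVI", (0, 0, 255), -1.0),
        ("ExG", (77, 77, 77), 0.0),
        ("NGRDI", (50, 50, 13), 0.0),
        ("CIVE", (200, 200, 200), 18.769117),
        ("EGRBDI", (90, 90, 90), 0.6),
        ("MGRVI", (30, 40, 0), (1600 - 900) / (1600 + 900)),
    ],
)
def test_pointwise_identities(name, rgb, expected):
    out = uv.compute_index(_single_pixel(*rgb), name)
    assert out.values[0, 0] == pytest.approx(expected, abs=1e-6)


def test_unknown_index_rejected_with_valid_names():
    with pytest.raises(ValueError, match="NGRDI"):
        uv.compute_index(_single_pixel(1, 2, 3), "NDVI")


def test_zero_denominator_yields_nodata_not_zero():
    black = _single_pixel(0, 0, 0)
    for name in ("VDVI", "ExG", "CIVE", "NGRDI", "MRBVI", "RGBVI", "EGRBDI"):
        assert np.isnan(uv.compute_index(black, name).values[0, 0])


@settings(max_examples=200, derandomize=True)
@given(
    st.integers(0, 255), st.integers(0, 255), st.integers(0, 255),
)
def test_range_conservation_on_valid_pixels(r, g, b):
    """Every finite index value of an 8-bit pixel lies in its theoretical range."""
    raster = _single_pixel(r, g, b)
    for name in INDEX_NAMES:
        v = uv.compute_index(raster, name).values[0, 0]
        if np.isfinite(v):
            lo, hi = INDEX_RANGES[name]
            assert lo - 1e-12 <= v <= hi + 1e-12


@settings(max_examples=100, derandomize=True)
@given(
    st.floats(0.5, 255), st.floats(0.5, 255), st.floats(0.5, 255),
    st.floats(0.01, 50),
)
def test_scale_invariance_before_clipping(r, g, b, k):
    """All nine indices are invariant under (R,G,B) -> (kR,kG,kB), k > 0."""
    base = np.array([[r, g, b]])
    for name in INDEX_NAMES:
        v1 = pointwise_index(base, name)[0]
        v2 = pointwise_index(k * base, name)[0]
        assert v2 == pytest.approx(v1, rel=1e-9, abs=1e-9)


def test_class_error_stats_basics():
    vals = np.array([[0.0, 1.0], [0.5, 0.5]])
    vi = uv.VIRaster("VDVI", vals, (-1, 1))
    labels = np.array([["a", "a"], ["b", "b"]])
    stats = uv.class_error_stats(vi, labels)
    assert stats.loc["a", "mean"] == pytest.approx(0.5)
    assert stats.loc["a", "std"] == pytest.approx(0.5)     # population std
    assert stats.loc["b", "std"] == pytest.approx(0.0)
    # empty class is absent, not zero
    stats2 = uv.class_error_stats(vi, labels, class_names=["a", "b", "c"])
    assert "c" not in stats2.index
    with pytest.raises(ValueError):
        uv.class_error_stats(vi, labels[:1])


def test_vdvi_spreads_less_than_mgrvi_on_bare_land(default_scene):
    """The published error-statistics ordering: VDVI has the tighter bare-land
    signature than the squared-band MGRVI."""
    vd = uv.class_error_stats(
        uv.compute_index(default_scene.rgb, "VDVI"), default_scene.truth_mask
    )
    mg = uv.class_error_stats(
        uv.compute_index(default_scene.rgb, "MGRVI"), default_scene.truth_mask
    )
    assert vd.loc["bare_land", "std"] < mg.loc["bare_land", "std"]


def _hist_from_samples(samples, lo=-1.0, hi=1.0):
    counts, edges = np.histogram(samples, bins=256, range=(lo, hi))
    return IndexHistogram("VDVI", edges, counts)


def test_bimodality_detects_well_separated_mixture(rng):
    samples = np.concatenate(
        [rng.normal(-0.5, 0.05, 5000), rng.normal(0.5, 0.05, 5000)]
    )
    out = bimodality(_hist_from_samples(samples))
    assert out.is_bimodal and out.n_major_peaks == 2
    assert out.peak_positions[0] == pytest.approx(-0.5, abs=0.05)
    assert out.peak_positions[1] == pytest.approx(0.5, abs=0.05)


def test_bimodality_single_gaussian_and_uniform(rng):
    single = bimodality(_hist_from_samples(rng.normal(0.0, 0.1, 10000)))
    assert not single.is_bimodal and single.n_major_peaks == 1
    flat = IndexHistogram("VDVI", np.linspace(-1, 1, 257), np.full(256, 7))
    out = bimodality(flat)
    assert out.n_major_peaks == 0 and not out.is_bimodal
    with pytest.raises(ValueError):
        bimodality(IndexHistogram("VDVI", np.array([0.0, 1.0]), np.array([3])))


def test_close_peaks_merge_into_one_mode(rng):
    samples = np.concatenate(
        [rng.normal(0.0, 0.02, 5000), rng.normal(0.08, 0.02, 5000)]
    )
    out = bimodality(_hist_from_samples(samples))  # separation 0.08 < 0.1 * span 2
    assert out.n_major_peaks == 1


def test_histogram_counts_conserve_finite_pixels():
    vals = np.array([[0.1, np.nan], [-0.5, 0.9]])
    hist = index_histogram(uv.VIRaster("VDVI", vals, (-1, 1)))
    assert hist.counts.sum() == 3


def _audit(name, stds, counts, vmin=None, vmax=None):
    lo, hi = INDEX_RANGES[name]
    stats = pd.DataFrame(
        {"mean": np.zeros(len(stds)), "std": stds},
        index=["vegetation", "bare_land", "tailing_sand", "water"],
    )
    edges = np.linspace(lo, hi, len(counts) + 1)
    return IndexAudit(
        name=name,
        stats=stats,
        histogram=IndexHistogram(name, edges, np.asarray(counts)),
        value_min=lo if vmin is None else vmin,
        value_max=hi if vmax is None else vmax,
        theoretical_range=(lo, hi),
    )


def _bimodal_counts(n=256):
    x = np.linspace(-1, 1, n)
    return (
        1000 * np.exp(-((x + 0.5) ** 2) / 0.005)
        + 1000 * np.exp(-((x - 0.5) ** 2) / 0.005)
    ).astype(int)


def _unimodal_counts(n=256):
    x = np.linspace(-1, 1, n)
    return (1000 * np.exp(-(x**2) / 0.005)).astype(int)


def test_select_index_forced_single_survivor():
    audits = {}
    for name in INDEX_NAMES:
        if name == "NGBDI":
            audits[name] = _audit(name, [0.2] * 4, _bimodal_counts())
        elif name == "VDVI":
            audits[name] = _audit(name, [0.01] * 4, _bimodal_counts(), vmax=1.5)
        else:
            audits[name] = _audit(name, [0.01] * 4, _unimodal_counts())
    report = select_index(audits)
    assert report.chosen == "NGBDI"
    assert "outside theoretical range" in report.eliminated["VDVI"]
    assert report.eliminated["NGRDI"].startswith("not bimodal")


def test_select_index_tie_breaks_in_canonical_order():
    audits = {n: _audit(n, [0.1] * 4, _bimodal_counts()) for n in INDEX_NAMES}
    report = select_index(audits)
    assert report.chosen == INDEX_NAMES[0]
    assert report.ranking == list(INDEX_NAMES)


def test_select_index_all_eliminated_raises():
    audits = {n: _audit(n, [0.1] * 4, _unimodal_counts()) for n in INDEX_NAMES}
    with pytest.raises(ValueError, match="eliminated"):
        select_index(audits)


def test_default_scene_selects_vdvi(default_scene):
    """On the calibrated synthetic scene the full selection procedure ranks
    VDVI first, matching the published choice for tailings-site mapping."""
    report, audits = uv.run_index_selection(
        default_scene.rgb, default_scene.truth_mask, uv.CLASS_NAMES
    )
    assert report.chosen == "VDVI"
    # in-range step can never fire on exact arithmetic; survivors are ranked
    assert all(audits[n].in_range for n in INDEX_NAMES)
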