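"""Noise-reduction stages (a)-(d) and channel assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specphenonet.mgf_io import METABOLOMIC, PROTEOMIC, SpectraFile
from specphenonet.preprocessing import (FeatureStream, FeatureVocabulary,
                                        MinMaxStats, PreprocessConfig,
                                        build_vocabulary,
                                        elliptic_envelope_filter,
                                        extract_features, filter_rare_features,
                                        fit_minmax, minmax_scale, quantize_mz,
                                        quantize_stream, to_model_channels)

from .conftest import make_file, make_spectrum

CFG = PreprocessConfig(channel_length=16)


def stream_of(mz, intensity=None, rt=None, layer=PROTEOMIC):
    mz = np.asarray(mz, dtype=float)
    if intensity is None:
        intensity = np.ones_like(mz)
    if rt is None:
        rt = np.zeros_like(mz)
    return FeatureStream(layer, np.asarray(rt, float), mz,
                         np.asarray(intensity, float))


# ---------------------------------------------------------------------------
# (a) extraction

def test_extract_snaps_rt_to_grid():
    sf = SpectraFile("f", PROTEOMIC,
                     [make_spectrum(1.04, [100.0, 200.0], [5.0, 7.0])])
    s = extract_features(sf, CFG)
    np.testing.assert_allclose(s.rt, [1.0, 1.0])
    np.testing.assert_allclose(s.mz, [100.0, 200.0])
    np.testing.assert_allclose(s.intensity, [5.0, 7.0])


def test_extract_empty_file_gives_empty_stream():
    s = extract_features(SpectraFile("f", PROTEOMIC, []), CFG)
    assert len(s) == 0


def test_extract_sorts_by_rt_then_mz():
    rng = np.random.default_rng(0)
    spectra = [make_spectrum(rng.uniform(0, 50), rng.uniform(100, 2000, 10))
               for _ in range(100)]
    sf = SpectraFile("f", PROTEOMIC, spectra)
    s = extract_features(sf, CFG)
    assert len(s) == 1000
    # brute-force oracle: lexicographic sort of the raw triples
    raw = sorted(
        (np.round(sp.rt_seconds / 0.1) * 0.1, m)
        for sp in spectra for m in sp.mz
    )
    np.testing.assert_allclose(s.rt, [r for r, _ in raw])
    np.testing.assert_allclose(s.mz, [m for _, m in raw])


# ---------------------------------------------------------------------------
# (c) ppm quantization

def test_quantize_error_bound_at_500():
    _, rep = quantize_mz(500.0, 10.0)
    assert abs(rep - 500.0) <= 0.0025 + 1e-9


def test_quantize_nearby_values_share_bin():
    # values within a quarter bin width of a bin center share its bin
    b0, rep = quantize_mz(500.0, 10.0)
    for delta_ppm in (-2.0, 2.0):
        b, _ = quantize_mz(rep * (1 + delta_ppm * 1e-6), 10.0)
        assert b == b0


def test_quantize_idempotent():
    bins, rep = quantize_mz(np.array([123.456, 987.654]), 10.0)
    bins2, rep2 = quantize_mz(rep, 10.0)
    np.testing.assert_array_equal(bins, bins2)
    np.testing.assert_array_equal(rep, rep2)


def test_quantize_rejects_nonpositive():
    with pytest.raises(ValueError):
        quantize_mz(0.0, 10.0)


@settings(max_examples=200, deadline=None)
@given(st.floats(min_value=50.0, max_value=2000.0),
       st.sampled_from([10.0, 100.0]))
def test_quantize_relative_error_within_ppm(mz, ppm):
    _, rep = quantize_mz(mz, ppm)
    assert abs(rep - mz) / mz <= ppm * 1e-6


# ---------------------------------------------------------------------------
# (b) rare-feature elimination

def _vocab_from_counts(counts, ppm=10.0):
    return FeatureVocabulary(layer=PROTEOMIC, ppm=ppm, counts=counts)


def test_filter_keeps_only_bins_exceeding_threshold():
    mzs = [100.0, 200.0, 300.0, 400.0]
    bins = [quantize_mz(m, 10.0)[0] for m in mzs]
    vocab = _vocab_from_counts(dict(zip(bins, [1, 2, 3, 5])))
    stream = stream_of(mzs)
    (out,) = filter_rare_features([stream], vocab, min_frequency=2)
    kept_bins = set(quantize_mz(out.mz, 10.0)[0])
    assert kept_bins == {bins[2], bins[3]}


def test_filter_unchanged_when_all_frequent():
    mzs = [100.0, 200.0]
    bins = [quantize_mz(m, 10.0)[0] for m in mzs]
    vocab = _vocab_from_counts({b: 10 for b in bins})
    (out,) = filter_rare_features([stream_of(mzs)], vocab, 2)
    assert len(out) == 2


def test_single_file_dataset_loses_everything():
    sf = make_file(20, seed=1)
    stream, _ = quantize_stream(extract_features(sf, CFG), 10.0)
    vocab = build_vocabulary([stream], PROTEOMIC, 10.0)
    assert all(c == 1 for c in vocab.counts.values())
    (out,) = filter_rare_features([stream], vocab, 2)
    assert len(out) == 0


def test_filter_idempotent():
    rng = np.random.default_rng(2)
    streams = [stream_of(rng.uniform(100, 2000, 50)) for _ in range(6)]
    streams = [quantize_stream(s, 10.0)[0] for s in streams]
    vocab = build_vocabulary(streams, PROTEOMIC, 10.0)
    once = filter_rare_features(streams, vocab, 2)
    twice = filter_rare_features(once, vocab, 2)
    for a, b in zip(once, twice):
        np.testing.assert_array_equal(a.mz, b.mz)


# ---------------------------------------------------------------------------
# (d) min-max scaling

def test_minmax_basic_mapping():
    stats = MinMaxStats(0.0, 1.0, 10.0, 30.0)
    out = minmax_scale(stream_of([0.5, 1.0], [10.0, 20.0]), stats)
    np.testing.assert_allclose(out.intensity, [0.0, 0.5])


def test_minmax_clips_outside_fitted_range():
    stats = MinMaxStats(100.0, 200.0, 1.0, 2.0)
    out = minmax_scale(stream_of([50.0, 300.0], [0.5, 5.0]), stats)
    np.testing.assert_allclose(out.mz, [0.0, 1.0])
    np.testing.assert_allclose(out.intensity, [0.0, 1.0])


def test_minmax_constant_channel_maps_to_zero():
    stats = MinMaxStats(100.0, 100.0, 1.0, 2.0)
    out = minmax_scale(stream_of([100.0, 100.0]), stats)
    np.testing.assert_allclose(out.mz, [0.0, 0.0])


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_minmax_outputs_in_unit_interval(seed):
    rng = np.random.default_rng(seed)
    streams = [stream_of(rng.uniform(50, 2000, 20), rng.lognormal(0, 2, 20))
               for _ in range(3)]
    stats = fit_minmax(streams[:2])        # deliberately not fit on all
    for s in streams:
        out = minmax_scale(s, stats)
        assert out.mz.min() >= 0 and out.mz.max() <= 1
        assert out.intensity.min() >= 0 and out.intensity.max() <= 1
        assert len(out) == len(s)
        np.testing.assert_array_equal(out.rt, s.rt)


def test_fit_minmax_empty_source_errors():
    with pytest.raises(ValueError):
        fit_minmax([stream_of([])])


# ---------------------------------------------------------------------------
# (d) elliptic envelope

def test_envelope_removes_planted_outliers():
    rng = np.random.default_rng(0)
    inliers = rng.multivariate_normal([0.5, 0.5], np.diag([0.01, 0.01]), 980)
    outliers = rng.uniform(5, 10, (20, 2))      # > 10 sigma away
    X = np.vstack([inliers, outliers])
    stream = stream_of(X[:, 0], X[:, 1])
    out = elliptic_envelope_filter(stream, 0.2, seed=0)
    assert len(stream) - len(out) <= 200
    assert np.sum(out.mz > 4) == 0              # 100% outlier recall


def test_envelope_small_stream_passthrough():
    s = stream_of(np.arange(10, dtype=float) + 100)
    out = elliptic_envelope_filter(s, 0.2, seed=0)
    assert out is s


def test_envelope_degenerate_cloud_passthrough():
    s = stream_of(np.full(50, 100.0), np.full(50, 1.0))
    with pytest.warns(UserWarning):
        out = elliptic_envelope_filter(s, 0.2, seed=0)
    assert len(out) == 50


@pytest.mark.parametrize("n", [30, 101, 500])
def test_envelope_removed_fraction_never_exceeds_cutoff(n):
    rng = np.random.default_rng(n)
    s = stream_of(rng.normal(0.5, 0.1, n), rng.normal(0.5, 0.1, n))
    out = elliptic_envelope_filter(s, 0.2, seed=1)
    assert (n - len(out)) / n <= 0.2


# ---------------------------------------------------------------------------
# channel assembly

def test_channels_equal_length_stream_passthrough():
    p = stream_of(np.linspace(0.1, 0.9, 16), np.linspace(0, 1, 16))
    m = stream_of(np.linspace(0.2, 0.8, 16), np.linspace(1, 0, 16),
                  layer=METABOLOMIC)
    ch = to_model_channels(p, m, CFG)
    assert ch.shape == (4, 16)
    np.testing.assert_allclose(ch[0], p.mz)
    np.testing.assert_allclose(ch[3], m.intensity)


def test_channels_double_length_keeps_every_other():
    vals = np.arange(32, dtype=float)
    p = stream_of(vals, vals)
    m = stream_of(vals[:16], vals[:16], layer=METABOLOMIC)
    ch = to_model_channels(p, m, CFG)
    np.testing.assert_allclose(ch[0], vals[::2])


def test_channels_short_stream_zero_padded():
    p = stream_of(np.full(10, 0.5))
    m = stream_of(np.full(10, 0.5), layer=METABOLOMIC)
    ch = to_model_channels(p, m, CFG)
    np.testing.assert_allclose(ch[0, 10:], 0.0)
    assert np.count_nonzero(ch[0]) == 10


def test_channels_both_empty_errors():
    with pytest.raises(ValueError):
        to_model_channels(stream_of([]), stream_of([], layer=METABOLOMIC), CFG)
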