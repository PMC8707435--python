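"""Noise reduction and channel assembly for the 1D classifier.

The stages, applied in order to a labeled mgf cohort:

(a) feature extraction — every fragment peak becomes an (RT, m/z, intensity)
    triple, RT snapped to a 0.1 s grid;
(b) rare-feature elimination — m/z bins present in too few files of the
    dataset are dropped (strictly "frequency must exceed" the threshold);
(c) ppm quantization — m/z rounded onto log-spaced bins, 10 ppm for the
    proteomic layer and 100 ppm for the metabolomic one;
(d) min-max scaling of m/z and intensity to [0, 1], followed by robust
    elliptic-envelope outlier removal at a 0.2 cut-off.

Internally quantization runs before the frequency filter (counting requires
quantized bins) which preserves the stated semantics of (b) and (c).
The output of the stack is four fixed-length channels per subject:
proteomic m/z, proteomic intensity, metabolomic m/z, metabolomic intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from sklearn.covariance import EllipticEnvelope

from .mgf_io import METABOLOMIC, PROTEOMIC, SpectraFile


@dataclass
class PreprocessConfig:
    rt_step: float = 0.1
    ppm_tolerance_proteomic: float = 10.0
    ppm_tolerance_metabolomic: float = 100.0
    min_feature_frequency: int = 2      # strict: keep bins with frequency > this
    outlier_fraction: float = 0.2
    channel_length: int = 2 ** 15
    envelope_min_points: int = 25

    def __post_init__(self) -> None:
        if self.rt_step <= 0:
            raise ValueError("rt_step must be positive")
        if not (0 < self.outlier_fraction < 0.5):
            raise ValueError("outlier_fraction must lie in (0, 0.5)")
        if self.ppm_tolerance_proteomic <= 0 or self.ppm_tolerance_metabolomic <= 0:
            raise ValueError("ppm tolerances must be positive")

    def ppm_for(self, layer: str) -> float:
        return (
            self.ppm_tolerance_proteomic
            if layer == PROTEOMIC
            else self.ppm_tolerance_metabolomic
        )


@dataclass
class FeatureStream:
    """Parallel (rt, mz, intensity) arrays for one file and layer."""

    layer: str
    rt: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray
    file_id: str = ""

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (len(self.rt) == len(self.mz) == len(self.intensity)):
            raise ValueError("rt, mz and intensity must be parallel arrays")

    def __len__(self) -> int:
        return int(self.rt.size)


@dataclass
class FeatureVocabulary:
    """Per-layer m/z bin occurrence counts across the files of a dataset."""

    layer: str
    ppm: float
    counts: dict[int, int] = field(default_factory=dict)

    def frequency(self, bin_id: int) -> int:
        return self.counts.get(bin_id, 0)


def extract_features(sf: SpectraFile, cfg: PreprocessConfig) -> FeatureStream:
    """Stage (a): flatten all fragment peaks to RT-grid-aligned triples."""
    rts, mzs, ints = [], [], []
    for s in sf.spectra:
        if len(s) == 0:
            continue
        grid_rt = np.round(s.rt_seconds / cfg.rt_step) * cfg.rt_step
        rts.append(np.full(len(s), grid_rt))
        mzs.append(s.mz)
        ints.append(s.intensity)
    if not rts:
        empty = np.empty(0)
        return FeatureStream(sf.omics_layer, empty, empty.copy(), empty.copy(),
                             file_id=sf.file_id)
    rt = np.concatenate(rts)
    mz = np.concatenate(mzs)
    inten = np.concatenate(ints)
    order = np.lexsort((mz, rt))
    return FeatureStream(sf.omics_layer, rt[order], mz[order], inten[order],
                         file_id=sf.file_id)


def quantize_mz(mz, ppm: float):
    """Stage (c): round m/z onto multiplicative (log-spaced) ppm bins.

    Bin ``k`` covers ``[r^k, r^(k+1))`` with ``r = 1 + ppm*1e-6``; the
    representative is the geometric bin center ``r^(k+0.5)``, so the relative
    rounding error never exceeds half the ppm tolerance (plus float slack).

    Returns ``(bin_id, representative_mz)``; accepts scalars or arrays.
    """
    arr = np.asarray(mz, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("m/z values must be positive")
    log_ratio = np.log1p(ppm * 1e-6)
    bins = np.floor(np.log(arr) / log_ratio).astype(np.int64)
    representative = np.exp((bins + 0.5) * log_ratio)
    if np.isscalar(mz):
        return int(bins), float(representative)
    return bins, representative


def quantize_stream(stream: FeatureStream, ppm: float) -> tuple[FeatureStream, np.ndarray]:
    """Replace m/z by bin representatives; also return the bin ids."""
    if len(stream) == 0:
        return stream, np.empty(0, dtype=np.int64)
    bins, rep = quantize_mz(stream.mz, ppm)
    return replace(stream, mz=rep), bins


def build_vocabulary(streams: Iterable[FeatureStream], layer: str, ppm: float) -> FeatureVocabulary:
    """Count, per m/z bin, the number of distinct files containing the bin."""
    vocab = FeatureVocabulary(layer=layer, ppm=ppm)
    for stream in streams:
        if stream.layer != layer or len(stream) == 0:
            continue
        bins, _ = quantize_mz(stream.mz, ppm)
        for b in np.unique(bins):
            vocab.counts[int(b)] = vocab.counts.get(int(b), 0) + 1
    return vocab


def filter_rare_features(
    streams: list[FeatureStream],
    vocab: FeatureVocabulary,
    min_frequency: int = 2,
) -> list[FeatureStream]:
    """Stage (b): drop triples whose m/z bin occurs in <= min_frequency files."""
    keep_bins = {b for b, c in vocab.counts.items() if c > min_frequency}
    out = []
    for stream in streams:
        if len(stream) == 0:
            out.append(stream)
            continue
        bins, _ = quantize_mz(stream.mz, vocab.ppm)
        mask = np.isin(bins, np.fromiter(keep_bins, dtype=np.int64, count=len(keep_bins))
                       ) if keep_bins else np.zeros(len(stream), bool)
        out.append(
            replace(stream, rt=stream.rt[mask], mz=stream.mz[mask],
                    intensity=stream.intensity[mask])
        )
    return out


@dataclass
class MinMaxStats:
    """Fitted per-layer min/max for the m/z and intensity channels."""

    mz_min: float
    mz_max: float
    intensity_min: float
    intensity_max: float


def fit_minmax(streams: Iterable[FeatureStream]) -> MinMaxStats:
    mzs = [s.mz for s in streams if len(s)]
    if not mzs:
        raise ValueError("cannot fit min-max statistics on an empty source")
    ints = [s.intensity for s in streams if len(s)]
    mz_all = np.concatenate(mzs)
    int_all = np.concatenate(ints)
    return MinMaxStats(
        float(mz_all.min()), float(mz_all.max()),
        float(int_all.min()), float(int_all.max()),
    )


def _scale(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi <= lo:
        return np.zeros_like(x)
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def minmax_scale(stream: FeatureStream, stats: MinMaxStats) -> FeatureStream:
    """Stage (d), first half: map m/z and intensity into [0, 1] with clipping."""
    return replace(
        stream,
        mz=_scale(stream.mz, stats.mz_min, stats.mz_max),
        intensity=_scale(stream.intensity, stats.intensity_min, stats.intensity_max),
    )


def elliptic_envelope_filter(
    stream: FeatureStream,
    outlier_fraction: float = 0.2,
    seed: int = 0,
    min_points: int = 25,
    fit_subsample: int = 600,
) -> FeatureStream:
    """Stage (d), second half: robust-covariance outlier removal.

    A minimum-covariance-determinant ellipsoid is fitted on the (m/z,
    intensity) pairs and exactly ``floor(outlier_fraction * n)`` points with
    the largest Mahalanobis distance are removed, so the removed fraction
    never exceeds the cut-off.  Streams below ``min_points`` and degenerate
    point clouds pass through unchanged.

    The MCD fit scales poorly with n, so for long streams the robust location
    and covariance are estimated on a seeded random subsample of
    ``fit_subsample`` points; Mahalanobis distances (and hence the removal
    set) are still computed for every point.
    """
    n = len(stream)
    if n < min_points:
        return stream
    X = np.column_stack((stream.mz, stream.intensity))
    if np.allclose(X.std(axis=0), 0.0):
        warnings.warn("degenerate (constant) feature cloud; envelope filter skipped")
        return stream
    k = int(np.floor(outlier_fraction * n))
    if k == 0:
        return stream
    est = EllipticEnvelope(
        contamination=outlier_fraction, random_state=seed, support_fraction=None
    )
    if n > fit_subsample:
        sub_idx = np.random.default_rng(seed).choice(n, fit_subsample, replace=False)
        X_fit = X[sub_idx]
    else:
        X_fit = X
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            est.fit(X_fit)
        except ValueError:
            warnings.warn("covariance fit failed; envelope filter skipped")
            return stream
    dist = est.mahalanobis(X)
    cut = np.argsort(dist, kind="stable")[: n - k]
    cut.sort()
    return replace(stream, rt=stream.rt[cut], mz=stream.mz[cut],
                   intensity=stream.intensity[cut])


def _resample(x: np.ndarray, length: int) -> np.ndarray:
    """Uniform order-preserving subsample (or zero right-pad) to `length`."""
    n = x.size
    if n == length:
        return x.astype(float)
    if n > length:
        idx = (np.arange(length) * n) // length
        return x[idx].astype(float)
    out = np.zeros(length)
    out[:n] = x
    return out


def to_model_channels(
    proteomic: FeatureStream,
    metabolomic: FeatureStream,
    cfg: PreprocessConfig,
) -> np.ndarray:
    """Assemble the four fixed-length model channels.

    Channel order: proteomic m/z, proteomic intensity, metabolomic m/z,
    metabolomic intensity — shape ``(4, channel_length)``.  RT orders the
    streams but is not itself a channel.
    """
    if len(proteomic) == 0 and len(metabolomic) == 0:
        raise ValueError("both streams are empty; nothing to encode")
    L = cfg.channel_length
    return np.stack(
        [
            _resample(proteomic.mz, L),
            _resample(proteomic.intensity, L),
            _resample(metabolomic.mz, L),
            _resample(metabolomic.intensity, L),
        ]
    )


def preprocess_cohort(
    files: Mapping[str, dict[str, SpectraFile]],
    cfg: PreprocessConfig,
    seed: int = 0,
    stats_source: str = "train_only",
    train_ids: set[str] | None = None,
) -> dict[str, np.ndarray]:
    """Run stages (a)-(d) over a cohort and emit per-subject channel arrays.

    Parameters
    ----------
    files:
        ``{file_id: {"proteomic": SpectraFile, "metabolomic": SpectraFile}}``.
    stats_source:
        ``"train_only"`` fits min-max and the vocabularies on the training
        subjects only (leakage-safe, requires ``train_ids``); ``"per_dataset"``
        fits them on everything.
    """
    if stats_source not in ("train_only", "per_dataset"):
        raise ValueError(f"unknown stats_source {stats_source!r}")
    if stats_source == "train_only" and not train_ids:
        raise ValueError("train_only scaling requires train_ids")

    streams: dict[str, dict[str, FeatureStream]] = {}
    for fid, pair in files.items():
        streams[fid] = {
            layer: extract_features(pair[layer], cfg) for layer in pair
        }

    fit_ids = set(train_ids) if stats_source == "train_only" else set(files)
    out: dict[str, np.ndarray] = {}
    per_layer: dict[str, dict[str, FeatureStream]] = {}
    for layer in (PROTEOMIC, METABOLOMIC):
        ppm = cfg.ppm_for(layer)
        layer_streams = {
            fid: quantize_stream(d[layer], ppm)[0]
            for fid, d in streams.items() if layer in d
        }
        vocab = build_vocabulary(
            [s for fid, s in layer_streams.items() if fid in fit_ids], layer, ppm
        )
        fids = list(layer_streams)
        filtered = filter_rare_features(
            [layer_streams[f] for f in fids], vocab, cfg.min_feature_frequency
        )
        stats = fit_minmax([s for f, s in zip(fids, filtered) if f in fit_ids])
        rng = np.random.default_rng(seed)
        done = {}
        for f, s in zip(fids, filtered):
            scaled = minmax_scale(s, stats)
            done[f] = elliptic_envelope_filter(
                scaled, cfg.outlier_fraction,
                seed=int(rng.integers(2 ** 31)),
                min_points=cfg.envelope_min_points,
            )
        per_layer[layer] = done

    for fid in files:
        out[fid] = to_model_channels(
            per_layer[PROTEOMIC][fid], per_layer[METABOLOMIC][fid], cfg
        )
    return out
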