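"""Synthetic labeled proteomic + metabolomic mgf cohorts.

Each phenotype class is defined by a set of class-specific marker m/z values
per omics layer.  Marker peaks elute with Gaussian chromatographic envelopes
at elevated intensity over a background of (i) shared background ions common
to all classes and (ii) uniform decoy peaks with log-normal intensities.
m/z values carry ppm-scale jitter; a configurable fraction of spectra are
pure noise scans.  Pairwise marker sharing (the overlap map) controls how
similar two phenotypes look, which lets tests plant a known inter-class
geometry and check that the learned distance matrix recovers it.

Seeding is hierarchical: one master seed plus a (subject, layer) counter
derives each file's seed, so cohorts are reproducible file by file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mgf_io import CLASS_LABELS, DatasetCatalog, LAYERS, METABOLOMIC, PROTEOMIC, \
    SpectraFile, Spectrum

DEFAULT_MZ_RANGE = {PROTEOMIC: (100.0, 2000.0), METABOLOMIC: (50.0, 1000.0)}
DEFAULT_JITTER_PPM = {PROTEOMIC: 5.0, METABOLOMIC: 50.0}


@dataclass
class PhenotypeProfile:
    label: str
    marker_mz: dict            # layer -> ndarray of class marker m/z (Thomson)
    marker_rt: dict            # layer -> ndarray of elution centers (fraction of rt_span)
    marker_rt_width: dict      # layer -> ndarray of envelope widths (fraction of rt_span)
    shared_background: dict    # layer -> ndarray of m/z common to all classes
    band_modulation: dict      # layer -> abundance factor per coarse m/z band
    marker_intensity_scale: float = 5.0

    def band_factors(self, layer: str, mz: np.ndarray,
                     mz_range: tuple[float, float]) -> np.ndarray:
        """Differential-abundance factor for each peak, by its m/z band."""
        factors = np.asarray(self.band_modulation[layer], dtype=float)
        lo, hi = mz_range
        idx = np.clip(((mz - lo) / (hi - lo) * factors.size).astype(int),
                      0, factors.size - 1)
        return factors[idx]


@dataclass
class GeneratorConfig:
    n_files_per_class: int = 30
    spectra_per_file: int = 200
    rt_span: float = 967.0
    peaks_per_spectrum: float = 30.0          # Poisson mean of decoy peaks
    mz_jitter_ppm: dict = field(default_factory=lambda: dict(DEFAULT_JITTER_PPM))
    intensity_noise_sigma: float = 0.3        # log-normal sigma
    noise_spectrum_fraction: float = 0.1
    mz_range: dict = field(default_factory=lambda: dict(DEFAULT_MZ_RANGE))
    rt_drift_fraction: float = 0.005   # per-file RT drift, fraction of rt_span
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_files_per_class < 1 or self.spectra_per_file < 1:
            raise ValueError("counts must be >= 1")
        if not (0 <= self.noise_spectrum_fraction <= 1):
            raise ValueError("noise_spectrum_fraction must lie in [0, 1]")


def default_profiles(
    overlap_map: dict | None = None,
    markers_per_class: int = 12,
    n_background: int = 20,
    mz_range: dict | None = None,
    effect_size: float = 1.0,
    seed: int = 7,
) -> dict[str, PhenotypeProfile]:
    """Build the four phenotype profiles with optional pairwise marker sharing.

    ``overlap_map`` maps unordered label pairs to the number of markers the
    two classes share, e.g. ``{("RNC", "OVC"): 6}``; shared markers count
    toward each class's ``markers_per_class`` budget.  ``effect_size``
    exponentiates the differential-abundance factors: 0 silences the
    between-class abundance signal, 1 is the default strength.
    """
    overlap_map = {frozenset(k): v for k, v in (overlap_map or {}).items()}
    mz_range = mz_range or DEFAULT_MZ_RANGE
    rng = np.random.default_rng(seed)
    shared_budget = {lab: 0 for lab in CLASS_LABELS}
    for pair, k in overlap_map.items():
        for lab in pair:
            shared_budget[lab] += k
    for lab, used in shared_budget.items():
        if used > markers_per_class:
            raise ValueError(f"class {lab} overlap exceeds markers_per_class")

    def draw_mz(n, layer):
        lo, hi = mz_range[layer]
        width = hi - lo
        return rng.uniform(lo + 0.05 * width, hi - 0.05 * width, size=n)

    def draw_marker(n, layer):
        # a marker is (m/z, elution center, envelope width); the elution
        # position is a property of the analyte, reproducible across runs
        return (draw_mz(n, layer),
                rng.uniform(0.15, 0.85, size=n),
                rng.uniform(0.05, 0.12, size=n))

    marker_sets: dict[str, dict[str, list]] = {
        lab: {layer: [] for layer in LAYERS} for lab in CLASS_LABELS
    }
    for layer in LAYERS:
        for pair, k in overlap_map.items():
            shared = draw_marker(k, layer)
            for lab in pair:
                marker_sets[lab][layer].extend(zip(*shared))
        for lab in CLASS_LABELS:
            need = markers_per_class - len(marker_sets[lab][layer])
            marker_sets[lab][layer].extend(zip(*draw_marker(need, layer)))
    background = {layer: draw_mz(n_background, layer) for layer in LAYERS}

    # differential abundance: each phenotype scales whole coarse m/z bands
    # (compound families) by its own factors; classes sharing markers also
    # share the corresponding fraction of their abundance profile, so the
    # overlap map controls similarity in both presence and abundance space
    n_bands = 8
    modulation = {
        lab: {layer: np.exp(effect_size *
                            rng.uniform(-np.log(2.5), np.log(2.5), n_bands))
              for layer in LAYERS}
        for lab in CLASS_LABELS
    }
    for pair in sorted(overlap_map, key=sorted):
        k = overlap_map[pair]
        a, b = sorted(pair)
        n_share = int(round(n_bands * k / markers_per_class))
        for layer in LAYERS:
            modulation[b][layer][:n_share] = modulation[a][layer][:n_share]

    profiles = {}
    for lab in CLASS_LABELS:
        mz, rt, width = {}, {}, {}
        for layer in LAYERS:
            triples = sorted(marker_sets[lab][layer])
            mz[layer] = np.array([t[0] for t in triples])
            rt[layer] = np.array([t[1] for t in triples])
            width[layer] = np.array([t[2] for t in triples])
        profiles[lab] = PhenotypeProfile(
            label=lab, marker_mz=mz, marker_rt=rt, marker_rt_width=width,
            shared_background={layer: background[layer].copy() for layer in LAYERS},
            band_modulation={layer: modulation[lab][layer].copy()
                             for layer in LAYERS},
        )
    return profiles


def _jitter(mz: np.ndarray, ppm: float, rng: np.random.Generator) -> np.ndarray:
    if ppm == 0:
        return mz.copy()
    return mz * (1.0 + rng.uniform(-ppm, ppm, size=mz.shape) * 1e-6)


def generate_file(
    profile: PhenotypeProfile,
    layer: str,
    cfg: GeneratorConfig,
    file_seed: int,
    file_id: str | None = None,
) -> SpectraFile:
    """Generate one mgf-equivalent file for a subject of the given class."""
    lo, hi = cfg.mz_range[layer]
    markers = np.asarray(profile.marker_mz[layer], dtype=float)
    if markers.size and (markers.min() < lo or markers.max() > hi):
        raise ValueError(
            f"marker m/z outside the {layer} range ({lo}, {hi})"
        )
    rng = np.random.default_rng(file_seed)
    ppm = cfg.mz_jitter_ppm[layer]
    sigma = cfg.intensity_noise_sigma
    background = np.asarray(profile.shared_background[layer], dtype=float)

    # marker elution structure is reproducible across runs up to a small
    # per-file chromatographic drift
    drift = rng.normal(0.0, cfg.rt_drift_fraction) * cfg.rt_span
    centers = np.asarray(profile.marker_rt[layer]) * cfg.rt_span + drift
    widths = np.asarray(profile.marker_rt_width[layer]) * cfg.rt_span

    rts = np.linspace(0.0, cfg.rt_span, cfg.spectra_per_file)
    spectra = []
    fid = file_id or profile.label
    for i, rt in enumerate(rts):
        is_noise = rng.random() < cfg.noise_spectrum_fraction
        mzs, ints = [], []
        # uniform decoys; outside pure-noise scans their abundance carries
        # the phenotype's band modulation (compound families shift together)
        n_decoy = rng.poisson(cfg.peaks_per_spectrum)
        if n_decoy:
            d_mz = rng.uniform(lo, hi, size=n_decoy)
            d_int = rng.lognormal(0.0, max(sigma, 1e-9), size=n_decoy)
            if not is_noise:
                d_int = d_int * profile.band_factors(layer, d_mz, (lo, hi))
            mzs.append(d_mz)
            ints.append(d_int)
        if not is_noise:
            # shared background ions, present in most scans
            present = rng.random(background.size) < 0.6
            if present.any():
                b_mz = background[present]
                b_int = rng.lognormal(0.0, max(sigma, 1e-9),
                                      size=int(present.sum()))
                mzs.append(_jitter(b_mz, ppm, rng))
                ints.append(b_int * profile.band_factors(layer, b_mz, (lo, hi)))
            # class markers under their elution envelopes
            envelope = np.exp(-0.5 * ((rt - centers) / widths) ** 2)
            active = envelope > 0.05
            if active.any():
                amp = profile.marker_intensity_scale * envelope[active]
                noise = (rng.lognormal(0.0, sigma, size=int(active.sum()))
                         if sigma > 0 else np.ones(int(active.sum())))
                mzs.append(_jitter(markers[active], ppm, rng))
                ints.append(amp * noise)
        mz = np.concatenate(mzs) if mzs else np.empty(0)
        inten = np.concatenate(ints) if ints else np.empty(0)
        spectra.append(
            Spectrum(
                title=f"{fid} scan={i} RT={rt:.4f}",
                precursor_mz=float(rng.uniform(lo, hi)),
                rt_seconds=float(rt),
                mz=mz,
                intensity=inten,
                charge=2,
            )
        )
    return SpectraFile(
        file_id=fid, omics_layer=layer, spectra=spectra, class_label=profile.label
    )


def _file_seed(master_seed: int, subject_index: int, layer_index: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed,
                                spawn_key=(subject_index, layer_index))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_cohort(
    profiles: dict[str, PhenotypeProfile],
    cfg: GeneratorConfig,
) -> tuple[dict[str, dict[str, SpectraFile]], DatasetCatalog, dict[str, str]]:
    """Generate the paired two-layer cohort.

    Returns ``(files, catalog, ground_truth)`` where ``files`` maps
    ``file_id -> {layer: SpectraFile}``; the ground-truth label map is kept
    separate from the catalog so evaluations can be run blind.
    """
    if sorted(profiles) != sorted(CLASS_LABELS):
        raise ValueError(f"profiles must cover exactly the labels {CLASS_LABELS}")
    files: dict[str, dict[str, SpectraFile]] = {}
    catalog = DatasetCatalog()
    truth: dict[str, str] = {}
    subject = 0
    for label in CLASS_LABELS:
        profile = profiles[label]
        for j in range(cfg.n_files_per_class):
            fid = f"{label}{j:03d}"
            files[fid] = {}
            for li, layer in enumerate(LAYERS):
                sf = generate_file(
                    profile, layer, cfg,
                    file_seed=_file_seed(cfg.seed, subject, li),
                    file_id=fid,
                )
                files[fid][layer] = sf
                catalog.add(fid, layer, label)
            truth[fid] = label
            subject += 1
    return files, catalog, truth


def marker_presence_matrix(
    files: dict[str, dict[str, SpectraFile]],
    profiles: dict[str, PhenotypeProfile],
    ppm_tolerance: float = 20.0,
) -> tuple[np.ndarray, list[str]]:
    """Binary subject x marker presence matrix (both layers concatenated).

    Intended as an independent separability oracle: with disjoint markers and
    no noise a nearest-centroid classifier on these features is perfect.
    """
    all_markers = {
        layer: np.unique(np.concatenate(
            [profiles[lab].marker_mz[layer] for lab in sorted(profiles)]))
        for layer in LAYERS
    }
    fids = sorted(files)
    rows = []
    for fid in fids:
        feats = []
        for layer in LAYERS:
            targets = all_markers[layer]
            present = np.zeros(targets.size)
            mz_all = np.concatenate(
                [s.mz for s in files[fid][layer].spectra if len(s)] or [np.empty(0)]
            )
            if mz_all.size:
                for t_idx, t in enumerate(targets):
                    tol = t * ppm_tolerance * 1e-6
                    if np.any(np.abs(mz_all - t) <= tol):
                        present[t_idx] = 1.0
            feats.append(present)
        rows.append(np.concatenate(feats))
    return np.stack(rows), fids
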