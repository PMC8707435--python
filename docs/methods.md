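# Methods

## The problem

Database search assigns only a minority of acquired tandem mass spectra to
peptides or metabolites; the unassigned remainder (the "dark" proteome and
metabolome, often ~70% of scans) still carries biological signal.
`specphenonet` classifies cancer phenotypes directly from raw `mgf` peak
lists — proteomic and metabolomic layers per subject — without any
identification step. Four classes are distinguished: control (CNT), ovarian
(OVC), renal (RNC) and prostate (PRC) cancer.

## Preprocessing (1D route)

Every fragment peak of every scan becomes an (RT, m/z, intensity) triple,
with RT snapped to a 0.1 s grid. The stack applied to a cohort is:

1. **ppm quantization.** m/z values are rounded onto log-spaced bins of
   relative width 10 ppm (proteomic) or 100 ppm (metabolomic): bin `k`
   covers `[r^k, r^(k+1))` with `r = 1 + ppm·1e-6`, and the representative
   is the geometric bin center, so the rounding error never exceeds half
   the tolerance. Log-spaced bins are the natural reading of a relative
   (ppm) tolerance: the absolute bin width grows proportionally with mass.
2. **Rare-feature elimination.** A bin is kept only if it occurs in *more
   than* 2 distinct files of the dataset (strict inequality, configurable).
   Frequency is counted across files, not within a file: a feature seen in
   a single subject cannot support a cohort-level classifier. Quantization
   runs first because frequency counting requires discrete features.
3. **Min–max scaling.** m/z and intensity are mapped to [0, 1] per layer.
   Two fitting modes exist: `per_dataset` (statistics over all files —
   global scaling, the default of the end-to-end experiment) and
   `train_only` (fit on the training split, clip the rest — leakage-safe).
   At desk scale the two differ materially: the intensity maximum is a
   heavy-tail statistic, and a train-only fit misplaces the test files'
   dynamic range, costing roughly 15 accuracy points in our experiments.
4. **Elliptic-envelope noise reduction.** A robust
   minimum-covariance-determinant ellipse is fitted per file on the scaled
   (m/z, intensity) pairs and exactly `floor(0.2·n)` points with the
   largest Mahalanobis distance are removed, so the removed fraction never
   exceeds the 0.2 cut-off. The MCD location/scatter is estimated on a
   seeded subsample of at most 600 points (the fit degrades from O(n) to a
   much slower regime above that size in the underlying solver) while
   distances are scored for every point. Streams shorter than 25 points
   and degenerate (constant) clouds pass through unchanged.

The model input is four fixed-length channels — proteomic m/z, proteomic
intensity, metabolomic m/z, metabolomic intensity — obtained by uniform,
order-preserving subsampling (or zero right-padding) of the (RT, m/z)-sorted
streams. RT itself is not a channel; it only orders the stream. The default
channel length is 2^15; the desk-scale experiments use 1024.

## Augmentation

Small cohorts are enlarged at the spectrum level: the first and last 5% of
each file's scans (by RT) are excised into an augmentation database, and
replicate files are synthesized by re-inserting randomly drawn database
spectra at uniformly random RT positions within the middle 90% span of a
file (`round(0.1·N)` insertions per replicate). Database elements are pooled
per train/test split and sampled only into files of their own split; every
insertion is logged, and `audit_leakage` verifies zero cross-split
contamination against the catalog.

## Image route (3D)

For the 3D classifier a file is rendered as a sequence of 512×512 grayscale
rasters, one per 96.7 s RT window starting at RT = 0 (a 0–9476.6 s run gives
exactly 98 frames). Within a window the horizontal axis is window-relative
RT, the vertical axis is m/z (proteomic 100–2000 Th, metabolomic 50–1000 Th
by default), and brightness encodes intensity (log1p then normalized to
[0, 1]; pixel collisions aggregate by max, switchable to sum). Sequences are
padded with blank frames or truncated to exactly 98 so every file yields a
fixed-shape volume. Thirty percent of frames, chosen uniformly, receive one
random transform (shift up to ±10% per axis, zeroing of a rectangle up to
10% of the area, or crop to 90% with rescale); the rest are bit-identical.
Frames are then area-averaged to 256×256 and stacked into a (256, 256, 98)
volume.

## Models

Both classifiers are built from declarative layer tables on a compact numpy
layer framework written for this package (convolutions via
`sliding_window_view` im2col, hand-derived backward passes, Adam).

**1D residual CNN.** A kernel-32, 64-filter, stride-2 stem; four stages of
residual blocks (4, 3, 3, 4 blocks with 64, 128, 256, 512 filters); 29
convolution layers in total. Each block is conv–BN–GELU–conv–BN with the
block input added back (kernel-1 projection with BN when shape changes, not
counted as a convolution layer) and a final GELU; the first convolution of
each block carries stride 2. GELU uses the tanh approximation
`0.5x(1 + tanh(√(2/π)(x + 0.044715x³)))`. The head is average pooling
(kernel 3), global average pooling to 512 features, dropout (p = 0.3), a
512→4 dense layer and softmax. The minimum channel length imposed by the
stride cascade is checked at construction.

**3D CNN.** Eight 3D convolutions — kernels (7,9,9)×16, (5,7,7)×16,
(5,7,7)×32, (2,5,5)×32, (2,5,5)×64, (1,3,3)×128, (1,3,3)×256, (1,3,3)×512 —
each followed by batch normalization and PReLU, with max-pools (3,3,3),
(2,2,2), (2,2,2) after the first three. Pools stride by their kernel (a
stride-1 pool cannot reduce a 256×256×98 volume to the dense head's input),
and an adaptive average pool to (2,2,2) guarantees the 512·8 = 4096-wide
flatten regardless of input size, honoring both the layer table and the
dense widths 4096→64→4.

Penultimate embeddings (512-dim for 1D, 64-dim for 3D) feed the phenotype
distance matrix: Euclidean (or cosine) distance between per-class centroids
of test-set embeddings. The distance definition is deliberately isolated in
one function — it is the least constrained design choice in the pipeline.

## Training and evaluation

Multiclass cross-entropy (natural log; true-class probabilities clamped at
1e-12) with Adam, initial learning rate 1e-3, halved whenever test accuracy
fails to improve for 2 consecutive epochs; 25 epochs by default. Evaluation
reports accuracy, macro recall/F1, per-class precision/recall/F1 and the
4×4 confusion matrix in the fixed order (CNT, OVC, RNC, PRC).

## Synthetic cohorts

The generator emulates the features of real LC-MS cohorts the pipeline
depends on, per subject and per omics layer:

- **Class markers**: 12 m/z values per class per layer, eluting with
  Gaussian envelopes at 5× background intensity. Marker m/z *and* elution
  RT/width are properties of the phenotype profile — retention time is
  reproducible across runs up to a small per-file drift (0.5% of the run),
  which is the premise of RT alignment.
- **Differential abundance**: each phenotype multiplies intensities in 8
  coarse m/z bands by its own factors (log-uniform in [1/2.5, 2.5]),
  modelling compound families shifting together. An `effect_size` exponent
  scales this signal (0 silences it).
- **Overlap control**: an overlap map makes class pairs share markers (and
  the matching fraction of their abundance profile), planting a known
  inter-class geometry that the learned distance matrix should recover.
- **Noise**: Poisson-count uniform decoy peaks, log-normal intensity noise,
  uniform ppm-scale m/z jitter (5 ppm proteomic / 50 ppm metabolomic), and
  a fraction of pure-noise scans (10%).

Defaults: 30 subjects per class (paired proteomic + metabolomic files), 200
scans per file over a 967 s run; the full 9476.6 s span is exercised only by
the frame-count checks. Seeding is hierarchical (master seed + subject/layer
counter), so cohorts are reproducible file by file.

What the generator does *not* emulate: isotope envelopes, charge-state
series, fragmentation chemistry, correlated (non-uniform) noise, batch
effects, or retention-time nonlinearity. Passing tests therefore show that
the pipeline recovers planted, well-behaved class structure at desk scale —
not that it matches real-cohort performance.

## Desk-scale experiment

`pipeline.run_1d_experiment` generates a cohort, assigns a stratified 60/40
split at the subject level, preprocesses with global min–max statistics, and
trains a reduced 1D model: the same stem/stage topology with one block per
stage, filters 32/64/64/128, channel length 1024 — the smallest variant that
cleanly recovers the planted structure on one CPU in a few minutes. On the
default cohort it reaches ≥0.9 test accuracy; on a cohort with planted
overlap (RNC/OVC share 6 of 12 markers, RNC/PRC 3, OVC/PRC 1, control none)
the learned distance matrix orders pairs accordingly, with the control most
distant — mirroring, as a recoverable property rather than a numeric claim,
the qualitative geometry reported for the real cohort.

## Numerical choices and degenerate inputs

- Quantization uses `floor` binning in log space; representative values are
  exactly idempotent under re-quantization.
- Min–max scaling clips out-of-range values to [0, 1]; a constant channel
  maps to 0.
- Empty mgf files parse to empty `SpectraFile`s; empty files render as
  blank frames with a warning; a missing RT or an unterminated `BEGIN IONS`
  block is a hard, line-identified parse error.
- Batch normalization uses running statistics in evaluation mode; dropout
  is active only in training mode, so evaluation forwards are deterministic.
- Max-pool gradient goes to the first maximum on ties; the adaptive average
  pool uses floor/ceil region boundaries and tolerates inputs smaller than
  the output grid.

A caution on effect sizes: because intensity scaling is linear min–max,
raising the raw amplitude of a few marker peaks inflates the global maximum
and *compresses* the dynamic range of everything else, which can hurt
downstream accuracy rather than help it. The generator's `effect_size` knob
therefore scales the differential-abundance signal, where "more signal, no
worse accuracy" genuinely holds, rather than the marker amplitude.

## Known limitations

- Training the full-width 1D model (2^15-long channels) and the full-size
  3D forward pass are supported but impractically slow on one CPU; the
  reduced specs exist for exactly this reason and are the tested
  configurations.
- The distance-matrix definition (centroid Euclidean distance in embedding
  space) is one of several defensible choices; conclusions about class
  geometry should be robust to the metric switch (`euclidean`/`cosine`)
  before being trusted.
- The frequency filter counts file-level presence; very large cohorts with
  dense decoy collisions will retain more noise bins than small ones.
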