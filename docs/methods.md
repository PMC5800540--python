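# Methods

This note documents the models, numerical conventions and design choices
behind `betamorph`, in the spirit of a statistical-software methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Measurement model

Beta-cell volume (BCV) is estimated by the Cavalieri principle: serial
sections of thickness 0.005 mm are cut and every 30th is analyzed, so
analyzed sections are spaced 0.150 mm apart and the sampled fraction is
1/30 (≈ 3.3%, conventionally rounded to 3%). The volume is the
inter-section spacing times the sum of insulin⁺ plane areas; the two
equivalent phrasings (spacing × Σ areas, or thickness × skipped-section
count × Σ areas) are numerically identical, and no end-correction terms are
applied. `cavalieri_error_sim` quantifies the error of this systematic
subsampling on smooth organ-like area profiles (Gaussian bump, random
amplitude/center/width over 600 virtual sections, plus 2% smooth Fourier
noise, clipped at zero) with a uniform-random start offset per replicate.
Point counting (`point_count_area`) is provided as the manual alternative;
averaged over all grid offsets it is exactly unbiased, which the tests
verify by exhaustive offset enumeration.

## 2. Segmentation chain

The automatic chain reproduces a script-driven ImageJ-style workflow:

* **Auto-threshold** — iterative intermeans (Ridler–Calvard / IsoData
  family) on the 256-bin histogram: `t ← round((mean(I ≤ t) + mean(I > t))/2)`
  from a mid-range start until a fixed point. ImageJ's legacy "Default"
  threshold differs in minor histogram-edge handling; intermeans is the
  documented approximation here. Rounding is half-up (deterministic); a
  2-cycle on a discrete histogram resolves to the smaller candidate;
  iteration is capped at 256 steps. Constant images raise
  `ConstantImageError`. Foreground is strict: intensity `> t`.
* **ROI confluence** — morphological closing with the digital Euclidean
  disk `{v : |v| ≤ r}`, r = 30 px for the tissue ROI, 10 px for the insulin
  ROI. The frame is padded by r before dilation so borders behave as in an
  unbounded plane; closing is therefore extensive and idempotent, which the
  suite checks property-based. The implementation uses two exact Euclidean
  distance transforms (equivalent to disk dilation+erosion, linear time);
  equivalence with an explicit brute-force disk sweep is asserted on random
  grids. Enlarge/shrink of polygonal ROI outlines may differ sub-pixel from
  raster closing; this is unknowable from a written protocol and the raster
  semantics are the documented choice.
* **Tissue boundary** — auto-threshold of the nuclear channel, closing,
  hole filling (on by default; the tissue ROI is meant to be confluent),
  and removal of components below `min_tissue_component_px` (default 64).
* **Insulin ROI** — signal outside the tissue ROI is zeroed
  (`clear_outside`); the automatic insulin threshold is computed from the
  histogram of in-ROI pixels only (a whole-image option exists); a
  calibrated fixed threshold may be used instead. `calibrate_fixed_threshold`
  scans all 256 candidates per reference field, maximizes Dice overlap
  (smallest t on ties, favouring sensitivity to weak signal), and returns
  the lower median across fields.
* **Particle analysis** — 8-connected components (raster-order labels),
  per-particle area = pixel count × pixel\_size², equivalent diameter
  2·√(A/π); particles are kept iff the diameter strictly exceeds
  `min_diameter_mm`.

**The diameter cutoff.** The default is kept literally at 6.5×10⁻⁵ mm as
specified in the protocol being reproduced. Note that 0.065 µm is below one
pixel at any plausible calibration and below any beta-cell diameter, so the
default keeps every particle; 6.5×10⁻³ mm (6.5 µm) is the plausible
intended value and is one flag away (`--min-diameter-mm 6.5e-3`). The
package does not silently reinterpret the printed number.

**Calibration.** Pixel calibration of real acquisitions is rarely embedded
in exported TIFFs; when absent, `DEFAULT_PIXEL_SIZE_MM = 3.2e-4`
(0.32 µm/px, a typical stitched 20× field) is assumed and always
overridable.

## 3. Correction ledger

Investigator remediation is modeled as an ordered, JSON-serializable ledger
of `remove_region`/`add_region` edits with reason tags (noise,
weak\_positive, adipose, lymph\_node, outside\_tissue), applied strictly in
order (set difference / union). Replaying a saved ledger reproduces the
corrected mask bit-exactly; provenance flips to `corrected` even for an
empty ledger. `oracle_corrections` builds the ledger an idealized
investigator would produce from ground truth: automatic components with
overlap fraction < 0.5 against the true beta mask are removed (the 0.5 is a
design choice — no numeric removal criterion exists in manual practice);
true islets with no surviving automatic overlap are added back, optionally
dilated by a seeded random jitter of up to `boundary_jitter_px` to emulate
imprecise manual outlining (jitter 0 is the idealized investigator, and in
that case correction provably never decreases Dice on the simulated
sections — removed components are re-added exactly if they contained missed
islets). `export_overlay` renders the peer-evaluation composite (nuclear →
blue, insulin → green, ROI outline red, kept particle labels stamped with a
built-in 3×5 bitmap font) deterministically, so re-exports are
byte-identical.

## 4. Synthetic sections: what they emulate, and what not

`generate_section` draws, per seed: a smooth tissue blob (ellipse with
low-order Fourier radial perturbation — organ-like, Cavalieri-friendly);
nuclei as Gaussian point-spread dots at ~1 per 6×6 px of tissue (sparse in
adipose regions, 5× dense in lymph-node-like round clusters that carry no
insulin signal); disk-like islets with log-normal radii; 1–5 px bright
insulin speckles inside and outside tissue (expected count = density ×
tissue area, Poisson); a multiplicative left-to-right bleach/illumination
ramp; Poisson shot noise plus Gaussian read noise, clipped and quantized to
8 bits. A fraction of islets is "dim" (intensity scaled by 0.30): with
bright islets anchoring the intermeans threshold these fall below it — the
weak-positivity artifact. Ground truth (tissue, beta, confounder masks;
per-islet table) is exact by construction: true areas equal pixel counts ×
pixel\_size², beta ⊆ tissue, confounders disjoint from beta.

Default geometry is a deliberately scaled-down section: 512 px at 2 µm/px
(a ~1 mm field) with ~6 islets of median radius 14 µm per section, so that
full two-arm studies run in minutes on one core. Two geometry choices are
load-bearing and worth knowing about:

* **Islet spacing.** Centers are dart-thrown with a minimum edge-to-edge
  gap (default 44 µm = 22 px) above the closing diameter (2×10 px), so the
  insulin ROI confluence step never fuses distinct islets. At these scaled
  densities unconstrained placement would fuse islets routinely — an
  artifact of scaling, not of the method.
* **Islet count.** Count per section is deterministic
  (floor + Bernoulli fractional part) rather than Poisson: sampled sections
  of one pancreas are far less dispersed than Poisson, and Poisson count
  noise would dominate the between-sample variance of true volumes.

`generate_study` builds a two-group design (defaults n = 10 Sham / 12 PDL,
8 sections per sample, matching the real studies' unbalanced sizes). PDL
sections shrink the tissue blob (default ×0.7, acinar loss) and the
configured `beta_fold_effect` is realized by shifting the PDL islet-radius
log-mean so the expected count × E[πr²] ratio equals the fold exactly; the
realized PDL/Sham ratio of true volumes then converges to the configured
fold. Per-sample seeds derive from the master seed via `SeedSequence`
spawn keys; everything is a pure function of (config, seed).

**Artifact burden is heterogeneous between samples.** Each sample scales
its dim-islet fraction and speckle density by lognormal factors with mean 1
(σ = 1.2 and 0.8): most samples are nearly clean, a few are heavily
affected, as uneven staining and cumulative photobleaching produce in
practice. This right-skewed burden is what makes the automatic method's
between-sample variance exceed the corrected one without introducing a
large mean bias. The default mean rates (3% dim islets, 26 specks/mm²)
are design choices — no quantitative artifact rates exist for real
material — and are exposed as configuration, not asserted as measured.

Passing tests on these synthetics show that the pipeline's logic,
arithmetic and statistics behave as specified under a controlled artifact
model; they do not certify performance on real micrographs, which add
stitching seams, optical blur, staining chemistry and 3-D section effects
that the generator deliberately omits. Absolute simulated volumes
(~10⁻³ mm³) are at the scaled-down geometry and are not comparable to real
pancreas BCV values.

## 5. Statistics

* **Factorial ANOVA** — OLS with sum-to-zero (effect) coding and Type-III
  tests (statsmodels), appropriate for the unbalanced 10 vs 12 design;
  whole-model F against the intercept-only fit; signed t ratios for the
  single-df terms. With zero residual variance a zero-SS term reports F = 0
  (the natural limit of the noise-free case); nonzero-SS terms report ∞.
  The pairing of methods within sample (each sample measured by both
  methods) is deliberately ignored, replicating the original analysis
  choice of treating method as a between factor.
* **One-way / Welch ANOVA** — classic pooled-variance F, and Welch's
  heteroscedastic F with Welch–Satterthwaite denominator df (computable
  from summary statistics alone); for two groups these equal the squared
  pooled and Welch t. All-zero within-group variance is reported as
  degenerate rather than a number that lies.
* **Levene's test** — mean-centred (the classic form, and the default in
  common commercial ANOVA software), implemented definitionally as one-way
  ANOVA on absolute deviations from group means.
* **Power / sample size** — exact two-sample t-test power via the
  noncentral t (df = n₁+n₂−2, ncp = δ/(σ√(1/n₁+1/n₂)), two-sided rejection
  including the lower tail). `sample_size_two_means` searches balanced n
  upward from 2 for the first n with power ≥ target and reports both n per
  group and 2n total. The reference scenarios use δ = 0.10 mm³ — the
  difference of the published automated group means (0.37 − 0.27) — because
  the effect size actually used in the original power analysis is not
  stated; this inference reproduces both published sample sizes (11 and 7
  per group from SDs 0.077 and 0.059 mm³). The published "total of 21
  samples (i.e. 11 per condition)" is internally inconsistent with 2×11;
  the package reports 2n.

## 6. Reproducibility conventions

Pixel coordinates are 0-based (row, col); areas are mm², volumes mm³.
Run manifests record a config snapshot, SHA-256 of every input channel,
all thresholds and the full seed registry; identical config + seed
reproduce every numeric output bit-identically, and all intermediate
artifacts (masks, ledgers, particle tables, reports) are written to disk
for audit. Test and acceptance studies use the scaled-down default
geometry above; the acceptance script's error simulation uses 200
replicates of 600-section profiles.
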