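# Methods

`nmquant` re-implements, as a tested library, the quantification workflow
used for zebrafish lateral-line hair-cell physiology: evoked fluorescence
kinetics from genetically encoded indicators, vital-dye uptake/clearance and
ratiometric oxidation readouts, ototoxin survival assays, spontaneous
afferent spike rates, developmental-age classification, and CRISPR indel
genotyping. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## Acquisition model and preprocessing

Functional movies are T×Z×Y×X stacks; the default metadata describes rapid
five-plane z-stacks at a 50 Hz frame rate (10 Hz volume rate) with 268 nm
pixels. The preprocessing chain applied to every evoked acquisition is:

1. **Trim** — the first 10 volumes are dropped to discard the initial
   photobleaching transient; timestamps keep the acquisition clock by
   advancing the t0 offset.
2. **Register** — translation-only x-y registration by phase
   cross-correlation of each volume's z-mean projection against the first
   post-trim volume, subpixel to 0.1 px, identical shift applied to every
   plane, edge replication at the borders. Translation-only is appropriate
   for a pinned preparation; the reference frame and algorithm are package
   choices since only "registered in x-y" is specified by the protocol this
   mirrors.
3. **Project** — per-pixel mean across z (max for dye assays). The volume
   clock is preserved through projection.
4. **Baseline** — F0 is the per-pixel mean over the pre-stimulus window,
   defaulting to everything before stimulus onset; the standard prestim
   interval is 2 s (20 volumes).
5. **ΔF** — F0 subtracted from every frame, signed.
6. **Bin/overlay** — for display, ΔF is averaged in non-overlapping 0.5 s
   bins (trailing partial bins dropped so bin means stay unbiased) and
   rendered as a colormapped layer alpha-blended over the grayscale F0,
   with the blend weight equal to the series-normalized ΔF: zero change is
   pure grayscale, the series maximum is the colormap's top color.

ΔF/F0 is always formed at trace level — the ROI-mean intensity against the
ROI-mean F0 — never per pixel, so near-zero background pixels cannot blow
up the ratio.

## ROI geometry and evoked-response metrics

ROIs are circular: 3.3 µm diameter at the cell base (presynaptic
compartment; 12 px at 268 nm/px) and 1.7 µm on hair bundles (6 px).
Diameters convert to whole pixels by nearest-integer rounding with a 1 px
floor; a pixel belongs to the disk when its center lies within
diameter/2 of the ROI center. ROIs that would extend outside the image
raise rather than silently clip.

Per-cell metrics from the ROI trace, given stimulus onset:

- **peak ΔF/F0** — maximum of (trace − F0)/F0 from onset to the end of the
  recording (responses may outlast the stimulus, e.g. mitochondrial
  signals after a 4 s step);
- **duration** — time from onset to peak;
- **slope** — peak/duration, a two-point secant (the protocol's phrase
  "slope from onset to peak" is a two-point definition absent further
  detail);
- **half-life** — one-phase exponential `A·exp(−kt) + C` least-squares
  fitted from the peak onward with C free, initialized from a log-linear
  regression of the final-value-subtracted tail; half-life = ln 2/k.
  Absent (flagged) when the peak falls on the final sample or the fit
  fails to converge;
- **resting intensity** — mean raw intensity over the 2 s prestim window.

**Activity classification.** Which cells count as synaptically active is
not specified by the protocol we mirror, so the package default is the 3σ
rule: active iff peak ΔF/F0 exceeds k·σ of the prestim ΔF/F0 samples,
k = 3, configurable. Because the peak is a maximum over every post-onset
sample, a per-sample threshold alone admits isolated noise excursions
(per-cell false-positive probability ≈ 1 − Φ(k)^m for m searched samples);
the pipeline therefore additionally requires the exceedance to persist for
at least 3 consecutive volumes (0.3 s at 10 Hz). A calcium transient with
a ~1 s half-life exceeds threshold for seconds, so the sustained criterion
costs no sensitivity while making the false-positive rate negligible.

**Aggregation.** Per-neuromast values average the selected cells' metrics:
active cells only for responding genotypes, or a seeded random subset of
comparable size for genotypes without signal. No active cell yields an
explicitly flagged empty summary, never a silent zero.

## Dye and ratiometric quantification

All dye readouts share one masking convention: mean automatic thresholding
(threshold = image mean, pixels strictly above it; the single-pass variant,
not an iterative one) applied to a reference channel, and the signal
channel averaged under the mask.

- **Uptake/clearance time series** — per time point: rigid drift
  correction against the first time point (same translation registration
  as functional movies), max projection across z, rolling-ball background
  subtraction (radius 50 px) of the dye channel, mask from the reference
  channel, masked mean; ΔF is relative to the first point (imaging starts
  at dye addition). Saturating uptake is fitted as
  `I(t) = Imax·(1 − e^(−t/τ))` and washout as
  `I(t) = I0·(f + (1−f)·e^(−t/τ))`, f being the retained fraction.
- **Single-channel baselines** — the two most central z slices are
  max-projected; green-channel mask, red-channel mean; no background
  subtraction (matching the single-wavelength dye protocol).
- **Ratiometric readouts** — red/green masked-mean ratio with the mask
  always from green; rolling-ball subtraction on both channels for the
  cumulative-oxidation reporter, none for the potentiometric dye, exactly
  as the respective protocols are written.

The rolling-ball background is the surface traced by a ball rolled under
the intensity landscape — mathematically a grayscale opening with a
spherical structuring element. The implementation delegates to
scikit-image's exact rolling-ball; the test suite checks it against an
independently written grayscale-opening oracle. On a plateau narrower than
the ball the background under the feature is bounded by
r − √(r² − (w/2)²), which for the default radius (50 px) and typical cell
footprints keeps feature-height distortion well under the 5% the tests
allow.

## Survival assays

Two estimators, matching the two assay designs:

- **Paired** (fast ototoxin, same neuromast imaged before/after):
  100 × (post cells with reporter AND vital-dye label)/(eligible pre
  cells). A surviving cell must show both labels; immature cells without
  visible bundles are excluded from the denominator. Survivors exceeding
  the pre count is an error, not a clamp.
- **Group-normalized** (slow ototoxin, no pre-imaging possible): each
  treated neuromast's count as a percentage of the untreated group's mean
  count. The mean (not matched pairs) is used; per-genotype pairing is the
  caller's responsibility.

## Spontaneous spikes

Events on loose-patch current traces are detected by a robust two-sided
threshold: deviations from the trace median exceeding k·σ, with σ the
MAD-based estimate (1.4826·MAD), k = 5 by default. Supra-threshold samples
are clustered, clusters closer than the 1 ms refractory window merge, each
event is timestamped at its extremum, and an event must contain at least
two supra-threshold samples — a biphasic spike always contributes both
lobes within the refractory window, whereas an isolated single-sample
excursion is indistinguishable from noise (with the default threshold this
keeps the false-positive rate on pure noise at zero events/min in
practice). Detection is invariant to offset and polarity. Rates are
reported per minute over a 5-min window; drug experiments use the 5-min
pre-treatment and 10-min post-treatment windows. The 20 kHz default
sampling matches a 50 µs/pt acquisition; rates below the 1 kHz recording
bandwidth warn.

## Age classification and genotyping

Cells split by kinocilial height into young (< 20 µm) and mature (≥ 20 µm,
boundary inclusive on the mature side). The indel genotyper locates the
longest common prefix and suffix of two sequences; they must jointly cover
the shorter sequence (single contiguous indel), and the length difference
is the indel size — 5 bp and 8 bp for the two mutant alleles the package
ships as worked examples. The operation is symmetric in its arguments.

## Statistical decision tree

Every group is screened with the D'Agostino-Pearson normality test; an F
test of variances is reported (not acted on — a config flag enables the
Welch variant) for two-group designs. All groups passing normality at
α = 0.05 selects the parametric branch: paired/unpaired t tests; one-way
ANOVA with Dunnett (control designated) or Tukey (all pairs); two-way
ANOVA with Sidak-corrected contrasts of the first factor within each level
of the second. Any group failing selects the rank branch: Wilcoxon or
Mann-Whitney; Kruskal-Wallis with Dunn's rank-based pairwise z tests
(tie-corrected, Bonferroni-adjusted over the contrast family — written
in-house as no installed package provides it). Requiring *all* groups to
pass is the conservative reading of a per-dataset branch choice. The
normality test needs n ≥ 8; smaller groups take the rank branch with a
flag. Dispersion is always mean ± SEM (sd/√n, absent for n = 1).

The empirical type-I error of the complete choose→run pipeline, measured
on 1000 two-group null simulations (n = 15 per group), stays at or below
7% — the nominal 5% plus Monte-Carlo slack.

## Synthetic-data generator

The generator produces ground-truthed inputs with the statistical
structure the analysis assumes, so every stage is testable without any
recorded data.

- **Functional movies** — hard-disk cells (no PSF: the analysis uses disk
  ROIs, so a PSF adds no testable behavior) on a constant background.
  Active cells follow `bleach(t)·F0·(1 + dff(t))` with dff rising linearly
  over the rise time to the peak during the stimulus and decaying
  exponentially with the stated half-life; inactive cells stay flat at F0.
  Early photobleaching is `bleach(t) = 1 − b·e^(−t/τ_b)` (b = 0.15,
  τ_b = 0.3 s), which recovers to within ~0.5% of unity by the default
  trim point — the transient the trim exists to remove. Rigid per-volume
  drift is applied by first-order interpolation with edge replication, so
  integer drifts are exact pixel shifts and the register∘shift = identity
  property holds exactly away from borders. The single-plane content is
  replicated across the five z planes with independent noise, since the
  pipeline immediately projects across z. Noise is Gaussian plus a
  signal-proportional-variance term standing in for shot noise (adequate
  at the simulated intensity ranges and fast). Defaults: 200-count
  baseline, 20-count background, stimulus onset at 3 s (1 s trim allowance
  + 2 s prestim), 500 ms step.
- **Dye series** — two channels (constant reference footprint for masking
  + dye channel following the saturating/washout closed forms), one
  volume per time point on the protocol grids (every 1 min for 10 min;
  every 90 s for 30 min).
- **Spike trains** — homogeneous Poisson events (thinned to one template
  width minimum separation) of a biphasic one-period sine template on
  white Gaussian noise.
- **Survival scenarios** — Bernoulli survival per cell and class;
  survivors keep reporter and vital-dye labels, dead cells lose both; a
  configurable fraction is flagged immature.
- **Age cohorts** — young heights uniform on [2.5, 20) µm, mature uniform
  on [20, 23.5] µm, reproducing the observed 2.5–23.5 µm spread with the
  20 µm class boundary; nuclear-dye positivity marks mature cells.

Every simulator is bit-reproducible given its seed. The camera's true
noise statistics are not published, so the noise defaults are documented
stand-ins and stay configurable.

**What passing tests do and do not show.** The generator reproduces the
geometry, timing, noise structure and closed-form signal models the
analysis assumes — it does not reproduce optics (PSF, depth attenuation),
bundle mechanics, indicator nonlinearity, or biological variability
between cells beyond the parameters drawn. Recovery tests therefore
validate the estimators against their own model class and the pipeline's
bookkeeping (timing, registration, masking, fitting), not performance on
real microscopy, where model mismatch adds error the tests cannot see.

## Problem sizes and numerical choices

Simulation-based tests and the acceptance script use sizes chosen to keep
the whole suite fast while leaving the statistics conclusive: 48×48 px
single-cell movies with 100 volumes for recovery (50 seeds at 5% noise),
96–260 px movies for classification and regression checks, 200 simulated
neuromasts of 12 hair cells for survival bias, 60 s traces at 10 kHz for
spike counting (20 seeds), and 1000 null simulations for the type-I error.
Tolerances asserted: noiseless recovery to 1e-6 (peak), one volume period
(duration), 1e-3 s (half-life); registration exact for integer and
0.25 px for half-pixel drifts; oracle equivalence exact for trace/mask/mean
operations and 5% of feature height for the rolling ball. Curve fits use
scipy's Levenberg-Marquardt/TRF with closed-form-motivated
initializations; degenerate cases (constant frames, empty masks, peaks on
the final sample, zero-variance traces) are flagged or raised, never
silently zeroed.

## Known limitations

- Registration is translation-only; rotation or non-rigid motion is out
  of scope.
- No automatic cell segmentation: ROIs come from the user or from
  simulation truth.
- The activity criterion and the spike-detection parameters are package
  defaults for quantities the original protocol left unspecified; both are
  configurable and echoed in outputs.
- The rank branch of the two-factor design falls back to the two-way
  ANOVA (flagged): no standard nonparametric equivalent is prescribed by
  the conventions this mirrors.
- Headline biological numbers (survival percentages per genotype, spike
  rates, dye intensities) derive from live-animal recordings that are not
  deposited; the package validates the measurement machinery on synthetic
  ground truth instead.
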