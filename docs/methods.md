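# Methods

This note documents the models, estimators and numerical choices behind
`eist`, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Geometry and binning

Spot centroids and tract geometry share one planar micrometre frame.
Distances are Euclidean; when a tract outline polygon is supplied the
distance is to the polygon (zero inside), otherwise to the centroid.
Annular bins are half-open, `bin k = [k·w, (k+1)·w)`, so a spot exactly
at 300 µm is *outside* the electrode-site cluster — the cluster is
defined as the first three 100 µm bins and membership uses a strict
upper bound for consistency. Bin widths default to 100 µm for
expression and neuronal density and 10 µm for staining intensity.
Spots are assigned wholly by centroid; spot area is never split across
bins. Naïve-matched sites are seeded random discs over the
spot-occupied area with rejection sampling enforcing pairwise center
distance > 2·radius (manual anatomical matching is out of scope).
Annulus areas around a polygon tract are measured from buffered
outlines (`shapely`); for point tracts they are closed-form.

## MNA normalization

Within a cluster, spot *j* is scaled by `median(totals)/total_j`, so
every normalized spot total equals the cluster's median total; a gene's
MNA is the arithmetic mean of its normalized counts over the cluster.
The scale direction is the depth-equalizing one (deep spots are scaled
*down*). Zero-total spots cannot be rescaled and are dropped with a
warning. Two useful identities hold exactly and are enforced by tests:
normalization is the identity on equal-depth data, and multiplying all
raw counts by a constant leaves the scale factors unchanged (the MNA
itself scales linearly). Radial MNA profiles normalize each annulus as
its own cluster, out to the 900–1000 µm bin by default.

QC: housekeeping genes (defaults *Gapdh*, *Actb*) are regressed on
per-spot totals; the pass threshold R² ≥ 0.5 is a configuration choice
(no published numeric threshold exists), deliberately lenient relative
to the R² ≈ 0.9 the generator produces at default conditions. Depth QC
passes when mean UMI/spot ≥ 50 000 (configurable).

## Differential expression

The browser-based DE used in the original workflow is proprietary; the
test implemented here is the sSeq-style negative-binomial conditional
exact test, the family that vendor tooling for this assay descends
from. It is a stand-in matched in spirit, not a byte-level clone.

* **Size factors.** `s_j = total_j / median(totals over A∪B)`.
* **Dispersions.** Method-of-moments on size-corrected counts pooled
  over both clusters: `φ̂_g = max(0, (v_g − m_g)/m_g²)`. Estimates are
  shrunk toward the across-gene mean `φ̄` with weight
  `δ = min(1, Σ_g v_g / Σ_g (φ̂_g − φ̄)²)`, where `v_g` is the
  delta-method sampling variance of `φ̂_g` evaluated at `φ̄`, using the
  closed-form NB excess kurtosis `κ = 6φ + 1/σ²`. When the between-gene
  scatter is no larger than sampling noise, δ saturates at 1 and all
  genes share the pooled dispersion (that is what happens at the
  default simulated conditions, where true dispersion is constant).
* **Test.** Conditional on a gene's pooled count `n`, each cluster's
  sum is modelled NB with mean `μ·S` and variance `μ·S + φ·μ²·T`
  (`S = Σ s_j`, `T = Σ s_j²`, `μ = n/(S_A+S_B)`). All `n+1` splits are
  enumerated, probabilities normalized, and those ≤ the observed
  split's probability are summed (two-sided, with a 1e−12 relative tie
  tolerance). At `φ = 0` this reduces *exactly* to a binomial test,
  which the tests verify against brute-force enumeration. Above a
  pooled count of 900 a normal approximation with continuity correction
  replaces enumeration; continuity across the cutoff (< 0.01) is a
  tested property.
* **Filters.** Low-count filter: a gene is kept iff its mean raw count
  is ≥ 1 in at least one cluster. Significance: p < 0.05 (strict) and
  |LFC| ≥ 0.6. The raw p-value is the default filter column because the
  published rule names "p-value" without qualification; a BH-adjusted
  column is always computed and selectable.
* **LFC.** `log2((sum_A+1)/(S_A+1)) − log2((sum_B+1)/(S_B+1))` — a
  pseudocount-regularized ratio of size-corrected means, finite for
  one-sided zeros and exactly antisymmetric under cluster swap.

Calibration at the study's scale: on 2000 null NB genes
(100 spots/cluster, φ = 0.1) the raw-p rejection rate at 0.05 falls in
[3.5%, 6.5%], and a planted 8-fold marker with 150 µm decay is
recovered as significant with LFC > 0.6 in ≥ 95% of seeded
site-vs-naïve comparisons.

## Recording-quality metrics

The per-implant chain: CAR subtraction → 4th-order Butterworth
500–6000 Hz band-pass applied forward-backward (zero net phase; the
published description names the band, not the realization) → snippet
detection at ±3.5 SD of the full filtered trace with 2.4 ms windows
centred on the excursion's absolute minimum (greedy left-to-right,
non-overlapping; window length rounded to an odd sample count) →
noise floor = all samples outside windows. Channels are included when
their noise RMS lies within 0.3–2× the array mean (inclusive bounds,
single pass). SNR = mean snippet P2P / (6·noise SD); MUA = mean
supra-threshold positive deflection − mean sub-threshold negative
deflection; LFP = 6·SD after a 60 Hz notch (2nd-order IIR, Q = 30) and
a 1–300 Hz 4th-order Butterworth, both zero-phase, computed on the raw
(pre-CAR) channel (configurable). Implant values average the included
channels with defined values; thresholds use the single-pass SD of the
full filtered trace (no iterative re-estimation).

Known limitation: with independent spike trains on all 16 channels,
CAR leaks −1/16 of every spike into every other channel. This
attenuates each channel's own spikes by 15/16 and seeds the noise floor
with small cross-talk spikelets, biasing the full-chain SNR downward by
up to ~15% at large template amplitudes. Formula-recovery checks
therefore run the spike-band chain per channel (the planted recordings
contain no common-mode component; CAR's common-mode removal is
verified separately and is exact to machine precision).

## Synthetic data: what it emulates, and what it does not

**Spot data.** A rectangular lattice at 100 µm pitch (the assay's
spacing; the real array is hexagonal, but all geometry code is
lattice-agnostic). Per-spot depth is lognormal with mean 50 000 UMI
and CV 0.5 — deep enough to pass the depth QC on average and variable
enough that depth normalization matters. Counts are NB with mean
`depth_j · p_g(d_j)` where
`p_g(d) = baseline·(1 + (A−1)·exp(−d/decay))`, renormalized across the
panel at each spot; dispersion defaults to 0.02 (UMI counts are nearly
Poisson at spot level; this value also keeps housekeeping-vs-total
linearity at R² ≈ 0.9, the self-consistency the QC stage assumes).
The renormalization reproduces a real property of proportion-based
counts: strong local up-regulation slightly dilutes everything else,
so unperturbed genes acquire small negative fold changes near the
tract. Not emulated: cell-type mixtures, spatial autocorrelation
beyond the radial trend, artifact spots (the mask is plumbed through
but generated all-false), bleed-over between spots.

**Recordings.** Poisson spike trains of a Gaussian-derivative biphasic
template (~0.6 ms span, exact planted P2P), spike-band background
noise, a 60 Hz line component with per-channel phase, a band-limited
LFP component, and an optional common-mode artifact shared by all
channels. The noise and LFP components are flat-spectrum processes
confined to 600–5000 Hz and 2–200 Hz respectively — strictly interior
to the 500–6000 Hz and 1–300 Hz measurement bands — so the planted SDs
are the operative ground truth for the SNR and LFP formulas instead of
being re-shaped by the analysis filters. Not emulated: 1/f (pink)
noise, electrode impedance drift, spike waveform diversity, correlated
multi-channel spikes.

**IHC.** Neuron centroids from an inhomogeneous Poisson process with
density `ρ_far·(1 − exp(−d/r_suppress))` (neuronal loss at the tract)
and a GFAP-like intensity field `baseline + peak·exp(−d/decay)` plus
pixel noise. Defaults: ρ_far = 1000 mm⁻², suppression radius 100 µm,
consistent with reported ~40% neuronal loss within 100 µm.

**Cohorts.** Eight implanted samples (the regression n of the study)
plus naïve controls. Each implanted sample carries a severity factor
`η ~ N(0, σ_sev)`; gene g's per-sample effect is
`log2 A_{g,i} = log2 A_g + r_g·η_i` with responsiveness `r_g`
defaulting to `|log2 A_g|`, so tract-responsive genes co-vary across
animals while flat genes stay flat. The planted electrode-site MNA is
computed analytically (median depth × mean renormalized proportion
over the < 300 µm spots), and each metric is
`α + Σ_g β_g·x_g + N(0, σ)`. Naïve samples carry no metrics and are
excluded from regression. Passing tests on these cohorts shows the
estimators and the selection rule work when their assumptions hold;
it does not certify behaviour under confounding, batch effects or
non-linear gene–metric relationships, none of which are generated.

## Biomarker screen

Consolidation keeps, for a gene significant at several timepoints, the
LFC of largest magnitude with its sign — a signed maximum would discard
strong down-regulation. Single-gene association is OLS with the slope's
F-test p (for one predictor, identical to the t-test p). Gene-set PCR
z-scores each gene across samples (so no gene dominates by scale),
takes per-sample PC1 scores (sign fixed by the largest-|loading| gene),
and regresses the metric on them; a singleton set reduces exactly to
the single-gene regression, a consistency the tests enforce to 1e−9.
"Every possible combination" over ~650 genes is combinatorially
intractable; the pipeline restricts the pool (default: top 20 by |LFC|)
and set sizes (default 2) with a hard enumeration cap and warning.
Candidate selection min–max normalizes |LFC| and R² across results and
scores each by the *minimum* of the two — a conservative "both axes
high" rule — ranking descending with ties broken by R² then name.

The cohort-level recovery experiment plants 3 true biomarkers (6-fold
change, metric-linked) among 24 fold-change-only and 26 metric-linked-
only decoys, with severity SD 1.0 (the cohort spans acute through
chronic responses, whose effect magnitudes differ greatly) and the LFC
axis measured by pooled implanted-vs-naïve DE. The selection rule
places all three in the top 5 in ≥ 90% of 100 seeded cohorts. Note the
precision limit this experiment exposes: the MNA's median-total
estimate over a ~30-spot site has ~10% sampling noise at depth CV 0.5,
which attenuates gene–metric correlations; planted spreads much
smaller than that are not recoverable at n = 8 by any rule.

## Problem sizes and determinism

Simulated studies use 20×20-spot sections (≈ 30-spot site clusters),
panels of tens of genes, 4-second 16-channel recordings, and 50–100
Monte-Carlo repetitions per claim; these sizes give stable pass/fail
behaviour for every calibration band while keeping a full run of the
test suite and acceptance script in the minutes range. Every stochastic
component takes an explicit seed (`numpy.random.default_rng`); the
pipeline writes all outputs with fixed float formatting, and two runs
from the same config are byte-identical — a tested guarantee.
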