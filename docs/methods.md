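# Methods

This note documents the models, conventions and numerical choices behind
each `calmkit` module, what the synthetic generators do and do not
emulate, and the known limitations.

## Transcript quantification

FPKM is computed as `count / (length_kb * library_millions)`; isoform
counts are pooled per gene before the call. The mutant transcript share
combines two independent measurements: the allelic read split at the
tagging variant (a binomial sample of the within-Calm1 allele ratio) and
the gene-level FPKM vector. Because the three Calm genes encode an
identical protein, `share = alt_fraction x FPKM_Calm1 / sum(FPKM_Calm1..3)`.
Shares are reported at one decimal place; raw values are available with
`ndigits=None`.

The 2^-ddCt estimator uses a single user-named reference gene (Gapdh in
the murine assay) rather than a multi-reference geometric mean, because
the assay it models used one. dCt = Ct(target) − Ct(reference) per
replicate; ddCt is the difference of tissue mean dCts; the error band is
2^-(ddCt ∓ SEM) with the SEM taken over the *target*-tissue dCt mean
only — this matches a single ± band per bar and avoids inventing a
pooling rule the assay does not state. Swapping target and calibrator
yields exactly reciprocal folds.

Allele counting starts from a pre-tabulated (ref, alt) read-count pair;
pileup extraction from alignments is upstream and out of scope.

## Protein quantification (stable-isotope dilution)

Quantification is single-point internal-standard calibration:
`amount = spike x light_area / heavy_area`. No calibration curve is
fitted, since a single heavy standard is spiked per peptide. The
light/heavy ratio cancels detector gain exactly, which the tests assert
as an invariance. The label mass shift uses monoisotopic excesses
13C − 12C = 1.003355 Da and 15N − 14N = 0.997035 Da; the common
Leu(13C6,15N1) label gives 7.017 Da, nominally 7 Da.

Group summaries report median and range; the even-n median is the
midpoint of the two central values, which matters visibly at n = 4 per
genotype. Two summary conventions circulating for the same cohort
(median vs other location statistics) are deliberately not reconciled;
the module reports the median/range and leaves alternatives to the
caller.

## Turnover

Percent remaining is `100 x (band/control)(t) / (band/control)(0)` —
invariant to common lane rescaling. Biological replicates should be the
average of technical replicates (`average_technical_replicates`) before
statistics. The optional decay fit is nonlinear least squares of
`100 x 2^(-t/half_life)` with the rate bounded at zero; a fitted rate
below 1e-9/h is reported as non-decaying (infinite half-life). The
amplitude is pinned at 100 because the series is normalized by
construction; consequently, noise in the time-0 observation propagates
into the whole curve, and half-life estimates from a *single* series are
biased when that point is unlucky. Averaging a handful of replicate
series before fitting (as the assay design prescribes) removes this in
practice; the recovery tests fit the mean of six replicates.

## ECG

Signal averaging aligns beats on the QRS maximum (or minimum) sample and
takes the pointwise mean over the common overlap window.

The rate correction is the power-law form QTc = QT / (RR/RR_ref)^n with
n fitted per cohort by OLS of ln(QT) on ln(RR/RR_ref). RR_ref defaults
to the series mean RR; for pooled cohorts the caller should pass the
cohort mean of per-animal 24-hour average RR intervals. The classic
100 ms normalization is available by passing `rr_reference_ms=100` —
the exponent is unaffected (only the intercept moves), as the
scale-invariance test asserts. QT ≥ RR triggers a warning, not a
rejection, since mis-annotated beats are a data-quality signal the
caller should see.

Arrhythmia scoring is worst-rule-wins: 1 none/isolated PVCs; 2 bigeminy
or a PVC rate above 10/min within the window; 3 couplet; 4 NSVT of
duration 3–15 s. Sustained VT (> 15 s) exceeds the rubric and is tracked
separately; BVT incidence counts animals (not episodes) with at least
one bidirectional-VT episode longer than 3 s.

## Cellular electrophysiology

r50 is the fraction of peak |I| remaining 50 ms after the peak, with the
peak searched in a window of +2 to +100 ms after step onset (skipping
the capacitive transient; the published analyses do not state a window,
so this is a convention of this package) and the 50 ms offset evaluated
by linear interpolation between samples (nearest-sample evaluation is
the other defensible reading; interpolation was chosen and is flagged
here). r50 is invariant to amplitude scaling and sign convention.
f50 = (r50_Ca − r50_Ba)/r50_Ba; the CDI decrement between groups is
100 x (|f50_ref| − |f50_group|)/|f50_ref|.

The generator's trace is an idealized step response: the current jumps
to its peak at onset and decays as the product of CDI and VDI
exponentials (VDI only for Ba2+). This makes the remaining fraction over
any 50 ms window exactly `exp(-50/tau_cdi - 50/tau_vdi)`, the analytic
oracle used by the tests. Real traces have activation rise times and
capacitive transients the generator omits, so passing tests demonstrate
the *measurement* is correct, not that the generator is a biophysical
channel model.

## Optical mapping

Activation time is the instant of maximum dF/dt, refined to sub-sample
precision by a parabolic fit through the three derivative samples around
the maximum. A pixel is masked unless its peak slope exceeds 5x the SD
of the derivative over the first 10 frames (pre-stimulus noise) — the
published criteria live in unavailable supplementary methods, so this
threshold is a convention, not a reproduction. APD at level L runs from
the activation time to the first interpolated crossing of
`peak − (L/100)(peak − baseline)`, baseline being the pre-upstroke mean.
This makes APD30 ≤ APD50 ≤ APD80 a structural invariant.

Conduction velocity: activation time is plane-fitted in a sliding 5x5
window (configurable); each pixel's speed is 1/|∇t| directed along the
gradient. Directions mod 180° are binned into 10° sectors; CV_max and
CV_min are the extreme sector-median speeds (bins with < 10 samples are
dropped), and the fast axis is estimated from the second circular
harmonic of speed vs direction, which is stabler than the argmax bin.
Median binning tolerates fit noise at edges and near the source.

The movie generator spreads an elliptical wavefront
`t = sqrt((u/CV_long)^2 + (v/CV_trans)^2)` from a point source (default
at the grid center so both axes cross the interior where plane fits are
defined) and stamps each pixel with an analytic template: a 2 ms
half-cosine upstroke whose midpoint is the nominal activation time,
then exponential repolarization with the rate chosen so the 80 %
crossing falls exactly APD80 after activation — every level crossing has
a closed form (`template_apd`). Default grid 30–40 px at 0.1 mm pitch,
dt 0.5 ms, CV 0.6/0.3 mm/ms and APD80 40 ms: representative of murine
epicardial mapping and small enough that a full map computes in well
under a second. The generator does not emulate motion artifacts,
photobleaching, dual-humped APs or wavefront collisions.

## Imaging

Fibrosis: the fibrotic mask thresholds the blue-minus-red difference
image (clipped at zero; collagen in a trichrome stain is blue-dominant —
the sign is configurable for opposite-contrast stains, since the
published description says only "difference of the red and blue
channels"); the tissue mask thresholds the grayscale (plain channel
mean; no luminance weights are specified by the method modeled).
Thresholds default to Otsu, making the fraction invariant to uniform
brightness scaling; fixed thresholds can be supplied. The fraction is
fibrotic∩tissue over tissue pixels.

Striations: the profile averages intensity over a 50-pixel-high band
perpendicular to a user-drawn line; peaks are detected with prominence
10 % of the profile's dynamic range; spacing is the mean successive
peak gap, scaled to µm when a pixel size is given.

The histology generator colors a central disk of tissue red, selects a
spatially correlated random-field quantile of exactly the requested
fraction as blue fibrosis, and leaves a near-black background. It does
not emulate stain variability, vessels, or section artifacts.

## Cohort statistics

The Mendelian chi-square uses expected counts from the observed total
partitioned by the segregation ratio (df = 2). Observed-over-expected
percentages support two anchors: the total (chi-square convention,
default) and the wild-type count (natural when lethality depletes mutant
classes). The protein filter is strict: log2FC > 0.5 (or < −0.5) *and*
P < 0.05, boundary values excluded, no multiple-testing correction — the
rule models a stated raw-P filter.

## Synthetic data and what passing tests mean

Each generator draws from the noise family its analysis assumes —
binomial allelic reads, Poisson fragment counts, multiplicative
lognormal measurement noise (unit median, specified CV), exponential
decay, product-exponential currents, elliptical wavefronts — and
returns its ground truth alongside. Determinism: identical seeds give
bit-identical outputs; `SimConfig.rng(label)` derives independent
per-dataset streams from one root seed. Default simulated sizes mirror
the modeled study designs (4 animals per genotype for protein, 200
beats per exponent fit, 8–21 cells per CDI group, 512² histology
fields). Recovery tests on these inputs validate estimator correctness
and noise propagation; they cannot validate behavior under model
misspecification (e.g., non-lognormal peak-area noise, curved
wavefronts), which is the main caveat when applying the toolkit to real
recordings.

## Interface note

The package's surface is its Python API; the `calmkit` CLI is a thin
CSV/NPZ wrapper over the same functions for shell use and makes no
decisions of its own.
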