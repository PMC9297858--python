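# Methods

`ictalscope` quantifies four recording modalities from larval zebrafish
epilepsy experiments: whole-brain/regional neuronal calcium imaging
(epifluorescence, 4 Hz), single-plane astroglial calcium imaging,
simultaneous LFP (10 kHz) + extracellular-glutamate (iGluSnFR, 1 Hz)
imaging, and ZebraBox-style locomotor tracking.  Because no raw recordings
are publicly deposited, the package ships a synthetic generator that
emulates the statistical structure each analysis assumes, with complete
ground truth, so every stage is testable by parameter recovery.

## ΔF/F₀ and baselines

Raw fluorescence F (arbitrary units) is normalized as
ΔF/F₀ = 100·(F − F₀)/F₀, reported in percent throughout because all the
downstream thresholds are percentages (5%, 50%, 100%).

Two baseline estimators are provided, matching the two imaging workflows:

* **Whole-trace percentile** (`PercentileBaseline`, default 1%): F₀ per ROI
  is the nearest-rank 1st percentile of the entire trace.  Used for the
  regional neuronal recordings, where seizures occupy a minority of samples.
* **Moving-window percentile** (`MovingWindowBaseline`, default 8% of an
  80-s window, 1-s anchor step): the windowed nearest-rank percentile is
  evaluated at 1-s anchors (window centered, truncated at the edges),
  linearly interpolated to the full grid, and smoothed with a centered
  moving average of the same window length.  Used for glutamate and glial
  imaging, where slow drift must be tracked.

The "8%"/"1%" levels are interpreted as lower-tail percentiles of the sample
distribution with the nearest-rank convention (k = ⌈p·n⌉-th smallest
sample).  Window alignment is centered with edge truncation; traces shorter
than the window fall back to the whole-trace percentile.  Whether the final
smoothing of the moving baseline is the interpolation itself or an
additional moving average is ambiguous in the source workflows; both are
implemented (`smooth=` flag) with the moving average as the default.

Resampling (10 kHz LFP → 1 Hz; 24 Hz glial imaging → 4 Hz) first takes block
means at roughly twice the target rate (anti-aliasing mean decimation) and
then interpolates the block-center series onto the uniform target grid with
a shape-preserving piecewise cubic (pchip).  The 2× intermediate rate keeps
a 0.05-Hz sinusoid's amplitude within 0.5% while still averaging away
broadband noise; full-period blocks would flatten band-edge features by
~1.6%.

## Event detection

**Noise-model detector** (glial calcium).  The ΔF/F₀ sample distribution is
reduced to its 8th–92nd interpercentile core; a Gaussian is fitted by
iteratively re-selecting samples within ±1.405σ of the running mean and
correcting the core SD for the truncation it induces
(Var[N(0,1) | |x| < 1.405] = 0.503, so σ = SD_core/0.709).  Positive-going
transients fall outside the core, making the fit robust to ≲5% event
contamination (verified to 10% accuracy against 10σ boxcar injections).
The detection threshold is the one-sided 95% bound μ + 1.645σ — events are
positive-going, so a one-sided interval is the faithful reading of a "95%
confidence" criterion.  An event is a maximal supra-threshold run of ≥2
samples; runs separated by a full sub-threshold sample stay distinct.  With
these defaults, pure Gaussian noise yields a supra-threshold sample fraction
of 5.0% and an event-occupied time fraction below 1% (both checked by
Monte-Carlo in the tests).  Each event carries its amplitude (maximum
ΔF/F₀, relative to zero by default; μ-relative behind a flag), half-height
width (crossings of μ + (peak − μ)/2, linearly interpolated, clamped to one
sample beyond the run), and trapezoidal AUC above μ.

**Peak detector** (glutamate transients).  Local maxima with minimum height
and topographic prominence of 5% each, width measured at half-prominence
above the higher adjacent base.  Backed by `scipy.signal.find_peaks`, whose
prominence convention matches the brute-force topographic oracle used in the
tests.

## Seizure detection, classification, propagation

Seizure candidates are maximal intervals where midbrain ΔF/F₀ exceeds 50%
(onset strictly above, offset at the first sample at or below — reading
"greater than 50%" / "below 50%" literally).  Runs separated by <5 s merge
(refractory choice; configurable).  A candidate is **global** when a region
exceeds 50% in [onset, offset + 10 s) for every monitored region including
the anterior forebrain *and* the duration exceeds 60 s; otherwise **local**.
The 5-s merge gap and 10-s recruitment look-ahead are implementation choices
where the source analysis is silent.

Propagation is timed for global seizures by each region's half-maximum: the
first upward crossing of max(ΔF/F₀)/2 inside the seizure window (linear
interpolation), reported relative to the earliest region, which defines the
origin.  The search window opens 30 s before the candidate onset because the
midbrain threshold crossing that defines the onset can lag the origin
region's own recruitment (hindbrain-origin seizures would otherwise have
their half-max clipped to the window start, biasing forebrain delays low by
~1 s).  Regions peaking below 100% are excluded with a flag; origin ties
resolve by fixed anatomical order (hindbrain, midbrain, anterior forebrain)
with a tie flag.

Basal (inter-ictal) activity is the population SD of whole-brain ΔF/F₀ in
two-minute windows, averaged over five windows per fish.  The source
methods text says "SD of F₀" while the corresponding figure says "SD of
ΔF/F₀ over 2 min"; the figure's reading is implemented since a constant F₀
has no SD.  Windows are placed at least 120 s from any seizure —
deterministically evenly spaced by default for reproducibility, with a
seeded random mode mirroring random placement adjusted away from seizures.

## Glial window metrics

Per-cell events (noise-model detector on 4 Hz-resampled ΔF/F₀) are assigned
to windows by peak time — not by overlap — so an event straddling a boundary
is counted exactly once.  A cell is active in a window if ≥1 event peaks in
it; active fraction, mean amplitude, and summed AUC are reported, with
population summaries over active cells only.  Peri-ictal analysis uses
120-s windows (preictal ends at onset; ictal starts at it; six basal
windows per fish by default), light-stimulus analysis uses the paired
[onset − 60 s, onset) / [onset, onset + 60 s) windows.  "Averaged over six
time points" is read as six basal windows per fish.

## Behavior

Tracking records report distance (mm) and moving time (s, movement above
1 mm/s) per accumulating 5-s interval.  Derived measures:

* active ratio = Σ moving time / (5 s · n intervals);
* bursts = intervals with distance strictly above 40 mm (strict ">", per the
  threshold's definition);
* long-burst velocity = distance / moving time for intervals with ≥3.5 s of
  movement.  The denominator is the moving time, since the definition is
  "distance divided by time" for intervals *in which the animal moved* at
  least 3.5 s; dividing by the fixed 5-s bin is available behind a flag.

An artifact filter zeroes intervals implying velocities above 100 mm/s — a
plausibility bound far above larval swimming, chosen arbitrarily since the
original artifact removal was manual.

## Statistics

Rank-sum, signed-rank and two-sample KS tests delegate to scipy.stats with
fixed conventions: two-sided; continuity-corrected normal approximation,
switching to exact enumeration for ≤10 (rank-sum) or ≤15 (signed-rank)
tie-free observations.  Dunn's post hoc test after Kruskal-Wallis is
implemented directly (z = ΔR̄/√[(N(N+1)/12 − T)(1/nᵢ + 1/nⱼ)] with the
standard tie correction T) and Benjamini-Hochberg-adjusted across the
pairwise family via statsmodels.  Tests verify against exhaustive
permutation/sign-flip oracles at small n.

## Synthetic generator: what it emulates, and the calibrations

All randomness flows from one integer seed through named sub-streams, so
recordings are bit-reproducible and per-entity draws are stable under
unrelated parameter changes.

**Neuronal recordings.**  Raw F = F₀·(1 + drift)·(1 + ΔF/F₀/100) + Gaussian
noise, with F₀ = 100 a.u., a slow sinusoidal drift (default 0.2% of F₀,
500-s period) and i.i.d. sensor noise.  Seizures (homozygous mutants only —
controls carry none) are smoothed tanh-edged plateaus whose width at half
height is drawn lognormally with median 127 s and SD 52 s, amplitude uniform
in [100, 300]% (the source only bounds ">100%"), occurring at 3/h.  Rise and
fall time constants (2 s / 5 s) keep the detected 50%-threshold duration
within a few seconds of the drawn half-height width.  Regional onsets are
the seizure onset plus per-region delays: origin 0 s (midbrain with
probability 2/3, hindbrain 1/3, matching the reported 8:4 split), the other
posterior region ~N(2.5, 1.5) s, and the anterior forebrain
~N(13, 5.67) s, all truncated at 0.  Basal activity is a Poisson train of
difference-of-exponential transients (rise 0.2 s, decay 1.8 s — GCaMP5/6
literature range; never stated in the source) plus the sensor noise.

*Basal-SD calibration.*  The genotype presets target the published
two-minute windowed SD group means (mutant 0.63%, het 1.54%, wt 1.44%).
Mutants get rare small transients (2/min, mean 1.5%), controls frequent
larger ones (12/min, ~2.5%); the sensor-noise σ is then solved from
Campbell's theorem, σ² = SD_target² − rate·E[amp²]·∫g(t)²dt, with the
kernel's L2 norm in closed form.  Recovery through the full pipeline
(percentile baseline → ΔF/F₀ → seizure-free window SD) lands within ~2% of
the target; the residual bias comes from the noise-floor bias of the 1st
percentile baseline and the drift contribution, both small by construction.

**Glial recordings.**  Per-cell traces with genotype-dependent inter-ictal
activity (mutants: 30% of cells active at 0.5 events/min; controls: 70% at
1.2/min), slower kernels (rise ≥0.5 s, decay ≥4 s), large lognormal event
amplitudes (mean 30%), and near-synchronous ictal participation (95% of
cells, plateau amplitudes 150-300%) so the all-cell mean exceeds 100%
ΔF/F₀ during injected seizures.

**Behavior.**  Each 5-s interval is active with genotype probability
p_move; active intervals draw moving time uniformly around
5·(target active ratio)/p_move so the expected active ratio equals the
published group mean exactly (mutant 4.7%, het 44.4%, wt 47.6%), and an
independent lognormal velocity whose mean is the published long-burst group
mean (mutant 7.31 mm/s with a heavy σ_ln = 0.5 tail — producing the
occasional >40 mm escape bursts — controls ~4.85 mm/s, σ_ln = 0.3).
Distance = velocity × moving time.

**LFP + glutamate.**  Co-timed events: iGluSnFR surges (mutant: amplitude
~N(25, 6)%, duration lognormal median 45 s; PTZ: ~N(12, 3)%, median 18 s —
directions and separations chosen to reproduce the reported contrast, exact
values unpublished) and damped 5-Hz LFP deflection bursts of condition-
independent amplitude ("comparable" between conditions).

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: pixel-level imaging and ROI segmentation,
motion artifacts, photobleaching beyond a slow sinusoid, correlated
(non-i.i.d.) sensor noise, heart-beat/breathing artifacts, non-stationary
seizure waveforms, and any biophysics of neurons or astroglia.  Recovery
results demonstrate the correctness of the quantification pipeline under
the stated statistical assumptions, not robustness to real-world artifacts.

## Problem sizes

The recovery studies use 36 seizures (duration), 200 seizures (propagation
delay), 24 larvae × 30 min (behavior), 20 fish × 60 min (basal SD), and
100-seed Monte-Carlo for the detector calibration — matching or exceeding
the reported group sizes while keeping a full run in seconds.

## Known limitations

* The noise fit assumes a unimodal, symmetric sub-threshold distribution;
  strongly bimodal traces (e.g. permanent plateau states) set the degenerate
  flag or mis-estimate σ.
* Half-height widths of events barely above threshold can extend one sample
  beyond the detected run (clamped).
* The seizure classifier keys on the region labels
  `anterior_forebrain`/`midbrain`/`hindbrain`; traces with other label sets
  need a `region_of` mapping.
* `basal_activity_sd` trusts the caller's seizure list; undetected seizures
  inside a window inflate the SD.
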