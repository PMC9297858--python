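# ictalscope

Quantification pipeline for larval zebrafish epilepsy experiments: seizure
detection and propagation timing on whole-brain neuronal calcium imaging,
astroglial network metrics, glutamate-transient (iGluSnFR) quantification
with simultaneous LFP, and locomotor bout/burst analysis — plus a synthetic
generator with full ground truth, so every stage can be validated by
parameter recovery without any external data.

Glutamate-transporter-deficient (*eaat2a* mutant) zebrafish larvae show a
striking double phenotype: recurrent spontaneous seizures with huge
calcium plateaus, yet *reduced* activity between seizures — basal neuronal
fluctuations and swimming both drop well below sibling levels.  Measuring
both sides of that phenotype requires a consistent chain of conventions
(baseline percentile, ΔF/F₀ scaling, thresholds, window placement), which
this package implements as a tested, reusable library for imaging and
behavior analysts.

## The quantities it computes

* **ΔF/F₀** = 100·(F − F₀)/F₀ (%), with F₀ the nearest-rank 1st percentile
  of the whole trace (regional neuronal imaging) or the 8th percentile of a
  moving 80-s window, interpolated at 1-s steps and smoothed (glutamate /
  glial imaging).
* **Seizures**: maximal intervals with midbrain ΔF/F₀ > 50%.  *Global* =
  recruits every region including the anterior forebrain **and** lasts
  > 60 s; otherwise *local*.  Propagation is timed per region by the first
  crossing of max(ΔF/F₀)/2 (peaks ≥ 100% only); the earliest region is the
  origin.
* **Calcium/glutamate events**: either supra-threshold runs against a
  fitted Gaussian noise model (one-sided 95% bound μ + 1.645σ) or peaks
  with ≥5% height and prominence; each with amplitude, half-height width
  and trapezoidal AUC.
* **Basal activity**: population SD of whole-brain ΔF/F₀ over five
  seizure-free 2-min windows.
* **Behavior**: active-swimming ratio (Σ moving time / total), counts of
  >40 mm/5 s bursts, and long-burst velocity (distance / moving time for
  intervals with ≥3.5 s of movement).
* **Statistics**: two-sided rank-sum with continuity correction,
  signed-rank, two-sample KS, and Dunn-Kruskal-Wallis post hoc with
  Benjamini-Hochberg adjustment.

See `docs/methods.md` for conventions, calibrations and limitations.

## Worked example

Simulate a 60-min mutant recording, detect and classify its seizures, time
forebrain recruitment, and measure inter-ictal basal activity:

```python
import ictalscope as ic
from ictalscope.synth import SynthBrainParams, generate_brain_recording
from ictalscope.seizure import SeizureDetector, pick_basal_windows, basal_activity_sd

params = SynthBrainParams(duration=3600.0, seed=42)
trace, truth = generate_brain_recording(params, "homozygous_mutant")
dff = ic.compute_dff(trace, ic.baseline_whole_trace(trace))

seizures = SeizureDetector().fit(dff).seizures_
for sz in seizures:
    print(f"{sz.seizure_class:6s} onset={sz.onset:7.1f} s  duration={sz.duration:6.1f} s  "
          f"origin={sz.origin}  forebrain_delay={sz.halfmax_time.get('anterior_forebrain', float('nan')):.1f} s")

windows = pick_basal_windows(trace.duration, seizures, n_windows=5)
sd = basal_activity_sd(dff.column("whole_brain"), windows, dff.sampling_rate,
                       seizures=seizures)
print(f"basal SD over {len(windows)} windows: {sd:.2f} %")
```

```
global onset=  365.2 s  duration=  85.0 s  origin=hindbrain  forebrain_delay=12.7 s
local  onset= 1684.5 s  duration=  28.8 s  origin=None  forebrain_delay=nan s
global onset= 2053.2 s  duration= 187.2 s  origin=midbrain  forebrain_delay=0.9 s
global onset= 2756.8 s  duration= 119.8 s  origin=hindbrain  forebrain_delay=12.1 s
basal SD over 5 windows: 0.66 %
```

Three of the four detected events recruit the forebrain and outlast one
minute, so they classify as global; their forebrain half-max times recover
the injected recruitment delays (drawn around 13 s — the third seizure
simply drew a short delay).  The basal SD of 0.66% sits at the mutant
preset's hypoactive level, far below the ~1.4-1.5% of control genotypes.

The same stages are scriptable from the shell:

```bash
ictalscope synth brain --genotype homozygous_mutant --duration 3600 --seed 42 --out run/
ictalscope dff run/brain_trace.csv --baseline whole --out run/dff.csv
ictalscope seizures run/dff.csv --threshold 50 --min-peak 100 --out run/seizures.csv
ictalscope run --genotype homozygous_mutant --seed 42 --out run/
```

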