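# hdieeg

EEG neurometrics for assessing driver distraction from a lightweight
8-channel frontal/parietal montage (AFz, AF3, AF4, AF7, AF8, Pz, P3, P4 at
125 Hz). The package implements the full processing chain from raw signal to
a per-second **Human Distraction Index (HDI)**, together with a
ground-truth synthetic-EEG generator and the group-level statistics layer,
so the whole method can be exercised and validated without access to any
recorded cohort.

## The method

After cleaning (5th-order Butterworth band-pass 2–30 Hz, 50 Hz notch, blink
detection plus multichannel Wiener correction) the signal is cut into 1-s
epochs, and epochs violating any of three criteria are discarded: absolute
amplitude exceeding ±80 µV, linear-trend slope exceeding 20 µV/s, or a
sample-to-sample difference exceeding 25 µV.

Frequency bands are anchored to the **Individual Alpha Frequency** (IAF) —
the largest spectral peak in 8–13 Hz during eyes-open rest:

```
theta = [IAF − 8, IAF − 4) Hz
alpha = [IAF − 2, IAF + 2) Hz
beta  = [IAF + 2, IAF + 20) Hz
```

(at IAF = 10 Hz these are the standard 2–6 / 8–12 / 12–30 Hz bands). For a
band *b* and channel region with *N* channels, the per-epoch **Global Field
Power** is

```
GFP_{b,region} = (1/N) Σ_i  x²_{i,b}(t)     [µV²]
```

with the band restriction done spectrally on the Hanning-tapered 1-s epoch
(1 Hz resolution). The neurometrics are

```
workload  = frontal theta GFP / parietal alpha GFP
attention = frontal beta GFP  / frontal theta GFP     (inverse theta–beta ratio)
HDI       = workload − attention
```

so distraction — more workload, less sustained attention — pushes the HDI
up. HDI is z-scored against a focused-driving baseline run from the same
scenario before group comparison. The statistics layer provides the
Shapiro–Wilk-gated t / Mann–Whitney choice, the Friedman rank ANOVA with
Kendall's W effect size, and the repeated-measures correlation.

## Worked example

```python
import hdieeg as h

base = h.SubjectSpec(seed=77)                       # IAF 10 Hz, realistic noise + blinks
rest = h.simulate_recording(base, 60.0)
scheme = h.subject_band_scheme(rest)                # clean, reject, estimate IAF
print(f"IAF {scheme.iaf_hz:.2f} Hz, theta {scheme.theta}")

baseline = h.simulate_recording(h.SubjectSpec(seed=78), 30.0)
distracted = h.simulate_recording(
    h.SubjectSpec(seed=79), 30.0, band_multipliers={"theta": 1.4, "beta": 0.8}
)
series = h.normalized_hdi(distracted, baseline, scheme)
print(f"{len(series.epoch_index)} epochs, mean HDI z = {series.hdi_z.mean():.2f}")
```

prints

```
IAF 10.01 Hz, theta (2.014797553583385, 6.014797553583385)
30 epochs, mean HDI z = 1.20
```

The estimated IAF lands on the generator's 10 Hz peak, the theta band is
anchored to it, and the distracted run (frontal theta raised ×1.4, frontal
beta suppressed ×0.8) sits about 1.2 baseline standard deviations above
the focused baseline — the per-epoch signature the group statistics then
test.

A `hdieeg` console script exposes the same chain from the shell:
`hdieeg simulate` writes a labeled synthetic cohort (plus
`ground_truth.csv`), `hdieeg process` turns one recording into a per-epoch
index table, and `hdieeg stats` runs the group tests on long-format CSVs.

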