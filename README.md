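# seachorus

Noise-robust detection of **fish choruses** in passive acoustic monitoring
(PAM) recordings with the **complexity-entropy (C-H) method**, alongside the
three classical acoustic indices (ACI, ADI, BI), calibrated band
sound-pressure levels, a threshold detection/evaluation scheme, and a
labeled synthetic-soundscape simulator so the whole pipeline can be
exercised and validated without field data.

Intended for marine ecoacousticians analyzing long-term hydrophone
deployments where biophony (e.g. Sciaenid croaker choruses at ~500–2500 Hz
with dawn/dusk peaks) must be separated from shipping noise, sediment
transport and other interference.

## The method

A recording `{x_t}` is symbolized with the Bandt–Pompe ordinal scheme:
every embedding vector of `d` samples at delay `τ` is mapped to the
permutation `π = (r0, …, r_{d−1})` of time offsets that sorts its values
in descending order, `x_{s−r0τ} ≥ x_{s−r1τ} ≥ … ≥ x_{s−r_{d−1}τ}`. The
relative frequencies of the `d!` patterns give the ordinal distribution
`P = {p(π_i)}`, from which two quantifiers are computed (natural logs):

- normalized permutation entropy `H = S[P] / ln d!`, with
  `S[P] = −Σ p_i ln p_i` — the randomness of the fluctuations;
- statistical complexity `C = Q_J[P, P_e] · H`, where
  `Q_J = Q_0 · J[P, P_e]` is the Jensen–Shannon disequilibrium between `P`
  and the uniform distribution `P_e`, normalized so a delta distribution
  has `Q_J = 1` — the degree of correlational structure.

On the C-H plane (bounded by the `C_min`/`C_max` limit curves), white
noise sits far right (`H` high, `C` low) and periodic signals far left
(`H` low, `C` high). Massed quasi-periodic fish calling pulls an hour of
audio toward the periodic corner — `H` dips, `C` peaks — while
low-frequency vessel or sediment noise barely moves either quantifier,
because at hydrophone sample rates with `τ = 1` the ordinal patterns probe
sub-millisecond timescales that slow noise cannot reorder.

Detection follows the study design the package mirrors: hourly index
series are min–max normalized over the deployment and thresholded at 0.5
(`C`, ACI, ADI, BI detect above; `H` below), then scored against annotated
chorus presence with a confusion matrix (accuracy `(TP+TN)/n`, error rate
`(FN+FP)/n`) and correlated against the chorus-band (500–2500 Hz) and
noise-band (50–200 Hz) SPLs.

## Worked example

```python
import numpy as np
from seachorus import OrdinalConfig, global_complexity

t = np.arange(100_001)
sine = global_complexity(np.sin(2 * np.pi * t / 20), OrdinalConfig(d=6))
noise = global_complexity(np.random.default_rng(0).standard_normal(100_000),
                          OrdinalConfig(d=6))
print(f"sine  : H = {sine.H:.3f}, C = {sine.C:.3f}")
print(f"noise : H = {noise.H:.3f}, C = {noise.C:.3f}")
```

prints

```
sine  : H = 0.337, C = 0.309
noise : H = 0.999, C = 0.001
```

— the two landmark corners of the C-H plane: a sinusoid (20 samples per
period) is highly ordered with strong correlation structure, long white
noise is maximally random with none. Finite windows shift the noise
marker left and up (length 900 gives `H ≈ 0.93`).

The full pipeline runs from the shell. A 24-hour synthetic scene with a
mild dawn/dusk chorus plus vessel and sediment interference:

```sh
seachorus simulate --preset b --seed 3 --out scene/
seachorus analyze scene/scene_b.wav --seconds-per-hour 10 --out results.csv
seachorus evaluate results.csv scene/scene_b_truth.csv --out report.json
```

```
H: accuracy 1.000 (TP 12 FP 0 TN 12 FN 0)
C: accuracy 1.000 (TP 12 FP 0 TN 12 FN 0)
ACI: accuracy 0.917 (TP 10 FP 0 TN 12 FN 2)
ADI: accuracy 0.583 (TP 12 FP 10 TN 2 FN 0)
BI: accuracy 1.000 (TP 12 FP 0 TN 12 FN 0)
CH: accuracy 1.000 (TP 12 FP 0 TN 12 FN 0)
```

Each line is one detector's confusion matrix over the 24 hourly windows:
the C-H quantifiers recover every programmed chorus hour on this day,
ACI misses the densest chorus hours, and ADI false-alarms on quiet hours.
`seachorus simulate --preset deployment` renders multi-day scenes for
correlation analyses, and `seachorus plane` exports the limit curves.

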