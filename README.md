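# mouseeg

Auditory EEG/ERP biomarker analysis for pharmacological mouse models.

Preclinical schizophrenia research leans on a small set of translational
EEG readouts recorded from awake mice under auditory stimulation: the N1
(N40) amplitude of the auditory event-related potential and its paired-click
sensory-gating ratio, basal and stimulus-evoked gamma (35–80 Hz) and theta
(4–12 Hz) oscillatory power, the power and intertrial coherence (ITC) of the
40 Hz auditory steady-state response (ASSR), and mismatch negativity (MMN)
from an oddball sequence. NMDA-receptor antagonists such as MK-801 or
ketamine shift these readouts in characteristic directions (N1 ↓, basal
gamma ↑, evoked gamma ↓, ASSR power ↓, ITC ↓, MMN ↓), mimicking the deficits
seen in patients.

`mouseeg` implements the complete analysis chain as a tested, reusable
library plus CLI:

* **Stimulation timelines** — paired clicks, 40 Hz click trains, flip-flop
  oddball sequences — as deterministic event tables.
* **A synthetic-EEG generator** with ground truth for every readout: 1/f
  background, Gaussian ERP deflections with per-trial jitter, gating,
  evoked gamma/theta bursts, phase-jittered 40 Hz entrainment, deviant
  enhancement, per-animal random gains, and multiplicative "drug effects".
* **Signal I/O** — plain EDF with a trigger channel (write and read),
  event recovery from rising trigger edges, peak-to-peak artifact
  rejection.
* **The readouts** — ERP segmentation/baseline/averaging, N1 and P1
  measures, gating ratio |N1(S2)|/|N1(S1)|, complex Morlet decomposition
  (c = 5), basal power (400 ms bin 3 s pre-stimulus) and evoked power
  (P1-anchored windows, total − basal), ASSR band-pass/epoching/power/ITC,
  and MMN via last-standard matching and peak-centered ±25 ms AUC.
* **Statistics** — per-parameter linear mixed models with a random animal
  intercept, dose-vs-baseline and washout-vs-baseline contrasts, and
  Bonferroni families (0.05 divided by doses × parameters per protocol).

The key quantities, in the field's notation: the gating ratio is
S2/S1 = |N1₂|/|N1₁|; evoked band power is P_evoked = P_total(win) − P_basal
with the window anchored at the measured P1 latency; the phase-locking
factor is ITC(t) = |n⁻¹ Σₖ cₖ(t)/|cₖ(t)|| ∈ [0, 1] for Morlet coefficients
cₖ; and MMN is the signed area ∫ (deviant − standard)(t) dt over peak ±25 ms.

## Worked example

Simulate the demo cohort (12 animals; vehicle baseline, a high
antagonist-like dose, washout; all three protocols), analyze every session,
and fit the mixed-model contrasts:

```python
from mouseeg.pipeline import default_demo_config, run_cohort, fit_all_contrasts

config = default_demo_config(seed=1)
table = run_cohort(config)              # tidy per-animal biomarker table
report = fit_all_contrasts(table, config)
print(report[~report.washout][["protocol", "parameter", "estimate",
                               "ci_low", "ci_high", "p_value", "significant"]])
```

prints (dose minus vehicle-at-baseline, 95% CIs, Bonferroni-corrected
significance):

```
protocol    parameter     estimate       ci_low      ci_high  p_value  significant
     erp       n1_amp     -59.5477     -63.8414     -55.2541   0.0000         True
     erp gating_ratio       0.0240      -0.0048       0.0528   0.0980        False
     erp  basal_gamma       9.3518       8.4916      10.2119   0.0000         True
     erp evoked_gamma     -26.2865     -30.3269     -22.2461   0.0000         True
     erp  basal_theta      -0.4447      -1.2813       0.3918   0.2821        False
     erp evoked_theta     -70.3460     -79.4220     -61.2700   0.0000         True
    assr   assr_power -318542.4053 -363480.0373 -273604.7733   0.0000         True
    assr     assr_itc      -0.4335      -0.4818      -0.3852   0.0000         True
     mmn      mmn_auc   -1845.9013   -2066.8714   -1624.9312   0.0000         True
```

The N1 amplitude drops by ~60 µV, basal gamma rises while evoked gamma and
theta fall, ASSR power and ITC collapse, and the MMN area shrinks — the
direction pattern expected of an NMDA-receptor antagonist — while the
gating ratio and basal theta (not targeted by this effect preset) stay
null. The same run is available from the shell:

```bash
mouseeg run-all --seed 1 --out-dir runs/demo     # CSVs + report + manifest
mouseeg simulate --seed 1 --out-dir runs/edf     # EDF files + event sidecars
mouseeg inspect runs/edf/recordings/erp_m00_vehicle_baseline.edf
```

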