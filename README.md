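# measpike

Analysis of multielectrode-array (MEA) extracellular recordings from
cultured neural networks — the longitudinal, per-device workflow used to
characterize network maturation and responses to insults such as
lipopolysaccharide (LPS) neuroinflammation in neuron–glia co- and
tri-cultures.

The package takes continuous multichannel voltage (or pre-detected spike
tables) through the full chain:

1. **Spike detection** — zero-phase 300 Hz high-pass, robust noise SD
   (`median(|x|)/0.6745`), dual ±8σ thresholds, extremum alignment, and
   deduplication of biphasic double-crossings.
2. **Activity census** — an electrode is *active* with ≥ 10 spikes per
   10-minute recording; features are per-device means over active
   electrodes.
3. **Max-interval burst detection** — bursts open at ISI ≤ 0.1 s, extend
   while ISI ≤ 0.25 s, merge under 0.5 s separation, and must last ≥ 0.05 s
   with ≥ 6 spikes; per-electrode percent-of-spikes-in-bursts, burst
   duration and within-burst ISI.
4. **Synchrony** — the time-resolved SPIKE-distance
   S(t) = (S₁·x_ISI,2 + S₂·x_ISI,1) / (2⟨x_ISI⟩²) between train pairs,
   integrated exactly over its piecewise-linear profile; device synchrony
   is 1 − mean pairwise distance over active electrodes.
5. **E/I classification** — density-mode unit assignment on snippet PCs,
   mean-waveform trough-to-peak width, and the 280 µs narrow/broad rule
   (narrow-spiking < 280 µs → putative inhibitory, broad-spiking → putative
   excitatory).
6. **Longitudinal statistics** — per-feature linear mixed models with a
   cubic B-spline time basis per group and a device random intercept
   (REML), estimated-marginal-mean contrasts at each session with
   Holm–Bonferroni adjustment, and Student's t-test for E/I percentages.

A first-class synthetic generator (`measpike.simulate`) produces
ground-truthed recordings and whole study designs — maturation across
DIV 7–21 and an LPS challenge over 0–72 h — so every stage can be validated
against a known answer.  See `docs/methods.md` for the models and choices.

## Worked example

```python
import pandas as pd
from measpike import (simulate_study, compute_active_channels,
                      fit_spline_lme, emm_contrasts_holm)

study = simulate_study("maturation", seed=1)   # co/tri cultures, DIV 7..21
rows = [dict(device=s.device, session=s.session, culture=s.culture,
             percent_active=compute_active_channels(s.truth.trains())[1])
        for s in study.sessions]
table = pd.DataFrame(rows)
print(table.groupby(["culture", "session"])["percent_active"].mean().round(1))

fit = fit_spline_lme(table, "percent_active")
contrasts = emm_contrasts_holm(fit)
print(contrasts[contrasts.comparison == "vs-baseline"]
      [["contrast", "estimate", "p_adj"]].head(4).to_string(index=False))
```

prints

```
culture  session
co       7.0        30.1
         10.0       46.5
         14.0       58.2
         17.0       66.4
         21.0       79.3
tri      7.0        26.2
         10.0       41.0
         14.0       54.3
         17.0       62.5
         21.0       73.0
Name: percent_active, dtype: float64
      contrast  estimate        p_adj
co: 10.0 - 7.0 16.406250 1.990917e-06
co: 14.0 - 7.0 28.125000 4.141017e-13
co: 17.0 - 7.0 36.328125 2.169064e-17
co: 21.0 - 7.0 49.218750 2.989173e-23
```

— the configured electrode recruitment (30% → 80% of 32 channels) is
recovered by the census, and the spline mixed model calls every
later-than-baseline timepoint significantly above DIV 7 after Holm
adjustment, while between-culture contrasts (not shown) stay null because
both arms share one trajectory.

The `examples/` directory has one short script per capability
(detection, bursts, synchrony, E/I classification, longitudinal stats,
and the full LPS pipeline).  A thin CLI wraps the staged pipeline:

```bash
measpike all --scenario lps --seed 5 --outdir out/
measpike analyze --spikes spikes.csv --n-channels 32 --duration 600 --outdir out/
```

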