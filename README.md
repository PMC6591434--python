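# hrvkit

Heart-rate-variability (HRV) analysis of murine telemetric RR-interval
series, built for the genotype-by-drug comparison design used in cardiac
autonomic physiology: wild-type (WT) versus cardiac-specific adenylyl
cyclase 8–overexpressing (TG^AC8) mice, recorded before and after
autonomic drugs (atropine, propranolol, dual blockade, dobutamine).

The package covers the full path from beat tables to statistics:

1. **Ingest** — delimited beat-time (s) or RR-interval (ms) tables, one
   series per (animal, condition).
2. **Segment selection** — non-overlapping candidate windows are kept
   when they are stationary (no significant linear trend larger than a
   practical drift bound) and contain ≥ 2048 usable intervals. Ectopic
   intervals — any interval deviating more than 2 SD from the window
   mean — are *removed* for time-domain/nonlinear metrics and *zeroed*
   for spectral analysis.
3. **Metrics per 2048-interval segment**
   - time domain: mean RR, RR range, SDRR (sample SD), CV = SDRR/mean;
   - frequency domain: FFT of the mean-centred beat sequence, per-bin
     power |X_k|²/T̄ (T̄ = mean RR in s), one-sided folding, band powers
     over VLF 0–0.4, LF 0.4–1.5, HF 1.5–5.0 Hz, where the Hz axis is
     cycles-per-beat divided by T̄ (a mouse at ~10 beats/s puts the
     per-beat Nyquist at ~5 Hz);
   - nonlinear: Poincaré SD1 = √(var(ΔRR)/2), SD2 = √(var(ΣRR)/2), and
     multiscale sample entropy, SampEn(m = 2, r = 0.2·SD) at
     coarse-graining scale 1 (E1).
4. **Statistics** — per metric, a linear mixed model
   `value ~ genotype * drug + (1 | animal)` fitted by REML
   (statsmodels `MixedLM`), F-tests for genotype, drug and interaction,
   and pairwise least-squares-mean differences with Satterthwaite
   degrees of freedom; significant effects are flagged ‡ (genotype),
   T (drug), * (pairwise under a significant interaction). A one-way
   genotype ANOVA handles per-hour average heart rate.
5. **Synthetic generator** — additive-sinusoid RR model (LF + HF
   modulation + Gaussian noise + rare ectopics) with versioned WT /
   TG^AC8 presets (higher heart rate, ~2.5-fold lower SDRR in the
   transgene) and per-drug, per-genotype multipliers, so the whole
   pipeline runs and is testable without animal data.
6. **Auxiliary quantifications** — corrected total cell fluorescence
   (CTCF = integrated density − area × mean background) and
   comparative-Ct relative expression (RQ = 2^(−ΔΔCt)).

## Worked example

Simulate a 6 + 6 animal atropine study, analyze it, and fit the mixed
model on SDRR:

```python
import numpy as np
from dataclasses import replace
from hrvkit import (genotype_preset, drug_effect_transform, generate_rr_series,
                    analyze_series, records_to_frame, fit_genotype_drug_model)

rng = np.random.default_rng(0)
records = []
for genotype in ("WT", "TGAC8"):
    for j in range(6):
        cfg = genotype_preset(genotype, n_beats=10000, seed=int(rng.integers(2**31 - 1)))
        cfg = replace(cfg, mean_rr=cfg.mean_rr + rng.normal(0, 2.0))  # animal effect
        pre = generate_rr_series(cfg, animal_id=f"{genotype}-{j}")
        post_cfg = replace(drug_effect_transform(cfg, "atropine"),
                           seed=int(rng.integers(2**31 - 1)))
        post = generate_rr_series(post_cfg, animal_id=f"{genotype}-{j}")
        records += analyze_series(pre) + analyze_series(post)

df = records_to_frame(records)
print(df.groupby(["genotype", "condition", "metric"])["value"]
        .mean().unstack("metric")[["mean_rr", "sdrr", "sd1", "sampen_e1"]].round(3))

res = fit_genotype_drug_model(df, metric="sdrr", drug="atropine")
print("flags:", res.flags)
for name, e in res.effects.items():
    print(f"{name:12s} F={e.f_value:8.2f}  df={e.df:5.1f}  p={e.p_value:.3g}")
```

prints

```
metric              mean_rr   sdrr    sd1  sampen_e1
genotype condition
TGAC8    atropine    81.225  1.526  1.391      2.221
         basal       85.484  2.144  2.031      2.215
WT       atropine    82.019  2.120  1.834      2.185
         basal      100.033  5.190  4.964      2.211
flags: ‡T*
genotype     F=15020.09  df= 92.0  p=1.12e-103
drug         F=15414.92  df= 92.0  p=3.09e-104
interaction  F= 6815.45  df= 92.0  p=4.44e-88
```

Reading the output: basal WT mice sit at a 100 ms mean RR with ~5.2 ms
SDRR; the transgenic preset beats faster (85 ms) with ~2.4-fold lower
variability. Atropine shortens RR and cuts variability in both
genotypes, but far more in WT — hence the significant
genotype × drug interaction (* flag) on top of the genotype (‡) and
drug (T) main effects.

The same flow is available from the shell:

```bash
hrvkit simulate --preset WT --n-beats 20000 --seed 7 -o beats.csv
hrvkit analyze beats.csv -o metrics.csv
hrvkit compare metrics.csv --metric sdrr --drug atropine   # needs both conditions
hrvkit entropy beats.csv --m 2 --r 0.2 --scale 1
```

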