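# macpheno

Quantitative three-way phenotyping of macrophages (M0 resting, M1
pro-inflammatory, M2 anti-inflammatory) from three independent readouts:

1. **Membrane-order imaging** — ratiometric generalized polarization (GP)
   from dual-channel Di-4-ANEPPDHQ fluorescence,
   GP = (I_o − G·I_d)/(I_o + G·I_d), with the instrument calibration factor
   G derived from reference vesicles of known GP, pixel-wise GP maps with
   HSB rendering, automated membrane-ring segmentation, and per-cell ROI
   summaries on the ×100 reporting scale.
2. **Relative cytokine expression** — 2^−ΔΔCq fold changes of IL-1β, IL-6
   and IL-10 against 18S rRNA and an M0 calibrator, plus standard-curve
   primer-efficiency estimation.
3. **Surface-marker profiling** — per-phenotype CD86/CD64/CD206/CD11b MFI
   contrasts with qualitative "elevated-in" calls.

All contrasts run through one statistics engine (unpaired two-tailed t
test, pooled/Welch/auto; F test of variance equality; η² = t²/(t²+df);
95% CI of the mean difference), and phenotypes are called multivariately
(PCA + multinomial logistic regression on cytokine features) or from GP
thresholds. Because the underlying study deposited no raw data, a
first-class synthetic module generates all inputs — Poisson-noise ring-cell
images with known GP, vesicle calibration pairs, and RQ/MFI tables whose
group structure matches the published mean differences and SEMs — so the
whole pipeline is testable offline with known ground truth.

Intended users: imaging and immunology labs quantifying membrane order with
environment-sensitive dyes, and anyone needing a reproducible ΔΔCq/MFI
comparison stack with honest effect sizes.

## Worked example

Reproduce a summary-statistics contrast (monocyte CD11b vs differentiated
M0 macrophages, n = 3 per group):

```python
from macpheno import GroupStats, compare_groups

a = GroupStats("THP-1", n=3, mean=6.33, sd=2.0)
b = GroupStats("M0", n=3, mean=431.0, sd=36.0)
r = compare_groups(a, b, variance_model="pooled")
print(f"diff={r.mean_diff:.1f}  sem={r.sem_diff:.2f}  t={r.t_stat:.2f}  df={r.df:.0f}")
print(f"p={r.p_two_tailed:.2e}  CI=[{r.ci_low:.1f}, {r.ci_high:.1f}]  R2={r.r_squared:.2f}")
```

prints

```
diff=424.7  sem=20.82  t=20.40  df=4
p=3.41e-05  CI=[366.9, 482.5]  R2=0.99
```

i.e. CD11b rises by 424.7 MFI units upon differentiation — a 20-fold-SEM
effect where group membership explains 99% of the variance.

Run the full pipeline on synthetic data (generates images, segments
membranes, computes calibrated GP, analyzes expression and markers, and
cross-tabulates phenotype calls against ground truth):

```sh
macpheno run-all --seed 1 --out demo/
```

```
expression: 88.9% of calls match ground truth
gp: 100.0% of calls match ground truth
marker: 100.0% of calls match ground truth
report: demo/report.json
```

GP and marker readouts call every cell/sample correctly; cytokine-only
classification is imperfect by design — the simulated within-group
variances (solved from the published SEMs) genuinely overlap between M0
and M2. Individual stages are exposed as `macpheno synth|segment|gp|qpcr|
markers|stats|classify` (see `--help`).

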