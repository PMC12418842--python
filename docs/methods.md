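# Methods

## The measurement model

`macpheno` analyzes three independent readouts used to distinguish resting
(M0), pro-inflammatory (M1, LPS + IFN-γ induced) and anti-inflammatory
(M2, IL-4 + IL-13 induced) macrophage phenotypes.

### Membrane-order imaging (generalized polarization)

Di-4-ANEPPDHQ partitions into the plasma membrane and its emission
blue-shifts with increasing lipid order. Two emission windows are recorded
per field — 500–580 nm ("ordered", I_o) and 620–750 nm ("disordered", I_d) —
and membrane order is quantified pixel-wise as

    GP = (I_o − G·I_d) / (I_o + G·I_d),   GP ∈ (−1, 1),

where G corrects for unequal channel detection efficiency. G is derived from
a reference sample (large unilamellar vesicles of defined composition) with
a known literature GP value GP_ref: with the instrument's raw (G = 1)
measurement of that sample GP_mes,

    G = (1 − GP_ref)(1 + GP_mes) / ((1 − GP_mes)(1 + GP_ref)).

This is the unique factor for which the calibrated GP of the reference
sample equals GP_ref (the round-trip identity, tested to 1e−9 over a grid
of reference/measured pairs). G = 1 recovers the uncalibrated estimator
exactly, and GP is strictly increasing in I_o/I_d at fixed G.

Per-cell summaries average GP over the valid pixels of a membrane ROI.
Pixels whose calibrated total intensity I_o + G·I_d does not exceed the
configured intensity floor (default 0, i.e. strictly positive signal) are
masked, never clamped — clamping would bias ROI means. Group means are
quoted on a ×100 reporting scale (`mean_gp_reported = 100 × mean_gp_internal`,
exactly); the package's reference group means on that scale are
M0 = 56.98, M1 = 63.56, M2 = 69.99, so higher membrane order in M2.

GP maps are rendered by an HSB merge: hue encodes GP linearly over a
configured range with blue at the ordered end and red at the disordered
end; saturation is 1; brightness is the two-channel mean intensity
normalized by a configured percentile (default 99th) over valid pixels;
invalid pixels are black.

### Membrane segmentation

The reference workflow selects membrane regions freehand; the automated
stand-in thresholds the summed-channel image (Otsu; a fixed threshold can
be supplied), fills holes, labels connected components, discards components
below `min_roi_px` (default 50) and, by default, components touching the
image border (truncated rings), then takes the ring mask as the filled
component minus its erosion by `ring_width` (default 3 px). The procedure
is deterministic; no minimum ROI size or ring width is dictated by the
reference workflow, so the defaults are package choices. Externally drawn
masks (labeled TIFF) and polygon ROIs (even-odd fill on the pixel grid) are
accepted with `provenance="manual"`.

### Relative expression (2^−ΔΔCq)

Per sample, ΔCq = Cq(target) − Cq(18S rRNA); ΔΔCq subtracts the calibrator
group's (M0) mean ΔCq; RQ = 2^−ΔΔCq. The calibrator group's mean ΔΔCq is 0
exactly and its geometric-mean RQ is 1. Technical replicates are treated as
listed rows by default; an averaging mode collapses them per sample first
(the reference analysis's df = 16 per comparison implies 9 values per
group, i.e. replicates treated as observations). Primer efficiency,
(10^(−1/slope) − 1)·100 from the least-squares slope of Cq versus log10
input, is reported for QC only; fold changes are not efficiency-corrected,
matching practice when efficiencies validate in the 95–101% range.

### Surface markers and statistics

Marker MFI tables (CD86, CD64, CD206, CD11b × THP-1/M0/M1/M2) are
summarized per group and every pairwise phenotype contrast per marker runs
through the shared engine: unpaired two-tailed t test (pooled or Welch;
"auto" picks pooled when the F test of variance equality has p ≥ 0.05),
95% CI of the mean difference, and effect size η² = t²/(t² + df) — the
point-biserial identity, which reproduces the published effect sizes for
every printed (t, df) pair. The F statistic is the larger-to-smaller
variance ratio with a doubled upper-tail p (capped at 1), symmetric in
group order. A marker is called "elevated" in a phenotype only when its
group mean is higher **and** the contrast is significant at α (default
0.05). No multiple-testing correction is applied anywhere, matching the
reference analysis.

### Classification

Three routes: PCA on standardized features (components sign-fixed by
making each component's largest-magnitude loading positive, so projections
are deterministic); multinomial logistic regression on standardized
features with a mild L2 ridge (C = 1e4) whose only role is to keep the fit
convergent when classes are perfectly separable — the reported metric is
*training* accuracy because no validation design is specified for the
reference analysis (cross-validation is available but off by default); and
a univariate GP-threshold rule cutting reported GP at the midpoints of the
reference group means (60.27, 66.775), with a value exactly at a threshold
assigned to the higher-order class.

## Synthetic study conditions

The generators define the conditions every stochastic test runs under; they
are fixed, not tunable per test.

**Images.** Ring-shaped cells (outer radius 10 px, thickness 3 px) on a
jittered, overlap-free grid in a 160×160 field; membrane pixels emit
Poisson counts with expected total `photon_budget` (default 2000) split
between channels as f = (1 + GP_true)/2; background pixels emit
`background_rate` (default 20) split evenly. Default GP_true per phenotype
is 0.5698/0.6356/0.6999 — the reference group means on the internal scale.
A noise-off flag emits expected counts exactly for algebraic tests. At
budget 2000 the per-group mean reported GP is recovered within ±1.5 units
with the M2 > M1 > M0 ordering in every tested seed.

**Expression.** Per gene × phenotype, n = 9 normal draws (df = 16 in the
two-group contrasts). Group means reproduce the published pairwise
differences exactly (additively consistent); baselines, which the pairwise
differences cannot fix, are IL-1β M0 = 1, IL-6 M0 = 1, IL-10 M0 = 100 RQ
units (IL-10's M1 mean lies 37.69 units below M0, so an M0 ≈ 1 baseline
would be unphysical). Group SDs are solved at run time from the published
SEMs of the differences via sem² = (var_a + var_b)/n — the solved SDs
reproduce those SEMs exactly, and Monte-Carlo SEMs match within 10%. Draws
are not truncated; with these variances occasional negative RQ draws occur
and are left in place (all downstream statistics are location/scale
statistics on an affine scale).

**MFI.** Same model at n = 3 (df = 4), means from the published contrasts
(CD64 high only in M1; CD206 high in M2; CD86 high in M1 and M2 vs M0 with
no M1–M2 difference; CD11b ≈ 431 in all macrophage groups vs 6.33 in
THP-1), SDs solved from the published SEM triples; draws clipped at 0
(worst-case clipping probability < 2%, negligible bias).

**What the generators do not emulate:** spectral bleed-through,
photobleaching, z-stacks, gating/event-level cytometry, correlated
between-gene biology, or the log-normal skew real RQ data likely has.
Passing tests therefore demonstrate correctness of the computations and
recoverability under the stated noise models, not robustness to optical or
enzymatic artifacts absent from those models.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; pipelines derive per-stage sub-seeds deterministically from the
  run seed. Equal spec + seed gives byte-identical outputs.
- Zero-total-intensity pixels are undefined, masked rather than zeroed; an
  empty valid ROI is an error, not a silent NaN.
- With both group SDs zero the t test is refused (degenerate); with one
  zero SD the F test is undefined but the t test proceeds.
- Stochastic-property sizes were chosen to make the checks sharp yet quick:
  10 seeds × 3 × 20 cells for GP recovery, 2000 null pairs for type-I
  calibration (tolerance 3 Monte-Carlo SEs), 100 seeds for the qualitative
  profile and classifier accuracy sweeps. The full suite runs in well under
  a minute on one core.
- Profile concordance is measured item-wise — the fraction of
  (seed × qualitative feature) pairs matching the expected profile. At the
  published effect sizes several individual contrasts have finite power
  (e.g. IL-10 M1-vs-M2 at t = 3.49, df = 16 has ≈ 0.91; the two deliberately
  null contrasts are non-significant ≈ 95% of the time), so requiring every
  feature in every seed would bound concordance near 0.80 by the data's own
  design; item-wise concordance measures ≈ 0.98.
- With the n = 9 expression design and the SEM-implied variances, the 27
  samples are linearly separable in only a minority of seeds, so median
  logistic *training* accuracy sits near 93% rather than 100%; perfect
  separation does occur in a substantial fraction of seeds. This is a
  property of the simulated variances, documented rather than hidden.

## Known limitations

Automated ring segmentation approximates, not replicates, freehand
membrane selection; touching cells are not split; no inter-channel
registration is estimated (an integer-pixel shift correction exists);
ΔΔCq uses a single reference gene with ideal base-2 amplification (no
Pfaffl correction); MFI is treated agnostically as mean-or-median
fluorescence; three-group ANOVA and nonparametric alternatives are out of
scope.
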