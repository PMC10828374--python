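# Methods

This note documents the statistical procedures, the synthetic-data
generator's assumptions, the numerical conventions, and the design choices
made where the design was genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Statistical kernel

**Mann–Whitney (two-tailed).** Exact enumeration of the U null when
n₁+n₂ ≤ 14 and the pooled data are tie-free; otherwise the normal
approximation with average-rank tie correction and continuity correction.
Ties always use average ranks.

**Spearman.** ρ is Pearson correlation on (average) ranks. The p-value is
an exact permutation of pairings for n ≤ 10 and the t-approximation
t = ρ√((n−2)/(1−ρ²)) above; the boundary is placed so the pooled
~47-sample reproduction screen always uses the t-approximation, which is
standard at that n. Constant input raises an error — ρ is undefined there
and a silent 0 would corrupt downstream sign logic.

**BH-FDR.** Standard step-up; q-values are p·m/rank with a running minimum
from the largest rank; rejection ⇔ q ≤ cutoff. In the aging screen BH is
applied within each timepoint pair's full feature-length p-list (not
across the pooled 3·m tests): each pair produces one "list of p-values"
and is corrected as such. The OR-pooling across pairs therefore inflates
the compound FDR above the per-pair level; the planted-null acceptance
test measures the realized false-discovery proportion instead of assuming
it.

**Permutation engines.** p = n_extreme/n_perm exactly, counting "equal to
or bigger" as extreme and applying no +1 smoothing — p may be exactly 0;
n_perm is configurable upward when finer resolution matters.

* *Median difference*: statistic |median(a) − median(b)| (two-sided
  default; a signed one-sided mode exists behind a flag). The absolute
  value is the conservative reading of a directional phrasing applied
  symmetrically across group comparisons.
* *Paired slope difference*: each hen's values are shuffled across months
  **within that hen only**, preserving every hen's multiset; the group
  noise trajectory (per-month CV across hens) and its OLS slope are
  recomputed per shuffle; the statistic is slope(A) − slope(B) with a
  **fixed** one-sided direction (order the groups so the alternative is
  slope(A) > slope(B)). Choosing the direction from the observed sign
  would double the null rejection rate; the fixed-direction convention
  keeps the null calibrated at nominal level, which the acceptance suite
  verifies empirically.

**Fisher / binomial.** Fisher's exact test is two-sided by summing
hypergeometric probabilities ≤ the observed table's. The two-group
survival comparison is a two-sided binomial test of one group's death
count against the other group's observed proportion; *which* group
supplies the null proportion is a genuine reporting ambiguity, so both
conventions sit behind a `null` flag and neither is asserted as canonical.

## Phenotypes

Laying efficiency is eggs/days per hen-month. A hen dying mid-month
contributes over days alive (denominator = alive days; a full-month
denominator is available behind a flag). Cohort efficiency is
median-of-counts then divide-by-days — the stated order, identical to the
median of per-hen efficiencies when month lengths agree. Sterility is 21
consecutive zero-egg days while alive ("three weeks" at the daily
resolution the log supports); mortality percent is rounded to the nearest
integer to match the field's reporting style. Months are calendar-like
(28–31 days), indexed by hen age; all hens share a hatching date
(single-flock design).

## Synthetic cohort generator

The generator states a world and sticks to it; it is not tuned to test
outcomes. Two arms of 32 hens; blood sampling at ages 21/23/27/33 months;
t23 is a control-only validation timepoint. Controls contribute a fresh
random 12-hen subset at every timepoint; the molted arm contributes one
12-hen subset chosen at t21 *after excluding hens strictly above the 90th
efficiency percentile* (a threshold on the value, ties kept — the "top
10%, ~100% efficiency" producers) and tracked longitudinally.

* **Latent fecundity**: logistic-declining per hen with a hen-level random
  intercept (baseline ≈ 0.85 ± 0.08), local slope ≈ 0.02/month near the
  operating point. Logistic was chosen for bounded (0,1) output; any
  monotone-declining family would serve. Molted hens drop to zero during
  the molt months (22–23) and restart at month 24 from a recovery level
  ≈ 0.90 ± 0.05, declining at 2/3 the control rate. Daily eggs are
  Bernoulli draws from the latent rate.
* **Metabolome**: 693 features, per-feature scale 10²–10⁶ (so scales span
  ≥ 3 orders of magnitude); log-normal intensities. 30% of features
  (round(0.3·693) = 208) drift monotonically: the log-median moves by
  `aging_effect_size` × σ_base per 12 months (σ_base from the baseline
  CV), attenuated ×2/3 in molted hens post-molt. 27% of features couple
  to each hen's fecundity *deviation from its group-age mean* with
  strength 2.0 log-units per unit deviation; coupling to the deviation
  rather than absolute efficiency keeps reproduction markers free of a
  built-in age trend (age–efficiency confounding still arises naturally
  through the aging features, as it would in real data). Features planted
  as both kinds get consistent signs (more-with-age ⇒ less-with-
  efficiency). The per-cell CV is cv_base + 0.005·(age−21) for controls,
  reduced by 0.05 post-molt for molted hens.
* **Mortality**: hens become sterile with probability 0.45 (control) /
  0.15 (molted) at a uniform post-recovery month; a sterile hen dies
  within ~3 months with probability 0.7 (death never precedes the
  observable 21-day sterile stretch); non-sterile background mortality
  0.05. These rates restate the emulated study's printed counts (≈ 14/32
  sterile controls, 34% vs 13% mortality) as generative probabilities.
* **Cytokines**: 9 log-normal channels declining ~0.4 log-units/year in
  controls, attenuated ×2/3 in molted hens, per-hen CV 0.25 — so molted
  panels sit above age-matched controls, and baseline-normalized medians
  start at exactly 1.

What the generator does **not** emulate: within-hen longitudinal
correlation of metabolite levels (each sample's noise is drawn fresh, so
the full planted CV is between-hen), missingness (a dropout knob exists
but defaults to 0), LC–MS physics (retention time, adducts, m/z), the
late-life survivor-bias dip in control noise (arises only implicitly via
mortality), and the one-sample drop that makes the emulated study's
pooled control count 47 rather than 48. A green recovery test therefore
establishes that the *procedures* behave as specified on data with the
stated structure — not that they would perform identically on real
plasma metabolomics.

### Statistical power of the stated world

At the default planted effect (1.0 σ per year) with 12 hens per cell, the
per-feature Mann–Whitney + BH(0.1) + monotonicity screen operates in a
low-sensitivity regime (BH's adaptive threshold tightens when few
features clear it), and the forest age model regresses strongly toward
the training mean, compressing predicted-age spans. The acceptance suite
asserts the stated recovery targets as written and documents where the
stated world cannot reach them; the per-module tests freeze thresholds
empirically derived from the generator itself. Individual reproduction
markers are deliberately weak (per-feature |ρ| ≈ 0.25, saturating near
0.45 as coupling grows, because efficiency variance is dominated by
hen-level deviation plus age decline that features only partly track);
the collective leave-one-out model is what carries predictive power —
the motivating regime for model-based biomarker panels.

## Age and efficiency models

Z-scoring always uses constants from a designated reference (training)
set; held-out and transfer samples are standardized with train-time
statistics — the only leakage-safe reading. The PCA age axis is fitted on
control reference samples and other samples are projected onto it; PC1's
sign is fixed so the older control median exceeds the younger (orientation
is a convention and is made deterministic). The regressor is a random
forest with frozen hyperparameters: 500 trees, unlimited depth,
1/3-feature subsampling, mandatory seed. "Stacking LASSO and RFR" is
implemented as a LASSO feature screen (nonzero coefficients at the
cross-validated penalty) feeding the forest — the simplest composition
consistent with that description; the marker set is fixed *before* the
leave-one-out loop (matching the stated order of operations), which
carries a known optimistic bias relative to per-fold reselection. The
capture rate reports, among samples with true efficiency > 0.5, the
fraction predicted > 0.5.

## Noise statistics

CVs use the sample SD (n−1) — material at n = 12 — divided by the mean,
computed on raw positive intensities only; z-scored input (mean ≈ 0) is
rejected rather than silently producing nonsense. The group noise scalar
is the median of the per-feature CVs, and the between-group test permutes
hen labels and recomputes the *full* median-of-CV statistic per shuffle
(statistic-level permutation, not per-feature p-value pooling). The
cytokine comparison averages each channel over hens, normalizes by the
same group's baseline-age average (every baseline channel is exactly 1),
takes the median of the 9 normalized channels as the representative
measure, and permutes whole hen trajectories between groups.

## Consistency filter for common markers

"Consistent with the intervention slowing aging and improving
performance" is operationalized as two individually toggleable
conditions on the aging ∩ reproduction intersection: (a) sign(ρ) =
−sign(age direction) — higher efficiency looks younger; (b) the molted
final-age median lies between the control young and old medians — molted
expression is younger than its age-matched control. Both are one
defensible reading of an informally stated filter and are flagged as
such.

## Numerical conventions and degenerate inputs

Permutation p-values may be exactly 0 (no smoothing). Strict inequalities
decide monotonicity (tied medians carry no direction; with continuous
intensities ties are measure-zero). The efficiency quantile for subset
exclusion uses linear interpolation with hens *strictly above* the cutoff
removed. Zero-variance features abort z-scoring with the feature named.
A one-feature marker panel still defines an age axis (PC2 ≡ 0). Seeds
propagate through `numpy.random.Generator` objects exclusively; every
stochastic stage of the pipeline derives its seed from the run seed, so
identical configs give byte-identical summaries.
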