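# Methods

This note documents the models, numerical conventions and design choices in
`ruminant_ghg`, at the level of detail a maintainer or reviewer needs. It
states no empirical results beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## 1. Chamber flux model

A static breathing chamber of volume `V` (default 7.776 m³, a
2.40 × 1.80 × 1.80 m sealed cage) encloses `N` animals. Under constant
emission the head-space mixing ratio rises linearly; the per-head flux is

```
F = dc/dt · (V/N) · (M/22.4) · (P/P₀) · (273/(273+T))
```

- `dc/dt` — OLS slope of concentration (ppm) on time (s), fitted over all
  session points;
- `M` — molar mass, 44 (CO₂) or 16 (CH₄) g mol⁻¹; 22.4 L mol⁻¹ the molar
  volume at STP;
- `P/P₀` and `273/(273+T)` — ideal-gas density corrections to chamber
  pressure (Pa, `P₀` = 1.013 × 10⁵) and temperature (°C).

**Unit audit.** With `dc/dt` in ppm s⁻¹ and `V` in m³, the product above is
numerically in mg s⁻¹ per head although the declared output unit is
g head⁻¹ h⁻¹; the required ×3600/1000 = ×3.6 conversion is applied
explicitly (`flux_conversion_factor`) and both the mg s⁻¹ and g h⁻¹ values
are exposed on `FluxEstimate`. The temperature correction uses 273, not
273.15, matching the equation as commonly printed; the difference is
< 0.06 %.

**Degenerate inputs.** A constant concentration series has zero total sum
of squares; R² is defined as 0 there (slope 0), so a flat trace always
fails QC — a flat trace carries no flux information. Negative fitted slopes
are kept (they can be physical, e.g. chamber leakage artifacts) and survive
QC if R² passes; downstream code may drop them.

**QC gate.** Sessions pass iff R² ≥ `qc_r2_min` (default 0.9, inclusive at
the boundary). One regression is fitted per 20-min session.

## 2. Cumulative emissions

Daily emission integrates the n = 12 two-hourly session fluxes by the
trapezoid rule. The open sum spans only 22 h, so the cycle is closed
periodically with a final trapezoid from `t_n` to `t_1 + 24 h` using
`(f_n + f_1)/2`. Periodic closure is the minimal assumption yielding a true
24-h total: for a constant flux it gives exactly 24·f, and for smooth
diurnal patterns it differs from the open sum or mean×24 by at most a few
percent. The open sum remains available (`closure="open"`).

Seasonal totals are `day × season_length / 1000` kg head⁻¹ with
season_length defaulting to 180 d — the value that makes day-level and
seasonal-level reporting mutually consistent for a May–October /
November–April split. Annual regime totals add warm and cold seasonal
values: TG = YWG + YCG, WGCF = YWG + YCF. When several animals share a
(group, gas, hour) cell, per-head fluxes are averaged before integration;
the join from sessions to groups is by *sample* (season-specific
observation), never by animal, because the same animal appears in both a
warm-season and a cold-season group.

Percent contrasts are `(a − b)/b × 100` with the comparison group as `b`.
All internal arithmetic is full precision; reporting rounds half-up to
2 decimals at the output layer only.

## 3. ANOVA, Duncan's test, letters

Classical one-way fixed-effects ANOVA; the pooled SEM reported per table
row is `sqrt(MSE / n̄)` with `n̄` the harmonic-mean group size (one SEM per
row, the animal-science reporting convention). If all observations are
identical, F is reported as 0 with p = 1 and a warning; if groups are
separated constants (MSE = 0), F = ∞, p = 0.

Duncan's multiple range test sorts the k means descending and tests the
range of every span of p consecutive means against
`R_p = q(1 − α_p; p, df_error) · sqrt(MSE/n̄)` with protection level
`α_p = 1 − (1−α)^{p−1}`. Studentized-range quantiles come from
`scipy.stats.studentized_range` (no hard-coded tables, arbitrary df and α).
The stepwise shielding rule is enforced: no pair inside a span already
declared non-significant is tested again or declared significant. Unbalanced
designs use the harmonic mean n with a warning. Ties in means are broken by
group label.

Compact letters use insert-and-absorb: start with one column holding all
groups; each significant pair splits every column containing both; columns
that become subsets are absorbed; columns are lettered in order of their
best (highest-mean) member. The display is provably consistent with the
input matrix (shared letter ⇔ non-significant), which a property test
checks on random designs.

## 4. Community statistics

- **Rarefaction**: one multivariate-hypergeometric draw per sample to
  `floor(fraction × min depth)` (default fraction 0.95). A single draw
  mirrors common practice; means over replicates can be built on top.
- **Shannon**: natural log by default (nats); base configurable. The source
  did not state a base.
- **Wilcoxon rank-sum**: exact enumeration of all C(n+m, n) rank-sum
  assignments when n+m ≤ 10 without ties (two-sided p = fraction of
  assignments at least as far from the null mean, exploiting the symmetric
  null); otherwise normal approximation with tie and continuity
  corrections. The n = 6 vs 6 design of the motivating experiment falls in
  the exact range.
- **Kruskal–Wallis**: the rank statistic with the standard tie correction;
  p from χ²(k−1). All-identical data returns H = 0, p = 1.
- Differential-abundance screening reports raw p-values with star
  thresholds (p < 0.05 / p < 0.01); Benjamini–Hochberg q-values optional,
  off by default, matching the raw-threshold reporting style of the
  motivating study.

## 5. Ordination

- **Bray–Curtis** via `scipy.spatial.distance.pdist`; all-zero samples are
  an error.
- **PCoA**: Gower double-centering of −d²/2, `eigh`, coordinates scaled by
  √λ over positive eigenvalues (tolerance 1e-10 relative to the largest
  magnitude). Negative eigenvalues are counted and reported, excluded from
  the proportion-explained denominator; no Cailliez/Lingoes correction.
- **PERMANOVA**: Anderson's pseudo-F from total and within-group sums of
  squared distances; Monte-Carlo label permutation with
  p = (1 + #{F_perm ≥ F_obs}) / (1 + permutations), so p is never 0; an
  exhaustive mode enumerates every distinct label assignment (the observed
  assignment is included in the reference set, p = #{F ≥ F_obs}/total).
  With equal group sizes the complement assignment reproduces the same
  partition and ties F exactly, so the minimum attainable exhaustive p for
  two equal groups is 2/C(n, n/2), not 1/C(n, n/2).
- **Mantel**: Pearson correlation (Spearman by flag) of condensed distance
  vectors; significance by simultaneous row/column permutation of the
  second matrix; the default alternative is one-sided "greater" (the vegan
  convention), two-sided available.
- **Nutrient distances**: each sample inherits its group's diet vector
  (nutrients are measured per diet, not per animal); columns z-scored
  across samples (ddof = 1, constant columns contribute 0), then Euclidean.
- **RDA**: community columns centered (no Hellinger transform by default;
  available upstream by transforming the input), constraints standardized;
  OLS fit, SVD of the fitted values, eigenvalues on the (n−1) variance
  scale. Axis percentages are relative to **total** community variance, not
  the constrained fraction. Site scores are the fitted-value projections
  (U·s), species scores the right singular vectors, biplot scores the
  correlations of each constraint with the site scores. Rank-deficient
  constraint sets raise an error naming the collinear columns.
- **Forward selection**: at each step the candidate maximizing adjusted R²
  (trace version, `1 − (1−R²)(n−1)/(n−m−1)`) is tested by permuting its
  sample rows while holding selected variables fixed; admitted if the
  marginal permutation p ≤ α and adjusted R² improves. Collinear candidates
  are skipped, so a duplicated variable is never admitted twice. Selection
  may return the empty set.

## 6. The synthetic world

The generator's defaults *are* the stated experimental conditions, chosen
once and not tuned:

- 18 samples = 3 groups × 6; the warm-season group draws half its animals
  from each regime, so animals recur across seasons under different group
  labels (this is why downstream joins are by sample).
- 12 sessions/day of 20 min, one per 2 h, sampled every 60 s; chamber
  7.776 m³, 1 head; ambient baselines 420 ppm CO₂ / 2 ppm CH₄; pressure
  70 kPa and 10 °C (a ~3000 m plateau site).
- True rates default to the motivating study's day emissions ÷ 24 (e.g.
  CO₂: 72.1 / 56.0 / 90.0 g h⁻¹ for YWG / YCG / YCF), i.e. a flat diurnal
  profile; per-animal rates scatter lognormally with CV 0.10
  (mean-preserving), consistent with the study's reported SEMs.
- Concentration noise: additive Gaussian, sd 2 ppm, no drift. Failure
  sessions (default 10 %) replace the ramp with an exponential saturation
  `c₀ + a(1 − e^{−t/τ})`, τ = session/3, matched in total rise; its linear
  fit has R² ≈ 0.87, below the 0.9 gate (at default noise a rare failure
  can still sneak past — the gate is statistical, not absolute).
- Count tables: per-group mean genus compositions (bacteria ≈ 48 %
  Firmicutes / 46 % Bacteroidetes / few % Proteobacteria; fungi dominated
  by Ascomycota and Basidiomycota with Neocallimastigomycota enriched under
  cold indoor feeding; archaea ≈ 99 % Euryarchaeota) with the qualitative
  group contrasts of the motivating study built in (Prevotella,
  Ruminococcus, Orpinomyces, Methanobrevibacter up in YCF; Butyrivibrio,
  Bacteroides, Methanobacterium up in the grazing groups). Magnitudes are
  free parameters, not study claims. Sampling is Dirichlet-multinomial
  with concentration θ·mean (θ defaults 150 / 80 / 150 for
  bacteria / fungi / archaea; θ = None uses the mean exactly), depth
  uniform on [30 000, 70 000] — the study's ~1.2–1.9 M high-quality reads
  over 18 samples put per-sample depth in this range.
- Nutrient tables default to the study's published diet point values.
- Reproducibility: one `SeedSequence`-spawned stream per generator, so the
  same seed is bit-identical and adding a generator does not perturb
  others.

**What a green test does not establish.** The generator draws iid
per-sample compositions within groups: no animal-level repeated-measures
correlation between a yak's warm and cold samples, no read-level error or
chimera structure, no seasonal temperature covariates, no compositional
zero-inflation beyond the multinomial. Parameter-recovery and power results
on this world therefore validate the estimators' arithmetic and
calibration, not robustness to those real-data features.

## 7. Known limitations

- No non-linear (HMR-type) flux model and no water-vapour dilution
  correction; failure sessions are rejected, not rescued.
- PERMANOVA exhaustive mode enumerates all assignments and is only
  feasible for small n (it is intended as an oracle and for tiny designs).
- RDA uses OLS throughout; no partial RDA or variance partitioning.
- The Mantel statistics of the motivating study (R = 0.385 / 0.640 /
  0.250) depend on its unreleased per-sample data and are format
  references only; no attempt is made to reproduce them numerically.
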