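# ruminant-ghg

Quantitative analysis pipeline for static-chamber greenhouse-gas experiments
on grazing ruminants, paired with rumen-microbiome community statistics. It
was built around a yak feeding-regime design on the Qinghai–Tibet Plateau —
traditional grazing (TG) versus warm-grazing + cold-indoor-feeding (WGCF),
observed as three season-groups (YWG warm grazing, YCG cold grazing, YCF
cold indoor feeding) — but every stage is generic: it needs only chamber
concentration series, ASV count tables with taxonomy, sample metadata and a
diet nutrient table.

## What it computes

**Flux estimation.** A sealed breathing chamber accumulates CO₂/CH₄; the
per-head flux follows from the fitted concentration slope by the ideal-gas
relation

```
F = dc/dt · (V/N) · (M/22.4) · (P/P₀) · (273/(273+T))      [mg s⁻¹ → ×3.6 → g head⁻¹ h⁻¹]
```

with `dc/dt` in ppm s⁻¹ (ordinary least squares over the session), chamber
volume `V` (m³), `N` animals, molar mass `M` (44 CO₂ / 16 CH₄), molar volume
22.4 L mol⁻¹ and a pressure/temperature density correction. Sessions with
R² < 0.9 fail QC and are dropped.

**Cumulative emissions.** Twelve 2-hourly session fluxes are integrated
over the day by the trapezoid rule with periodic closure
(`E_day = Σ (fᵢ+fᵢ₊₁)/2 · (tᵢ₊₁−tᵢ)`, closing from the last session back to
the first + 24 h), scaled by season length (default 180 d) to seasonal
kg head⁻¹, and summed warm + cold into annual regime totals
(TG = YWG + YCG, WGCF = YWG + YCF), with percent-difference contrasts.

**Group comparison.** One-way ANOVA with a single pooled SEM per row,
Duncan's multiple range test (studentized-range quantiles computed
numerically, protection level `α_p = 1−(1−α)^{p−1}`) and compact-letter
displays.

**Community statistics.** Rarefaction to 95 % of the minimum depth,
rank-level relative abundance, Shannon diversity, exact/approximate Wilcoxon
rank-sum and Kruskal–Wallis tests, Bray–Curtis distances, PCoA, PERMANOVA
(with a complete-enumeration option), the Mantel test against diet nutrient
distances, and RDA of genus-level communities on nutrient parameters with
forward variable selection.

**Synthetic data.** `ruminant_ghg.synthetic` generates the whole experiment
— chamber ramps whose slope is the exact algebraic inverse of the flux
equation, Dirichlet-multinomial count tables with group-specific
compositions, and the diet nutrient table — so the full pipeline runs and
is testable without any sequencing download.

## Worked example

```
ruminant-ghg simulate --out data --seed 1
ruminant-ghg flux --series data/chamber_series.csv --out results
ruminant-ghg cumulate --flux results/flux_estimates.tsv --metadata data/metadata.tsv --out results
```

or equivalently in one line, `python scripts/acceptance.py --seed 1 --out
results/acceptance.json`, which prints (seed 1):

```
flux: 385 sessions kept, 47 dropped by R^2 gate
label  level gas   day_g  seasonal_kg  annual_kg
  YCF  group CH4   45.80         8.24        NaN
  YCF  group CO2 2170.10       390.62        NaN
  YCG  group CH4   31.51         5.67        NaN
  YCG  group CO2 1246.50       224.37        NaN
  YWG  group CH4   57.25        10.31        NaN
  YWG  group CO2 1626.52       292.77        NaN
   TG regime CH4     NaN          NaN      15.98
   TG regime CO2     NaN          NaN     517.14
 WGCF regime CH4     NaN          NaN      18.55
 WGCF regime CO2     NaN          NaN     683.39
bacteria: mean Shannon 2.099; PERMANOVA F=5.445 p=0.0010; Mantel r=0.211 p=0.0050; selected nutrients ['NDF', 'DM']
```

Reading: 47 of 432 simulated sessions were non-linear failures rejected by
the R² ≥ 0.9 gate. Day emissions (g head⁻¹ d⁻¹) recover the simulator's true
rates — cold indoor feeding emits the most CO₂, cold grazing the least — and
the annual regime totals show WGCF above TG for both gases. PERMANOVA
confirms the simulated group structure in the bacterial community
(p = 0.001 at 999 permutations) and the Mantel test links community and
diet-nutrient distances.

## Acceptance script

`python scripts/acceptance.py --seed <int> --out <path>` regenerates the
synthetic experiment from the given seed, runs every pipeline stage (flux →
QC → cumulation → community statistics → ordination) and writes the results
manifest to `--out`. It touches nothing outside the repository.
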