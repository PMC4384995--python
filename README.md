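# mulchdeg

Biodegradable mulch films (aliphatic polyesters such as
poly(butylene succinate-*co*-adipate), PBSA) are buried in farmland soil and
broken down by native soil fungi that secrete esterases. Whether a given
field soil will degrade a film quickly is an open practical question for
farmers choosing between film products. `mulchdeg` implements, as a tested
reusable pipeline, the quantitative chain used to answer it in an 11-soil
laboratory incubation design:

1. **Film degradation from scanned images** (`film_quant`). A black film
   piece is scanned on a light background; opacity loss is scored from mean
   gray values:

   degradation ratio (%) = 100 · (ḡ_residual − ḡ_fresh) / (ḡ_background − ḡ_fresh)

   Ratios are summarised per soil and week (mean ± SE of replicates), and a
   per-week degradation *rate* is derived from the near-linear first three
   weeks (three selectable definitions).

2. **Viable counts and degrader isolation rates** (`plate_counts`). Dilution-
   plate colony counts convert to CFU g⁻¹ dry soil; on emulsified-polymer
   overlay plates, colonies with a clear zone are polymer degraders, and the
   isolation rate is their percent share of the total count.

3. **Soil esterase activity** (`esterase_assay`). A405 readings of released
   p-nitrophenol from pNP-valerate, blank- and background-corrected, convert
   to nmol g⁻¹ dry soil min⁻¹ via a calibration slope and the assay's volume,
   mass and time bookkeeping; replicates are summarised by geometric means.

4. **Ordered-trend and correlation statistics** (`trend_stats`). Spearman
   rank correlation with ties (exact permutation p at small n), Williams'
   and Shirley-Williams' step-down trend tests against a time-0 control at
   one-tailed α = 0.025 (isotonic amalgamation via an in-package PAVA;
   reference values from seeded Monte-Carlo null quantiles), exact-
   enumeration two-sided Mann-Whitney U, and a Lilliefors/KS normality check.

A seeded generator (`synthetic_data`) emulates every input with known ground
truth — film scans with holes of exact area fraction, Poisson plate counts,
logistic degrader growth over a 4-week incubation, and multi-soil datasets
with a prescribed rank correlation — so every stage has parameter-recovery
tests. The three summary tables of the reference study are bundled as
fixtures, and a reproduce workflow recomputes its published aggregates.

## Worked example

```python
from mulchdeg import io_cli, film_quant, trend_stats

fx = io_cli.load_fixtures()                      # bundled 11-soil tables
rates = io_cli.degradation_rates(fx.table2)      # % per week, "endpoint"
isolation = fx.fungal()["isolation_rate_percent"]
res = trend_stats.spearman(rates[isolation.index], isolation)
print(f"rho = {res.rho:.3f}, p = {res.p_value:.3f}, n = {res.n}")
```

prints

```
rho = 0.651, p = 0.030, n = 11
```

— soils with a larger share of polymer-degrading fungi degrade the film
faster; the correlation is significant at the 5 % level and robust to the
rate definition (ρ = 0.65–0.72 across the three variants).

The same tables give the cross-soil ranges: total culturable fungi
2.88 × 10⁴ – 2.10 × 10⁵ CFU g⁻¹, degrader isolation rates 4.1 – 42.3 %, and
week-4 degradation ratios from 1.4 % (slowest soil) to 95.9 % (fastest).
Run `mulchdeg reproduce --out report/` for the full recomputation with
pass/fail flags (including two internal inconsistencies of the source
tables that the workflow surfaces rather than hides).

The CLI mirrors the library: `mulchdeg quantify-film`, `mulchdeg counts`,
`mulchdeg esterase`, `mulchdeg trend`, `mulchdeg simulate`,
`mulchdeg reproduce` (see `--help` on each).

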