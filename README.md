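# epirange

Do epiphytes — plants that germinate and root on other plants — have
larger or smaller geographic ranges than terrestrial plants? Ordinary
comparisons say *smaller*: epiphytes are concentrated in a few
species-rich, small-ranged lineages (orchids above all), so the average
epiphyte is rarer than the average terrestrial species. But range size is
heritable, and once shared ancestry is controlled for, the epiphytic
lifeform itself is associated with *larger* ranges — a sign reversal with
direct conservation implications, since roughly half of epiphytes fall
under common rarity thresholds.

`epirange` implements that comparative analysis as a tested, reusable
pipeline for ecologists and conservation scientists:

- **Occurrence cleaning** — separate procedures for georeferenced records
  (native-range filter at botanical-country level, coordinate-precision
  cutoff, zero/equal-coordinate and centroid/capital/institution filters,
  per-species deduplication at 3 decimal places plus 110 m spatial
  thinning) and non-georeferenced records (duplicate collection localities,
  duplicate year × administrative unit, non-native countries via an
  ISO→botanical-country mapping), with a per-filter audit report.
- **Range metrics** — native botanical-country count; cleaned specimen
  count; extent of occurrence (EOO) as the minimum convex polygon of the
  cleaned points, evaluated as a geodesic polygon on the authalic sphere
  (radius 6371.0072 km), for species in ≤4 botanical countries with ≥3
  georeferenced records.
- **Regression layer** — log-response OLS; quasi-Poisson GLM (IRLS,
  Pearson dispersion) for the botanical-country count; and phylogenetic
  GLS with Pagel's λ estimated by profile maximum likelihood, where the
  residual covariance is `σ² C_λ` with `C[i,j]` the shared root-to-MRCA
  path length and λ scaling the off-diagonal. Effects are reported as
  percentage differences `100·(e^β − 1)` with Wald 95% CIs, and fits are
  aggregated across a set of trees (mean ± between-tree SD) to propagate
  phylogenetic-placement uncertainty.
- **Rarity** — EOO < 20,000 km² (the IUCN criterion B1 threshold, strict)
  and specimen count ≤ 5 (inclusive), with per-group proportions over the
  species whose metric is defined.
- **Synthetic data** — Yule trees, Markov lifeform evolution, log range
  sizes with known λ and lifeform effect, and occurrence records with
  labelled planted violations of every cleaning rule, so each stage can be
  tested against ground truth.

## Worked example

The headline phenomenon in one script — a scenario in which epiphytes
cluster in a deeply diverged, small-ranged clade while epiphytism itself
*increases* range size by a factor 1.5 (β = ln 1.5):

```python
import numpy as np
from epirange.synthetic_data import make_scenario
from epirange.phylo_regression import pgls_ml, ols_log, effect_size_percent

sc = make_scenario("confounded_clades", {"stem_length": 60.0}, seed=42)
X = np.column_stack([np.ones(len(sc.taxa)),
                     [1.0 if sc.lifeform[t] == "epiphyte" else 0.0
                      for t in sc.taxa]])
ols = ols_log(np.exp(sc.log_range), X)
pgls = pgls_ml(sc.log_range, X, sc.tree, sc.taxa)
for name, fit in [("OLS", ols), ("PGLS", pgls)]:
    e = effect_size_percent(fit, 1)
    lam = (f", lambda-hat = {fit.lambda_hat:.3f}"
           if fit.lambda_hat is not None else "")
    print(f"{name:4s} lifeform effect: {e.percent:+.1f}% "
          f"(95% CI {e.ci_low:+.1f}% to {e.ci_high:+.1f}%){lam}")
```

prints

```
OLS  lifeform effect: -99.5% (95% CI -99.7% to -99.1%)
PGLS lifeform effect: +47.7% (95% CI +40.5% to +55.2%), lambda-hat = 1.000
```

Ignoring phylogeny, epiphytes look dramatically smaller-ranged (they sit
in the clade whose deep Brownian displacement is negative); partitioning
out the phylogenetic covariance recovers the true positive effect, with CI
covering the planted +50%.

The same analysis runs end to end from files via the CLI:

```sh
epirange simulate --scenario baseline --n-species 200 --seed 1 --out-dir sim/
epirange clean --occurrences sim/occurrences_geo.csv \
    --occurrences sim/occurrences_nongeo.csv --checklist sim/checklist.csv \
    --regions sim/regions.geojson --ref-points sim/ref_points.csv \
    --out-geo g.csv --out-nongeo n.csv --report report.csv
epirange metrics --checklist sim/checklist.csv --clean-geo g.csv \
    --clean-nongeo n.csv --out range_table.csv
epirange regress --table range_table.csv --trees sim/trees.nwk \
    --metric eoo --model pgls --out fits.csv
epirange rarity --table range_table.csv --out rarity.csv
```

or in one shot from a flat config file with `epirange run --config analysis.cfg`
(cleaning report, range table, per-tree and aggregated fits, rarity summary
and a checksummed run manifest).

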