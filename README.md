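# ipwdid

Impact evaluation for two-wave household panels by inverse-probability
weighting combined with difference-in-differences (IPW-DID), plus the
composite nutrition and food-security indicators such evaluations typically
analyze.

The package covers the full workflow:

- **`ipwdid.synthdata`** — a synthetic panel generator with probit
  selection-on-observables, village clustering, outcome equations with known
  treatment effects, and raw instrument responses (knowledge-exam items,
  24-hour food recall, 7-day food frequencies, month calendars), so the
  whole pipeline is testable end to end without any external data.
- **`ipwdid.indicators`** — inverse-difficulty-weighted knowledge scores,
  household/child dietary diversity (HDDS, CDDS), 10-group food-group
  diversity, vitamin-A diversity, the food consumption score (FCS, WFP/HKI
  weights), 7-day vitamin-A consumption frequency, and food-security
  aggregates (MIHFP, relief months, asset sales, coping-strategy index).
  The 12-category-to-group mapping ships as an editable YAML data file.
- **`ipwdid.propensity`** — probit participation model (statsmodels MLE
  behind an explicit contract: separation and convergence diagnostics, HC1
  robust SEs, McFadden pseudo-R²), average marginal effects, and
  common-support trimming (intersection or treated-preserving conventions).
- **`ipwdid.matching`** — nearest-neighbour, radius and Epanechnikov-kernel
  matching; standardized-bias and balance reports (per-covariate bias and
  t-statistics, overall mean |bias|, probit re-fit pseudo-R² and LR test).
- **`ipwdid.estimation`** — IPW weights (1/p treated, 1/(1−p) control),
  weighted DID with village-clustered CR1 sandwich SEs, and placebo
  regressions of baseline outcomes on endline participation.
- **`ipwdid.report`** — one-config orchestration writing every table as CSV
  with a JSON manifest; deterministic under a fixed seed.
- **`ipwdid.recovery`** — Monte-Carlo parameter-recovery study used by the
  validity tests.

## CLI

```sh
# simulate a panel
ipwdid simulate --seed 1 --n-households 434 --out panel.csv

# probit + marginal-effects table
ipwdid score panel.csv --covariate male_head --covariate mwanza \
    --log-var age_head --out propensity.csv

# matching balance table
ipwdid match panel.csv --covariate male_head --covariate mwanza \
    --algorithm radius --out balance.csv

# IPW-DID effects and placebo checks
ipwdid estimate panel.csv --outcome adoption --covariate male_head \
    --covariate mwanza --out effects.csv
ipwdid placebo panel.csv --outcome knowledge --covariate male_head \
    --covariate mwanza --out placebo.csv

# everything from one config
ipwdid run-all --config examples/run_config.yaml --seed 1 --out runs/demo
```

See `examples/run_config.yaml` for the config schema.

## Python API

```python
import ipwdid as iw

panel = iw.generate_panel(iw.default_config(seed=1))
base = panel.baseline().set_index("household_id")

fit = iw.fit_probit(base[list(panel.covariate_kinds)], base["treated"],
                    log_vars=["age_head", "assets_usd"])
support = iw.common_support(fit.scores, base["treated"])
kept = support.kept[support.kept].index

weights = iw.ipw_weights(fit.scores.loc[kept], base.loc[kept, "treated"]).weights
result = iw.did_estimate(panel.df[panel.df.household_id.isin(kept)],
                         "adoption", weights=weights)
print(result.theta, result.theta_se)
```

## Notes on defaults

- Village count (30) and intra-cluster spread in the synthetic generator are
  package choices; survey instruments rarely report them.
- The FCS weight vector is the standard WFP/HKI one with sugar folded into
  the oil group (7 groups); it is fully configurable via the YAML map.
- The 10-group diversity count may be 0 for a household consuming nothing,
  although instruments usually presume at least one group.
- Knowledge weights are fitted on the pooled baseline sample and held fixed
  across waves so scores are comparable over time.
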