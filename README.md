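# pm25panel

Hybrid econometric / machine-learning analysis of premature mortality
attributable to PM2.5 air pollution in EU-27-style country-year panels.

Premature death from fine particulate matter (PM2.5, particles ≤ 2.5 µm)
is driven by an entangled mix of economic conditions (income, poverty,
government spending, inequality) and environmental/epidemiological ones
(exposure, disease incidence and mortality).  This package implements, as
a tested reusable pipeline, an analysis that treats the two modelling
cultures symmetrically and then merges them:

1. **Panel econometrics** — pooled OLS, fixed entity/time/both effects
   (LSDV), feasible-GLS random effects, and IV2SLS in which PM2.5
   *exposure* instruments an endogenous *welfare-loss* regressor
   (correlation ≈ 0.94 with the target raises reverse-causation concern;
   Durbin and Wu–Hausman tests decide).  Data is z-scored on the train
   partition only, so all coefficients are beta coefficients.
2. **Tree-ensemble regression** — random forest, extra trees, AdaBoost
   (stumps), gradient boosting, XGBoost, LightGBM, with exhaustive
   cross-validated grid search and impurity-based feature importances.
3. **Importance harmonization** — a linear model with coefficients β and
   p-values p gets *emulated* feature importances

   f_v = |β_v| (1 − p_v)^γ / Σ_j |β_j| (1 − p_j)^γ,  γ = 2 by default,

   a probability vector directly comparable to tree importances.  Column
   concentration is summarized by the Gini coefficient and Simpson's
   (Herfindahl) index λ = Σ p_i²; 1/λ is the equivalent number of equally
   weighted features.
4. **Stacking** — the 12 models' predictions form level 0; a tree
   blender (extra trees by default) learns level 1 and its importances W
   weight the grand 23 × 12 importance matrix **F** = (**L** | **M**):
   **V** = **F**·**W** is the aggregated feature-weight vector.
5. **Predictive unsupervised learning** — the full scaled 297 × 23 array,
   either equally weighted ("prior") or with columns scaled by V
   ("posterior"), feeds affinity-propagation clustering and six
   dimensionality-reduction methods (PCA, MDS, t-SNE, isomap, LLE,
   factor analysis).  Each 1-D embedding, standardized and sign-aligned,
   becomes a prediction of mortality; an "MDS ecliptic" uses the dominant
   plane of a 3-D MDS embedding, and an OLS blend unites all of them.
6. **Environmental Kuznets curves** — PCA composite indexes of the 11
   economic and 12 health variables, averaged per country, fitted against
   country mean mortality by polynomials of degree 1–4 (plus the average
   of the degree-2/3/4 curves), with cluster covariance ellipses and
   "sundew" model-comparison plots.

The assembled EU-27 panel (27 countries × 2008–2018, 297 rows) is not
publicly deposited, so a **synthetic-panel generator** reproduces its
statistical structure — two latent factors inducing within-group feature
correlation, entity effects, a year trend with the published sign
pattern, reference effect sizes, an endogenous welfare variable
calibrated to the published correlations (0.940138 / 0.769063), and the
reference missingness pattern (54/2/3 cells) repaired by LOESS + spline
imputation.  Reference tables from the original analysis (model
importances, emulated importances, linear coefficients, the
Kuznets index table) ship with the package for exact validation of the
diversity statistics.

## Worked example

```python
import pm25panel as pp

panel = pp.generate_endogenous_welfare(pp.generate_panel())
res = pp.run_analysis(
    panel,
    ensemble_params={m: {"n_estimators": 150} for m in pp.ENSEMBLE_MODELS},
    blender_estimators=300,
)
d = res.blender.diversity
print(f"blender: Gini {d.gini:.4f}, Simpson {d.simpson:.4f} "
      f"-> equivalent of {d.inv_simpson:.2f} models")
print(res.V.as_series().sort_values(ascending=False).head(3))
print(res.group_shares)
```

prints (seed 1 defaults):

```
blender: Gini 0.5207, Simpson 0.1578 -> equivalent of 6.34 models
exposure         0.2639
ischemic_death   0.0808
cardio_death     0.0645
{'economic': 0.298..., 'health': 0.702...}
```

Exposure dominates the aggregated weights and the economic/health split
lands near 30/70 — the same structure reported for the real panel.  The
payoff of the weighting is visible in the unsupervised stage
(`examples/04_unsupervised.py`): the mean r² of the six predictive
manifolds rises from −0.03 on the equally weighted array to +0.20 on the
importance-weighted array, and the OLS blend reaches 0.35 without ever
training on the target split.

The `examples/` directory holds one short narrative script per
capability (synthetic panel + imputation, linear models + specification
tests, importance harmonization + stacking, weighted clustering +
manifolds, Kuznets curves); each prints the numbers it computes and a
line on what they mean.

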