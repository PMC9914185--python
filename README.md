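# poriaopt

Surrogate modelling and multi-response optimization of ultrasonic-assisted
extraction of *Poria cocos* (Fu-ling) bioactives.

Extraction of natural products is a trade-off problem: ethanol
concentration, sonication time and solvent volume affect triterpene-acid
yield, polysaccharide and phenolic content and antioxidant activity in
different directions, and wet-lab budgets allow only a handful of runs.
`poriaopt` packages the standard design-of-experiments answer and its
machine-learning refinement in one tested pipeline, built around a 17-run
three-factor Box–Behnken design with eight measured responses:

- **RSM** — modified-cubic response surfaces
  Y = α₀ + Σαᵢ Xᵢ + Σαᵢᵢ Xᵢ² + Σαᵢⱼ XᵢXⱼ + Σαᵢᵢⱼ Xᵢ²Xⱼ fit by OLS on
  coded factors, with full ANOVA (lack of fit vs pure error, R²,
  adequate precision).
- **PCA / correlation grouping** of the responses into a triterpene-acid
  group and a polysaccharide/phenolic/antioxidant group.
- **Desirability optimization** — Derringer–Suich composite
  D = (∏ dᵢ^wᵢ)^(1/Σwᵢ) maximized over the factor box by deterministic
  multistart.
- **ANN-GA** — a 3-10-m tansig perceptron surrogate trained by
  Levenberg–Marquardt with early stopping, searched by a real-coded
  genetic algorithm (rank scaling, stochastic-uniform selection,
  elitism, intermediate crossover).
- **Synthetic data** — seeded ground-truth surfaces for parameter- and
  optimum-recovery testing of every stage.

The audience is process chemists and method developers who want the
RSM-vs-ANN-GA comparison reproducible from a table of run means rather
than locked inside desktop software. See `docs/methods.md` for the
modelling details and design choices.

## Worked example

```python
import poriaopt as po

table = po.poria_dataset()               # packaged 17-run BBD, 8 responses
group1, group2 = po.default_groups()

# response surface for pachymic acid, automatic term selection
basis = po.select_terms(table, "PA", "auto")
fit = po.fit_rsm(table, "PA", basis)
print(round(po.predict(fit, [50, 40, 40]), 2))   # 422.08 — centre prediction, ug/g
an = po.anova_table(fit, table)
print(round(an.r_squared, 4), round(an.adequate_precision, 1))  # 0.9994 97.0

# desirability optimum for the antioxidant/polysaccharide group
fits = [po.fit_rsm(table, m, po.select_terms(table, m, "auto"))
        for m in group2.members]
res = po.optimize_desirability(fits, po.goals_from_table(table, group2.members))
print(res.x_actual.round(2), round(res.composite_desirability, 2))
# [25.   30.89 20.  ] 0.92
```

The centre-point prediction (422.08 μg/g) equals the mean of the five
centre-replicate runs — an exact property of least squares on a
Box–Behnken design. The Group-2 optimum puts ethanol and solvent volume
at their lower bounds (25 %, 20 mL) with a composite desirability of
0.92: mild, low-volume extraction favours the polysaccharide, phenolic
and antioxidant responses, whereas the triterpene-acid group (Group 1)
is driven to high solvent volume (60 mL).

The same workflow is available from the shell:

```sh
poriaopt fit-rsm --out out/           # ANOVA, surface grids, optima JSON
poriaopt pca --replicate-level --include-factors --out out/
poriaopt ann-ga --seed 1 --out out/   # surrogate + GA vs RSM comparison table
poriaopt simulate --seed 3 --noise-sd 0 --out out/
```

`ann-ga` writes `comparison_table.csv` with the factor settings and
predicted responses of both optimizers side by side. YAML configuration
(`--config`) accepts `dataset`, `groups` (name → member list), `rsm`
(`basis_mode`: quadratic | full_modified_cubic | auto,
`grid_resolution`), `ann` (`max_epochs`, `patience`, `optimizer`) and
`ga` (any `GAConfig` field) blocks.

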