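# fiberknn

Predict the dietary fiber content of packaged foods and beverages from the six
nutrients commonly printed on nutrition panels (total sugar, carbohydrate,
protein, saturated fat, total fat, sodium), using category-restricted,
inverse-distance-weighted k-nearest neighbors.

The package covers the full workflow for food-supply monitoring:

- **`fiberknn.products`** — product data model, CSV I/O, record-level
  exclusion rules (missing panel / ingredients / brand, unbalanced
  parentheses in ingredients, duplicate ids) and category filtering by
  fiber-reporting rate or allow-list.
- **`fiberknn.features`** — six-feature derivation (starch = carbohydrate −
  total sugar; unsaturated fat = total fat − saturated fat) and min–max
  normalization against training-set statistics.
- **`fiberknn.knn`** — exhaustive-scan KNN within the query's food category
  under Manhattan (or Euclidean) distance, inverse-distance (or uniform)
  weighting, neighbor provenance, a first-neighbor-distance (d₁ > 0.08)
  caution flag, and JSON model artifacts.
- **`fiberknn.selection`** — brand-grouped 75/25 train/test splitting (whole
  brands travel together, preventing leakage of near-identical formulations)
  and five-fold cross-validated hyperparameter grid search.
- **`fiberknn.evaluation`** — R², MAE, Spearman ρ, fiber-density
  classification (negligible/low/medium/high at 0.9 / 3.7 / 7.3 g per 100 g
  or 100 mL), d₁-quartile stratification, rank-sum comparison of reporting vs
  non-reporting products, and supply-level median (IQR) summaries.
- **`fiberknn.simulate`** — synthetic supply generator with known fiber
  ground truth: Dirichlet mass compositions per category, brand clustering,
  a linear fiber relation with controllable noise, and logistic
  fiber-reporting masking biased toward high-fiber products.

## CLI

The `fiberknn` entry point chains the workflow end to end:

```bash
fiberknn simulate --out products.csv --truth-out truth.csv \
    --categories 6 --n-per-category 500 --seed 1
fiberknn clean    --in products.csv --out cleaned.csv --log-out exclusions.json
fiberknn split    --in cleaned.csv --train-out train.csv --test-out test.csv --seed 1
fiberknn tune     --in train.csv --out cv.csv --folds 5 --seed 1   # optional grid search
fiberknn fit      --in train.csv --model-out model.json --k 8
fiberknn predict  --model model.json --in test.csv --out predictions.csv
fiberknn evaluate --model model.json --in test.csv --out metrics.json
fiberknn summarize --model model.json --in cleaned.csv --out summary.csv
```

Every output carries a `#` metadata header (tool version, command, seed), so
reruns with identical configuration are byte-identical.

## Notes

- Sodium stays in mg; min–max scaling makes the unit immaterial.
- Per-100g and per-100mL products are pooled.
- Query features outside the training range are not clipped.
- Predictions with d₁ > 0.08 (configurable) are flagged `caution`: sparse
  neighborhoods predict markedly worse.
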