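"""Train the kernel-ridge surrogate and evaluate it on held-out prints.

80:20 split, per-feature standardization learned on the training side,
10-fold cross-validated grid search over the regularization strength,
then R^2 / MAE / RMSE on the untouched test rows.
"""

from printopt import (FactorLevels, ResponseSurface, apply_scaler,
                      compute_metrics, fit_scaler, generate_full_factorial,
                      grid_search_cv, krr_fit, krr_predict,
                      sample_measurements, split_dataset)

dataset = sample_measurements(ResponseSurface(),
                              generate_full_factorial(FactorLevels()),
                              replicates=5, seed=0)
train, test = split_dataset(dataset, test_share=0.20, seed=0)
print(f"train rows: {len(train)}, test rows: {len(test)}")

scaler = fit_scaler(train.X)
lam, kernel, cv_table = grid_search_cv(apply_scaler(scaler, train.X),
                                       train.y, seed=0)
print(f"selected lambda: {lam} (degree-{kernel.degree} polynomial kernel, "
      f"coef0 {kernel.coef0})")

model = krr_fit(apply_scaler(scaler, train.X), train.y, lam, kernel)
pred = krr_predict(model, apply_scaler(scaler, test.X))
m = compute_metrics(test.y, pred)
print(f"test R^2:  {m.r2:.4f}")
print(f"test MAE:  {100 * m.mae:.2f}% defect")
print(f"test RMSE: {100 * m.rmse:.2f}% defect")
# R^2 near 1 means the four parameters explain the defect level; MAE/RMSE
# are on the defect-percentage scale.
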