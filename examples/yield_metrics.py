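"""Fit and score yield regressors on synthetic remote-sensing features.

Generates linear yield data from soil moisture, chlorophyll, NDVI and NDSI,
fits ordinary least squares and a bagged tree ensemble, and reports
MAE/MSE/RMSE with their percentage twins.
"""

from agriflow.model_eval import (
    PredictionSet,
    SyntheticYieldConfig,
    evaluate_predictions,
    fit_linear,
    fit_tree_ensemble,
    generate_yield_data,
    train_test_split_indices,
)

cfg = SyntheticYieldConfig(n=300, noise_sd=0.25, seed=0)
X, y = generate_yield_data(cfg)
tr, te = train_test_split_indices(cfg.n, seed=0)

for name, model in (("linear", fit_linear(X[tr], y[tr])),
                    ("tree ensemble", fit_tree_ensemble(X[tr], y[tr], seed=0))):
    rep = evaluate_predictions(PredictionSet(y[te], model.predict(X[te])))
    print(f"{name:>13}: MAE={rep.mae:.3f} MSE={rep.mse:.3f} RMSE={rep.rmse:.3f} "
          f"(MAE accuracy {rep.accuracy_pct['mae']:.1f}%)")
# On linear ground truth OLS nearly reaches the noise floor (sd 0.25); the
# percentage maps each loss onto 100*(1 - loss/mean |y|).
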