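"""Regression models and evaluation for chlorophyll estimation.

Three learners are compared on every feature combination: an RBF-kernel
support vector machine (C = 20, gamma = 0.02), a random forest of 100 CART
trees, and a single-hidden-layer back-propagation network (10 logistic
units). Each model is trained ``n_repeats`` times with distinct seeds and
the per-sample prediction is the mean across repeats; SVM and the network
see z-scored features (statistics from the modeling split only), the
forest sees raw features.

Fits are scored on both the modeling and validation splits with

* R^2  = 1 - sum (y - yhat)^2 / sum (y - ybar)^2,
* RMSE = sqrt(mean (y - yhat)^2)            (trait units),
* MRE  = (100 / n) * sum |y - yhat| / y     (percent).

:class:`RepeatedAverageRegressor` is the scikit-learn estimator at the
core; :func:`fit_predict` and :func:`run_experiment` wrap it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

__all__ = [
    "ModelConfig",
    "RepeatedAverageRegressor",
    "split_dataset",
    "fit_predict",
    "evaluate",
    "run_experiment",
    "MODEL_NAMES",
]

MODEL_NAMES = ("svm", "rf", "bpnn")


@dataclass
class ModelConfig:
    """Hyper-parameters for the three learners and the protocol around them."""

    svm_kernel: str = "rbf"            # 'rbf' (Gaussian) or 'poly'
    svm_c: float = 20.0
    svm_gamma: float = 0.02
    rf_n_trees: int = 100
    bpnn_hidden: tuple[int, ...] = (10,)
    bpnn_activation: str = "logistic"
    bpnn_max_epochs: int = 3000
    n_repeats: int = 10
    validation_fraction: float = 1.0 / 3.0   # modeling : validation = 2 : 1
    split_seed: int = 0
    model_seed: int = 0

    def __post_init__(self) -> None:
        if self.svm_c <= 0 or self.svm_gamma <= 0:
            raise ValueError("SVM C and gamma must be positive")
        if self.rf_n_trees < 1:
            raise ValueError("rf_n_trees must be >= 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation fraction must be in (0, 1)")


class RepeatedAverageRegressor(BaseEstimator, RegressorMixin):
    """One of the three learners, fitted repeatedly and averaged.

    Parameters
    ----------
    model : {'svm', 'rf', 'bpnn'}, default 'rf'
        Base learner. 'svm' and 'bpnn' are wrapped in a StandardScaler
        pipeline (z-score from the training data); 'rf' is fitted raw.
    n_repeats : int, default 10
        Number of refits with distinct seeds; predictions are averaged.
        (The SVM is deterministic, so its repeats coincide.)
    config : ModelConfig, optional
        Hyper-parameters; defaults used when omitted.
    random_state : int, default 0
        Seed for the repeat seeds.

    Attributes
    ----------
    estimators_ : list
        The fitted per-repeat pipelines.
    """

    def __init__(self, model: str = "rf", n_repeats: int = 10,
                 config: ModelConfig | None = None, random_state: int = 0):
        self.model = model
        self.n_repeats = n_repeats
        self.config = config
        self.random_state = random_state

    def _base(self, cfg: ModelConfig, seed: int):
        if self.model == "svm":
            return make_pipeline(
                StandardScaler(),
                SVR(kernel=cfg.svm_kernel, C=cfg.svm_c, gamma=cfg.svm_gamma),
            )
        if self.model == "rf":
            return RandomForestRegressor(
                n_estimators=cfg.rf_n_trees, random_state=seed
            )
        if self.model == "bpnn":
            return make_pipeline(
                StandardScaler(),
                MLPRegressor(
                    hidden_layer_sizes=cfg.bpnn_hidden,
                    activation=cfg.bpnn_activation,
                    solver="lbfgs",
                    max_iter=cfg.bpnn_max_epochs,
                    random_state=seed,
                ),
            )
        raise ValueError(f"unknown model {self.model!r}; expected one of {MODEL_NAMES}")

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if np.ptp(y) == 0:
            # degenerate constant target: forests interpolate it, but the
            # scaled learners cannot be meaningfully trained
            if self.model != "rf":
                raise ValueError("constant target: nothing to regress")
        cfg = self.config or ModelConfig()
        rng = np.random.default_rng(self.random_state)
        seeds = rng.integers(0, 2**31 - 1, size=self.n_repeats)
        self.estimators_ = []
        for s in seeds:
            est = self._base(cfg, int(s))
            est.fit(X, y)
            self.estimators_.append(est)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "estimators_")
        X = check_array(X)
        preds = np.stack([est.predict(X) for est in self.estimators_])
        return preds.mean(axis=0)


def split_dataset(
    features: np.ndarray,
    target: np.ndarray,
    validation_fraction: float = 1.0 / 3.0,
    split_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Target-stratified deterministic split into modeling/validation indices.

    Samples are sorted by the target (ties shuffled reproducibly by
    ``split_seed``) and every third sorted position — the middle of each
    consecutive triple — goes to validation, so both splits span the trait
    range. Only the 2:1 ratio is supported, matching a modeling set twice
    the validation set.
    """
    y = np.asarray(target, dtype=float)
    n = y.size
    if n < 6:
        raise ValueError(f"need at least 6 samples to split, got {n}")
    if abs(validation_fraction - 1.0 / 3.0) > 1e-9:
        raise ValueError("only a 2:1 modeling:validation split is supported")
    rng = np.random.default_rng(split_seed)
    perm = rng.permutation(n)
    order = perm[np.argsort(y[perm], kind="stable")]
    positions = np.arange(n)
    val_mask = positions % 3 == 1
    val_idx = np.sort(order[val_mask])
    model_idx = np.sort(order[~val_mask])
    return model_idx, val_idx


def fit_predict(
    model: str,
    config: ModelConfig,
    X_model: np.ndarray,
    y_model: np.ndarray,
    X_val: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Train with repeat-averaging; return predictions for both splits."""
    est = RepeatedAverageRegressor(
        model=model,
        n_repeats=config.n_repeats,
        config=config,
        random_state=config.model_seed,
    ).fit(X_model, y_model)
    return est.predict(X_model), est.predict(X_val)


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """R^2, RMSE and MRE (%) of predictions against observations.

    R^2 is NaN (flagged) when the observations have zero variance; MRE
    requires strictly positive observations.
    """
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if y.shape != p.shape:
        raise ValueError("length mismatch")
    if np.any(y <= 0):
        raise ValueError("MRE requires positive observations")
    resid = y - p
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    rmse = float(np.sqrt(ss_res / y.size))
    mre = float(100.0 * np.mean(np.abs(resid) / y))
    return {"r2": r2, "rmse": rmse, "mre": mre}


def run_experiment(
    features: pd.DataFrame,
    targets: dict[str, np.ndarray],
    combinations: dict[str, dict],
    config: ModelConfig | None = None,
    models: tuple[str, ...] = MODEL_NAMES,
) -> pd.DataFrame:
    """Full trait x combination x model grid, scored on both splits.

    Parameters
    ----------
    features
        Master feature table (samples x all candidate features).
    targets
        Trait name -> per-sample values, aligned with ``features`` rows.
    combinations
        Trait name -> {combination name -> FeatureCombination}.
    config
        Protocol and hyper-parameters.
    models
        Subset of ``MODEL_NAMES`` to run.

    Returns
    -------
    Tidy DataFrame with one row per (trait, combination, model, split) and
    columns r2, rmse, mre.
    """
    cfg = config or ModelConfig()
    rows = []
    for trait, y in targets.items():
        y = np.asarray(y, dtype=float)
        model_idx, val_idx = split_dataset(
            features.to_numpy(), y, cfg.validation_fraction, cfg.split_seed
        )
        for comb_name, comb in combinations[trait].items():
            X = features[comb.feature_names].to_numpy(dtype=float)
            for model in models:
                p_model, p_val = fit_predict(
                    model, cfg, X[model_idx], y[model_idx], X[val_idx]
                )
                for split, idx, pred in (
                    ("modeling", model_idx, p_model),
                    ("validation", val_idx, p_val),
                ):
                    metrics = evaluate(y[idx], pred)
                    rows.append(
                        {
                            "trait": trait,
                            "combination": comb_name,
                            "model": model,
                            "split": split,
                            **metrics,
                        }
                    )
    return pd.DataFrame(rows)
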