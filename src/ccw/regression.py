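"""Area -> weight regression: feature assembly, model fitting, uncertainty.

Four feature groups ("mods") are regressed against the matching weight:

* Mod1 — overall silhouette area (sum of all parts) per view vs total weight
* Mod2 — torso (carcass) area per view vs torso weight
* Mod3 — head area per view vs head weight
* Mod4 — leg area per view vs leg weight

Each mod yields exactly three features — the calibrated area (cm^2) in the
ventral, dorsal, and lateral views, with the three replicate captures per
view averaged first.  Five regressor families are supported: a multilayer
perceptron, RBF-kernel support vector regression, Bayesian ridge regression,
LightGBM, and XGBoost gradient boosting.  Models are fitted on the training
carcasses, hyperparameters are chosen on the validation carcasses, and R^2
and RMSE are reported on the held-out test carcasses, together with
percentile-bootstrap 95% confidence intervals and a +/-2-sigma residual
outlier flagging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import BayesianRidge
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

MODS = {
    "Mod1": ("overall", "weight_total_g"),
    "Mod2": ("torso", "weight_torso_g"),
    "Mod3": ("head", "weight_head_g"),
    "Mod4": ("leg", "weight_leg_g"),
}
MODEL_NAMES = ("mlp", "svr", "bayes", "lgbm", "xgb")
_VIEWS = ("ventral", "dorsal", "lateral")


@dataclass
class RegressionResult:
    model: str
    mod: str
    r2: float
    rmse: float
    ci_r2: tuple[float, float]
    ci_rmse: tuple[float, float]
    n_test: int
    best_params: dict

    def as_row(self) -> dict:
        return {
            "model": self.model, "mod": self.mod, "r2": self.r2,
            "rmse_g": self.rmse,
            "ci_r2_lo": self.ci_r2[0], "ci_r2_hi": self.ci_r2[1],
            "ci_rmse_lo": self.ci_rmse[0], "ci_rmse_hi": self.ci_rmse[1],
            "n_test": self.n_test,
        }


def assemble_features(areas: pd.DataFrame, weights: pd.DataFrame,
                      mod: str) -> pd.DataFrame:
    """Build the per-carcass feature table for one mod.

    ``areas`` has columns carcass_id, view, replicate, part, area_cm2;
    ``weights`` has carcass_id plus weight_*_g columns.  Replicates are
    averaged per view; carcasses missing a view are dropped with a warning.
    """
    if mod not in MODS:
        raise ValueError(f"unknown mod {mod!r}; choose from {sorted(MODS)}")
    group, target_col = MODS[mod]
    df = areas.copy()
    if group == "overall":
        df = (df.groupby(["carcass_id", "view", "replicate"], as_index=False)
                .area_cm2.sum())
    else:
        df = df[df.part == group][
            ["carcass_id", "view", "replicate", "area_cm2"]]
    per_view = (df.groupby(["carcass_id", "view"], as_index=False)
                  .area_cm2.mean())
    wide = per_view.pivot(index="carcass_id", columns="view", values="area_cm2")
    views = [v for v in _VIEWS if v in wide.columns]
    incomplete = wide[views].isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"dropping {int(incomplete.sum())} carcass(es) missing a view",
            stacklevel=2,
        )
        wide = wide[~incomplete]
    wide = wide[views].rename(columns={v: f"area_{v}_cm2" for v in views})
    table = wide.reset_index().merge(
        weights[["carcass_id", target_col]], on="carcass_id", how="inner"
    ).rename(columns={target_col: "target_g"})
    table["mod"] = mod
    return table


def _candidate_models(name: str, seed: int):
    """Small fixed hyperparameter grids per model family."""
    if name == "mlp":
        return [
            make_pipeline(StandardScaler(), MLPRegressor(
                hidden_layer_sizes=h, solver="lbfgs", max_iter=5000,
                alpha=1e-4, random_state=seed))
            for h in [(32,), (64,)]
        ]
    if name == "svr":
        return [
            make_pipeline(StandardScaler(),
                          SVR(kernel="rbf", C=c, gamma="scale", epsilon=eps))
            for c in (10.0, 100.0, 1000.0) for eps in (1e-3, 1e-2)
        ]
    if name == "bayes":
        return [BayesianRidge()]
    if name == "lgbm":
        from lightgbm import LGBMRegressor

        return [
            LGBMRegressor(n_estimators=300, learning_rate=0.05,
                          num_leaves=leaves, min_child_samples=5,
                          random_state=seed, verbose=-1)
            for leaves in (15, 31)
        ]
    if name == "xgb":
        from xgboost import XGBRegressor

        return [
            XGBRegressor(n_estimators=300, learning_rate=0.05,
                         max_depth=depth, random_state=seed,
                         verbosity=0)
            for depth in (3, 5)
        ]
    raise ValueError(
        f"unknown model {name!r}; supported models: {', '.join(MODEL_NAMES)}"
    )


def _fit_predict(est, x_tr, y_tr, x_te, scale_target: bool):
    """Fit with an optionally standardized target and predict on x_te."""
    if scale_target:
        mu, sd = y_tr.mean(), y_tr.std()
        sd = sd if sd > 0 else 1.0
        est.fit(x_tr, (y_tr - mu) / sd)
        return est.predict(x_te) * sd + mu
    est.fit(x_tr, y_tr)
    return est.predict(x_te)


def r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """R^2 = 1 - SSres/SStot; degenerate SStot=0 -> 1 if perfect else 0."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    ssres = float(((y_true - y_pred) ** 2).sum())
    sstot = float(((y_true - y_true.mean()) ** 2).sum())
    if sstot == 0:
        return 1.0 if ssres == 0 else 0.0
    return 1.0 - ssres / sstot


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(y_true) - np.asarray(y_pred)) ** 2)))


def fit_and_evaluate(table: pd.DataFrame, model_name: str, split,
                     seed: int = 0, n_bootstrap: int = 1000) -> RegressionResult:
    """Fit one model family on one mod's feature table and score the test split.

    The split is carcass-wise (a SplitManifest); train/val/test rows are
    disjoint by construction.  Hyperparameters are selected on the validation
    RMSE, then the winning configuration is refitted on the training split
    and evaluated once on the test split.
    """
    feat_cols = [c for c in table.columns if c.startswith("area_")]
    sub = {
        name: table[table.carcass_id.map(split.assignment.get) == name]
        for name in ("train", "val", "test")
    }
    for name, t in sub.items():
        if t.empty:
            raise ValueError(f"{name} split has no feature rows")
    x = {k: t[feat_cols].to_numpy(float) for k, t in sub.items()}
    y = {k: t["target_g"].to_numpy(float) for k, t in sub.items()}

    scale_target = model_name in ("mlp", "svr")
    best, best_rmse = None, np.inf
    for cand in _candidate_models(model_name, seed):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred_val = _fit_predict(cand, x["train"], y["train"], x["val"],
                                    scale_target)
        err = rmse(y["val"], pred_val)
        if err < best_rmse:
            best, best_rmse = cand, err
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred_test = _fit_predict(best, x["train"], y["train"], x["test"],
                                 scale_target)
    ci_r2, ci_rmse = bootstrap_ci(y["test"], pred_test, n_boot=n_bootstrap,
                                  seed=seed)
    params = best.get_params() if hasattr(best, "get_params") else {}
    params = {k: v for k, v in params.items()
              if isinstance(v, (int, float, str, tuple))}
    return RegressionResult(
        model=model_name, mod=str(table["mod"].iloc[0]),
        r2=r2_score(y["test"], pred_test), rmse=rmse(y["test"], pred_test),
        ci_r2=ci_r2, ci_rmse=ci_rmse, n_test=len(pred_test),
        best_params=params,
    )


def bootstrap_ci(y_true, y_pred, n_boot: int = 1000, level: float = 0.95,
                 seed: int = 0) -> tuple[tuple[float, float], tuple[float, float]]:
    """Percentile-bootstrap CIs for R^2 and RMSE over paired resamples."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    n = len(y_true)
    if n < 5:
        raise ValueError("bootstrap CI requires at least 5 paired observations")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    yt = y_true[idx]
    yp = y_pred[idx]
    res2 = (yt - yp) ** 2
    ssres = res2.sum(axis=1)
    sstot = ((yt - yt.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    r2s = np.where(sstot > 0, 1.0 - ssres / np.where(sstot > 0, sstot, 1.0),
                   np.where(ssres == 0, 1.0, 0.0))
    rmses = np.sqrt(res2.mean(axis=1))
    lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
    ci_r2 = tuple(float(v) for v in np.percentile(r2s, [lo, hi]))
    ci_rmse = tuple(float(v) for v in np.percentile(rmses, [lo, hi]))
    return ci_r2, ci_rmse


def residual_outliers(y_true, y_pred) -> tuple[np.ndarray, float]:
    """Flag predictions whose |residual| exceeds twice the residual SD.

    Returns (boolean flags, sigma); sigma uses the n-1 denominator, and
    sigma = 0 yields no flags.
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if len(y_true) < 2:
        raise ValueError("residual outlier flagging requires at least 2 points")
    res = y_true - y_pred
    sigma = float(res.std(ddof=1))
    if sigma == 0:
        return np.zeros(len(res), dtype=bool), 0.0
    return np.abs(res) > 2 * sigma, sigma


def evaluate_all(table_by_mod: dict[str, pd.DataFrame], split, seed: int = 0,
                 models=MODEL_NAMES, n_bootstrap: int = 1000) -> pd.DataFrame:
    """Fit every (model, mod) combination; return a tidy results table."""
    rows = []
    for mod, table in table_by_mod.items():
        for name in models:
            rows.append(
                fit_and_evaluate(table, name, split, seed=seed,
                                 n_bootstrap=n_bootstrap).as_row())
    return pd.DataFrame(rows)
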