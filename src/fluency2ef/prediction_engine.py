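"""Confound-corrected repeated cross-validation prediction of EF scores.

For every executive-function target variable, fluency features are used to
predict scores of unseen participants with a random-forest regressor inside a
repeated k-fold cross-validation (default 10 folds x 10 repetitions = 100
fitted models per target).  All preprocessing — median imputation of missing
features, z-scoring, and ordinary-least-squares removal of the sex/age/
education confounds — is estimated on the training rows of each fold only and
applied to the held-out rows with the training parameters, so no information
leaks across the fold boundary.

Prediction performance is the mean Pearson correlation between true and
predicted scores over all fold models.  Its p-value treats the mean r as a
correlation observed on n participants (t = r*sqrt(n-2)/sqrt(1-r^2),
two-sided); a pooled variant (correlating all held-out predictions at once)
is available.  Targets with p below the screening level (default 0.01) count
as highly predictable.

Feature importance is Breiman-style out-of-bag permutation importance:
per tree, the increase in mean-squared error on its out-of-bag rows when one
feature column is permuted, averaged over trees and over the fold models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

DEFAULT_CONFOUNDS = ("sex", "age", "education")


@dataclass
class CVConfig:
    """Settings of the repeated cross-validation procedure."""

    n_folds: int = 10
    n_repetitions: int = 10
    n_trees: int = 100
    alpha: float = 0.01
    seed: int = 0
    feature_set: str = "full"  # "full" | "classical"
    confounds: tuple[str, ...] = DEFAULT_CONFOUNDS
    #: Fraction of features considered at each split; 1/3 is the regression-
    #: forest default in the classic literature.
    max_features: float = 1 / 3
    p_method: str = "parametric"  # "parametric" | "pooled"
    standardize_target: bool = False

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.feature_set not in ("full", "classical"):
            raise ValueError(f"unknown feature_set {self.feature_set!r}")
        if self.p_method not in ("parametric", "pooled"):
            raise ValueError(f"unknown p_method {self.p_method!r}")


@dataclass
class PredictionResult:
    """Per-target outcome of the repeated-CV procedure."""

    target: str
    fold_r: np.ndarray  # shape (n_repetitions, n_folds)
    mean_r: float
    p_value: float
    significant: bool
    n_models: int
    n_participants: int
    feature_names: list[str]
    importance: np.ndarray | None = None  # averaged over models
    top5: pd.DataFrame | None = None
    skipped: str | None = None


class FoldPreprocessor:
    """Train-fold imputation + z-scoring + confound residualization.

    Every parameter (medians, means, standard deviations, OLS coefficients)
    is estimated from the training rows handed to :meth:`fit`; held-out rows
    are transformed with those frozen parameters.
    """

    def __init__(self) -> None:
        self.medians_: np.ndarray | None = None
        self.means_: np.ndarray | None = None
        self.sds_: np.ndarray | None = None
        self.coefs_: np.ndarray | None = None  # (n_confounds + 1, n_features)

    def fit(self, X: np.ndarray, confounds: np.ndarray) -> "FoldPreprocessor":
        X = np.asarray(X, dtype=float)
        self.medians_ = np.nanmedian(X, axis=0)
        # All-NaN training column: impute 0 so the column passes through inert.
        self.medians_ = np.where(np.isnan(self.medians_), 0.0, self.medians_)
        Xi = self._impute(X)
        self.means_ = Xi.mean(axis=0)
        sds = Xi.std(axis=0, ddof=0)
        self.sds_ = np.where(sds == 0.0, 1.0, sds)  # zero-variance -> all-zero column
        Z = (Xi - self.means_) / self.sds_
        C = self._design(confounds)
        self.coefs_, *_ = np.linalg.lstsq(C, Z, rcond=None)
        return self

    def transform(self, X: np.ndarray, confounds: np.ndarray) -> np.ndarray:
        if self.medians_ is None:
            raise RuntimeError("FoldPreprocessor.transform before fit")
        Z = (self._impute(np.asarray(X, dtype=float)) - self.means_) / self.sds_
        return Z - self._design(confounds) @ self.coefs_

    def fit_transform(self, X: np.ndarray, confounds: np.ndarray) -> np.ndarray:
        return self.fit(X, confounds).transform(X, confounds)

    def _impute(self, X: np.ndarray) -> np.ndarray:
        Xi = X.copy()
        nan_rows, nan_cols = np.nonzero(np.isnan(Xi))
        Xi[nan_rows, nan_cols] = self.medians_[nan_cols]
        return Xi

    @staticmethod
    def _design(confounds: np.ndarray) -> np.ndarray:
        C = np.asarray(confounds, dtype=float)
        return np.column_stack([np.ones(len(C)), C])


def residualize_confounds(
    train_X: np.ndarray,
    train_confounds: np.ndarray,
    test_X: np.ndarray,
    test_confounds: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score and regress confounds out of features, train-parameters only."""
    prep = FoldPreprocessor().fit(train_X, train_confounds)
    return prep.transform(train_X, train_confounds), prep.transform(test_X, test_confounds)


# ---------------------------------------------------------------------------
# Correlation and significance helpers
# ---------------------------------------------------------------------------

def _safe_pearson(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Pearson r; 0 when either side is constant (no usable signal)."""
    if np.std(y_true) == 0.0 or np.std(y_pred) == 0.0:
        return 0.0
    return float(np.corrcoef(y_true, y_pred)[0, 1])


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p treating r as a correlation observed on n samples."""
    if n < 3 or abs(r) >= 1.0:
        return 0.0 if abs(r) >= 1.0 and n >= 3 else 1.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Uniform random partition into n_folds sets (no stratification)."""
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, n_folds)]


# ---------------------------------------------------------------------------
# Out-of-bag permutation importance
# ---------------------------------------------------------------------------

def oob_permutation_importance(
    forest: RandomForestRegressor,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-feature mean increase in out-of-bag MSE under column permutation.

    For each tree, predictions on its out-of-bag rows give a baseline error;
    permuting one feature among those rows and re-predicting measures how much
    the tree relied on it.  Averaged over trees; features a forest never uses
    score ~0.
    """
    n, p = X.shape
    increases = np.zeros(p)
    counts = np.zeros(p)
    for tree, samples in zip(forest.estimators_, forest.estimators_samples_):
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[samples] = False
        if oob_mask.sum() < 2:
            continue
        X_oob = X[oob_mask]
        y_oob = y[oob_mask]
        base = np.mean((tree.predict(X_oob) - y_oob) ** 2)
        for j in range(p):
            X_perm = X_oob.copy()
            X_perm[:, j] = rng.permutation(X_perm[:, j])
            err = np.mean((tree.predict(X_perm) - y_oob) ** 2)
            increases[j] += err - base
            counts[j] += 1
    counts[counts == 0] = 1
    return increases / counts


def top_k(
    importance: np.ndarray, feature_names: list[str], k: int = 5
) -> list[str]:
    """Top-k features by importance; ties broken by canonical name order."""
    order = sorted(
        range(len(feature_names)),
        key=lambda j: (-importance[j], feature_names[j]),
    )
    return [feature_names[j] for j in order[:k]]


# ---------------------------------------------------------------------------
# Repeated cross-validation for one target
# ---------------------------------------------------------------------------

def run_repeated_cv(
    features: pd.DataFrame,
    target: pd.Series,
    confounds: pd.DataFrame,
    config: CVConfig,
    compute_importance: bool = False,
) -> PredictionResult:
    """Score one EF target with the repeated-CV random-forest procedure.

    Rows with a missing target value are dropped; missing *features* are
    median-imputed inside each training fold.  Returns the per-fold r matrix,
    its mean, the significance screen, and (optionally) out-of-bag
    permutation importances averaged over all fitted models.
    """
    feature_names = list(features.columns)
    joined = features.join(target.rename("__target__"), how="inner") \
                     .join(confounds, how="inner")
    joined = joined[~joined["__target__"].isna()]
    n = len(joined)
    if n < 20:
        return _skipped_result(target.name, feature_names, n,
                               f"only {n} participants with a target value")
    y_all = joined["__target__"].to_numpy(dtype=float)
    if np.std(y_all) == 0.0:
        return _skipped_result(target.name, feature_names, n, "constant target")
    X_all = joined[feature_names].to_numpy(dtype=float)
    C_all = joined[list(config.confounds)].to_numpy(dtype=float)

    master = np.random.SeedSequence(config.seed)
    fold_seed, forest_seed, perm_seed = master.spawn(3)
    fold_rngs = [np.random.default_rng(s) for s in fold_seed.spawn(config.n_repetitions)]
    forest_states = [
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in forest_seed.spawn(config.n_repetitions * config.n_folds)
    ]
    perm_rng = np.random.default_rng(perm_seed)

    fold_r = np.zeros((config.n_repetitions, config.n_folds))
    importance_sum = np.zeros(len(feature_names))
    n_importance = 0
    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []

    model_idx = 0
    for rep in range(config.n_repetitions):
        folds = _fold_indices(n, config.n_folds, fold_rngs[rep])
        for f, test_idx in enumerate(folds):
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            prep = FoldPreprocessor().fit(X_all[train_mask], C_all[train_mask])
            X_train = prep.transform(X_all[train_mask], C_all[train_mask])
            X_test = prep.transform(X_all[test_idx], C_all[test_idx])
            y_train = y_all[train_mask]
            y_test = y_all[test_idx]
            if config.standardize_target:
                mu, sd = y_train.mean(), y_train.std() or 1.0
                y_train = (y_train - mu) / sd
                y_test = (y_test - mu) / sd
            forest = RandomForestRegressor(
                n_estimators=config.n_trees,
                max_features=config.max_features,
                random_state=forest_states[model_idx],
                bootstrap=True,
            ).fit(X_train, y_train)
            y_pred = forest.predict(X_test)
            fold_r[rep, f] = _safe_pearson(y_test, y_pred)
            pooled_true.append(y_test)
            pooled_pred.append(y_pred)
            if compute_importance:
                importance_sum += oob_permutation_importance(
                    forest, X_train, y_train, perm_rng
                )
                n_importance += 1
            model_idx += 1

    mean_r = float(fold_r.mean())
    if config.p_method == "pooled":
        pooled_r = _safe_pearson(np.concatenate(pooled_true), np.concatenate(pooled_pred))
        p_value = correlation_p_value(pooled_r, n)
    else:
        p_value = correlation_p_value(mean_r, n)

    importance = importance_sum / n_importance if n_importance else None
    return PredictionResult(
        target=str(target.name),
        fold_r=fold_r,
        mean_r=mean_r,
        p_value=p_value,
        significant=bool(p_value < config.alpha),
        n_models=model_idx,
        n_participants=n,
        feature_names=feature_names,
        importance=importance,
    )


def _skipped_result(
    name: object, feature_names: list[str], n: int, reason: str
) -> PredictionResult:
    return PredictionResult(
        target=str(name), fold_r=np.zeros((0, 0)), mean_r=float("nan"),
        p_value=float("nan"), significant=False, n_models=0,
        n_participants=n, feature_names=feature_names, skipped=reason,
    )


# ---------------------------------------------------------------------------
# Battery-level orchestration
# ---------------------------------------------------------------------------

def run_battery(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    confounds: pd.DataFrame,
    config: CVConfig,
    importance_for: str = "significant",
) -> dict[str, PredictionResult]:
    """Run the repeated-CV procedure for every target column.

    ``importance_for``: ``"none"``, ``"significant"`` (re-run importance on
    targets passing the screen — the follow-up analysis only concerns highly
    predictable targets) or ``"all"``.
    """
    results: dict[str, PredictionResult] = {}
    for name in targets.columns:
        res = run_repeated_cv(features, targets[name], confounds, config,
                              compute_importance=(importance_for == "all"))
        results[name] = res
    if importance_for == "significant":
        for name, res in results.items():
            if res.significant:
                results[name] = run_repeated_cv(
                    features, targets[name], confounds, config,
                    compute_importance=True,
                )
    return results


def screen_targets(
    results: dict[str, PredictionResult],
    schema: pd.DataFrame | None = None,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Table of targets passing the significance screen, sorted by mean r."""
    rows = []
    for name, res in results.items():
        if res.skipped:
            continue
        flag = res.p_value < alpha if alpha is not None else res.significant
        if not flag:
            continue
        row = {"target": name, "mean_r": res.mean_r, "p_value": res.p_value}
        if schema is not None:
            meta = schema.loc[schema["variable"] == name]
            if len(meta):
                row["test"] = meta["test"].iloc[0]
                row["domain"] = meta["domain"].iloc[0]
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("mean_r", ascending=False).reset_index(drop=True)
    return out


def followup_spearman(
    features: pd.DataFrame,
    target: pd.Series,
    top_features: list[str],
) -> pd.DataFrame:
    """Spearman rank correlation of each top feature with the raw target.

    Complete pairs only; flags mark trend (p < 0.1) and significant (p < 0.05)
    correlations, the conventional bold/star report marks.
    """
    rows = []
    for feat in top_features:
        pair = pd.concat([features[feat], target], axis=1, join="inner").dropna()
        if len(pair) < 3:
            rho, p = float("nan"), float("nan")
        else:
            rho, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            rho, p = float(rho), float(p)
        rows.append({
            "feature": feat,
            "spearman_rho": rho,
            "p_value": p,
            "trend": bool(p < 0.1) if p == p else False,
            "significant": bool(p < 0.05) if p == p else False,
        })
    return pd.DataFrame(rows)


def attach_followup(
    results: dict[str, PredictionResult],
    features: pd.DataFrame,
    targets: pd.DataFrame,
    k: int = 5,
) -> None:
    """Fill the top-k importance ranking and Spearman follow-up in place."""
    for name, res in results.items():
        if res.importance is None:
            continue
        top = top_k(res.importance, res.feature_names, k=k)
        res.top5 = followup_spearman(features, targets[name], top)


def compare_feature_sets(
    full_results: dict[str, PredictionResult],
    classical_results: dict[str, PredictionResult],
    schema: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-target comparison of the full and classical (sum-score) arms.

    Both runs must cover the same targets and participants; the caller
    guarantees identical folds by using the same seed in both configs.
    """
    if set(full_results) != set(classical_results):
        raise ValueError("feature-set comparison needs identical target sets")
    rows = []
    for name in full_results:
        fr, cr = full_results[name], classical_results[name]
        if fr.skipped or cr.skipped:
            continue
        if fr.n_participants != cr.n_participants:
            raise ValueError(f"target {name}: participant sets differ between arms")
        row = {
            "target": name,
            "mean_r_full": fr.mean_r,
            "mean_r_classical": cr.mean_r,
            "delta_mean_r": fr.mean_r - cr.mean_r,
            "significant_full": fr.significant,
            "significant_classical": cr.significant,
        }
        if schema is not None:
            meta = schema.loc[schema["variable"] == name]
            if len(meta):
                row["domain"] = meta["domain"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def results_table(
    results: dict[str, PredictionResult],
    schema: pd.DataFrame | None = None,
    feature_set: str | None = None,
) -> pd.DataFrame:
    """Flat per-target results table (the on-disk ``results.tsv`` layout)."""
    rows = []
    for name, res in results.items():
        row = {
            "target": name,
            "mean_r": res.mean_r,
            "p_value": res.p_value,
            "significant": res.significant,
            "n_models": res.n_models,
            "n_participants": res.n_participants,
            "skipped": res.skipped or "",
        }
        if feature_set is not None:
            row["feature_set"] = feature_set
        if schema is not None:
            meta = schema.loc[schema["variable"] == name]
            if len(meta):
                row["test"] = meta["test"].iloc[0]
                row["domain"] = meta["domain"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)
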