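"""ADHD-vs-TD logistic classification.

Feature selection is bidirectional stepwise logistic regression driven by
Rao's score test (entry and removal both, threshold 0.035): at each step the
excluded feature with the smallest score-test p enters if below threshold,
and the included feature with the largest p leaves if at/above it, until a
fixed point.  The selected features feed a logistic model evaluated by
stratified five-fold cross-validation repeated 50 times; per repetition the
out-of-fold probabilities are pooled, and accuracy, F1 (with precision and
recall), midrank AUC and Cohen's kappa are averaged over repetitions.
Finally, non-significant features are pruned in order of increasing
coefficient |z| for as long as the mean AUC does not decrease.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import (
    accuracy_score,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

DEFAULT_ALPHA = 0.035
POSITIVE_CLASS = "ADHD"


# ---------------------------------------------------------------------------
# logistic likelihood machinery

@dataclass
class LogisticFit:
    beta: np.ndarray           # includes intercept at position 0
    cov: np.ndarray            # inverse observed information
    converged: bool
    ridged: bool               # True when a ridge stabilizer was needed

    @property
    def z(self) -> np.ndarray:
        se = np.sqrt(np.diag(self.cov))
        return self.beta / se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * sps.norm.sf(np.abs(self.z))


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
                 max_iter: int = 100, tol: float = 1e-9) -> LogisticFit:
    """Newton-Raphson logistic MLE with optional ridge stabilization.

    On non-convergence or runaway coefficients (quasi-separation) the fit is
    repeated with a small ridge penalty (excluding the intercept) and
    flagged.  ``X`` carries the features only; an intercept is added here.
    """
    Xd = _design(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = Xd.shape
    pen = np.zeros(p)
    pen[1:] = ridge
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(Xd @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = Xd.T @ (y - mu) - pen * beta
        info = (Xd * w[:, None]).T @ Xd + np.diag(pen)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    separated = (not converged) or np.max(np.abs(beta[1:] if p > 1 else beta)) > 30.0
    if separated and ridge == 0.0:
        stabilized = fit_logistic(X, y, ridge=1e-3 * n, max_iter=max_iter, tol=tol)
        return LogisticFit(stabilized.beta, stabilized.cov, stabilized.converged, ridged=True)
    eta = np.clip(Xd @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = (Xd * w[:, None]).T @ Xd + np.diag(pen)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return LogisticFit(beta, cov, converged, ridged=ridge > 0)


def predict_proba(fit: LogisticFit, X: np.ndarray) -> np.ndarray:
    eta = np.clip(_design(np.asarray(X, dtype=float)) @ fit.beta, -35, 35)
    return 1.0 / (1.0 + np.exp(-eta))


def rao_score_test(X_null: np.ndarray, x_new: np.ndarray, y: np.ndarray) -> float:
    """p-value of Rao's score test for adding one feature to a logistic model.

    The score and information are evaluated at the null-restricted MLE (the
    model without the candidate).  With the candidate column collinear with
    the null design the effective information vanishes and p = 1.
    """
    y = np.asarray(y, dtype=float)
    x_new = np.asarray(x_new, dtype=float)
    null_fit = fit_logistic(X_null, y)
    Xd = _design(np.asarray(X_null, dtype=float))
    eta = np.clip(Xd @ null_fit.beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    u = float(x_new @ (y - mu))
    xwx = float(x_new @ (w * x_new))
    xwX = (x_new * w) @ Xd
    XwX = (Xd * w[:, None]).T @ Xd
    try:
        v = xwx - float(xwX @ np.linalg.solve(XwX, xwX))
    except np.linalg.LinAlgError:
        return 1.0
    if v <= 1e-10:
        return 1.0
    stat = u * u / v
    return float(sps.chi2.sf(stat, df=1))


def stepwise_select(
    X: pd.DataFrame, y, alpha: float = DEFAULT_ALPHA, max_steps: int = 200,
) -> list[str]:
    """Bidirectional stepwise selection by Rao's score test.

    Entry: among excluded features, add the smallest score-test p if below
    ``alpha``.  Removal: among included features, drop the largest p
    (assessed by the score test of re-adding it to the remaining model) if
    at/above ``alpha``.  Iterates to a fixed point; deterministic, with ties
    broken by column order.  ``y`` may be labels or a binary vector.
    """
    yv = _binary_labels(y)
    cols = list(X.columns)
    Xv = {c: pd.to_numeric(X[c], errors="coerce").to_numpy(dtype=float) for c in cols}
    if any(np.isnan(v).any() for v in Xv.values()):
        raise ValueError("missing values must be imputed before selection")
    included: list[str] = []
    for _ in range(max_steps):
        changed = False
        X_null = _stack(Xv, included)
        best_col, best_p = None, np.inf
        for c in cols:
            if c in included:
                continue
            p = rao_score_test(X_null, Xv[c], yv)
            if p < best_p - 1e-15:
                best_col, best_p = c, p
        if best_col is not None and best_p < alpha:
            included.append(best_col)
            changed = True
        if included:
            worst_col, worst_p = None, -np.inf
            for c in included:
                rest = [k for k in included if k != c]
                p = rao_score_test(_stack(Xv, rest), Xv[c], yv)
                if p > worst_p + 1e-15:
                    worst_col, worst_p = c, p
            if worst_col is not None and worst_p >= alpha:
                included.remove(worst_col)
                changed = True
        if not changed:
            break
    return included


def _stack(Xv: dict, cols: list[str]) -> np.ndarray:
    if not cols:
        return np.empty((len(next(iter(Xv.values()))), 0))
    return np.column_stack([Xv[c] for c in cols])


def _binary_labels(y) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "OUS":
        return (arr == POSITIVE_CLASS).astype(float)
    return arr.astype(float)


# ---------------------------------------------------------------------------
# metrics

def compute_kappa(confusion) -> float:
    """Cohen's kappa from a square confusion-count table.

    ``(p_o - p_e) / (1 - p_e)`` with observed agreement ``p_o`` on the
    diagonal and chance agreement ``p_e`` from the margins; undefined (NaN)
    when chance agreement is 1.
    """
    c = np.asarray(confusion, dtype=float)
    total = c.sum()
    if total <= 0 or np.any(c < 0):
        raise ValueError("confusion table needs nonnegative counts, total > 0")
    po = np.trace(c) / total
    pe = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / total**2
    if pe >= 1.0:
        return float("nan")
    return float((po - pe) / (1.0 - pe))


def kappa_label(kappa: float) -> str:
    """Conventional agreement band for a kappa value."""
    if np.isnan(kappa):
        return "undefined"
    if kappa <= 0:
        return "poor agreement"
    if kappa <= 0.20:
        return "slight agreement"
    if kappa <= 0.40:
        return "fair agreement"
    if kappa <= 0.60:
        return "moderate agreement"
    if kappa <= 0.80:
        return "substantial agreement"
    return "perfect agreement"


@dataclass
class ModelReport:
    """Cross-validated logistic model summary."""

    features: list[str]
    coef_table: pd.DataFrame          # full-data fit: beta, z, p per feature
    kappa: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    traces: dict = field(default_factory=dict)  # per-repetition metric lists
    seed: int | None = None
    ridged: bool = False
    n_fold_redraws: int = 0

    @property
    def kappa_band(self) -> str:
        return kappa_label(self.kappa)

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "coefficients": self.coef_table.reset_index().to_dict(orient="records"),
            "kappa": self.kappa, "kappa_band": self.kappa_band,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "auc": self.auc,
            "seed": self.seed, "ridged": self.ridged,
            "n_fold_redraws": self.n_fold_redraws,
        }


def _full_data_table(X: pd.DataFrame, yv: np.ndarray, features: list[str]):
    if not features:
        empty = pd.DataFrame(columns=["beta", "z", "p"])
        return empty, False
    fit = fit_logistic(X[features].to_numpy(dtype=float), yv)
    table = pd.DataFrame(
        {"beta": fit.beta, "z": fit.z, "p": fit.p},
        index=["intercept"] + features,
    )
    return table, fit.ridged


def cross_validate(
    X: pd.DataFrame, y, features: list[str] | None = None,
    k: int = 5, repeats: int = 50, seed: int = 0, threshold: float = 0.5,
) -> ModelReport:
    """Repeated stratified k-fold cross-validation of the logistic model.

    Fold assignment is stratified and re-randomized per repetition; each
    repetition pools out-of-fold predicted probabilities, from which
    accuracy, precision, recall, F1 (positive class ADHD, threshold 0.5),
    midrank AUC and Cohen's kappa (pooled confusion table) are computed.
    Reported metrics are means across repetitions.  With an empty feature
    set the model predicts the training prevalence for every case, which
    pins AUC at 0.5.  Deterministic given ``seed``.
    """
    yv = _binary_labels(y)
    if yv.min() == yv.max():
        raise ValueError("both classes must be present")
    minority = int(min(np.sum(yv == 0), np.sum(yv == 1)))
    if minority < 2:
        raise ValueError("each class needs at least 2 members for stratified folds")
    k = max(2, min(k, minority))  # stratification cannot exceed the minority class
    features = list(X.columns) if features is None else list(features)
    Xm = X[features].to_numpy(dtype=float) if features else np.empty((len(yv), 0))
    rng = np.random.default_rng(seed)
    traces: dict[str, list[float]] = {m: [] for m in
                                      ("kappa", "accuracy", "precision", "recall", "f1", "auc")}
    redraws = 0
    any_ridged = False
    for _ in range(repeats):
        for _attempt in range(10):
            skf = StratifiedKFold(n_splits=k, shuffle=True,
                                  random_state=int(rng.integers(2**31)))
            splits = list(skf.split(Xm, yv))
            if all(len(np.unique(yv[tr])) == 2 for tr, _ in splits):
                break
            redraws += 1
        probs = np.empty(len(yv))
        for tr, te in splits:
            fit = fit_logistic(Xm[tr], yv[tr], ridge=1e-6)
            any_ridged |= fit.ridged
            probs[te] = predict_proba(fit, Xm[te]) if Xm.shape[1] else yv[tr].mean()
        pred = (probs >= threshold).astype(float)
        prec, rec, f1, _ = precision_recall_fscore_support(
            yv, pred, average="binary", zero_division=0)
        conf = np.array([
            [np.sum((yv == 0) & (pred == 0)), np.sum((yv == 0) & (pred == 1))],
            [np.sum((yv == 1) & (pred == 0)), np.sum((yv == 1) & (pred == 1))],
        ])
        traces["kappa"].append(compute_kappa(conf))
        traces["accuracy"].append(accuracy_score(yv, pred))
        traces["precision"].append(float(prec))
        traces["recall"].append(float(rec))
        traces["f1"].append(float(f1))
        traces["auc"].append(float(roc_auc_score(yv, probs)))
    coef_table, ridged_full = _full_data_table(X, yv, features)
    return ModelReport(
        features=features, coef_table=coef_table,
        kappa=float(np.nanmean(traces["kappa"])),
        accuracy=float(np.mean(traces["accuracy"])),
        precision=float(np.mean(traces["precision"])),
        recall=float(np.mean(traces["recall"])),
        f1=float(np.mean(traces["f1"])),
        auc=float(np.mean(traces["auc"])),
        traces=traces, seed=seed, ridged=ridged_full or any_ridged,
        n_fold_redraws=redraws,
    )


def prune_by_importance(
    X: pd.DataFrame, y, features: list[str],
    k: int = 5, repeats: int = 50, seed: int = 0,
    alpha: float = 0.05, tolerance: float = 0.0,
) -> tuple[list[str], ModelReport]:
    """Iteratively drop low-importance features while the mean AUC holds.

    Importance is |z| of each coefficient in the full-data fit; at each step
    the least important *non-significant* feature (p at/above ``alpha``) is
    dropped and the model re-cross-validated.  The drop is kept iff the mean
    AUC does not fall by more than ``tolerance`` (default: strict
    non-decrease); otherwise pruning stops.  Single-feature models are never
    pruned.
    """
    yv = _binary_labels(y)
    current = list(features)
    report = cross_validate(X, y, current, k=k, repeats=repeats, seed=seed)
    while len(current) > 1:
        table, _ = _full_data_table(X, yv, current)
        stats = table.drop(index="intercept")
        weak = stats[stats["p"] >= alpha]
        if weak.empty:
            break
        drop = weak["z"].abs().idxmin()
        candidate = [c for c in current if c != drop]
        trial = cross_validate(X, y, candidate, k=k, repeats=repeats, seed=seed)
        if trial.auc >= report.auc - tolerance:
            current, report = candidate, trial
        else:
            break
    return current, report
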