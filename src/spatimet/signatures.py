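"""Metabolic signature discovery: univariate AUC ranking and logistic panels.

Each candidate marker is scored by the area under its ROC curve (rank-sum
form, ties counted half), with tiers at AUC >= 0.75 ("high") and >= 0.85
("top"). Multivariate panels combine a small set of members in a binary
logistic regression fitted by iteratively reweighted least squares with a
tiny ridge penalty for stability under quasi-separation; panel performance is
the in-sample AUC of the linear predictor plus a stratified k-fold
cross-validated AUC (mean +/- sd over folds, default 5 folds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(f"{message}; |score| trace: "
                         + ", ".join(f"{t:.3g}" for t in trace))
        self.trace = trace


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(
            f"labels must contain exactly 2 classes, got {list(classes)}")
    return (y == classes[1]).astype(float)


def auc_univariate(values, labels) -> float:
    """AUC = (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg).

    Computed via midranks: positive class is the second of the two sorted
    label values.
    """
    y = _check_binary(labels)
    x = np.asarray(values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("values and labels length mismatch")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(x)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _tier(auc_oriented: float) -> str:
    if auc_oriented >= 0.85:
        return ">=0.85"
    if auc_oriented >= 0.75:
        return ">=0.75"
    return "below"


def rank_signatures(matrix, labels, names=None) -> pd.DataFrame:
    """Univariate AUC for every column of ``matrix``, sorted descending.

    Returns columns: name, auc (P(pos > neg)), auc_oriented (max(auc, 1-auc)),
    orientation (which class scores higher), tier.
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    names = (list(names) if names is not None
             else [f"feature_{j}" for j in range(X.shape[1])])
    if len(names) != X.shape[1]:
        raise ValueError("names length does not match number of columns")
    rows = []
    for j, name in enumerate(names):
        a = auc_univariate(X[:, j], labels)
        oriented = max(a, 1 - a)
        rows.append({
            "name": name,
            "auc": a,
            "auc_oriented": oriented,
            "orientation": "positive_high" if a >= 0.5 else "negative_high",
            "tier": _tier(oriented),
        })
    cols = ["name", "auc", "auc_oriented", "orientation", "tier"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values("auc_oriented", ascending=False,
                           kind="mergesort").reset_index(drop=True)


def _irls_logistic(X: np.ndarray, y: np.ndarray, ridge: float,
                   tol: float = 1e-8, max_iter: int = 100) -> np.ndarray:
    """Ridge-penalized logistic fit by damped Newton / IRLS.

    The intercept is unpenalized. Convergence: max |penalized score| < tol.
    """
    n, p = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    pen = np.full(p + 1, ridge)
    pen[0] = 0.0
    beta = np.zeros(p + 1)
    trace: list[float] = []

    def score_and_mu(b):
        eta = np.clip(Xd @ b, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        return Xd.T @ (y - mu) - 2 * pen * b, mu

    def objective(b):
        eta = np.clip(Xd @ b, -35, 35)
        # negative penalized log-likelihood
        return float(np.sum(np.log1p(np.exp(eta)) - y * eta)
                     + np.sum(pen * b ** 2))

    for _ in range(max_iter):
        g, mu = score_and_mu(beta)
        trace.append(float(np.max(np.abs(g))))
        if trace[-1] < tol:
            return beta
        W = mu * (1 - mu)
        H = (Xd * W[:, None]).T @ Xd + 2 * np.diag(pen)
        H[np.diag_indices_from(H)] += 1e-12
        step = np.linalg.solve(H, g)
        # backtracking line search on the penalized deviance
        f0 = objective(beta)
        alpha = 1.0
        for _ in range(40):
            cand = beta + alpha * step
            if objective(cand) <= f0 - 1e-12 * alpha * float(g @ step):
                break
            alpha *= 0.5
        if np.max(np.abs(alpha * step)) < 1e-13 and trace[-1] < 1e-5:
            # stalled at the double-precision floor with a negligible score:
            # converged to machine-attainable accuracy
            return beta
        beta = beta + alpha * step
    g, _ = score_and_mu(beta)
    trace.append(float(np.max(np.abs(g))))
    if trace[-1] < tol:
        return beta
    raise ConvergenceError(
        f"IRLS did not reach |score| < {tol} in {max_iter} iterations", trace)


@dataclass
class PanelModel:
    """A fitted multivariate signature panel."""

    members: list[str]
    coef: np.ndarray
    intercept: float
    auc_insample: float
    ridge: float = 1e-6
    cv_folds: int = 5
    cv_auc_mean: float | None = None
    cv_auc_sd: float | None = None
    cv_fold_aucs: list[float] = field(default_factory=list)
    seed: int | None = None
    classes: tuple = (0, 1)

    def decision_scores(self, X) -> np.ndarray:
        return np.asarray(X, float) @ self.coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "members": list(self.members),
            "coef": [float(c) for c in self.coef],
            "intercept": float(self.intercept),
            "ridge": self.ridge,
            "auc_insample": self.auc_insample,
            "cv_folds": self.cv_folds,
            "cv_auc_mean": self.cv_auc_mean,
            "cv_auc_sd": self.cv_auc_sd,
            "cv_fold_aucs": [float(a) for a in self.cv_fold_aucs],
            "seed": self.seed,
        }

    def summary(self) -> str:
        lines = [
            f"Logistic panel ({len(self.members)} members, ridge={self.ridge:g})",
            f"  in-sample AUC = {self.auc_insample:.3f}",
        ]
        if self.cv_auc_mean is not None:
            lines.append(
                f"  {self.cv_folds}-fold CV AUC = {self.cv_auc_mean:.3f} "
                f"+/- {self.cv_auc_sd:.3f}"
            )
        for m, c in zip(self.members, self.coef):
            lines.append(f"    {m}: {c:+.4f}")
        lines.append(f"    intercept: {self.intercept:+.4f}")
        return "\n".join(lines)


def fit_logistic_panel(
    matrix,
    labels,
    members=None,
    ridge: float = 1e-6,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> PanelModel:
    """Fit a binary logistic panel on ``matrix`` (samples x members).

    Member values are standardized internally (the returned coefficients are
    on the original scale). In-sample AUC is that of the linear predictor.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("a panel needs at least 2 member columns")
    y = _check_binary(labels)
    classes = tuple(np.unique(np.asarray(labels)))
    members = (list(members) if members is not None
               else [f"m{j}" for j in range(X.shape[1])])

    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    beta_std = _irls_logistic((X - mu) / sd, y, ridge, tol, max_iter)
    coef = beta_std[1:] / sd
    intercept = float(beta_std[0] - np.sum(beta_std[1:] * mu / sd))

    scores = X @ coef + intercept
    auc = auc_univariate(scores, y)
    return PanelModel(members, coef, intercept, auc, ridge, classes=classes)


def cv_auc(
    matrix,
    labels,
    folds: int = 5,
    seed: int = 0,
    ridge: float = 1e-6,
) -> tuple[float, float, list[float]]:
    """Stratified k-fold cross-validated panel AUC.

    Folds preserve class proportions and are assigned deterministically from
    ``seed``; the panel is refitted on each training portion only. Returns
    (mean, sample sd, per-fold AUCs).
    """
    X = np.asarray(matrix, dtype=float)
    y = _check_binary(labels)
    counts = np.bincount(y.astype(int))
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < {folds} folds; "
            "use fewer folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs = []
    for tr, te in skf.split(X, y):
        model = fit_logistic_panel(X[tr], y[tr], ridge=ridge)
        fold_aucs.append(auc_univariate(model.decision_scores(X[te]), y[te]))
    mean = float(np.mean(fold_aucs))
    sd = float(np.std(fold_aucs, ddof=1))
    return mean, sd, fold_aucs


def fit_panel_with_cv(
    matrix,
    labels,
    members=None,
    ridge: float = 1e-6,
    folds: int = 5,
    seed: int = 0,
) -> PanelModel:
    """Convenience: in-sample fit plus stratified CV in one PanelModel."""
    model = fit_logistic_panel(matrix, labels, members, ridge)
    mean, sd, fold_aucs = cv_auc(matrix, labels, folds, seed, ridge)
    model.cv_folds = folds
    model.cv_auc_mean = mean
    model.cv_auc_sd = sd
    model.cv_fold_aucs = fold_aucs
    model.seed = seed
    return model


def top_k_members(ranked: pd.DataFrame, k: int) -> list[str]:
    """Names of the top-k markers from a rank_signatures table."""
    return list(ranked["name"].head(k))


def roc_curve_points(values, labels) -> pd.DataFrame:
    """(FPR, TPR) coordinates of the empirical ROC curve."""
    from sklearn.metrics import roc_curve

    y = _check_binary(labels)
    fpr, tpr, _ = roc_curve(y, np.asarray(values, float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})
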