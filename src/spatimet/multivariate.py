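"""PCA and OPLS-DA with permutation validation.

OPLS-DA follows the orthogonal-signal-correction form: components orthogonal
to the class response are stripped from X iteratively, then a single
predictive PLS component is fitted to the filtered matrix. Model quality is
summarised by R2Y (explained response variance on the training fit) and Q2
(cross-validated predictive ability, venetian-blind k-fold by row index,
k = 7 by default). Validity is assessed by refitting under label permutations:
a sound model has all (or almost all) permuted Q2 below the original, and the
intercept of the Q2-versus-label-correlation regression line below ~0.05.

Scaling options: ``uv`` (unit variance, the default), ``pareto`` (divide by
sqrt of the standard deviation) and ``none``; all center columns first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _scale_params(X: np.ndarray, scaling: str):
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if len(X) > 1 else np.zeros(X.shape[1])
    if scaling == "none":
        scale = np.ones(X.shape[1])
    elif scaling == "uv":
        scale = np.where(sd > 0, sd, 1.0)  # constant columns left centered only
    elif scaling == "pareto":
        scale = np.where(sd > 0, np.sqrt(sd), 1.0)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return mean, scale


@dataclass
class PCAModel:
    scaling: str
    loadings: np.ndarray  # (n_features, n_components)
    scores: np.ndarray  # (n_rows, n_components)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: np.ndarray

    def transform(self, X) -> np.ndarray:
        Z = (np.asarray(X, float) - self.mean) / self.scale
        return Z @ self.loadings

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, columns=cols)


def fit_pca(matrix, scaling: str = "uv", n_components: int | None = None) -> PCAModel:
    """Principal component analysis by SVD of the centered (scaled) matrix.

    Sign convention: within each component, the largest-magnitude loading is
    positive, so results are deterministic across runs and row orderings.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("PCA needs a 2-D matrix with at least 2 rows")
    max_comp = min(len(X) - 1, X.shape[1])
    k = max_comp if n_components is None else n_components
    if k > max_comp:
        raise ValueError(f"requested {k} components, at most {max_comp} available")

    mean, scale = _scale_params(X, scaling)
    Z = (X - mean) / scale
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]

    # deterministic sign: largest-|loading| positive per component
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1

    var = s ** 2
    total = (Z ** 2).sum()
    ratio = var / total if total > 0 else np.zeros(k)
    return PCAModel(scaling, Vt.T, U * s, ratio, mean, scale)


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

def _opls_core(Z: np.ndarray, yc: np.ndarray, n_ortho: int):
    """Orthogonal filtering + one predictive component on preprocessed data.

    Returns (w_orth list, p_orth list, w_pred, p_pred, q, t_pred, t_orth).
    """
    X = Z.copy()
    w_os, p_os, t_os = [], [], []
    for _ in range(n_ortho):
        w = X.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w = w / nw
        t = X @ w
        p = X.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:  # no response-orthogonal structure left
            break
        w_o = w_o / n_wo
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        X = X - np.outer(t_o, p_o)
        w_os.append(w_o)
        p_os.append(p_o)
        t_os.append(t_o)

    w = X.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("response carries no covariance with the matrix")
    w = w / nw
    t = X @ w
    p = X.T @ t / (t @ t)
    q = (yc @ t) / (t @ t)
    return w_os, p_os, w, p, q, t, (np.array(t_os).T if t_os else
                                    np.empty((len(Z), 0)))


def _opls_predict(Xnew, mean, scale, w_os, p_os, w, q, y_mean):
    Z = (np.asarray(Xnew, float) - mean) / scale
    for w_o, p_o in zip(w_os, p_os):
        t_o = Z @ w_o
        Z = Z - np.outer(t_o, p_o)
    return (Z @ w) * q + y_mean


@dataclass
class OplsModel:
    """Fitted OPLS-DA model for a binary response."""

    weights: np.ndarray  # predictive weight vector (filtered space)
    loadings: np.ndarray  # predictive loadings
    q: float  # y-loading of the predictive component
    scores: np.ndarray  # predictive scores t (n_rows,)
    ortho_scores: np.ndarray  # (n_rows, n_ortho_effective)
    ortho_weights: list = field(default_factory=list)
    ortho_loadings: list = field(default_factory=list)
    r2y: float = 0.0
    q2: float = 0.0
    n_ortho: int = 1
    k_cv: int = 7
    scaling: str = "uv"
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None
    y_mean: float = 0.0
    classes: tuple = (0, 1)

    def predict(self, Xnew) -> np.ndarray:
        """Continuous class score (around 0 / 1 for the two classes)."""
        return _opls_predict(Xnew, self.mean, self.scale, self.ortho_weights,
                             self.ortho_loadings, self.weights, self.q,
                             self.y_mean)

    def summary(self) -> str:
        return (
            f"OPLS-DA: 1 predictive + {len(self.ortho_weights)} orthogonal "
            f"component(s), scaling={self.scaling}\n"
            f"  R2Y = {self.r2y:.4f}   Q2 ({self.k_cv}-fold) = {self.q2:.4f}\n"
            f"  classes: {self.classes[0]} (y=0) vs {self.classes[1]} (y=1)"
        )


def _encode_binary(y):
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"response must have exactly 2 classes, got {len(classes)}")
    return (y == classes[1]).astype(float), tuple(classes)


def _venetian_folds(n: int, k: int) -> np.ndarray:
    return np.arange(n) % k


def fit_oplsda(
    matrix,
    y,
    n_ortho: int = 1,
    k_cv: int = 7,
    scaling: str = "uv",
) -> OplsModel:
    """Fit a binary OPLS-DA model and cross-validate Q2.

    Q2 uses venetian-blind folds (row i -> fold i mod k); each fold's model
    is refitted from scratch, including centering/scaling, on the remaining
    rows.
    """
    X = np.asarray(matrix, dtype=float)
    y01, classes = _encode_binary(y)
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    mean, scale = _scale_params(X, scaling)
    Z = (X - mean) / scale
    y_mean = y01.mean()
    yc = y01 - y_mean

    w_os, p_os, w, p, q, t, t_os = _opls_core(Z, yc, n_ortho)
    resid = yc - t * q
    ssy = float(yc @ yc)
    r2y = 1.0 - float(resid @ resid) / ssy if ssy > 0 else 0.0

    # venetian-blind cross-validation
    folds = _venetian_folds(len(X), min(k_cv, len(X)))
    press = 0.0
    for f in range(folds.max() + 1):
        tr = folds != f
        te = ~tr
        if tr.sum() < 2 or not te.any():
            continue
        m_tr, s_tr = _scale_params(X[tr], scaling)
        Z_tr = (X[tr] - m_tr) / s_tr
        ym_tr = y01[tr].mean()
        yc_tr = y01[tr] - ym_tr
        try:
            w_os_f, p_os_f, w_f, _, q_f, _, _ = _opls_core(Z_tr, yc_tr, n_ortho)
        except ValueError:
            press += float(((y01[te] - ym_tr) ** 2).sum())
            continue
        pred = _opls_predict(X[te], m_tr, s_tr, w_os_f, p_os_f, w_f, q_f, ym_tr)
        press += float(((y01[te] - pred) ** 2).sum())
    q2 = 1.0 - press / ssy if ssy > 0 else 0.0

    return OplsModel(
        weights=w, loadings=p, q=q, scores=t, ortho_scores=t_os,
        ortho_weights=w_os, ortho_loadings=p_os, r2y=r2y, q2=q2,
        n_ortho=n_ortho, k_cv=k_cv, scaling=scaling, mean=mean, scale=scale,
        y_mean=y_mean, classes=classes,
    )


@dataclass
class PermutationResult:
    """Label-permutation validation of an OPLS-DA model."""

    n_perm: int
    correlation: np.ndarray  # |corr(y_perm, y)|; last entry = original (1.0)
    r2y: np.ndarray
    q2: np.ndarray
    r2_intercept: float
    q2_intercept: float
    seed: int
    original_r2y: float = 0.0
    original_q2: float = 0.0

    @property
    def fraction_q2_below(self) -> float:
        """Fraction of permuted models with Q2 below the original."""
        return float(np.mean(self.q2[:-1] < self.original_q2))

    @property
    def no_overfitting(self) -> bool:
        return bool(np.all(self.q2[:-1] < self.original_q2)
                    and self.q2_intercept < 0.05)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "correlation": self.correlation, "r2y": self.r2y, "q2": self.q2,
        })

    def summary(self) -> str:
        verdict = "no overfitting" if self.no_overfitting else "possible overfitting"
        return (
            f"{self.n_perm} permutations: R2 intercept = {self.r2_intercept:.3f}, "
            f"Q2 intercept = {self.q2_intercept:.3f}; "
            f"{100 * self.fraction_q2_below:.1f}% of permuted Q2 below original "
            f"({self.original_q2:.3f}) -> {verdict}"
        )


def permutation_test(
    matrix,
    y,
    n_perm: int = 200,
    seed: int = 0,
    n_ortho: int = 1,
    k_cv: int = 7,
    scaling: str = "uv",
) -> PermutationResult:
    """Refit the OPLS-DA model under ``n_perm`` label permutations.

    Intercepts of the R2 and Q2 regression lines versus |corr(y_perm, y)| are
    least-squares fits over all points including the original model at
    correlation 1.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    X = np.asarray(matrix, dtype=float)
    y01, _ = _encode_binary(y)
    rng = np.random.default_rng(seed)

    original = fit_oplsda(X, y01, n_ortho, k_cv, scaling)
    corrs, r2s, q2s = [], [], []
    for _ in range(n_perm):
        yp = rng.permutation(y01)
        with np.errstate(invalid="ignore"):
            c = np.corrcoef(yp, y01)[0, 1]
        try:
            m = fit_oplsda(X, yp, n_ortho, k_cv, scaling)
            r2, q2v = m.r2y, m.q2
        except ValueError:  # degenerate permutation (all-equal response)
            r2, q2v = 0.0, 0.0
        corrs.append(abs(c) if np.isfinite(c) else 0.0)
        r2s.append(r2)
        q2s.append(q2v)
    corrs.append(1.0)
    r2s.append(original.r2y)
    q2s.append(original.q2)

    corr = np.array(corrs)
    r2 = np.array(r2s)
    q2 = np.array(q2s)
    r2_line = np.polyfit(corr, r2, 1)
    q2_line = np.polyfit(corr, q2, 1)
    return PermutationResult(
        n_perm=n_perm, correlation=corr, r2y=r2, q2=q2,
        r2_intercept=float(r2_line[1]), q2_intercept=float(q2_line[1]),
        seed=seed, original_r2y=original.r2y, original_q2=original.q2,
    )


def fit_plsda_scores(matrix, labels, n_components: int = 2,
                     scaling: str = "uv") -> pd.DataFrame:
    """Multiclass PLS-DA scores for plotting (one-hot response PLS2).

    The permutation machinery above is binary-only; for more than two region
    classes this provides the scores-plot view.
    """
    from sklearn.cross_decomposition import PLSRegression

    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    Y = (labels[:, None] == classes[None, :]).astype(float)
    mean, scale = _scale_params(X, scaling)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit((X - mean) / scale, Y)
    scores = pd.DataFrame(
        pls.x_scores_, columns=[f"t{i + 1}" for i in range(n_components)]
    )
    scores["label"] = labels
    return scores
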