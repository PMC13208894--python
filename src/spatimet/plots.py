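"""Plot helpers: ion images, volcano plots, OPLS-DA scores and permutation
scatter. All functions take an explicit matplotlib Axes or create one, and
return the Axes, so they compose into figure panels."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402


def plot_ion_image(image: np.ndarray, mz: float | None = None, ax=None):
    ax = ax or plt.subplots()[1]
    im = ax.imshow(image, origin="upper", interpolation="nearest", cmap="viridis")
    ax.figure.colorbar(im, ax=ax, shrink=0.8, label="intensity")
    if mz is not None:
        ax.set_title(f"m/z {mz:.4f}")
    ax.set_xlabel("col")
    ax.set_ylabel("row")
    return ax


def plot_volcano(diff_result, ax=None):
    ax = ax or plt.subplots()[1]
    data = diff_result.volcano_data()
    colors = {"up": "tab:red", "down": "tab:blue", "ns": "0.7"}
    for direction, sub in data.groupby("direction"):
        ax.scatter(sub["log2fc"], sub["neg_log10_q"], s=8,
                   c=colors.get(direction, "0.7"), label=direction)
    ax.axhline(-np.log10(diff_result.config.alpha), ls="--", lw=0.8, c="k")
    for x in (-diff_result.config.lfc_min, diff_result.config.lfc_min):
        ax.axvline(x, ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 q")
    ax.legend(frameon=False)
    return ax


def plot_scores(scores_frame, x="t1", y="t2", label_col="label", ax=None):
    ax = ax or plt.subplots()[1]
    for lab, sub in scores_frame.groupby(label_col):
        ax.scatter(sub[x], sub[y], s=20, label=str(lab))
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.legend(frameon=False)
    return ax


def plot_permutation(perm_result, ax=None):
    ax = ax or plt.subplots()[1]
    ax.scatter(perm_result.correlation[:-1], perm_result.r2y[:-1], s=12,
               c="tab:green", label="R2Y (permuted)")
    ax.scatter(perm_result.correlation[:-1], perm_result.q2[:-1], s=12,
               c="tab:blue", label="Q2 (permuted)")
    ax.scatter([1.0], [perm_result.original_r2y], marker="*", s=120,
               c="tab:green", edgecolors="k", label="R2Y (original)")
    ax.scatter([1.0], [perm_result.original_q2], marker="*", s=120,
               c="tab:blue", edgecolors="k", label="Q2 (original)")
    for intercept, slope_y, color in (
            (perm_result.r2_intercept, perm_result.original_r2y, "tab:green"),
            (perm_result.q2_intercept, perm_result.original_q2, "tab:blue")):
        ax.plot([0, 1], [intercept, slope_y], lw=0.8, c=color, alpha=0.6)
    ax.set_xlabel("|corr(permuted y, y)|")
    ax.set_ylabel("R2Y / Q2")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_roc(points, auc=None, ax=None):
    ax = ax or plt.subplots()[1]
    label = f"AUC = {auc:.3f}" if auc is not None else None
    ax.plot(points["fpr"], points["tpr"], lw=1.5, label=label)
    ax.plot([0, 1], [0, 1], ls="--", lw=0.8, c="0.6")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    if label:
        ax.legend(frameon=False)
    return ax
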