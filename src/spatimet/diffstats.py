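"""Univariate differential screening, Venn integration and trend labels.

Per aligned ion, two groups of ROI-averaged spectra are compared with a
two-sided Mann-Whitney U test (normal approximation, tie-corrected) or
Welch's t on log2 intensities. P values are Benjamini-Hochberg adjusted
within each comparison; an ion is called up/down when q < alpha and
|log2 fold change| exceeds a minimum (defaults: alpha 0.05, |log2FC| > 0.25).
Fold changes are computed on linear-scale group means with a pseudo-count.

Pairwise comparisons are integrated as Venn set bookkeeping (sizes, union,
intersection, sign concordance), and the two consecutive comparisons along
the progression axis (N -> PT -> LT) are condensed to a per-ion trend label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import FeatureTable

TREND_LABELS = (
    "monotone_increase", "monotone_decrease", "up_then_down",
    "down_then_up", "flat", "mixed",
)


@dataclass
class ScreenConfig:
    alpha: float = 0.05
    lfc_min: float = 0.25
    test: str = "mann_whitney"  # or "welch_t"
    pseudo_count: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if self.test not in ("mann_whitney", "welch_t"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.pseudo_count <= 0:
            raise ValueError("pseudo_count must be positive")


@dataclass
class DiffResult:
    """Per-feature statistics for one two-group comparison."""

    table: pd.DataFrame  # feature_mz, mean_a, mean_b, log2fc, p, q, direction
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    config: ScreenConfig = field(default_factory=ScreenConfig)

    @property
    def feature_mz(self) -> np.ndarray:
        return self.table["feature_mz"].to_numpy()

    @property
    def direction(self) -> pd.Series:
        return self.table["direction"]

    def significant(self) -> np.ndarray:
        """Indices of features called up or down."""
        return np.flatnonzero(self.table["direction"].isin(["up", "down"]))

    @property
    def n_up(self) -> int:
        return int((self.table["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["direction"] == "down").sum())

    @property
    def n_significant(self) -> int:
        return self.n_up + self.n_down

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def volcano_data(self) -> pd.DataFrame:
        """(log2fc, -log10 q, direction) triples for volcano plotting."""
        q = self.table["q"].clip(lower=np.finfo(float).tiny)
        return pd.DataFrame({
            "log2fc": self.table["log2fc"],
            "neg_log10_q": -np.log10(q),
            "direction": self.table["direction"],
        })


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (q values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _test_pvalues(a: np.ndarray, b: np.ndarray, config: ScreenConfig) -> np.ndarray:
    """Two-sided per-column p values for groups a (rows) vs b (rows)."""
    if config.test == "mann_whitney":
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.mannwhitneyu(
                b, a, axis=0, alternative="two-sided", method="asymptotic"
            )
        p = np.asarray(res.pvalue, dtype=float)
        # all-tied columns: tie correction zeroes the variance -> NaN -> no evidence
        return np.where(np.isnan(p), 1.0, np.clip(p, 0.0, 1.0))
    # Welch's t on log2(x + pseudo-count)
    la = np.log2(a + config.pseudo_count)
    lb = np.log2(b + config.pseudo_count)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(lb, la, axis=0, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isnan(p), 1.0, np.clip(p, 0.0, 1.0))


def compare_groups(
    table: FeatureTable,
    group_a,
    group_b,
    config: ScreenConfig | None = None,
    name_a: str = "A",
    name_b: str = "B",
) -> DiffResult:
    """Screen every feature for a difference between two groups of rows.

    ``group_a``/``group_b`` are row selectors (see FeatureTable.select_rows).
    log2FC is log2((mean_B + pc) / (mean_A + pc)), i.e. positive = higher in B.
    """
    config = config or ScreenConfig()
    if table.log_transformed:
        raise ValueError("compare_groups expects a linear-scale feature table")
    mask_a = table.select_rows(group_a)
    mask_b = table.select_rows(group_b)
    if mask_a.sum() < 3:
        raise ValueError(f"group {name_a!r} has {int(mask_a.sum())} rows (< 3)")
    if mask_b.sum() < 3:
        raise ValueError(f"group {name_b!r} has {int(mask_b.sum())} rows (< 3)")
    if np.any(mask_a & mask_b):
        raise ValueError("groups overlap")

    a = table.matrix[mask_a]
    b = table.matrix[mask_b]
    pc = config.pseudo_count
    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    log2fc = np.log2((mean_b + pc) / (mean_a + pc))
    p = _test_pvalues(a, b, config)
    q = bh_adjust(p)

    direction = np.full(table.n_features, "ns", dtype=object)
    direction[(q < config.alpha) & (log2fc > config.lfc_min)] = "up"
    direction[(q < config.alpha) & (log2fc < -config.lfc_min)] = "down"

    out = pd.DataFrame({
        "feature_mz": table.feature_mz,
        "mean_a": mean_a,
        "mean_b": mean_b,
        "log2fc": log2fc,
        "p": p,
        "q": q,
        "direction": direction,
    })
    return DiffResult(out, name_a, name_b, int(mask_a.sum()), int(mask_b.sum()),
                      config)


@dataclass
class VennSummary:
    """Set bookkeeping for two significant-ion lists on one feature space."""

    n_a: int
    n_b: int
    n_intersection: int
    up_up: int = 0
    down_down: int = 0
    discordant: int = 0

    def __post_init__(self) -> None:
        if self.n_intersection > min(self.n_a, self.n_b):
            raise ValueError("intersection larger than a set")
        if self.up_up + self.down_down + self.discordant != self.n_intersection:
            raise ValueError("concordance counts must sum to the intersection")

    @property
    def n_union(self) -> int:
        return self.n_a + self.n_b - self.n_intersection

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a, "n_b": self.n_b,
            "n_intersection": self.n_intersection, "n_union": self.n_union,
            "up_up": self.up_up, "down_down": self.down_down,
            "discordant": self.discordant,
        }


def integrate_comparisons(sig_a: DiffResult, sig_b: DiffResult) -> VennSummary:
    """Venn integration of two comparisons over the same feature space."""
    if len(sig_a.table) != len(sig_b.table) or not np.allclose(
            sig_a.feature_mz, sig_b.feature_mz):
        raise ValueError("comparisons are not indexed on the same feature space")
    da = sig_a.table["direction"].to_numpy()
    db = sig_b.table["direction"].to_numpy()
    in_a = (da == "up") | (da == "down")
    in_b = (db == "up") | (db == "down")
    both = in_a & in_b
    up_up = int(np.sum(both & (da == "up") & (db == "up")))
    down_down = int(np.sum(both & (da == "down") & (db == "down")))
    return VennSummary(
        n_a=int(in_a.sum()),
        n_b=int(in_b.sum()),
        n_intersection=int(both.sum()),
        up_up=up_up,
        down_down=down_down,
        discordant=int(both.sum()) - up_up - down_down,
    )


def classify_trend(direction_n_pt: str, direction_pt_lt: str) -> str:
    """Trend label over the ordered stages (N, PT, LT) from the two
    consecutive-comparison directions."""
    for d in (direction_n_pt, direction_pt_lt):
        if d not in ("up", "down", "ns"):
            raise ValueError(f"unknown direction {d!r}")
    table = {
        ("up", "up"): "monotone_increase",
        ("down", "down"): "monotone_decrease",
        ("up", "down"): "up_then_down",
        ("down", "up"): "down_then_up",
        ("ns", "ns"): "flat",
    }
    return table.get((direction_n_pt, direction_pt_lt), "mixed")


def classify_trends(diff_n_pt: DiffResult, diff_pt_lt: DiffResult) -> pd.Series:
    """Per-feature trend labels from the PT-vs-N and LT-vs-PT screens."""
    if len(diff_n_pt.table) != len(diff_pt_lt.table):
        raise ValueError("comparisons are not indexed on the same feature space")
    labels = [
        classify_trend(d1, d2)
        for d1, d2 in zip(diff_n_pt.direction, diff_pt_lt.direction)
    ]
    return pd.Series(labels, index=diff_n_pt.feature_mz, name="trend")
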