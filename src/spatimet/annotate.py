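"""MS1 adduct annotation of aligned features against a metabolite database.

Positive-mode ions are matched at a ppm tolerance (default 5 ppm) over six
adduct forms: [M+H]+, [M+Na]+, [M+K]+, [M+NH4]+, [M-H2O+H]+ and the radical
cation [M]+. Annotation here is m/z-only ("putative"): every in-tolerance
(metabolite, adduct) pair is kept and ranked, because MS1 accuracy alone
cannot resolve isobaric candidates. A systematic instrument mass shift can be
estimated from confident matches at a widened tolerance and corrected before
final matching.

ppm error convention: (observed - theoretical) / theoretical * 1e6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Monoisotopic masses (Da), CODATA/NIST values.
PROTON = 1.007276466621
ELECTRON = 0.000548579909
H = 1.0078250319
N = 14.0030740052
O = 15.9949146221
NA = 22.98976928
K = 38.9637064864
H2O = 2 * H + O
NH4 = N + 4 * H

#: Adduct name -> signed m/z shift added to the neutral monoisotopic mass.
ADDUCT_SHIFTS: dict[str, float] = {
    "[M+H]+": PROTON,
    "[M+Na]+": NA - ELECTRON,
    "[M+K]+": K - ELECTRON,
    "[M+NH4]+": NH4 - ELECTRON,
    "[M-H2O+H]+": PROTON - H2O,
    "[M]+": -ELECTRON,
}

#: Tie-break priority when two matches have equal |ppm error| (protonated and
#: ammoniated species dominate in acetonitrile sprays, hence NH4 above Na/K).
ADDUCT_PRIORITY = ("[M+H]+", "[M+NH4]+", "[M+Na]+", "[M+K]+", "[M-H2O+H]+", "[M]+")


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """Theoretical m/z of ``adduct`` for a neutral monoisotopic mass (Da)."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    try:
        return neutral_mass + ADDUCT_SHIFTS[adduct]
    except KeyError:
        raise ValueError(
            f"unknown adduct {adduct!r}; known: {list(ADDUCT_SHIFTS)}"
        ) from None


def ppm_error(observed: float, theoretical: float) -> float:
    return (observed - theoretical) / theoretical * 1e6


@dataclass
class AnnotationConfig:
    tolerance_ppm: float = 5.0
    adducts: tuple[str, ...] = ADDUCT_PRIORITY
    mass_shift_correction: bool = False
    shift_match_tolerance_ppm: float = 10.0
    shift_min_matches: int = 5

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance_ppm must be positive")
        unknown = set(self.adducts) - set(ADDUCT_SHIFTS)
        if unknown:
            raise ValueError(f"unknown adducts: {sorted(unknown)}")


@dataclass
class AnnotationRecord:
    feature_mz: float
    metabolite: str
    adduct: str
    theoretical_mz: float
    ppm_error: float
    rank: int


@dataclass
class Annotations:
    """All in-tolerance matches plus the features that found none."""

    records: pd.DataFrame  # feature_mz, metabolite, adduct, theoretical_mz, ppm_error, rank
    unannotated: np.ndarray
    shift_ppm: float | None = None
    config: AnnotationConfig = field(default_factory=AnnotationConfig)

    def best(self) -> pd.DataFrame:
        """Rank-1 match per feature."""
        if self.records.empty:
            return self.records
        return self.records[self.records["rank"] == 1].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def read_database(path) -> pd.DataFrame:
    """Read a metabolite database CSV: ``name,neutral_mass,class,pathways``.

    ``pathways`` is a semicolon-separated list of pathway ids (may be empty).
    """
    db = pd.read_csv(path, dtype={"name": str, "class": str, "pathways": str})
    required = {"name", "neutral_mass", "class", "pathways"}
    missing = required - set(db.columns)
    if missing:
        raise ValueError(f"database missing columns: {sorted(missing)}")
    bad = pd.to_numeric(db["neutral_mass"], errors="coerce").isna()
    if bad.any():
        rows = list(db.index[bad] + 2)
        raise ValueError(f"database rows lacking a valid mass at lines {rows}")
    db["neutral_mass"] = db["neutral_mass"].astype(float)
    db["pathways"] = db["pathways"].fillna("")
    return db


def _theoretical_grid(database: pd.DataFrame, adducts) -> pd.DataFrame:
    """One row per (metabolite, adduct) with its theoretical m/z."""
    bad = pd.to_numeric(database["neutral_mass"], errors="coerce").isna()
    if bad.any():
        raise ValueError(
            f"database rows lacking a valid mass: {list(database.index[bad])}"
        )
    frames = []
    for add in adducts:
        frames.append(pd.DataFrame({
            "metabolite": database["name"].to_numpy(),
            "adduct": add,
            "theoretical_mz": database["neutral_mass"].to_numpy() + ADDUCT_SHIFTS[add],
        }))
    grid = pd.concat(frames, ignore_index=True)
    return grid.sort_values("theoretical_mz", kind="mergesort").reset_index(drop=True)


def _match(features: np.ndarray, grid: pd.DataFrame, tol_ppm: float) -> pd.DataFrame:
    theo = grid["theoretical_mz"].to_numpy()
    out = []
    for f in features:
        half = f * tol_ppm * 1e-6  # window in Da around the observed m/z
        lo = np.searchsorted(theo, f - 1.5 * half)
        hi = np.searchsorted(theo, f + 1.5 * half)
        for j in range(lo, hi):
            err = ppm_error(f, theo[j])
            if abs(err) <= tol_ppm:
                out.append((f, grid["metabolite"].iat[j], grid["adduct"].iat[j],
                            theo[j], err))
    return pd.DataFrame(
        out, columns=["feature_mz", "metabolite", "adduct", "theoretical_mz", "ppm_error"]
    )


def annotate_features(
    features,
    database: pd.DataFrame,
    config: AnnotationConfig | None = None,
) -> Annotations:
    """Match feature m/z values against all database (metabolite, adduct) pairs.

    Every match with |ppm error| <= tolerance is returned; per feature,
    matches are ranked by |ppm error| with ties broken by adduct priority.
    When ``config.mass_shift_correction`` is on, a systematic shift is
    estimated first and removed before matching.
    """
    config = config or AnnotationConfig()
    if len(database) == 0:
        raise ValueError("database is empty")
    features = np.asarray(features, dtype=float)

    shift = None
    matched_features = features
    if config.mass_shift_correction:
        shift = evaluate_mass_shift(features, database, config)
        if shift is not None:
            matched_features = features / (1.0 + shift * 1e-6)

    grid = _theoretical_grid(database, config.adducts)
    rec = _match(matched_features, grid, config.tolerance_ppm)
    if shift is not None and not rec.empty:
        # report the original observed m/z; ppm_error is post-correction
        corr = dict(zip(matched_features, features))
        rec["feature_mz"] = rec["feature_mz"].map(corr)

    if rec.empty:
        rec = rec.assign(rank=pd.Series(dtype=int))
        unann = features.copy()
        return Annotations(rec, unann, shift, config)

    prio = {a: i for i, a in enumerate(ADDUCT_PRIORITY)}
    rec["_absppm"] = rec["ppm_error"].abs()
    rec["_prio"] = rec["adduct"].map(prio)
    rec = rec.sort_values(
        ["feature_mz", "_absppm", "_prio"], kind="mergesort"
    ).reset_index(drop=True)
    rec["rank"] = rec.groupby("feature_mz").cumcount() + 1
    rec = rec.drop(columns=["_absppm", "_prio"])

    unann = features[~np.isin(features, rec["feature_mz"].unique())]
    n_hit = rec["feature_mz"].nunique()
    logger.info(
        "annotated %d/%d features (%d matches total)", n_hit, len(features), len(rec)
    )
    return Annotations(rec, unann, shift, config)


def evaluate_mass_shift(
    features,
    database: pd.DataFrame,
    config: AnnotationConfig | None = None,
) -> float | None:
    """Estimate a systematic instrument mass shift in ppm.

    Features are matched at a widened tolerance; the estimate is the median
    signed ppm error over unique best (rank-1) matches. Returns None ("no
    correction") when fewer than ``shift_min_matches`` features match.
    """
    config = config or AnnotationConfig()
    features = np.asarray(features, dtype=float)
    grid = _theoretical_grid(database, config.adducts)
    rec = _match(features, grid, config.shift_match_tolerance_ppm)
    if rec.empty:
        logger.info("mass shift: no matches at widened tolerance; no correction")
        return None
    best = rec.loc[rec.groupby("feature_mz")["ppm_error"].transform(
        lambda e: e.abs() == e.abs().min())]
    best = best.drop_duplicates("feature_mz")
    if len(best) < config.shift_min_matches:
        logger.info(
            "mass shift: only %d confident match(es) (< %d); no correction",
            len(best), config.shift_min_matches,
        )
        return None
    est = float(np.median(best["ppm_error"]))
    logger.info("mass shift estimate: %+.2f ppm from %d matches", est, len(best))
    return est
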