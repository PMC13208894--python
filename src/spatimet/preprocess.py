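"""Peak alignment across region spectra into a single feature table.

ROI-averaged spectra from different sections carry slightly different m/z
values for the same ion (ppm-scale mass error). All peaks are pooled, sorted,
and split into clusters wherever the gap between consecutive peaks exceeds a
ppm tolerance (single-linkage gap rule). The rule is deterministic and
independent of input spectrum order. Consensus m/z is the intensity-weighted
mean of the cluster; spectra not contributing to a cluster get intensity 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .msi_core import RegionSpectrum, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """Aligned ions x region-spectra intensity matrix with group labels.

    Attributes
    ----------
    feature_mz : ndarray (n_features,)
        Strictly increasing consensus m/z values.
    rows : list of RegionSpectrum
        One row per ROI-averaged spectrum, carrying its group labels.
    matrix : ndarray (n_rows, n_features)
        Non-negative intensities (log2-transformed when ``log_transformed``).
    provenance : dict feature index -> list of (section_id, original m/z)
    """

    feature_mz: np.ndarray
    rows: list[RegionSpectrum]
    matrix: np.ndarray
    provenance: dict[int, list[tuple[str, float]]] = field(default_factory=dict)
    tol_ppm: float = 5.0
    log_transformed: bool = False
    pseudo_count: float | None = None

    def __post_init__(self) -> None:
        self.feature_mz = np.asarray(self.feature_mz, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.rows), len(self.feature_mz)):
            raise ValidationError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.rows)} rows x {len(self.feature_mz)} features"
            )
        if len(self.feature_mz) > 1 and np.any(np.diff(self.feature_mz) <= 0):
            raise ValidationError("feature_mz must be strictly increasing")

    @property
    def n_features(self) -> int:
        return len(self.feature_mz)

    def row_labels(self) -> pd.DataFrame:
        return pd.DataFrame({
            "section_id": [s.section_id for s in self.rows],
            "region": [s.region for s in self.rows],
            "patient_id": [s.patient_id for s in self.rows],
            "group_tags": [";".join(sorted(s.group_tags)) for s in self.rows],
        })

    def select_rows(self, selector) -> np.ndarray:
        """Boolean row mask from a selector.

        ``selector`` may be: a boolean mask / index array; a dict matching on
        ``region``, ``section_id``, ``patient_id`` and/or ``tag`` (a group
        tag); or a callable RegionSpectrum -> bool.
        """
        n = len(self.rows)
        if callable(selector):
            return np.array([bool(selector(s)) for s in self.rows])
        if isinstance(selector, dict):
            mask = np.ones(n, dtype=bool)
            for key, val in selector.items():
                if key == "tag":
                    mask &= np.array([val in s.group_tags for s in self.rows])
                elif key in ("region", "section_id", "patient_id"):
                    mask &= np.array([getattr(s, key) == val for s in self.rows])
                else:
                    raise ValueError(f"unknown selector key {key!r}")
            return mask
        arr = np.asarray(selector)
        if arr.dtype == bool:
            if len(arr) != n:
                raise ValueError("boolean selector length mismatch")
            return arr
        mask = np.zeros(n, dtype=bool)
        mask[arr] = True
        return mask

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=[f"{m:.6f}" for m in self.feature_mz])
        return pd.concat([self.row_labels(), df], axis=1)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def align_peaks(spectra: list[RegionSpectrum], tol_ppm: float = 5.0) -> FeatureTable:
    """Pool peaks from all spectra and cluster them by the ppm gap rule.

    Consecutive sorted peaks closer than ``tol_ppm`` (relative to the lower
    m/z) join one cluster. A spectrum contributing several peaks to one
    cluster has them summed, so total intensity is conserved. Clusters whose
    full span exceeds 2x ``tol_ppm`` (chain effect) are kept but logged.
    """
    if not spectra:
        raise ValueError("align_peaks requires at least one spectrum")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")

    mzs, ints, owners = [], [], []
    for i, spec in enumerate(spectra):
        pos = spec.intensity > 0
        mzs.append(spec.mz[pos])
        ints.append(spec.intensity[pos])
        owners.append(np.full(int(pos.sum()), i))
    mz = np.concatenate(mzs)
    inten = np.concatenate(ints)
    owner = np.concatenate(owners)

    order = np.argsort(mz, kind="mergesort")
    mz, inten, owner = mz[order], inten[order], owner[order]

    if len(mz) == 0:
        return FeatureTable(np.array([]), list(spectra),
                            np.zeros((len(spectra), 0)), {}, tol_ppm)

    gaps_ppm = np.diff(mz) / mz[:-1] * 1e6
    cluster = np.concatenate([[0], np.cumsum(gaps_ppm > tol_ppm)])
    n_clusters = int(cluster[-1]) + 1

    consensus = np.zeros(n_clusters)
    matrix = np.zeros((len(spectra), n_clusters))
    provenance: dict[int, list[tuple[str, float]]] = {}
    n_wide = 0
    for k in range(n_clusters):
        sel = cluster == k
        w = inten[sel]
        m = mz[sel]
        consensus[k] = np.average(m, weights=w) if w.sum() > 0 else m.mean()
        np.add.at(matrix[:, k], owner[sel], w)
        provenance[k] = [(spectra[o].section_id, float(v))
                         for o, v in zip(owner[sel], m)]
        span_ppm = (m.max() - m.min()) / m.min() * 1e6
        if span_ppm > 2 * tol_ppm:
            n_wide += 1
            logger.warning(
                "feature %.5f: cluster span %.1f ppm exceeds 2x tolerance "
                "(chain effect)", consensus[k], span_ppm,
            )
    if n_wide:
        logger.info("%d/%d clusters wider than 2x tolerance", n_wide, n_clusters)

    # weighted means of disjoint increasing groups can tie only at equal m/z;
    # enforce strict monotonicity for degenerate duplicated peaks
    for k in range(1, n_clusters):
        if consensus[k] <= consensus[k - 1]:
            consensus[k] = np.nextafter(consensus[k - 1], np.inf)

    return FeatureTable(consensus, list(spectra), matrix, provenance, tol_ppm)


def prepare_matrix(
    table: FeatureTable, log_transform: bool = False, pseudo_count: float = 1.0
) -> FeatureTable:
    """Optionally apply log2(x + pseudo_count); records the transform."""
    if not log_transform:
        return table
    if pseudo_count <= 0:
        raise ValueError("pseudo_count must be positive when log-transforming")
    if table.log_transformed:
        raise ValueError("table already log-transformed")
    return replace(
        table,
        matrix=np.log2(table.matrix + pseudo_count),
        log_transformed=True,
        pseudo_count=pseudo_count,
    )
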