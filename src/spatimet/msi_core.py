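"""Data model and I/O for mass spectrometry imaging (MSI) sections.

An MSI section is a grid of pixels, each carrying a full positive-mode mass
spectrum. Histology-guided region-of-interest (ROI) masks label pixels with a
tissue region (normal colorectal mucosa ``N``, primary tumor ``PT``, liver
tumor ``LT``, normal liver ``LN``, plus ``necrotic`` and ``background``).
The statistical unit of the downstream analysis is the ROI-averaged spectrum:
one mean spectrum per (section, region).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Region labels usable in ROI masks.
REGION_LABELS = ("N", "PT", "LT", "LN", "necrotic", "background")

#: Regions that enter group statistics by default (necrotic/background excluded).
ANALYSIS_REGIONS = ("N", "PT", "LT", "LN")

#: Tissue classes a section may belong to.
TISSUE_CLASSES = ("normal_colorectal", "primary_tumor", "liver_metastasis")

DEFAULT_MZ_RANGE = (70.0, 1000.0)


class ValidationError(ValueError):
    """Input data violates a structural invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


@dataclass
class MSIDataset:
    """One imaged tissue section: pixel coordinates and a pixel x m/z matrix.

    Parameters
    ----------
    section_id : str
        Unique identifier of the tissue section.
    pixels : ndarray of shape (n_pixels, 2)
        0-based (row, col) integer coordinates; unique.
    mz_index : ndarray of shape (n_mz,)
        Strictly increasing m/z centroids in Da, all inside ``mz_range``.
    intensities : ndarray of shape (n_pixels, n_mz)
        Non-negative intensities (missing peaks are stored as 0, not NaN).
    """

    section_id: str
    pixels: np.ndarray
    mz_index: np.ndarray
    intensities: np.ndarray
    polarity: str = "positive"
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        self.mz_index = np.asarray(self.mz_index, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2:
            raise ValidationError("pixels must have shape (n_pixels, 2)")
        if self.intensities.shape != (len(self.pixels), len(self.mz_index)):
            raise ValidationError(
                f"intensities shape {self.intensities.shape} does not match "
                f"{len(self.pixels)} pixels x {len(self.mz_index)} m/z channels"
            )
        if len(self.mz_index) and np.any(np.diff(self.mz_index) <= 0):
            raise ValidationError("mz_index must be strictly increasing")
        lo, hi = self.mz_range
        if len(self.mz_index) and (
            self.mz_index[0] < lo or self.mz_index[-1] > hi
        ):
            raise ValidationError(f"m/z values outside mz_range ({lo}, {hi})")
        if np.any(self.intensities < 0):
            raise ValidationError("intensities must be non-negative")
        if len(np.unique(self.pixels, axis=0)) != len(self.pixels):
            raise ValidationError("pixel coordinates must be unique")

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    def pixel_indices(self, coords) -> np.ndarray:
        """Row indices into ``intensities`` for the given (row, col) pairs."""
        lookup = {tuple(p): i for i, p in enumerate(self.pixels)}
        try:
            return np.array([lookup[tuple(c)] for c in coords], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise ValidationError(
                f"pixel {exc.args[0]} not present in section {self.section_id}"
            ) from None


@dataclass
class ROIMask:
    """Region labels for (a subset of) a section's pixels."""

    section_id: str
    labels: dict[tuple[int, int], str]

    def __post_init__(self) -> None:
        for coord, lab in self.labels.items():
            if lab not in REGION_LABELS:
                raise ValidationError(
                    f"unknown region label {lab!r} at pixel {coord}"
                )

    def pixels_of(self, region: str) -> list[tuple[int, int]]:
        return [c for c, lab in self.labels.items() if lab == region]

    @property
    def regions(self) -> list[str]:
        """Region labels present in the mask, in REGION_LABELS order."""
        present = set(self.labels.values())
        return [r for r in REGION_LABELS if r in present]


@dataclass
class RegionSpectrum:
    """ROI-averaged spectrum — the pipeline's statistical unit."""

    section_id: str
    region: str
    mz: np.ndarray
    intensity: np.ndarray
    patient_id: str | None = None
    group_tags: frozenset[str] = field(default_factory=frozenset)
    n_pixels: int = 0

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValidationError("mz and intensity lengths differ")
        if np.any(self.intensity < 0):
            raise ValidationError("mean intensities must be non-negative")
        self.group_tags = frozenset(self.group_tags)


class SampleManifest:
    """Per-section study metadata: patient, tissue class, metastasis status."""

    def __init__(self, records: pd.DataFrame):
        required = {"section_id", "patient_id", "tissue", "metastasis"}
        missing = required - set(records.columns)
        if missing:
            raise ValidationError(f"manifest missing columns: {sorted(missing)}")
        if records["section_id"].duplicated().any():
            dupes = records.loc[records["section_id"].duplicated(), "section_id"]
            raise ValidationError(f"duplicate sections in manifest: {list(dupes)}")
        bad = set(records["tissue"]) - set(TISSUE_CLASSES)
        if bad:
            raise ValidationError(f"unknown tissue classes: {sorted(bad)}")
        self.records = records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def row(self, section_id: str) -> pd.Series:
        hit = self.records[self.records["section_id"] == section_id]
        if hit.empty:
            raise KeyError(f"section {section_id!r} not in manifest")
        return hit.iloc[0]

    def sections(self, tissue: str | None = None) -> list[str]:
        rec = self.records
        if tissue is not None:
            rec = rec[rec["tissue"] == tissue]
        return list(rec["section_id"])

    @classmethod
    def from_csv(cls, path) -> "SampleManifest":
        return cls(pd.read_csv(path, dtype=str))

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_dataset(
    path,
    format: str = "long_csv",
    section_id: str | None = None,
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE,
) -> MSIDataset:
    """Read an MSI section from disk.

    ``long_csv`` is a UTF-8 table with header ``row,col,mz,intensity``; one
    line per (pixel, peak). ``imzml`` reads continuous- or processed-mode
    imzML via pyimzml. Peaks outside ``mz_range`` are dropped (a count is
    logged), mirroring a fixed acquisition window of m/z 70-1000.
    """
    if format == "long_csv":
        return _load_long_csv(path, section_id, mz_range)
    if format == "imzml":
        return _load_imzml(path, section_id, mz_range)
    raise ValueError(f"unknown format {format!r}")


def _load_long_csv(path, section_id, mz_range) -> MSIDataset:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    required = ["row", "col", "mz", "intensity"]
    if list(df.columns[:4]) != required:
        raise ParseError(
            f"{path}: expected header {','.join(required)}, got {list(df.columns)}"
        )
    for col in required:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            line = int((bad | df[col].isna()).idxmax()) + 2  # header + 1-based
            raise ParseError(f"{path}: malformed value in column {col!r} at line {line}")
    df = df.astype({"row": int, "col": int, "mz": float, "intensity": float})
    if (df["intensity"] < 0).any():
        line = int((df["intensity"] < 0).idxmax()) + 2
        raise ValidationError(f"{path}: negative intensity at line {line}")

    lo, hi = mz_range
    out_of_range = (df["mz"] < lo) | (df["mz"] > hi)
    if out_of_range.any():
        logger.warning(
            "%s: dropped %d peak(s) outside m/z range (%g, %g)",
            path, int(out_of_range.sum()), lo, hi,
        )
        df = df[~out_of_range]

    wide = df.pivot_table(
        index=["row", "col"], columns="mz", values="intensity",
        aggfunc="sum", fill_value=0.0,
    )
    pixels = np.array(list(wide.index), dtype=int).reshape(-1, 2)
    return MSIDataset(
        section_id=section_id or str(path),
        pixels=pixels,
        mz_index=np.asarray(wide.columns, dtype=float),
        intensities=wide.to_numpy(dtype=float),
        mz_range=mz_range,
    )


def _load_imzml(path, section_id, mz_range):
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    coords, spectra = [], []
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mzs, ints = parser.getspectrum(i)
        coords.append((int(y) - 1, int(x) - 1))  # imzML is 1-based (x, y)
        spectra.append((np.asarray(mzs, float), np.asarray(ints, float)))
    all_mz = np.unique(np.concatenate([m for m, _ in spectra]))
    lo, hi = mz_range
    keep = (all_mz >= lo) & (all_mz <= hi)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("%s: dropped %d m/z channel(s) outside range", path, n_drop)
    all_mz = all_mz[keep]
    mat = np.zeros((len(coords), len(all_mz)))
    for i, (mzs, ints) in enumerate(spectra):
        idx = np.searchsorted(all_mz, mzs)
        ok = (idx < len(all_mz)) & np.isin(mzs, all_mz)
        np.add.at(mat[i], idx[ok], ints[ok])
    return MSIDataset(
        section_id=section_id or str(path),
        pixels=np.array(coords, dtype=int),
        mz_index=all_mz,
        intensities=mat,
        mz_range=mz_range,
    )


def save_dataset(dataset: MSIDataset, path) -> None:
    """Write a section in the long_csv dialect (all entries, zeros included)."""
    n_pix, n_mz = dataset.intensities.shape
    df = pd.DataFrame({
        "row": np.repeat(dataset.pixels[:, 0], n_mz),
        "col": np.repeat(dataset.pixels[:, 1], n_mz),
        "mz": np.tile(dataset.mz_index, n_pix),
        "intensity": dataset.intensities.ravel(),
    })
    df.to_csv(path, index=False)


def load_mask(path, section_id: str | None = None) -> ROIMask:
    """Read an ROI mask CSV with header ``row,col,label``."""
    df = pd.read_csv(path)
    if list(df.columns[:3]) != ["row", "col", "label"]:
        raise ParseError(f"{path}: expected header row,col,label")
    labels = {
        (int(r), int(c)): str(lab)
        for r, c, lab in zip(df["row"], df["col"], df["label"])
    }
    return ROIMask(section_id=section_id or str(path), labels=labels)


def save_mask(mask: ROIMask, path) -> None:
    rows = [(r, c, lab) for (r, c), lab in sorted(mask.labels.items())]
    pd.DataFrame(rows, columns=["row", "col", "label"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def tic_normalize(dataset: MSIDataset, target: float = 1.0) -> MSIDataset:
    """Total-ion-current normalization: scale each pixel spectrum to ``target``.

    Pixels whose total intensity is zero are left untouched (their count is
    logged). Idempotent and invariant to per-pixel rescaling.
    """
    if target <= 0:
        raise ValueError(f"target must be positive, got {target}")
    totals = dataset.intensities.sum(axis=1)
    if not np.any(totals > 0):
        raise ValidationError("no pixel with positive total intensity")
    n_zero = int((totals == 0).sum())
    if n_zero:
        logger.info(
            "%s: %d all-zero pixel(s) left unnormalized", dataset.section_id, n_zero
        )
    scale = np.where(totals > 0, target / np.where(totals > 0, totals, 1.0), 1.0)
    return replace(dataset, intensities=dataset.intensities * scale[:, None])


def median_normalize(dataset: MSIDataset, target: float = 1.0) -> MSIDataset:
    """Scale each pixel so the median of its positive intensities is ``target``."""
    if target <= 0:
        raise ValueError(f"target must be positive, got {target}")
    mat = dataset.intensities
    scale = np.ones(len(mat))
    for i, row in enumerate(mat):
        pos = row[row > 0]
        if pos.size:
            scale[i] = target / np.median(pos)
    return replace(dataset, intensities=mat * scale[:, None])


def normalize(dataset: MSIDataset, method: str = "tic", target: float = 1.0) -> MSIDataset:
    if method == "tic":
        return tic_normalize(dataset, target)
    if method == "median":
        return median_normalize(dataset, target)
    raise ValueError(f"unknown normalization method {method!r}")


# ---------------------------------------------------------------------------
# ROI extraction and ion images
# ---------------------------------------------------------------------------

def extract_roi_spectrum(
    dataset: MSIDataset,
    mask: ROIMask,
    region: str,
    patient_id: str | None = None,
    group_tags=(),
) -> RegionSpectrum:
    """Average the spectra of all pixels labeled ``region`` in ``mask``."""
    coords = mask.pixels_of(region)
    if not coords:
        raise ValidationError(
            f"region {region!r} empty in mask for section {dataset.section_id}"
        )
    idx = dataset.pixel_indices(coords)
    mean = dataset.intensities[idx].mean(axis=0)
    return RegionSpectrum(
        section_id=dataset.section_id,
        region=region,
        mz=dataset.mz_index.copy(),
        intensity=mean,
        patient_id=patient_id,
        group_tags=frozenset(group_tags),
        n_pixels=len(idx),
    )


def render_ion_image(dataset: MSIDataset, mz: float, tol_ppm: float = 5.0) -> np.ndarray:
    """Per-pixel summed intensity of all m/z channels within ``tol_ppm`` of ``mz``.

    Returns a 2-D array indexed by (row, col); grid positions with no pixel
    are NaN. An empty selection yields an all-NaN/zero image with a warning.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    ppm = np.abs(dataset.mz_index - mz) / mz * 1e6
    sel = ppm <= tol_ppm
    if not sel.any():
        logger.warning(
            "%s: no m/z channel within %g ppm of %g", dataset.section_id, tol_ppm, mz
        )
    values = dataset.intensities[:, sel].sum(axis=1)
    nrow = int(dataset.pixels[:, 0].max()) + 1
    ncol = int(dataset.pixels[:, 1].max()) + 1
    img = np.full((nrow, ncol), np.nan)
    img[dataset.pixels[:, 0], dataset.pixels[:, 1]] = values
    return img
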