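"""Synthetic MSI study generator with planted ground truth.

Emulates a region-of-interest spatial-metabolomics study of colorectal cancer
progression: 10 normal-colorectal sections (region N), 10 primary-tumor
sections (regions N and PT, from patients with and without liver metastasis)
and 3 liver-metastasis sections (regions LT and LN). Each planted metabolite
emits peaks at the m/z of one or more positive adducts, with Gaussian
ppm-scale mass error per (section, adduct) peak; pixel intensity is

    lognormal baseline x per-section biological factor x 2^(region log2 effect)
    x adduct weight x multiplicative noise,

with Bernoulli dropout. Every planted effect (differential flags per
comparison, N->PT->LT trend label, metastasis-arm PT effect) is recorded in a
GroundTruth object, so recovery by the pipeline can be scored exactly.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as _ann
from .msi_core import MSIDataset, ROIMask, SampleManifest

METABOLITE_CLASSES = ("amino_acid", "glycerolipid", "phospholipid", "carnitine", "other")
PATHWAY_NAMES = tuple(f"path{i:02d}" for i in range(1, 11))

#: Comparisons for which differential flags are planted.
COMPARISONS = ("PT_vs_N", "LT_vs_PT", "LT_vs_LN", "met_vs_free")


@dataclass
class StudyConfig:
    """Design of the synthetic study; defaults mirror the emulated design."""

    n_sections: tuple[int, int, int] = (10, 10, 3)  # normal / primary / metastasis
    pixels_per_region: int = 30
    n_metabolites: int = 150
    fraction_differential: float = 0.3
    effect_range: tuple[float, float] = (0.5, 2.0)  # |log2FC| bounds
    mass_error_ppm: float = 1.5
    systematic_shift_ppm: float = 0.0
    pixel_noise_cv: float = 0.3
    section_sdlog: float = 0.3  # between-section biological variability (ln scale)
    dropout: float = 0.05
    fraction_metastasis_markers: float = 0.15
    n_metastatic_patients: int = 5  # of the primary-tumor patients
    n_decoys: int = 50
    decoy_spacing_ppm: float = 20.0
    mass_range: tuple[float, float] = (100.0, 900.0)
    baseline_meanlog: float = 10.0
    baseline_sdlog: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_sections):
            raise ValueError("all section counts must be >= 1")
        if not (0 <= self.fraction_differential <= 1):
            raise ValueError("fraction_differential must be in [0, 1]")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if self.pixels_per_region < 1 or self.n_metabolites < 1:
            raise ValueError("counts must be >= 1")
        if self.n_metastatic_patients > self.n_sections[1]:
            raise ValueError("more metastatic patients than primary-tumor sections")


@dataclass
class GroundTruth:
    """Everything planted: metabolites, effects, flags, trends."""

    metabolites: pd.DataFrame  # name, neutral_mass, class, pathways, adducts(json)
    region_effects: pd.DataFrame  # index metabolite, columns N/PT/LT/LN (log2 vs N)
    met_marker_effect: pd.Series  # extra PT log2 effect in the metastatic arm
    differential: dict[str, pd.DataFrame]  # comparison -> (metabolite, log2fc, flag)
    trend: pd.Series  # metabolite -> trend label over (N, PT, LT)

    def adduct_profile(self, name: str) -> dict[str, float]:
        row = self.metabolites.set_index("name").loc[name]
        return json.loads(row["adducts"])

    def theoretical_mz(self) -> pd.DataFrame:
        """All true (metabolite, adduct, m/z) triples."""
        out = []
        for _, row in self.metabolites.iterrows():
            for add in json.loads(row["adducts"]):
                out.append((row["name"], add,
                            _ann.adduct_mz(row["neutral_mass"], add)))
        return pd.DataFrame(out, columns=["metabolite", "adduct", "mz"])

    def to_json(self, path) -> None:
        payload = {
            "metabolites": self.metabolites.to_dict(orient="records"),
            "region_effects": self.region_effects.reset_index()
                                  .rename(columns={"index": "metabolite"})
                                  .to_dict(orient="records"),
            "met_marker_effect": self.met_marker_effect.to_dict(),
            "differential": {k: v.to_dict(orient="records")
                             for k, v in self.differential.items()},
            "trend": self.trend.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        eff = pd.DataFrame(payload["region_effects"]).set_index("metabolite")
        eff.index.name = None
        return cls(
            metabolites=pd.DataFrame(payload["metabolites"]),
            region_effects=eff,
            met_marker_effect=pd.Series(payload["met_marker_effect"], dtype=float),
            differential={k: pd.DataFrame(v)
                          for k, v in payload["differential"].items()},
            trend=pd.Series(payload["trend"]),
        )


@dataclass
class SyntheticStudy:
    datasets: list[MSIDataset]
    masks: list[ROIMask]
    manifest: SampleManifest
    database: pd.DataFrame  # name, neutral_mass, class, pathways (true + decoys)
    ground_truth: GroundTruth
    config: StudyConfig = field(default_factory=StudyConfig)


def _trend_label(d1: str, d2: str) -> str:
    table = {
        ("up", "up"): "monotone_increase",
        ("down", "down"): "monotone_decrease",
        ("up", "down"): "up_then_down",
        ("down", "up"): "down_then_up",
        ("ns", "ns"): "flat",
    }
    return table.get((d1, d2), "mixed")


def _sample_metabolites(cfg: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = cfg.mass_range
    masses = np.sort(rng.uniform(lo, hi, cfg.n_metabolites))
    classes = rng.choice(METABOLITE_CLASSES, cfg.n_metabolites)
    adduct_names = list(_ann.ADDUCT_SHIFTS)
    rows = []
    for i in range(cfg.n_metabolites):
        n_add = int(rng.integers(1, 4))
        adds = list(rng.choice(adduct_names, n_add, replace=False))
        weights = rng.dirichlet(np.ones(n_add) * 2.0)
        n_path = int(rng.integers(1, 3))
        paths = sorted(rng.choice(PATHWAY_NAMES, n_path, replace=False))
        rows.append({
            "name": f"MET{i + 1:04d}",
            "neutral_mass": float(masses[i]),
            "class": str(classes[i]),
            "pathways": ";".join(paths),
            "adducts": json.dumps(dict(zip(adds, map(float, weights)))),
        })
    return pd.DataFrame(rows)


def _plant_effects(cfg: StudyConfig, mets: pd.DataFrame,
                   rng: np.random.Generator) -> GroundTruth:
    n = cfg.n_metabolites
    n_diff = int(round(cfg.fraction_differential * n))
    diff_idx = rng.choice(n, n_diff, replace=False)
    lo, hi = cfg.effect_range

    eff = pd.DataFrame(0.0, index=mets["name"], columns=["N", "PT", "LT", "LN"])
    eff.index.name = None
    for i in diff_idx:
        # per differential metabolite: each stage changes with prob 0.8
        while True:
            s1 = rng.choice([-1, 0, 1], p=[0.4, 0.2, 0.4])
            s2 = rng.choice([-1, 0, 1], p=[0.4, 0.2, 0.4])
            if s1 or s2:
                break
        e_pt = s1 * rng.uniform(lo, hi)
        e_lt = e_pt + s2 * rng.uniform(lo, hi)
        name = mets["name"].iat[i]
        eff.loc[name, "PT"] = e_pt
        eff.loc[name, "LT"] = e_lt
        # normal liver background differs mildly and non-differentially
        eff.loc[name, "LN"] = e_lt - s2 * rng.uniform(lo, hi) if s2 else e_lt

    n_mark = int(round(cfg.fraction_metastasis_markers * n))
    mark_idx = rng.choice(n, n_mark, replace=False)
    marker = pd.Series(0.0, index=mets["name"])
    marker.index.name = None
    for i in mark_idx:
        marker.iloc[i] = rng.choice([-1, 1]) * rng.uniform(1.0, hi)

    def _dir(delta: float) -> str:
        return "up" if delta > 0 else ("down" if delta < 0 else "ns")

    differential = {}
    comps = {
        "PT_vs_N": eff["PT"] - eff["N"],
        "LT_vs_PT": eff["LT"] - eff["PT"],
        "LT_vs_LN": eff["LT"] - eff["LN"],
        "met_vs_free": marker,
    }
    for comp, delta in comps.items():
        differential[comp] = pd.DataFrame({
            "metabolite": mets["name"],
            "log2fc": delta.to_numpy(),
            "flag": delta.to_numpy() != 0,
        })

    trend = pd.Series(
        [_trend_label(_dir(p), _dir(l - p))
         for p, l in zip(eff["PT"], eff["LT"])],
        index=mets["name"],
    )
    trend.index.name = None
    return GroundTruth(mets, eff, marker, differential, trend)


def generate_database(
    ground_truth: GroundTruth,
    n_decoys: int,
    min_spacing_ppm: float,
    rng: np.random.Generator | None = None,
    mass_range: tuple[float, float] = (100.0, 900.0),
    max_attempts: int = 200_000,
) -> pd.DataFrame:
    """True metabolites plus decoys whose every adduct m/z is >= min_spacing_ppm
    from every true adduct m/z, so any decoy match is an unambiguous error."""
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    rng = rng or np.random.default_rng(0)
    true_db = ground_truth.metabolites[
        ["name", "neutral_mass", "class", "pathways"]].copy()
    if n_decoys == 0:
        return true_db.reset_index(drop=True)

    shifts = np.array(list(_ann.ADDUCT_SHIFTS.values()))
    true_mz = np.sort(
        (ground_truth.metabolites["neutral_mass"].to_numpy()[:, None] + shifts).ravel()
    )
    lo, hi = mass_range
    decoys, attempts = [], 0
    accepted: list[float] = []
    while len(decoys) < n_decoys:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n_decoys} decoys at {min_spacing_ppm} ppm "
                "spacing; reduce n_decoys or the spacing"
            )
        mass = rng.uniform(lo, hi)
        cand = mass + shifts
        j = np.searchsorted(true_mz, cand)
        ok = True
        for c, jj in zip(cand, j):
            for neighbor in true_mz[max(jj - 1, 0):jj + 1]:
                if abs(c - neighbor) / neighbor * 1e6 < min_spacing_ppm:
                    ok = False
        # decoys must also not collide with each other at the match tolerance
        for prev in accepted:
            if ok and np.any(np.abs(cand[:, None] - (prev + shifts)[None, :])
                             / cand[:, None] * 1e6 < min_spacing_ppm):
                ok = False
        if ok:
            accepted.append(mass)
            decoys.append({
                "name": f"DECOY{len(decoys) + 1:04d}",
                "neutral_mass": float(mass),
                "class": "decoy",
                "pathways": "",
            })
    return pd.concat([true_db, pd.DataFrame(decoys)], ignore_index=True)


def _section_layout(regions: list[str], pixels_per_region: int) -> ROIMask:
    """Stack square-ish region blocks vertically on one pixel grid."""
    ncol = max(1, int(np.ceil(np.sqrt(pixels_per_region))))
    labels = {}
    row0 = 0
    for reg in regions:
        placed = 0
        r = row0
        while placed < pixels_per_region:
            for c in range(ncol):
                if placed >= pixels_per_region:
                    break
                labels[(r, c)] = reg
                placed += 1
            r += 1
        row0 = r + 1  # one empty row between region blocks
    return ROIMask(section_id="", labels=labels)


def generate_study(config: StudyConfig | None = None) -> SyntheticStudy:
    """Generate the full study: sections, masks, manifest, database, truth."""
    cfg = config or StudyConfig()
    rng = np.random.default_rng(cfg.seed)

    mets = _sample_metabolites(cfg, rng)
    truth = _plant_effects(cfg, mets, rng)
    database = generate_database(
        truth, cfg.n_decoys, cfg.decoy_spacing_ppm, rng, cfg.mass_range
    )

    theo = truth.theoretical_mz()
    theo_mz = theo["mz"].to_numpy()
    met_of_peak = theo["metabolite"].to_numpy()
    weights = np.array([
        truth.adduct_profile(m)[a]
        for m, a in zip(theo["metabolite"], theo["adduct"])
    ])
    met_index = {name: i for i, name in enumerate(mets["name"])}
    peak_met = np.array([met_index[m] for m in met_of_peak])

    baseline = rng.lognormal(cfg.baseline_meanlog, cfg.baseline_sdlog,
                             cfg.n_metabolites)
    eff = truth.region_effects
    marker = truth.met_marker_effect

    n_norm, n_pt, n_lm = cfg.n_sections
    plan = []  # (section_id, patient_id, tissue, metastasis, regions)
    for i in range(n_norm):
        plan.append((f"S_N{i + 1:02d}", f"P_N{i + 1:02d}",
                     "normal_colorectal", "na", ["N"]))
    for i in range(n_pt):
        status = "metastatic" if i < cfg.n_metastatic_patients else "metastasis_free"
        plan.append((f"S_T{i + 1:02d}", f"P_T{i + 1:02d}",
                     "primary_tumor", status, ["N", "PT"]))
    for i in range(n_lm):
        plan.append((f"S_M{i + 1:02d}", f"P_T{i + 1:02d}",
                     "liver_metastasis", "metastatic", ["LT", "LN"]))

    noise_sdlog = float(np.sqrt(np.log1p(cfg.pixel_noise_cv ** 2)))
    datasets, masks, records = [], [], []
    for section_id, patient_id, tissue, status, regions in plan:
        layout = _section_layout(regions, cfg.pixels_per_region)
        layout.section_id = section_id

        # per-(section, peak) observed m/z: systematic + random ppm error
        ppm = cfg.systematic_shift_ppm + rng.normal(0, cfg.mass_error_ppm,
                                                    len(theo_mz))
        obs_mz = theo_mz * (1 + ppm * 1e-6)
        order = np.argsort(obs_mz, kind="mergesort")
        obs_mz = obs_mz[order]
        for j in range(1, len(obs_mz)):  # guard against rare exact collisions
            if obs_mz[j] <= obs_mz[j - 1]:
                obs_mz[j] = np.nextafter(obs_mz[j - 1], np.inf)

        sec_factor = rng.lognormal(0.0, cfg.section_sdlog, cfg.n_metabolites)
        coords = sorted(layout.labels)
        pixels = np.array(coords, dtype=int)
        inten = np.zeros((len(coords), len(theo_mz)))
        for p, coord in enumerate(coords):
            reg = layout.labels[coord]
            log2_eff = eff[reg].to_numpy().copy()
            if reg == "PT" and status == "metastatic":
                log2_eff = log2_eff + marker.to_numpy()
            level = baseline * sec_factor * np.exp2(log2_eff)
            peak_level = level[peak_met] * weights
            noise = rng.lognormal(-0.5 * noise_sdlog ** 2, noise_sdlog,
                                  len(theo_mz))
            keep = rng.random(len(theo_mz)) >= cfg.dropout
            inten[p] = peak_level * noise * keep
        inten = inten[:, order]

        lo_keep = (obs_mz >= 70.0) & (obs_mz <= 1000.0)
        datasets.append(MSIDataset(
            section_id=section_id,
            pixels=pixels,
            mz_index=obs_mz[lo_keep],
            intensities=inten[:, lo_keep],
        ))
        masks.append(layout)
        records.append({"section_id": section_id, "patient_id": patient_id,
                        "tissue": tissue, "metastasis": status})

    manifest = SampleManifest(pd.DataFrame(records))
    return SyntheticStudy(datasets, masks, manifest, database, truth, cfg)


def write_study(study: SyntheticStudy, out_dir) -> None:
    """Write all study files in the package's text dialects."""
    from .msi_core import save_dataset, save_mask

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ds, mask in zip(study.datasets, study.masks):
        save_dataset(ds, out / f"{ds.section_id}.csv")
        save_mask(mask, out / f"{ds.section_id}.mask.csv")
    study.manifest.to_csv(out / "manifest.csv")
    study.database.to_csv(out / "database.csv", index=False)
    study.ground_truth.to_json(out / "ground_truth.json")
    Path(out / "config.json").write_text(json.dumps(asdict(study.config), indent=1))


# ---------------------------------------------------------------------------
# Direct matrix-level simulators (for calibration of the statistical stages)
# ---------------------------------------------------------------------------

def simulate_group_matrix(
    n_features: int = 1000,
    n_per_group: tuple[int, int] = (10, 10),
    n_differential: int = 0,
    effect_low: float = 1.0,
    effect_high: float = 2.0,
    sdlog2: float = 0.43,  # ~0.3 on the natural-log scale
    seed: int = 0,
):
    """Two-group lognormal intensity matrix with planted log2 effects.

    Emulates ROI-level feature intensities directly (bypassing pixels) for
    calibration studies of the screening stage. Returns ``(matrix, labels,
    truth)`` where truth is a DataFrame with the planted per-feature log2fc.
    """
    rng = np.random.default_rng(seed)
    n_a, n_b = n_per_group
    base = rng.lognormal(10.0, 1.0, n_features)
    lfc = np.zeros(n_features)
    if n_differential:
        idx = rng.choice(n_features, n_differential, replace=False)
        lfc[idx] = rng.choice([-1, 1], n_differential) * rng.uniform(
            effect_low, effect_high, n_differential)
    log2_a = np.log2(base) + rng.normal(0, sdlog2, (n_a, n_features))
    log2_b = np.log2(base) + lfc + rng.normal(0, sdlog2, (n_b, n_features))
    matrix = np.exp2(np.vstack([log2_a, log2_b]))
    labels = np.array([0] * n_a + [1] * n_b)
    truth = pd.DataFrame({"log2fc": lfc, "flag": lfc != 0})
    return matrix, labels, truth


def simulate_panel_data(
    n_samples: int = 60,
    n_members: int = 4,
    target_auc: float = 0.95,
    seed: int = 0,
):
    """Gaussian panel with a known large-sample AUC.

    Each member is N(0,1) in class 0 and N(d,1) in class 1 with d chosen so
    the equal-weight combination has binormal AUC = ``target_auc``
    (AUC = Phi(D / sqrt(2)) with D the Mahalanobis-type separation).
    """
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    total_d = np.sqrt(2.0) * norm.ppf(target_auc)
    d = total_d / np.sqrt(n_members)
    y = np.array([0] * (n_samples // 2) + [1] * (n_samples - n_samples // 2))
    rng.shuffle(y)
    X = rng.normal(0, 1, (n_samples, n_members)) + d * y[:, None]
    return X, y
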