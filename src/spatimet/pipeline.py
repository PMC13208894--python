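"""End-to-end pipeline: load -> normalize -> ROI spectra -> align -> annotate
-> differential screens -> integration/trends -> multivariate -> enrichment ->
signature panels, driven by a single YAML config and fully seeded.

Each run writes its artifacts plus a run manifest (config hash, seed, package
version) to the output directory, so identical config + seed reproduces
identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import AnnotationConfig, Annotations, annotate_features, read_database
from .diffstats import (DiffResult, ScreenConfig, VennSummary, classify_trends,
                        compare_groups, integrate_comparisons)
from .enrich import ora_enrich, pathways_from_database, read_pathways
from .msi_core import (ANALYSIS_REGIONS, SampleManifest, extract_roi_spectrum,
                       load_dataset, load_mask, normalize)
from .multivariate import fit_oplsda, fit_plsda_scores, permutation_test
from .preprocess import FeatureTable, align_peaks, prepare_matrix
from .signatures import fit_panel_with_cv, rank_signatures, top_k_members

logger = logging.getLogger(__name__)


class PipelineValidationError(ValueError):
    """Config or input files invalid; raised before any computation."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


DEFAULT_COMPARISONS = [
    {"name": "PT_vs_N", "group_a": {"region": "N"}, "group_b": {"region": "PT"}},
    {"name": "LT_vs_PT", "group_a": {"region": "PT"}, "group_b": {"region": "LT"},
     "test": "welch_t"},
    {"name": "LT_vs_LN", "group_a": {"region": "LN"}, "group_b": {"region": "LT"},
     "test": "welch_t"},
    # the metastasis arms are small (a few sections each); Welch's t on log
    # intensities keeps usable power where the rank test's p floor is binding
    {"name": "met_vs_free",
     "group_a": {"region": "PT", "tag": "metastasis_free"},
     "group_b": {"region": "PT", "tag": "metastatic"},
     "test": "welch_t"},
]


@dataclass
class PipelineConfig:
    data_dir: str
    output_dir: str
    manifest: str = "manifest.csv"
    database: str = "database.csv"
    pathway_file: str | None = None
    # counts-like TIC target keeps the fold-change pseudo-count (default 1)
    # negligible relative to per-feature means
    normalization: dict = field(default_factory=lambda: {"method": "tic", "target": 1e4})
    alignment_tol_ppm: float = 5.0
    log_transform: bool = False
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    comparisons: list[dict] = field(default_factory=lambda: list(DEFAULT_COMPARISONS))
    trend_pair: tuple[str, str] = ("PT_vs_N", "LT_vs_PT")
    integrate_pair: tuple[str, str] = ("PT_vs_N", "LT_vs_PT")
    oplsda: dict = field(default_factory=lambda: {
        "comparison": "PT_vs_N", "n_ortho": 1, "k_cv": 7, "n_perm": 200,
        "scaling": "uv"})
    enrichment: dict = field(default_factory=lambda: {
        "comparison": "met_vs_free", "cutoff": 0.05})
    panel: dict = field(default_factory=lambda: {
        "comparison": "met_vs_free", "top_k": 4, "folds": 5, "ridge": 1e-6})
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "PipelineConfig":
        raw = dict(raw)
        if "annotation" in raw and isinstance(raw["annotation"], dict):
            raw["annotation"] = AnnotationConfig(**raw["annotation"])
        if "screen" in raw and isinstance(raw["screen"], dict):
            raw["screen"] = ScreenConfig(**raw["screen"])
        for key in ("trend_pair", "integrate_pair"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        if base_dir is not None:
            for attr in ("data_dir", "output_dir"):
                p = Path(getattr(cfg, attr))
                if not p.is_absolute():
                    setattr(cfg, attr, str(base_dir / p))
        return cfg

    def to_canonical_json(self) -> str:
        def enc(o):
            if isinstance(o, (AnnotationConfig, ScreenConfig)):
                return vars(o)
            if isinstance(o, tuple):
                return list(o)
            return str(o)
        return json.dumps(vars(self), default=enc, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_json().encode()).hexdigest()[:16]


def _validate(cfg: PipelineConfig) -> None:
    data = Path(cfg.data_dir)
    if not data.is_dir():
        raise PipelineValidationError(f"data_dir {data} does not exist")
    for name in (cfg.manifest, cfg.database):
        if not (data / name).exists():
            raise PipelineValidationError(f"missing input file: {data / name}")
    manifest = SampleManifest.from_csv(data / cfg.manifest)
    for sec in manifest.sections():
        for suffix in (".csv", ".mask.csv"):
            if not (data / f"{sec}{suffix}").exists():
                raise PipelineValidationError(
                    f"section {sec}: missing {data / (sec + suffix)}")
    if cfg.pathway_file and not (data / cfg.pathway_file).exists():
        raise PipelineValidationError(f"missing pathway file: {cfg.pathway_file}")
    names = {c["name"] for c in cfg.comparisons}
    for key, pair in (("trend_pair", cfg.trend_pair),
                      ("integrate_pair", cfg.integrate_pair)):
        for nm in pair:
            if nm not in names:
                raise PipelineValidationError(
                    f"{key} references undeclared comparison {nm!r}")
    for key in ("oplsda", "enrichment", "panel"):
        nm = getattr(cfg, key).get("comparison")
        if nm not in names:
            raise PipelineValidationError(
                f"{key} references undeclared comparison {nm!r}")


@dataclass
class RunResult:
    config: PipelineConfig
    table: FeatureTable
    annotations: Annotations
    diff: dict[str, DiffResult]
    venn: VennSummary
    trends: pd.Series
    opls_summary: dict
    plsda_scores: pd.DataFrame
    enrichment: pd.DataFrame
    signature_ranking: pd.DataFrame
    panel: dict
    run_dir: Path


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (PipelineValidationError, PipelineStageError):
                raise
            except Exception as exc:
                raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("extract")
def _extract_spectra(cfg: PipelineConfig, manifest: SampleManifest):
    data = Path(cfg.data_dir)
    spectra = []
    for sec in manifest.sections():
        row = manifest.row(sec)
        ds = load_dataset(data / f"{sec}.csv", "long_csv", section_id=sec)
        ds = normalize(ds, **cfg.normalization)
        mask = load_mask(data / f"{sec}.mask.csv", section_id=sec)
        for region in mask.regions:
            if region not in ANALYSIS_REGIONS:
                continue  # necrotic/background never enter group statistics
            spectra.append(extract_roi_spectrum(
                ds, mask, region,
                patient_id=row["patient_id"],
                group_tags={row["tissue"], row["metastasis"]},
            ))
    return spectra


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute every declared stage; write artifacts and a run manifest."""
    _validate(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = Path(config.data_dir)

    manifest = SampleManifest.from_csv(data / config.manifest)
    database = read_database(data / config.database)

    spectra = _extract_spectra(config, manifest)
    table = align_peaks(spectra, config.alignment_tol_ppm)
    table.to_csv(out / "feature_table.csv")
    # screens run on the linear-scale table; the log2 view is exported
    if config.log_transform:
        prepare_matrix(table, True).to_csv(out / "feature_table_log2.csv")

    ann = annotate_features(table.feature_mz, database, config.annotation)
    ann.to_csv(out / "annotations.csv")

    diff: dict[str, DiffResult] = {}
    for comp in config.comparisons:
        name = comp["name"]
        screen = config.screen
        if "test" in comp:  # per-comparison test override
            screen = ScreenConfig(alpha=screen.alpha, lfc_min=screen.lfc_min,
                                  test=comp["test"],
                                  pseudo_count=screen.pseudo_count)
        try:
            res = compare_groups(table, comp["group_a"], comp["group_b"],
                                 screen, name_a=str(comp["group_a"]),
                                 name_b=str(comp["group_b"]))
        except ValueError as exc:
            raise PipelineStageError(f"stage 'diff:{name}' failed: {exc}") from exc
        res.to_csv(out / f"diff_{name}.csv")
        diff[name] = res

    a, b = config.integrate_pair
    venn = integrate_comparisons(diff[a], diff[b])
    (out / "venn.json").write_text(json.dumps(venn.to_dict(), indent=1))

    t1, t2 = config.trend_pair
    trends = classify_trends(diff[t1], diff[t2])
    trends.rename_axis("feature_mz").to_frame().to_csv(out / "trends.csv")

    opls_cfg = config.oplsda
    comp = next(c for c in config.comparisons
                if c["name"] == opls_cfg["comparison"])
    mask_a = table.select_rows(comp["group_a"])
    mask_b = table.select_rows(comp["group_b"])
    rows = mask_a | mask_b
    y = mask_b[rows].astype(int)
    try:
        model = fit_oplsda(table.matrix[rows], y, opls_cfg.get("n_ortho", 1),
                           opls_cfg.get("k_cv", 7), opls_cfg.get("scaling", "uv"))
        perm = permutation_test(
            table.matrix[rows], y, opls_cfg.get("n_perm", 200), config.seed,
            opls_cfg.get("n_ortho", 1), opls_cfg.get("k_cv", 7),
            opls_cfg.get("scaling", "uv"))
    except ValueError as exc:
        raise PipelineStageError(f"stage 'oplsda' failed: {exc}") from exc
    opls_summary = {
        "comparison": opls_cfg["comparison"],
        "r2y": model.r2y, "q2": model.q2,
        "n_ortho": model.n_ortho, "k_cv": model.k_cv, "scaling": model.scaling,
        "n_perm": perm.n_perm,
        "r2_intercept": perm.r2_intercept, "q2_intercept": perm.q2_intercept,
        "fraction_q2_below": perm.fraction_q2_below,
        "no_overfitting": perm.no_overfitting,
        "seed": config.seed,
    }
    (out / "oplsda.json").write_text(json.dumps(opls_summary, indent=1))
    perm.to_frame().to_csv(out / "permutation.csv", index=False)

    regions = np.array([s.region for s in table.rows])
    plsda_scores = fit_plsda_scores(table.matrix, regions)
    plsda_scores.to_csv(out / "plsda_scores.csv", index=False)

    # annotation-driven stages use the rank-1 metabolite per feature
    best = ann.best()
    feat_to_met = dict(zip(best["feature_mz"], best["metabolite"]))

    en_cfg = config.enrichment
    hits_idx = diff[en_cfg["comparison"]].significant()
    hit_mz = table.feature_mz[hits_idx]
    universe = sorted(set(feat_to_met.values()))
    hits = sorted({feat_to_met[m] for m in hit_mz if m in feat_to_met})
    pathways = (read_pathways(data / config.pathway_file)
                if config.pathway_file else pathways_from_database(database))
    enrichment = ora_enrich(hits, universe, pathways, en_cfg.get("cutoff", 0.05))
    enrichment.to_csv(out / "enrichment.csv", index=False)

    pn_cfg = config.panel
    pdiff = diff[pn_cfg["comparison"]]
    comp = next(c for c in config.comparisons
                if c["name"] == pn_cfg["comparison"])
    mask_a = table.select_rows(comp["group_a"])
    mask_b = table.select_rows(comp["group_b"])
    rows = mask_a | mask_b
    y = mask_b[rows].astype(int)
    sig_idx = pdiff.significant()
    annotated_sig = [i for i in sig_idx if table.feature_mz[i] in feat_to_met]
    marker_pool = "differential"
    if len(annotated_sig) < 2:
        # screen found (almost) nothing annotated: rank every annotated
        # feature by AUC instead of leaving the signature stage empty
        marker_pool = "all_annotated"
        annotated_sig = [i for i in range(table.n_features)
                         if table.feature_mz[i] in feat_to_met]
    names = [f"{feat_to_met[table.feature_mz[i]]}@{table.feature_mz[i]:.4f}"
             for i in annotated_sig]
    ranking = rank_signatures(table.matrix[np.ix_(rows, annotated_sig)], y, names)
    ranking.to_csv(out / "signature_auc.csv", index=False)

    k = min(pn_cfg.get("top_k", 4), len(ranking))
    panel_dict: dict = {"members": [], "note": "not enough annotated markers",
                        "marker_pool": marker_pool}
    if k >= 2:
        members = top_k_members(ranking, k)
        cols = [names.index(m) for m in members]
        sub = table.matrix[np.ix_(rows, [annotated_sig[c] for c in cols])]
        panel = fit_panel_with_cv(
            sub, y, members, pn_cfg.get("ridge", 1e-6),
            pn_cfg.get("folds", 5), config.seed)
        panel_dict = panel.to_dict()
        panel_dict["marker_pool"] = marker_pool
    (out / "panel.json").write_text(json.dumps(panel_dict, indent=1))

    run_manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_sections": len(manifest),
        "n_region_spectra": len(spectra),
        "n_features": table.n_features,
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=1))

    return RunResult(config, table, ann, diff, venn, trends, opls_summary,
                     plsda_scores, enrichment, ranking, panel_dict, out)
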