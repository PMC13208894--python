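import numpy as np
import pandas as pd
import pytest

from spatimet import (
    StudyConfig, annotate_features, extract_roi_spectrum, generate_database,
    generate_study, write_study,
)
from spatimet.annotate import ADDUCT_SHIFTS, read_database
from spatimet.synthetic import GroundTruth


class TestGenerateStudy:
    def test_same_seed_identical_outputs(self):
        cfg = StudyConfig(n_metabolites=20, pixels_per_region=5, n_decoys=5,
                          seed=9)
        a = generate_study(cfg)
        b = generate_study(cfg)
        for da, db in zip(a.datasets, b.datasets):
            np.testing.assert_array_equal(da.intensities, db.intensities)
            np.testing.assert_array_equal(da.mz_index, db.mz_index)
        pd.testing.assert_frame_equal(a.database, b.database)
        pd.testing.assert_frame_equal(a.ground_truth.metabolites,
                                      b.ground_truth.metabolites)

    def test_default_design_has_23_sections(self, small_study):
        assert len(small_study.manifest) == 23
        m = small_study.manifest.records
        assert (m["tissue"] == "normal_colorectal").sum() == 10
        assert (m["tissue"] == "primary_tumor").sum() == 10
        assert (m["tissue"] == "liver_metastasis").sum() == 3

    def test_differential_fraction_flags(self):
        study = generate_study(StudyConfig(
            n_metabolites=200, fraction_differential=0.1,
            pixels_per_region=2, n_decoys=0, seed=4))
        flags = study.ground_truth.differential["PT_vs_N"]["flag"] | \
            study.ground_truth.differential["LT_vs_PT"]["flag"]
        assert flags.sum() == 20

    def test_adduct_profiles_sum_to_one(self, small_study):
        for name in small_study.ground_truth.metabolites["name"]:
            profile = small_study.ground_truth.adduct_profile(name)
            assert sum(profile.values()) == pytest.approx(1.0)

    def test_trend_labels_consistent_with_effect_signs(self, small_study):
        truth = small_study.ground_truth
        for name, label in truth.trend.items():
            e = truth.region_effects.loc[name]
            d1 = np.sign(e["PT"])
            d2 = np.sign(e["LT"] - e["PT"])
            if label == "monotone_increase":
                assert d1 > 0 and d2 > 0
            elif label == "up_then_down":
                assert d1 > 0 and d2 < 0
            elif label == "flat":
                assert d1 == 0 and d2 == 0

    def test_noise_free_roi_means_equal_planted_levels(self):
        cfg = StudyConfig(n_metabolites=15, pixels_per_region=4,
                          pixel_noise_cv=0.0, dropout=0.0, section_sdlog=0.0,
                          mass_error_ppm=0.0, n_decoys=0, seed=11,
                          fraction_metastasis_markers=0.0)
        study = generate_study(cfg)
        truth = study.ground_truth
        theo = truth.theoretical_mz().sort_values("mz").reset_index(drop=True)
        baseline_by_peak = {}
        ds, mask = study.datasets[10], study.masks[10]  # a primary-tumor section
        spec_n = extract_roi_spectrum(ds, mask, "N")
        spec_pt = extract_roi_spectrum(ds, mask, "PT")
        eff = truth.region_effects
        for j, row in theo.iterrows():
            ratio = spec_pt.intensity[j] / spec_n.intensity[j]
            expected = 2.0 ** eff.loc[row["metabolite"], "PT"]
            assert ratio == pytest.approx(expected, rel=1e-9)

    def test_group_mean_log2fc_converges_to_planted_effect(self):
        # many pixels, no between-section variability: ROI-mean fold change
        # should recover the planted PT effect closely
        cfg = StudyConfig(n_metabolites=10, pixels_per_region=500,
                          section_sdlog=0.0, dropout=0.05, pixel_noise_cv=0.3,
                          mass_error_ppm=0.0, n_decoys=0, seed=2,
                          fraction_metastasis_markers=0.0)
        study = generate_study(cfg)
        truth = study.ground_truth
        theo = truth.theoretical_mz().sort_values("mz").reset_index(drop=True)
        ds, mask = study.datasets[12], study.masks[12]
        spec_n = extract_roi_spectrum(ds, mask, "N")
        spec_pt = extract_roi_spectrum(ds, mask, "PT")
        for j, row in theo.iterrows():
            realized = np.log2(spec_pt.intensity[j] / spec_n.intensity[j])
            planted = truth.region_effects.loc[row["metabolite"], "PT"]
            assert realized == pytest.approx(planted, abs=0.1)

    def test_mass_errors_at_configured_scale(self, small_study):
        truth_mz = np.sort(small_study.ground_truth.theoretical_mz()["mz"])
        ds = small_study.datasets[0]
        # each observed channel should sit within ~5 sd of a true peak
        idx = np.searchsorted(truth_mz, ds.mz_index)
        idx = np.clip(idx, 1, len(truth_mz) - 1)
        nearest = np.minimum(
            np.abs(ds.mz_index - truth_mz[idx - 1]),
            np.abs(ds.mz_index - truth_mz[idx]))
        ppm = nearest / ds.mz_index * 1e6
        assert np.all(ppm < 5 * small_study.config.mass_error_ppm + 0.1)


class TestGenerateDatabase:
    def test_zero_decoys_identity(self, small_study):
        db = generate_database(small_study.ground_truth, 0, 20.0)
        assert list(db["name"]) == list(
            small_study.ground_truth.metabolites["name"])

    def test_decoys_respect_spacing(self, small_study, rng):
        db = generate_database(small_study.ground_truth, 50, 20.0, rng)
        shifts = np.array(list(ADDUCT_SHIFTS.values()))
        true_mz = (small_study.ground_truth.metabolites["neutral_mass"]
                   .to_numpy()[:, None] + shifts).ravel()
        decoy_mz = (db[db["class"] == "decoy"]["neutral_mass"]
                    .to_numpy()[:, None] + shifts).ravel()
        ppm = np.abs(decoy_mz[:, None] - true_mz[None, :]) / true_mz * 1e6
        assert ppm.min() >= 20.0

    def test_roundtrips_through_annotate_reader(self, tmp_path, small_study):
        small_study.database.to_csv(tmp_path / "db.csv", index=False)
        back = read_database(tmp_path / "db.csv")
        assert len(back) == len(small_study.database)
        np.testing.assert_allclose(back["neutral_mass"],
                                   small_study.database["neutral_mass"])

    def test_infeasible_spacing_raises(self, small_study):
        with pytest.raises(RuntimeError, match="decoys"):
            generate_database(small_study.ground_truth, 2000, 5000.0,
                              max_attempts=4000)


class TestAnnotationRecovery:
    def test_rank1_recall_and_decoy_rate(self, small_study):
        """At 1.5 ppm mass error and 20 ppm decoy spacing, rank-1 annotation
        recovers nearly all true peaks and never hits a decoy."""
        truth = small_study.ground_truth
        ds = small_study.datasets[0]
        ann = annotate_features(ds.mz_index, small_study.database)
        best = ann.best()
        assert not best["metabolite"].str.startswith("DECOY").any()
        theo = truth.theoretical_mz()
        theo_sorted = np.sort(theo["mz"].to_numpy())
        recalled = 0
        for f, met in zip(best["feature_mz"], best["metabolite"]):
            j = np.searchsorted(theo["mz"].to_numpy(), f)
            true_here = theo.iloc[(theo["mz"] - f).abs().argmin()]
            if true_here["metabolite"] == met:
                recalled += 1
        assert recalled / len(ds.mz_index) >= 0.95


def test_write_study_roundtrip(tmp_path, small_study):
    write_study(small_study, tmp_path)
    gt = GroundTruth.from_json(tmp_path / "ground_truth.json")
    pd.testing.assert_frame_equal(gt.metabolites,
                                  small_study.ground_truth.metabolites)
    pd.testing.assert_frame_equal(gt.region_effects,
                                  small_study.ground_truth.region_effects)
    assert (tmp_path / "manifest.csv").exists()
    assert len(list(tmp_path.glob("S_*.csv"))) == 46  # 23 data + 23 masks
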