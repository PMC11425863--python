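import filecmp
from dataclasses import replace

import numpy as np
import pytest

from fluidprint.errors import CompoundLookupError, ConfigError, EmptyInputError
from fluidprint.synth import (
    CohortConfig,
    PeakSpec,
    SurvivalConfig,
    default_config,
    generate_cohort,
    generate_spectrum,
    generate_standard_mix,
    generate_survival,
    simulate_fingerprints,
)
from fluidprint.core_io import save_cohort


class TestGenerateSpectrum:
    def test_single_clean_peak_apex(self, clean_config):
        # full-density grid so discretization error at the apex is negligible
        cfg = replace(clean_config, n_points=57_600)
        rng = np.random.default_rng(0)
        panel = [PeakSpec(203.05, 100.0, width_sigma=0.1)]
        s = generate_spectrum(panel, "HC", cfg, rng)
        i = np.argmax(s.intensity)
        grid = cfg.grid()
        assert abs(grid[i] - 203.05) <= np.diff(grid)[0]
        # worst-case apex discretization: exp(-(dx/2)^2 / (2 sigma^2)) with
        # dx ~ 0.01215 Da and sigma 0.1 Da -> at most ~0.19% below the peak
        assert s.intensity[i] == pytest.approx(100.0, rel=2e-3)

    def test_noiseless_spectrum_is_exact_gaussian_mixture(self, clean_config):
        rng = np.random.default_rng(1)
        s = generate_spectrum(clean_config.serum_panel, "HC", clean_config, rng)
        grid = clean_config.grid()
        expected = sum(
            p.base_height * np.exp(-0.5 * ((grid - p.mz) / p.width_sigma) ** 2)
            for p in clean_config.serum_panel
        )
        np.testing.assert_allclose(s.intensity, expected, atol=1e-9)

    def test_class_multiplier_doubles_mean_apex(self, clean_config):
        cfg = replace(clean_config, peak_scale_sigma=0.2, sample_scale_sigma=0.1)
        panel = [PeakSpec(300.0, 100.0, width_sigma=0.2,
                          class_multiplier={"ccRCC": 2.0})]
        rng = np.random.default_rng(5)
        heights = {g: [] for g in ("HC", "ccRCC")}
        for _ in range(200):
            for g in heights:
                s = generate_spectrum(panel, g, cfg, rng)
                heights[g].append(s.intensity.max())
        ratio = np.mean(heights["ccRCC"]) / np.mean(heights["HC"])
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_identical_rng_state_gives_identical_spectra(self, small_config):
        s1 = generate_spectrum(small_config.serum_panel, "HC", small_config,
                               np.random.default_rng(9))
        s2 = generate_spectrum(small_config.serum_panel, "HC", small_config,
                               np.random.default_rng(9))
        np.testing.assert_array_equal(s1.intensity, s2.intensity)

    def test_peak_outside_window_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(
                n_per_group={"HC": 1},
                serum_panel=[PeakSpec(950.0, 10.0)],
                urine_panel=[PeakSpec(200.0, 10.0)],
            )


class TestGenerateCohort:
    def test_counts_and_truth(self, clean_config):
        cfg = replace(clean_config, n_per_group={"HC": 10, "ccRCC": 10})
        res = generate_cohort(cfg)
        assert len(res.clinical) == 20
        assert len(res.serum) == len(res.urine) == 20
        assert set(res.truth.planted_labels("serum")) == {
            p.label("serum") for p in cfg.serum_panel
        }

    def test_demo_proportions_scale_study_composition(self):
        n = default_config().n_per_group
        assert n == {"HC": 20, "ccRCC": 22, "pRCC": 10, "chRCC": 10, "AML": 4}

    def test_same_seed_byte_identical_manifests(self, tmp_path, clean_config):
        for d in ("a", "b"):
            res = generate_cohort(clean_config)
            save_cohort(res.serum, res.urine, res.clinical, tmp_path / d)
        cmp = filecmp.cmp(tmp_path / "a" / "manifest.json",
                          tmp_path / "b" / "manifest.json", shallow=False)
        assert cmp

    def test_zero_subjects_rejected(self, clean_config):
        with pytest.raises(ConfigError):
            generate_cohort(replace(clean_config, n_per_group={"HC": 0}))

    def test_survival_only_for_malignant(self, small_config):
        cfg = replace(small_config, n_points=720,
                      n_per_group={"HC": 3, "AML": 3, "ccRCC": 3})
        res = generate_cohort(cfg)
        c = res.clinical.set_index("sample_id")
        benign = c["group"].isin(["HC", "AML"])
        assert c.loc[benign, "dfs_time"].isna().all()
        assert c.loc[~benign, "dfs_time"].notna().all()


class TestGenerateSurvival:
    def test_full_censoring_means_no_events(self, small_config, rng):
        cfg = replace(small_config,
                      survival=SurvivalConfig(0.05, {}, censoring_rate=1.0))
        times, events = generate_survival(np.zeros(50), cfg, rng)
        assert events.sum() == 0
        assert np.all(times >= 0)

    def test_hazard_ratio_recovered(self, small_config):
        # planted log-HR of log(3) between two halves; the empirical HR
        # over replicates should sit near 3
        from lifelines import CoxPHFitter
        import pandas as pd

        cfg = replace(small_config, survival=SurvivalConfig(0.05, {}, 0.2))
        hrs = []
        for rep in range(10):
            rng = np.random.default_rng(rep)
            risk = np.r_[np.zeros(100), np.full(100, np.log(3.0))]
            t, e = generate_survival(risk, cfg, rng)
            df = pd.DataFrame({"g": (risk > 0).astype(int), "time": t, "event": e})
            cph = CoxPHFitter().fit(df, "time", "event")
            hrs.append(float(np.exp(cph.summary.loc["g", "coef"])))
        assert 2.2 <= np.mean(hrs) <= 4.0

    def test_negative_baseline_hazard_rejected(self):
        with pytest.raises(ConfigError):
            SurvivalConfig(baseline_hazard=-1.0)


class TestStandardMix:
    def test_five_standards_sodium_apexes(self, small_config):
        s = generate_standard_mix(
            ["histidine", "phenylalanine", "arginine", "glucose", "tryptophan"],
            adduct="Na", config=small_config,
        )
        from scipy.signal import find_peaks

        idx, _ = find_peaks(s.intensity, height=1000)
        nominal = sorted(int(round(m)) for m in s.mz[idx])
        assert nominal == [178, 188, 197, 203, 227]

    def test_cellobiose_sodium_apex(self, small_config):
        s = generate_standard_mix(["cellobiose"], "Na", small_config)
        assert int(round(s.mz[np.argmax(s.intensity)])) == 365

    def test_empty_compound_list_rejected(self, small_config):
        with pytest.raises(EmptyInputError):
            generate_standard_mix([], "Na", small_config)

    def test_unknown_compound_rejected(self, small_config):
        with pytest.raises(CompoundLookupError):
            generate_standard_mix(["unobtainium"], "Na", small_config)


class TestTruthRecord:
    def test_bayes_auc_null_is_half(self, clean_config):
        _, _, truth = simulate_fingerprints(
            replace(clean_config, n_per_group={"HC": 3, "AML": 3})
        )
        assert truth.bayes_auc("HC", "AML") == 0.5

    def test_bayes_auc_increases_with_effect(self, clean_config):
        aucs = []
        for mult in (1.2, 1.5, 2.0):
            cfg = replace(
                clean_config,
                peak_scale_sigma=0.2,
                serum_panel=[PeakSpec(300.0, 100.0,
                                      class_multiplier={"ccRCC": mult})],
            )
            _, _, truth = simulate_fingerprints(cfg)
            aucs.append(truth.bayes_auc("HC", "ccRCC"))
        assert aucs == sorted(aucs)
        assert aucs[0] > 0.5

    def test_fingerprint_areas_match_intensity_model(self, clean_config):
        cfg = replace(clean_config, peak_scale_sigma=0.3, sample_scale_sigma=0.1)
        sf, _, truth = simulate_fingerprints(cfg)
        p = cfg.serum_panel[0]
        lab = p.label("serum")
        expected = (
            p.base_height * p.width_sigma * np.sqrt(2 * np.pi)
            * np.exp(truth.log_factors[lab])
        )
        np.testing.assert_allclose(sf[lab], expected, rtol=1e-12)
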