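from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fluidprint.biomarker import (
    ADDUCTS,
    adduct_mz,
    annotate_feature,
    load_compounds,
    monoisotopic_mass,
    nominal_adduct_mz,
    panel_evaluate,
    select_biomarkers,
)
from fluidprint.errors import FormulaError, UndefinedMetricError
from fluidprint.synth import simulate_fingerprints, PeakSpec, SurvivalConfig, CohortConfig


class TestAdductMz:
    @pytest.mark.parametrize(
        "formula,adduct,exact,nominal",
        [
            ("C6H12O6", "Na", 203.053, 203),   # glucose sodium adduct
            ("C6H12O6", "K", 219.027, 219),
            ("", "Na", 22.990, 23),            # bare cation
            ("C6H9N3O2", "Na", 178.059, 178),  # histidine
            ("C12H22O11", "Na", 365.106, 365), # cellobiose
        ],
    )
    def test_printed_adduct_masses(self, formula, adduct, exact, nominal):
        assert adduct_mz(formula, adduct) == pytest.approx(exact, abs=2e-3)
        assert nominal_adduct_mz(formula, adduct) == nominal

    def test_unknown_element_rejected(self):
        with pytest.raises(FormulaError):
            adduct_mz("Xx2O", "Na")

    def test_unknown_adduct_rejected(self):
        with pytest.raises(FormulaError):
            adduct_mz("C6H12O6", "Cs")

    @pytest.mark.parametrize("formula", ["C6H12O6", "C9H11NO2", "CH4N2O", "C5H4N4O3"])
    def test_sodium_hydrogen_offset_constant(self, formula):
        # additivity: the Na-vs-H adduct spacing is a property of the
        # cations alone (22.98977 - 1.00783 = 21.98194 Da)
        delta = adduct_mz(formula, "Na") - adduct_mz(formula, "H")
        assert delta == pytest.approx(21.98194, abs=1e-4)


class TestCompoundTable:
    def test_loads_and_self_checks(self):
        table = load_compounds()
        assert len(table) >= 60
        names = {c.name for c in table}
        assert {"glucose", "histidine", "cellobiose", "creatinine"} <= names
        for c in table[:5]:
            assert abs(monoisotopic_mass(c.formula) - c.monoisotopic) < 1e-3


class TestAnnotateFeature:
    def test_glucose_candidate_at_203(self):
        out = annotate_feature(203.05, adducts=("Na",), tolerance=0.05)
        assert "glucose" in set(out["compound"])
        assert (out["mass_error"].abs() <= 0.05).all()

    def test_no_match_returns_empty_frame(self):
        out = annotate_feature(150.00, tolerance=0.01)
        assert len(out) == 0

    def test_degenerate_tolerance_returns_everything_sorted(self):
        table = load_compounds()
        out = annotate_feature(300.0, compounds=table, tolerance=1e6)
        assert len(out) == len(table) * len(ADDUCTS)
        err = out["mass_error"].abs().to_numpy()
        assert np.all(np.diff(err) >= 0)


class TestSelectBiomarkers:
    def _matrix(self, rng, n=60, planted_mult=1.0, base=3000.0):
        cfg = CohortConfig(
            n_per_group={"HC": n // 2, "ccRCC": n // 2},
            serum_panel=[
                PeakSpec(179.1, base, class_multiplier={"ccRCC": planted_mult}),
                PeakSpec(300.0, 200.0),   # low-intensity feature
                PeakSpec(400.0, base),    # null feature
            ],
            urine_panel=[PeakSpec(143.1, base)],
            survival=SurvivalConfig(baseline_hazard=0.0),
            seed=int(rng.integers(0, 2**31)),
        )
        sf, uf, truth = simulate_fingerprints(cfg)
        from fluidprint.core_io import FeatureMatrix

        fused = FeatureMatrix(pd.concat([sf, uf], axis=1))
        y = (truth.groups.loc[fused.sample_ids] == "ccRCC").astype(int).to_numpy()
        return fused, y

    def test_low_intensity_feature_always_excluded(self, rng):
        fused, y = self._matrix(rng, planted_mult=2.0)
        scores = {lab: 1.0 for lab in fused.feature_labels}
        selected, table = select_biomarkers(fused, y, scores, positive_class=1)
        row = table.set_index("feature").loc["S300.0"]
        assert row["mean_intensity"] < 1000
        assert "S300.0" not in selected

    def test_zero_model_score_excluded_by_strict_inequality(self, rng):
        fused, y = self._matrix(rng, planted_mult=2.0)
        scores = {lab: 0.0 for lab in fused.feature_labels}
        selected, _ = select_biomarkers(fused, y, scores, positive_class=1)
        assert selected == []

    def test_planted_twofold_feature_selected(self, rng):
        hits = 0
        for _ in range(10):
            fused, y = self._matrix(rng, planted_mult=2.0, n=200)
            scores = {lab: 1.0 for lab in fused.feature_labels}
            selected, table = select_biomarkers(fused, y, scores, positive_class=1)
            hits += "S179.1" in selected
            assert table.set_index("feature").loc["S179.1", "direction"] == "up"
        assert hits == 10


class TestPanelEvaluate:
    def _split_matrices(self, rng, panel, n=120):
        cfg = CohortConfig(
            n_per_group={"HC": n // 2, "ccRCC": n // 2},
            serum_panel=panel,
            urine_panel=[PeakSpec(133.1, 5000.0)],
            survival=SurvivalConfig(baseline_hazard=0.0),
            seed=int(rng.integers(0, 2**31)),
        )
        sf, uf, truth = simulate_fingerprints(cfg)
        from fluidprint.core_io import FeatureMatrix

        fused = FeatureMatrix(np.log10(1 + pd.concat([sf, uf], axis=1)))
        y = (truth.groups.loc[fused.sample_ids] == "ccRCC").astype(int).to_numpy()
        from sklearn.model_selection import train_test_split

        tr, te = train_test_split(np.arange(len(y)), test_size=0.3,
                                  stratify=y, random_state=0)
        ids = np.asarray(fused.sample_ids)
        return (fused.subset_samples(ids[tr]), y[tr],
                fused.subset_samples(ids[te]), y[te])

    def test_singleton_panel_matches_univariate_auc(self, rng):
        panel = [PeakSpec(179.1, 3000.0, class_multiplier={"ccRCC": 1.8})]
        Xtr, ytr, Xte, yte = self._split_matrices(rng, panel)
        out = panel_evaluate(["S179.1"], Xtr, ytr, Xte, yte, n_boot=200, seed=0)
        assert out.test_auc == pytest.approx(out.feature_auc["S179.1"], abs=0.08)

    def test_complementary_panel_beats_best_single_feature(self, rng):
        mult = 1.35  # weak individual features (AUC ~ 0.6-0.8 regime)
        panel = [PeakSpec(150.0 + 30 * j, 3000.0,
                          class_multiplier={"ccRCC": mult}) for j in range(7)]
        Xtr, ytr, Xte, yte = self._split_matrices(rng, panel, n=240)
        feats = [p.label("serum") for p in panel]
        out = panel_evaluate(feats, Xtr, ytr, Xte, yte, n_boot=100, seed=0)
        assert out.test_auc > max(out.feature_auc.values())

    def test_oriented_feature_auc_never_below_half(self, rng):
        panel = [PeakSpec(179.1, 3000.0, class_multiplier={"ccRCC": 0.5}),
                 PeakSpec(210.0, 3000.0)]
        Xtr, ytr, Xte, yte = self._split_matrices(rng, panel)
        out = panel_evaluate(["S179.1", "S210.0"], Xtr, ytr, Xte, yte,
                             n_boot=100, seed=0)
        assert all(a >= 0.5 for a in out.feature_auc.values())

    def test_single_class_test_labels_rejected(self, rng, matrix_factory):
        m = matrix_factory(np.ones((4, 1)), labels=["S100.0"])
        with pytest.raises(UndefinedMetricError):
            panel_evaluate(["S100.0"], m, [0, 1, 0, 1], m, [1, 1, 1, 1])
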