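"""Tests for hemisphere combining, covariate adjustment, effect-size
selection and z-scoring."""

import numpy as np
import pandas as pd
import pytest

from sustain_psp import synthetic
from sustain_psp.preprocess import (CovariateAdjuster, apply_adjuster,
                                    cohens_d, combine_hemispheres,
                                    compute_zscores, fit_covariate_adjuster,
                                    preprocess_cohort,
                                    residual_age_association,
                                    select_biomarkers)
from sustain_psp.synthetic import CovariateEffect, default_config


def make_controls(n=200, seed=0, age_slope=0.0, roi_mean=5000.0, roi_sd=150.0):
    rng = np.random.default_rng(seed)
    age = rng.normal(62, 9, n)
    df = pd.DataFrame({
        "subject_id": [f"C{i}" for i in range(n)],
        "visit": 0,
        "group": "control",
        "age": age,
        "tiv_mm3": rng.normal(1.45e6, 1.2e5, n),
        "sex": rng.choice(["F", "M"], n),
        "field_strength": rng.choice([1.5, 3.0], n),
        "manufacturer": rng.choice(["Siemens", "GE", "Philips"], n),
        "roi_a": roi_mean + age_slope * (age - 65)
        + rng.normal(0, roi_sd, n),
    })
    return df


class TestCombineHemispheres:
    def test_paired_labels_sum(self):
        assert combine_hemispheres({"thal_L": 5000, "thal_R": 5200}) == \
            {"thal": 10200.0}

    def test_midline_passthrough(self):
        assert combine_hemispheres({"pons": 14000}) == {"pons": 14000.0}

    def test_orphan_hemisphere_names_missing_partner(self):
        with pytest.raises(ValueError, match="amyg_R"):
            combine_hemispheres({"amyg_L": 800})

    def test_dataframe_combining_preserves_totals(self):
        df = pd.DataFrame({
            "subject_id": ["s1", "s2"],
            "roi_thal_L": [5000.0, 5100.0],
            "roi_thal_R": [5200.0, 5150.0],
            "roi_pons": [14000.0, 13800.0],
        })
        out = combine_hemispheres(df)
        assert out["roi_thal"].tolist() == [10200.0, 10250.0]
        assert out["roi_pons"].tolist() == [14000.0, 13800.0]
        assert "roi_thal_L" not in out.columns


class TestCovariateAdjuster:
    def test_null_effects_give_null_coefficients(self):
        controls = make_controls(n=400, seed=1)
        adj = fit_covariate_adjuster(controls)
        coef = adj.coefficients["roi_a"]
        se = adj.standard_errors["roi_a"]
        for term in coef.index:
            if term == "const":
                continue
            assert abs(coef[term]) < 3 * se[term], term

    def test_injected_age_slope_recovered(self):
        controls = make_controls(n=400, seed=2, age_slope=-20.0)
        adj = fit_covariate_adjuster(controls)
        assert abs(adj.coefficients["roi_a"]["age"] + 20.0) < \
            3 * adj.standard_errors["roi_a"]["age"]

    def test_single_control_insufficient(self):
        with pytest.raises(ValueError):
            fit_covariate_adjuster(make_controls(n=1))

    def test_single_level_categorical_dropped(self):
        controls = make_controls(n=100, seed=3)
        controls["manufacturer"] = "Siemens"
        adj = fit_covariate_adjuster(controls)
        assert "manufacturer" in adj.dropped_covariates
        assert not any(t.startswith("manufacturer")
                       for t in adj.coefficients.index)

    def test_control_at_covariate_mean_unchanged(self):
        controls = make_controls(n=500, seed=4, age_slope=-15.0)
        adj = fit_covariate_adjuster(controls)
        probe = controls.iloc[[0]].copy()
        probe["age"] = controls["age"].mean()
        probe["tiv_mm3"] = controls["tiv_mm3"].mean()
        # categorical covariates at the reference level, continuous at the
        # control mean: prediction ~ mean prediction, adjustment ~ 0
        for term in adj.design_terms:
            if term["kind"] == "categorical":
                probe[term["name"]] = term["reference"]
        out = apply_adjuster(adj, probe)
        shift = float((out["roi_a"] - probe["roi_a"]).iloc[0])
        # shift only from the categorical composition of the control pool
        assert abs(shift) < 0.05 * 5000.0

    def test_unseen_manufacturer_maps_to_reference(self):
        controls = make_controls(n=150, seed=5)
        adj = fit_covariate_adjuster(controls)
        probe = controls.iloc[[0]].copy()
        probe["manufacturer"] = "Canon"
        with pytest.warns(UserWarning, match="unseen"):
            apply_adjuster(adj, probe)

    def test_residual_age_slope_removed(self):
        controls = make_controls(n=400, seed=6, age_slope=-25.0)
        adj = fit_covariate_adjuster(controls)
        adjusted = apply_adjuster(adj, controls)
        t = residual_age_association(adjusted)["t"].iloc[0]
        assert abs(t) < 2


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1, 2, 3, 4], [1, 2, 3, 4]) == 0.0

    def test_hand_computed_value(self):
        # pooled SD = 1, means differ by -2
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)

    def test_one_pooled_sd_difference(self):
        # pooled SD of both triples is exactly 1; means differ by exactly 1
        assert cohens_d([1, 2, 3], [0, 1, 2]) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0], [1.0, 2.0])


def _selection_frame(n=300, seed=0, strong=1.0, weak=0.2):
    """Adjusted-volume table with 5 strong-effect and 5 weak-effect ROIs."""
    rng = np.random.default_rng(seed)
    rows = {"visit": 0,
            "group": ["control"] * n + ["patient"] * n}
    for i in range(5):
        rows[f"roi_s{i}"] = np.concatenate(
            [rng.normal(0, 1, n), rng.normal(-strong, 1, n)])
    for i in range(5):
        rows[f"roi_w{i}"] = np.concatenate(
            [rng.normal(0, 1, n), rng.normal(-weak, 1, n)])
    return pd.DataFrame(rows)


class TestSelection:
    def test_strong_rois_selected_weak_dropped(self):
        df = _selection_frame(seed=8)
        selected, table = select_biomarkers(df, threshold=0.6)
        assert sorted(selected) == [f"roi_s{i}" for i in range(5)]
        assert table["cohens_d"].is_monotonic_decreasing

    def test_zero_threshold_keeps_everything_positive(self):
        df = _selection_frame(seed=9)
        selected, _ = select_biomarkers(df, threshold=-np.inf)
        assert len(selected) == 10

    def test_unreachable_threshold_raises(self):
        df = _selection_frame(seed=10)
        with pytest.raises(ValueError, match="threshold"):
            select_biomarkers(df, threshold=np.inf)

    def test_selection_invariant_to_affine_rescaling(self):
        df = _selection_frame(seed=11)
        sel1, _ = select_biomarkers(df, threshold=0.6)
        df2 = df.copy()
        df2["roi_s0"] = df2["roi_s0"] * 1000.0 + 5.0
        df2["roi_w0"] = df2["roi_w0"] * 0.001 - 7.0
        sel2, _ = select_biomarkers(df2, threshold=0.6)
        assert sel1 == sel2


class TestZScores:
    def _panel(self, seed=12):
        controls = make_controls(n=300, seed=seed)
        adj = fit_covariate_adjuster(controls)
        patients = make_controls(n=100, seed=seed + 1)
        patients["group"] = "patient"
        patients["roi_a"] -= 400.0  # two-ish control SDs of atrophy
        both = pd.concat([controls, patients], ignore_index=True)
        adjusted = apply_adjuster(adj, both)
        return adjusted, adj

    def test_patient_at_control_mean_scores_zero(self):
        adjusted, adj = self._panel()
        probe = adjusted.iloc[[0]].copy()
        probe["roi_a"] = adj.control_mean["roi_a"]
        panel = compute_zscores(probe, adj, ["roi_a"])
        assert panel.zscores["a"].iloc[0] == pytest.approx(0.0)

    def test_sign_flip_two_sds_below_mean_is_plus_two(self):
        adjusted, adj = self._panel()
        probe = adjusted.iloc[[0]].copy()
        probe["roi_a"] = adj.control_mean["roi_a"] - 2 * adj.control_sd["roi_a"]
        panel = compute_zscores(probe, adj, ["roi_a"])
        assert panel.zscores["a"].iloc[0] == pytest.approx(2.0)

    def test_controls_self_standardize(self):
        adjusted, adj = self._panel()
        ctrl = adjusted[adjusted["group"] == "control"]
        panel = compute_zscores(ctrl, adj, ["roi_a"])
        assert panel.zscores["a"].mean() == pytest.approx(0.0, abs=1e-10)
        assert panel.zscores["a"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_zero_control_sd_rejected(self):
        adjusted, adj = self._panel()
        adj.control_sd["roi_a"] = 0.0
        with pytest.raises(ValueError):
            compute_zscores(adjusted, adj, ["roi_a"])

    def test_scans_missing_selected_roi_are_excluded(self):
        adjusted, adj = self._panel()
        adjusted.loc[adjusted.index[:3], "roi_a"] = np.nan
        panel = compute_zscores(adjusted, adj, ["roi_a"])
        assert len(panel.zscores) == len(adjusted) - 3


class TestPipeline:
    def test_end_to_end_is_deterministic_and_sign_correct(self):
        cfg = default_config(n_controls=80, n_patients=120, seed=21)
        cohort, truth = synthetic.generate_cohort(cfg)
        p1, _, d1 = preprocess_cohort(cohort)
        p2, _, d2 = preprocess_cohort(cohort)
        assert np.array_equal(p1.matrix(), p2.matrix())
        assert d1.equals(d2)
        # more advanced true stage => larger mean z (sign convention)
        bp = p1.baseline_patients()
        merged = p1.meta[bp].merge(truth, on=["subject_id", "visit"])
        mean_z = p1.zscores[bp].mean(axis=1)
        lo = mean_z[(merged["true_stage"] <= 10).to_numpy()]
        hi = mean_z[(merged["true_stage"] >= 30).to_numpy()]
        assert hi.mean() > lo.mean() + 1.0

    def test_control_z_columns_standardized(self):
        cfg = default_config(n_controls=100, n_patients=100, seed=22)
        cohort, _ = synthetic.generate_cohort(cfg)
        panel, _, _ = preprocess_cohort(cohort)
        ctrl = (panel.meta["group"] == "control").to_numpy()
        Z = panel.matrix()[ctrl]
        # z-scored against the controls' own adjusted statistics
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-10)
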