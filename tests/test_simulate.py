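"""Synthetic-study generators: determinism, documented ranges, noise structure."""

import numpy as np
import pandas as pd
import pytest

import phytoplex as px
from phytoplex.errors import ConfigurationError, DomainError, SchemaError
from phytoplex.simulate import METABOLITE_CLASSES, metabolite_columns


class TestMetaboliteTable:
    def test_design_shape_and_labels(self):
        cfg = px.SimulationConfig(seed=0)
        t = px.generate_metabolite_table(cfg)
        assert len(t) == 18 * 2 * 3
        assert t["cultivar"].nunique() == 18
        assert t["vintage"].nunique() == 2
        assert t["sample_id"].is_unique

    def test_zero_noise_replicates_identical(self):
        cfg = px.SimulationConfig(replicate_cv=0.0, vintage_shift_sd=0.0, seed=1)
        t = px.generate_metabolite_table(cfg)
        mets = metabolite_columns(t)
        for _, grp in t.groupby("cultivar"):
            assert (grp[mets].nunique() == 1).all()

    def test_default_means_within_documented_ranges(self):
        cfg = px.SimulationConfig(seed=2)
        means = cfg.resolved_means()
        antho = means[["cyanidin_3_glucoside", "cyanidin_3_rutinoside"]].sum(axis=1)
        assert antho.between(14, 114).all()
        assert means["ascorbic_acid"].between(7, 15).all()

    def test_large_replicate_mean_recovers_cultivar_mean(self):
        # unit-mean lognormal replicate noise: law of large numbers
        cfg = px.SimulationConfig(
            n_cultivars=1, n_vintages=1, n_replicates=10_000,
            replicate_cv=0.1, vintage_shift_sd=0.0, seed=4,
        )
        t = px.generate_metabolite_table(cfg)
        mets = metabolite_columns(t)
        mu = cfg.resolved_means().iloc[0]
        rel = (t[mets].mean() - mu[mets]).abs() / mu[mets]
        assert (rel < 0.01).all()

    def test_determinism_under_seed(self):
        a = px.generate_metabolite_table(px.SimulationConfig(seed=9))
        b = px.generate_metabolite_table(px.SimulationConfig(seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            px.SimulationConfig(n_cultivars=0)


class TestResponses:
    def test_intercept_only(self, small_table):
        cfg = px.SimulationConfig(
            n_cultivars=4, seed=3, response_coefficients={}, synergy_terms=[],
            response_noise_sd=0.0, response_intercept=2.5,
        )
        r = px.generate_responses(small_table, cfg)
        assert (r["teac"] == 2.5).all()

    def test_additive_response_recovered_by_ols(self, small_table):
        cfg = px.SimulationConfig(
            n_cultivars=4, seed=3, synergy_terms=[], response_noise_sd=0.0,
        )
        r = px.generate_responses(small_table, cfg)
        mets = metabolite_columns(small_table)
        A = np.column_stack([np.ones(len(small_table)), small_table[mets].to_numpy()])
        coef, *_ = np.linalg.lstsq(A, r["teac"].to_numpy(), rcond=None)
        expected = [cfg.response_intercept] + [cfg.response_coefficients[m] for m in mets]
        np.testing.assert_allclose(coef, expected, atol=1e-8)

    def test_positive_interaction_exceeds_additive(self, small_table):
        base = px.SimulationConfig(n_cultivars=4, seed=3, synergy_terms=[],
                                   response_noise_sd=0.0)
        with_syn = px.SimulationConfig(
            n_cultivars=4, seed=3, response_noise_sd=0.0,
            synergy_terms=[("cyanidin_3_rutinoside", "ascorbic_acid", 0.01)],
        )
        r0 = px.generate_responses(small_table, base)["teac"]
        r1 = px.generate_responses(small_table, with_syn)["teac"]
        both_present = (
            (small_table["cyanidin_3_rutinoside"] > 0)
            & (small_table["ascorbic_acid"] > 0)
        ).to_numpy()
        assert (r1.to_numpy()[both_present] > r0.to_numpy()[both_present]).all()

    def test_unknown_coefficient_is_schema_error(self, small_table):
        cfg = px.SimulationConfig(
            n_cultivars=4, seed=3, response_coefficients={"unobtainium": 1.0},
        )
        with pytest.raises(SchemaError):
            px.generate_responses(small_table, cfg)


class TestFeatureMatrix:
    def test_isotope_ratio_exact_without_noise(self):
        means = pd.DataFrame({"chlorogenic_acid": [10.0]},
                             index=pd.Index(["cv01"], name="cultivar"))
        cfg = px.SimulationConfig(
            n_cultivars=1, n_vintages=1, n_replicates=2, cultivar_means=means,
            replicate_cv=0.0, vintage_shift_sd=0.0, n_noise_features=0,
            isotope_fraction=0.1, adduct_fraction=0.0,
            intensity_factor_sd=0.0, feature_noise_cv=0.0, seed=0,
        )
        t = px.generate_metabolite_table(cfg)
        fm = px.generate_feature_matrix(t, cfg)
        assert fm.values.shape[1] == 2
        mono = fm.values["chlorogenic_acid|M"]
        iso = fm.values["chlorogenic_acid|M+1"]
        np.testing.assert_allclose(mono / iso, 10.0)

    def test_normalization_recovers_intensity_factors(self):
        # injected lognormal per-sample factors are recovered (up to the
        # arbitrary global scale) by median fold change normalization
        cfg = px.SimulationConfig(seed=5, feature_noise_cv=0.01, noise_feature_cv=0.01)
        t = px.generate_metabolite_table(cfg)
        fm = px.generate_feature_matrix(t, cfg)
        _, fac, _ = px.median_fold_change_normalize(fm.values)
        rel = fac / fm.true_intensity_factors
        rel = rel / rel.median()
        assert float((rel - 1).abs().max()) < 0.01

    def test_noise_features_carry_no_cultivar_effect(self):
        from scipy import stats
        fstats = []
        for seed in range(5):
            cfg = px.SimulationConfig(n_cultivars=6, n_noise_features=30,
                                      intensity_factor_sd=0.0, seed=seed)
            t = px.generate_metabolite_table(cfg)
            fm = px.generate_feature_matrix(t, cfg)
            labels = t.set_index("sample_id")["cultivar"]
            for col in fm.values.columns:
                if not col.startswith("noise"):
                    continue
                groups = [g.to_numpy() for _, g in fm.values[col].groupby(labels)]
                fstats.append(stats.f_oneway(*groups).statistic)
        assert np.mean(fstats) == pytest.approx(1.0, abs=0.15)

    def test_cultivar_dominates_vintage_in_pca(self):
        cfg = px.SimulationConfig(seed=6)
        t = px.generate_metabolite_table(cfg)
        fm = px.generate_feature_matrix(t, cfg)
        norm, _, _ = px.median_fold_change_normalize(fm.values)
        mm = px.log_mean_center(norm)
        scores, _, _ = px.pca(mm.X, 4)
        sc = _silhouette(scores, t["cultivar"].to_numpy())
        sv = _silhouette(scores, t["vintage"].to_numpy())
        assert sc > sv


class TestAssayPlate:
    def test_round_trip_zero_noise(self, trolox_curve, protocol):
        true = {"s1": 15.0, "s2": 3.5, "s3": 0.0}
        plate = px.simulate_assay_plate(true, trolox_curve, protocol, noise_sd=0.0)
        for sid, teac in true.items():
            wells = plate[(plate["sample_id"] == sid)]
            r = px.teac_from_absorbance(wells["absorbance"].to_list(), trolox_curve, protocol)
            assert r.teac == pytest.approx(teac, abs=1e-10)

    def test_zero_teac_reads_blank(self, trolox_curve, protocol):
        plate = px.simulate_assay_plate({"s": 0.0}, trolox_curve, protocol, noise_sd=0.0)
        sample = plate[plate["role"] == "sample"]
        np.testing.assert_allclose(sample["absorbance"], trolox_curve.intercept)

    def test_negative_teac_rejected(self, trolox_curve, protocol):
        with pytest.raises(DomainError):
            px.simulate_assay_plate({"s": -1.0}, trolox_curve, protocol)

    def test_noise_propagation_matches_delta_method(self, trolox_curve, protocol):
        # sd of the triplicate-mean TEAC should be (noise/slope)*scale/sqrt(3)
        noise_sd = 0.005
        recovered = []
        for seed in range(1000):
            plate = px.simulate_assay_plate({"s": 10.0}, trolox_curve, protocol,
                                            noise_sd=noise_sd, seed=seed)
            wells = plate[plate["role"] == "sample"]
            r = px.teac_from_absorbance(wells["absorbance"].to_list(),
                                        trolox_curve, protocol)
            recovered.append(r.teac)
        recovered = np.asarray(recovered)
        predicted_sd = noise_sd / trolox_curve.slope * protocol.concentration_scale / np.sqrt(3)
        assert recovered.mean() == pytest.approx(10.0, rel=0.01)
        assert recovered.std() == pytest.approx(predicted_sd, rel=0.10)


def _silhouette(scores: np.ndarray, labels: np.ndarray) -> float:
    from scipy.spatial.distance import cdist

    D = cdist(scores, scores)
    vals = []
    for i in range(len(scores)):
        same = labels == labels[i]
        same[i] = False
        a = D[i, same].mean()
        b = min(D[i, labels == l].mean() for l in np.unique(labels) if l != labels[i])
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))
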