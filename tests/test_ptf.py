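"""Built-in pedotransfer functions, prediction and regression fitting."""

import numpy as np
import pytest

import soilptf as sp
from soilptf.exceptions import InputError, UnknownModelError
from soilptf.ptf import coefficient_sets_from_json, coefficient_sets_to_json


class TestBuiltinCollections:
    @pytest.mark.parametrize("provenance,count", [
        ("table4", 14), ("table5", 8), ("table6", 4),
    ])
    def test_row_counts(self, provenance, count):
        assert len(sp.builtin_models(provenance)) == count

    def test_main_collection_covers_every_antibiotic_both_responses(self):
        pairs = {(m.antibiotic, m.response) for m in sp.builtin_models("table4")}
        for code in sp.list_compounds():
            assert (code, "Kf") in pairs and (code, "Kd") in pairs

    def test_improved_collection_has_no_smt_model(self):
        assert not any(m.antibiotic == "SMT" for m in sp.builtin_models("table5"))

    def test_comparator_collection_antibiotics(self):
        assert [(m.antibiotic, m.response) for m in sp.builtin_models("table6")] == [
            ("SCP", "Kf"), ("SMT", "Kd"), ("SDZ", "Kf"), ("OTC", "Kf")]

    def test_unknown_provenance(self):
        with pytest.raises(UnknownModelError):
            sp.builtin_models("table7")

    @pytest.mark.parametrize("code,response,unit_sum", [
        ("SCP", "Kf", 5.129), ("SCP", "Kd", 3.748),
        ("SMT", "Kf", 1.638), ("SMT", "Kd", 0.888),
        ("SDZ", "Kf", 2.172), ("SDZ", "Kd", 0.205),
        ("SMX", "Kf", 4.595), ("SMX", "Kd", 3.270),
        ("OTC", "Kf", 4215.182), ("OTC", "Kd", 421.905),
        ("TC", "Kf", 2595.413), ("TC", "Kd", 284.921),
        ("CTC", "Kf", 3269.709), ("CTC", "Kd", 11.529),
    ])
    def test_unit_sum_guards_transcription(self, code, response, unit_sum):
        # hand-computed intercept + sum(coefficients) for every main model;
        # evaluating the stored set at unit predictors must match
        m = sp.get_builtin_model("table4", code, response)
        got = m.intercept + sum(c * 1.0 for c in m.terms.values())
        assert got == pytest.approx(unit_sum, abs=1e-9)


class TestPredict:
    def test_scp_intercept(self):
        m = sp.get_builtin_model("table4", "SCP", "Kf")
        pred = sp.predict(m, sp.SoilSample(pH=0.0, OC=0.0))
        assert pred.value == 4.198

    def test_smx_intercept_four_predictors(self):
        m = sp.get_builtin_model("table4", "SMX", "Kf")
        pred = sp.predict(m, sp.SoilSample(pH=0.0, OC=0.0, CEC=0.0, silt=0.0))
        assert pred.value == 4.717

    @pytest.mark.parametrize("code,response,soil,expected", [
        ("SCP", "Kf", dict(pH=1.0, OC=1.0), 4.198 + 1.666 - 0.735),
        ("SMX", "Kf", dict(pH=1.0, OC=1.0, CEC=1.0, silt=1.0),
         4.717 + 0.464 - 0.565 + 0.006 - 0.027),
        ("TC", "Kd", dict(pH=6.0, CEC=1.0, sand=1.0, clay=1.0),
         274.636 + 1.151 - 5.607 + 14.741),
    ])
    def test_frozen_worked_examples(self, code, response, soil, expected):
        m = sp.get_builtin_model("table4", code, response)
        pred = sp.predict(m, sp.SoilSample(**soil))
        assert pred.value == pytest.approx(expected, abs=1e-12)

    def test_negative_prediction_flagged_not_clamped(self):
        m = sp.get_builtin_model("table4", "CTC", "Kd")
        pred = sp.predict(m, sp.SoilSample(pH=6.0, OC=0.0, clay=0.0))
        assert pred.value == pytest.approx(-588.94)
        assert "negative_prediction" in pred.flags

    def test_extrapolation_flag(self):
        m = sp.get_builtin_model("table4", "SCP", "Kf")
        inside = sp.predict(m, sp.SoilSample(pH=6.0, OC=2.0))
        outside = sp.predict(m, sp.SoilSample(pH=10.5, OC=2.0))
        assert "extrapolation:pH" not in inside.flags
        assert "extrapolation:pH" in outside.flags

    def test_missing_predictor_named(self):
        m = sp.get_builtin_model("table4", "TC", "Kd")
        with pytest.raises(InputError, match="CEC"):
            sp.predict(m, sp.SoilSample(pH=6.0, sand=30.0, clay=30.0))

    def test_species_fraction_terms(self):
        # improved SCP Kd model: -1.149 + 1.657*OC + 183.089*alpha_plus
        m = sp.get_builtin_model("table5", "SCP", "Kd")
        soil = sp.SoilSample(pH=4.0, OC=2.0)
        alpha = sp.species_fractions("SCP", 4.0).alpha_plus
        pred = sp.predict(m, soil)
        assert pred.value == pytest.approx(-1.149 + 1.657 * 2.0 + 183.089 * alpha, rel=1e-12)

    def test_slr_and_cimax_conditions(self):
        m = sp.get_builtin_model("table5", "CTC", "Kf")
        soil = sp.SoilSample(pH=6.0, OC=1.0)
        pred = sp.predict(m, soil, conditions={"cimax": 10.0})
        assert pred.value == pytest.approx(-256.377 + 1219.651 + 6.639 * 10.0)
        with pytest.raises(InputError, match="Cimax"):
            sp.predict(m, soil)

    def test_published_otc_model_expects_cec_in_cmol(self):
        # 1/CEC term with CEC in cmol/kg: a soil at 100 mmol/kg enters as 10
        m = sp.get_builtin_model("table6", "OTC", "Kf")
        soil = sp.SoilSample(pH=6.0, OC=1.0, CEC=100.0)
        pred = sp.predict(m, soil)
        assert pred.value == pytest.approx(96.924 + 701.607 + 8118.902 / 10.0)

    def test_affine_in_edaphic_predictors(self):
        m = sp.get_builtin_model("table4", "SCP", "Kf")

        def f(oc, ph):
            return sp.predict(m, sp.SoilSample(pH=ph, OC=oc)).value

        assert f(1.5, 3.0) + f(2.5, 4.0) - f(0.0, 0.0) == pytest.approx(f(4.0, 7.0), abs=1e-9)

    def test_otc_kf_strictly_decreasing_in_ph(self):
        m = sp.get_builtin_model("table4", "OTC", "Kf")
        values = [sp.predict(m, sp.SoilSample(pH=p, OC=2.0)).value
                  for p in np.linspace(3.0, 9.0, 13)]
        assert all(b < a for a, b in zip(values, values[1:]))


class TestSerialization:
    def test_json_round_trip_bit_exact(self, tmp_path):
        models = (sp.builtin_models("table4") + sp.builtin_models("table5")
                  + sp.builtin_models("table6"))
        path = tmp_path / "models.json"
        coefficient_sets_to_json(models, path)
        back = coefficient_sets_from_json(path)
        assert back == models


def _records_from_model(model, soils, noise_sd=0.0, seed=0, conditions=None):
    rng = np.random.default_rng(seed)
    records = []
    for soil in soils:
        value = sp.predict(model, soil, conditions=conditions).value
        value += rng.normal(0.0, noise_sd) if noise_sd else 0.0
        records.append(sp.SorptionRecord(
            model.antibiotic, soil,
            Kf=value if model.response == "Kf" else None,
            n=1.2 if model.response == "Kf" else None,
            Kd=value if model.response == "Kd" else None,
        ))
    return records


class TestFitMlr:
    def test_exact_recovery_of_noise_free_coefficients(self, scp_kf_model, soils_50):
        records = _records_from_model(scp_kf_model, soils_50)
        fit = sp.fit_mlr(records, "Kf", ["OC", "pH"])
        assert fit.coefficients.intercept == pytest.approx(4.198, abs=1e-9)
        assert fit.coefficients.terms["OC"] == pytest.approx(1.666, abs=1e-9)
        assert fit.coefficients.terms["pH"] == pytest.approx(-0.735, abs=1e-9)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_response_identical_to_predictor(self, soils_50):
        records = [sp.SorptionRecord("SMT", s, Kf=s.OC, n=1.0) for s in soils_50]
        fit = sp.fit_mlr(records, "Kf", ["OC"])
        assert fit.coefficients.terms["OC"] == pytest.approx(1.0, abs=1e-10)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_predictor_columns_rejected(self, soils_50):
        # silt mirrors sand exactly -> rank-deficient design
        soils = [sp.SoilSample(pH=s.pH, OC=s.OC, sand=s.sand, silt=s.sand)
                 for s in soils_50]
        records = [sp.SorptionRecord("SMT", s, Kf=1.0 + s.OC, n=1.0) for s in soils]
        with pytest.raises(InputError, match="Sand|Silt"):
            sp.fit_mlr(records, "Kf", ["Sand", "Silt"])

    def test_constant_predictor_named(self, soils_50):
        soils = [sp.SoilSample(pH=s.pH, OC=s.OC, CEC=100.0) for s in soils_50]
        records = [sp.SorptionRecord("SMT", s, Kf=1.0 + s.OC, n=1.0) for s in soils]
        with pytest.raises(InputError, match="CEC"):
            sp.fit_mlr(records, "Kf", ["OC", "CEC"])

    def test_insufficient_records(self, soils_50):
        records = [sp.SorptionRecord("SMT", s, Kf=1.0, n=1.0) for s in soils_50[:3]]
        with pytest.raises(InputError, match="at least"):
            sp.fit_mlr(records, "Kf", ["OC", "pH"])

    def test_adjusted_r2_formula(self, scp_kf_model, soils_50):
        records = _records_from_model(scp_kf_model, soils_50, noise_sd=0.2, seed=42)
        fit = sp.fit_mlr(records, "Kf", ["OC", "pH"])
        # recompute adj r2 = 1 - (1-R2)(N-1)/(N-k-1) from scratch
        y = np.array([r.Kf for r in records])
        X = np.column_stack([np.ones(len(records)),
                             [r.soil.OC for r in records],
                             [r.soil.pH for r in records]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        n, k = len(y), 2
        assert fit.adj_r2 == pytest.approx(1 - (1 - r2) * (n - 1) / (n - k - 1), abs=1e-10)


class TestForwardSelect:
    def test_dominant_predictor_only(self, soils_50):
        rng = np.random.default_rng(7)
        records = [sp.SorptionRecord("SMT", s, Kf=0.82 + 0.818 * s.OC + rng.normal(0, 1e-6),
                                     n=1.0) for s in soils_50]
        fit = sp.forward_select(records, "Kf", ["OC", "Sand", "Silt", "Clay"])
        assert set(fit.coefficients.terms) == {"OC"}
        assert fit.coefficients.terms["OC"] == pytest.approx(0.818, abs=1e-4)

    def test_alpha_enter_zero_gives_intercept_only(self, soils_50):
        records = [sp.SorptionRecord("SMT", s, Kf=1.0 + s.OC, n=1.0) for s in soils_50]
        fit = sp.forward_select(records, "Kf", ["OC", "pH"], alpha_enter=0.0)
        assert fit.coefficient_p_values == {}
        assert fit.coefficients.intercept == pytest.approx(
            np.mean([r.Kf for r in records]))

    def test_two_true_predictors_recovered_within_2se(self, soils_50):
        rng = np.random.default_rng(123)
        records = [sp.SorptionRecord("SCP", s, Kf=4.198 + 1.666 * s.OC - 0.735 * s.pH
                                     + rng.normal(0, 0.2), n=1.2) for s in soils_50]
        fit = sp.forward_select(records, "Kf", ["OC", "pH", "Sand", "CEC"])
        assert {"OC", "pH"} <= set(fit.coefficients.terms)
        for name, truth in (("OC", 1.666), ("pH", -0.735)):
            lo, hi = fit.conf_int[name]
            assert lo <= truth <= hi
        assert fit.trace  # selection history recorded
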