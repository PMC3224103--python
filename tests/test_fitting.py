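"""SSR fitting engine, covariate parsimony, residual diagnostics."""

import numpy as np
import pytest

from washin import (
    DeliverySettings,
    NoUsableObservationsError,
    PatientCovariates,
    WashInModel,
    WashInRecord,
    fit_model,
    residual_diagnostics,
    select_covariates,
)
from washin.params import PRINTED_PARAMS
from washin.synthetic import NoiseModel, generate_cohort_records


def _record(times, fas, ht=170.0, fgf=2.0, dial=10.0, pid="p"):
    return WashInRecord(
        patient=PatientCovariates(height_cm=ht, weight_kg=70.0, age_years=50.0),
        settings=DeliverySettings(fgf=fgf, dial=dial),
        time_s=np.asarray(times, float), fa_pct=np.asarray(fas, float),
        patient_id=pid)


class TestExclusionFilters:
    def test_sub_minute_samples_excluded(self):
        rec = _record([50.0, 70.0], [0.8, 1.2])
        assert rec.n_usable() == 1  # only the 70-s sample survives

    def test_samples_above_8_percent_excluded(self):
        rec = _record([60.0, 70.0], [8.1, 7.9])
        assert rec.usable_mask().tolist() == [False, True]

    def test_record_with_too_few_usable_samples_is_not_fit(self):
        recs = [_record([30.0], [0.5], pid="a"),
                _record([40.0, 50.0], [0.5, 0.6], pid="b")]
        with pytest.raises(NoUsableObservationsError, match="no usable"):
            WashInModel(recs)

    def test_requires_two_records(self):
        with pytest.raises(ValueError, match="2 records"):
            WashInModel([_record([60, 120, 180], [1, 2, 3])])


class TestRecordValidation:
    def test_times_must_strictly_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            _record([60.0, 60.0], [1.0, 1.1])

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            _record([60.0, 70.0], [-0.1, 1.0])

    def test_samples_property_round_trips(self):
        rec = _record([60.0, 70.0], [1.0, 1.2])
        assert rec.samples == [(60.0, 1.0), (70.0, 1.2)]


class TestFit:
    def test_noiseless_self_consistency(self, noiseless_records):
        res = fit_model(noiseless_records, n_restarts=1)
        assert res.ssr < 1e-8
        for name in res.model.free:
            est = getattr(res.params, name)
            true = getattr(PRINTED_PARAMS, name)
            assert est == pytest.approx(true, rel=1e-4)

    def test_ssr_equals_sum_of_squared_residuals(self, noiseless_records):
        res = fit_model(noiseless_records, n_restarts=1)
        assert res.ssr == pytest.approx(float(res.residuals @ res.residuals),
                                        abs=1e-9)
        assert len(res.residuals) == res.n_obs

    def test_best_ssr_across_restarts_is_reported(self):
        recs = generate_cohort_records(n=6, noise=NoiseModel(sd=0.25), seed=3)
        res = fit_model(recs, n_restarts=4, seed=1)
        assert res.ssr == pytest.approx(min(res.restart_costs), rel=1e-12)

    def test_deterministic_given_seed(self):
        recs = generate_cohort_records(n=6, noise=NoiseModel(sd=0.25), seed=3)
        r1 = fit_model(recs, n_restarts=3, seed=7)
        r2 = fit_model(recs, n_restarts=3, seed=7)
        assert r1.ssr == r2.ssr and r1.params == r2.params

    def test_parameter_recovery_under_noise(self):
        """Median relative error of tau, k1, k2 stays below 10% (sd 0.25%)."""
        taus, k1s, k2s = [], [], []
        for seed in range(20):
            recs = generate_cohort_records(
                n=50, noise=NoiseModel(sd=0.25), seed=100 + seed)
            res = fit_model(recs, n_restarts=5, seed=seed)
            taus.append(res.params.tau)
            k1s.append(res.params.k1)
            k2s.append(res.params.k2)
        assert np.median(np.abs(np.array(taus) - 4.08) / 4.08) <= 0.10
        assert np.median(np.abs(np.array(k1s) - 0.23) / 0.23) <= 0.10
        assert np.median(np.abs(np.array(k2s) - 0.24) / 0.24) <= 0.10
        assert abs(np.mean(taus) / 4.08 - 1.0) <= 0.05  # tau bias

    def test_summary_lists_estimates(self, noiseless_records):
        res = fit_model(noiseless_records, n_restarts=1)
        text = res.summary()
        assert "tau" in text and "SSR" in text and "std err" in text


class TestCovariateSelection:
    def test_infinite_threshold_selects_nothing(self):
        recs = generate_cohort_records(n=6, noise=NoiseModel(sd=0.25), seed=3)
        rep = select_covariates(recs, threshold=np.inf, n_restarts=1)
        assert rep.selected == []

    def test_height_detected_with_inverse_power(self):
        recs = generate_cohort_records(n=12, noise=NoiseModel(sd=0.25), seed=5)
        rep = select_covariates(recs, n_restarts=2)
        height = rep.entries["height"]
        assert height.selected
        # the model's height effect is 1/Ht, i.e. power -1
        assert height.theta == pytest.approx(-1.0, abs=0.2)

    def test_per_candidate_failures_do_not_abort(self):
        recs = [
            WashInRecord(
                patient=PatientCovariates(height_cm=165.0 + i),
                settings=DeliverySettings(fgf=2.0, dial=10.0),
                time_s=np.array([60.0, 120.0, 180.0]),
                fa_pct=np.array([1.5, 2.5, 3.0]),
                patient_id=f"p{i}")
            for i in range(3)
        ]  # age and weight missing
        rep = select_covariates(recs, n_restarts=1)
        assert rep.entries["age"].error is not None
        assert rep.entries["weight"].error is not None
        assert rep.entries["height"].delta_objective is not None


class TestResidualDiagnostics:
    def test_zero_residuals_have_zero_r2(self, noiseless_records):
        res = fit_model(noiseless_records, n_restarts=1)
        diag = residual_diagnostics(res)
        for slope, r2 in diag.values():
            assert r2 == pytest.approx(0.0, abs=1e-6)

    def test_residuals_equal_to_height_have_unit_r2(self, noiseless_records):
        res = fit_model(noiseless_records, n_restarts=1)
        idx = res.model.data.record_index
        heights = np.array([noiseless_records[i].patient.height_cm
                            for i in idx])
        res.residuals = heights
        diag = residual_diagnostics(res)
        assert diag["height"][1] == pytest.approx(1.0, abs=1e-12)

    def test_constant_covariate_warns_and_reports_zero(self):
        recs = [_record([60, 120, 180], [1.4, 2.4, 2.9], ht=166.0, pid="a",
                        fgf=1.5),
                _record([60, 120, 180], [1.5, 2.5, 3.0], ht=166.0, pid="b")]
        res = fit_model(recs, n_restarts=1)
        with pytest.warns(UserWarning, match="constant"):
            diag = residual_diagnostics(res)
        assert diag["height"] == (0.0, 0.0)

    def test_height_covariate_model_leaves_no_height_structure(self):
        recs = generate_cohort_records(n=20, noise=NoiseModel(sd=0.25), seed=9)
        res = fit_model(recs, n_restarts=3, seed=0)
        diag = residual_diagnostics(res)
        assert diag["height"][1] <= 0.05
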