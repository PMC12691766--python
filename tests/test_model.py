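"""Monte Carlo EDI simulation: arithmetic, invariances, sampling modes."""

import math

import numpy as np
import pytest

from cpexposure.data import ConsumptionRecord
from cpexposure.distributions import FittedDistribution, point_mass
from cpexposure.model import (
    ExposureConfig,
    ExposureModel,
    simulate_edi,
    summarize_exposure,
)

LN = lambda mu, sigma: FittedDistribution("lognormal", {"mu": mu, "sigma": sigma}, (0.0, np.inf))


def cfg(n=1000, seed=0, **kw):
    return ExposureConfig(n_iterations=n, seed=seed, **kw)


class TestSimulateEdi:
    def test_single_oil_point_masses(self):
        res = simulate_edi(
            {"peanut": point_mass(30.0)}, {"peanut": point_mass(100.0)},
            point_mass(60.0), cfg(100),
        )
        assert np.all(res.draws == 50.0)  # 30 g/d * 100 ng/g / 60 kg

    def test_two_oils_additive_point_masses(self):
        res = simulate_edi(
            {"a": point_mass(30.0), "b": point_mass(10.0)},
            {"a": point_mass(100.0), "b": point_mass(60.0)},
            point_mass(60.0), cfg(100),
        )
        assert np.all(res.draws == 60.0)

    def test_lognormal_consumption_matches_closed_form_mean(self):
        mu, sigma, c, bw, n = 3.0, 0.6, 100.0, 60.0, 10_000
        res = simulate_edi(
            {"corn": LN(mu, sigma)}, {"corn": point_mass(c)}, point_mass(bw), cfg(n, seed=2)
        )
        expected = math.exp(mu + sigma**2 / 2) * c / bw
        var = (math.exp(sigma**2) - 1) * math.exp(2 * mu + sigma**2) * (c / bw) ** 2
        se = math.sqrt(var / n)
        assert abs(res.mean - expected) < 3 * se

    def test_missing_concentration_model_rejected_before_sampling(self):
        with pytest.raises(ValueError, match="sesame"):
            simulate_edi(
                {"sesame": point_mass(1.0)}, {}, point_mass(60.0), cfg(10)
            )


class TestInvariants:
    def setup_method(self):
        self.consumption = {"a": LN(3.0, 0.5), "b": LN(2.0, 0.7)}
        self.concentration = {"a": LN(4.0, 0.6), "b": LN(4.5, 0.4)}
        self.bw = LN(math.log(60.0), 0.15)

    def test_concentration_scaling_is_linear(self):
        base = simulate_edi(self.consumption, self.concentration, self.bw, cfg(2000, 7))
        scaled_models = {
            oil: FittedDistribution(
                "lognormal",
                {"mu": d.params["mu"] + math.log(3.0), "sigma": d.params["sigma"]},
                d.support,
            )
            for oil, d in self.concentration.items()
        }
        scaled = simulate_edi(self.consumption, scaled_models, self.bw, cfg(2000, 7))
        np.testing.assert_allclose(scaled.draws, 3.0 * base.draws, rtol=1e-10)

    def test_doubling_constant_bodyweight_halves_draws(self):
        r60 = simulate_edi(self.consumption, self.concentration, point_mass(60.0), cfg(2000, 7))
        r120 = simulate_edi(self.consumption, self.concentration, point_mass(120.0), cfg(2000, 7))
        np.testing.assert_allclose(r120.draws, r60.draws / 2.0, rtol=1e-12)

    def test_additivity_over_oils_under_shared_streams(self):
        both = simulate_edi(self.consumption, self.concentration, self.bw, cfg(2000, 7))
        only_a = simulate_edi(
            {"a": self.consumption["a"]}, {"a": self.concentration["a"]}, self.bw, cfg(2000, 7)
        )
        only_b = simulate_edi(
            {"b": self.consumption["b"]}, {"b": self.concentration["b"]}, self.bw, cfg(2000, 7)
        )
        np.testing.assert_allclose(both.draws, only_a.draws + only_b.draws, rtol=1e-10)

    def test_identical_seed_bit_identical(self):
        r1 = simulate_edi(self.consumption, self.concentration, self.bw, cfg(500, 9))
        r2 = simulate_edi(self.consumption, self.concentration, self.bw, cfg(500, 9))
        np.testing.assert_array_equal(r1.draws, r2.draws)
        for key in r1.input_draws:
            np.testing.assert_array_equal(r1.input_draws[key], r2.input_draws[key])


class TestSummarizeExposure:
    def test_constant_draws(self):
        res = simulate_edi(
            {"a": point_mass(30.0)}, {"a": point_mass(100.0)}, point_mass(60.0), cfg(50)
        )
        s = summarize_exposure(res)
        assert s.mean == s.median == s.p95 == 50.0

    def test_order_statistics_match_sort_oracle(self):
        draws = np.arange(1.0, 10_001.0)
        res = simulate_edi(
            {"a": point_mass(1.0)}, {"a": point_mass(1.0)}, point_mass(1.0), cfg(10_000)
        )
        object.__setattr__(res, "draws", draws)
        s = summarize_exposure(res, percentiles=(50, 95))
        assert s.median == np.percentile(draws, 50)
        assert s.p95 == np.percentile(draws, 95)

    def test_right_skewed_draws_mean_exceeds_median(self):
        res = simulate_edi(
            {"a": LN(3.0, 0.8)}, {"a": point_mass(100.0)}, point_mass(60.0), cfg(5000, 3)
        )
        s = summarize_exposure(res)
        assert s.mean > s.median


class TestBootstrapPairedMode:
    def make_records(self):
        recs = []
        for i, (intake, bw) in enumerate([(10.0, 50.0), (20.0, 60.0), (30.0, 80.0)]):
            recs.append(
                ConsumptionRecord(f"i{i}", "corn", intake, bw, "F", 30.0)
            )
        return recs

    def test_pairing_preserved(self):
        recs = self.make_records()
        res = simulate_edi(
            {"corn": point_mass(0.0)},  # unused in paired mode for intake
            {"corn": point_mass(100.0)},
            recs,
            cfg(1000, seed=4, mode="bootstrap_paired"),
        )
        # with constant concentration, every draw must equal 100*intake/bw of
        # one actual individual — never a mixed pairing
        valid = {100.0 * i / b for i, b in [(10.0, 50.0), (20.0, 60.0), (30.0, 80.0)]}
        assert set(np.round(res.draws, 9)) <= {round(v, 9) for v in valid}

    def test_requires_records(self):
        with pytest.raises(TypeError):
            simulate_edi(
                {"corn": point_mass(1.0)}, {"corn": point_mass(1.0)},
                point_mass(60.0), cfg(10, mode="bootstrap_paired"),
            )


class TestExposureModelResults:
    def make_model(self):
        return ExposureModel(
            {"corn": LN(3.0, 0.5)},
            {"SCCP": {"corn": LN(4.5, 0.5)}, "MCCP": {"corn": LN(4.8, 0.5)}},
            bodyweight_model=LN(math.log(60.0), 0.15),
        )

    def test_fit_returns_per_analyte_results(self):
        results = self.make_model().fit(cfg(2000, 1))
        assert results.analytes == ["MCCP", "SCCP"]
        frame = results.summary_frame()
        assert set(frame.columns) >= {"mean", "median", "p95"}

    def test_moe_consistent_with_edi(self):
        results = self.make_model().fit(cfg(2000, 1))
        for row in results.moe():
            bmdl = results.model.analytes[row.analyte].bmdl10
            assert row.moe == pytest.approx(bmdl * 1e6 / row.edi)

    def test_sensitivity_groups_cover_all_inputs(self):
        results = self.make_model().fit(cfg(2000, 1))
        sens = results.sensitivity("SCCP")
        assert set(sens.contributions) == {"consumption", "concentration", "bodyweight"}
        total = sum(sens.contributions.values()) + sens.residual
        assert total == pytest.approx(100.0, abs=1e-6)

    def test_summary_text_mentions_all_analytes(self):
        text = self.make_model().fit(cfg(500, 1)).summary()
        assert "SCCP" in text and "MCCP" in text and "MOE" in text

    def test_from_records_rejects_unsubstituted_censored(self):
        from cpexposure.data import ConcentrationRecord

        survey = [
            ConsumptionRecord(f"i{k}", "corn", float(k + 1), 60.0, "F", 30.0)
            for k in range(15)
        ]
        conc = [
            ConcentrationRecord(f"s{k}", "corn", "SCCP", None, True, 32.0)
            for k in range(15)
        ]
        with pytest.raises(ValueError, match="substitute_censored"):
            ExposureModel.from_records(survey, conc)
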