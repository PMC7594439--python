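import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehsra import (
    CalibrationWarning,
    IndexSpec,
    InputError,
    RiskBand,
    ThermalSample,
    aggregate_repeats,
    classify_risk,
    compute_ehsra,
    hrmax,
    hrmax_screen,
    normalize,
    tympanic_screen,
)
from ehsra.core_index import VARIABLES, score_frame

MINIMA = (21.97, 12.10, 23.40, 0.0, 130.0, 0.50)
MAXIMA = (48.20, 37.57, 62.70, 4.20, 490.0, 1.35)  # minima + normalization ranges


def sample_from(values, **kw) -> ThermalSample:
    return ThermalSample(**dict(zip(VARIABLES, values)), **kw)


def reasonable_sample(rng: np.random.Generator) -> ThermalSample:
    lo, hi = np.array(MINIMA), np.array(MAXIMA)
    return sample_from(rng.uniform(lo, hi))


class TestThermalSample:
    def test_negative_air_velocity_rejected(self):
        with pytest.raises(InputError, match="v_air"):
            sample_from((30, 20, 40, -0.1, 300, 0.8))

    @pytest.mark.parametrize("field,value", [("metabolism", 0.0), ("clo", -1.0)])
    def test_nonpositive_workload_rejected(self, field, value):
        values = dict(zip(VARIABLES, (30, 20, 40, 1.0, 300, 0.8)))
        values[field] = value
        with pytest.raises(InputError, match=field):
            ThermalSample(**values)

    def test_dry_above_globe_warns_but_accepts(self):
        with pytest.warns(CalibrationWarning, match="globe"):
            s = sample_from((45, 20, 40, 1.0, 300, 0.8))
        assert s.t_dry == 45


class TestIndexSpec:
    def test_defaults_match_published_constants(self, default_spec):
        assert default_spec.coefficients == (0.752, 0.686, 0.774, 0.244, 0.491, 0.387)
        assert default_spec.norm_min == (21.97, 12.10, 23.40, 0.0, 130.0, 0.50)
        assert default_spec.norm_range == (26.23, 25.47, 39.30, 4.20, 360.0, 0.85)
        assert default_spec.scale_factor == 10.0
        assert default_spec.skin_temp_threshold == 35.0

    def test_shipped_json_equals_defaults(self, default_spec):
        assert IndexSpec.default() == default_spec

    def test_json_round_trip(self, tmp_path, default_spec):
        path = tmp_path / "spec.json"
        default_spec.to_json(path)
        assert IndexSpec.from_json(path) == default_spec

    def test_bands_must_increase(self):
        with pytest.raises(InputError, match="increasing"):
            IndexSpec(bands=(RiskBand("a", -math.inf), RiskBand("b", 5.0),
                             RiskBand("c", 4.0)))

    def test_nonpositive_range_rejected(self):
        with pytest.raises(InputError, match="positive"):
            IndexSpec(norm_range=(26.23, 25.47, 0.0, 4.20, 360.0, 0.85))


class TestNormalize:
    def test_minimum_maps_to_zero(self, default_spec):
        normed = normalize(sample_from((21.97, 20, 40, 1.0, 300, 0.8)), default_spec)
        assert normed[0] == 0.0

    def test_range_maximum_maps_to_one(self, default_spec):
        # published measured maximum of dry temperature; denominator 26.23
        normed = normalize(sample_from((48.20, 20, 40, 1.0, 300, 0.8)), default_spec)
        assert normed[0] == pytest.approx(1.0)

    def test_globe_hand_value(self, default_spec):
        normed = normalize(sample_from((30, 20, 40.0, 1.0, 300, 0.8)), default_spec)
        assert normed[2] == pytest.approx(16.60 / 39.30, abs=1e-12)
        assert normed[2] == pytest.approx(0.42239, abs=5e-6)

    def test_out_of_range_warns_not_clips(self, default_spec):
        with pytest.warns(CalibrationWarning, match="t_wet"):
            normed = normalize(sample_from((30, 40.0, 42, 1.0, 300, 0.8)), default_spec)
        assert normed[1] > 1.0

    def test_non_finite_rejected_naming_field(self, default_spec):
        with pytest.raises(InputError, match="t_globe"):
            normalize(sample_from((30, 20, math.nan, 1.0, 300, 0.8)), default_spec)


class TestComputeEhsra:
    def test_all_minima_is_zero(self, default_spec):
        assert compute_ehsra(sample_from(MINIMA), default_spec) == 0.0

    def test_all_maxima_is_coefficient_sum(self, default_spec):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CalibrationWarning)
            score = compute_ehsra(sample_from(MAXIMA), default_spec)
        assert score == pytest.approx(10 * sum(default_spec.coefficients), abs=1e-12)
        assert round(score, 2) == 33.34

    def test_mid_example_with_negative_air_term(self, default_spec):
        score = compute_ehsra(sample_from((30, 20, 40, 1.0, 300, 0.8)), default_spec)
        assert score == pytest.approx(10.80, abs=0.01)

    def test_air_sign_positive_at_threshold(self, default_spec):
        below = compute_ehsra(sample_from((34.999, 20, 40, 2.0, 300, 0.8)), default_spec)
        at = compute_ehsra(sample_from((35.0, 20, 40, 2.0, 300, 0.8)), default_spec)
        # crossing the threshold flips the air term from -|t| to +|t|
        air_term = 10 * 0.244 * (2.0 / 4.20)
        assert at - below == pytest.approx(2 * air_term, abs=1e-3)

    def test_term_by_term_oracle(self, rng, default_spec):
        spec = default_spec
        for _ in range(1000):
            s = reasonable_sample(rng)
            expected = 0.0
            for i, name in enumerate(VARIABLES):
                c = spec.coefficients[i]
                if name == "v_air" and s.t_dry < spec.skin_temp_threshold:
                    c = -c
                expected += c * (getattr(s, name) - spec.norm_min[i]) / spec.norm_range[i]
            expected *= spec.scale_factor
            assert compute_ehsra(s, spec) == pytest.approx(expected, abs=1e-12)

    def test_monotone_directions(self, rng, default_spec):
        """Direction of the score in each variable, including the air-sign switch."""
        eps = {"t_dry": 1e-4, "t_wet": 1e-4, "t_globe": 1e-4,
               "v_air": 1e-4, "metabolism": 1e-2, "clo": 1e-4}
        for _ in range(400):
            s = reasonable_sample(rng)
            base = compute_ehsra(s, default_spec)
            for name in VARIABLES:
                if name == "t_dry" and abs(s.t_dry - 35.0) < 1e-3:
                    continue  # not monotone across the switch point itself
                values = dict(zip(VARIABLES, s.values()))
                values[name] += eps[name]
                bumped = compute_ehsra(ThermalSample(**values), default_spec)
                if name == "v_air" and s.t_dry < 35.0:
                    assert bumped < base
                else:
                    assert bumped > base


class TestClassifyRisk:
    @pytest.mark.parametrize(
        "score,label",
        [
            (10.0, "Low"),
            (12.01, "Low"),
            (12.02, "Moderate"),
            (15.87, "Moderate"),
            (15.879, "Moderate"),
            (15.88, "High"),
            (16.0, "High"),
            (17.56, "High"),
            (17.561, "Very high"),
            (18.0, "Very high"),
            (-5.0, "Low"),
        ],
    )
    def test_published_bands(self, score, label, default_spec):
        assert classify_risk(score, default_spec) == label

    def test_total_and_order_preserving(self, default_spec):
        order = [b.label for b in default_spec.bands]
        scores = np.linspace(-5, 40, 2001)
        labels = [classify_risk(s, default_spec) for s in scores]
        ranks = [order.index(l) for l in labels]
        assert ranks == sorted(ranks)

    def test_non_finite_rejected(self, default_spec):
        with pytest.raises(InputError):
            classify_risk(math.nan, default_spec)

    @given(st.floats(min_value=-100, max_value=100, allow_nan=False))
    def test_every_score_gets_a_band(self, score):
        assert classify_risk(score) in {"Low", "Moderate", "High", "Very high"}


class TestScreening:
    def test_hrmax_formula(self):
        assert hrmax(40) == pytest.approx(180.0)
        assert hrmax(20) == pytest.approx(194.0)
        assert hrmax(0) == 208.0

    def test_pass_at_exact_limit(self):
        assert hrmax_screen(40, 180.0)  # not strictly greater -> pass

    def test_fail_above_limit(self):
        assert not hrmax_screen(20, 195.0)

    def test_tympanic_screen(self):
        assert tympanic_screen(39.0)
        assert not tympanic_screen(39.2)


class TestAggregateRepeats:
    def test_thermal_mean_physio_max(self):
        s = aggregate_repeats(
            thermal={"t_dry": (30, 32, 34), "t_wet": (20,), "t_globe": (40,),
                     "v_air": (1.0,), "metabolism": (300,), "clo": (0.8,)},
            physio={"tympanic": (37.2, 37.6, 37.5), "heart_rate": (110, 130, 120)},
        )
        assert s.t_dry == 32.0
        assert s.tympanic == 37.6
        assert s.heart_rate == 130

    def test_single_repeat_identity(self):
        s = aggregate_repeats(
            thermal={v: (x,) for v, x in zip(VARIABLES, (30, 20, 40, 1.0, 300, 0.8))},
            physio={"tympanic": (37.5,)},
        )
        assert s.values() == (30, 20, 40, 1.0, 300, 0.8)
        assert s.tympanic == 37.5

    def test_empty_repeats_error(self):
        thermal = {v: (x,) for v, x in zip(VARIABLES, (30, 20, 40, 1.0, 300, 0.8))}
        thermal["t_dry"] = ()
        with pytest.raises(InputError, match="t_dry"):
            aggregate_repeats(thermal=thermal)

    def test_missing_variable_error(self):
        with pytest.raises(InputError, match="t_globe"):
            aggregate_repeats(thermal={"t_dry": (30,)})


class TestScoreFrame:
    def test_matches_scalar_path(self, scored_cohort, default_spec):
        # the raw MVN cohort can have (physically invalid) tail values that the
        # record-level constructor rejects; compare on the valid subset
        valid = (
            (scored_cohort["v_air"] >= 0)
            & (scored_cohort["metabolism"] > 0)
            & (scored_cohort["clo"] > 0)
        )
        rows = scored_cohort[valid].head(50)
        for _, row in rows.iterrows():
            s = ThermalSample(**{v: row[v] for v in VARIABLES})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", CalibrationWarning)
                assert row["ehsra_score"] == pytest.approx(
                    compute_ehsra(s, default_spec), abs=1e-12)

    def test_missing_column_error(self, scored_cohort):
        with pytest.raises(InputError, match="t_globe"):
            score_frame(scored_cohort.drop(columns=["t_globe"]))
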