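"""Reference study construction, synthetic generators and calibration."""

import math

import numpy as np
import pytest
import yaml

from t2dmcea.cea import WHO_CHOICE_1X_GDP, WHO_CHOICE_3X_GDP, analyze
from t2dmcea.config import ParameterDistribution
from t2dmcea.outcomes import evaluate_strategy
from t2dmcea.study import (
    CalibrationError,
    PACKAGED_DEFAULTS,
    StudyDefaults,
    apply_parameters,
    build_reference_model,
    calibrate_defaults,
    default_pattern,
    generate_mortality_schedule,
    generate_psa_spec,
    packaged_config_path,
    packaged_life_table_path,
    parameter_names,
)


class TestReferenceModel:
    def test_strategy_costs(self, reference_inputs):
        costs = {s.name: s.annual_treatment_cost for s in reference_inputs.strategies}
        assert costs == {
            "metformin_only": 70.0,
            "metformin_glibenclamide": 75.0,
            "metformin_saxagliptin": 309.0,
        }
        assert all(s.uncontrolled_treatment_cost == 208.0 for s in reference_inputs.strategies)

    def test_event_rewards(self, reference_inputs):
        for s in reference_inputs.strategies:
            assert s.event.event_cost == 228.0
            assert s.event.event_disutility == 0.13

    def test_progression_probabilities_and_disutilities(self, reference_inputs):
        p = {s.name: s.p_complication_controlled for s in reference_inputs.strategies}
        assert p == {
            "metformin_only": 0.122,
            "metformin_glibenclamide": 0.053,
            "metformin_saxagliptin": 0.013,
        }
        for s in reference_inputs.strategies:
            assert s.p_complication_uncontrolled == 0.4
            assert s.disutility_uncomplicated == 0.220
            assert s.disutility_complicated == 0.274
            assert s.disutility_death == 1.0

    def test_spec_structure(self, reference_inputs):
        spec = reference_inputs.spec
        assert (spec.start_age, spec.n_cycles) == (40, 40)
        assert spec.discount_rate_cost == spec.discount_rate_effect == 0.03
        assert spec.half_cycle_correction

    def test_single_cycle_override(self):
        inputs = build_reference_model(n_cycles=1)
        assert inputs.spec.n_cycles == 1
        res, _ = evaluate_strategy(
            inputs.strategy("metformin_glibenclamide"), inputs.spec, inputs.mortality
        )
        assert res.expected_cost > 0


class TestMortalityGenerator:
    def test_zero_level_is_zero(self):
        d = StudyDefaults({}, gompertz_background=(0.0, 0.07), t2dm_excess=(0.0, 0.1))
        sched = generate_mortality_schedule(d, range(40, 81))
        assert all(q == 0.0 for q in sched.q_background)
        assert all(q == 0.0 for q in sched.q_t2dm_complicated)

    def test_closed_form_at_baseline_age(self):
        d = StudyDefaults({}, gompertz_background=(0.01, 0.07), t2dm_excess=(0.02, 0.05))
        sched = generate_mortality_schedule(d, range(40, 81))
        assert sched.q_background[0] == pytest.approx(1 - math.exp(-0.01))
        assert sched.q_t2dm_complicated[0] == pytest.approx(1 - math.exp(-0.02))

    def test_monotone_nondecreasing_for_positive_slope(self):
        sched = generate_mortality_schedule(PACKAGED_DEFAULTS, range(40, 81))
        assert np.all(np.diff(sched.q_background) >= 0)
        assert np.all(np.diff(sched.q_t2dm_complicated) >= 0)
        assert max(sched.q_background) <= 1.0


@pytest.fixture(scope="module")
def spec_rows():
    return {d.name: d for d in generate_psa_spec()}


class TestPSASpec:
    def test_saxagliptin_cost_row(self, spec_rows):
        d = spec_rows["cost_metformin_saxagliptin"]
        assert (d.family, d.mean, d.sd) == ("gamma", 309.0, 30.9)

    def test_glibenclamide_progression_row(self, spec_rows):
        d = spec_rows["p_progression_glibenclamide"]
        assert (d.family, d.mean, d.sd) == ("beta", 0.053, 0.01)

    def test_event_decrement_fixed(self, spec_rows):
        d = spec_rows["event_disutility"]
        assert (d.family, d.mean) == ("fixed", 0.13)

    def test_cost_rows_gamma_probability_rows_beta(self, spec_rows):
        for name, d in spec_rows.items():
            if name.startswith("cost_"):
                assert d.family == "gamma"
            elif name.startswith(("p_", "disutility")):
                assert d.family == "beta"

    def test_every_distribution_maps_to_a_parameter(self, spec_rows):
        assert set(spec_rows) <= set(parameter_names())


class TestApplyParameters:
    def test_roundtrip_identity(self, reference_inputs):
        same = apply_parameters(reference_inputs, {})
        assert same is reference_inputs

    def test_sets_strategy_cost(self, reference_inputs):
        out = apply_parameters(reference_inputs, {"cost_metformin_saxagliptin": 250.0})
        assert out.strategy("metformin_saxagliptin").annual_treatment_cost == 250.0
        # base inputs untouched
        assert reference_inputs.strategy("metformin_saxagliptin").annual_treatment_cost == 309.0

    def test_shared_parameters_hit_every_arm(self, reference_inputs):
        out = apply_parameters(reference_inputs, {"cost_metformin_insulin": 300.0})
        assert all(s.uncontrolled_treatment_cost == 300.0 for s in out.strategies)

    def test_unknown_name_raises(self, reference_inputs):
        with pytest.raises(KeyError):
            apply_parameters(reference_inputs, {"nope": 1.0})


class TestCalibration:
    def test_packaged_defaults_satisfy_pattern(self, reference_fit):
        checks = default_pattern(reference_fit.table)
        assert all(ok for _, ok in checks), [name for name, ok in checks if not ok]

    def test_packaged_defaults_reproduce_published_orderings(self, reference_fit):
        t = reference_fit.table.set_index("strategy")
        assert (
            t.loc["metformin_saxagliptin", "cost"]
            > t.loc["metformin_only", "cost"]
            > t.loc["metformin_glibenclamide", "cost"]
        )
        assert (
            t.loc["metformin_saxagliptin", "dalys"]
            < t.loc["metformin_glibenclamide", "dalys"]
            < t.loc["metformin_only", "dalys"]
        )

    def test_calibration_is_stable_and_matches_packaged(self):
        best1, log1 = calibrate_defaults()
        best2, _ = calibrate_defaults()
        assert best1 == best2 == PACKAGED_DEFAULTS
        assert any("selected" in line for line in log1)

    def test_degenerate_failing_grid_raises(self):
        bad = StudyDefaults(
            failure_probabilities={
                "metformin_only": 0.0,
                "metformin_glibenclamide": 0.0,
                "metformin_saxagliptin": 0.0,
            },
            gompertz_background=(0.0, 0.0),
            t2dm_excess=(0.0, 0.0),
        )
        with pytest.raises(CalibrationError):
            calibrate_defaults(grid=[bad])

    def test_empty_pattern_selects_deterministically(self):
        """With no pattern conditions every point qualifies and the
        nearest-anchor score decides; a single-point grid returns that point."""
        grid = [PACKAGED_DEFAULTS]
        best, _ = calibrate_defaults(pattern=lambda table: [], grid=grid)
        assert best == grid[0]
        again, _ = calibrate_defaults(pattern=lambda table: [], grid=grid)
        assert again == best


class TestPackagedConfig:
    def test_loads_and_matches_builder(self, reference_inputs):
        from t2dmcea.config import load_model

        loaded = load_model(packaged_config_path())
        assert loaded.strategies == reference_inputs.strategies
        assert loaded.spec == reference_inputs.spec
        assert loaded.mortality == reference_inputs.mortality
        assert loaded.distributions == reference_inputs.distributions

    def test_table_constants_appear_exactly_once(self):
        """Audit: each published unit cost / probability is a single source of
        truth in the packaged config (no duplicated magic numbers)."""
        doc = yaml.safe_load(packaged_config_path().read_text())
        flat = []

        def walk(x):
            if isinstance(x, dict):
                for v in x.values():
                    walk(v)
            elif isinstance(x, list):
                for v in x.items() if isinstance(x, dict) else x:
                    walk(v)
            elif isinstance(x, (int, float)) and not isinstance(x, bool):
                flat.append(float(x))

        walk({k: v for k, v in doc.items() if k != "distributions"})
        for constant in (70.0, 75.0, 309.0, 228.0, 0.122, 0.053, 0.013, 0.274, 0.220, 0.13):
            assert flat.count(constant) == 1, constant
        # insulin cost is shared by the three arms by construction
        assert flat.count(208.0) == 3

    def test_life_table_covers_horizon(self):
        from t2dmcea.config import load_life_table

        sched = load_life_table(packaged_life_table_path())
        assert sched.covers(40, 40)
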