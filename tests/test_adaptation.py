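"""Ability updates, difficulty control, recommendation, and the selection loop."""

import json

import pytest
from hypothesis import given, settings, strategies as st

from prltrain import (
    AbilityModel,
    ConfigError,
    DomainError,
    ExerciseResponder,
    adjust_difficulty,
    catalogue,
    check_compliance,
    difficulty_index,
    exercises_only,
    make_patient,
    recommend_next,
    rolling_success,
    run_selection_loop,
    update_ability,
)
from prltrain.exercises import ExerciseResult, spec_by_id


def result_for(spec, hits, misses, timestamp=0.0, rts=()):
    return ExerciseResult(
        spec_id=spec.id, version=spec.version, hits=hits, misses=misses,
        false_alarms=0, attempts=hits + misses, reaction_times_s=tuple(rts),
        timestamp=timestamp,
    )


class TestDifficultyIndex:
    def test_bounded(self):
        for version in ("initial", "revised"):
            for spec in catalogue(version):
                assert 0.0 <= difficulty_index(spec) <= 1.0

    def test_decreasing_in_size_and_interval(self):
        import dataclasses

        spec = spec_by_id("revised", 2)
        bigger = dataclasses.replace(
            spec, params=dataclasses.replace(spec.params, stimulus_size_cm=3.0)
        )
        slower = dataclasses.replace(
            spec, params=dataclasses.replace(spec.params, inter_stimulus_s=8.0)
        )
        assert difficulty_index(bigger) < difficulty_index(spec)
        assert difficulty_index(slower) < difficulty_index(spec)

    def test_increasing_in_complexity_rank(self):
        d = [difficulty_index(spec_by_id("revised", i)) for i in (2, 3, 4, 5)]
        assert d == sorted(d) and len(set(d)) == 4


class TestUpdateAbility:
    def test_closed_form_ewma(self):
        spec = spec_by_id("revised", 2)
        model = AbilityModel(abilities={s: 0.4 for s in spec.skill_requirements})
        out = update_ability(model, result_for(spec, 8, 2), spec,
                             {"recommender": {"alpha": 0.5}})
        for skill in spec.skill_requirements:
            assert out.abilities[skill] == pytest.approx(0.5 * 0.4 + 0.5 * 0.8)

    def test_perfect_session_raises_every_touched_skill(self):
        spec = spec_by_id("revised", 2)
        model = AbilityModel(abilities={s: 0.5 for s in spec.skill_requirements})
        out = update_ability(model, result_for(spec, 5, 0), spec)
        for skill in spec.skill_requirements:
            assert out.abilities[skill] > 0.5

    def test_all_miss_session_lowers_every_touched_skill(self):
        spec = spec_by_id("revised", 2)
        model = AbilityModel(abilities={s: 0.5 for s in spec.skill_requirements})
        out = update_ability(model, result_for(spec, 0, 5), spec)
        for skill in spec.skill_requirements:
            assert out.abilities[skill] < 0.5

    def test_mismatched_spec_rejected(self):
        with pytest.raises(DomainError):
            update_ability(AbilityModel(), result_for(spec_by_id("revised", 2), 1, 1),
                           spec_by_id("revised", 3))

    def test_reaction_time_running_mean(self):
        spec = spec_by_id("revised", 2)
        model = AbilityModel()
        model = update_ability(model, result_for(spec, 5, 0, rts=(1.0, 1.0)), spec)
        model = update_ability(model, result_for(spec, 5, 0, rts=(2.0, 2.0)), spec)
        for skill in spec.skill_requirements:
            assert model.rt_mean_s[skill] == pytest.approx(1.5)

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 10), st.integers(0, 10)), max_size=25))
    def test_abilities_stay_bounded_under_arbitrary_histories(self, sessions):
        spec = spec_by_id("revised", 2)
        model = AbilityModel()
        for hits, misses in sessions:
            model = update_ability(model, result_for(spec, hits, misses), spec)
            assert all(0.0 <= a <= 1.0 for a in model.abilities.values())


class TestAdjustDifficulty:
    def test_failure_lowers_difficulty(self):
        spec = spec_by_id("revised", 2)
        easier = adjust_difficulty(spec, result_for(spec, 2, 8))
        assert difficulty_index(easier) < difficulty_index(spec)

    def test_high_success_raises_difficulty(self):
        spec = spec_by_id("revised", 2)
        harder = adjust_difficulty(spec, result_for(spec, 10, 0))
        assert difficulty_index(harder) > difficulty_index(spec)

    def test_tie_holds_difficulty(self):
        spec = spec_by_id("revised", 2)
        assert adjust_difficulty(spec, result_for(spec, 5, 5)) == spec

    def test_in_band_success_holds(self):
        spec = spec_by_id("revised", 2)
        assert adjust_difficulty(spec, result_for(spec, 7, 3)) == spec

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 10), st.integers(0, 10)), max_size=30))
    def test_difficulty_stays_bounded_under_arbitrary_histories(self, sessions):
        spec = spec_by_id("revised", 2)
        for hits, misses in sessions:
            spec = adjust_difficulty(spec, result_for(spec, hits, misses))
            assert 0.0 <= difficulty_index(spec) <= 1.0


class TestRecommendNext:
    def test_empty_enabled_set_rejected(self):
        with pytest.raises(ConfigError):
            recommend_next(AbilityModel(), [])

    def test_max_ability_gets_hardest_enabled_spec(self):
        enabled = exercises_only(catalogue("revised"))
        skills = {s for spec in enabled for s in spec.skill_requirements}
        model = AbilityModel(abilities={s: 1.0 for s in skills}, prior=1.0)
        rec = recommend_next(model, enabled)
        assert rec.difficulty == max(difficulty_index(s) for s in enabled)

    def test_low_ability_gets_easy_spec(self):
        enabled = exercises_only(catalogue("revised"))
        skills = {s for spec in enabled for s in spec.skill_requirements}
        model = AbilityModel(abilities={s: 0.0 for s in skills}, prior=0.0)
        rec = recommend_next(model, enabled)
        assert rec.difficulty == min(difficulty_index(s) for s in enabled)

    def test_equal_distance_tie_breaks_on_lower_id(self):
        import dataclasses

        base = spec_by_id("revised", 2)
        twin = dataclasses.replace(base, id=99)
        model = AbilityModel(prior=0.0)
        for _ in range(3):
            rec = recommend_next(model, [twin, base])
            assert rec.spec.id == base.id


class TestSelectionLoop:
    def test_single_session_trace(self):
        patient = make_patient(seed=1)
        enabled = exercises_only(catalogue("revised"))
        history = run_selection_loop(
            AbilityModel(), enabled, ExerciseResponder(patient), 1, seed=0
        )
        assert len(history) == 1
        rec = history[0]
        assert rec.recommendation is not None and rec.result is not None
        assert rec.model is not None and not rec.skipped

    def test_seeded_loop_reproducible(self):
        def run():
            patient = make_patient(seed=9)
            enabled = exercises_only(catalogue("revised"))
            hist = run_selection_loop(
                AbilityModel(), enabled, ExerciseResponder(patient), 10, seed=4
            )
            return json.dumps([h.to_dict() for h in hist], sort_keys=True)

        assert run() == run()

    def test_responder_failure_truncates_with_error_record(self):
        enabled = exercises_only(catalogue("revised"))

        class Dying:
            def __init__(self):
                self.n = 0

            def __call__(self, stream, difficulty, rng):
                self.n += 1
                if self.n == 3:
                    raise RuntimeError("gave up")
                return []

        history = run_selection_loop(AbilityModel(), enabled, Dying(), 10, seed=0)
        assert len(history) == 3
        assert history[-1].error is not None

    def test_rolling_success_settles_in_band(self):
        patient = make_patient(seed=42)
        enabled = exercises_only(catalogue("revised"))
        history = run_selection_loop(
            AbilityModel(), enabled, ExerciseResponder(patient), 30, seed=42
        )
        post = rolling_success(history)[10:]
        assert sum(0.6 <= r <= 0.8 for r in post) / len(post) >= 0.5


class TestCompliance:
    @pytest.mark.parametrize("prescribed, completed, alert", [(5, 5, False), (5, 3, True), (0, 0, False)])
    def test_alert_iff_under_prescription(self, prescribed, completed, alert):
        patient = make_patient(seed=1)
        enabled = exercises_only(catalogue("revised"))
        history = run_selection_loop(
            AbilityModel(), enabled, ExerciseResponder(patient), max(completed, 1), seed=0
        )[:completed]
        record = check_compliance(history, prescribed)
        assert record.completed == completed
        assert record.alert is alert

    def test_zero_compliance_patient_skips_everything_and_alerts(self):
        patient = make_patient({"simulator": {"compliance_prob": 0.0}}, seed=1)
        enabled = exercises_only(catalogue("revised"))
        history = run_selection_loop(
            AbilityModel(), enabled, ExerciseResponder(patient), 5, seed=0
        )
        assert all(h.skipped for h in history)
        assert check_compliance(history, prescribed=5).alert
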