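"""Exercise catalogues, stimulus streams, and session scoring."""

import json

import pytest

from prltrain import (
    ConfigError,
    GridSpec,
    PlacementError,
    Point,
    TreatmentArea,
    build_stimulus_stream,
    catalogue,
    exercises_only,
    sanitize_timing,
    score_session,
)
from prltrain.exercises import (
    PRACTITIONER_ADJUSTABLE_PARAMS,
    FixationMode,
    ResponseMode,
    Tap,
    TaskKind,
    spec_by_id,
)


class TestCatalogue:
    def test_initial_has_fifteen_exercises_ids_1_to_15(self):
        specs = catalogue("initial")
        assert len(specs) == 15
        assert [s.id for s in specs] == list(range(1, 16))

    def test_revised_has_eleven_exercises_plus_demo(self):
        specs = catalogue("revised")
        assert len(exercises_only(specs)) == 11
        demos = [s for s in specs if s.is_demo]
        assert len(demos) == 1 and demos[0].task_kind is TaskKind.DEMO

    def test_revised_drops_letter_line_exercises(self):
        ids = {s.id for s in catalogue("revised")}
        assert 14 not in ids and 15 not in ids

    def test_revised_merges_faces_into_one(self):
        faces = [s for s in catalogue("revised") if s.task_kind is TaskKind.FACES]
        assert len(faces) == 1

    @pytest.mark.parametrize("spec_id", [2, 3, 4, 5, 10])
    def test_revised_touch_anywhere_and_5s_interval(self, spec_id):
        spec = spec_by_id("revised", spec_id)
        assert spec.params.response_mode is ResponseMode.TOUCH_ANYWHERE
        assert spec.params.inter_stimulus_s == 5.0

    @pytest.mark.parametrize("spec_id", [2, 3, 4, 5, 10])
    def test_initial_interval_was_10s(self, spec_id):
        assert spec_by_id("initial", spec_id).params.inter_stimulus_s == 10.0

    @pytest.mark.parametrize("spec_id", [6, 7, 8, 9])
    def test_revised_alternation_is_sequential_and_voice_guided(self, spec_id):
        spec = spec_by_id("revised", spec_id)
        assert spec.params.fixation_mode is FixationMode.ALTERNATING
        assert spec.params.sequential_alternation
        assert spec.params.voice_guided

    def test_revised_scene_search_forces_voice(self):
        spec = spec_by_id("revised", 13)
        assert spec.params.forced_voice and spec.params.voice_guided

    def test_revised_object_exercise_shrinks_stimulus(self):
        assert (
            spec_by_id("revised", 10).params.stimulus_size_cm
            < spec_by_id("initial", 10).params.stimulus_size_cm
        )

    def test_figure_complexity_ordering(self):
        # solid figures < hollow figures < bold letters < plain letters
        ranks = [spec_by_id("revised", i).complexity_rank for i in (2, 3, 4, 5)]
        assert ranks == sorted(ranks) and len(set(ranks)) == 4

    def test_unknown_version_rejected(self):
        with pytest.raises(ConfigError):
            catalogue("v3")

    def test_practitioner_adjustable_parameter_set(self):
        assert PRACTITIONER_ADJUSTABLE_PARAMS == {
            "inter_stimulus_s", "n_stimuli", "stimulus_size_cm", "duration_s",
        }


class TestStimulusStream:
    @pytest.mark.parametrize("seed", range(8))
    def test_revised_object_target_appears_at_least_twice(self, area, seed):
        spec = spec_by_id("revised", 10)
        stream = build_stimulus_stream(spec, area, seed)
        assert sum(e.is_target for e in stream.events) >= 2

    def test_same_seed_gives_identical_streams(self, area):
        spec = spec_by_id("revised", 2)
        a = build_stimulus_stream(spec, area, seed=5)
        b = build_stimulus_stream(spec, area, seed=5)
        assert json.dumps(a.to_dict(), sort_keys=True) == json.dumps(b.to_dict(), sort_keys=True)

    def test_events_sit_at_treatment_area_offset(self, area):
        spec = spec_by_id("revised", 2)
        stream = build_stimulus_stream(spec, area, seed=1)
        for ev in stream.events:
            assert ev.offset == area.center
            assert ev.absolute_position() == Point(2.5, 0.0)  # single fixation at centre

    def test_alternating_positions_follow_each_fixation_point(self, area):
        spec = spec_by_id("revised", 6)
        stream = build_stimulus_stream(spec, area, seed=1)
        assert len(stream.fixation_points) == 2
        for fp in stream.fixation_points:
            for ev in stream.events:
                assert ev.absolute_position(fp) - fp == area.center

    def test_off_grid_placement_rejected(self):
        spec = spec_by_id("revised", 2)
        far_area = TreatmentArea(center=Point(6.0, 0.0))
        with pytest.raises(PlacementError):
            build_stimulus_stream(spec, far_area, seed=0)

    def test_no_immediate_filler_repetition(self, area):
        spec = spec_by_id("revised", 3)
        for seed in range(5):
            stream = build_stimulus_stream(spec, area, seed)
            images = [e.image for e in stream.events]
            for prev, cur in zip(images, images[1:]):
                if prev != spec.target and cur != spec.target:
                    assert prev != cur


class TestScoring:
    def test_perfect_responder_hits_all_targets(self, area):
        spec = spec_by_id("revised", 2)
        stream = build_stimulus_stream(spec, area, seed=2)
        taps = [Tap(e.onset_s + 1.0) for e in stream.events if e.is_target]
        result = score_session(stream, taps)
        n_targets = sum(e.is_target for e in stream.events)
        assert result.hits == n_targets and result.misses == 0
        assert result.attempts == 2 * n_targets

    def test_no_responses_miss_every_target(self, area):
        spec = spec_by_id("revised", 2)
        stream = build_stimulus_stream(spec, area, seed=2)
        result = score_session(stream, [])
        n_targets = sum(e.is_target for e in stream.events)
        assert result.hits == 0 and result.misses == n_targets
        assert result.attempts == n_targets

    def test_scripted_responses_match_independent_recount(self, area):
        """Oracle: brute-force interval intersection of taps and event windows."""
        spec = spec_by_id("revised", 2)
        stream = build_stimulus_stream(spec, area, seed=3)
        taps = [Tap(t) for t in (1.0, 7.5, 12.0, 23.0, 23.5, 41.0, 200.0)]

        hits = fas = missed = 0
        for ev in stream.events:
            in_window = [t for t in taps if ev.onset_s <= t.time_s < ev.onset_s + ev.duration_s]
            if ev.is_target:
                hits += bool(in_window)
                missed += not in_window
            else:
                fas += bool(in_window)

        result = score_session(stream, taps)
        assert (result.hits, result.false_alarms) == (hits, fas)
        assert result.misses == missed + fas
        assert result.attempts == len(taps) + hits + missed

    def test_unknown_event_reference_rejected(self, area):
        spec = spec_by_id("revised", 2)
        stream = build_stimulus_stream(spec, area, seed=2)
        with pytest.raises(Exception):
            score_session(stream, [Tap(1.0, event_index=999)])

    def test_fixation_switch_prompted_only_after_missed_target(self, area):
        spec = spec_by_id("revised", 6)
        stream = build_stimulus_stream(spec, area, seed=4)
        targets = [e for e in stream.events if e.is_target]
        # hit the first target, miss the rest
        taps = [Tap(targets[0].onset_s + 0.5)]
        result = score_session(stream, taps)
        assert list(result.fixation_switches) == [e.index for e in targets[1:]]

    def test_touch_target_mode_requires_on_target(self, area):
        spec = spec_by_id("initial", 2)  # touch_target in the initial catalogue
        stream = build_stimulus_stream(spec, area, seed=2)
        target = next(e for e in stream.events if e.is_target)
        off = score_session(stream, [Tap(target.onset_s + 1.0, on_target=False)])
        on = score_session(stream, [Tap(target.onset_s + 1.0, on_target=True)])
        assert off.hits == 0 and on.hits == 1


class TestSanitizeTiming:
    @pytest.mark.parametrize(
        "raw, expected, used_default, has_warning",
        [
            ("", 5.0, True, False),
            (None, 5.0, True, False),
            ("7", 7.0, False, False),
            (7.0, 7.0, False, False),
            (-2.0, 5.0, True, True),
            ("abc", 5.0, True, True),
            (0.0, 5.0, True, True),
        ],
    )
    def test_fallback_semantics(self, raw, expected, used_default, has_warning):
        out = sanitize_timing(raw, 5.0)
        assert out.value_s == expected
        assert out.used_default is used_default
        assert (out.warning is not None) is has_warning
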