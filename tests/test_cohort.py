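"""Synthetic cohort generator: stimuli, schedules, responses, whole studies."""

import numpy as np
import pytest

from facemimic import (
    AU_CHANNELS,
    CohortConfig,
    ExpressionTemplate,
    QuestionnaireModel,
    ResponseParams,
    generate_cohort,
    generate_instructed_response,
    generate_schedule,
    generate_spontaneous_response,
    generate_stimulus_series,
)
from facemimic.cohort import (
    cohort_frame,
    default_templates,
    draw_instructed_latents,
    render_instructed_response,
    render_spontaneous_response,
    write_cohort,
)
from facemimic.patterns import EMOTION_PATTERNS, EMOTIONS
from facemimic.preprocess import trim_instructed_buffers
from facemimic.records import ARTIFICIAL_EMBODIMENTS

from _oracles import brute_crp


# ---------------------------------------------------------------------------
# stimulus templates
# ---------------------------------------------------------------------------

class TestStimulus:
    def test_anger_apex_holds_peak(self):
        tpl = ExpressionTemplate("anger", {"AU4": 4}, 30, 90, 30, 150)
        s = generate_stimulus_series(tpl)
        au4 = s.channel("AU4")
        assert (au4[30:120] == 4).all()
        others = np.delete(s.values, AU_CHANNELS.index("AU4"), axis=1)
        assert not others.any()

    def test_onset_ramp_matches_independent_formula(self):
        tpl = ExpressionTemplate("anger", {"AU4": 4}, 30, 90, 30, 150)
        s = generate_stimulus_series(tpl)

        def ramp(peak, t, onset):  # exact-rational half-up rounding
            import math
            from fractions import Fraction
            return math.floor(Fraction(peak * t, onset) + Fraction(1, 2))

        for t in (0, 7, 15, 29):
            assert s.channel("AU4")[t] == ramp(4, t, 30)
        assert s.channel("AU4")[15] == 2

    def test_all_zero_template_gives_zero_series(self):
        tpl = ExpressionTemplate("anger", {"AU4": 0}, 30, 90, 30, 150)
        assert not generate_stimulus_series(tpl).values.any()

    def test_invalid_frame_partition_rejected(self):
        with pytest.raises(ValueError):
            ExpressionTemplate("anger", {"AU4": 4}, 30, 90, 31, 150)

    @pytest.mark.parametrize("emotion", EMOTIONS)
    def test_default_templates_cover_a_detection_alternative(self, emotion):
        tpl = default_templates()[emotion]
        active = {au for au, p in tpl.au_peaks.items() if p >= 1}
        alts = EMOTION_PATTERNS[emotion].alternatives
        assert any(alt <= active for alt in alts)
        assert tpl.onset_frames + tpl.apex_frames + tpl.offset_frames == 150


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

class TestSchedule:
    def test_no_adjacent_emotion_repeats_and_balance(self):
        cfg = CohortConfig()
        stubs = generate_schedule(cfg, seed=3)
        blocks = {}
        for r in stubs:
            blocks.setdefault(
                (r.participant_id, r.phase, r.embodiment), []).append(r.emotion)
        assert len(blocks) == 45 * 2 * 4
        for emotions in blocks.values():
            assert len(emotions) == 12
            assert all(a != b for a, b in zip(emotions, emotions[1:]))
            for emo in EMOTIONS:
                assert emotions.count(emo) == 2

    def test_schedule_deterministic_under_seed(self):
        cfg = CohortConfig()
        a = generate_schedule(cfg, seed=9)
        b = generate_schedule(cfg, seed=9)
        assert [r.key for r in a] == [r.key for r in b]
        c = generate_schedule(cfg, seed=10)
        assert [r.key for r in a] != [r.key for r in c]

    def test_embodiment_order_varies_across_participants(self):
        cfg = CohortConfig()
        stubs = generate_schedule(cfg, seed=0)
        orders = set()
        for pid in {r.participant_id for r in stubs}:
            seq = [r.embodiment for r in stubs
                   if r.participant_id == pid and r.phase == "spontaneous"]
            orders.add(tuple(dict.fromkeys(seq)))
        assert len(orders) > 1


# ---------------------------------------------------------------------------
# spontaneous responses
# ---------------------------------------------------------------------------

class TestSpontaneousResponse:
    def test_null_params_give_all_zero_response(self, quiet_params):
        stim = generate_stimulus_series(default_templates()["anger"])
        resp = generate_spontaneous_response(stim, quiet_params, 5, "anger")
        assert not resp.values.any()
        assert resp.n_frames == stim.n_frames

    def test_certain_injection_stays_low_intensity_and_in_pattern(self, quiet_params):
        quiet_params.p_mimic_rfr = 1.0
        quiet_params.p_mimic_cfr = 1.0
        stim = generate_stimulus_series(default_templates()["happiness"])
        for seed in range(20):
            resp = generate_spontaneous_response(stim, quiet_params, seed,
                                                 "happiness")
            assert resp.values.max() <= 2  # subtle regime
            active_chans = {AU_CHANNELS[c]
                            for c in np.flatnonzero(resp.values.any(axis=0))}
            alt = EMOTION_PATTERNS["happiness"].alternatives[0]
            assert active_chans == set(alt)

    def test_injection_never_exceeds_ordinal_cap(self, quiet_params):
        quiet_params.p_mimic_rfr = 1.0
        quiet_params.p_mimic_cfr = 1.0
        quiet_params.mimic_peak_range = (5, 5)
        quiet_params.baseline_flicker_rate = 0.5
        stim = generate_stimulus_series(default_templates()["anger"])
        resp = generate_spontaneous_response(stim, quiet_params, 0, "anger")
        assert resp.values.max() <= 5


# ---------------------------------------------------------------------------
# instructed responses
# ---------------------------------------------------------------------------

class TestInstructedResponse:
    def test_perfect_fidelity_reproduces_stimulus(self, perfect_copy_params):
        stim = generate_stimulus_series(default_templates()["surprise"])
        resp = generate_instructed_response(stim, perfect_copy_params, 0)
        assert resp.n_frames == stim.n_frames + 60
        trimmed = trim_instructed_buffers(resp)
        np.testing.assert_array_equal(trimmed.values, stim.values)

    def test_lag_shifts_longest_diagonal(self, perfect_copy_params, rng):
        """A pure 8-frame lag moves the exact-match diagonal to offset -8."""
        perfect_copy_params.instructed_lag_frames = (8, 8)
        stim_vals = rng.integers(0, 6, size=(60, len(AU_CHANNELS)))
        from facemimic import AUSeries
        stim = AUSeries(stim_vals)
        resp = trim_instructed_buffers(
            generate_instructed_response(stim, perfect_copy_params, 1))
        crp = brute_crp(resp.values, stim.values, eps=2, strict=True)
        # oracle scan: longest run per diagonal offset
        best_len, best_k = -1, None
        n, m = crp.shape
        for k in range(-(n - 1), m):
            run = longest = 0
            for i in range(n):
                j = i + k
                if 0 <= j < m:
                    run = run + 1 if crp[i, j] else 0
                    longest = max(longest, run)
            if longest > best_len:
                best_len, best_k = longest, k
        assert best_k == -8
        assert best_len == 60 - 8

    def test_mean_crr_decreases_with_noise(self, quiet_params):
        from facemimic.crqa import CRQAConfig, snippet_crqa
        stim = generate_stimulus_series(default_templates()["happiness"])
        means = []
        for noise in (0.2, 0.8, 2.0):
            params = ResponseParams(
                p_occlusion=0.0, instructed_lag_frames=(0, 0),
                instructed_gain_sd=0.0, instructed_noise_sd=noise)
            crrs = []
            for seed in range(30):
                resp = trim_instructed_buffers(
                    generate_instructed_response(stim, params, seed))
                crrs.append(snippet_crqa(resp, stim, "happiness",
                                         CRQAConfig()).crr)
            means.append(np.mean(crrs))
        assert means[0] > means[1] > means[2]


# ---------------------------------------------------------------------------
# whole cohorts
# ---------------------------------------------------------------------------

class TestCohort:
    def test_default_design_shape(self):
        coh = generate_cohort(seed=0)
        pids = {r.participant_id for r in coh.records}
        assert len(pids) == 45
        for phase in ("spontaneous", "instructed"):
            per_pid = {}
            for r in coh.records:
                if r.phase == phase:
                    per_pid[r.participant_id] = per_pid.get(r.participant_id, 0) + 1
            assert set(per_pid.values()) == {48}

    def test_cohort_files_byte_identical_under_seed(self, tmp_path, small_config):
        for sub in ("a", "b"):
            write_cohort(generate_cohort(small_config, seed=4), tmp_path / sub)
        for name in ("au_series.csv", "stimuli.csv", "questionnaire.csv",
                     "manifest.json", "ground_truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_zero_occlusion_gives_no_invalid_snippets(self, small_config, quiet_params):
        coh = generate_cohort(small_config, quiet_params, seed=1)
        assert not any(r.occluded for r in coh.records)

    def test_occlusion_fraction_binomial(self):
        cfg = CohortConfig(phases=("spontaneous",))
        par = ResponseParams(p_occlusion=0.2)
        coh = generate_cohort(cfg, par, seed=2)
        occluded = np.array([r.occluded for r in coh.records])
        n = occluded.size
        sd = np.sqrt(0.2 * 0.8 / n)
        assert abs(occluded.mean() - 0.2) < 3 * sd

    def test_ground_truth_reconstructs_every_response(self, small_config):
        """Closure: the recorded latents regenerate each series exactly."""
        coh = generate_cohort(small_config, seed=6)
        by_key = {(r.participant_id, r.phase, r.embodiment, r.emotion, r.trial): r
                  for r in coh.records}
        for gt in coh.ground_truth["snippets"]:
            rec = by_key[(gt["participant_id"], gt["phase"], gt["embodiment"],
                          gt["emotion"], gt["trial"])]
            if gt["kind"] == "spontaneous":
                rebuilt = render_spontaneous_response(gt["latents"])
            else:
                rebuilt = render_instructed_response(
                    coh.stimuli[gt["emotion"]], gt["latents"], coh.params)
            np.testing.assert_array_equal(rebuilt.values, rec.series.values)

    def test_questionnaire_within_bounds_and_complete(self, small_config):
        coh = generate_cohort(small_config, seed=7)
        q = coh.questionnaire
        assert len(q) == 6 * len(ARTIFICIAL_EMBODIMENTS)
        scales = QuestionnaireModel().scale_names
        for s in scales:
            assert q[s].between(1.0, 5.0).all()
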