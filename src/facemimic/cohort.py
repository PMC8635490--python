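"""Synthetic cohort generator.

Emulates the mixed 3 x 3 + 1 study this pipeline analyzes: 45 participants
split over three humanlikeness groups (characterlike / humanlike / morph)
each observe four embodiments (virtual agent, physical robot, video-recorded
robot, and a video-recorded human control) in two phases.  Per phase and
embodiment a participant sees 12 snippets (2 trials x 6 basic emotions) of
5-s onset-apex-offset expressions at 30 fps, with no emotion shown twice in
a row.

The generator produces, with known ground truth:

* agent-side stimulus AU series (piecewise onset/apex/offset ramps),
* spontaneous-phase responses -- probabilistic, low-intensity injections of
  the target emotion's AU pattern inside the rapid (RFR, 0-1000 ms) and
  controlled (CFR, 1000-5000 ms) reaction windows, plus baseline flicker,
* instructed-phase responses -- the stimulus trajectory lagged, gain-scaled,
  noised and re-quantized to the ordinal 0-5 scale, padded with 1-s buffers,
* snippet-level occlusion (missingness), and
* questionnaire scale scores coupled to each participant x embodiment's
  latent mimicry propensity.

Every stochastic choice is drawn from a per-snippet generator seeded by
``(seed, participant, phase, embodiment, snippet)`` and recorded in the
ground-truth bundle, so each response series can be reconstructed exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .au import AU_CHANNELS, AUSeries, DEFAULT_FPS, MAX_INTENSITY, quantize_intensity
from .patterns import EMOTION_PATTERNS, EMOTIONS
from .records import (
    ARTIFICIAL_EMBODIMENTS,
    EMBODIMENTS,
    HUMANLIKENESS_GROUPS,
    PHASES,
    SnippetRecord,
)

__all__ = [
    "ExpressionTemplate",
    "CohortConfig",
    "ResponseParams",
    "QuestionnaireModel",
    "Cohort",
    "default_templates",
    "generate_stimulus_series",
    "generate_schedule",
    "generate_spontaneous_response",
    "generate_instructed_response",
    "generate_cohort",
    "write_cohort",
]


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionTemplate:
    """Onset-apex-offset ramp template for one emotion's expression.

    The stimulus rises linearly from 0 to each AU's peak over ``onset_frames``,
    holds the peak over ``apex_frames`` and decays linearly over
    ``offset_frames``; frame counts must sum to ``total_frames``.
    """

    emotion: str
    au_peaks: Mapping[str, int]
    onset_frames: int = 30
    apex_frames: int = 90
    offset_frames: int = 30
    total_frames: int = 150

    def __post_init__(self) -> None:
        if self.onset_frames + self.apex_frames + self.offset_frames != self.total_frames:
            raise ValueError(
                "onset + apex + offset frames must equal total_frames "
                f"({self.onset_frames}+{self.apex_frames}+{self.offset_frames}"
                f" != {self.total_frames})"
            )
        if min(self.onset_frames, self.apex_frames, self.offset_frames) < 0:
            raise ValueError("frame counts must be non-negative")
        for au, peak in self.au_peaks.items():
            if au not in AU_CHANNELS:
                raise ValueError(f"unknown AU channel {au!r}")
            if not 0 <= peak <= MAX_INTENSITY:
                raise ValueError(f"peak for {au} outside [0, {MAX_INTENSITY}]")


def default_templates(
    fps: float = DEFAULT_FPS,
    onset_s: float = 1.0,
    apex_s: float = 3.0,
    offset_s: float = 1.0,
) -> dict[str, ExpressionTemplate]:
    """One 5-s template per basic emotion (onset 1 s / apex 3 s / offset 1 s).

    Peak AU sets are modest-intensity FACS prototypes chosen so that each
    emotion's active channels are a superset of at least one of its
    detection alternatives in :data:`~facemimic.patterns.EMOTION_PATTERNS`.
    """
    onset = int(round(onset_s * fps))
    apex = int(round(apex_s * fps))
    offset = int(round(offset_s * fps))
    total = onset + apex + offset
    peaks = {
        "happiness": {"AU6": 3, "AU12": 4},
        "sadness": {"AU1": 3, "AU15": 3},
        "surprise": {"AU1": 3, "AU2": 3, "AU26": 4},
        "anger": {"AU4": 4},
        "fear": {"AU1": 2, "AU2": 2, "AU4": 2, "AU20": 3},
        "disgust": {"AU4": 3, "AU25": 3},
    }
    return {
        emo: ExpressionTemplate(emo, p, onset, apex, offset, total)
        for emo, p in peaks.items()
    }


def _as_embodiment_map(value, embodiments: Sequence[str]) -> dict[str, float]:
    if isinstance(value, Mapping):
        out = {e: float(value[e]) for e in embodiments}
    else:
        out = {e: float(value) for e in embodiments}
    for e, p in out.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability for {e!r} outside [0, 1]: {p}")
    return out


@dataclass(frozen=True)
class CohortConfig:
    """Design structure of the simulated study."""

    n_participants: int = 45
    group_sizes: tuple[int, ...] = (15, 15, 15)
    groups: tuple[str, ...] = HUMANLIKENESS_GROUPS
    embodiments: tuple[str, ...] = EMBODIMENTS
    phases: tuple[str, ...] = PHASES
    snippets_per_embodiment_per_phase: int = 12
    fps: float = DEFAULT_FPS
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.group_sizes) != self.n_participants:
            raise ValueError("group_sizes must sum to n_participants")
        if len(self.group_sizes) != len(self.groups):
            raise ValueError("one size per group required")
        if self.snippets_per_embodiment_per_phase != 2 * len(EMOTIONS):
            raise ValueError("snippet count must equal 2 x number of emotions")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def participant_groups(self) -> list[tuple[str, str]]:
        """(participant_id, group) pairs, P01.. in group-block order."""
        out = []
        k = 0
        for g, size in zip(self.groups, self.group_sizes):
            for _ in range(size):
                k += 1
                out.append((f"P{k:02d}", g))
        return out


@dataclass
class ResponseParams:
    """Ground-truth behavioral parameters of the simulated participants.

    Spontaneous mimicry is injected with probability ``p_mimic_rfr`` /
    ``p_mimic_cfr`` (scalar, or a mapping per embodiment) as a subtle
    (peak 1-2) activation of the target emotion's AU pattern lasting
    ``mimic_duration_frames`` and starting at a latency drawn uniformly
    from the window-specific interval.  Instructed mimicry copies the
    stimulus with a sampled lag and multiplicative gain plus Gaussian
    noise before re-quantization.  ``p_occlusion`` (scalar or per phase)
    is the chance a snippet is unusable; ``participant_effect_sd`` spreads
    a per-participant propensity offset shared by both windows.
    """

    p_mimic_rfr: float | Mapping[str, float] = 0.25
    p_mimic_cfr: float | Mapping[str, float] = 0.35
    mimic_peak_range: tuple[int, int] = (1, 2)
    rfr_latency_ms: tuple[float, float] = (0.0, 800.0)
    cfr_latency_ms: tuple[float, float] = (1100.0, 4000.0)
    mimic_duration_frames: tuple[int, int] = (3, 15)
    instructed_lag_frames: tuple[int, int] = (0, 6)
    instructed_gain_sd: float = 0.15
    instructed_noise_sd: float = 0.3
    p_occlusion: float | Mapping[str, float] = field(
        default_factory=lambda: {"spontaneous": 0.15, "instructed": 0.06}
    )
    baseline_flicker_rate: float = 0.01
    participant_effect_sd: float = 0.08
    #: index into the emotion's alternatives used for injections; None samples.
    injection_alternative: int | None = 0

    def __post_init__(self) -> None:
        if self.mimic_duration_frames[0] < 1:
            raise ValueError("mimicry duration lower bound must be >= 1")
        if not 0.0 <= self.baseline_flicker_rate <= 1.0:
            raise ValueError("flicker rate outside [0, 1]")
        if self.instructed_gain_sd < 0 or self.instructed_noise_sd < 0:
            raise ValueError("dispersions must be non-negative")

    def p_rfr(self, embodiment: str) -> float:
        return _as_embodiment_map(self.p_mimic_rfr, [embodiment])[embodiment]

    def p_cfr(self, embodiment: str) -> float:
        return _as_embodiment_map(self.p_mimic_cfr, [embodiment])[embodiment]

    def p_occluded(self, phase: str) -> float:
        if isinstance(self.p_occlusion, Mapping):
            p = float(self.p_occlusion[phase])
        else:
            p = float(self.p_occlusion)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p_occlusion outside [0, 1]: {p}")
        return p


DEFAULT_SCALES: tuple[str, ...] = (
    "anthropomorphism", "likability", "perceived_threat", "co_presence",
    "attentional_allocation", "affective_understanding",
    "emotional_interdependence", "behavioral_interdependence",
)

_DEFAULT_COUPLING = {
    "anthropomorphism": -0.15,
    "likability": -0.25,
    "perceived_threat": 0.08,
    "co_presence": -0.20,
    "attentional_allocation": -0.22,
    "affective_understanding": -0.20,
    "emotional_interdependence": -0.15,
    "behavioral_interdependence": -0.08,
}


@dataclass
class QuestionnaireModel:
    """Linear coupling of 1-5 perception scales to latent mimicry propensity.

    Each participant x embodiment cell has a latent propensity (the true
    injection probability averaged over the two windows); its cohort-wide
    z-score enters each scale mean with the signed ``coupling`` coefficient
    around a midpoint of 3, plus Gaussian noise, clipped to ``scale_bounds``.
    """

    scale_names: tuple[str, ...] = DEFAULT_SCALES
    coupling: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_COUPLING))
    noise_sd: float = 0.5
    scale_bounds: tuple[float, float] = (1.0, 5.0)


# ---------------------------------------------------------------------------
# stimulus generation
# ---------------------------------------------------------------------------

def generate_stimulus_series(
    template: ExpressionTemplate, fps: float = DEFAULT_FPS
) -> AUSeries:
    """Render a template as an onset-apex-offset AU intensity series.

    Frame ``t`` of the onset carries ``round(peak * t / onset_frames)``
    (so the first apex frame is the first to reach the full peak), apex
    frames hold the peak, and the offset decays mirror-symmetrically.
    Channels without a peak stay zero.
    """
    n = template.total_frames
    values = np.zeros((n, len(AU_CHANNELS)))
    on, ap, off = template.onset_frames, template.apex_frames, template.offset_frames
    t = np.arange(n, dtype=float)
    profile = np.zeros(n)
    if on:
        profile[:on] = t[:on] / on
    profile[on:on + ap] = 1.0
    if off:
        profile[on + ap:] = (n - t[on + ap:]) / off
    for au, peak in template.au_peaks.items():
        values[:, AU_CHANNELS.index(au)] = peak * profile
    return AUSeries(quantize_intensity(values), AU_CHANNELS, fps)


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

def _non_repeating_order(rng: np.random.Generator, items: Sequence[str]) -> list[str]:
    """Random permutation with no two equal labels adjacent (rejection sampled).

    For 2 copies of each of 6 emotions, a valid order exists and rejection
    sampling accepts quickly (roughly 2 of 3 shuffles).
    """
    items = list(items)
    while True:
        order = list(rng.permutation(items))
        if all(a != b for a, b in zip(order, order[1:])):
            return order


def generate_schedule(config: CohortConfig, seed: int | None = None) -> list[SnippetRecord]:
    """Snippet stubs (no series) for the full design, deterministic under seed.

    Per participant and phase the embodiment order is shuffled, and within
    each embodiment block the 12 emotion trials (2 x 6) are ordered randomly
    with no emotion repeated back-to-back.
    """
    if seed is None:
        seed = config.seed
    stubs: list[SnippetRecord] = []
    for p_idx, (pid, group) in enumerate(config.participant_groups()):
        for ph_idx, phase in enumerate(config.phases):
            rng = np.random.default_rng([seed, 7, p_idx, ph_idx])
            emb_order = list(rng.permutation(config.embodiments))
            for emb in emb_order:
                order = _non_repeating_order(rng, list(EMOTIONS) * 2)
                seen: dict[str, int] = {}
                for emo in order:
                    seen[emo] = seen.get(emo, 0) + 1
                    stubs.append(SnippetRecord(
                        participant_id=pid, group=group, embodiment=emb,
                        phase=phase, emotion=emo, trial=seen[emo],
                    ))
    return stubs


# ---------------------------------------------------------------------------
# response generation: latents are drawn, then rendered deterministically
# ---------------------------------------------------------------------------

def _injection_au_indices(emotion: str, alternative: int | None,
                          rng: np.random.Generator) -> tuple[int, ...]:
    alts = EMOTION_PATTERNS[emotion].alternatives
    if alternative is None:
        alt = alts[rng.integers(len(alts))]
    else:
        alt = alts[alternative]
    return tuple(AU_CHANNELS.index(au) for au in sorted(alt))


def draw_spontaneous_latents(
    rng: np.random.Generator,
    emotion: str,
    params: ResponseParams,
    p_rfr: float,
    p_cfr: float,
    n_frames: int,
    fps: float = DEFAULT_FPS,
) -> dict:
    """Sample every stochastic choice behind one spontaneous response."""
    lat: dict = {"emotion": emotion, "n_frames": int(n_frames), "fps": fps}
    for window, p, (lo_ms, hi_ms) in (
        ("rfr", p_rfr, params.rfr_latency_ms),
        ("cfr", p_cfr, params.cfr_latency_ms),
    ):
        mimic = bool(rng.random() < p)
        lat[f"{window}_mimic"] = mimic
        if mimic:
            start = int(round(rng.uniform(lo_ms, hi_ms) / 1000.0 * fps))
            dur = int(rng.integers(params.mimic_duration_frames[0],
                                   params.mimic_duration_frames[1] + 1))
            peak = int(rng.integers(params.mimic_peak_range[0],
                                    params.mimic_peak_range[1] + 1))
            lat[f"{window}_start"] = start
            lat[f"{window}_duration"] = dur
            lat[f"{window}_peak"] = peak
    lat["injection_aus"] = _injection_au_indices(
        emotion, params.injection_alternative, rng)
    if params.baseline_flicker_rate > 0:
        flicker_frames = np.flatnonzero(
            rng.random(n_frames) < params.baseline_flicker_rate)
        flicker_chans = rng.integers(len(AU_CHANNELS), size=flicker_frames.size)
        lat["flicker"] = [(int(f), int(c))
                          for f, c in zip(flicker_frames, flicker_chans)]
    else:
        lat["flicker"] = []
    return lat


def render_spontaneous_response(latents: dict) -> AUSeries:
    """Deterministically rebuild a spontaneous response from its latents."""
    n = latents["n_frames"]
    values = np.zeros((n, len(AU_CHANNELS)), dtype=np.int64)
    aus = list(latents["injection_aus"])
    for window in ("rfr", "cfr"):
        if latents.get(f"{window}_mimic"):
            s = latents[f"{window}_start"]
            e = min(n, s + latents[f"{window}_duration"])
            values[s:e, aus] = np.maximum(values[s:e, aus],
                                          latents[f"{window}_peak"])
    for frame, chan in latents["flicker"]:
        values[frame, chan] = max(values[frame, chan], 1)
    return AUSeries(values, AU_CHANNELS, latents["fps"])


def generate_spontaneous_response(
    stimulus: AUSeries,
    params: ResponseParams,
    seed,
    emotion: str,
    embodiment: str | None = None,
) -> AUSeries:
    """One spontaneous-phase response to ``stimulus`` (same length, same fps)."""
    rng = np.random.default_rng(seed)
    p_rfr = params.p_rfr(embodiment) if embodiment else _scalar_p(params.p_mimic_rfr)
    p_cfr = params.p_cfr(embodiment) if embodiment else _scalar_p(params.p_mimic_cfr)
    lat = draw_spontaneous_latents(
        rng, emotion, params, p_rfr, p_cfr, stimulus.n_frames, stimulus.fps)
    return render_spontaneous_response(lat)


def _scalar_p(value) -> float:
    if isinstance(value, Mapping):
        raise ValueError("per-embodiment probabilities require an embodiment")
    return float(value)


def draw_instructed_latents(rng: np.random.Generator,
                            params: ResponseParams) -> dict:
    lag = int(rng.integers(params.instructed_lag_frames[0],
                           params.instructed_lag_frames[1] + 1))
    gain = float(rng.normal(1.0, params.instructed_gain_sd)) \
        if params.instructed_gain_sd > 0 else 1.0
    noise_seed = int(rng.integers(2 ** 31))
    return {"lag": lag, "gain": gain, "noise_seed": noise_seed}


def render_instructed_response(
    stimulus: AUSeries,
    latents: dict,
    params: ResponseParams,
    buffer_frames: int = 30,
) -> AUSeries:
    """Lag + gain + noise copy of the stimulus, re-quantized, with 1-s buffers.

    The returned series is ``buffer_frames`` of neutral face, the perturbed
    copy of the stimulus, then another buffer -- the segmentation convention
    for instructed snippets cut one second before and after the mimicry.
    """
    core = np.zeros_like(stimulus.values, dtype=float)
    lag = latents["lag"]
    if lag == 0:
        core[:] = stimulus.values
    elif lag > 0:
        core[lag:] = stimulus.values[:-lag]
    else:
        core[:lag] = stimulus.values[-lag:]
    core *= latents["gain"]
    if params.instructed_noise_sd > 0:
        noise_rng = np.random.default_rng(latents["noise_seed"])
        core += noise_rng.normal(0.0, params.instructed_noise_sd, core.shape)
    core = quantize_intensity(core)
    pad = np.zeros((buffer_frames, core.shape[1]), dtype=core.dtype)
    return AUSeries(np.vstack([pad, core, pad]), stimulus.channels, stimulus.fps)


def generate_instructed_response(
    stimulus: AUSeries,
    params: ResponseParams,
    seed,
    buffer_frames: int = 30,
) -> AUSeries:
    """One instructed-phase response (length = stimulus + 2 buffers)."""
    rng = np.random.default_rng(seed)
    lat = draw_instructed_latents(rng, params)
    return render_instructed_response(stimulus, lat, params, buffer_frames)


# ---------------------------------------------------------------------------
# whole cohort
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """In-memory synthetic study: snippets, stimuli, questionnaire, truth."""

    config: CohortConfig
    params: ResponseParams
    qmodel: QuestionnaireModel
    seed: int
    records: list[SnippetRecord]
    stimuli: dict[str, AUSeries]
    questionnaire: pd.DataFrame
    ground_truth: dict


def generate_cohort(
    config: CohortConfig | None = None,
    params: ResponseParams | None = None,
    qmodel: QuestionnaireModel | None = None,
    seed: int | None = None,
    templates: Mapping[str, ExpressionTemplate] | None = None,
) -> Cohort:
    """Simulate the full study with known ground truth.

    Each snippet's randomness comes from ``default_rng([seed, tag, indices...])``
    so cohorts are reproducible and each response can be regenerated from the
    ground-truth record alone.
    """
    config = config or CohortConfig()
    params = params or ResponseParams()
    qmodel = qmodel or QuestionnaireModel()
    if seed is None:
        seed = config.seed
    templates = templates or default_templates(config.fps)
    stimuli = {emo: generate_stimulus_series(tpl, config.fps)
               for emo, tpl in templates.items()}

    participants = config.participant_groups()
    p_index = {pid: i for i, (pid, _) in enumerate(participants)}
    # participant-level propensity offsets, shared by both windows
    offset_rng = np.random.default_rng([seed, 11])
    offsets = (offset_rng.normal(0.0, params.participant_effect_sd,
                                 len(participants))
               if params.participant_effect_sd > 0
               else np.zeros(len(participants)))

    stubs = generate_schedule(config, seed)
    gt_snippets: list[dict] = []
    emb_index = {e: i for i, e in enumerate(config.embodiments)}
    phase_index = {ph: i for i, ph in enumerate(config.phases)}

    snip_counter: dict[tuple, int] = {}
    latent_p: dict[tuple[str, str], list[float]] = {}
    for rec in stubs:
        p_idx = p_index[rec.participant_id]
        ph_idx = phase_index[rec.phase]
        e_idx = emb_index[rec.embodiment]
        block = (p_idx, ph_idx, e_idx)
        s_idx = snip_counter.get(block, 0)
        snip_counter[block] = s_idx + 1
        entropy = [seed, 13, p_idx, ph_idx, e_idx, s_idx]
        rng = np.random.default_rng(entropy)
        rec.occluded = bool(rng.random() < params.p_occluded(rec.phase))
        stim = stimuli[rec.emotion]
        gt: dict = {
            "participant_id": rec.participant_id, "phase": rec.phase,
            "embodiment": rec.embodiment, "emotion": rec.emotion,
            "trial": rec.trial, "entropy": entropy, "occluded": rec.occluded,
        }
        if rec.phase == "spontaneous":
            p_rfr = float(np.clip(params.p_rfr(rec.embodiment) + offsets[p_idx], 0, 1))
            p_cfr = float(np.clip(params.p_cfr(rec.embodiment) + offsets[p_idx], 0, 1))
            latent_p.setdefault((rec.participant_id, rec.embodiment), []).append(
                0.5 * (p_rfr + p_cfr))
            lat = draw_spontaneous_latents(
                rng, rec.emotion, params, p_rfr, p_cfr,
                stim.n_frames, config.fps)
            rec.series = render_spontaneous_response(lat)
            gt.update({"kind": "spontaneous", "p_rfr": p_rfr, "p_cfr": p_cfr,
                       "latents": lat})
        else:
            lat = draw_instructed_latents(rng, params)
            rec.series = render_instructed_response(stim, lat, params)
            gt.update({"kind": "instructed", "latents": lat})
        gt_snippets.append(gt)

    questionnaire = _generate_questionnaire(
        participants, config, qmodel, latent_p, seed)

    ground_truth = {
        "seed": seed,
        "participant_offsets": {pid: float(offsets[i])
                                for i, (pid, _) in enumerate(participants)},
        "snippets": gt_snippets,
    }
    return Cohort(config, params, qmodel, seed, stubs, stimuli,
                  questionnaire, ground_truth)


def _generate_questionnaire(
    participants: list[tuple[str, str]],
    config: CohortConfig,
    qmodel: QuestionnaireModel,
    latent_p: dict[tuple[str, str], list[float]],
    seed: int,
) -> pd.DataFrame:
    """Scale scores per participant x embodiment from the latent propensity."""
    rng = np.random.default_rng([seed, 17])
    rows = []
    cells = [(pid, grp, emb) for pid, grp in participants
             for emb in config.embodiments]
    lat = np.array([np.mean(latent_p.get((pid, emb), [0.0]))
                    for pid, _, emb in cells])
    sd = lat.std()
    z = (lat - lat.mean()) / sd if sd > 0 else np.zeros_like(lat)
    lo, hi = qmodel.scale_bounds
    for (pid, grp, emb), zval in zip(cells, z):
        row = {"participant_id": pid, "group": grp, "embodiment": emb}
        for scale in qmodel.scale_names:
            c = float(qmodel.coupling.get(scale, 0.0))
            score = 3.0 + c * zval + rng.normal(0.0, qmodel.noise_sd)
            row[scale] = float(np.clip(score, lo, hi))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file interface
# ---------------------------------------------------------------------------

def cohort_frame(cohort: Cohort) -> pd.DataFrame:
    """Long per-frame table of every snippet (the ``au_series.csv`` layout)."""
    chunks = []
    for rec in cohort.records:
        n = rec.series.n_frames
        df = pd.DataFrame(rec.series.values, columns=list(rec.series.channels))
        df.insert(0, "participant_id", rec.participant_id)
        df.insert(1, "group", rec.group)
        df.insert(2, "embodiment", rec.embodiment)
        df.insert(3, "phase", rec.phase)
        df.insert(4, "emotion", rec.emotion)
        df.insert(5, "trial", rec.trial)
        df.insert(6, "frame", np.arange(n))
        df["occluded"] = int(rec.occluded)
        chunks.append(df)
    return pd.concat(chunks, ignore_index=True)


def stimuli_frame(cohort: Cohort) -> pd.DataFrame:
    chunks = []
    for emo, series in cohort.stimuli.items():
        df = pd.DataFrame(series.values, columns=list(series.channels))
        df.insert(0, "emotion", emo)
        df.insert(1, "frame", np.arange(series.n_frames))
        chunks.append(df)
    return pd.concat(chunks, ignore_index=True)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write au_series.csv, stimuli.csv, questionnaire.csv, manifest.json,
    ground_truth.json under ``outdir``; byte-identical under a fixed seed."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_frame(cohort).to_csv(out / "au_series.csv", index=False)
    stimuli_frame(cohort).to_csv(out / "stimuli.csv", index=False)
    cohort.questionnaire.to_csv(out / "questionnaire.csv", index=False,
                                float_format="%.6f")
    manifest = {
        "config": asdict(cohort.config),
        "seed": cohort.seed,
        "snippets": [
            {"participant_id": r.participant_id, "group": r.group,
             "embodiment": r.embodiment, "phase": r.phase,
             "emotion": r.emotion, "trial": r.trial,
             "occluded": bool(r.occluded)}
            for r in cohort.records
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "ground_truth.json").write_text(
        json.dumps(cohort.ground_truth, indent=1, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
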