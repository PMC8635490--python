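"""Spontaneous facial-mimicry detection.

A snippet counts as mimicked in a window when the AU set of one of the
target emotion's alternatives is simultaneously active (intensity >= trace)
for at least 3 consecutive frames (100 ms, the shortest muscle movement)
whose onset-relative times fall inside the window:

* RFR (rapid facial reactions):      [0, 1000) ms after stimulus onset
* CFR (controlled facial reactions): [1000, 5000) ms after stimulus onset

Activation is binary -- intensity is not considered, since spontaneous
mimicry is expected to be subtle.  Each window is evaluated independently:
a run straddling the 1-s boundary counts for a window only if at least
``min_run`` of its frames lie inside that window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .au import AUSeries
from .patterns import EMOTION_PATTERNS, EmotionPattern
from .records import SnippetRecord

__all__ = [
    "MimicryWindows", "MimicryOutcome", "binarize_activation",
    "detect_window", "detect_snippet", "mimicry_rates",
]


@dataclass(frozen=True)
class MimicryWindows:
    """Post-onset evaluation windows in milliseconds, plus the run minimum."""

    rfr_ms: tuple[float, float] = (0.0, 1000.0)
    cfr_ms: tuple[float, float] = (1000.0, 5000.0)
    min_run: int = 3

    def __post_init__(self) -> None:
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if not (self.rfr_ms[0] < self.rfr_ms[1] <= self.cfr_ms[0] < self.cfr_ms[1]):
            raise ValueError("windows must be ordered and disjoint")

    def frame_range(self, window: str, fps: float, n_frames: int) -> tuple[int, int]:
        """Half-open frame interval whose frame-onset times fall in the window."""
        lo_ms, hi_ms = self.rfr_ms if window == "RFR" else self.cfr_ms
        lo = int(np.ceil(lo_ms / 1000.0 * fps))
        hi = int(np.ceil(hi_ms / 1000.0 * fps))
        return max(lo, 0), min(hi, n_frames)


@dataclass(frozen=True)
class MimicryOutcome:
    participant_id: str
    embodiment: str
    emotion: str
    trial: int
    rfr_mimicked: bool
    cfr_mimicked: bool


def binarize_activation(series: AUSeries, threshold: int = 1) -> np.ndarray:
    """Binary activation mask: 1 where intensity >= threshold (trace)."""
    return (np.asarray(series.values) >= threshold).astype(np.int8)


def _has_run(active: np.ndarray, min_run: int) -> bool:
    """True iff ``active`` (1-D boolean) has >= min_run consecutive True."""
    if active.size < min_run:
        return False
    if min_run == 1:
        return bool(active.any())
    s = np.cumsum(active, dtype=np.int32)
    window_sums = s[min_run - 1:].copy()
    window_sums[1:] -= s[:-min_run]
    return bool((window_sums >= min_run).any())


def detect_window(
    mask: np.ndarray,
    pattern: EmotionPattern,
    window: tuple[int, int],
    channels: Sequence[str],
    min_run: int = 3,
) -> bool:
    """Mimicry flag for one window of one snippet.

    ``mask`` is the frames x channels binary activation matrix; ``window``
    is a half-open frame interval.  The flag is true iff some alternative
    AU set of the pattern is simultaneously active on >= ``min_run``
    consecutive frames within the interval.
    """
    lo, hi = window
    lo = max(lo, 0)
    hi = min(hi, mask.shape[0])
    if hi - lo < min_run:
        return False
    channels = list(channels)
    for alt in pattern.alternatives:
        try:
            idx = [channels.index(au) for au in alt]
        except ValueError as err:
            raise KeyError(f"pattern for {pattern.emotion!r} references a "
                           f"channel absent from the series: {err}") from None
        conj = mask[lo:hi, idx].all(axis=1)
        if _has_run(conj, min_run):
            return True
    return False


def detect_snippet(
    record: SnippetRecord,
    windows: MimicryWindows = MimicryWindows(),
    threshold: int = 1,
) -> MimicryOutcome:
    """RFR and CFR mimicry flags for one valid spontaneous snippet."""
    series = record.series
    mask = binarize_activation(series, threshold)
    pattern = EMOTION_PATTERNS[record.emotion]
    flags = {}
    for w in ("RFR", "CFR"):
        rng = windows.frame_range(w, series.fps, series.n_frames)
        flags[w] = detect_window(mask, pattern, rng, series.channels,
                                 windows.min_run)
    return MimicryOutcome(record.participant_id, record.embodiment,
                          record.emotion, record.trial,
                          flags["RFR"], flags["CFR"])


def mimicry_rates(
    records: Iterable[SnippetRecord],
    windows: MimicryWindows = MimicryWindows(),
    threshold: int = 1,
) -> pd.DataFrame:
    """Per participant x embodiment x window mimicry rates.

    Only valid snippets enter; the rate is mimicked / valid snippet count.
    Embodiment blocks with no valid snippets are absent from the table.
    Columns: participant_id, group, embodiment, window, n_valid,
    n_mimicked, rate.
    """
    counts: dict[tuple, list] = {}
    for rec in records:
        if rec.phase != "spontaneous" or not rec.valid:
            continue
        outcome = detect_snippet(rec, windows, threshold)
        for window, hit in (("RFR", outcome.rfr_mimicked),
                            ("CFR", outcome.cfr_mimicked)):
            key = (rec.participant_id, rec.group, rec.embodiment, window)
            cell = counts.setdefault(key, [0, 0])
            cell[0] += 1
            cell[1] += int(hit)
    rows = [
        {"participant_id": pid, "group": grp, "embodiment": emb,
         "window": window, "n_valid": n, "n_mimicked": k, "rate": k / n}
        for (pid, grp, emb, window), (n, k) in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows, columns=["participant_id", "group", "embodiment", "window",
                       "n_valid", "n_mimicked", "rate"])
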