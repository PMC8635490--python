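"""Cross-recurrence quantification of instructed mimicry.

The participant's AU intensity trajectory and the agent's stimulus
trajectory are compared through a cross-recurrence plot (CRP): the binary
N x M matrix with a 1 wherever the Manhattan distance between the two
feature vectors is below a threshold (eps = 2 on the ordinal 0-5 scale by
default).  Diagonal-line structure in the CRP is then summarized by

* cRR   -- recurrence density, 100 * (# recurrent points) / (N * M), in %;
* L     -- mean length of diagonal lines of length >= l_min (8 samples,
           about 250 ms at 30 fps);
* L_max -- longest diagonal line;
* DET   -- share of recurrent points on diagonal lines of length >= l_min.

Two DET conventions are implemented.  ``normalized`` divides the recurrent
points on qualifying lines by *all* recurrent points
(sum_{l>=l_min} l P(l) / sum_{l>=1} l P(l)), which is bounded in [0, 1].
``as_printed`` divides by the *count* of all diagonal lines
(sum_{l>=l_min} l P(l) / sum_{l>=1} P(l)), which can exceed 1; it is kept
selectable because published tables based on that formula report DET > 1.
Every maximal diagonal run of 1s counts as a line of its exact length
(isolated points are lines of length 1; border-touching runs count at
their visible length), and the main diagonal is not excluded -- the two
systems are distinct, so lag-0 matching carries signal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .au import AUSeries
from .patterns import pattern_channels
from .preprocess import smooth as _smooth
from .records import SnippetRecord

__all__ = [
    "CRQAConfig", "CRQAResult", "cross_recurrence_matrix",
    "diagonal_histogram", "crqa_measures", "snippet_crqa",
    "instructed_crqa_table", "aggregate_instructed",
]


@dataclass(frozen=True)
class CRQAConfig:
    """Parameters of the cross-recurrence analysis.

    ``theta_convention='strict'`` marks a recurrence when distance < eps
    (a Manhattan distance of exactly 2 does *not* recur under the default);
    ``'inclusive'`` uses distance <= eps, the Heaviside-at-zero convention
    of standard recurrence software.  ``channel_policy`` selects the AU
    channels entering the feature vector: ``'emotion_union'`` (default)
    takes the target emotion's detection-pattern AU union (2-4 channels),
    or pass an explicit tuple of channel labels.  With
    ``scale_eps_by_dim`` the threshold becomes ``eps * d / 3`` so that
    tolerance per channel is constant across feature dimensions (off by
    default).
    """

    eps: float = 2.0
    norm: str = "manhattan"
    l_min: int = 8
    det_variant: str = "normalized"
    theta_convention: str = "strict"
    channel_policy: str | tuple[str, ...] = "emotion_union"
    scale_eps_by_dim: bool = False

    def __post_init__(self) -> None:
        if self.eps < 0:
            raise ValueError("eps must be >= 0")
        if self.l_min < 1:
            raise ValueError("l_min must be >= 1")
        if self.norm not in ("manhattan", "euclidean"):
            raise ValueError(f"unknown norm {self.norm!r}")
        if self.det_variant not in ("normalized", "as_printed"):
            raise ValueError(f"unknown det_variant {self.det_variant!r}")
        if self.theta_convention not in ("strict", "inclusive"):
            raise ValueError(f"unknown theta_convention {self.theta_convention!r}")

    def channels_for(self, emotion: str) -> tuple[str, ...]:
        if self.channel_policy == "emotion_union":
            return pattern_channels(emotion)
        return tuple(self.channel_policy)


@dataclass
class CRQAResult:
    """Line-based CRQA measures plus the diagonal-line histogram."""

    crr: float
    l_avg: float
    l_max: int
    det: float
    det_normalized: float
    det_as_printed: float
    histogram: dict[int, int]
    n: int
    m: int
    n_recurrent: int
    defined_empty: bool
    has_lines: bool


def cross_recurrence_matrix(
    f1: AUSeries | np.ndarray,
    f2: AUSeries | np.ndarray,
    config: CRQAConfig = CRQAConfig(),
) -> np.ndarray:
    """Binary N x M cross-recurrence matrix between two feature series.

    Row i, column j is 1 iff the distance between frame i of ``f1`` and
    frame j of ``f2`` is below (strict) or up to (inclusive) eps.
    """
    a = f1.values if isinstance(f1, AUSeries) else np.asarray(f1)
    b = f2.values if isinstance(f2, AUSeries) else np.asarray(f2)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"channel mismatch: {a.shape[1]} vs {b.shape[1]} feature dims")
    if isinstance(f1, AUSeries) and isinstance(f2, AUSeries) \
            and f1.channels != f2.channels:
        raise ValueError("the two series carry different channel sets")
    diff = a[:, None, :] - b[None, :, :]
    if config.norm == "manhattan":
        dist = np.abs(diff).sum(axis=2)
    else:
        dist = np.sqrt((diff ** 2).sum(axis=2))
    eps = config.eps * a.shape[1] / 3.0 if config.scale_eps_by_dim else config.eps
    if config.theta_convention == "strict":
        return (dist < eps).astype(np.int8)
    return (dist <= eps).astype(np.int8)


def diagonal_histogram(crp: np.ndarray) -> dict[int, int]:
    """Histogram P(l): count of maximal diagonal runs of 1s of each length.

    Every diagonal offset k in [-(N-1), M-1] is scanned; isolated points
    contribute lines of length 1, so sum_l l * P(l) equals the number of
    recurrent points.
    """
    crp = np.asarray(crp)
    n, m = crp.shape
    hist: Counter[int] = Counter()
    for k in range(-(n - 1), m):
        diag = np.diagonal(crp, offset=k)
        if not diag.any():
            continue
        padded = np.concatenate(([0], diag, [0]))
        edges = np.diff(padded)
        lengths = np.flatnonzero(edges == -1) - np.flatnonzero(edges == 1)
        hist.update(lengths.tolist())
    return dict(hist)


def crqa_measures(
    crp: np.ndarray,
    config: CRQAConfig = CRQAConfig(),
    histogram: Mapping[int, int] | None = None,
) -> CRQAResult:
    """All line-based measures of one CRP.

    With no recurrent point at all, every measure is 0 and
    ``defined_empty`` is set; with recurrences but no line >= l_min,
    L is reported as 0 and ``has_lines`` is False.
    """
    crp = np.asarray(crp)
    n, m = crp.shape
    n_rec = int(crp.sum())
    if histogram is None:
        histogram = diagonal_histogram(crp)
    hist = dict(histogram)
    if n_rec == 0:
        return CRQAResult(0.0, 0.0, 0, 0.0, 0.0, 0.0, {}, n, m, 0,
                          defined_empty=True, has_lines=False)
    crr = 100.0 * n_rec / (n * m)
    lengths = np.array(sorted(hist))
    counts = np.array([hist[l] for l in lengths])
    long_mask = lengths >= config.l_min
    n_long_points = int((lengths[long_mask] * counts[long_mask]).sum())
    n_long_lines = int(counts[long_mask].sum())
    has_lines = n_long_lines > 0
    l_avg = n_long_points / n_long_lines if has_lines else 0.0
    l_max = int(lengths.max())
    total_points = int((lengths * counts).sum())
    total_lines = int(counts.sum())
    det_norm = n_long_points / total_points
    det_printed = n_long_points / total_lines
    det = det_norm if config.det_variant == "normalized" else det_printed
    return CRQAResult(crr, l_avg, l_max, det, det_norm, det_printed, hist,
                      n, m, n_rec, defined_empty=False, has_lines=has_lines)


def snippet_crqa(
    response: AUSeries,
    stimulus: AUSeries,
    emotion: str,
    config: CRQAConfig = CRQAConfig(),
    smooth_window: int | None = None,
) -> CRQAResult:
    """CRQA of one participant response against the agent's stimulus.

    Both series are restricted to the configured channel set for the
    emotion and optionally low-pass filtered before the plot is built.
    """
    chans = config.channels_for(emotion)
    resp = response.select_channels(chans)
    stim = stimulus.select_channels(chans)
    if smooth_window and smooth_window > 1:
        resp = _smooth(resp, smooth_window)
        stim = _smooth(stim, smooth_window)
    crp = cross_recurrence_matrix(resp, stim, config)
    return crqa_measures(crp, config)


def instructed_crqa_table(
    records: Iterable[SnippetRecord],
    stimuli: Mapping[str, AUSeries],
    config: CRQAConfig = CRQAConfig(),
    smooth_window: int | None = None,
) -> pd.DataFrame:
    """Per-snippet CRQA measures for every valid instructed snippet."""
    rows = []
    for rec in records:
        if rec.phase != "instructed" or not rec.valid:
            continue
        res = snippet_crqa(rec.series, stimuli[rec.emotion], rec.emotion,
                           config, smooth_window)
        rows.append({
            "participant_id": rec.participant_id, "group": rec.group,
            "embodiment": rec.embodiment, "emotion": rec.emotion,
            "trial": rec.trial, "cRR": res.crr, "L": res.l_avg,
            "Lmax": res.l_max, "DET": res.det,
        })
    return pd.DataFrame(
        rows, columns=["participant_id", "group", "embodiment", "emotion",
                       "trial", "cRR", "L", "Lmax", "DET"])


def aggregate_instructed(per_snippet: pd.DataFrame) -> pd.DataFrame:
    """Mean cRR, L, L_max and DET per participant x embodiment.

    Arithmetic means over valid snippets; participant x embodiment blocks
    with no surviving snippets are simply absent.  Columns: participant_id,
    group, embodiment, avg_cRR, avg_L, avg_Lmax, avg_DET, n_valid.
    """
    if per_snippet.empty:
        return pd.DataFrame(columns=["participant_id", "group", "embodiment",
                                     "avg_cRR", "avg_L", "avg_Lmax",
                                     "avg_DET", "n_valid"])
    grouped = per_snippet.groupby(
        ["participant_id", "group", "embodiment"], as_index=False).agg(
        avg_cRR=("cRR", "mean"), avg_L=("L", "mean"),
        avg_Lmax=("Lmax", "mean"), avg_DET=("DET", "mean"),
        n_valid=("cRR", "size"))
    return grouped
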