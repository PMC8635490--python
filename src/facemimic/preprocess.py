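"""AU time-series preprocessing: smoothing, trimming, validity filtering.

The upstream intensity detector emits ordinal categories per frame; this
module low-pass filters the series (centered moving average, window 10
samples), removes the 1-s segmentation buffers of instructed snippets, and
applies the snippet-exclusion rules:

* a snippet is invalid if occluded (or otherwise undetected);
* spontaneous phase -- if more than half of an embodiment's snippets for a
  participant are missing, the remaining valid ones are excluded too;
* instructed phase -- if 5 or fewer valid snippets remain for an
  embodiment x participant, all of them are excluded.
"""

from __future__ import annotations

import json
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .au import AU_CHANNELS, AUSeries, MAX_INTENSITY
from .records import SnippetRecord

DEFAULT_SMOOTH_WINDOW = 10
DEFAULT_BUFFER_FRAMES = 30


def smooth(series: AUSeries, window: int = DEFAULT_SMOOTH_WINDOW) -> AUSeries:
    """Centered moving-average low-pass filter, per channel.

    An even window of size ``w`` spans frames ``[t - w//2, t + w - w//2 - 1]``
    (window 10: five frames back, four forward).  At the edges the window
    shrinks to the available frames, so output length equals input length
    and constants are preserved.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = series.n_frames
    if n == 0:
        raise ValueError("cannot smooth an empty series")
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    if window == 1:
        return series.copy()
    left = window // 2
    right = window - 1 - left
    csum = np.vstack([np.zeros((1, series.values.shape[1])),
                      np.cumsum(series.values, axis=0, dtype=float)])
    t = np.arange(n)
    lo = np.maximum(t - left, 0)
    hi = np.minimum(t + right, n - 1)
    sums = csum[hi + 1] - csum[lo]
    counts = (hi - lo + 1).astype(float)[:, None]
    return AUSeries(sums / counts, series.channels, series.fps)


def trim_instructed_buffers(
    series: AUSeries, buffer: int = DEFAULT_BUFFER_FRAMES
) -> AUSeries | None:
    """Drop the 1-s segmentation buffers at both ends of an instructed snippet.

    Returns ``None`` (snippet too short, to be marked invalid) when fewer
    than one frame would remain.
    """
    if buffer < 0:
        raise ValueError("buffer must be non-negative")
    if buffer == 0:
        return series.copy()
    if series.n_frames <= 2 * buffer:
        return None
    return AUSeries(series.values[buffer:series.n_frames - buffer],
                    series.channels, series.fps)


def _blocks(records: Iterable[SnippetRecord]) -> dict[tuple[str, str], list[SnippetRecord]]:
    grouped: dict[tuple[str, str], list[SnippetRecord]] = defaultdict(list)
    for rec in records:
        grouped[(rec.participant_id, rec.embodiment)].append(rec)
    return grouped


def filter_spontaneous_validity(
    records: Sequence[SnippetRecord],
    nominal_count: int | None = 12,
) -> list[SnippetRecord]:
    """Apply the spontaneous-phase exclusion rule in place.

    Occluded snippets are invalid; if the number of missing snippets in a
    participant x embodiment block exceeds half the block's snippet count,
    every snippet of the block becomes invalid.  ``nominal_count`` is the
    denominator of "half" (the designed 12 by default); pass ``None`` to use
    the recorded count instead.  Idempotent.
    """
    for block in _blocks(records).values():
        denom = nominal_count if nominal_count is not None else len(block)
        n_missing = sum(r.occluded for r in block)
        # designed snippets never recorded at all also count as missing
        n_missing += max(denom - len(block), 0)
        wipe = n_missing > denom / 2
        for r in block:
            r.valid = (not r.occluded) and not wipe
    return list(records)


def filter_instructed_validity(
    records: Sequence[SnippetRecord],
    min_valid: int = 6,
) -> list[SnippetRecord]:
    """Apply the instructed-phase exclusion rule in place.

    Occluded (or too-short) snippets are invalid; blocks retaining fewer
    than ``min_valid`` valid snippets (i.e. 5 or less under the default)
    are excluded entirely.  Idempotent: only ``occluded`` and a pre-set
    ``valid=False`` (e.g. from buffer trimming) are treated as missing.
    """
    for block in _blocks(records).values():
        for r in block:
            if r.occluded:
                r.valid = False
            elif r.valid is None:
                r.valid = True
        n_valid = sum(bool(r.valid) for r in block)
        if n_valid < min_valid:
            for r in block:
                r.valid = False
    return list(records)


def exclusion_summary(records: Sequence[SnippetRecord]) -> dict:
    """Per-phase counts and fractions of excluded snippets."""
    out: dict = {}
    by_phase: dict[str, list[SnippetRecord]] = defaultdict(list)
    for r in records:
        by_phase[r.phase].append(r)
    for phase, recs in by_phase.items():
        n = len(recs)
        n_excluded = sum(not r.valid for r in recs)
        out[phase] = {
            "n_snippets": n,
            "n_excluded": n_excluded,
            "n_valid": n - n_excluded,
            "fraction_excluded": n_excluded / n if n else float("nan"),
        }
    return out


# ---------------------------------------------------------------------------
# file interface
# ---------------------------------------------------------------------------

def frame_to_records(df: pd.DataFrame, fps: float = 30.0) -> list[SnippetRecord]:
    """Rebuild snippet records from the long per-frame ``au_series.csv`` table."""
    keys = ["participant_id", "group", "embodiment", "phase", "emotion", "trial"]
    records = []
    for key, sub in df.groupby(keys, sort=False):
        sub = sub.sort_values("frame")
        values = sub[list(AU_CHANNELS)].to_numpy()
        records.append(SnippetRecord(
            participant_id=key[0], group=key[1], embodiment=key[2],
            phase=key[3], emotion=key[4], trial=int(key[5]),
            series=AUSeries(values, AU_CHANNELS, fps),
            occluded=bool(sub["occluded"].iloc[0]),
        ))
    return records


def read_au_series(path, fps: float = 30.0) -> list[SnippetRecord]:
    return frame_to_records(pd.read_csv(path), fps)


def preprocess_records(
    records: Sequence[SnippetRecord],
    nominal_count: int | None = 12,
    min_valid: int = 6,
    buffer: int = DEFAULT_BUFFER_FRAMES,
) -> list[SnippetRecord]:
    """Run the full validity stage: trim instructed buffers, then filter.

    Instructed series are replaced by their trimmed versions; snippets too
    short to trim are marked invalid before the block-level rule runs.
    """
    spont = [r for r in records if r.phase == "spontaneous"]
    instr = [r for r in records if r.phase == "instructed"]
    if spont:
        filter_spontaneous_validity(spont, nominal_count)
    for r in instr:
        trimmed = trim_instructed_buffers(r.series, buffer)
        if trimmed is None:
            r.valid = False
        else:
            r.series = trimmed
    if instr:
        filter_instructed_validity(instr, min_valid)
    return list(records)


def write_validity(records: Sequence[SnippetRecord], outdir) -> None:
    """Write ``snippets_valid.csv`` plus the exclusions summary JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {"participant_id": r.participant_id, "group": r.group,
         "embodiment": r.embodiment, "phase": r.phase, "emotion": r.emotion,
         "trial": r.trial, "occluded": int(r.occluded),
         "valid": int(bool(r.valid))}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(out / "snippets_valid.csv", index=False)
    (out / "exclusions.json").write_text(
        json.dumps(exclusion_summary(records), indent=1))
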