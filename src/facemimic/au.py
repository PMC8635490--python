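"""Action Unit (AU) intensity time series.

The atomic data object of the pipeline is a frames x channels matrix of
FACS intensity categories.  An upstream detector grades each AU frame by
frame on Ekman's six-category ordinal scale -- N (neutral), A (trace),
B (slight), C (marked), D (severe), E (maximum) -- which we map onto the
integers 0..5.  Nine AUs are tracked, grouped by facial region:

* frown:  AU4 (brow lowerer)
* eyes:   AU1 (inner brow raiser), AU2 (outer brow raiser), AU6 (cheek raiser)
* mouth:  AU12 (lip corner puller), AU15 (lip corner depressor),
          AU20 (lip stretcher), AU25 (lips part), AU26 (jaw drop)

Raw series hold integers in [0, 5]; low-pass filtered series hold reals in
the same range.  The channel order below is fixed everywhere (files, arrays,
distance computations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AU_CHANNELS: tuple[str, ...] = (
    "AU1", "AU2", "AU4", "AU6", "AU12", "AU15", "AU20", "AU25", "AU26",
)

#: Ekman intensity categories in ascending order; index = ordinal value.
INTENSITY_CODES: tuple[str, ...] = ("N", "A", "B", "C", "D", "E")

MAX_INTENSITY = 5

_CODE_TO_ORDINAL = {c: i for i, c in enumerate(INTENSITY_CODES)}

DEFAULT_FPS = 30.0


class CategoryCodeError(ValueError):
    """An intensity label outside N/A/B/C/D/E, with its location."""


def map_intensity_categories(labels, *, row: int | None = None) -> np.ndarray:
    """Map a sequence of category codes (N..E) to ordinal intensities 0..5.

    Parameters
    ----------
    labels
        Sequence (or nested sequence) of one-letter category codes.
    row
        Optional row index reported in error messages when a code is unknown.

    Returns
    -------
    numpy.ndarray of int, same shape as ``labels``.
    """
    arr = np.asarray(labels)
    out = np.empty(arr.shape, dtype=np.int64)
    flat_in = arr.ravel()
    flat_out = out.ravel()
    for k, code in enumerate(flat_in):
        try:
            flat_out[k] = _CODE_TO_ORDINAL[str(code)]
        except KeyError:
            idx = np.unravel_index(k, arr.shape) if arr.ndim > 1 else (k,)
            loc = f"row {row}, " if row is not None else ""
            raise CategoryCodeError(
                f"unknown intensity category {code!r} at {loc}position {idx}"
            ) from None
    return out


def unmap_intensity_categories(values) -> list[str]:
    """Inverse of :func:`map_intensity_categories` for ordinal values 0..5."""
    out = []
    for v in np.asarray(values).ravel():
        iv = int(v)
        if not 0 <= iv <= MAX_INTENSITY:
            raise ValueError(f"ordinal intensity {v!r} outside [0, 5]")
        out.append(INTENSITY_CODES[iv])
    return out


@dataclass
class AUSeries:
    """A frames x channels matrix of AU intensities at a fixed frame rate.

    ``values[t, c]`` is the intensity of channel ``channels[c]`` at frame
    ``t``.  Raw series are integer-valued in [0, 5]; filtered series are
    real-valued in [0, 5].
    """

    values: np.ndarray
    channels: tuple[str, ...] = AU_CHANNELS
    fps: float = DEFAULT_FPS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("AUSeries values must be 2-D (frames x channels)")
        if self.values.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.values.shape[1]} columns for {len(self.channels)} channels"
            )
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"unknown AU channel {label!r}") from None

    def channel(self, label: str) -> np.ndarray:
        return self.values[:, self.channel_index(label)]

    def select_channels(self, labels) -> "AUSeries":
        """Restrict to the given channels, preserving their listed order."""
        idx = [self.channel_index(lab) for lab in labels]
        return AUSeries(self.values[:, idx], tuple(labels), self.fps)

    def copy(self) -> "AUSeries":
        return AUSeries(self.values.copy(), self.channels, self.fps)


def quantize_intensity(values: np.ndarray) -> np.ndarray:
    """Round real intensities to the ordinal 0..5 grid.

    Rounding is half-away-from-zero (so 1.5 -> 2), then values are clipped
    to [0, 5]; this keeps synthetic or rescaled trajectories on the scale
    the intensity detector emits.
    """
    rounded = np.sign(values) * np.floor(np.abs(values) + 0.5)
    return np.clip(rounded, 0, MAX_INTENSITY).astype(np.int64)
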