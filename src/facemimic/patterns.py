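"""FACS patterns for the six basic emotions.

Each emotion is detected through one or more alternative AU sets; an
alternative counts as the target expression only when *all* of its AUs are
simultaneously active (conjunctive reading), while alternatives themselves
are disjunctive -- any one suffices.

Default mapping:

========== =============================================
emotion    alternatives
========== =============================================
anger      {AU4}
disgust    {AU4, AU25}
fear       {AU20}, {AU1, AU2, AU4}
happiness  {AU6}, {AU12}, {AU6, AU12}
sadness    {AU1}, {AU15}, {AU1, AU4}
surprise   {AU26}, {AU1, AU2}
========== =============================================

The fear row is read as the two alternatives {AU20} and {AU1+AU2+AU4} by
analogy with the other multi-alternative rows; override
``EMOTION_PATTERNS`` (or pass a custom :class:`EmotionPattern`) to change
this reading.
"""

from __future__ import annotations

from dataclasses import dataclass

from .au import AU_CHANNELS

EMOTIONS: tuple[str, ...] = (
    "happiness", "sadness", "surprise", "anger", "fear", "disgust",
)


@dataclass(frozen=True)
class EmotionPattern:
    """Alternative AU sets any of which counts as the target expression."""

    emotion: str
    alternatives: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise ValueError("pattern needs at least one alternative AU set")
        for alt in self.alternatives:
            unknown = alt - set(AU_CHANNELS)
            if unknown:
                raise ValueError(
                    f"pattern for {self.emotion!r} references unknown "
                    f"channels {sorted(unknown)}"
                )

    @property
    def union(self) -> frozenset[str]:
        """All AUs appearing in any alternative (the emotion's channel set)."""
        out: frozenset[str] = frozenset()
        for alt in self.alternatives:
            out |= alt
        return out


def _pat(emotion: str, *alts) -> EmotionPattern:
    return EmotionPattern(emotion, tuple(frozenset(a) for a in alts))


EMOTION_PATTERNS: dict[str, EmotionPattern] = {
    "anger": _pat("anger", {"AU4"}),
    "disgust": _pat("disgust", {"AU4", "AU25"}),
    "fear": _pat("fear", {"AU20"}, {"AU1", "AU2", "AU4"}),
    "happiness": _pat("happiness", {"AU6"}, {"AU12"}, {"AU6", "AU12"}),
    "sadness": _pat("sadness", {"AU1"}, {"AU15"}, {"AU1", "AU4"}),
    "surprise": _pat("surprise", {"AU26"}, {"AU1", "AU2"}),
}


def pattern_channels(emotion: str) -> tuple[str, ...]:
    """The emotion's AU-set union, in fixed channel order."""
    union = EMOTION_PATTERNS[emotion].union
    return tuple(ch for ch in AU_CHANNELS if ch in union)
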