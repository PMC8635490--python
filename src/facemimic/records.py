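"""Snippet records: one stimulus-response episode with its design coordinates.

A snippet is the unit of analysis throughout: one presentation of one
emotional expression by one embodiment to one participant, in one phase
(spontaneous observation or instructed imitation), together with the
participant's AU intensity response series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .au import AUSeries

HUMANLIKENESS_GROUPS: tuple[str, ...] = ("characterlike", "humanlike", "morph")
EMBODIMENTS: tuple[str, ...] = ("virtual", "physical", "video_robot", "video_human")
ARTIFICIAL_EMBODIMENTS: tuple[str, ...] = ("virtual", "physical", "video_robot")
HUMAN_EMBODIMENT = "video_human"
PHASES: tuple[str, ...] = ("spontaneous", "instructed")


@dataclass
class SnippetRecord:
    participant_id: str
    group: str
    embodiment: str
    phase: str
    emotion: str
    trial: int
    series: AUSeries | None = None
    occluded: bool = False
    #: None until a validity filter has run; valid implies not occluded.
    valid: bool | None = None

    @property
    def key(self) -> tuple:
        return (self.participant_id, self.phase, self.embodiment,
                self.emotion, self.trial)
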