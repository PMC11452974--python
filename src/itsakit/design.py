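"""TMT channel layouts for isothermal shift assay experiments.

An iTSA experiment quantifies, in a single TMT plex, matched aliquots of a
lysate that received either vehicle (control) or drug (treated) before a
brief thermal challenge.  The channel design records which reporter-ion
label carries which condition; every downstream statistic (fold change,
t-test) is defined relative to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

Condition = Literal["control", "treated"]

#: Reporter labels of the standard TMT 10-plex, in mass order.
TMT10_LABELS = ("126", "127N", "127C", "128N", "128C",
                "129N", "129C", "130N", "130C", "131")


@dataclass(frozen=True)
class Channel:
    label: str
    condition: Condition


@dataclass(frozen=True)
class ChannelDesign:
    """Ordered channel -> condition assignment for one TMT plex.

    Invariants: labels are unique and each condition has at least two
    channels (a two-sample t-test needs at least one degree of freedom).
    """

    plex_id: str
    channels: tuple[Channel, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate channel labels in plex {self.plex_id!r}: {dupes}")
        for cond in ("control", "treated"):
            if sum(c.condition == cond for c in self.channels) < 2:
                raise ValueError(
                    f"plex {self.plex_id!r}: need >= 2 {cond} channels, "
                    f"got {sum(c.condition == cond for c in self.channels)}"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.channels)

    def labels_for(self, condition: Condition) -> tuple[str, ...]:
        return tuple(c.label for c in self.channels if c.condition == condition)

    @property
    def control_labels(self) -> tuple[str, ...]:
        return self.labels_for("control")

    @property
    def treated_labels(self) -> tuple[str, ...]:
        return self.labels_for("treated")

    def replicate_counts(self) -> dict[str, int]:
        return {cond: len(self.labels_for(cond)) for cond in ("control", "treated")}

    @classmethod
    def from_pairs(cls, plex_id: str, pairs: Iterable[tuple[str, Condition]]) -> "ChannelDesign":
        return cls(plex_id, tuple(Channel(l, c) for l, c in pairs))


def default_10plex(plex_id: str = "plex1") -> ChannelDesign:
    """The 5 control + 5 treated layout: 126..128C vehicle, 129N..131 drug."""
    conditions = ("control",) * 5 + ("treated",) * 5
    return ChannelDesign.from_pairs(plex_id, zip(TMT10_LABELS, conditions))
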