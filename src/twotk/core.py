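"""Domain model for topological-kinetic (2TK) dialogue analysis.

A dialogue is represented hierarchically: a sequence of planes, each a
sequence of concatenations (thematic units), each an ordered sequence of
speech acts.  Every speech act carries a dialogical time index ``epsilon``,
a topological address ``(x, y)`` (theme index, depth within the theme), an
act type, per-object polarity flags and a decisivity flag.  These
annotations are the inputs to the kinetic metrics (vergence, celerity) and
the topological encodings computed elsewhere in the package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

__all__ = [
    "ActType",
    "Address",
    "SpeechAct",
    "Concatenation",
    "Plane",
    "Dialogue",
    "Violation",
    "validate_dialogue",
    "build_dialogue",
    "TASK",
    "INTERLOCUTOR",
]

#: Canonical object-of-analysis identifiers.  Polarity is always relative to
#: an object of analysis; these two are the ones used throughout the package,
#: but any string key is admissible.
TASK = "task"
INTERLOCUTOR = "interlocutor"


class ActType(str, enum.Enum):
    """The five admissible speech-act types.

    DO   -- an action performed, verbally or non-verbally;
    MK   -- make-know: an informational statement;
    DMK  -- do make-know: a request for information;
    DC   -- do can: an invitation or offer leaving the interlocutor a choice;
    DM   -- do must: a directive leaving no alternative.
    """

    DO = "DO"
    MK = "MK"
    DMK = "DMK"
    DC = "DC"
    DM = "DM"

    @classmethod
    def parse(cls, code: str) -> "ActType":
        try:
            return cls(code.strip().upper())
        except ValueError:
            raise ValueError(
                f"unknown act type {code!r}; expected one of "
                f"{[t.value for t in cls]}"
            ) from None


@dataclass(frozen=True, order=True)
class Address:
    """Topological address xi = (x, y): theme index and depth within theme."""

    x: int
    y: int

    def __post_init__(self) -> None:
        if self.x < 1 or self.y < 1:
            raise ValueError(f"address coordinates must be >= 1, got {(self.x, self.y)}")


@dataclass
class SpeechAct:
    """One annotated utterance or nonverbal action.

    Nonverbal actions (laughter, gestures, singing) are regular speech acts,
    conventionally of type DO or MK with bracketed content.

    Parameters
    ----------
    speaker : str
        Participant identifier.
    epsilon : int
        Dialogical time: the 1-based rank of the act in the exchange.
    content : str
        Verbatim content (free text).
    act_type : ActType
    address : Address
    polarity : mapping object-id -> {0, 1}
        Whether the act positively proves the dialogue's orientation toward
        each object of analysis (delta).
    decisivity : {0, 1}
        Whether the act directly advances task resolution (d).
    """

    speaker: str
    epsilon: int
    content: str
    act_type: ActType
    address: Optional[Address] = None
    polarity: dict = field(default_factory=dict)
    decisivity: int = 0

    def delta(self, object_id: str) -> int:
        """Polarity toward ``object_id``; unlisted objects read as 0."""
        return int(self.polarity.get(object_id, 0))


@dataclass
class Concatenation:
    """A thematic unit: the ordered speech acts sharing one x coordinate."""

    index: int
    acts: list
    label: str = ""

    def __iter__(self) -> Iterator[SpeechAct]:
        return iter(self.acts)

    def __len__(self) -> int:
        return len(self.acts)


@dataclass
class Plane:
    """An ordered sequence of concatenations forming one thematic plan."""

    concatenations: list

    def __iter__(self) -> Iterator[Concatenation]:
        return iter(self.concatenations)

    def acts(self) -> list:
        out = []
        for c in self.concatenations:
            out.extend(c.acts)
        out.sort(key=lambda a: a.epsilon)
        return out


@dataclass
class Dialogue:
    """A complete two-or-more-party exchange.

    ``state_annotations`` optionally carries per-act metadata (rhetorical
    relation labels and the like) keyed by epsilon; together with the act
    type, address and epsilon these house the arguments of the interaction
    state description without committing to a computable form for it.
    """

    identifier: str
    participants: list
    planes: list
    condition: str = ""
    state_annotations: dict = field(default_factory=dict)

    def acts(self) -> list:
        out = []
        for p in self.planes:
            out.extend(p.acts())
        out.sort(key=lambda a: a.epsilon)
        return out

    def concatenations(self) -> list:
        out = []
        for p in self.planes:
            out.extend(p.concatenations)
        return out

    def objects(self) -> list:
        """All object-of-analysis identifiers referenced anywhere."""
        seen: dict = {}
        for a in self.acts():
            for k in a.polarity:
                seen.setdefault(k, None)
        return list(seen)

    def speaker_acts(self, speaker: str) -> list:
        return [a for a in self.acts() if a.speaker == speaker]


@dataclass(frozen=True)
class Violation:
    """One broken invariant, located by the offending act's epsilon."""

    epsilon: Optional[int]
    rule: str
    message: str
    severity: str = "error"  # "error" or "warning"


def validate_dialogue(dialogue: Dialogue) -> list:
    """Check every structural invariant; return violation records.

    Validation never raises: an empty return value means the dialogue is
    well formed.  Checked rules:

    * at least two participants, and every act's speaker is in the roster;
    * epsilon values globally unique and strictly increasing;
    * addresses present, with (x, y) unique within each plane;
    * concatenations non-empty, internally epsilon-ordered, all member acts
      sharing the concatenation's x index; indices contiguous from 1;
    * a decisive act (d = 1) must be positively task-polarized
      (delta_task = 1), the premise of the primacy inequality C <= V;
    * objects of analysis referenced anywhere should carry a polarity entry
      on every act (missing entries default to 0 and are flagged as
      warnings, not errors).
    """
    v: list = []
    if len(dialogue.participants) < 2:
        v.append(Violation(None, "participants", "dialogue needs >= 2 participants"))

    acts = dialogue.acts()
    roster = set(dialogue.participants)
    seen_eps: set = set()
    prev_eps = 0
    for a in acts:
        if a.speaker not in roster:
            v.append(Violation(a.epsilon, "speaker", f"speaker {a.speaker!r} not in roster"))
        if a.epsilon < 1:
            v.append(Violation(a.epsilon, "epsilon_positive", "epsilon must be >= 1"))
        if a.epsilon in seen_eps:
            v.append(Violation(a.epsilon, "duplicate_epsilon", f"duplicate epsilon {a.epsilon}"))
        elif a.epsilon <= prev_eps:
            v.append(Violation(a.epsilon, "epsilon_order", "epsilon not strictly increasing"))
        seen_eps.add(a.epsilon)
        prev_eps = max(prev_eps, a.epsilon)
        if a.address is None:
            v.append(Violation(a.epsilon, "address_missing", "act has no topological address"))
        if a.decisivity not in (0, 1):
            v.append(Violation(a.epsilon, "decisivity_range", "d must be 0 or 1"))
        for obj, d in a.polarity.items():
            if d not in (0, 1):
                v.append(Violation(a.epsilon, "polarity_range", f"delta[{obj!r}] must be 0 or 1"))
        if a.decisivity == 1 and a.delta(TASK) != 1:
            v.append(
                Violation(
                    a.epsilon,
                    "decisive_not_task_polarized",
                    "decisive act not task-polarized (d=1 requires delta_task=1)",
                )
            )

    for p_idx, plane in enumerate(dialogue.planes):
        seen_addr: set = set()
        for a in plane.acts():
            if a.address is not None:
                if a.address in seen_addr:
                    v.append(
                        Violation(
                            a.epsilon, "duplicate_address",
                            f"address {(a.address.x, a.address.y)} reused in plane {p_idx}",
                        )
                    )
                seen_addr.add(a.address)
        indices = [c.index for c in plane.concatenations]
        if indices != list(range(1, len(indices) + 1)):
            v.append(
                Violation(
                    None, "concatenation_indices",
                    f"plane {p_idx} concatenation indices {indices} not contiguous from 1",
                )
            )
        for c in plane.concatenations:
            if not c.acts:
                v.append(Violation(None, "empty_concatenation", f"concatenation {c.index} is empty"))
                continue
            eps = [a.epsilon for a in c.acts]
            if eps != sorted(eps) or len(set(eps)) != len(eps):
                v.append(
                    Violation(eps[0], "concatenation_order",
                              f"concatenation {c.index}: epsilon not strictly increasing")
                )
            for a in c.acts:
                if a.address is not None and a.address.x != c.index:
                    v.append(
                        Violation(a.epsilon, "concatenation_x",
                                  f"act x={a.address.x} inside concatenation {c.index}")
                    )

    objects = dialogue.objects()
    for a in acts:
        for obj in objects:
            if obj not in a.polarity:
                v.append(
                    Violation(
                        a.epsilon, "polarity_default",
                        f"no delta[{obj!r}] entry; defaulting to 0",
                        severity="warning",
                    )
                )
    return v


def _shift_epsilons(acts: Sequence[SpeechAct]) -> list:
    """Shift non-positive epsilon values to a 1-based index, preserving order.

    Transcripts sometimes index pre-task talk with zero or negative
    dialogical time; internally epsilon is 1-based.
    """
    if not acts:
        return list(acts)
    lo = min(a.epsilon for a in acts)
    if lo >= 1:
        return list(acts)
    shift = 1 - lo
    return [
        SpeechAct(a.speaker, a.epsilon + shift, a.content, a.act_type,
                  a.address, dict(a.polarity), a.decisivity)
        for a in acts
    ]


def build_dialogue(
    acts: Sequence[SpeechAct],
    theme_breaks: Optional[Iterable[int]] = None,
    *,
    identifier: str = "dialogue",
    participants: Optional[Sequence[str]] = None,
    condition: str = "",
) -> Dialogue:
    """Assemble a Dialogue from an epsilon-ordered act sequence.

    Acts are partitioned into concatenations by their x coordinate; the
    same theme may be returned to later in the exchange (back-references),
    so membership is by x, not by contiguity.  When acts carry no
    addresses, ``theme_breaks`` (a set of epsilon values at which a new
    theme opens) is used to assign them: x increments at each break and y
    counts depth within the theme.

    Raises
    ------
    ValueError
        If the act sequence is not strictly increasing in epsilon, or if
        addresses are absent and no ``theme_breaks`` policy can place them.
    """
    acts = _shift_epsilons(acts)
    eps = [a.epsilon for a in acts]
    if eps != sorted(eps) or len(set(eps)) != len(eps):
        raise ValueError("acts must be strictly increasing in epsilon")

    if any(a.address is None for a in acts):
        breaks = set(theme_breaks or ())
        unknown = breaks - set(eps)
        if unknown:
            raise ValueError(f"theme_breaks {sorted(unknown)} not observed in acts")
        x, y = 1, 0
        placed = []
        for a in acts:
            if a.epsilon in breaks and y > 0:
                x += 1
                y = 1
            else:
                y += 1
            addr = a.address if a.address is not None else Address(x, y)
            placed.append(SpeechAct(a.speaker, a.epsilon, a.content, a.act_type,
                                    addr, dict(a.polarity), a.decisivity))
        acts = placed

    by_x: dict = {}
    for a in acts:
        by_x.setdefault(a.address.x, []).append(a)
    concats = [Concatenation(index=x, acts=by_x[x]) for x in sorted(by_x)]

    if participants is None:
        seen: dict = {}
        for a in acts:
            seen.setdefault(a.speaker, None)
        participants = list(seen)
    return Dialogue(
        identifier=identifier,
        participants=list(participants),
        planes=[Plane(concatenations=concats)],
        condition=condition,
    )
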