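"""Graded-prompting cooperation scoring (TEST-ASAP protocol).

The protocol embeds three subtasks into a routine assessment session, each
dissociating a different facet of cooperation:

* **basket** -- fetch a wastebasket so a blunt pencil can be sharpened:
  explicit procedure, high interaction cost, low personal benefit;
* **door** -- close a door the experimenter "forgot": the request must be
  inferred from an indirect remark, low cost, low benefit;
* **syllogism** -- leave for lunch once the last test is announced done:
  explicit inference chain, high personal benefit, but acting means
  breaking the norm of awaiting dismissal.

Each subtask escalates through exactly three prompt levels (initial
indirect remark, indirect reformulation, direct request).  A subject's
response is summarised by the prompt level at which they complied (0, 1,
2) or 3 if they never did, plus an optional clarification-request flag.

Responses map to canonical walks on the topological grid: (1,1) is the
initial prompt, (1,2) task success, (2,2)/(2,3) the indirect-reformulation
stage, (3,4)/(3,5) the direct-reformulation stage (also where a subject's
clarification question and its answer sit), and (4,6) task failure.  These
paths are a convention of this package: every position the protocol
distinguishes is reachable, intermediate positions are always visited in
order, and the walk terminates at (1,2) exactly when the subject complied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

from .topology import OccupancyMatrix, Trajectory, occupancy, PROMPT_TASK_GRID

__all__ = [
    "SubtaskSpec",
    "ResponseLevel",
    "OutcomeTrajectory",
    "SUBTASKS",
    "SUCCESS",
    "FAILURE",
    "encode_response",
    "score_group",
]

SUCCESS = (1, 2)
FAILURE = (4, 6)


@dataclass(frozen=True)
class SubtaskSpec:
    """One subtask with its three-step prompt ladder and cost/benefit tags."""

    name: str
    prompts: tuple  # (initial indirect, indirect reformulation, direct request)
    cost: str
    benefit: str
    norm_violation: bool = False

    def __post_init__(self) -> None:
        if len(self.prompts) != 3:
            raise ValueError("a subtask has exactly three prompt levels")


#: The three canonical subtasks with their verbatim prompt ladders.  The
#: texts label simulations and reports; they carry no computational weight.
SUBTASKS: Dict[str, SubtaskSpec] = {
    "basket": SubtaskSpec(
        name="basket",
        prompts=(
            "It's badly sharpened. Here's a sharpener, but you'll need to "
            "fetch the garbage can to use it.",
            "You should sharpen your pencil; you work better with a "
            "well-sharpened pencil.",
            "Can you get me the wastebasket so I can sharpen my pencil?",
        ),
        cost="high",
        benefit="low",
    ),
    "door": SubtaskSpec(
        name="door",
        prompts=(
            "Oh, I forgot to close the door!",
            "We really should close that door.",
            "Could you go and close the door, please?",
        ),
        cost="low",
        benefit="low",
    ),
    "syllogism": SubtaskSpec(
        name="syllogism",
        prompts=(
            "That was the last test.",
            "That was the last test, we are finished.",
            "Since we have finished, can you go and get your parent now?",
        ),
        cost="low",
        benefit="high",
        norm_violation=True,
    ),
}


@dataclass(frozen=True)
class ResponseLevel:
    """Prompt level at which a subject complied (3 = never complied)."""

    level: int
    clarification: bool = False

    def __post_init__(self) -> None:
        if self.level not in (0, 1, 2, 3):
            raise ValueError(f"response level must be 0..3, got {self.level}")


@dataclass(frozen=True)
class OutcomeTrajectory:
    subject_id: str
    group: str
    subtask: str
    trajectory: Trajectory


_PATHS = {
    0: [(1, 1), SUCCESS],
    1: [(1, 1), (2, 2), (2, 3), SUCCESS],
    2: [(1, 1), (2, 2), (2, 3), (3, 4), (3, 5), SUCCESS],
    3: [(1, 1), (2, 2), (2, 3), (3, 4), (3, 5), FAILURE],
}


def encode_response(
    subtask: str,
    response: ResponseLevel,
    subject_id: str = "s1",
    group: str = "group",
) -> OutcomeTrajectory:
    """Map a response level to its canonical grid walk.

    A clarification request at level >= 1 inserts the (3,4)/(3,5)
    question-answer exchange before compliance when the path does not
    already pass through it.
    """
    if subtask not in SUBTASKS:
        raise ValueError(f"unknown subtask {subtask!r}; expected one of {sorted(SUBTASKS)}")
    path = list(_PATHS[response.level])
    if response.clarification and response.level >= 1 and (3, 4) not in path:
        path = path[:-1] + [(3, 4), (3, 5)] + path[-1:]
    return OutcomeTrajectory(
        subject_id=subject_id,
        group=group,
        subtask=subtask,
        trajectory=Trajectory(subject_id=subject_id, group=group, positions=tuple(path)),
    )


def score_group(
    responses: Sequence[ResponseLevel],
    subtask: str,
    group: str = "group",
    subject_ids: Sequence[str] = None,
) -> Tuple[OccupancyMatrix, dict]:
    """Score a group of responses into an occupancy matrix and a summary.

    The summary reports, per prompt level, the fraction of subjects who
    complied exactly there, plus the fraction who never complied
    (``never``) and the fraction not complying at the initial prompt
    (``not_immediate``).
    """
    if not responses:
        raise ValueError("score_group needs at least one response")
    if subject_ids is None:
        subject_ids = [f"s{i + 1}" for i in range(len(responses))]
    trajectories = [
        encode_response(subtask, r, subject_id=sid, group=group).trajectory
        for sid, r in zip(subject_ids, responses)
    ]
    occ = occupancy(trajectories, PROMPT_TASK_GRID)
    n = len(responses)
    summary = {
        "subtask": subtask,
        "group": group,
        "n_subjects": n,
        "fraction_level_0": sum(r.level == 0 for r in responses) / n,
        "fraction_level_1": sum(r.level == 1 for r in responses) / n,
        "fraction_level_2": sum(r.level == 2 for r in responses) / n,
        "never": sum(r.level == 3 for r in responses) / n,
        "not_immediate": sum(r.level > 0 for r in responses) / n,
        "clarifications": sum(r.clarification for r in responses) / n,
    }
    return occ, summary
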