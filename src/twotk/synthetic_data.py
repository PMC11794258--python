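"""Synthetic dialogue generator with known annotation parameters.

Clinical transcripts are rarely shareable, so every pipeline stage is
exercised on simulated two-party task dialogues whose statistical structure
is fully controlled: per-speaker act-type distributions, per-speaker (and
per-phase) probabilities of positive task and interlocutor polarity, the
conditional probability that a task-positive act is decisive, turn-taking
persistence, and an optional mid-dialogue change point at which the
task-polarity probability jumps (a "prompt" regime change).

The generator enforces the structural rule that decisivity requires
positive task polarity, so everything it emits passes validation and
satisfies the primacy inequality C <= V by construction.  Act content is a
templated placeholder ("utt-<epsilon>"); nothing downstream inspects text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np

from .core import ActType, Address, Dialogue, SpeechAct, build_dialogue
from .metrics import MetricSeries, running_vergence, DEFAULT_WINDOW
from .testasap import ResponseLevel

__all__ = [
    "GeneratorConfig",
    "generate_dialogue",
    "generate_regime_series",
    "generate_group_responses",
]

_DEFAULT_ACT_DIST = {
    ActType.MK: 0.50,
    ActType.DO: 0.15,
    ActType.DMK: 0.20,
    ActType.DC: 0.10,
    ActType.DM: 0.05,
}


def _check_prob(p: float, name: str) -> float:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {p}")
    return float(p)


@dataclass
class GeneratorConfig:
    """Parameters of one simulated dialogue.

    ``p_delta_task`` / ``p_delta_interlocutor`` may be a single float
    (both speakers, whole dialogue) or a mapping speaker -> float.  With a
    ``change_point`` set, task polarity switches to ``p_delta_task_post``
    from that dialogical time onward, emulating a prompt-induced regime
    change.
    """

    n_concatenations: int = 10
    acts_per_concatenation: Union[int, Tuple[int, int]] = (5, 15)
    speakers: Tuple[str, str] = ("Exp", "Subj")
    act_type_dist: Optional[Dict] = None  # speaker -> {ActType: p} or one dict
    p_delta_task: Union[float, Dict[str, float]] = 0.8
    p_delta_interlocutor: Union[float, Dict[str, float]] = 0.7
    p_decisive_given_positive: float = 0.6
    change_point: Optional[int] = None  # epsilon at which the task regime flips
    p_delta_task_post: Union[float, Dict[str, float]] = 0.2
    turn_persistence: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.speakers) != 2:
            raise ValueError("generator simulates two-party dialogues")
        if self.n_concatenations < 1:
            raise ValueError("need at least one concatenation")
        _check_prob(self.p_decisive_given_positive, "p_decisive_given_positive")
        _check_prob(self.turn_persistence, "turn_persistence")
        for name in ("p_delta_task", "p_delta_interlocutor", "p_delta_task_post"):
            v = getattr(self, name)
            if isinstance(v, dict):
                for k, p in v.items():
                    _check_prob(p, f"{name}[{k!r}]")
            else:
                _check_prob(v, name)

    def _per_speaker(self, value, speaker: str) -> float:
        return value[speaker] if isinstance(value, dict) else value

    def _acts_in_concat(self, rng: np.random.Generator) -> int:
        a = self.acts_per_concatenation
        if isinstance(a, int):
            n = a
        else:
            lo, hi = a
            n = int(rng.integers(lo, hi + 1))
        if n < 1:
            raise ValueError("acts per concatenation must be >= 1")
        return n

    def _type_dist(self, speaker: str) -> Dict:
        d = self.act_type_dist
        if d is None:
            d = _DEFAULT_ACT_DIST
        elif speaker in d and isinstance(d[speaker], dict):
            d = d[speaker]
        total = sum(d.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"act-type distribution sums to {total}, not 1")
        return d


def generate_dialogue(config: GeneratorConfig) -> Dialogue:
    """Simulate one annotated two-party dialogue.

    Speakers alternate, holding the floor with probability
    ``turn_persistence``.  Task polarity is Bernoulli per phase and
    speaker; decisivity is drawn only for task-positive acts, so the
    resulting dialogue always validates.
    """
    rng = np.random.default_rng(config.seed)
    types = list(ActType)
    acts = []
    epsilon = 0
    speaker_idx = int(rng.integers(0, 2))
    for x in range(1, config.n_concatenations + 1):
        n_acts = config._acts_in_concat(rng)
        for y in range(1, n_acts + 1):
            epsilon += 1
            if acts and rng.random() >= config.turn_persistence:
                speaker_idx = 1 - speaker_idx
            speaker = config.speakers[speaker_idx]
            dist = config._type_dist(speaker)
            probs = [dist.get(t, 0.0) for t in types]
            act_type = types[int(rng.choice(len(types), p=probs))]
            post = config.change_point is not None and epsilon >= config.change_point
            p_task = config._per_speaker(
                config.p_delta_task_post if post else config.p_delta_task, speaker
            )
            p_int = config._per_speaker(config.p_delta_interlocutor, speaker)
            d_task = int(rng.random() < p_task)
            d_int = int(rng.random() < p_int)
            decisive = int(d_task == 1 and rng.random() < config.p_decisive_given_positive)
            acts.append(
                SpeechAct(
                    speaker=speaker,
                    epsilon=epsilon,
                    content=f"utt-{epsilon}",
                    act_type=act_type,
                    address=Address(x, y),
                    polarity={"task": d_task, "interlocutor": d_int},
                    decisivity=decisive,
                )
            )
    dialogue = build_dialogue(
        acts,
        identifier=f"synthetic-seed{config.seed}",
        participants=list(config.speakers),
        condition="synthetic",
    )
    dialogue.state_annotations["generator_seed"] = config.seed
    return dialogue


def generate_regime_series(
    config: GeneratorConfig,
    window: Union[int, str] = DEFAULT_WINDOW,
    object_id: str = "task",
) -> MetricSeries:
    """Running-vergence series of a simulated dialogue with a regime change.

    Requires ``config.change_point`` to lie within the generated dialogue.
    """
    dialogue = generate_dialogue(config)
    n = len(dialogue.acts())
    if config.change_point is not None and not (1 <= config.change_point <= n):
        raise ValueError(f"change_point {config.change_point} outside dialogue of {n} acts")
    return running_vergence(dialogue, object_id=object_id, window=window)


def generate_group_responses(
    n_subjects: int,
    level_distribution: Sequence[float],
    clarification_rate: float = 0.0,
    seed: int = 0,
) -> list:
    """Sample per-subject graded-prompting response levels.

    ``level_distribution`` gives the probabilities of complying at prompt
    level 0, 1, 2 and of never complying (level 3); it must sum to 1.
    Clarification flags are drawn independently for levels >= 1.
    """
    dist = np.asarray(level_distribution, dtype=float)
    if dist.shape != (4,):
        raise ValueError("level_distribution needs 4 entries (levels 0..3)")
    if np.any(dist < 0) or abs(dist.sum() - 1.0) > 1e-9:
        raise ValueError("level_distribution must be non-negative and sum to 1")
    _check_prob(clarification_rate, "clarification_rate")
    rng = np.random.default_rng(seed)
    levels = rng.choice(4, size=n_subjects, p=dist)
    return [
        ResponseLevel(
            level=int(lv),
            clarification=bool(lv >= 1 and rng.random() < clarification_rate),
        )
        for lv in levels
    ]
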