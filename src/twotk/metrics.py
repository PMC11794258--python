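"""Kinetic metrics: vergence, celerity, trajectories, profiles, correlation.

Vergence ``V`` is the proportion of positively polarized speech acts
(delta = 1 toward a chosen object of analysis) among all acts of a segment:
``V = sum(kappa_i with delta=1) / sum(kappa_i)``.  Values above 0.5 read as
cooperation toward that object, below 0.5 as divergence.

Celerity ``C`` is the proportion of decisive acts (d = 1) among all acts:
``C = sum(kappa_i with d=1) / sum(kappa_i)``.  It measures how directly the
exchange advances task resolution; ``(1 - C)`` is the relative slowdown
compared with an exchange stripped of every non-decisive act.

Because a decisive act must be task-polarized (d = 1 implies delta_task = 1),
celerity never exceeds task vergence on validated input: C <= V, the primacy
inequality.  Cooperation bounds efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .core import ActType, Dialogue, SpeechAct, TASK

__all__ = [
    "MetricPoint",
    "MetricSeries",
    "ActTypeProfile",
    "CorrelationResult",
    "UndefinedMetricError",
    "DIVERGENCE_THRESHOLD",
    "vergence",
    "celerity",
    "slowdown",
    "per_concatenation_metrics",
    "running_vergence",
    "act_type_profile",
    "vc_correlation",
    "primacy_check",
]

#: Conventional cooperation threshold: V above it reads as effective
#: cooperation, below it as divergence.  Reported alongside results, never
#: hard-coded into any computation.
DIVERGENCE_THRESHOLD = 0.5

#: Default trailing window (in acts) for running vergence, sized so that
#: regime changes stay visible at typical task-dialogue lengths of a few
#: hundred acts.
DEFAULT_WINDOW = 20


class UndefinedMetricError(ValueError):
    """A metric was requested on an empty or degenerate act set."""


@dataclass(frozen=True)
class MetricPoint:
    index: int  # epsilon or concatenation number
    vergence: float
    celerity: float
    n_acts: int


@dataclass
class MetricSeries:
    """Aligned vergence/celerity values, per concatenation or per act."""

    granularity: str  # "per_concatenation" or "running_per_act"
    object_id: str
    points: list = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [p.index for p in self.points]
        if idx != sorted(set(idx)):
            raise ValueError("MetricSeries indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    @property
    def indices(self) -> np.ndarray:
        return np.array([p.index for p in self.points], dtype=int)

    @property
    def vergences(self) -> np.ndarray:
        return np.array([p.vergence for p in self.points], dtype=float)

    @property
    def celerities(self) -> np.ndarray:
        return np.array([p.celerity for p in self.points], dtype=float)


@dataclass(frozen=True)
class ActTypeProfile:
    """Per-speaker frequency of each of the five act types (proportions)."""

    speaker: str
    frequencies: dict  # ActType -> proportion

    def __getitem__(self, t: ActType) -> float:
        return self.frequencies[t]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    df: int


def _require_acts(acts: Sequence[SpeechAct], what: str) -> None:
    if len(acts) == 0:
        raise UndefinedMetricError(f"{what} is undefined on an empty act set")


def vergence(acts: Sequence[SpeechAct], object_id: str = TASK) -> float:
    """Proportion of acts positively polarized toward ``object_id``.

    Raises
    ------
    UndefinedMetricError
        On an empty act set.
    KeyError
        If any act lacks a polarity annotation for ``object_id``.
    """
    _require_acts(acts, "vergence")
    for a in acts:
        if object_id not in a.polarity:
            raise KeyError(
                f"act at epsilon={a.epsilon} has no polarity entry for {object_id!r}"
            )
    return sum(a.polarity[object_id] for a in acts) / len(acts)


def celerity(acts: Sequence[SpeechAct]) -> float:
    """Proportion of decisive acts (d = 1)."""
    _require_acts(acts, "celerity")
    return sum(a.decisivity for a in acts) / len(acts)


def slowdown(acts: Sequence[SpeechAct]) -> float:
    """Relative slowdown (1 - C) * 100, in percent.

    The fraction of the exchange that non-decisive acts add on top of a
    maximally efficient resolution.
    """
    return (1.0 - celerity(acts)) * 100.0


def per_concatenation_metrics(dialogue: Dialogue, object_id: str = TASK) -> MetricSeries:
    """One (V, C) point per concatenation, in concatenation order."""
    points = []
    for c in dialogue.concatenations():
        points.append(
            MetricPoint(
                index=c.index,
                vergence=vergence(c.acts, object_id),
                celerity=celerity(c.acts),
                n_acts=len(c.acts),
            )
        )
    return MetricSeries("per_concatenation", object_id, points)


def running_vergence(
    dialogue: Dialogue,
    object_id: str = TASK,
    window: Union[int, str] = DEFAULT_WINDOW,
    speaker: Optional[str] = None,
    strict: bool = False,
) -> MetricSeries:
    """Per-act vergence trajectory over a trailing window.

    For each act (optionally restricted to one speaker's acts), the
    vergence of the trailing ``window`` acts is reported at that act's
    epsilon; ``window="cumulative"`` uses all acts so far.  Celerity over
    the same window is carried along in each point.

    With ``strict=True`` a window longer than the dialogue is an error;
    otherwise the available prefix is used.
    """
    acts = dialogue.acts()
    if speaker is not None:
        if speaker not in dialogue.participants:
            raise ValueError(f"unknown speaker {speaker!r}")
        acts = [a for a in acts if a.speaker == speaker]
    _require_acts(acts, "running vergence")

    cumulative = window == "cumulative"
    if not cumulative:
        w = int(window)
        if w < 1:
            raise ValueError("window must be >= 1 or 'cumulative'")
        if strict and w > len(acts):
            raise ValueError(f"window {w} exceeds dialogue length {len(acts)}")

    deltas = np.array([a.delta(object_id) for a in acts], dtype=float)
    ds = np.array([a.decisivity for a in acts], dtype=float)
    points = []
    for i, a in enumerate(acts):
        lo = 0 if cumulative else max(0, i + 1 - w)
        n = i + 1 - lo
        points.append(
            MetricPoint(
                index=a.epsilon,
                vergence=float(deltas[lo : i + 1].mean()),
                celerity=float(ds[lo : i + 1].mean()),
                n_acts=n,
            )
        )
    return MetricSeries("running_per_act", object_id, points)


def act_type_profile(dialogue: Dialogue, speaker: str) -> ActTypeProfile:
    """Proportion of each act type among one speaker's acts."""
    if speaker not in dialogue.participants:
        raise ValueError(f"unknown speaker {speaker!r}")
    acts = dialogue.speaker_acts(speaker)
    if not acts:
        raise UndefinedMetricError(f"speaker {speaker!r} has no acts")
    n = len(acts)
    freq = {t: sum(1 for a in acts if a.act_type is t) / n for t in ActType}
    return ActTypeProfile(speaker=speaker, frequencies=freq)


def vc_correlation(series: MetricSeries) -> CorrelationResult:
    """Pearson correlation between paired vergence and celerity values.

    The two metrics live on the same segmentation (typically one point per
    concatenation), so their coupling is directly measurable: a strong
    positive r says efficiency tracks cooperation.  p is two-tailed from
    the t transform with n - 2 degrees of freedom.
    """
    if len(series) < 3:
        raise UndefinedMetricError("correlation needs >= 3 points")
    v = series.vergences
    c = series.celerities
    if np.ptp(v) == 0 or np.ptp(c) == 0:
        raise UndefinedMetricError("correlation undefined on a constant series")
    res = stats.pearsonr(v, c)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), df=len(series) - 2)


def primacy_check(obj: Union[Dialogue, MetricSeries, Sequence[SpeechAct]]):
    """Verify the primacy inequality C <= V.

    Accepts a dialogue (checked whole and per concatenation), a metric
    series (checked pointwise) or a bare act sequence.  Returns
    ``(ok, violating_indices)``; on validated input the check can never
    fail, since every decisive act is task-polarized by construction.
    """
    tol = 1e-12
    if isinstance(obj, MetricSeries):
        bad = [p.index for p in obj if p.celerity > p.vergence + tol]
        return (not bad, bad)
    if isinstance(obj, Dialogue):
        bad = []
        acts = obj.acts()
        if acts and celerity(acts) > vergence(acts, TASK) + tol:
            bad.append(0)  # index 0 = whole dialogue
        for c in obj.concatenations():
            if celerity(c.acts) > vergence(c.acts, TASK) + tol:
                bad.append(c.index)
        return (not bad, bad)
    acts = list(obj)
    _require_acts(acts, "primacy check")
    if celerity(acts) > vergence(acts, TASK) + tol:
        return (False, [a.epsilon for a in acts if a.decisivity == 1 and a.delta(TASK) == 0])
    return (True, [])
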