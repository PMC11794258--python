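"""Packaged fixture data.

* ``load_monte_cristo`` -- the canonical eight-act Faria/Dantes exchange
  from *The Count of Monte Cristo*, fully annotated (two thematic
  concatenations; every act task-positive, two acts non-decisive).  The
  standard worked example of the topological-kinetic encoding.
* ``load_group_responses`` -- graded-prompting response levels for the
  five-subject Shwachman-Diamond (SDS) and control groups on the three
  cooperation subtasks, encoded from the published group-level
  descriptions.
* ``load_cohort_summaries`` -- published per-group summary statistics
  (mean, SD, n) of the cognitive and socio-emotional measures for the same
  two cohorts.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, Tuple

import pandas as pd

from .core import Dialogue
from .group_analysis import GroupSummary
from .testasap import ResponseLevel
from .transcript_io import read_transcript

__all__ = [
    "load_monte_cristo",
    "load_group_responses",
    "load_cohort_summaries",
    "monte_cristo_path",
]


def _data_path(name: str):
    return resources.files("twotk.data").joinpath(name)


def monte_cristo_path() -> str:
    """Filesystem path of the packaged transcript fixture."""
    return str(_data_path("monte_cristo.tsv"))


def load_monte_cristo() -> Dialogue:
    """The annotated eight-act Monte Cristo exchange (V = 1, C = 0.75)."""
    return read_transcript(monte_cristo_path())


def load_group_responses() -> Dict[Tuple[str, str], list]:
    """Response levels keyed by (group, subtask).

    Each value is a list of :class:`~twotk.testasap.ResponseLevel`, one per
    subject, in stable subject order.
    """
    df = pd.read_csv(_data_path("group_responses.tsv"), sep="\t")
    out: Dict[Tuple[str, str], list] = {}
    for (group, subtask), rows in df.groupby(["group", "subtask"], sort=False):
        out[(group, subtask)] = [
            ResponseLevel(level=int(r.level), clarification=bool(r.clarification))
            for r in rows.itertuples()
        ]
    return out


def load_cohort_summaries() -> Dict[str, Dict[str, GroupSummary]]:
    """Per-measure, per-group summary statistics.

    Returns ``{measure: {group_label: GroupSummary}}``.  Note that only
    some published p-values reproduce from these summaries under a
    two-group test on means (Age and VS do); see the methods note.
    """
    df = pd.read_csv(_data_path("cohort_summaries.tsv"), sep="\t")
    out: Dict[str, Dict[str, GroupSummary]] = {}
    for r in df.itertuples():
        out.setdefault(r.measure, {})[r.group] = GroupSummary(
            label=r.group, mean=float(r.mean), sd=float(r.sd), n=int(r.n)
        )
    return out
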