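"""Topological encodings: act matrices, trajectories, group occupancy.

The topological matrix lays a plane's speech acts on the (x, y) grid:
themes increment along x, depth of elaboration within a theme along y.
A theme opened in reaction to an act deep in another theme may start at
y > 1, leaving the cells above it empty.

Group behaviour on a task is summarised as an occupancy matrix: for each
grid position, the fraction of subjects whose trajectory passes through it
at least once (repeat visits count once).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union
from pathlib import Path

import numpy as np

from .core import Plane, Dialogue

__all__ = [
    "TopologicalMatrix",
    "Trajectory",
    "OccupancyMatrix",
    "encode_matrix",
    "decode_matrix",
    "occupancy",
    "matrix_to_tsv",
]

#: Default grid for the graded-prompting cooperation task: covers the
#: success position (1,2), the indirect-reformulation stage (2,2)/(2,3),
#: the direct-reformulation stage (3,4)/(3,5) and the failure position
#: (4,6).  A convention of this package: extents are the smallest grid
#: containing every named position.
PROMPT_TASK_GRID = (4, 6)


@dataclass
class TopologicalMatrix:
    """Grid mapping (x, y) -> act content; at most one act per cell."""

    cells: Dict[Tuple[int, int], str]
    dims: Tuple[int, int]  # (max x, max y)

    def get(self, x: int, y: int) -> Optional[str]:
        return self.cells.get((x, y))

    def __getitem__(self, xy: Tuple[int, int]) -> Optional[str]:
        return self.cells.get(tuple(xy))


@dataclass(frozen=True)
class Trajectory:
    """One subject's ordered walk through grid positions during a task."""

    subject_id: str
    group: str
    positions: tuple  # tuple of (x, y)

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("trajectory must visit at least one position")


@dataclass
class OccupancyMatrix:
    """Per-cell probability of at-least-one visit, for one subject group."""

    group: str
    probabilities: Dict[Tuple[int, int], float]
    dims: Tuple[int, int]
    n_subjects: int

    def __getitem__(self, xy: Tuple[int, int]) -> float:
        return self.probabilities.get(tuple(xy), 0.0)

    def to_array(self) -> np.ndarray:
        """Dense (y, x) array mirroring the tabular layout (y as rows)."""
        mx, my = self.dims
        arr = np.zeros((my, mx))
        for (x, y), p in self.probabilities.items():
            arr[y - 1, x - 1] = p
        return arr


def encode_matrix(plane: Union[Plane, Dialogue]) -> TopologicalMatrix:
    """Place each act's content at its (x, y) address.

    Raises
    ------
    ValueError
        If two acts share an address or any act lacks one.
    """
    if isinstance(plane, Dialogue):
        if len(plane.planes) != 1:
            raise ValueError("encode_matrix takes a single plane")
        plane = plane.planes[0]
    cells: Dict[Tuple[int, int], str] = {}
    for act in plane.acts():
        if act.address is None:
            raise ValueError(f"act at epsilon={act.epsilon} has no address")
        key = (act.address.x, act.address.y)
        if key in cells:
            raise ValueError(f"duplicate address {key}")
        cells[key] = act.content
    if not cells:
        raise ValueError("plane has no acts to encode")
    dims = (max(x for x, _ in cells), max(y for _, y in cells))
    return TopologicalMatrix(cells=cells, dims=dims)


def decode_matrix(matrix: TopologicalMatrix) -> set:
    """The set of occupied addresses (encode round-trip check)."""
    return set(matrix.cells)


def occupancy(
    trajectories: Sequence[Trajectory],
    grid_dims: Tuple[int, int] = PROMPT_TASK_GRID,
) -> OccupancyMatrix:
    """Fraction of subjects visiting each cell at least once.

    All trajectories must belong to one group and stay within
    ``grid_dims``; a cell visited by every subject scores exactly 1 and an
    unvisited cell exactly 0, independent of trajectory order and of
    within-trajectory repeats.
    """
    if not trajectories:
        raise ValueError("occupancy needs at least one trajectory")
    groups = {t.group for t in trajectories}
    if len(groups) > 1:
        raise ValueError(f"trajectories span multiple groups: {sorted(groups)}")
    mx, my = grid_dims
    counts: Dict[Tuple[int, int], int] = {}
    for t in trajectories:
        for (x, y) in t.positions:
            if not (1 <= x <= mx and 1 <= y <= my):
                raise ValueError(
                    f"subject {t.subject_id!r}: position {(x, y)} outside grid {grid_dims}"
                )
        for pos in set(t.positions):
            counts[pos] = counts.get(pos, 0) + 1
    n = len(trajectories)
    return OccupancyMatrix(
        group=groups.pop(),
        probabilities={pos: c / n for pos, c in counts.items()},
        dims=grid_dims,
        n_subjects=n,
    )


def matrix_to_tsv(
    matrix: Union[TopologicalMatrix, OccupancyMatrix],
    path: Optional[Union[str, Path]] = None,
) -> str:
    """Tabulate a matrix with x as columns and y as rows.

    Returns the TSV text; writes it to ``path`` when given.
    """
    mx, my = matrix.dims
    header = "y\\x\t" + "\t".join(str(x) for x in range(1, mx + 1))
    rows = [header]
    for y in range(1, my + 1):
        cells = []
        for x in range(1, mx + 1):
            v = matrix[(x, y)]
            if v is None:
                cells.append("")
            elif isinstance(v, float):
                cells.append(f"{v:.6g}")
            else:
                cells.append(str(v).replace("\t", " "))
        rows.append(f"{y}\t" + "\t".join(cells))
    text = "\n".join(rows) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
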