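"""Workspace geometry and the target grid of the visual-matching task.

The measurement workspace is a rectangle in front of the seated
participant, 487.6 mm wide and 269.6 mm deep, with its near edge 200 mm
from the body.  One hundred visual targets tile it as a 5 (row) x 20
(column) matrix; row 1 is nearest the body and column 1 is leftmost.

Coordinates are in mm throughout this module.  The body midline is x = 0
and y increases away from the body, so all target y >= body_offset.
Targets sit at cell centers: the printed inter-column spacing (24.38 mm)
and inter-row spacing (53.92 mm) equal extent/count, which is the
cell-center convention, not a fence-post one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WorkspaceGeometry", "TargetGrid", "make_target_grid"]


@dataclass(frozen=True)
class WorkspaceGeometry:
    """Dimensions of the tablet workspace and the target lattice on it."""

    width: float = 487.6  # mediolateral extent, mm
    depth: float = 269.6  # near-far extent, mm
    body_offset: float = 200.0  # body to near workspace edge, mm
    n_rows: int = 5
    n_cols: int = 20

    def __post_init__(self) -> None:
        if self.width <= 0 or self.depth <= 0 or self.body_offset <= 0:
            raise ValueError("workspace dimensions must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def n_targets(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def col_spacing(self) -> float:
        return self.width / self.n_cols

    @property
    def row_spacing(self) -> float:
        return self.depth / self.n_rows


@dataclass(frozen=True)
class TargetGrid:
    """Cell-center target coordinates on the workspace lattice.

    ``x`` has shape (n_cols,), symmetric about the body midline;
    ``y`` has shape (n_rows,), increasing away from the body.
    ``positions`` has shape (n_rows, n_cols, 2) with (x, y) per target.
    """

    geometry: WorkspaceGeometry
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    @property
    def positions(self) -> np.ndarray:
        xx, yy = np.meshgrid(self.x, self.y)  # (n_rows, n_cols)
        return np.stack([xx, yy], axis=-1)

    @property
    def n_targets(self) -> int:
        return self.geometry.n_targets

    def target_position(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) of the 1-based (row, col) target."""
        if not (1 <= row <= self.geometry.n_rows):
            raise IndexError(f"row {row} outside 1..{self.geometry.n_rows}")
        if not (1 <= col <= self.geometry.n_cols):
            raise IndexError(f"col {col} outside 1..{self.geometry.n_cols}")
        return float(self.x[col - 1]), float(self.y[row - 1])


def make_target_grid(geometry: WorkspaceGeometry | None = None) -> TargetGrid:
    """Lay out the target lattice for a workspace.

    Targets are centered in their grid cells:
    ``x_j = -width/2 + (j - 0.5) * width/n_cols`` and
    ``y_i = body_offset + (i - 0.5) * depth/n_rows`` (1-based i, j).
    """
    geom = geometry if geometry is not None else WorkspaceGeometry()
    j = np.arange(1, geom.n_cols + 1)
    i = np.arange(1, geom.n_rows + 1)
    x = -geom.width / 2.0 + (j - 0.5) * geom.col_spacing
    y = geom.body_offset + (i - 0.5) * geom.row_spacing
    return TargetGrid(geometry=geom, x=x, y=y)
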