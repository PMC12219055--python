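"""Whisker array geometry and the matching barrel-column map.

The task stimulates a 3x3 grid of whiskers (rows x arcs). Cortical
coordinates place one barrel-column centroid per whisker on a regular
lattice. Grid coordinates use the convention: x along the arc axis
(rostral positive), y along the row axis (up positive), so offsets from
a reference whisker live on the integer lattice {-1, 0, 1}^2 for its
immediate neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WhiskerGrid", "generate_whisker_grid", "OFFSET_CLASSES"]

#: Somatotopic offset classes of a prior-hit whisker relative to the
#: current whisker, ordered by proximity.
OFFSET_CLASSES = ("same", "same-row adjacent", "same-arc adjacent",
                  "diagonal adjacent", "further")


@dataclass(frozen=True)
class WhiskerGrid:
    """A rows x arcs whisker array with its barrel-column lattice.

    coordinates maps whisker label -> (x, y) integer grid position;
    barrel_centroids maps whisker label -> (x_um, y_um) cortical position.
    """

    rows: tuple[str, ...]
    arcs: tuple[str, ...]
    coordinates: dict[str, tuple[int, int]] = field(repr=False)
    barrel_centroids: dict[str, tuple[float, float]] = field(repr=False)
    mean_barrel_width: float

    def __post_init__(self):
        if self.mean_barrel_width <= 0:
            raise ValueError("mean_barrel_width must be positive")
        coords = list(self.coordinates.values())
        if len(set(coords)) != len(coords):
            raise ValueError("whisker grid coordinates must be unique")

    @property
    def whiskers(self) -> tuple[str, ...]:
        """All whisker labels in row-major order (row, then arc)."""
        return tuple(f"{r}{a}" for r in self.rows for a in self.arcs)

    def offset(self, whisker: str, reference: str) -> tuple[int, int]:
        """Grid offset (dx, dy) of ``whisker`` relative to ``reference``."""
        x, y = self.coordinates[whisker]
        xr, yr = self.coordinates[reference]
        return (x - xr, y - yr)

    def offset_class(self, whisker: str, reference: str) -> str:
        """Somatotopic class of ``whisker`` relative to ``reference``."""
        dx, dy = self.offset(whisker, reference)
        if dx == 0 and dy == 0:
            return "same"
        if dy == 0 and abs(dx) == 1:
            return "same-row adjacent"
        if dx == 0 and abs(dy) == 1:
            return "same-arc adjacent"
        if abs(dx) == 1 and abs(dy) == 1:
            return "diagonal adjacent"
        return "further"

    def centroid(self, whisker: str) -> np.ndarray:
        return np.asarray(self.barrel_centroids[whisker], dtype=float)

    def column_distance(self, xy_um, whisker: str) -> float:
        """Distance (µm) from a cortical point to a whisker's column center."""
        return float(np.linalg.norm(np.asarray(xy_um, dtype=float)
                                    - self.centroid(whisker)))

    def nearest_column(self, xy_um) -> str:
        """Column label whose centroid is nearest to a cortical point."""
        return min(self.barrel_centroids,
                   key=lambda w: self.column_distance(xy_um, w))


def generate_whisker_grid(
    rows=("C", "D", "E"),
    arcs=("1", "2", "3"),
    barrel_pitch: float = 300.0,
) -> WhiskerGrid:
    """Build a regular rows x arcs whisker grid.

    Grid x increases with arc index (rostral positive), y decreases with
    row index (upper rows positive), centered so the middle whisker of an
    odd grid sits at (0, 0). Barrel centroids form a lattice with spacing
    ``barrel_pitch`` µm; with circular barrels the mean barrel width
    equals the pitch.
    """
    rows = tuple(str(r) for r in rows)
    arcs = tuple(str(a) for a in arcs)
    if not rows or not arcs:
        raise ValueError("rows and arcs must be non-empty")
    x0 = (len(arcs) - 1) / 2.0
    y0 = (len(rows) - 1) / 2.0
    coordinates: dict[str, tuple[int, int]] = {}
    centroids: dict[str, tuple[float, float]] = {}
    for i, r in enumerate(rows):
        for j, a in enumerate(arcs):
            label = f"{r}{a}"
            gx = j - x0
            gy = y0 - i
            coordinates[label] = (int(round(gx)), int(round(gy)))
            centroids[label] = (gx * barrel_pitch, gy * barrel_pitch)
    return WhiskerGrid(rows=rows, arcs=arcs, coordinates=coordinates,
                       barrel_centroids=centroids,
                       mean_barrel_width=float(barrel_pitch))
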