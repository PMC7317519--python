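"""Cubic analysis grids and scalar-field I/O.

All pharmacophore fields in this package live on a cubic, axis-aligned grid
placed over the binding pocket. The grid is defined by its geometric center,
its edge length and the spacing between neighbouring points; grid point
``(i, j, k)`` sits at ``center - edge/2 + (i, j, k) * spacing``. Coordinates
are in Ångström throughout, indices are 0-based, and point assignment is by
nearest grid point with ties broken towards the lower index so that binning
is deterministic.

Scalar fields are exported in the OpenDX regular-grid format, readable by
common molecular visualisation tools (PyMOL, VMD, LigandScout).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from gridData import Grid as _DXGrid

__all__ = [
    "GridSpec",
    "ScalarField",
    "make_grid",
    "write_dx",
    "read_dx",
]


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Cubic grid over the binding pocket.

    Parameters
    ----------
    center : (3,) float array, Å
    edge_length : float, Å
        Full extent of the cube along each axis.
    spacing : float, Å
        Distance between neighbouring grid points; must divide the edge
        length to within 1e-9 relative tolerance.
    """

    center: tuple[float, float, float]
    edge_length: float
    spacing: float
    points_per_axis: int

    @property
    def origin(self) -> np.ndarray:
        """Coordinate of grid point (0, 0, 0): ``center - edge/2``."""
        return np.asarray(self.center, dtype=float) - self.edge_length / 2.0

    @property
    def n_points(self) -> int:
        return self.points_per_axis**3

    def point_coords(self, idx: np.ndarray) -> np.ndarray:
        """Map integer indices ``(..., 3)`` to Cartesian coordinates."""
        idx = np.asarray(idx)
        return self.origin + idx * self.spacing

    def nearest_index(self, coords: np.ndarray) -> np.ndarray:
        """Nearest grid index for Cartesian coordinates ``(..., 3)``.

        Ties (coordinates exactly halfway between two grid points) are
        assigned to the lower index. Indices are not clipped; use
        :meth:`contains` to test whether a coordinate falls on the grid.
        """
        frac = (np.asarray(coords, dtype=float) - self.origin) / self.spacing
        # floor(x + 0.5) rounds half up; shift exact halves down to the
        # lower index for deterministic tie-breaking.
        shifted = frac + 0.5
        idx = np.floor(shifted)
        tie = shifted == idx  # frac was exactly k + 0.5
        return (idx - tie).astype(int)

    def contains(self, coords: np.ndarray) -> np.ndarray:
        """Boolean mask: does each coordinate lie inside the cube?

        The cube is closed on all faces: ``origin <= x <= origin + edge``.
        """
        coords = np.asarray(coords, dtype=float)
        lo = self.origin
        hi = lo + self.edge_length
        return np.all((coords >= lo) & (coords <= hi), axis=-1)

    def axis_coords(self) -> np.ndarray:
        """1-D coordinates along one axis (identical for all three)."""
        return self.origin[0] + np.arange(self.points_per_axis) * self.spacing


def make_grid(center, edge_length: float, spacing: float) -> GridSpec:
    """Create a cubic :class:`GridSpec`.

    Raises
    ------
    ValueError
        If ``edge_length`` or ``spacing`` is non-positive, or if the ratio
        ``edge_length / spacing`` is not an integer (within 1e-9 relative
        tolerance) — the grid must place a point on both faces.
    """
    center = tuple(float(c) for c in center)
    if len(center) != 3:
        raise ValueError(f"center must be a 3-vector, got {center!r}")
    edge_length = float(edge_length)
    spacing = float(spacing)
    if edge_length <= 0:
        raise ValueError(f"edge_length must be > 0, got {edge_length}")
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    ratio = edge_length / spacing
    n_cells = round(ratio)
    if n_cells < 1 or abs(ratio - n_cells) > 1e-9 * max(1.0, abs(ratio)):
        raise ValueError(
            f"edge_length ({edge_length} Å) is not an integer multiple of "
            f"spacing ({spacing} Å): ratio = {ratio}"
        )
    return GridSpec(
        center=center,
        edge_length=edge_length,
        spacing=spacing,
        points_per_axis=int(n_cells) + 1,
    )


@dataclasses.dataclass
class ScalarField:
    """One scalar value per grid point, indexed ``values[ix, iy, iz]``."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self):
        n = self.grid.points_per_axis
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({n}, {n}, {n})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")

    @classmethod
    def zeros(cls, grid: GridSpec) -> "ScalarField":
        n = grid.points_per_axis
        return cls(grid=grid, values=np.zeros((n, n, n)))

    def max_position(self) -> np.ndarray:
        """Coordinate of the maximum value (ties: lowest flat C-order index)."""
        flat = int(np.argmax(self.values))
        idx = np.unravel_index(flat, self.values.shape)
        return self.grid.point_coords(np.array(idx))


def write_dx(field: ScalarField, path) -> None:
    """Write a scalar field as an OpenDX regular-grid file."""
    g = field.grid
    delta = np.full(3, g.spacing)
    dx = _DXGrid(field.values, origin=g.origin, delta=delta)
    dx.export(str(path), file_format="dx")


def read_dx(path) -> ScalarField:
    """Read an OpenDX regular-grid file written by :func:`write_dx`.

    The grid metadata (origin, spacing, shape) must describe a cubic grid
    with uniform spacing; otherwise a ``ValueError`` is raised.
    """
    dx = _DXGrid(str(path))
    shape = dx.grid.shape
    if len(shape) != 3 or len(set(shape)) != 1:
        raise ValueError(f"not a cubic grid: shape {shape}")
    deltas = [float(dx.delta[i]) for i in range(3)]
    if not np.allclose(deltas, deltas[0], rtol=1e-9, atol=1e-12):
        raise ValueError(f"anisotropic spacing {deltas} not supported")
    spacing = deltas[0]
    n = shape[0]
    edge = spacing * (n - 1)
    origin = np.asarray(dx.origin, dtype=float)
    center = origin + edge / 2.0
    grid = GridSpec(
        center=tuple(center),
        edge_length=edge,
        spacing=spacing,
        points_per_axis=n,
    )
    return ScalarField(grid=grid, values=np.asarray(dx.grid, dtype=float))
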