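"""Trajectory loading, time-window slicing, and grid-placement diagnostics.

Trajectories are read with MDAnalysis (multi-model PDB as the reference
interchange format; DCD/XTC work wherever MDAnalysis provides a reader) and
materialised into an in-memory :class:`TrajectoryView` holding per-frame
coordinates for a named selection plus atom metadata. Trajectories are
assumed pre-aligned on the protein; no fitting is performed here.

Water molecules are identified by residue name (configurable whitelist) and
represented by their oxygen atom only.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

import MDAnalysis as mda

__all__ = [
    "WATER_RESNAMES",
    "TrajectoryView",
    "GridPlacementReport",
    "load_trajectory",
    "slice_frames",
    "expected_frame_count",
    "grid_test_report",
]

#: Default residue-name whitelist identifying water molecules.
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "TIP4", "SOL", "T4P"})


@dataclasses.dataclass
class TrajectoryView:
    """In-memory view of a trajectory selection.

    Attributes
    ----------
    frame_times : (n_frames,) float array, ps
        Strictly increasing frame times.
    coords : (n_frames, n_atoms, 3) float array, Å
    atoms : pandas.DataFrame
        One row per atom with columns ``name``, ``resname``, ``resid``,
        ``element``.
    water_resnames : frozenset of str
        Residue names treated as water in this view.
    """

    frame_times: np.ndarray
    coords: np.ndarray
    atoms: pd.DataFrame
    water_resnames: frozenset = WATER_RESNAMES

    def __post_init__(self):
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (n_frames, n_atoms, 3), got {self.coords.shape}")
        if len(self.frame_times) != self.coords.shape[0]:
            raise ValueError("frame_times and coords disagree on frame count")
        if len(self.atoms) != self.coords.shape[1]:
            raise ValueError("atom table and coords disagree on atom count")
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def water_oxygen_indices(self) -> np.ndarray:
        """Indices of water oxygen atoms (water position = oxygen only)."""
        is_water = self.atoms["resname"].isin(self.water_resnames)
        is_oxy = self.atoms["element"].str.upper() == "O"
        return np.flatnonzero(is_water & is_oxy)

    @property
    def protein_atom_indices(self) -> np.ndarray:
        """Indices of non-water atoms."""
        return np.flatnonzero(~self.atoms["resname"].isin(self.water_resnames))

    def water_coords(self, frame: int) -> np.ndarray:
        return self.coords[frame, self.water_oxygen_indices]


@dataclasses.dataclass
class GridPlacementReport:
    """Diagnostics for choosing where to place the analysis grid.

    ``octant_counts`` orders octants by the sign pattern of (x, y, z)
    relative to the grid center: index ``b`` has bit 0 = x >= center_x,
    bit 1 = y >= center_y, bit 2 = z >= center_z.
    """

    mean_waters_in_grid: float
    octant_counts: np.ndarray  # (8,) mean per-frame counts
    fraction_inside: float
    suggested_shift: np.ndarray  # (3,) Å

    def __post_init__(self):
        if not 0.0 <= self.fraction_inside <= 1.0:
            raise ValueError("fraction_inside must lie in [0, 1]")
        if np.any(np.asarray(self.octant_counts) < 0):
            raise ValueError("octant counts must be >= 0")


def _elements_from(atoms: mda.AtomGroup) -> list[str]:
    try:
        return [str(e) for e in atoms.elements]
    except mda.exceptions.NoDataError:
        return [mda.topology.guessers.guess_atom_element(n) for n in atoms.names]


def load_trajectory(
    topology_path,
    trajectory_paths=None,
    selection: str = "all",
    *,
    dt: float | None = None,
    water_resnames: Sequence[str] | frozenset = WATER_RESNAMES,
) -> TrajectoryView:
    """Load a trajectory selection into memory.

    Parameters
    ----------
    topology_path : path
        Topology naming residues and atoms (PDB works as both topology and
        trajectory when ``trajectory_paths`` is omitted).
    trajectory_paths : path or list of paths, optional
        Coordinate file(s) (multi-model PDB, DCD, XTC, ...).
    selection : str
        MDAnalysis selection string; the shorthand ``"water"`` is expanded
        to the residue-name whitelist so that fixture waters are found
        regardless of force-field naming.
    dt : float, optional
        Frame spacing in ps to assign when the format carries no time
        information (e.g. PDB models); frame ``i`` gets time ``(i + 1)·dt``,
        matching the convention that the saved trajectory starts after the
        first integration interval.

    Raises
    ------
    ValueError
        If the selection matches no atoms.
    """
    water_resnames = frozenset(water_resnames)
    if trajectory_paths is None:
        u = mda.Universe(str(topology_path))
    else:
        if isinstance(trajectory_paths, (str, bytes)) or hasattr(trajectory_paths, "__fspath__"):
            trajectory_paths = [trajectory_paths]
        u = mda.Universe(str(topology_path), *[str(p) for p in trajectory_paths])

    sel = selection.strip()
    if sel == "water":
        sel = "resname " + " ".join(sorted(water_resnames))
    atoms = u.select_atoms(sel)
    if len(atoms) == 0:
        raise ValueError(f"selection {selection!r} matched no atoms")

    elements = _elements_from(atoms)
    table = pd.DataFrame(
        {
            "name": [str(n) for n in atoms.names],
            "resname": [str(r) for r in atoms.resnames],
            "resid": [int(r) for r in atoms.resids],
            "element": elements,
        }
    )

    n_frames = len(u.trajectory)
    coords = np.empty((n_frames, len(atoms), 3))
    times = np.empty(n_frames)
    for i, ts in enumerate(u.trajectory):
        coords[i] = atoms.positions
        if dt is None:
            with warnings.catch_warnings():
                # readers without time metadata warn and report index-based
                # times; that fallback is exactly what we want here
                warnings.filterwarnings("ignore", message=".*no dt information.*")
                times[i] = ts.time
    if dt is not None:
        times = (np.arange(n_frames) + 1) * float(dt)
    elif len(times) > 1 and not np.all(np.diff(times) > 0):
        # formats without time info report 0 everywhere; fall back to 1 ps
        times = np.arange(n_frames) + 1.0

    return TrajectoryView(
        frame_times=times, coords=coords, atoms=table, water_resnames=water_resnames
    )


def slice_frames(traj: TrajectoryView, t_start: float, t_end: float) -> TrajectoryView:
    """Keep frames with ``t_start < t <= t_end`` (times in ps).

    The half-open window matches the convention of analysing "the last
    N ns": slicing (20 ns, 30 ns] of a 30 ns / 10 ps run keeps exactly
    1000 frames and excludes the frame at 20 ns itself.

    Raises
    ------
    ValueError
        If ``t_start >= t_end`` or the window selects no frames.
    """
    if t_start >= t_end:
        raise ValueError(f"empty window: t_start={t_start} >= t_end={t_end}")
    mask = (traj.frame_times > t_start) & (traj.frame_times <= t_end)
    if not mask.any():
        raise ValueError(
            f"window ({t_start}, {t_end}] ps selects no frames; trajectory "
            f"covers [{traj.frame_times[0]}, {traj.frame_times[-1]}] ps"
        )
    return TrajectoryView(
        frame_times=traj.frame_times[mask],
        coords=traj.coords[mask],
        atoms=traj.atoms,
        water_resnames=traj.water_resnames,
    )


def expected_frame_count(duration_ns: float, save_interval_ps: float) -> int:
    """Number of saved frames for a run of ``duration_ns`` at the given
    save interval; the t=0 configuration is not counted.

    30 ns saved every 10 ps gives 3000 frames.
    """
    if duration_ns <= 0:
        raise ValueError("duration must be > 0")
    if save_interval_ps <= 0:
        raise ValueError("save interval must be > 0")
    return int(np.floor(duration_ns * 1000.0 / save_interval_ps))


def grid_test_report(traj: TrajectoryView, grid) -> GridPlacementReport:
    """Water statistics for a candidate grid placement.

    Reports the mean per-frame water count inside the grid, the split of
    that count over the eight octants around the grid center, the fraction
    of all waters that fall inside, and a suggested center shift — the
    vector from the grid center to the centroid of in-grid waters. A
    well-placed grid has a small suggested shift and balanced octants.
    """
    center = np.asarray(grid.center, dtype=float)
    n_frames = traj.n_frames
    octants = np.zeros(8)
    total_inside = 0
    total_waters = 0
    centroid_sum = np.zeros(3)
    for f in range(n_frames):
        w = traj.water_coords(f)
        total_waters += len(w)
        if len(w) == 0:
            continue
        inside = grid.contains(w)
        win = w[inside]
        total_inside += len(win)
        if len(win) == 0:
            continue
        centroid_sum += win.sum(axis=0)
        ge = win >= center  # (n, 3) sign pattern
        codes = ge[:, 0].astype(int) | (ge[:, 1].astype(int) << 1) | (ge[:, 2].astype(int) << 2)
        octants += np.bincount(codes, minlength=8)
    if total_inside > 0:
        shift = centroid_sum / total_inside - center
    else:
        shift = np.zeros(3)
    frac = total_inside / total_waters if total_waters else 0.0
    return GridPlacementReport(
        mean_waters_in_grid=total_inside / n_frames,
        octant_counts=octants / n_frames,
        fraction_inside=frac,
        suggested_shift=shift,
    )
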