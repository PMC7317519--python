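"""Dynamic molecular interaction fields (dMIFs).

A dMIF is a per-feature-class scalar field over the analysis grid, built by
profiling the protein environment of every water molecule in every frame of
an MD trajectory. Each water oxygen inside the grid is asked, frame by
frame: which ligand interactions could a ligand atom placed here form with
the protein? A protein hydrogen-bond donor pointing at the water means a
ligand *acceptor* could sit there (class HBA); a protein acceptor means a
ligand *donor* could (HBD); a nearby carboxylate means a positively
ionizable group would be rewarded (PI); a cationic side chain marks a
negative-ionizable site (NI); apolar protein atoms within contact range
count towards the hydrophobic field (H); aromatic ring centroids in the
stacking distance band towards the aromatic field (AR).

Counts are deposited on the grid point nearest the water oxygen and, after
the last frame, scaled by ``100 / n_frames``. A site occupied every frame
with a single qualifying partner therefore scores 100; hydrophobic scores
can exceed 100 because several contacts per water are summed. Scores are
per-frame frequencies, so they are independent of trajectory length.

Geometric criteria (distance windows, donor angle) are conventional
hydrogen-bond/contact definitions and fully configurable via
:class:`GeometryParams`. With ``heavy_atom_only`` set, hydrogen-bond checks
use heavy-atom distances only — useful when water hydrogens are absent or
their orientations are not meaningful (as in synthetic fixtures).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .grids import GridSpec, ScalarField
from .trajectory import TrajectoryView

__all__ = [
    "FEATURE_CLASSES",
    "GeometryParams",
    "AtomRoles",
    "InteractionCounts",
    "DMIFSet",
    "assign_atom_roles",
    "water_environment",
    "accumulate",
    "half_max_cutoff",
]

#: The six pharmacophore feature classes mapped by dMIFs.
FEATURE_CLASSES = ("HBA", "HBD", "PI", "NI", "H", "AR")


@dataclasses.dataclass(frozen=True)
class GeometryParams:
    """Geometric interaction criteria (distances in Å, angles in degrees).

    Defaults are conventional cutoffs: hydrogen bonds at heavy-atom
    distance 2.5–3.6 Å with donor angle ≥ 130°, ionic contacts ≤ 4.0 Å,
    hydrophobic contacts ≤ 4.1 Å, aromatic centroid distance 3.1–6.0 Å.
    """

    hb_dist_min: float = 2.5
    hb_dist_max: float = 3.6
    hb_angle_min: float = 130.0
    ionic_dist_max: float = 4.0
    hydrophobic_dist_max: float = 4.1
    aromatic_dist_min: float = 3.1
    aromatic_dist_max: float = 6.0
    heavy_atom_only: bool = False

    def __post_init__(self):
        for lo, hi, what in [
            (self.hb_dist_min, self.hb_dist_max, "hb_dist"),
            (self.aromatic_dist_min, self.aromatic_dist_max, "aromatic_dist"),
        ]:
            if not 0 < lo < hi:
                raise ValueError(f"need 0 < {what}_min < {what}_max, got {lo}, {hi}")
        if self.ionic_dist_max <= 0 or self.hydrophobic_dist_max <= 0:
            raise ValueError("distance cutoffs must be > 0")


# ---------------------------------------------------------------------------
# Residue chemistry tables (standard amino-acid naming, PDB v3 atom names).
# An atom may carry several roles; ring groups are disjoint atom-name sets.
# ---------------------------------------------------------------------------

_BACKBONE_ACCEPTORS = {"O", "OXT"}
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1"},  # default tautomer: NE2-H, ND1 lone pair
    "HSD": {"NE2"},
    "HID": {"NE2"},
    "HSE": {"ND1"},
    "HIE": {"ND1"},
    "ACE": {"O"},
}

# donor heavy atom -> names of its hydrogens (used for the angle criterion
# when present in the topology)
_BACKBONE_DONOR_H = ("H", "HN", "H1", "H2", "H3")
_SIDECHAIN_DONORS: dict[str, dict[str, tuple[str, ...]]] = {
    "ARG": {"NE": ("HE",), "NH1": ("HH11", "HH12"), "NH2": ("HH21", "HH22")},
    "LYS": {"NZ": ("HZ1", "HZ2", "HZ3")},
    "ASN": {"ND2": ("HD21", "HD22")},
    "GLN": {"NE2": ("HE21", "HE22")},
    "TRP": {"NE1": ("HE1",)},
    "SER": {"OG": ("HG",)},
    "THR": {"OG1": ("HG1",)},
    "TYR": {"OH": ("HH",)},
    "HIS": {"NE2": ("HE2",)},
    "HSD": {"ND1": ("HD1",)},
    "HID": {"ND1": ("HD1",)},
    "HSE": {"NE2": ("HE2",)},
    "HIE": {"NE2": ("HE2",)},
    "HIP": {"ND1": ("HD1",), "NE2": ("HE2",)},
    "HSP": {"ND1": ("HD1",), "NE2": ("HE2",)},
    "NME": {"N": ("H", "HN")},
}

_ANIONIC_GROUPS = {
    "ASP": ("OD1", "OD2", "CG"),
    "GLU": ("OE1", "OE2", "CD"),
}
_CTERM_GROUP = ("O", "OXT", "C")

_CATIONIC_GROUPS = {
    "LYS": ("NZ",),
    "ARG": ("CZ", "NH1", "NH2", "NE"),
    "HIP": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "HSP": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

_AROMATIC_RINGS: dict[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"),
    ),
}
for _h in ("HIS", "HSD", "HID", "HSE", "HIE", "HIP", "HSP"):
    _AROMATIC_RINGS[_h] = (("CG", "ND1", "CD2", "CE1", "NE2"),)

# C/S side-chain atoms with no bonded N or O
_HYDROPHOBIC = {
    "ALA": {"CB"},
    "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "ILE": {"CB", "CG1", "CG2", "CD1", "CD"},
    "MET": {"CB", "CG", "SD", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
    "TRP": {"CB", "CG", "CD2", "CE3", "CZ3", "CH2", "CZ2"},
    "PRO": {"CB", "CG"},
    "LYS": {"CB", "CG", "CD"},
    "ARG": {"CB", "CG"},
    "GLU": {"CB", "CG"},
    "GLN": {"CB", "CG"},
    "ASP": {"CB"},
    "ASN": {"CB"},
    "THR": {"CG2"},
    "CYS": {"CB", "SG"},
    "ACE": {"CH3"},
}
for _h in ("HIS", "HSD", "HID", "HSE", "HIE", "HIP", "HSP"):
    _HYDROPHOBIC[_h] = {"CB"}

_KNOWN_RESIDUES = (
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
        "ACE", "NME",
    }
    | {"HSD", "HID", "HSE", "HIE", "HIP", "HSP"}
)


@dataclasses.dataclass
class AtomRoles:
    """Interaction roles assigned to the atoms of a trajectory selection.

    All indices refer to columns of ``TrajectoryView.coords``. Group
    centroids (rings, charged groups) are recomputed per frame from the
    member atoms.
    """

    acceptor_idx: np.ndarray
    donors: list[tuple[int, np.ndarray]]  # (heavy atom idx, H atom idxs)
    hydrophobic_idx: np.ndarray
    aromatic_rings: list[np.ndarray]
    cationic_groups: list[np.ndarray]
    anionic_groups: list[np.ndarray]
    excluded_residues: list[tuple[str, int]]

    @property
    def donor_idx(self) -> np.ndarray:
        return np.array([d[0] for d in self.donors], dtype=int)


def assign_atom_roles(traj: TrajectoryView) -> AtomRoles:
    """Dictionary-driven role typing of protein atoms.

    Standard residues are typed from (residue name, atom name) tables:
    backbone and side-chain O/N acceptors, N–H and O–H donors, Asp/Glu
    carboxylates and the C-terminus as anionic centers, Lys/Arg/His(+) as
    cationic centers, Phe/Tyr/Trp/His rings as aromatic groups, and C/S
    atoms with no bonded N/O as hydrophobic. Water residues are skipped.
    Residues with no rule are collected in ``excluded_residues`` and
    reported with a warning, never silently dropped.
    """
    atoms = traj.atoms
    acceptors: list[int] = []
    donors: list[tuple[int, np.ndarray]] = []
    hydrophobic: list[int] = []
    rings: list[np.ndarray] = []
    cations: list[np.ndarray] = []
    anions: list[np.ndarray] = []
    excluded: list[tuple[str, int]] = []

    for (resid, resname), res in atoms.groupby(["resid", "resname"], sort=True):
        resname = str(resname)
        if resname in traj.water_resnames:
            continue
        if resname not in _KNOWN_RESIDUES:
            excluded.append((resname, int(resid)))
            continue
        by_name = {str(row["name"]): int(i) for i, row in res.iterrows()}

        for aname, i in by_name.items():
            if aname in _BACKBONE_ACCEPTORS or aname in _SIDECHAIN_ACCEPTORS.get(resname, ()):
                acceptors.append(i)
            if aname in _HYDROPHOBIC.get(resname, ()):
                hydrophobic.append(i)

        if "N" in by_name and resname != "PRO" and resname != "ACE":
            h_idx = [by_name[h] for h in _BACKBONE_DONOR_H if h in by_name]
            donors.append((by_name["N"], np.array(h_idx, dtype=int)))
        for heavy, h_names in _SIDECHAIN_DONORS.get(resname, {}).items():
            if heavy in by_name:
                h_idx = [by_name[h] for h in h_names if h in by_name]
                donors.append((by_name[heavy], np.array(h_idx, dtype=int)))

        for ring_names in _AROMATIC_RINGS.get(resname, ()):
            members = [by_name[a] for a in ring_names if a in by_name]
            if len(members) >= 5:
                rings.append(np.array(members, dtype=int))

        grp = _CATIONIC_GROUPS.get(resname)
        if grp is not None:
            members = [by_name[a] for a in grp if a in by_name]
            if members:
                cations.append(np.array(members, dtype=int))
        grp = _ANIONIC_GROUPS.get(resname)
        if grp is not None:
            members = [by_name[a] for a in grp if a in by_name]
            if members:
                anions.append(np.array(members, dtype=int))
        if "OXT" in by_name:  # C-terminal carboxylate
            members = [by_name[a] for a in _CTERM_GROUP if a in by_name]
            anions.append(np.array(members, dtype=int))

    if excluded:
        warnings.warn(
            f"{len(excluded)} residue(s) without typing rules excluded: "
            f"{sorted(set(excluded))[:10]}",
            stacklevel=2,
        )
    return AtomRoles(
        acceptor_idx=np.array(sorted(acceptors), dtype=int),
        donors=donors,
        hydrophobic_idx=np.array(sorted(hydrophobic), dtype=int),
        aromatic_rings=rings,
        cationic_groups=cations,
        anionic_groups=anions,
        excluded_residues=excluded,
    )


@dataclasses.dataclass(frozen=True)
class InteractionCounts:
    """Interaction partners of one water in one frame, per feature class."""

    HBA: int = 0
    HBD: int = 0
    PI: int = 0
    NI: int = 0
    H: int = 0
    AR: int = 0

    def as_dict(self) -> dict[str, int]:
        return {c: getattr(self, c) for c in FEATURE_CLASSES}


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a–b–c in degrees."""
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def water_environment(
    frame_coords: np.ndarray,
    water_pos: np.ndarray,
    roles: AtomRoles,
    params: GeometryParams,
    water_h_pos: np.ndarray | None = None,
) -> InteractionCounts:
    """Count interaction partners of a single water oxygen in one frame.

    Parameters
    ----------
    frame_coords : (n_atoms, 3) array
        Coordinates of the full selection for this frame.
    water_pos : (3,) array
        The water oxygen position being profiled.
    water_h_pos : (n_H, 3) array, optional
        Water hydrogen positions, used for the donor-angle criterion when
        the water donates; without them (or in heavy-atom-only mode) the
        distance window alone decides.

    Notes
    -----
    HBA counts protein *donors* hydrogen-bonded to the water (a ligand
    acceptor could replace it); HBD counts protein *acceptors*. The donor
    angle (donor–H···acceptor ≥ ``hb_angle_min``) is evaluated only when
    the donating side has hydrogens available and heavy-atom-only mode is
    off; hydrogens missing from the topology degrade gracefully to the
    distance-only check.
    """
    w = np.asarray(water_pos, dtype=float)

    def _dist(idx: np.ndarray) -> np.ndarray:
        if len(idx) == 0:
            return np.empty(0)
        return np.linalg.norm(frame_coords[idx] - w, axis=1)

    # HBD: water (or future ligand donor) donates to protein acceptors
    hbd = 0
    d_acc = _dist(roles.acceptor_idx)
    for k, d in zip(roles.acceptor_idx, d_acc):
        if not (params.hb_dist_min <= d <= params.hb_dist_max):
            continue
        if params.heavy_atom_only or water_h_pos is None or len(water_h_pos) == 0:
            hbd += 1
            continue
        # donor angle is donor–H···acceptor, evaluated at the hydrogen
        best = max(
            _angle_deg(w, h, frame_coords[k]) for h in np.asarray(water_h_pos, dtype=float)
        )
        if best >= params.hb_angle_min:
            hbd += 1

    # HBA: protein donors donate towards the water
    hba = 0
    for heavy, h_idx in roles.donors:
        d = np.linalg.norm(frame_coords[heavy] - w)
        if not (params.hb_dist_min <= d <= params.hb_dist_max):
            continue
        if params.heavy_atom_only or len(h_idx) == 0:
            hba += 1
            continue
        best = max(_angle_deg(frame_coords[heavy], frame_coords[h], w) for h in h_idx)
        if best >= params.hb_angle_min:
            hba += 1

    pi = sum(
        1
        for grp in roles.anionic_groups
        if np.linalg.norm(frame_coords[grp].mean(axis=0) - w) <= params.ionic_dist_max
    )
    ni = sum(
        1
        for grp in roles.cationic_groups
        if np.linalg.norm(frame_coords[grp].mean(axis=0) - w) <= params.ionic_dist_max
    )
    h_count = int(np.sum(_dist(roles.hydrophobic_idx) <= params.hydrophobic_dist_max))
    ar = sum(
        1
        for ring in roles.aromatic_rings
        if params.aromatic_dist_min
        <= np.linalg.norm(frame_coords[ring].mean(axis=0) - w)
        <= params.aromatic_dist_max
    )
    return InteractionCounts(HBA=hba, HBD=hbd, PI=pi, NI=ni, H=h_count, AR=ar)


@dataclasses.dataclass
class DMIFSet:
    """One scalar field per feature class plus bookkeeping.

    Values are ``100 × (accumulated counts) / n_frames``: a grid point whose
    water reports one qualifying partner in every frame scores 100.
    """

    fields: dict[str, ScalarField]
    n_frames: int
    n_waters_processed: int

    def __getitem__(self, feature_class: str) -> ScalarField:
        return self.fields[feature_class]


def accumulate(
    traj: TrajectoryView,
    grid: GridSpec,
    roles: AtomRoles,
    params: GeometryParams | None = None,
    *,
    water_hydrogens: bool = True,
) -> DMIFSet:
    """Accumulate dMIFs over all frames of a trajectory.

    For every frame, each water oxygen inside the grid contributes its
    :func:`water_environment` counts at the nearest grid point; the final
    fields are scaled by ``100 / n_frames``. Deterministic for fixed input.

    Parameters
    ----------
    water_hydrogens : bool
        Look up the two atoms following each water oxygen as its hydrogens
        for the donor-angle criterion. Disable for oxygen-only waters.

    Raises
    ------
    ValueError
        If the trajectory has no frames.
    """
    if params is None:
        params = GeometryParams()
    if traj.n_frames == 0:
        raise ValueError("trajectory has no frames")
    n = grid.points_per_axis
    acc = {c: np.zeros((n, n, n)) for c in FEATURE_CLASSES}
    w_idx = traj.water_oxygen_indices

    # map water oxygen -> its hydrogen atom indices (same residue, element H)
    h_map: dict[int, np.ndarray] = {}
    if water_hydrogens and not params.heavy_atom_only:
        is_h = traj.atoms["element"].str.upper() == "H"
        for o in w_idx:
            resid = traj.atoms.iloc[o]["resid"]
            same_res = (traj.atoms["resid"] == resid) & is_h
            h_map[int(o)] = np.flatnonzero(same_res.to_numpy())

    n_waters_processed = 0
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        waters = frame[w_idx]
        if len(waters) == 0:
            continue
        inside = grid.contains(waters)
        for o, pos, ok in zip(w_idx, waters, inside):
            if not ok:
                continue
            n_waters_processed += 1
            h_idx = h_map.get(int(o))
            h_pos = frame[h_idx] if h_idx is not None and len(h_idx) else None
            counts = water_environment(frame, pos, roles, params, water_h_pos=h_pos)
            ix, iy, iz = grid.nearest_index(pos)
            for c, v in counts.as_dict().items():
                if v:
                    acc[c][ix, iy, iz] += v

    scale = 100.0 / traj.n_frames
    fields = {c: ScalarField(grid=grid, values=a * scale) for c, a in acc.items()}
    return DMIFSet(fields=fields, n_frames=traj.n_frames, n_waters_processed=n_waters_processed)


def half_max_cutoff(field: ScalarField) -> float:
    """Display/extraction cutoff at half the field maximum."""
    return float(field.values.max()) / 2.0
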