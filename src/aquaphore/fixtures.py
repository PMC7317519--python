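"""Synthetic pocket trajectories and ligand libraries with known truth.

These generators emulate the *statistics* a binding-pocket water analysis
sees — site occupancy frequencies, role-consistent protein scaffolds,
planted actives and decoys — without any physics. A pocket spec plants
interaction sites: per frame, each site emits a water oxygen at its
position (plus Gaussian jitter) with probability p, in front of a static
scaffold group that presents the matching protein chemistry (a carbonyl
behind a donor site, a carboxylate behind a positive-ionizable site, and
so on). The resulting dMIF at the site converges to 100·p.

A library spec plants actives whose fragments realize every feature of a
target pharmacophore at its exact geometry (rigidly transformed per
molecule) and decoys that break exactly one requirement — a displaced
feature group or a heavy atom parked at an exclusion-volume center.

Everything is driven by a single seeded generator; the same spec and seed
produce byte-identical files. Waters "absent" in a frame are parked far
outside any plausible grid so that every model in the multi-model PDB has
the same atom count.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

from .pharmacophore import Pharmacophore

__all__ = [
    "Site",
    "ScaffoldAtom",
    "PocketSpec",
    "LibrarySpec",
    "default_scaffold",
    "build_pocket",
    "build_library",
]

_PARK_OFFSET = np.array([500.0, 500.0, 500.0])  # "absent" water parking lot


@dataclasses.dataclass(frozen=True)
class Site:
    """A planted interaction site: a water hotspot of one feature class."""

    feature_class: str  # HBA | HBD | PI | NI | H | AR
    position: tuple[float, float, float]
    occupancy: float = 1.0
    jitter: float = 0.0  # σ of isotropic Gaussian positional noise, Å

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")

    @property
    def pos(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclasses.dataclass(frozen=True)
class ScaffoldAtom:
    resname: str
    resid: int
    name: str
    element: str
    position: tuple[float, float, float]


@dataclasses.dataclass
class PocketSpec:
    """Specification of a synthetic pocket trajectory.

    If ``scaffold`` is None, a role-consistent scaffold is generated
    automatically behind each site (see :func:`default_scaffold`).
    """

    sites: list[Site]
    n_frames: int = 1000
    seed: int = 0
    scaffold: list[ScaffoldAtom] | None = None

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def _orthonormal_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors perpendicular to u (deterministic)."""
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, u)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, a)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    return v, w


def default_scaffold(sites: Sequence[Site], *, pocket_center=None) -> list[ScaffoldAtom]:
    """Static protein chemistry behind each site, placed so that each site
    sees exactly one qualifying partner of its own class and none of the
    other classes (distances chosen against the default geometric
    criteria in heavy-atom-only mode).

    Scaffold groups point outward, away from the pocket center.
    """
    if pocket_center is None:
        pocket_center = np.mean([s.pos for s in sites], axis=0) if sites else np.zeros(3)
    pocket_center = np.asarray(pocket_center, dtype=float)

    atoms: list[ScaffoldAtom] = []
    resid = 1

    def _add(resname, names_elements_positions):
        nonlocal resid
        for name, element, pos in names_elements_positions:
            atoms.append(
                ScaffoldAtom(
                    resname=resname,
                    resid=resid,
                    name=name,
                    element=element,
                    position=tuple(float(x) for x in pos),
                )
            )
        resid += 1

    for site in sites:
        s = site.pos
        u = s - pocket_center
        nrm = np.linalg.norm(u)
        u = u / nrm if nrm > 1e-6 else np.array([0.0, 0.0, 1.0])
        v, w = _orthonormal_frame(u)
        cls = site.feature_class
        if cls == "HBD":
            # ligand-donor site: a carbonyl acceptor 2.9 Å behind it
            o = s + 2.9 * u
            c = o + 1.23 * u
            _add("GLN", [("OE1", "O", o), ("CD", "C", c)])
        elif cls == "HBA":
            # ligand-acceptor site: a backbone amide donor 2.9 Å behind it
            _add("GLY", [("N", "N", s + 2.9 * u), ("CA", "C", s + 2.9 * u + 1.47 * v)])
        elif cls == "PI":
            # carboxylate centroid 3.8 Å behind; O atoms kept outside the
            # hydrogen-bond distance window to avoid HBD cross-talk
            m = s + 3.8 * u
            _add(
                "ASP",
                [
                    ("CG", "C", m - 0.8 * u),
                    ("OD1", "O", m + 0.4 * u + 1.1 * v),
                    ("OD2", "O", m + 0.4 * u - 1.1 * v),
                ],
            )
        elif cls == "NI":
            _add("LYS", [("NZ", "N", s + 3.8 * u)])
        elif cls == "H":
            _add("ALA", [("CB", "C", s + 3.5 * u)])
        elif cls == "AR":
            centroid = s + 4.5 * u
            ring = []
            for k, name in enumerate(("CG", "CD1", "CE1", "CZ", "CE2", "CD2")):
                theta = 2 * math.pi * k / 6
                ring.append(
                    (name, "C", centroid + 1.39 * (math.cos(theta) * v + math.sin(theta) * w))
                )
            _add("PHE", ring)
        else:
            raise ValueError(f"no scaffold rule for feature class {cls!r}")
    return atoms


def _format_pdb_atom(serial, name, resname, resid, pos, element) -> str:
    nm = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:>5d} {nm:<4.4s} {resname:<3.3s} A{resid:>4d}    "
        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00          {element:>2.2s}\n"
    )


def build_pocket(spec: PocketSpec, pdb_path, truth_path=None) -> dict:
    """Write a multi-model PDB pocket trajectory plus a truth document.

    Returns the truth dict: per site the feature class, planted position,
    occupancy and expected dMIF score (100·p), plus frame and seed info.

    Raises
    ------
    ValueError
        If two scaffold atoms overlap (< 1 Å apart).
    """
    scaffold = spec.scaffold if spec.scaffold is not None else default_scaffold(spec.sites)
    if scaffold:
        pos = np.array([a.position for a in scaffold])
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1.0:
            i, j = np.unravel_index(int(np.argmin(d)), d.shape)
            raise ValueError(
                f"overlapping scaffold atoms (<1 Å): {scaffold[i]} / {scaffold[j]}"
            )
    rng = np.random.default_rng(spec.seed)
    max_resid = max((a.resid for a in scaffold), default=0)

    # pre-draw all stochastic quantities so file content is a pure function
    # of the spec
    n_sites = len(spec.sites)
    present = np.zeros((spec.n_frames, n_sites), dtype=bool)
    offsets = np.zeros((spec.n_frames, n_sites, 3))
    for si, site in enumerate(spec.sites):
        present[:, si] = rng.random(spec.n_frames) < site.occupancy
        if site.jitter > 0:
            offsets[:, si] = rng.normal(0.0, site.jitter, size=(spec.n_frames, 3))

    with open(pdb_path, "w") as fh:
        fh.write("REMARK   1 synthetic pocket fixture (aquaphore)\n")
        fh.write(
            "CRYST1  999.000  999.000  999.000  90.00  90.00  90.00 P 1           1\n"
        )
        for f in range(spec.n_frames):
            fh.write(f"MODEL     {f + 1:>4d}\n")
            serial = 1
            for a in scaffold:
                fh.write(
                    _format_pdb_atom(serial, a.name, a.resname, a.resid, a.position, a.element)
                )
                serial += 1
            for si, site in enumerate(spec.sites):
                if present[f, si]:
                    p = site.pos + offsets[f, si]
                else:
                    p = site.pos + _PARK_OFFSET + 10.0 * si
                fh.write(
                    _format_pdb_atom(serial, "O", "HOH", max_resid + 1 + si, p, "O")
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")

    truth = {
        "n_frames": spec.n_frames,
        "seed": spec.seed,
        "n_scaffold_atoms": len(scaffold),
        "sites": [
            {
                "feature_class": s.feature_class,
                "position": list(s.position),
                "occupancy": s.occupancy,
                "jitter": s.jitter,
                "expected_score": 100.0 * s.occupancy,
                "observed_occupancy": float(present[:, i].mean()),
            }
            for i, s in enumerate(spec.sites)
        ],
    }
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=2)
            fh.write("\n")
    return truth


# ---------------------------------------------------------------------------
# ligand libraries
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class LibrarySpec:
    """Specification of a planted screening library.

    Actives realize every feature of ``pharmacophore`` at its geometry
    (each molecule rigidly moved by a random rotation + translation);
    decoys break exactly one requirement: a feature group displaced by
    ``displacement`` Å radially away from the remaining features (must
    exceed the largest feature tolerance), or — when the pharmacophore
    carries exclusion volumes — a heavy atom parked at an exclusion-volume
    center.
    """

    pharmacophore: Pharmacophore
    n_planted_actives: int = 100
    n_planted_decoys: int = 6350
    displacement: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.pharmacophore.n_features < 3:
            raise ValueError("target pharmacophore needs >= 3 features")
        max_tol = max(f.tolerance for f in self.pharmacophore.features)
        if self.displacement <= max_tol:
            raise ValueError(
                f"displacement {self.displacement} must exceed the largest "
                f"feature tolerance {max_tol} to guarantee decoys"
            )


def _fragment(cls: str):
    """Local-coordinate fragment realizing one feature class at the origin.

    Returns (atoms, bonds) where atoms are (symbol, formal_charge, xyz)
    and bonds are (i, j, rdkit bond type).
    """
    B = Chem.BondType
    if cls == "PI":  # methylammonium: N+ at the anchor
        return (
            [("N", 1, (0.0, 0.0, 0.0)), ("C", 0, (1.5, 0.0, 0.0))],
            [(0, 1, B.SINGLE)],
        )
    if cls == "HBD":  # methanol: hydroxyl O at the anchor
        return (
            [("O", 0, (0.0, 0.0, 0.0)), ("C", 0, (1.4, 0.0, 0.0))],
            [(0, 1, B.SINGLE)],
        )
    if cls == "HBA":  # formaldehyde: carbonyl O at the anchor
        return (
            [("O", 0, (0.0, 0.0, 0.0)), ("C", 0, (1.2, 0.0, 0.0))],
            [(0, 1, B.DOUBLE)],
        )
    if cls == "NI":  # carboxylate: charged O at the anchor
        return (
            [
                ("O", -1, (0.0, 0.0, 0.0)),
                ("C", 0, (1.3, 0.0, 0.0)),
                ("O", 0, (1.95, 1.1, 0.0)),
            ],
            [(0, 1, B.SINGLE), (1, 2, B.DOUBLE)],
        )
    if cls == "H":  # ethane: apolar pair, centroid at the anchor
        return (
            [("C", 0, (-0.75, 0.0, 0.0)), ("C", 0, (0.75, 0.0, 0.0))],
            [(0, 1, B.SINGLE)],
        )
    if cls == "AR":  # benzene: ring centroid at the anchor
        atoms = []
        for k in range(6):
            th = 2 * math.pi * k / 6
            atoms.append(("C", 0, (1.39 * math.cos(th), 1.39 * math.sin(th), 0.0)))
        bonds = [(k, (k + 1) % 6, B.AROMATIC) for k in range(6)]
        return atoms, bonds
    raise ValueError(f"unrealizable feature class {cls!r}")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _build_molecule(
    pharm: Pharmacophore,
    rng: np.random.Generator,
    *,
    displaced_feature: int | None = None,
    displacement: float = 0.0,
    ev_clash: bool = False,
) -> Chem.Mol:
    mol = Chem.RWMol()
    coords: list[np.ndarray] = []
    for k, feat in enumerate(pharm.features):
        atoms, bonds = _fragment(feat.type)
        frag_rot = _random_rotation(rng)
        anchor = feat.pos.copy()
        if displaced_feature is not None and k == displaced_feature:
            # displace radially away from the other features: this grows the
            # pairwise distances to every remaining anchor, which no rigid
            # motion can undo — a random direction could be absorbed by a
            # rotation about the axis through the remaining features
            others = [f.pos for j, f in enumerate(pharm.features) if j != k]
            direction = anchor - np.mean(others, axis=0)
            nrm = np.linalg.norm(direction)
            if nrm < 1e-9:
                direction = rng.normal(size=3)
                nrm = np.linalg.norm(direction)
            anchor = anchor + displacement * direction / nrm
        base = mol.GetNumAtoms()
        for sym, chg, xyz in atoms:
            a = Chem.Atom(sym)
            if chg:
                a.SetFormalCharge(chg)
            if feat.type == "AR":
                a.SetIsAromatic(True)
            mol.AddAtom(a)
            coords.append(anchor + frag_rot @ np.asarray(xyz))
        for i, j, bt in bonds:
            mol.AddBond(base + i, base + j, bt)
    if ev_clash and pharm.exclusion_volumes:
        ev = pharm.exclusion_volumes[rng.integers(len(pharm.exclusion_volumes))]
        mol.AddAtom(Chem.Atom("C"))  # methane carbon inside the EV sphere
        coords.append(ev.pos.copy())

    # whole-molecule rigid motion: matching must be invariant to it
    R = _random_rotation(rng)
    t = rng.uniform(-20.0, 20.0, size=3)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, p in enumerate(coords):
        moved = R @ p + t
        conf.SetAtomPosition(i, Point3D(*(float(x) for x in moved)))
    m = mol.GetMol()
    Chem.SanitizeMol(m)
    m.AddConformer(conf, assignId=True)
    return m


def build_library(spec: LibrarySpec, sdf_path, labels_path=None) -> "pandas.DataFrame":
    """Write a planted SDF library and a labels CSV; return the label table.

    By construction every active matches the target pharmacophore and no
    decoy does. Decoys alternate between a displaced feature group and —
    when exclusion volumes exist — an otherwise perfect geometry with a
    heavy atom at an exclusion-volume center.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    pharm = spec.pharmacophore
    rows = []
    writer = Chem.SDWriter(str(sdf_path))
    try:
        for i in range(spec.n_planted_actives):
            lid = f"active_{i:05d}"
            m = _build_molecule(pharm, rng)
            m.SetProp("_Name", lid)
            m.SetProp("activity_label", "active")
            writer.write(m)
            rows.append({"id": lid, "label": "active"})
        has_ev = bool(pharm.exclusion_volumes)
        for i in range(spec.n_planted_decoys):
            lid = f"decoy_{i:05d}"
            use_ev = has_ev and (i % 2 == 1)
            if use_ev:
                m = _build_molecule(pharm, rng, ev_clash=True)
            else:
                k = int(rng.integers(pharm.n_features))
                m = _build_molecule(
                    pharm, rng, displaced_feature=k, displacement=spec.displacement
                )
            m.SetProp("_Name", lid)
            m.SetProp("activity_label", "decoy")
            writer.write(m)
            rows.append({"id": lid, "label": "decoy"})
    finally:
        writer.close()
    table = pd.DataFrame(rows)
    if labels_path is not None:
        table.to_csv(labels_path, index=False)
    return table
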