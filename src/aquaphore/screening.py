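"""Ligand feature perception, geometric pharmacophore matching, and
retrospective-screen scoring.

A pharmacophore matches a conformer when an injective, type-compatible
assignment of features to ligand feature points exists such that, after a
least-squares rigid superposition of the matched points onto the feature
positions, every point lies inside its feature's tolerance sphere and no
ligand heavy atom penetrates an exclusion volume. The assignment search is
exact depth-first branch-and-bound with pairwise-distance pruning
(|d_ligand − d_pharmacophore| ≤ tol_i + tol_j), which is tractable at the
scale these models are used (≤ ~6 features, a handful of points per type).

The fit score is ``Σ_i 10·(1 − d_i / tol_i)`` over matched features, so a
perfect geometric match of an n-feature model scores 10·n. Screens are
ranked by fit score (descending; ties by ligand id ascending) and scored
with the retrieval rate and the early enrichment factor EF_f, whose ceiling
for A actives among A+D molecules is (A+D)/A.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from typing import Sequence

import numpy as np
from rdkit import Chem
from scipy.spatial.transform import Rotation

from .pharmacophore import Pharmacophore

__all__ = [
    "LigandRecord",
    "FeaturePoint",
    "LigandFeatureSet",
    "MatchResult",
    "Hit",
    "EnrichmentReport",
    "read_library_sdf",
    "perceive_features",
    "match",
    "screen",
    "enrichment",
]

logger = logging.getLogger(__name__)

#: ligand point types a pharmacophore feature type may match
_COMPATIBLE = {c: (c,) for c in ("HBA", "HBD", "PI", "NI", "H", "AR")}


@dataclasses.dataclass
class LigandRecord:
    """A library molecule with one or more 3D conformers and a label."""

    id: str
    mol: Chem.Mol  # all conformers attached
    label: str = "unknown"

    def __post_init__(self):
        if self.mol.GetNumConformers() < 1:
            raise ValueError(f"ligand {self.id!r} has no 3D conformer")
        if self.label not in ("active", "decoy", "unknown"):
            raise ValueError(f"bad label {self.label!r}")

    @property
    def n_conformers(self) -> int:
        return self.mol.GetNumConformers()


@dataclasses.dataclass(frozen=True)
class FeaturePoint:
    type: str
    position: tuple[float, float, float]
    atom_indices: tuple[int, ...]

    @property
    def pos(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclasses.dataclass
class LigandFeatureSet:
    """Perceived pharmacophoric points, one list per conformer."""

    ligand_id: str
    conformer_points: list[list[FeaturePoint]]
    conformer_heavy_coords: list[np.ndarray]


def read_library_sdf(sdf_path, labels=None, *, label_tag: str = "activity_label") -> list[LigandRecord]:
    """Read a multi-conformer SDF library.

    Consecutive SDF entries with the same title are merged into one
    :class:`LigandRecord` with multiple conformers. Labels come from a
    mapping/DataFrame-like ``labels`` (id → 'active'/'decoy') or, failing
    that, from the SD tag ``label_tag``. Unparsable entries are skipped
    with a logged id.
    """
    if labels is not None and hasattr(labels, "set_index"):
        labels = dict(zip(labels["id"].astype(str), labels["label"].astype(str)))
    supplier = Chem.SDMolSupplier(str(sdf_path), removeHs=False, sanitize=True)
    records: dict[str, LigandRecord] = {}
    order: list[str] = []
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("skipping unparsable SDF entry #%d", i)
            continue
        lid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        label = "unknown"
        if labels is not None and lid in labels:
            label = labels[lid]
        elif mol.HasProp(label_tag):
            label = mol.GetProp(label_tag)
        if lid in records:
            records[lid].mol.AddConformer(mol.GetConformer(), assignId=True)
        else:
            records[lid] = LigandRecord(id=lid, mol=mol, label=label)
            order.append(lid)
    return [records[lid] for lid in order]


# ---------------------------------------------------------------------------
# feature perception
# ---------------------------------------------------------------------------

_ACCEPTOR_SMARTS = Chem.MolFromSmarts(
    # O/N acceptors: carbonyl/hydroxyl/ether O, sp2/sp3 N with lone pair;
    # amide N, pyrrole-type N and positively charged N excluded
    "[$([O;X1,X2;+0]),$([n;X2;+0]),$([N;X1,X2,X3;+0;!$([N]C=[O,N,S]);!$([N]a)])]"
)
_DONOR_SMARTS = Chem.MolFromSmarts("[$([N,O;!H0]),$([N+;!H0])]")
_PI_SMARTS = Chem.MolFromSmarts(
    "[$([N+;!$(N=O)]),$([NX3][CX3](=[NX2])[NX3]),$([NX2]=[CX3]([NX3])[NX3])]"
)
_NI_SMARTS = Chem.MolFromSmarts("[$([O-]),$([S-]),$([N-])]")


def _apolar_carbon(atom: Chem.Atom) -> bool:
    if atom.GetSymbol() != "C":
        return False
    return all(n.GetSymbol() in ("C", "H") for n in atom.GetNeighbors())


def perceive_features(record: LigandRecord) -> LigandFeatureSet:
    """Rule-based pharmacophoric point perception per conformer.

    PI at positively charged N (and neutral amidine/guanidine N); HBD at
    H-bearing N/O heavy atoms; HBA at O/N acceptors (amide and aromatic
    pyrrole-type N excluded); NI at negatively charged O/S/N; AR at
    aromatic ring centroids; H at centroids of maximal connected groups of
    ≥2 apolar carbons (carbons bonded only to C/H).
    """
    mol = record.mol
    typed_atoms: list[tuple[str, tuple[int, ...]]] = []
    for patt, cls in ((_PI_SMARTS, "PI"), (_DONOR_SMARTS, "HBD"),
                      (_ACCEPTOR_SMARTS, "HBA"), (_NI_SMARTS, "NI")):
        for (aidx,) in mol.GetSubstructMatches(patt):
            typed_atoms.append((cls, (aidx,)))

    ring_info = mol.GetRingInfo()
    aromatic_rings = [
        tuple(ring)
        for ring in ring_info.AtomRings()
        if all(mol.GetAtomWithIdx(a).GetIsAromatic() for a in ring)
    ]

    # maximal connected apolar-carbon groups of size >= 2
    apolar = {a.GetIdx() for a in mol.GetAtoms() if _apolar_carbon(a)}
    seen: set[int] = set()
    hydrophobic_groups: list[tuple[int, ...]] = []
    for start in sorted(apolar):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            a = stack.pop()
            comp.append(a)
            for n in mol.GetAtomWithIdx(a).GetNeighbors():
                ni = n.GetIdx()
                if ni in apolar and ni not in seen:
                    seen.add(ni)
                    stack.append(ni)
        if len(comp) >= 2:
            hydrophobic_groups.append(tuple(sorted(comp)))

    conformer_points: list[list[FeaturePoint]] = []
    conformer_heavy: list[np.ndarray] = []
    heavy_idx = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    for conf in mol.GetConformers():
        xyz = np.asarray(conf.GetPositions(), dtype=float)
        pts: list[FeaturePoint] = []
        for cls, idxs in typed_atoms:
            p = xyz[list(idxs)].mean(axis=0)
            pts.append(FeaturePoint(type=cls, position=tuple(p), atom_indices=idxs))
        for ring in aromatic_rings:
            p = xyz[list(ring)].mean(axis=0)
            pts.append(FeaturePoint(type="AR", position=tuple(p), atom_indices=ring))
        for grp in hydrophobic_groups:
            p = xyz[list(grp)].mean(axis=0)
            pts.append(FeaturePoint(type="H", position=tuple(p), atom_indices=grp))
        conformer_points.append(pts)
        conformer_heavy.append(xyz[heavy_idx])
    return LigandFeatureSet(
        ligand_id=record.id,
        conformer_points=conformer_points,
        conformer_heavy_coords=conformer_heavy,
    )


# ---------------------------------------------------------------------------
# geometric matching
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MatchResult:
    ligand_id: str
    conformer: int
    mapping: dict[str, int]  # feature id -> ligand point index
    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    deviations: dict[str, float]  # feature id -> Å after superposition
    fit_score: float


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform mapping src onto dst: x -> R x + t."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    with warnings.catch_warnings():
        # two-point matches have a rotation null space; any minimiser is fine
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(dst - dc, src - sc)
    R = rot.as_matrix()
    t = dc - R @ sc
    return R, t


def match(pharm: Pharmacophore, feats: LigandFeatureSet) -> MatchResult | None:
    """Best geometric match of a pharmacophore on any conformer, or None.

    Exact search over injective type-compatible assignments with pairwise
    distance pruning, followed by a least-squares rigid superposition of
    the matched ligand points onto the feature positions. A candidate is
    accepted iff every deviation is within its feature tolerance and no
    ligand heavy atom falls strictly inside an exclusion volume. Among
    accepted candidates the highest fit score wins; the best conformer is
    returned.
    """
    if pharm.n_features == 0:
        raise ValueError("cannot match an empty pharmacophore")
    features = sorted(pharm.features, key=lambda f: f.id)
    fpos = np.array([f.pos for f in features])
    ftol = np.array([f.tolerance for f in features])
    fdist = np.linalg.norm(fpos[:, None, :] - fpos[None, :, :], axis=2)
    ev_centers = np.array([ev.pos for ev in pharm.exclusion_volumes]).reshape(-1, 3)
    ev_radii = np.array([ev.radius for ev in pharm.exclusion_volumes])

    best: MatchResult | None = None
    for ci, (points, heavy) in enumerate(
        zip(feats.conformer_points, feats.conformer_heavy_coords)
    ):
        cand = [
            [j for j, p in enumerate(points) if p.type in _COMPATIBLE[f.type]]
            for f in features
        ]
        if any(len(c) == 0 for c in cand):
            continue
        ppos = np.array([p.pos for p in points]).reshape(-1, 3)
        pdist = np.linalg.norm(ppos[:, None, :] - ppos[None, :, :], axis=2)

        assignment: list[int] = []

        def _extend(depth: int):
            nonlocal best
            if depth == len(features):
                lig = ppos[assignment]
                R, t = _kabsch(lig, fpos)
                moved = lig @ R.T + t
                dev = np.linalg.norm(moved - fpos, axis=1)
                if np.any(dev > ftol):
                    return
                if len(ev_centers):
                    hv = heavy @ R.T + t
                    d_ev = np.linalg.norm(hv[:, None, :] - ev_centers[None, :, :], axis=2)
                    if np.any(d_ev < ev_radii[None, :]):
                        return
                score = float(np.sum(10.0 * (1.0 - dev / ftol)))
                if best is None or score > best.fit_score:
                    best = MatchResult(
                        ligand_id=feats.ligand_id,
                        conformer=ci,
                        mapping={f.id: j for f, j in zip(features, assignment)},
                        rotation=R,
                        translation=t,
                        deviations={f.id: float(d) for f, d in zip(features, dev)},
                        fit_score=score,
                    )
                return
            for j in cand[depth]:
                if j in assignment:
                    continue
                ok = True
                for prev_depth, jp in enumerate(assignment):
                    slack = ftol[depth] + ftol[prev_depth]
                    if abs(pdist[j, jp] - fdist[depth, prev_depth]) > slack:
                        ok = False
                        break
                if ok:
                    assignment.append(j)
                    _extend(depth + 1)
                    assignment.pop()

        _extend(0)
    return best


@dataclasses.dataclass
class Hit:
    ligand_id: str
    fit_score: float
    conformer: int
    label: str = "unknown"


def screen(library: Sequence[LigandRecord], pharm: Pharmacophore) -> list[Hit]:
    """Match every library molecule; return ranked hits.

    Ranking is by fit score descending, ties by ligand id ascending.
    Non-matching molecules are excluded.
    """
    if not library:
        raise ValueError("library is empty")
    hits: list[Hit] = []
    for rec in library:
        feats = perceive_features(rec)
        m = match(pharm, feats)
        if m is not None:
            hits.append(Hit(ligand_id=rec.id, fit_score=m.fit_score, conformer=m.conformer, label=rec.label))
    hits.sort(key=lambda h: (-h.fit_score, h.ligand_id))
    return hits


@dataclasses.dataclass
class EnrichmentReport:
    """Retrieval and early-enrichment statistics of one screen."""

    n_actives: int
    n_decoys: int
    fraction: float
    n_selected: int
    tp_selected: int
    ef: float
    retrieval_pct: float
    hit_ids: list[str]

    def __post_init__(self):
        ceiling = (self.n_actives + self.n_decoys) / self.n_actives
        if not 0.0 <= self.ef <= ceiling + 1e-9:
            raise ValueError(f"EF {self.ef} outside [0, {ceiling}]")
        if not 0.0 <= self.retrieval_pct <= 100.0:
            raise ValueError("retrieval_pct outside [0, 100]")


def enrichment(
    hits: Sequence[Hit],
    labels: dict[str, str] | None,
    n_actives: int,
    n_decoys: int,
    fraction: float = 0.01,
) -> EnrichmentReport:
    """Score a ranked hit list against a labelled A-active/D-decoy library.

    The early enrichment factor at fraction f considers the top
    ``n_top = ceil(f·(A+D))`` of the ranked hit list — or the whole list if
    it is shorter — and compares its precision with the library's active
    fraction::

        EF_f = (TP_selected / n_selected) / (A / (A + D))

    An empty selection yields EF = 0. The ceiling (A+D)/A is attained by
    any all-active hit list of size ≤ n_top. ``retrieval_pct`` is the
    percentage of all actives present anywhere in the hit list.

    Raises
    ------
    KeyError
        If a hit id has no label.
    """
    if n_actives <= 0:
        raise ValueError("need n_actives > 0")
    if n_decoys < 0:
        raise ValueError("need n_decoys >= 0")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")

    def _label(h: Hit) -> str:
        if labels is not None:
            if h.ligand_id not in labels:
                raise KeyError(f"hit {h.ligand_id!r} has no label")
            return labels[h.ligand_id]
        if h.label == "unknown":
            raise KeyError(f"hit {h.ligand_id!r} has no label")
        return h.label

    total = n_actives + n_decoys
    n_top = math.ceil(fraction * total)
    selected = list(hits[: min(len(hits), n_top)])
    tp_sel = sum(1 for h in selected if _label(h) == "active")
    if selected:
        ef = (tp_sel / len(selected)) / (n_actives / total)
    else:
        ef = 0.0
    tp_all = sum(1 for h in hits if _label(h) == "active")
    return EnrichmentReport(
        n_actives=n_actives,
        n_decoys=n_decoys,
        fraction=fraction,
        n_selected=len(selected),
        tp_selected=tp_sel,
        ef=ef,
        retrieval_pct=100.0 * tp_all / n_actives,
        hit_ids=[h.ligand_id for h in hits],
    )
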