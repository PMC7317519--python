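"""Pharmacophore construction, focusing, enumeration and persistence.

The super-pharmacophore is the union of all feature candidates extracted
from the dMIFs: per feature class, peaks above a threshold (half the field
maximum by default) are picked greedily, each suppressing a merge-radius
sphere around itself. Manual focusing then keeps a named subset, and the
combinatorial enumerator expands the focused model into all sub-models
that satisfy count constraints (total features, per-type bounds, hydrogen
bonds counted jointly over donors and acceptors).

The native on-disk format is a JSON schema that round-trips losslessly; a
PML dialect (LigandScout-style XML) is exported best-effort for use in
external visualisation tools.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import xml.etree.ElementTree as ET
from typing import Iterable, Sequence

import numpy as np

from .dmif import FEATURE_CLASSES, DMIFSet
from .trajectory import TrajectoryView

__all__ = [
    "PharmFeature",
    "ExclusionVolume",
    "Pharmacophore",
    "ComboConstraints",
    "ExtractionParams",
    "extract_features",
    "make_exclusion_volumes",
    "focus",
    "enumerate_subpharmacophores",
    "write_pharmacophore",
    "read_pharmacophore",
]


@dataclasses.dataclass(frozen=True)
class PharmFeature:
    """A typed interaction requirement at a 3D position.

    ``tolerance`` is the radius of the sphere a matched ligand point must
    fall into. ``score`` records the dMIF value at placement. Hydrogen-bond
    features may carry a projection point towards the protein partner plus
    its own tolerance (checked only when enabled in matching).
    """

    id: str
    type: str
    position: tuple[float, float, float]
    tolerance: float = 1.5
    score: float = 0.0
    projection: tuple[float, float, float] | None = None
    projection_tolerance: float | None = None

    def __post_init__(self):
        if self.type not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature type {self.type!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")

    @property
    def pos(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclasses.dataclass(frozen=True)
class ExclusionVolume:
    center: tuple[float, float, float]
    radius: float = 1.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("exclusion volume radius must be > 0")

    @property
    def pos(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclasses.dataclass
class Pharmacophore:
    """Named set of required features plus exclusion volumes.

    All features are required for a match; there are no optional features.
    Feature ids must be unique.
    """

    name: str
    features: list[PharmFeature]
    exclusion_volumes: list[ExclusionVolume] = dataclasses.field(default_factory=list)

    def __post_init__(self):
        ids = [f.id for f in self.features]
        if len(set(ids)) != len(ids):
            raise ValueError("feature ids must be unique")

    @property
    def n_features(self) -> int:
        return len(self.features)

    def composition(self) -> dict[str, int]:
        """Feature count by type, e.g. ``{"PI": 2, "HBD": 4, ...}``."""
        out: dict[str, int] = {}
        for f in self.features:
            out[f.type] = out.get(f.type, 0) + 1
        return out

    def feature(self, fid: str) -> PharmFeature:
        for f in self.features:
            if f.id == fid:
                return f
        raise KeyError(fid)


@dataclasses.dataclass(frozen=True)
class ExtractionParams:
    """Peak-picking parameters for super-pharmacophore extraction.

    ``threshold`` maps feature class to the minimum dMIF value for feature
    placement; classes not listed use half the field maximum. Peaks within
    ``merge_radius`` of a placed feature are suppressed.
    """

    threshold: dict[str, float] = dataclasses.field(default_factory=dict)
    merge_radius: float = 2.0
    max_features_per_class: int = 50
    tolerance: float = 1.5


def extract_features(
    dmifs: DMIFSet,
    params: ExtractionParams | None = None,
    *,
    name: str = "super",
) -> Pharmacophore:
    """Greedy per-class peak picking over the dMIFs.

    Per class: take the global maximum above threshold, place a feature
    there, zero out a ``merge_radius`` sphere, repeat. Ties are broken by
    the lowest flat grid index (C order over ix, iy, iz), which makes the
    result deterministic and independent of grid-point storage order.
    Returns an empty pharmacophore if nothing exceeds threshold.
    """
    if params is None:
        params = ExtractionParams()
    features: list[PharmFeature] = []
    for cls in FEATURE_CLASSES:
        field = dmifs[cls]
        thr = params.threshold.get(cls, field.values.max() / 2.0)
        if thr <= 0:
            continue
        values = field.values.copy()
        grid = field.grid
        n = grid.points_per_axis
        idx_grid = np.indices((n, n, n)).reshape(3, -1).T  # flat C order
        coords = grid.point_coords(idx_grid)
        flat = values.reshape(-1)
        for rank in range(params.max_features_per_class):
            best = int(np.argmax(flat))  # lowest flat index on ties
            if flat[best] < thr or flat[best] <= 0:
                break
            pos = coords[best]
            features.append(
                PharmFeature(
                    id=f"{cls}{rank + 1}",
                    type=cls,
                    position=tuple(float(x) for x in pos),
                    tolerance=params.tolerance,
                    score=float(flat[best]),
                )
            )
            suppress = np.linalg.norm(coords - pos, axis=1) <= params.merge_radius
            flat[suppress] = -np.inf
    return Pharmacophore(name=name, features=features)


def add_hb_projections(
    pharm: Pharmacophore,
    traj: TrajectoryView,
    roles,
    *,
    hb_dist_max: float = 3.6,
    projection_tolerance: float = 1.5,
) -> Pharmacophore:
    """Attach projection points to hydrogen-bond features.

    The projection point of an HBD feature is the unweighted centroid of
    time-averaged protein *acceptor* atoms within ``hb_dist_max`` of the
    feature position (the partners a ligand donor would reach); HBA
    features project onto nearby protein donor heavy atoms. Features with
    no partner in range are left unchanged.
    """
    mean_coords = traj.coords.mean(axis=0)
    out = []
    for f in pharm.features:
        partner_idx = None
        if f.type == "HBD":
            partner_idx = roles.acceptor_idx
        elif f.type == "HBA":
            partner_idx = roles.donor_idx
        if partner_idx is None or len(partner_idx) == 0:
            out.append(f)
            continue
        partners = mean_coords[partner_idx]
        near = np.linalg.norm(partners - f.pos, axis=1) <= hb_dist_max
        if not near.any():
            out.append(f)
            continue
        proj = partners[near].mean(axis=0)
        out.append(
            dataclasses.replace(
                f,
                projection=tuple(float(x) for x in proj),
                projection_tolerance=projection_tolerance,
            )
        )
    return Pharmacophore(name=pharm.name, features=out, exclusion_volumes=list(pharm.exclusion_volumes))


def make_exclusion_volumes(
    traj: TrajectoryView,
    features: Sequence[PharmFeature],
    *,
    ev_radius: float = 1.0,
    min_feature_dist: float = 1.5,
    near_feature_dist: float = 8.0,
) -> list[ExclusionVolume]:
    """Place exclusion volumes on time-averaged protein heavy atoms.

    Candidate centers are mean positions of non-water, non-hydrogen atoms
    within ``near_feature_dist`` of any feature. Candidates closer than
    ``min_feature_dist`` to a feature position are dropped (they would
    forbid the very interaction the feature demands), and the remainder is
    deduplicated greedily at ``2 · ev_radius`` spacing in atom order.
    """
    if not features:
        return []
    prot = traj.protein_atom_indices
    if len(prot) == 0:
        return []
    heavy = prot[traj.atoms.iloc[prot]["element"].str.upper().to_numpy() != "H"]
    if len(heavy) == 0:
        return []
    mean_pos = traj.coords[:, heavy].mean(axis=0)
    fpos = np.array([f.pos for f in features])
    d_feat = np.linalg.norm(mean_pos[:, None, :] - fpos[None, :, :], axis=2)
    keep = (d_feat.min(axis=1) <= near_feature_dist) & (d_feat.min(axis=1) >= min_feature_dist)
    centers: list[np.ndarray] = []
    for p in mean_pos[keep]:
        if all(np.linalg.norm(p - c) >= 2 * ev_radius for c in centers):
            centers.append(p)
    return [ExclusionVolume(center=tuple(float(x) for x in c), radius=ev_radius) for c in centers]


def focus(pharm: Pharmacophore, keep_ids: Iterable[str], *, name: str | None = None) -> Pharmacophore:
    """Keep a subset of features (exclusion volumes are retained).

    Raises
    ------
    KeyError
        If an id does not exist.
    ValueError
        If the subset would be empty.
    """
    keep = list(keep_ids)
    known = {f.id for f in pharm.features}
    unknown = [k for k in keep if k not in known]
    if unknown:
        raise KeyError(f"unknown feature id(s): {unknown}")
    if not keep:
        raise ValueError("an empty pharmacophore is not allowed")
    keep_set = set(keep)
    return Pharmacophore(
        name=name or f"{pharm.name}/focused",
        features=[f for f in pharm.features if f.id in keep_set],
        exclusion_volumes=list(pharm.exclusion_volumes),
    )


@dataclasses.dataclass(frozen=True)
class ComboConstraints:
    """Count constraints for combinatorial sub-pharmacophore enumeration.

    ``per_type`` maps a type key to (min, max) inclusive counts. The key
    ``"HB"`` counts hydrogen-bond features jointly (HBA + HBD). Optional
    ``exclusive_pairs`` lists id pairs that must never be co-selected.
    """

    min_total: int = 3
    max_total: int = 5
    per_type: dict[str, tuple[int, int]] = dataclasses.field(default_factory=dict)
    exclusive_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if not 0 <= self.min_total <= self.max_total:
            raise ValueError("need 0 <= min_total <= max_total")
        for key, (lo, hi) in self.per_type.items():
            if not 0 <= lo <= hi:
                raise ValueError(f"bad bounds for {key}: ({lo}, {hi})")

    def admits(self, features: Sequence[PharmFeature]) -> bool:
        k = len(features)
        if not self.min_total <= k <= self.max_total:
            return False
        counts: dict[str, int] = {}
        for f in features:
            counts[f.type] = counts.get(f.type, 0) + 1
        counts["HB"] = counts.get("HBA", 0) + counts.get("HBD", 0)
        for key, (lo, hi) in self.per_type.items():
            if not lo <= counts.get(key, 0) <= hi:
                return False
        if self.exclusive_pairs:
            ids = {f.id for f in features}
            for a, b in self.exclusive_pairs:
                if a in ids and b in ids:
                    return False
        return True


def enumerate_subpharmacophores(
    pharm: Pharmacophore, constraints: ComboConstraints
) -> list[Pharmacophore]:
    """All feature subsets satisfying the constraints.

    Exclusion volumes are copied into every child. Output order is
    deterministic: subsets are emitted by size, then lexicographically by
    the sorted tuple of feature ids. Returns an empty list when the
    constraints are unsatisfiable.
    """
    feats = sorted(pharm.features, key=lambda f: f.id)
    out: list[Pharmacophore] = []
    kmax = min(constraints.max_total, len(feats))
    for k in range(constraints.min_total, kmax + 1):
        for combo in itertools.combinations(feats, k):
            if constraints.admits(combo):
                ids = "+".join(f.id for f in combo)
                out.append(
                    Pharmacophore(
                        name=f"{pharm.name}[{ids}]",
                        features=list(combo),
                        exclusion_volumes=list(pharm.exclusion_volumes),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Persistence — native JSON (lossless) and PML export (best effort)
# ---------------------------------------------------------------------------

_SCHEMA_VERSION = 1


def _feature_to_dict(f: PharmFeature) -> dict:
    d = {
        "id": f.id,
        "type": f.type,
        "position": list(f.position),
        "tolerance": f.tolerance,
        "score": f.score,
    }
    if f.projection is not None:
        d["projection"] = list(f.projection)
        d["projection_tolerance"] = f.projection_tolerance
    return d


def write_pharmacophore(pharm: Pharmacophore, path, format: str = "json") -> None:
    """Persist a pharmacophore.

    ``json`` is the lossless native schema; ``pml`` exports a
    LigandScout-style XML dialect (point features, plane for aromatics,
    exclusion volumes) for external tools and does not round-trip scores.
    """
    if format == "json":
        doc = {
            "schema": "aquaphore-pharmacophore",
            "version": _SCHEMA_VERSION,
            "name": pharm.name,
            "features": [_feature_to_dict(f) for f in pharm.features],
            "exclusion_volumes": [
                {"center": list(ev.center), "radius": ev.radius}
                for ev in pharm.exclusion_volumes
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")
    elif format == "pml":
        _write_pml(pharm, path)
    else:
        raise ValueError(f"unknown format {format!r}")


_PML_NAMES = {
    "HBA": "HBA",
    "HBD": "HBD",
    "PI": "PI",
    "NI": "NI",
    "H": "H",
    "AR": "AR",
}


def _pml_vec(el: ET.Element, tag: str, xyz, extra: dict | None = None) -> None:
    at = {"x3": f"{xyz[0]:.4f}", "y3": f"{xyz[1]:.4f}", "z3": f"{xyz[2]:.4f}"}
    if extra:
        at.update(extra)
    ET.SubElement(el, tag, at)


def _write_pml(pharm: Pharmacophore, path) -> None:
    root = ET.Element("pharmacophore", {"name": pharm.name, "pharmacophoreType": "LIGAND_SCOUT"})
    for i, f in enumerate(pharm.features):
        kind = "plane" if f.type == "AR" else "point"
        el = ET.SubElement(
            root,
            kind,
            {
                "name": _PML_NAMES[f.type],
                "featureId": f.id,
                "optional": "false",
                "disabled": "false",
                "weight": "1.0",
                "id": f"feature{i}",
            },
        )
        _pml_vec(el, "position", f.position, {"tolerance": f"{f.tolerance:.4f}"})
        if f.projection is not None:
            tol = f.projection_tolerance if f.projection_tolerance is not None else f.tolerance
            _pml_vec(el, "target", f.projection, {"tolerance": f"{tol:.4f}"})
    for j, ev in enumerate(pharm.exclusion_volumes):
        el = ET.SubElement(
            root,
            "volume",
            {"type": "exclusion", "featureId": f"ev{j}", "optional": "false",
             "disabled": "false", "weight": "1.0", "id": f"volume{j}"},
        )
        _pml_vec(el, "position", ev.center, {"tolerance": f"{ev.radius:.4f}"})
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(str(path), xml_declaration=True, encoding="unicode")


def read_pharmacophore(path) -> Pharmacophore:
    """Read a pharmacophore from the native JSON schema.

    Raises
    ------
    ValueError
        On schema violations or truncated files.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"not a valid pharmacophore JSON file: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("schema") != "aquaphore-pharmacophore":
        raise ValueError("missing schema marker 'aquaphore-pharmacophore'")
    try:
        features = [
            PharmFeature(
                id=str(f["id"]),
                type=str(f["type"]),
                position=tuple(float(x) for x in f["position"]),
                tolerance=float(f["tolerance"]),
                score=float(f.get("score", 0.0)),
                projection=(
                    tuple(float(x) for x in f["projection"]) if "projection" in f else None
                ),
                projection_tolerance=(
                    float(f["projection_tolerance"]) if f.get("projection_tolerance") is not None else None
                ),
            )
            for f in doc["features"]
        ]
        evs = [
            ExclusionVolume(center=tuple(float(x) for x in e["center"]), radius=float(e["radius"]))
            for e in doc.get("exclusion_volumes", [])
        ]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed pharmacophore document: {exc}") from exc
    return Pharmacophore(name=str(doc.get("name", "pharmacophore")), features=features, exclusion_volumes=evs)
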