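"""Shared fixtures: synthetic pockets, toy pharmacophores, tiny libraries."""

import numpy as np
import pytest

import aquaphore as aq


@pytest.fixture(scope="session")
def six_class_sites():
    """One planted site per feature class, spread around the pocket."""
    return [
        aq.Site("HBD", (-8.0, 0.0, 0.0), occupancy=0.8),
        aq.Site("HBA", (8.0, 0.0, 0.0), occupancy=0.6),
        aq.Site("PI", (0.0, -8.0, 0.0), occupancy=0.9),
        aq.Site("NI", (0.0, 8.0, 0.0), occupancy=0.5),
        aq.Site("H", (0.0, 0.0, -8.0), occupancy=1.0),
        aq.Site("AR", (0.0, 0.0, 8.0), occupancy=0.7),
    ]


@pytest.fixture(scope="session")
def hotspot_pocket(tmp_path_factory, six_class_sites):
    """1000-frame pocket trajectory with one site per class (no jitter),
    loaded once per session. Returns (trajectory, truth, sites)."""
    spec = aq.PocketSpec(sites=six_class_sites, n_frames=1000, seed=2024)
    path = tmp_path_factory.mktemp("pocket") / "pocket.pdb"
    truth = aq.build_pocket(spec, path)
    traj = aq.load_trajectory(path, dt=10.0)
    return traj, truth, six_class_sites


@pytest.fixture(scope="session")
def toy_pharmacophore():
    """Five-feature pharmacophore with one exclusion volume, features
    spread far enough apart that assignments are unambiguous."""
    feats = [
        aq.PharmFeature("PI1", "PI", (0.0, 0.0, 0.0)),
        aq.PharmFeature("HBD1", "HBD", (7.0, 0.0, 0.0)),
        aq.PharmFeature("HBA1", "HBA", (0.0, 7.0, 0.0)),
        aq.PharmFeature("H1", "H", (0.0, 0.0, 7.0)),
        aq.PharmFeature("AR1", "AR", (6.0, 6.0, 6.0)),
    ]
    return aq.Pharmacophore(
        "toy", feats, [aq.ExclusionVolume((3.5, 3.5, 3.5), 1.0)]
    )


@pytest.fixture(scope="session")
def fifteen_feature_inventory():
    """Inventory with the focused-model composition: 2 PI, 8 hydrogen-bond
    class (4 donors + 4 acceptors), 4 hydrophobic, 1 aromatic."""
    feats = (
        [aq.PharmFeature(f"PI{i}", "PI", (float(i), 0.0, 0.0)) for i in range(1, 3)]
        + [aq.PharmFeature(f"HBD{i}", "HBD", (float(i), 1.0, 0.0)) for i in range(1, 5)]
        + [aq.PharmFeature(f"HBA{i}", "HBA", (float(i), 2.0, 0.0)) for i in range(1, 3)]
        + [aq.PharmFeature(f"HB{i}", "HBD" if i % 2 else "HBA", (float(i), 3.0, 0.0)) for i in range(1, 3)]
        + [aq.PharmFeature(f"H{i}", "H", (float(i), 4.0, 0.0)) for i in range(1, 5)]
        + [aq.PharmFeature("AR1", "AR", (0.0, 5.0, 0.0))]
    )
    return aq.Pharmacophore("focused", feats)


def write_pdb_models(path, models, resname="HOH", atom="O", element="O"):
    """Write a minimal multi-model PDB of identical single-atom residues."""
    lines = []
    for m, coords in enumerate(models, start=1):
        lines.append(f"MODEL     {m:>4d}")
        for i, (x, y, z) in enumerate(coords, start=1):
            nm = f" {atom:<3s}"
            lines.append(
                f"ATOM  {i:>5d} {nm:<4s} {resname:<3s} A{i:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
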