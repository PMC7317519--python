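"""Atom-role typing, water-environment counting, and dMIF accumulation.

The accumulation test checks the production path against an independent
brute-force double loop over frames × waters × partner groups written
directly from the geometric definitions.
"""

import numpy as np
import pandas as pd
import pytest

import aquaphore as aq
from aquaphore.dmif import AtomRoles, water_environment
from aquaphore.trajectory import TrajectoryView


def _view_from_atoms(rows, coords):
    """rows: list of (name, resname, resid, element); coords: (F, N, 3)."""
    table = pd.DataFrame(rows, columns=["name", "resname", "resid", "element"])
    coords = np.asarray(coords, dtype=float)
    times = (np.arange(coords.shape[0]) + 1) * 10.0
    return TrajectoryView(frame_times=times, coords=coords, atoms=table)


class TestAssignAtomRoles:
    def test_aspartate_side_chain_gives_one_anionic_center(self):
        rows = [
            ("CB", "ASP", 1, "C"),
            ("CG", "ASP", 1, "C"),
            ("OD1", "ASP", 1, "O"),
            ("OD2", "ASP", 1, "O"),
        ]
        traj = _view_from_atoms(rows, np.zeros((1, 4, 3)))
        roles = aq.assign_atom_roles(traj)
        assert len(roles.anionic_groups) == 1
        # centroid over OD1/OD2/CG
        assert sorted(roles.anionic_groups[0]) == [1, 2, 3]
        assert list(roles.hydrophobic_idx) == [0]  # CB only

    def test_phenylalanine_gives_one_six_atom_ring(self):
        names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
        rows = [(n, "PHE", 1, "C") for n in names]
        traj = _view_from_atoms(rows, np.zeros((1, 6, 3)))
        roles = aq.assign_atom_roles(traj)
        assert len(roles.aromatic_rings) == 1
        assert len(roles.aromatic_rings[0]) == 6

    def test_alanine_cb_is_hydrophobic(self):
        rows = [("CA", "ALA", 1, "C"), ("CB", "ALA", 1, "C")]
        traj = _view_from_atoms(rows, np.zeros((1, 2, 3)))
        roles = aq.assign_atom_roles(traj)
        assert list(roles.hydrophobic_idx) == [1]

    def test_unknown_residue_warns_and_is_reported_not_dropped_silently(self):
        rows = [("X1", "LIG", 9, "C")]
        traj = _view_from_atoms(rows, np.zeros((1, 1, 3)))
        with pytest.warns(UserWarning, match="LIG"):
            roles = aq.assign_atom_roles(traj)
        assert ("LIG", 9) in roles.excluded_residues

    def test_lysine_is_donor_and_cationic(self):
        rows = [("NZ", "LYS", 1, "N")]
        traj = _view_from_atoms(rows, np.zeros((1, 1, 3)))
        roles = aq.assign_atom_roles(traj)
        assert len(roles.cationic_groups) == 1
        assert 0 in [d[0] for d in roles.donors]


def _roles(acceptors=(), donors=(), hydrophobic=(), rings=(), cations=(), anions=()):
    return AtomRoles(
        acceptor_idx=np.array(acceptors, dtype=int),
        donors=[(int(i), np.array(h, dtype=int)) for i, h in donors],
        hydrophobic_idx=np.array(hydrophobic, dtype=int),
        aromatic_rings=[np.array(r, dtype=int) for r in rings],
        cationic_groups=[np.array(g, dtype=int) for g in cations],
        anionic_groups=[np.array(g, dtype=int) for g in anions],
        excluded_residues=[],
    )


HEAVY = aq.GeometryParams(heavy_atom_only=True)


class TestWaterEnvironment:
    def test_carbonyl_oxygen_at_2p9_counts_one_hbd(self):
        frame = np.array([[2.9, 0.0, 0.0]])
        counts = water_environment(frame, np.zeros(3), _roles(acceptors=[0]), HEAVY)
        assert counts.HBD == 1 and counts.HBA == 0

    def test_everything_at_5A_counts_nothing(self):
        frame = np.full((3, 3), 5.0 / np.sqrt(3))
        roles = _roles(acceptors=[0], donors=[(1, [])], hydrophobic=[2])
        counts = water_environment(frame, np.zeros(3), roles, HEAVY)
        assert counts.as_dict() == {c: 0 for c in aq.FEATURE_CLASSES}

    def test_carboxylate_center_at_3p5_counts_one_pi(self):
        # group centroid at 3.5 Å from the water
        frame = np.array([[3.5, 1.0, 0.0], [3.5, -1.0, 0.0], [3.5, 0.0, 0.0]])
        counts = water_environment(
            frame, np.zeros(3), _roles(anions=[[0, 1, 2]]), HEAVY
        )
        assert counts.PI == 1

    def test_donor_angle_criterion_on_hand_placed_hydrogens(self):
        params = aq.GeometryParams(heavy_atom_only=False)
        # donor N at 3.0 Å along x; H between N and water: angle N-H...O = 180
        frame_good = np.array([[3.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        roles = _roles(donors=[(0, [1])])
        assert water_environment(frame_good, np.zeros(3), roles, params).HBA == 1
        # H perpendicular: angle ~63 degrees, fails the 130 degree minimum
        frame_bad = np.array([[3.0, 0.0, 0.0], [3.0, 1.0, 0.0]])
        assert water_environment(frame_bad, np.zeros(3), roles, params).HBA == 0

    def test_water_donor_angle_uses_water_hydrogens(self):
        params = aq.GeometryParams(heavy_atom_only=False)
        roles = _roles(acceptors=[0])
        frame = np.array([[3.0, 0.0, 0.0]])
        h_towards = np.array([[1.0, 0.0, 0.0]])
        h_away = np.array([[-1.0, 0.0, 0.0], [0.0, -1.0, 0.0]])
        assert water_environment(frame, np.zeros(3), roles, params, h_towards).HBD == 1
        assert water_environment(frame, np.zeros(3), roles, params, h_away).HBD == 0

    def test_aromatic_band_is_two_sided(self):
        ring = [[4.5, 1.39, 0.0], [4.5, -1.39, 0.0], [4.5, 0.0, 1.39],
                [4.5, 0.0, -1.39], [4.5, 0.98, 0.98]]
        counts = water_environment(np.array(ring), np.zeros(3), _roles(rings=[range(5)]), HEAVY)
        assert counts.AR == 1
        too_close = np.array(ring) * (2.0 / 4.5)
        assert water_environment(too_close, np.zeros(3), _roles(rings=[range(5)]), HEAVY).AR == 0


def _brute_force_dmifs(traj, grid, roles, params):
    """Independent accumulation: explicit loops and explicit geometry."""
    n = grid.points_per_axis
    acc = {c: np.zeros((n, n, n)) for c in aq.FEATURE_CLASSES}
    origin = np.asarray(grid.center) - grid.edge_length / 2.0
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        for w_idx in traj.water_oxygen_indices:
            w = frame[w_idx]
            if np.any(w < origin) or np.any(w > origin + grid.edge_length):
                continue
            frac = (w - origin) / grid.spacing
            idx = []
            for x in frac:
                lo = int(np.floor(x))
                # nearest point, exact ties to the lower index
                idx.append(lo if (x - lo) <= 0.5 else lo + 1)
            ix, iy, iz = idx
            for k in roles.acceptor_idx:
                if params.hb_dist_min <= np.linalg.norm(frame[k] - w) <= params.hb_dist_max:
                    acc["HBD"][ix, iy, iz] += 1
            for heavy, _h in roles.donors:
                if params.hb_dist_min <= np.linalg.norm(frame[heavy] - w) <= params.hb_dist_max:
                    acc["HBA"][ix, iy, iz] += 1
            for grp in roles.anionic_groups:
                if np.linalg.norm(frame[grp].mean(axis=0) - w) <= params.ionic_dist_max:
                    acc["PI"][ix, iy, iz] += 1
            for grp in roles.cationic_groups:
                if np.linalg.norm(frame[grp].mean(axis=0) - w) <= params.ionic_dist_max:
                    acc["NI"][ix, iy, iz] += 1
            for k in roles.hydrophobic_idx:
                if np.linalg.norm(frame[k] - w) <= params.hydrophobic_dist_max:
                    acc["H"][ix, iy, iz] += 1
            for ring in roles.aromatic_rings:
                d = np.linalg.norm(frame[ring].mean(axis=0) - w)
                if params.aromatic_dist_min <= d <= params.aromatic_dist_max:
                    acc["AR"][ix, iy, iz] += 1
    return {c: a * 100.0 / traj.n_frames for c, a in acc.items()}


def _toy_trajectory(seed=5, n_frames=5, n_waters=3):
    """Small mixed system: one acceptor, one donor, one hydrophobic atom,
    one carboxylate, one cation, one 5-ring, and mobile waters."""
    rng = np.random.default_rng(seed)
    rows = [
        ("O", "GLY", 1, "O"),
        ("N", "GLY", 2, "N"),
        ("CB", "ALA", 3, "C"),
        ("CG", "ASP", 4, "C"), ("OD1", "ASP", 4, "O"), ("OD2", "ASP", 4, "O"),
        ("NZ", "LYS", 5, "N"),
    ] + [("CG", "PHE", 6, "C"), ("CD1", "PHE", 6, "C"), ("CD2", "PHE", 6, "C"),
         ("CE1", "PHE", 6, "C"), ("CE2", "PHE", 6, "C"), ("CZ", "PHE", 6, "C")]
    protein = np.array(
        [[2.9, 0, 0], [-3.0, 0, 0], [0, 3.6, 0],
         [0, -3.5, 0], [1.0, -3.8, 0], [-1.0, -3.8, 0],
         [0, 0, 3.7],
         [4.0, 1.39, 2.0], [4.0, -1.39, 2.0], [4.0, 0.6, 3.2],
         [4.0, -0.6, 3.2], [4.0, 0.6, 0.8], [4.0, -0.6, 0.8]]
    )
    rows += [("O", "HOH", 10 + i, "O") for i in range(n_waters)]
    coords = np.empty((n_frames, len(rows), 3))
    for f in range(n_frames):
        coords[f, : len(protein)] = protein
        coords[f, len(protein):] = rng.uniform(-4.5, 4.5, size=(n_waters, 3))
    return _view_from_atoms(rows, coords)


class TestAccumulate:
    def test_matches_independent_brute_force_on_toy_systems(self):
        for seed in (1, 2, 3):
            traj = _toy_trajectory(seed=seed)
            grid = aq.make_grid((0, 0, 0), 10, 1.0)
            roles = aq.assign_atom_roles(traj)
            dm = aq.accumulate(traj, grid, roles, HEAVY, water_hydrogens=False)
            expected = _brute_force_dmifs(traj, grid, roles, HEAVY)
            for cls in aq.FEATURE_CLASSES:
                np.testing.assert_allclose(
                    dm[cls].values, expected[cls], atol=1e-12, err_msg=cls
                )

    def test_duplicating_every_frame_leaves_scores_unchanged(self):
        traj = _toy_trajectory()
        doubled = TrajectoryView(
            frame_times=np.arange(1, 2 * traj.n_frames + 1, dtype=float),
            coords=np.repeat(traj.coords, 2, axis=0),
            atoms=traj.atoms,
        )
        grid = aq.make_grid((0, 0, 0), 10, 1.0)
        roles = aq.assign_atom_roles(traj)
        a = aq.accumulate(traj, grid, roles, HEAVY, water_hydrogens=False)
        b = aq.accumulate(doubled, grid, roles, HEAVY, water_hydrogens=False)
        for cls in aq.FEATURE_CLASSES:
            np.testing.assert_allclose(a[cls].values, b[cls].values)

    def test_joint_translation_of_system_and_grid_is_invariant(self):
        traj = _toy_trajectory()
        shift = np.array([7.0, -3.0, 2.0])
        moved = TrajectoryView(
            frame_times=traj.frame_times,
            coords=traj.coords + shift,
            atoms=traj.atoms,
        )
        roles = aq.assign_atom_roles(traj)
        a = aq.accumulate(traj, aq.make_grid((0, 0, 0), 10, 1.0), roles, HEAVY, water_hydrogens=False)
        b = aq.accumulate(moved, aq.make_grid(shift, 10, 1.0), roles, HEAVY, water_hydrogens=False)
        for cls in aq.FEATURE_CLASSES:
            np.testing.assert_allclose(a[cls].values, b[cls].values, atol=1e-9)

    def test_appending_a_qualifying_frame_strictly_increases_the_accumulator(self):
        traj = _toy_trajectory(n_frames=3, n_waters=1)
        grid = aq.make_grid((0, 0, 0), 10, 1.0)
        roles = aq.assign_atom_roles(traj)
        base = aq.accumulate(traj, grid, roles, HEAVY, water_hydrogens=False)
        extra = traj.coords[-1:].copy()
        extra[0, -1] = [0.0, 0.0, 0.0]  # water 2.9 Å from the acceptor
        longer = TrajectoryView(
            frame_times=np.append(traj.frame_times, traj.frame_times[-1] + 10.0),
            coords=np.concatenate([traj.coords, extra]),
            atoms=traj.atoms,
        )
        more = aq.accumulate(longer, grid, roles, HEAVY, water_hydrogens=False)
        n0, n1 = traj.n_frames, longer.n_frames
        pre_base = base["HBD"].values * n0 / 100.0
        pre_more = more["HBD"].values * n1 / 100.0
        g = tuple(grid.nearest_index(np.zeros(3)))
        assert pre_more[g] == pre_base[g] + 1

    def test_zero_frames_rejected(self):
        traj = _toy_trajectory(n_frames=1)
        empty = TrajectoryView(
            frame_times=np.empty(0), coords=np.empty((0, traj.n_atoms, 3)), atoms=traj.atoms
        )
        with pytest.raises(ValueError, match="no frames"):
            aq.accumulate(empty, aq.make_grid((0, 0, 0), 10, 1.0), aq.assign_atom_roles(traj), HEAVY)

    def test_values_are_bounded_by_count_ceiling(self):
        traj = _toy_trajectory(n_frames=5, n_waters=3)
        grid = aq.make_grid((0, 0, 0), 10, 1.0)
        roles = aq.assign_atom_roles(traj)
        dm = aq.accumulate(traj, grid, roles, HEAVY, water_hydrogens=False)
        max_partners = {
            "HBD": len(roles.acceptor_idx), "HBA": len(roles.donors),
            "PI": len(roles.anionic_groups), "NI": len(roles.cationic_groups),
            "H": len(roles.hydrophobic_idx), "AR": len(roles.aromatic_rings),
        }
        for cls in aq.FEATURE_CLASSES:
            assert dm[cls].values.min() >= 0
            assert dm[cls].values.max() <= 100 * max_partners[cls] * 3


class TestHalfMaxCutoff:
    @pytest.mark.parametrize("mx,expected", [(55.6, 27.8), (223.6, 111.8), (30.6, 15.3), (50.6, 25.3)])
    def test_half_of_field_maximum(self, mx, expected):
        grid = aq.make_grid((0, 0, 0), 2, 1.0)
        values = np.zeros((3, 3, 3))
        values[1, 1, 1] = mx
        field = aq.ScalarField(grid, values)
        assert aq.half_max_cutoff(field) == pytest.approx(expected)

    def test_all_zero_field_gives_zero(self):
        grid = aq.make_grid((0, 0, 0), 2, 1.0)
        assert aq.half_max_cutoff(aq.ScalarField.zeros(grid)) == 0.0
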