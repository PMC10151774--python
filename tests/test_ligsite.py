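import numpy as np
import pytest

from helpers import ca_cloud
from oracles import pockets_bruteforce, psp_counts_bruteforce

from msmdock import (
    ToyProteinSpec,
    build_grid,
    detect_pockets,
    filter_pockets,
    make_toy_protein,
    psp_scan,
    residue_pocket_scores,
    total_pocket_volume,
)
from msmdock.ligsite import Pocket, PocketGrid
from msmdock.structures_io import DegenerateStructureError


def grid_from_occupancy(occ: np.ndarray) -> PocketGrid:
    return PocketGrid(origin=np.zeros(3), spacing=1.0, occupancy=np.asarray(occ, bool))


def hollow_cube_occupancy(outer: int, pad: int = 2) -> np.ndarray:
    """A one-voxel-thick occupied shell inside an empty margin."""
    dims = outer + 2 * pad
    occ = np.zeros((dims, dims, dims), dtype=bool)
    sl = slice(pad, pad + outer)
    occ[sl, sl, sl] = True
    inner = slice(pad + 1, pad + outer - 1)
    occ[inner, inner, inner] = False
    return occ


class TestBuildGrid:
    def test_single_atom_digital_ball_matches_brute_force(self):
        s = ca_cloud([[0.0, 0.0, 0.0]])
        grid = build_grid(s, spacing=1.0, probe_radius=1.4)
        radius = 1.7 + 1.4
        idx = np.indices(grid.occupancy.shape).reshape(3, -1).T
        coords = grid.point_coords(idx)
        expect = (np.linalg.norm(coords, axis=1) <= radius).reshape(grid.occupancy.shape)
        np.testing.assert_array_equal(grid.occupancy, expect)

    def test_occupancy_monotone_in_probe_radius(self):
        s = ca_cloud([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        none = build_grid(s, probe_radius=0.0).occupancy.sum()
        some = build_grid(s, probe_radius=1.4).occupancy.sum()
        assert none <= some

    def test_no_occupied_point_on_boundary(self, toy_pair):
        _, open_ = toy_pair
        occ = build_grid(open_).occupancy
        assert not occ[0].any() and not occ[-1].any()
        assert not occ[:, 0].any() and not occ[:, -1].any()
        assert not occ[:, :, 0].any() and not occ[:, :, -1].any()

    def test_hydrogen_only_structure_rejected(self):
        from helpers import make_structure

        s = make_structure([(1, "HA", "H", (0.0, 0.0, 0.0))])
        with pytest.raises(DegenerateStructureError):
            build_grid(s)


class TestPspScan:
    def test_open_space_scores_zero(self):
        grid = grid_from_occupancy(np.zeros((6, 6, 6)))
        psp_scan(grid)
        assert grid.psp_count.max() == 0

    def test_center_of_closed_cube_scores_seven(self):
        occ = np.zeros((5, 5, 5), dtype=bool)
        occ[1:4, 1:4, 1:4] = True
        occ[2, 2, 2] = False
        grid = grid_from_occupancy(occ)
        psp_scan(grid)
        assert grid.psp_count[2, 2, 2] == 7

    def test_points_outside_hull_not_fully_enclosed(self):
        occ = hollow_cube_occupancy(5)
        grid = grid_from_occupancy(occ)
        psp_scan(grid)
        assert grid.psp_count[0, 0, 0] < 7
        assert (grid.psp_count[occ] == 0).all()

    def test_matches_ray_walk_oracle_on_random_grids(self, rng):
        for shape in [(6, 6, 6), (7, 5, 8), (9, 9, 9)]:
            occ = rng.random(shape) < 0.3
            grid = grid_from_occupancy(occ)
            psp_scan(grid)
            np.testing.assert_array_equal(grid.psp_count, psp_counts_bruteforce(occ))


class TestDetectPockets:
    def test_single_atom_has_no_pockets(self):
        s = ca_cloud([[0.0, 0.0, 0.0]])
        grid = build_grid(s)
        assert detect_pockets(psp_scan(grid)) == []

    def test_hollow_cube_single_pocket(self):
        # 5-voxel shell encloses a 3x3x3 interior: one 27-point pocket
        grid = grid_from_occupancy(hollow_cube_occupancy(5))
        pockets = detect_pockets(grid, min_psp=7, min_cluster_size=3)
        assert len(pockets) == 1
        assert pockets[0].n_points == 27
        assert pockets[0].volume == pytest.approx(27.0)

    def test_removing_a_wall_shrinks_the_pocket(self):
        occ = hollow_cube_occupancy(5)
        sealed = total_pocket_volume(detect_pockets(grid_from_occupancy(occ)))
        occ_open = occ.copy()
        occ_open[6, :, :] = False  # drop the +x wall
        opened = total_pocket_volume(detect_pockets(grid_from_occupancy(occ_open)))
        assert opened < sealed

    def test_equals_bruteforce_oracle_on_random_grids(self, rng):
        for shape in [(7, 7, 7), (8, 6, 9), (10, 10, 10)]:
            for _ in range(3):
                occ = rng.random(shape) < 0.35
                pockets = detect_pockets(
                    grid_from_occupancy(occ), min_psp=5, min_cluster_size=2
                )
                expected = pockets_bruteforce(occ, min_psp=5, min_cluster_size=2)
                assert len(pockets) == len(expected)
                for got, (want_points, _) in zip(pockets, expected):
                    assert {tuple(p) for p in got.point_indices} == want_points

    def test_min_psp_monotonicity(self, rng):
        occ = rng.random((9, 9, 9)) < 0.4
        grid = grid_from_occupancy(occ)
        vols = [
            total_pocket_volume(detect_pockets(grid, min_psp=k, min_cluster_size=1))
            for k in range(1, 8)
        ]
        assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_min_cluster_size_monotonicity(self, rng):
        occ = rng.random((9, 9, 9)) < 0.4
        grid = grid_from_occupancy(occ)
        vols = [
            total_pocket_volume(detect_pockets(grid, min_psp=5, min_cluster_size=m))
            for m in (1, 3, 5, 9)
        ]
        assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_lining_residues_recorded(self, toy_pair):
        _, open_ = toy_pair
        grid = build_grid(open_)
        pockets = detect_pockets(psp_scan(grid), structure=open_)
        assert pockets and pockets[0].lining_residues
        # lining residues must actually sit within the cutoff of some point
        points = grid.point_coords(pockets[0].point_indices)
        for rid in pockets[0].lining_residues:
            atom = open_.coord[open_.res_id == rid]
            d = np.linalg.norm(points[:, None, :] - atom[None, :, :], axis=-1).min()
            assert d <= 4.0 + 1e-9


class TestRigidMotionRobustness:
    def test_axis_aligned_quarter_turn_preserves_volume(self, toy_pair):
        _, open_ = toy_pair
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        turned = open_.transformed(rot, np.array([3.0, -2.0, 7.0]))
        v0 = total_pocket_volume(detect_pockets(build_grid(open_)))
        v1 = total_pocket_volume(detect_pockets(build_grid(turned)))
        assert v1 == pytest.approx(v0)

    def test_arbitrary_rotation_within_discretization_tolerance(self, toy_pair, rng):
        from helpers import random_rotation

        # spacing fine relative to the cavity so snapping aliasing is small
        _, open_ = toy_pair
        v0 = total_pocket_volume(detect_pockets(build_grid(open_, spacing=0.4)))
        turned = open_.transformed(random_rotation(rng), np.zeros(3))
        v1 = total_pocket_volume(detect_pockets(build_grid(turned, spacing=0.4)))
        assert abs(v1 - v0) / v0 < 0.2


class TestOpeningSignal:
    def test_open_conformation_has_strictly_larger_pocket_volume(self, toy_pair):
        closed, open_ = toy_pair
        v_closed = total_pocket_volume(detect_pockets(build_grid(closed)))
        v_open = total_pocket_volume(detect_pockets(build_grid(open_)))
        assert v_open > v_closed
        assert v_closed == 0.0


class TestResidueScores:
    def test_no_pockets_gives_zero_scores(self):
        s = ca_cloud([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        grid = build_grid(s)
        scores = residue_pocket_scores(s, grid, [])
        assert all(r.score == 0.0 for r in scores)

    def test_scores_match_formula_on_brute_forced_counts(self, toy_pair):
        _, open_ = toy_pair
        grid = build_grid(open_)
        pockets = detect_pockets(psp_scan(grid))
        scores = {r.residue_number: r.score for r in residue_pocket_scores(open_, grid, pockets)}
        points = np.vstack([grid.point_coords(p.point_indices) for p in pockets])
        for rid in open_.residue_ids():
            atoms = open_.coord[(open_.res_id == rid) & open_.heavy_mask]
            n_r = int(
                ((np.linalg.norm(points[:, None, :] - atoms[None, :, :], axis=-1) <= 4.0).any(axis=1)).sum()
            )
            assert scores[int(rid)] == pytest.approx(1.0 - np.exp(-0.05 * n_r), abs=1e-12)

    def test_adjacent_residue_outscores_distant_residue(self, toy_pair):
        _, open_ = toy_pair
        grid = build_grid(open_)
        pockets = detect_pockets(psp_scan(grid))
        scores = {r.residue_number: r.score for r in residue_pocket_scores(open_, grid, pockets)}
        center = open_.coord.mean(axis=0)
        dists = {
            int(rid): float(np.linalg.norm(open_.coord[open_.res_id == rid].mean(axis=0) - center))
            for rid in open_.residue_ids()
        }
        nearest = min(dists, key=dists.get)
        farthest = max(dists, key=dists.get)
        assert scores[nearest] > scores[farthest]
        assert all(0.0 <= v <= 1.0 for v in scores.values())


class TestFilterPockets:
    @staticmethod
    def _pocket(n):
        return Pocket(point_indices=np.zeros((n, 3), int), volume=float(n), lining_residues={})

    def test_threshold_zero_keeps_positive_scores(self):
        pairs = [(self._pocket(3), 0.3), (self._pocket(4), 0.9)]
        assert filter_pockets(pairs, 0.0) == pairs

    def test_threshold_filters_strictly(self):
        pairs = [(self._pocket(3), 0.1), (self._pocket(4), 0.3)]
        kept = filter_pockets(pairs, 0.2)
        assert len(kept) == 1 and kept[0][1] == 0.3

    def test_threshold_one_empties(self):
        pairs = [(self._pocket(3), 1.0)]
        assert filter_pockets(pairs, 1.0) == []


def test_total_volume_additivity():
    p27 = Pocket(point_indices=np.zeros((27, 3), int), volume=27.0, lining_residues={})
    p8 = Pocket(point_indices=np.zeros((8, 3), int), volume=8.0, lining_residues={})
    assert total_pocket_volume([]) == 0.0
    assert total_pocket_volume([p27]) == pytest.approx(27.0)
    assert total_pocket_volume([p27, p8]) == pytest.approx(35.0)
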