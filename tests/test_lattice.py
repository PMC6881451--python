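"""Lattice substrate: neighbourhoods, division sites, seeding, compaction."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spheroidca as sc
from spheroidca.lattice import neighbourhood_offsets, neighbourhood_sites

from oracles import brute_force_offsets

DIMS = (9, 9, 9)


class TestNeighbourhoods:
    @pytest.mark.parametrize(
        "order,kind,expected",
        [
            (1, sc.VONNEUMANN, 6),
            (1, sc.MOORE, 26),
            (2, sc.MOORE, 124),
            (2, sc.VONNEUMANN, 24),
        ],
    )
    def test_interior_counts_match_closed_forms(self, order, kind, expected):
        sites = neighbourhood_sites((4, 4, 4), order, kind, DIMS)
        assert len(sites) == expected
        assert len(set(sites)) == expected  # no duplicates
        assert (4, 4, 4) not in sites

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        x=st.tuples(*[st.integers(0, 8)] * 3),
        order=st.sampled_from([1, 2]),
        kind=st.sampled_from([sc.MOORE, sc.VONNEUMANN]),
    )
    def test_matches_brute_force_enumeration(self, x, order, kind):
        sites = set(neighbourhood_sites(x, order, kind, DIMS))
        expected = {
            tuple(np.add(x, o))
            for o in brute_force_offsets(order, kind)
            if all(0 <= c < d for c, d in zip(np.add(x, o), DIMS))
        }
        assert sites == expected

    def test_out_of_lattice_coordinate_rejected(self):
        with pytest.raises(ValueError):
            neighbourhood_sites((9, 0, 0), 1, sc.MOORE, DIMS)

    def test_offsets_metric(self):
        moore2 = neighbourhood_offsets(2, sc.MOORE)
        assert np.abs(moore2).max(axis=1).max() == 2
        vn2 = neighbourhood_offsets(2, sc.VONNEUMANN)
        assert np.abs(vn2).sum(axis=1).max() == 2


class TestFindDivisionSite:
    def test_single_central_cell_picks_a_face_neighbour(self, small_grid, rng):
        # the six face neighbours tie as nearest the centroid
        picks = {
            sc.find_division_site(small_grid, (4, 4, 4), parity=0, rng=rng)
            for _ in range(50)
        }
        faces = set(neighbourhood_sites((4, 4, 4), 1, sc.VONNEUMANN, DIMS))
        assert picks <= faces
        assert len(picks) > 1  # RNG actually breaks ties

    def test_fully_occupied_neighbourhood_returns_none(self, rng):
        grid = sc.CellGrid(sc.LatticeConfig(dims=(7, 7, 7)))
        grid.phase[...] = np.int8(int(sc.Phase.G0))
        assert sc.find_division_site(grid, (3, 3, 3), 0, rng) is None

    def test_rim_cell_with_single_empty_voxel_finds_it(self, rng):
        grid = sc.dense_sphere_grid(60.0, margin=4)
        coords = np.argwhere(grid.occupied)
        c = coords.mean(axis=0)
        d = np.sqrt(((coords - c) ** 2).sum(axis=1))
        rim = tuple(coords[np.argmax(d)])
        # occupy every empty voxel in both order-2 neighbourhoods except one
        sites = set(neighbourhood_sites(rim, 2, sc.MOORE, grid.dims)) | set(
            neighbourhood_sites(rim, 2, sc.VONNEUMANN, grid.dims)
        )
        empties = [s for s in sites if grid.phase[s] == -1]
        keep = empties[0]
        for s in empties[1:]:
            grid.set_cell(s, sc.Cell())
        for parity in (0, 1):
            found = sc.find_division_site(grid, rim, parity, rng)
            if found is not None:
                assert found == keep

    def test_unoccupied_origin_rejected(self, small_grid, rng):
        with pytest.raises(ValueError):
            sc.find_division_site(small_grid, (0, 0, 0), 0, rng)


class TestSeedSphere:
    def test_zero_and_one_cell(self, rng):
        grid = sc.CellGrid(sc.LatticeConfig(dims=(9, 9, 9)))
        sc.seed_sphere(grid, 0, rng)
        assert grid.n_cells == 0
        sc.seed_sphere(grid, 1, rng)
        assert grid.n_cells == 1
        assert grid.phase[4, 4, 4] != -1

    def test_seven_cells_are_centre_plus_faces(self, rng):
        grid = sc.CellGrid(sc.LatticeConfig(dims=(9, 9, 9)))
        sc.seed_sphere(grid, 7, rng)
        occ = set(map(tuple, np.argwhere(grid.occupied)))
        assert occ == {(4, 4, 4)} | set(neighbourhood_sites((4, 4, 4), 1, sc.VONNEUMANN, DIMS))

    def test_occupied_voxels_are_the_nearest_to_centre(self, rng):
        grid = sc.CellGrid(sc.LatticeConfig(dims=(11, 11, 11)))
        n = 57
        sc.seed_sphere(grid, n, rng)
        coords = np.argwhere(grid.occupied)
        centre = (np.asarray(grid.dims) - 1) / 2
        d_occ = np.sqrt(((coords - centre) ** 2).sum(axis=1))
        d_emp = np.sqrt(((np.argwhere(~grid.occupied) - centre) ** 2).sum(axis=1))
        assert d_occ.max() <= d_emp.min() + 1e-9

    def test_capacity_error(self, rng):
        grid = sc.CellGrid(sc.LatticeConfig(dims=(3, 3, 3)))
        with pytest.raises(ValueError):
            sc.seed_sphere(grid, 28, rng)

    def test_random_phases_and_clocks_within_durations(self, rng):
        grid = sc.CellGrid(sc.LatticeConfig(dims=(15, 15, 15)))
        sc.seed_sphere(grid, 500, rng)
        durs = np.asarray(sc.lattice.DEFAULT_PHASE_DURATIONS_H)
        phases = set()
        for xyz, cell in grid.iter_cells():
            assert cell.phase in (sc.Phase.G1, sc.Phase.S, sc.Phase.G2, sc.Phase.M)
            assert 0 <= cell.cycle_clock <= durs[int(cell.phase)] * cell.duration_scale
            phases.add(cell.phase)
        assert phases == {sc.Phase.G1, sc.Phase.S, sc.Phase.G2, sc.Phase.M}


class TestCompaction:
    def test_empty_grid_unchanged(self, rng):
        grid = sc.CellGrid(sc.LatticeConfig(dims=(9, 9, 9)))
        sc.compact_inward(grid, rng)
        assert grid.n_cells == 0

    def test_conserves_count_and_cell_state(self, rng):
        grid = sc.dense_sphere_grid(100.0)
        # tag cells with distinct clocks so state transport is checkable
        coords = np.argwhere(grid.occupied)
        grid.clock[tuple(coords.T)] = np.arange(len(coords), dtype=np.float64)
        before = sorted(grid.clock[tuple(np.argwhere(grid.occupied).T)])
        c = coords.mean(axis=0)
        d = np.sqrt(((coords - c) ** 2).sum(axis=1))
        for xyz in coords[np.argsort(d)][:5]:
            grid.remove_cell(tuple(xyz))
        removed = grid.n_cells
        sc.compact_inward(grid, rng)
        assert grid.n_cells == removed
        after = sorted(grid.clock[tuple(np.argwhere(grid.occupied).T)])
        assert len(after) == len(before) - 5

    def test_radial_occupancy_monotone_after_holes(self, rng):
        grid = sc.dense_sphere_grid(120.0)
        coords = np.argwhere(grid.occupied)
        c = coords.mean(axis=0)
        d = np.sqrt(((coords - c) ** 2).sum(axis=1))
        interior = coords[d < d.max() - 3]
        pick = interior[rng.choice(len(interior), size=10, replace=False)]
        for xyz in pick:
            grid.remove_cell(tuple(xyz))
        sc.compact_inward(grid, rng)
        # radial histogram oracle: every empty voxel lies at radii at or beyond
        # the outer occupied shell (no interior vacancies remain)
        occ = np.argwhere(grid.occupied)
        c2 = occ.mean(axis=0)
        d_occ = np.sqrt(((occ - c2) ** 2).sum(axis=1))
        emp = np.argwhere(~grid.occupied)
        d_emp = np.sqrt(((emp - c2) ** 2).sum(axis=1))
        assert d_emp.min() >= d_occ.max() - np.sqrt(3) - 1e-9

    def test_no_outward_neighbour_of_any_hole(self, rng):
        grid = sc.dense_sphere_grid(80.0)
        coords = np.argwhere(grid.occupied)
        c = coords.mean(axis=0)
        d = np.sqrt(((coords - c) ** 2).sum(axis=1))
        grid.remove_cell(tuple(coords[np.argmin(d)]))
        sc.compact_inward(grid, rng)
        c2 = np.argwhere(grid.occupied).mean(axis=0)
        for e in np.argwhere(~grid.occupied):
            de = ((e - c2) ** 2).sum()
            for o in neighbourhood_offsets(1, sc.MOORE):
                nb = e + o
                if np.all(nb >= 0) and np.all(nb < grid.dims) and grid.occupied[tuple(nb)]:
                    assert ((nb - c2) ** 2).sum() <= de + 1e-6


class TestCellGrid:
    def test_occupancy_exclusivity_by_construction(self, rng):
        grid = sc.CellGrid(sc.LatticeConfig(dims=(9, 9, 9)))
        sc.seed_sphere(grid, 40, rng)
        assert grid.n_cells == 40  # one cell per voxel: mask cardinality

    def test_cell_roundtrip(self):
        grid = sc.CellGrid(sc.LatticeConfig(dims=(5, 5, 5)))
        cell = sc.Cell(
            phase=sc.Phase.S,
            cycle_clock=3.0,
            duration_scale=1.05,
            fate=sc.Fate.DYING_HT,
            death_delay=40.0,
            arrest_remaining=2.0,
            hypoxic=True,
            division_parity=1,
        )
        grid.set_cell((2, 2, 2), cell)
        assert grid.get_cell((2, 2, 2)) == cell
        assert grid.get_cell((0, 0, 0)) is None

    def test_centroid_tracks_occupied_voxels(self):
        grid = sc.CellGrid(sc.LatticeConfig(dims=(9, 9, 9)))
        assert grid.centroid is None
        grid.set_cell((1, 1, 1), sc.Cell())
        grid.set_cell((3, 1, 1), sc.Cell())
        assert np.allclose(grid.centroid, [2, 1, 1])

    def test_invalid_config_rejected(self):
        with pytest.raises(Exception):
            sc.LatticeConfig(dims=(2, 9, 9))
        with pytest.raises(Exception):
            sc.LatticeConfig(voxel_edge_mm=0.0)
        with pytest.raises(ValueError):
            sc.Cell(cycle_clock=-1.0)
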