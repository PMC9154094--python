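"""Grid construction, occupancy pruning, void clustering, H-bond filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bridgewater import (
    PlacementParams,
    build_grid,
    classify_polar_atoms,
    cluster_voids,
    hbond_filter,
    load_complex,
    place_waters,
    place_waters_detailed,
    prune_occupied,
)
from bridgewater.structio import Atom, PolarAtomSet

from conftest import MINIMAL_PDB


def _atoms(xyz, element="C", role="protein", resname="GLY"):
    return [Atom(i + 1, element, element, np.asarray(p, float), resname,
                 i + 1, "A", role) for i, p in enumerate(xyz)]


def brute_single_linkage(points: np.ndarray, cutoff: float) -> list[frozenset]:
    """Union-find oracle: components of the <=cutoff proximity graph."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) <= cutoff:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [frozenset(g) for g in groups.values()]


class TestBuildGrid:
    def test_two_atom_ligand_box(self):
        grid = build_grid(np.array([[0.0, 0, 0], [4.0, 0, 0]]), spacing=1.0,
                          min_edge=0.5)
        np.testing.assert_allclose(grid.center, [2, 0, 0])
        assert grid.edge == 4.0
        lo, hi = grid.points.min(axis=0), grid.points.max(axis=0)
        np.testing.assert_allclose(lo, [0, -2, -2])
        np.testing.assert_allclose(hi, [4, 2, 2])

    def test_single_atom_ligand_floored_to_min_edge(self):
        grid = build_grid(np.array([[1.0, 2.0, 3.0]]), spacing=1.0, min_edge=6.0)
        assert grid.edge == 6.0
        assert np.max(np.abs(grid.points - grid.center)) <= 3.0 + 1e-12

    def test_point_count_matches_lattice_enumeration(self):
        lig = np.array([[0.0, 0, 0], [3.0, 0, 0], [0.0, 4.0, 0]])  # right triangle
        grid = build_grid(lig, spacing=1.0, min_edge=0.5)
        n_axis = int(np.floor(grid.edge / 1.0 + 1e-9)) + 1
        assert len(grid.points) == n_axis**3
        # explicit enumeration oracle
        axis = grid.center[0] - grid.edge / 2 + np.arange(n_axis) * 1.0
        assert np.isclose(axis[0], grid.points[:, 0].min())
        expected = {(round(x, 6), round(y, 6), round(z, 6))
                    for x in axis
                    for y in grid.center[1] - grid.edge / 2 + np.arange(n_axis) * 1.0
                    for z in grid.center[2] - grid.edge / 2 + np.arange(n_axis) * 1.0}
        got = {tuple(np.round(p, 6)) for p in grid.points}
        assert got == expected

    def test_points_in_lexicographic_order(self):
        grid = build_grid(np.array([[0.0, 0, 0]]), spacing=2.0, min_edge=4.0)
        as_tuples = [tuple(p) for p in np.round(grid.points, 9)]
        assert as_tuples == sorted(as_tuples)


class TestPruneOccupied:
    def test_no_obstacles_keeps_all_points(self):
        grid = build_grid(np.array([[0.0, 0, 0]]), spacing=1.0, min_edge=4.0)
        out = prune_occupied(grid, np.empty((0, 3)), clash_dist=2.0)
        assert len(out) == len(grid.points)

    def test_single_central_atom_removes_inner_shell(self):
        grid = build_grid(np.array([[0.0, 0, 0]]), spacing=1.0, min_edge=6.0)
        out = prune_occupied(grid, np.array([[0.0, 0, 0]]), clash_dist=2.0)
        survivors = {tuple(p) for p in out}
        assert (0.0, 0.0, 0.0) not in survivors
        assert (1.0, 0.0, 0.0) not in survivors          # face neighbor at 1.0
        assert (1.0, 1.0, 1.0) not in survivors          # corner at sqrt(3) < 2
        assert (2.0, 0.0, 0.0) in survivors              # boundary kept (>=)
        # brute-force all-pairs oracle
        keep = [p for p in grid.points
                if np.linalg.norm(p - np.array([0.0, 0, 0])) >= 2.0]
        np.testing.assert_array_equal(out, np.array(keep))

    def test_oversized_clash_empties_the_box(self):
        grid = build_grid(np.array([[0.0, 0, 0]]), spacing=1.0, min_edge=6.0)
        out = prune_occupied(grid, np.array([[0.5, 0.5, 0.5]]), clash_dist=50.0)
        assert len(out) == 0

    def test_grid_order_preserved(self, rng):
        grid = build_grid(np.array([[0.0, 0, 0]]), spacing=1.0, min_edge=6.0)
        obstacles = rng.uniform(-3, 3, size=(5, 3))
        out = prune_occupied(grid, obstacles, clash_dist=2.0)
        mask = [any(np.allclose(p, q) for q in out) for p in grid.points]
        np.testing.assert_array_equal(out, grid.points[mask])


class TestClusterVoids:
    def test_two_close_points_one_cluster(self):
        clusters = cluster_voids(np.array([[0.0, 0, 0], [1.0, 0, 0]]), 1.5, 2.0)
        assert len(clusters) == 1
        np.testing.assert_allclose(clusters[0].centroid, [0.5, 0, 0])

    def test_two_far_points_two_clusters(self):
        clusters = cluster_voids(np.array([[0.0, 0, 0], [5.0, 0, 0]]), 1.5, 2.0)
        assert len(clusters) == 2
        np.testing.assert_allclose(clusters[0].centroid, [0, 0, 0])
        np.testing.assert_allclose(clusters[1].centroid, [5, 0, 0])

    def test_empty_input(self):
        assert cluster_voids(np.empty((0, 3)), 2.0, 2.0) == []

    def test_merge_uses_mean_over_all_members(self):
        # two 2-point clusters at linkage > cluster_dist but centroids within
        # merge_dist; merged centroid is the mean over all four points, not
        # the mean of the two centroids (equal sizes here, so distinguish by
        # a 3-point vs 1-point pair)
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.6, 0, 0]])
        clusters = cluster_voids(pts, cluster_dist=1.1, merge_dist=2.7)
        assert len(clusters) == 1
        np.testing.assert_allclose(clusters[0].centroid, pts.mean(axis=0))

    def test_partition_matches_union_find_oracle(self, rng):
        for _ in range(10):
            pts = rng.uniform(0, 10, size=(30, 3))
            clusters = cluster_voids(pts, cluster_dist=1.8, merge_dist=1e-9)
            got = set()
            for c in clusters:
                idx = frozenset(int(np.argmin(np.linalg.norm(pts - m, axis=1)))
                                for m in c.members)
                got.add(idx)
            assert got == set(brute_single_linkage(pts, 1.8))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_post_merge_centroids_separated(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 8, size=(rng.integers(1, 60), 3))
        clusters = cluster_voids(pts, cluster_dist=1.5, merge_dist=2.0)
        cents = np.array([c.centroid for c in clusters])
        for i in range(len(cents)):
            for j in range(i + 1, len(cents)):
                assert np.linalg.norm(cents[i] - cents[j]) > 2.0

    def test_output_sorted_by_centroid(self, rng):
        pts = rng.uniform(0, 10, size=(40, 3))
        clusters = cluster_voids(pts, 1.2, 1.5)
        cents = [tuple(c.centroid) for c in clusters]
        assert cents == sorted(cents)


class TestHbondFilter:
    def _polar(self):
        lig = _atoms([[3.0, 0, 0]], element="O", role="ligand", resname="LIG")
        prot = _atoms([[-3.2, 0, 0]], element="N")
        return PolarAtomSet(ligand_polar=lig, protein_polar=prot)

    def test_accepts_with_contacts_recorded(self):
        placed = hbond_filter([np.zeros(3)], self._polar(), 0.0, 3.5)
        assert len(placed) == 1
        assert placed[0].ligand_contact == (1, 3.0)
        assert placed[0].protein_contact[1] == pytest.approx(3.2)

    def test_rejects_when_protein_side_out_of_shell(self):
        polar = self._polar()
        polar.protein_polar[0].coord = np.array([-4.1, 0.0, 0.0])
        assert hbond_filter([np.zeros(3)], polar, 0.0, 3.5) == []

    def test_inner_radius_excludes_too_close_contacts(self):
        polar = self._polar()
        assert len(hbond_filter([np.zeros(3)], polar, 2.0, 3.5)) == 1
        assert hbond_filter([np.zeros(3)], polar, 3.1, 3.5) == []

    def test_widening_shell_never_loses_waters(self, rng):
        lig = _atoms(rng.uniform(-4, 4, (5, 3)), element="O", role="ligand",
                     resname="LIG")
        prot = _atoms(rng.uniform(-4, 4, (8, 3)), element="N")
        polar = PolarAtomSet(ligand_polar=lig, protein_polar=prot)
        cents = list(rng.uniform(-4, 4, (20, 3)))
        narrow = {tuple(p.coord) for p in hbond_filter(cents, polar, 0.5, 3.0)}
        wide = {tuple(p.coord) for p in hbond_filter(cents, polar, 0.2, 3.8)}
        assert narrow <= wide


class TestPlaceWaters:
    def test_all_carbon_ligand_places_nothing(self):
        cx = load_complex(MINIMAL_PDB, "LIG")
        assert place_waters(cx) == []

    def test_planted_site_uniquely_recovered(self, pocket_fixture):
        placed = place_waters(pocket_fixture.complex)
        site = pocket_fixture.planted_sites[0].coord
        dists = [np.linalg.norm(p.coord - site) for p in placed]
        assert sum(d <= 1.4 for d in dists) == 1

    def test_placed_waters_stay_inside_grid_box(self, two_site_fixture):
        result = place_waters_detailed(two_site_fixture.complex)
        half = result.grid.edge / 2 + 1e-9
        for p in result.placed:
            assert np.all(np.abs(p.coord - result.grid.center) <= half)

    def test_increasing_clash_dist_never_adds_candidates(self, pocket_fixture):
        import dataclasses

        cx = pocket_fixture.complex
        counts = []
        for clash in (1.6, 2.0, 2.4, 2.8):
            params = dataclasses.replace(PlacementParams(), clash_dist=clash)
            counts.append(len(place_waters_detailed(cx, params).candidates))
        assert counts == sorted(counts, reverse=True)

    def test_contacts_come_from_polar_atoms(self, pocket_fixture):
        cx = pocket_fixture.complex
        polar = classify_polar_atoms(cx)
        lig_serials = {a.serial for a in polar.ligand_polar}
        prot_serials = {a.serial for a in polar.protein_polar}
        for p in place_waters(cx):
            assert p.ligand_contact[0] in lig_serials
            assert p.protein_contact[0] in prot_serials
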