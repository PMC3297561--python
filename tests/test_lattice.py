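"""Lattice geometry: construction, topology, paths, extents."""

import math

import numpy as np
import pytest

from mtencode.errors import BoundaryError, ParameterError
from mtencode.lattice import (
    Direction,
    LatticeSpec,
    PatchKind,
    build_lattice,
    monomer_extent,
    neighborhood_patch,
    patch_extent,
    trace_path,
)


def distance_threshold_graph(lattice):
    """Independent geometric oracle: sites are neighbors iff their minimum
    monomer-center distance is below 1.2x the lateral lattice constant."""
    spec = lattice.spec
    chord = 2 * spec.radius * math.sin(math.pi / spec.n_protofilaments)
    # lateral monomer-contact offset is 0.92 nm for both lattice families
    threshold = 1.2 * math.hypot(chord, 0.92)
    idxs = lattice.site_indices
    coords = {i: lattice.site(*i).monomer_centers() for i in idxs}
    edges = set()
    for i, a in enumerate(idxs):
        for b in idxs[i + 1 :]:
            d = np.linalg.norm(
                coords[a][:, None] - coords[b][None, :], axis=-1
            ).min()
            if d <= threshold:
                edges.add(frozenset((a, b)))
    return edges


class TestBuild:
    def test_site_count_single_ring(self):
        lat = build_lattice(LatticeSpec(lattice_type="B", n_dimer_rings=1))
        assert len(lat) == 13

    @pytest.mark.parametrize("lattice_type", ["A", "B"])
    def test_site_count(self, lattice_type):
        lat = build_lattice(
            LatticeSpec(lattice_type=lattice_type, n_dimer_rings=10)
        )
        assert len(lat) == 13 * 10

    def test_monomer_centers_on_centerline_cylinder(self, lattice_B):
        # 25 nm outer / 15 nm inner wall -> 10 nm centerline radius
        pts = lattice_B.monomer_coordinates()
        radii = np.hypot(pts[:, 0], pts[:, 1])
        assert np.allclose(radii, 10.0, atol=1e-6)

    def test_beta_offset_along_protofilament(self, lattice_A):
        for site in lattice_A.sites[:20]:
            d = np.asarray(site.beta_center) - np.asarray(site.alpha_center)
            assert np.allclose(d, [0, 0, lattice_A.spec.monomer_length])

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            (dict(n_protofilaments=2), "n_protofilaments"),
            (dict(outer_diameter=10.0), "diameters"),
            (dict(monomer_length=0.0), "monomer_length"),
            (dict(n_dimer_rings=0), "n_dimer_rings"),
        ],
    )
    def test_invalid_spec_names_field(self, kwargs, field):
        base = dict(lattice_type="B", n_dimer_rings=5)
        base.update(kwargs)
        with pytest.raises(ParameterError, match=field):
            LatticeSpec(**base)


class TestTopology:
    @pytest.mark.parametrize("lattice_type,rings", [("A", 20), ("B", 20)])
    def test_neighbor_map_matches_distance_oracle(self, lattice_type, rings):
        lat = build_lattice(
            LatticeSpec(lattice_type=lattice_type, n_dimer_rings=rings)
        )
        labeled = {
            frozenset((a, s.index))
            for a in lat.site_indices
            for s in lat.neighbors(a).values()
        }
        assert labeled == distance_threshold_graph(lat)

    @pytest.mark.parametrize("fixture", ["lattice_A", "lattice_B"])
    def test_interior_degree_six(self, fixture, request):
        lat = request.getfixturevalue(fixture)
        margin = lat.spec.wrap_offset + 1
        for p in range(13):
            for a in range(margin, lat.spec.n_dimer_rings - margin):
                assert lat.degree((p, a)) == 6

    @pytest.mark.parametrize("fixture", ["lattice_A", "lattice_B"])
    def test_neighbor_symmetry(self, fixture, request):
        lat = request.getfixturevalue(fixture)
        for a in lat.site_indices:
            for d, s in lat.neighbors(a).items():
                back = lat.neighbors(s.index)
                assert back[d.opposite].index == a

    def test_edge_degrees_below_six(self, lattice_B):
        degs = {lat_deg for idx in lattice_B.site_indices
                if (lat_deg := lattice_B.degree(idx)) < 6}
        assert degs and all(d < 6 for d in degs)


class TestTracePath:
    def test_protofilament_path_is_axial(self, lattice_B):
        start = lattice_B.site(4, 5)
        path = trace_path(lattice_B, start, "protofilament", 3)
        assert [s.index for s in path] == [(4, 5), (4, 6), (4, 7), (4, 8)]
        assert not path.truncated

    @pytest.mark.parametrize(
        "fixture", ["lattice_A", "lattice_B"]
    )
    def test_full_helical_turn_returns_to_protofilament(self, fixture, request):
        # a 13-step lateral walk closes the cylinder; the axial shift is the
        # helix pitch in dimer rings: accumulate 13 x lateral_rise / 8 nm,
        # rounded up to the dimer ring the seam contacts actually reach
        lat = request.getfixturevalue(fixture)
        start = lat.site(0, 2)
        path = trace_path(lat, start, "helical", 13)
        assert not path.truncated
        end = path.sites[-1]
        assert end.protofilament_index == 0
        pitch = 13 * lat.spec.lateral_rise / lat.spec.dimer_length
        assert end.axial_index - 2 == math.ceil(pitch - 1e-9)

    def test_anti_helical_decrements_protofilament(self, lattice_B):
        start = lattice_B.site(0, 5)
        path = trace_path(lattice_B, start, "anti_helical", 1)
        assert path.sites[-1].protofilament_index == 12

    def test_path_exiting_axially_is_truncated_not_error(self, lattice_B):
        last = lattice_B.spec.n_dimer_rings - 1
        path = trace_path(lattice_B, lattice_B.site(3, last - 1), "protofilament", 5)
        assert path.truncated
        assert len(path) == 2

    def test_consecutive_sites_are_neighbors_in_class(self, lattice_A):
        path = trace_path(lattice_A, lattice_A.site(2, 1), "anti_helical", 6)
        for s1, s2 in zip(path.sites, path.sites[1:]):
            assert lattice_A.neighbor(s1, Direction.ANTI_HELICAL_PLUS).index == s2.index


class TestPatches:
    def test_a_lattice_patch_has_seven_dimers(self, patch_A):
        assert patch_A.patch_kind is PatchKind.A7
        assert len(patch_A.members) == 7
        assert patch_A.members[0] is patch_A.center

    def test_b_lattice_patch_has_nine_dimers(self, patch_B):
        assert patch_B.patch_kind is PatchKind.B9
        assert len(patch_B.members) == 9

    def test_a7_members_are_center_plus_neighbors(self, lattice_A, patch_A):
        neigh = {s.index for s in lattice_A.neighbors(patch_A.center).values()}
        assert {m.index for m in patch_A.peripheral} == neigh

    def test_edge_center_raises_boundary_error(self, lattice_A):
        with pytest.raises(BoundaryError):
            neighborhood_patch(lattice_A, lattice_A.site(3, 0))


class TestExtent:
    def test_degenerate_single_dimer_extent_is_monomer_length(self, lattice_A):
        assert monomer_extent([lattice_A.site(1, 1)]) == pytest.approx(4.0)

    def test_a7_extent_near_camkii_breadth(self, patch_A):
        assert 16.0 <= patch_extent(patch_A) <= 24.0

    def test_a7_and_b9_target_extents_agree(self, patch_A, patch_B):
        from mtencode.hexagon import target_dimers

        ext_a = patch_extent(patch_A)
        ext_b6 = monomer_extent(target_dimers(patch_B, "B1"))
        assert abs(ext_a - ext_b6) < 1.0
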