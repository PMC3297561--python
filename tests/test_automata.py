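"""MAP rules, motor guidance, tail patterns, and emergent logic gates."""

import pytest

from mtencode.automata import (
    Circuit,
    GateConfig,
    GateType,
    IOMode,
    MAPAttachment,
    MAPRole,
    guide_motor,
    map_attachment_sites,
    run_gate,
    tail_pattern,
    validate_map_spacing,
)
from mtencode.encoding import LatticePhospho
from mtencode.errors import ConfigurationError, ParameterError
from mtencode.lattice import TailState, trace_path


def phosphorylate(lattice, indices, state=1):
    ph = LatticePhospho(lattice)
    for idx in indices:
        ph.set_state(idx, state)
    return ph


class TestMAPAttachment:
    def test_all_zero_pattern_gives_no_sites(self, lattice_B):
        ph = LatticePhospho(lattice_B)
        assert map_attachment_sites(lattice_B, ph) == set()

    def test_site_with_two_phosphorylated_neighbors_included(self, lattice_B):
        # a 3-dimer phosphorylated protofilament run: only the middle dimer
        # has two phosphorylated neighbors
        ph = phosphorylate(lattice_B, [(4, 8), (4, 9), (4, 10)])
        sites = map_attachment_sites(lattice_B, ph, rules=("neighbors",))
        assert sites == {(4, 9)}

    def test_crossing_paths_mark_intersection(self, lattice_B):
        pf_run = [(6, a) for a in range(9, 16)]
        helical_run = [
            s.index for s in trace_path(lattice_B, lattice_B.site(3, 12), "helical", 6)
        ]
        assert (6, 12) in helical_run
        ph = phosphorylate(lattice_B, pf_run + helical_run)
        sites = map_attachment_sites(lattice_B, ph, rules=("intersections",))
        assert (6, 12) in sites

    def test_default_rule_is_union(self, lattice_B):
        pf_run = [(6, a) for a in range(9, 16)]
        ph = phosphorylate(lattice_B, pf_run)
        union = map_attachment_sites(lattice_B, ph)
        neigh = map_attachment_sites(lattice_B, ph, rules=("neighbors",))
        inter = map_attachment_sites(lattice_B, ph, rules=("intersections",))
        assert union == neigh | inter

    def test_unknown_rule_rejected(self, lattice_B):
        with pytest.raises(ParameterError):
            map_attachment_sites(lattice_B, LatticePhospho(lattice_B), rules=("x",))


class TestSpacing:
    def test_two_dimer_spacing_within_band(self, lattice_B):
        report = validate_map_spacing(lattice_B, [(0, 5), (0, 7)])
        assert len(report.spacings) == 1
        assert report.spacings[0]["spacing_nm"] == pytest.approx(16.0)
        assert report.spacings[0]["within_band"]

    def test_one_dimer_spacing_flagged(self, lattice_B):
        report = validate_map_spacing(lattice_B, [(0, 5), (0, 6)])
        assert report.flagged and report.flagged[0]["spacing_nm"] == pytest.approx(8.0)

    def test_single_map_gives_empty_report(self, lattice_B):
        assert validate_map_spacing(lattice_B, [(0, 5)]).spacings == []


class TestMotor:
    def test_straight_run_delivers_at_map(self, lattice_B):
        track = [(3, a) for a in range(5, 11)]
        ph = phosphorylate(lattice_B, track)
        maps = [MAPAttachment((3, 10), MAPRole.STRUCTURAL)]
        walk = guide_motor(lattice_B, ph, lattice_B.site(3, 5), maps)
        assert walk.status == "delivered"
        assert [s.index for s in walk.sites] == track

    def test_isolated_start_stalls(self, lattice_B):
        ph = phosphorylate(lattice_B, [(5, 5)])
        walk = guide_motor(lattice_B, ph, lattice_B.site(5, 5))
        assert walk.status == "stalled"
        assert len(walk.sites) == 1

    def test_unphosphorylated_start_rejected(self, lattice_B):
        ph = LatticePhospho(lattice_B)
        with pytest.raises(ParameterError):
            guide_motor(lattice_B, ph, lattice_B.site(5, 5))

    def test_helical_track_follows_trace_path(self, lattice_B):
        oracle = trace_path(lattice_B, lattice_B.site(2, 5), "helical", 6)
        ph = phosphorylate(lattice_B, [s.index for s in oracle])
        walk = guide_motor(lattice_B, ph, lattice_B.site(2, 5))
        assert [s.index for s in walk.sites] == [s.index for s in oracle.sites]

    def test_never_leaves_phosphorylated_track(self, lattice_B):
        ph = phosphorylate(lattice_B, [(3, a) for a in range(4, 12)] + [(4, 6)])
        walk = guide_motor(lattice_B, ph, lattice_B.site(3, 4))
        assert all(ph.is_phosphorylated(s) for s in walk.sites)

    def test_walk_is_deterministic(self, lattice_B):
        ph = phosphorylate(lattice_B, [(3, a) for a in range(4, 12)])
        w1 = guide_motor(lattice_B, ph, lattice_B.site(3, 4))
        w2 = guide_motor(lattice_B, ph, lattice_B.site(3, 4))
        assert [s.index for s in w1.sites] == [s.index for s in w2.sites]


class TestTails:
    def test_all_zero_all_down(self, lattice_B):
        tails = tail_pattern(lattice_B, LatticePhospho(lattice_B))
        assert all(
            t["alpha"] is TailState.DOWN and t["beta"] is TailState.DOWN
            for t in tails.values()
        )

    def test_beta_phosphorylation_raises_beta_tail(self, lattice_B):
        ph = phosphorylate(lattice_B, [(2, 3)], state=1)
        tails = tail_pattern(lattice_B, ph)
        assert tails[(2, 3)] == {"alpha": TailState.DOWN, "beta": TailState.UP}

    def test_alpha_phosphorylation_raises_alpha_tail(self, lattice_B):
        ph = phosphorylate(lattice_B, [(2, 3)], state=2)
        tails = tail_pattern(lattice_B, ph)
        assert tails[(2, 3)] == {"alpha": TailState.UP, "beta": TailState.DOWN}

    def test_hexagonal_pattern_maps_to_hexagonal_up_motif(self, lattice_B, patch_B):
        up_ring = [m.index for m in patch_B.peripheral]
        ph = phosphorylate(lattice_B, up_ring, state=1)
        tails = tail_pattern(lattice_B, ph)
        up_sites = {i for i, t in tails.items() if t["beta"] is TailState.UP}
        assert up_sites == set(up_ring)


TRUTH_TABLES = {
    GateType.AND: {(0, 0): 0, (1, 0): 0, (0, 1): 0, (1, 1): 1},
    GateType.XOR: {(0, 0): 0, (1, 0): 1, (0, 1): 1, (1, 1): 0},
}


class TestGates:
    @pytest.mark.parametrize("gate", [GateType.AND, GateType.XOR])
    @pytest.mark.parametrize("io_mode", [IOMode.MAPS_AS_INPUT, IOMode.MAPS_AS_OUTPUT])
    @pytest.mark.parametrize("bits", [(0, 0), (1, 0), (0, 1), (1, 1)])
    def test_truth_tables_emerge(self, lattice_B, gate, io_mode, bits):
        config = GateConfig(gate=gate, io_mode=io_mode, junction=(6, 12))
        run = run_gate(lattice_B, config, bits)
        assert run.output == TRUTH_TABLES[gate][bits]

    def test_and_coincidence_logs_merge(self, lattice_B):
        config = GateConfig(gate="AND", io_mode="maps_as_input", junction=(6, 12))
        run = run_gate(lattice_B, config, (1, 1))
        assert [c["event"] for c in run.cancellations] == ["merge"]
        assert run.cancellations[0]["site"] == (6, 12)

    def test_xor_coincidence_logs_annihilation(self, lattice_B):
        config = GateConfig(gate="XOR", io_mode="maps_as_input", junction=(6, 12))
        run = run_gate(lattice_B, config, (1, 1))
        assert [c["event"] for c in run.cancellations] == ["annihilate"]

    @pytest.mark.parametrize("junction", [(6, 8), (6, 14), (1, 12)])
    def test_truth_table_invariant_under_translation(self, lattice_B, junction):
        for gate in GateType:
            config = GateConfig(gate=gate, io_mode="maps_as_input", junction=junction)
            row = tuple(
                run_gate(lattice_B, config, bits).output
                for bits in ((0, 0), (1, 0), (0, 1), (1, 1))
            )
            expected = (0, 0, 0, 1) if gate is GateType.AND else (0, 1, 1, 0)
            assert row == expected

    def test_edge_junction_rejected(self, lattice_B):
        config = GateConfig(gate="AND", io_mode="maps_as_input", junction=(6, 0))
        with pytest.raises(ConfigurationError):
            run_gate(lattice_B, config, (1, 1))

    def test_bad_inputs_rejected(self, lattice_B):
        config = GateConfig(gate="AND", io_mode="maps_as_input", junction=(6, 12))
        with pytest.raises(ParameterError):
            run_gate(lattice_B, config, (1, 2))


class TestCircuits:
    def test_not_from_xor_with_constant(self, lattice_B):
        c = Circuit(lattice_B)
        c.add_gate("not", "XOR", ("x", 1))
        assert [c.evaluate({"x": x})["not"] for x in (0, 1)] == [1, 0]

    def test_or_from_xor_and_and(self, lattice_B):
        c = Circuit(lattice_B)
        c.add_gate("x1", "XOR", ("a", "b"))
        c.add_gate("a1", "AND", ("a", "b"))
        c.add_gate("or", "XOR", ("x1", "a1"))
        for a in (0, 1):
            for b in (0, 1):
                assert c.evaluate({"a": a, "b": b})["or"] == (a | b)

    def test_single_gate_circuit_matches_run_gate(self, lattice_B):
        c = Circuit(lattice_B)
        c.add_gate("g", "AND", ("a", "b"))
        config = GateConfig(
            gate="AND", io_mode="maps_as_input", junction=Circuit._default_junction(lattice_B)
        )
        for bits in ((0, 0), (1, 0), (0, 1), (1, 1)):
            direct = run_gate(lattice_B, config, bits).output
            assert c.evaluate({"a": bits[0], "b": bits[1]})["g"] == direct

    def test_cyclic_wiring_rejected(self, lattice_B):
        c = Circuit(lattice_B)
        c.add_gate("g1", "XOR", ("g2", 1))
        c.add_gate("g2", "XOR", ("g1", 1))
        with pytest.raises(ParameterError, match="cyclic"):
            c.evaluate()
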