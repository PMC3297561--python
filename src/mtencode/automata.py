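"""Pattern-driven lattice behaviors: MAP attachment rules, motor-protein
guidance, C-terminal tail patterns, and signal-propagation logic gates.

The logic gates are discrete-time token automata on the lattice graph.  A
token occupies one site per timestep and advances one neighbor per step
along its direction class.  The only non-trivial mechanics live at a single
junction site:

* two tokens co-arriving with equal phase cancel their lateral components
  and merge into one token emitted along the gate's output line;
* two tokens co-arriving with opposite phase annihilate;
* a lone token either passes straight through (AND junctions) or is
  redirected onto the output line (XOR junctions).

With inputs injected in phase (AND) or in opposite phase (XOR), the AND and
XOR truth tables emerge from propagation alone — there is no table lookup.
Gates read inputs from MAPs and write output along the central protofilament,
or read from helical/anti-helical tubulin paths and write output onto a MAP.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .encoding import LatticePhospho, STATE_ALPHA, STATE_BETA
from .errors import ConfigurationError, ParameterError, SimulationError
from .lattice import (
    Direction,
    DimerSite,
    MTLattice,
    TailState,
    trace_path,
)

__all__ = [
    "MAPRole",
    "MAPAttachment",
    "map_attachment_sites",
    "validate_map_spacing",
    "MotorWalk",
    "guide_motor",
    "tail_pattern",
    "GateType",
    "IOMode",
    "GateConfig",
    "Signal",
    "GateRun",
    "run_gate",
    "Circuit",
    "MAP_SPACING_BAND_NM",
]

#: optimal MAP spacing along a protofilament, nm (two to three dimers)
MAP_SPACING_BAND_NM = (15.0, 25.0)


class MAPRole(str, enum.Enum):
    INPUT = "input"
    OUTPUT = "output"
    STRUCTURAL = "structural"


@dataclass(frozen=True)
class MAPAttachment:
    site: Tuple[int, int]
    role: MAPRole = MAPRole.STRUCTURAL


# ---------------------------------------------------------------------------
# MAP attachment rules
# ---------------------------------------------------------------------------

_PATH_CLASSES = ("protofilament", "helical", "anti_helical")


def _phospho_runs(lattice, phospho, direction_class, min_run):
    """Sites on maximal phosphorylated runs of >= min_run along one class."""
    plus = {
        "protofilament": Direction.PROTOFILAMENT_PLUS,
        "helical": Direction.HELICAL_PLUS,
        "anti_helical": Direction.ANTI_HELICAL_PLUS,
    }[direction_class]
    on_path: Set[tuple] = set()
    seen: Set[tuple] = set()
    for idx in phospho.phosphorylated_indices():
        if idx in seen:
            continue
        # rewind to the start of this run
        start = idx
        while True:
            prev = lattice.neighbor(start, plus.opposite)
            if prev is None or not phospho.is_phosphorylated(prev):
                break
            start = prev.index
            if start == idx:  # closed loop around the cylinder
                break
        run = [start]
        while True:
            nxt = lattice.neighbor(run[-1], plus)
            if nxt is None or not phospho.is_phosphorylated(nxt):
                break
            if nxt.index == start:
                break
            run.append(nxt.index)
        seen.update(run)
        if len(run) >= min_run:
            on_path.update(run)
    return on_path


def map_attachment_sites(
    lattice: MTLattice,
    phospho: LatticePhospho,
    rules: Iterable[str] = ("neighbors", "intersections"),
    min_run: int = 3,
) -> Set[tuple]:
    """Sites marked for MAP attachment by the phosphorylation pattern.

    Rule ``"neighbors"``: a phosphorylated dimer with at least two
    phosphorylated lattice neighbors.  Rule ``"intersections"``: a site
    where phosphorylated paths of two different direction classes
    (protofilament / helical / anti-helical, runs of at least ``min_run``
    dimers) cross.  The default is the union of both rules.
    """
    rules = set(rules)
    unknown = rules - {"neighbors", "intersections"}
    if unknown:
        raise ParameterError(f"unknown MAP rules: {sorted(unknown)}")
    out: Set[tuple] = set()
    if "neighbors" in rules:
        for idx in phospho.phosphorylated_indices():
            n_phos = sum(
                phospho.is_phosphorylated(s)
                for s in lattice.neighbors(idx).values()
            )
            if n_phos >= 2:
                out.add(idx)
    if "intersections" in rules:
        per_class = [
            _phospho_runs(lattice, phospho, c, min_run) for c in _PATH_CLASSES
        ]
        for i in range(len(per_class)):
            for j in range(i + 1, len(per_class)):
                out |= per_class[i] & per_class[j]
    return out


@dataclass
class SpacingReport:
    """Nearest-neighbor MAP spacings per protofilament, with out-of-band
    flags (optimal band 15-25 nm, i.e. two to three dimer lengths)."""

    spacings: List[dict] = field(default_factory=list)

    @property
    def flagged(self) -> List[dict]:
        return [s for s in self.spacings if not s["within_band"]]


def validate_map_spacing(
    lattice: MTLattice, attachments: Iterable
) -> SpacingReport:
    """Check consecutive MAP spacings along each protofilament against the
    optimal motor-transport band."""
    lo, hi = MAP_SPACING_BAND_NM
    by_pf: Dict[int, List[int]] = {}
    for att in attachments:
        idx = att.site if isinstance(att, MAPAttachment) else tuple(att)
        by_pf.setdefault(idx[0], []).append(idx[1])
    report = SpacingReport()
    for pf, axials in sorted(by_pf.items()):
        axials.sort()
        for a1, a2 in zip(axials, axials[1:]):
            nm = (a2 - a1) * lattice.spec.dimer_length
            report.spacings.append(
                {
                    "protofilament": pf,
                    "pair": ((pf, a1), (pf, a2)),
                    "spacing_nm": nm,
                    "within_band": lo <= nm <= hi,
                }
            )
    return report


# ---------------------------------------------------------------------------
# Motor guidance
# ---------------------------------------------------------------------------

#: preference order for plus-end progress (ties never occur: strict order)
_MOTOR_PREFERENCE = (
    Direction.PROTOFILAMENT_PLUS,
    Direction.HELICAL_PLUS,
    Direction.ANTI_HELICAL_PLUS,
)


@dataclass
class MotorWalk:
    sites: List[DimerSite]
    status: str  # "delivered" | "stalled" | "exited"


def guide_motor(
    lattice: MTLattice,
    phospho: LatticePhospho,
    start: DimerSite,
    attachments: Iterable = (),
    max_steps: int = 10000,
) -> MotorWalk:
    """Deterministic plus-end walk along the phosphorylated pathway.

    At each step the motor moves to the phosphorylated neighbor that
    maximizes plus-end progress (protofilament+ preferred, then helical+,
    then anti-helical+).  It terminates ``delivered`` on reaching a
    structural/output MAP site, ``stalled`` when no phosphorylated
    plus-ward neighbor exists, and ``exited`` on walking off the lattice.
    """
    start = lattice.site(*start.index) if isinstance(start, DimerSite) else lattice.site(*start)
    near_phos = phospho.is_phosphorylated(start) or any(
        phospho.is_phosphorylated(s) for s in lattice.neighbors(start).values()
    )
    if not near_phos:
        raise ParameterError(
            "motor start must be phosphorylated or adjacent to a "
            "phosphorylated site"
        )
    stop_sites = {
        (a.site if isinstance(a, MAPAttachment) else tuple(a))
        for a in attachments
        if not isinstance(a, MAPAttachment) or a.role is not MAPRole.INPUT
    }
    walk = [start]
    for _ in range(max_steps):
        here = walk[-1]
        if here.index in stop_sites and len(walk) > 1:
            return MotorWalk(walk, "delivered")
        candidates = [
            lattice.neighbor(here, d)
            for d in _MOTOR_PREFERENCE
        ]
        step = next(
            (s for s in candidates if s is not None and phospho.is_phosphorylated(s)),
            None,
        )
        if step is None:
            # off the plus edge with a phosphorylated track continuing?
            if all(
                lattice.neighbor(here, d) is None for d in _MOTOR_PREFERENCE
            ):
                return MotorWalk(walk, "exited")
            return MotorWalk(walk, "stalled")
        walk.append(step)
    return MotorWalk(walk, "stalled")


# ---------------------------------------------------------------------------
# C-terminal tail pattern
# ---------------------------------------------------------------------------


def tail_pattern(lattice: MTLattice, phospho: LatticePhospho) -> Dict[tuple, dict]:
    """Per-dimer C-terminal tail states implied by the phosphorylation map.

    A phosphorylated monomer's tail flips to the extended up-state (state 1:
    beta tail up; state 2: alpha tail up); all other tails stay down.
    """
    out = {}
    for idx in lattice.site_indices:
        s = phospho.state(idx)
        out[idx] = {
            "alpha": TailState.UP if s == STATE_ALPHA else TailState.DOWN,
            "beta": TailState.UP if s == STATE_BETA else TailState.DOWN,
        }
    return out


# ---------------------------------------------------------------------------
# Logic gates
# ---------------------------------------------------------------------------


class GateType(str, enum.Enum):
    AND = "AND"
    XOR = "XOR"


class IOMode(str, enum.Enum):
    MAPS_AS_INPUT = "maps_as_input"
    MAPS_AS_OUTPUT = "maps_as_output"


#: direction of travel of the two gate inputs toward the junction
_INPUT_DIRECTIONS = (Direction.HELICAL_PLUS, Direction.ANTI_HELICAL_PLUS)

_MAP_DIRECTION = "map"


@dataclass(frozen=True)
class Signal:
    """A propagating token: one site per timestep, phase fixed at injection."""

    site: tuple
    direction: object  # Direction or "map"
    phase: int
    timestep: int


@dataclass(frozen=True)
class GateConfig:
    """One two-input gate anchored at an interior junction site.

    Inputs approach the junction along the helical+ and anti-helical+
    classes from ``arm_length`` steps away; in ``maps_as_input`` mode those
    entry sites carry the input MAPs, in ``maps_as_output`` mode the output
    MAP sits on the junction and the protofilament output line is unused.
    """

    gate: GateType
    io_mode: IOMode
    junction: Tuple[int, int]
    arm_length: int = 4
    output_arm_length: int = 3
    step_cap: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "gate", GateType(self.gate))
        object.__setattr__(self, "io_mode", IOMode(self.io_mode))
        if self.arm_length < 1 or self.output_arm_length < 1:
            raise ParameterError("arm lengths must be >= 1")

    @property
    def input_phases(self) -> Tuple[int, int]:
        """AND inputs are injected in phase, XOR inputs in opposite phase."""
        return (1, 1) if self.gate is GateType.AND else (1, -1)

    @property
    def redirect_lone(self) -> bool:
        """XOR junction geometry turns a lone token onto the output line."""
        return self.gate is GateType.XOR

    def input_sites(self, lattice: MTLattice) -> Tuple[tuple, tuple]:
        sites = []
        for d in _INPUT_DIRECTIONS:
            s = lattice.site(*self.junction)
            for _ in range(self.arm_length):
                s = lattice.neighbor(s, d.opposite)
                if s is None:
                    raise ConfigurationError(
                        "gate input arm leaves the lattice; move the "
                        "junction inward or shorten arm_length"
                    )
            sites.append(s.index)
        return tuple(sites)

    def output_site(self, lattice: MTLattice):
        """Site whose crossing constitutes output 1 (protofilament mode),
        or the virtual MAP edge marker in maps_as_output mode."""
        if self.io_mode is IOMode.MAPS_AS_OUTPUT:
            return _MAP_DIRECTION
        s = lattice.site(*self.junction)
        for _ in range(self.output_arm_length):
            s = lattice.neighbor(s, Direction.PROTOFILAMENT_PLUS)
            if s is None:
                raise ConfigurationError(
                    "gate output arm leaves the lattice; move the junction "
                    "inward or shorten output_arm_length"
                )
        return s.index


@dataclass
class GateRun:
    """Full record of one gate evaluation."""

    output: int
    trace: List[Signal]
    cancellations: List[dict]
    steps: int


def _advance(lattice: MTLattice, token: Signal) -> Optional[Signal]:
    if token.direction == _MAP_DIRECTION:
        # one step along the MAP edge delivers the signal off-lattice
        return None
    nxt = lattice.neighbor(token.site, token.direction)
    if nxt is None:
        return None  # exits the open lattice end and is discarded
    return Signal(nxt.index, token.direction, token.phase, token.timestep + 1)


def run_gate(
    lattice: MTLattice, config: GateConfig, inputs: Tuple[int, int]
) -> GateRun:
    """Propagate gate inputs to quiescence and read the emergent output bit.

    Input bits inject tokens at t=0 on the two input attachment sites,
    travelling toward the junction.  All junction mechanics are the local
    rules documented in the module docstring; the output bit is 1 iff a
    token crosses the output attachment (or leaves along the output MAP).
    """
    if len(inputs) != 2 or any(b not in (0, 1) for b in inputs):
        raise ParameterError("inputs must be a pair of bits")
    junction = tuple(config.junction)
    if not lattice.is_interior(junction):
        raise ConfigurationError("gate junction must be an interior site")
    in_sites = config.input_sites(lattice)
    out_marker = config.output_site(lattice)
    phases = config.input_phases

    tokens: List[Signal] = [
        Signal(in_sites[i], _INPUT_DIRECTIONS[i], phases[i], 0)
        for i in (0, 1)
        if inputs[i]
    ]
    trace: List[Signal] = list(tokens)
    cancellations: List[dict] = []
    output = 0
    cap = config.step_cap or 10 * (
        lattice.spec.n_protofilaments + lattice.spec.n_dimer_rings
    )

    step = 0
    while tokens:
        step += 1
        if step > cap:
            raise SimulationError(
                f"gate did not reach quiescence within {cap} steps", trace
            )
        tokens = [t for t in (_advance(lattice, t) for t in tokens) if t]
        # junction mechanics
        at_junction = [t for t in tokens if t.site == junction]
        if len(at_junction) == 2:
            rest = [t for t in tokens if t.site != junction]
            a, b = at_junction
            if a.phase == b.phase:
                # lateral components cancel; one token leaves on the output line
                out_dir = (
                    _MAP_DIRECTION
                    if config.io_mode is IOMode.MAPS_AS_OUTPUT
                    else Direction.PROTOFILAMENT_PLUS
                )
                merged = Signal(junction, out_dir, a.phase, step)
                tokens = rest + [merged]
                cancellations.append(
                    {"site": junction, "timestep": step, "event": "merge"}
                )
                if out_dir == _MAP_DIRECTION:
                    output = 1
            else:
                tokens = rest
                cancellations.append(
                    {"site": junction, "timestep": step, "event": "annihilate"}
                )
        elif len(at_junction) == 1 and config.redirect_lone:
            t = at_junction[0]
            out_dir = (
                _MAP_DIRECTION
                if config.io_mode is IOMode.MAPS_AS_OUTPUT
                else Direction.PROTOFILAMENT_PLUS
            )
            tokens = [x for x in tokens if x is not t] + [
                Signal(junction, out_dir, t.phase, step)
            ]
            if out_dir == _MAP_DIRECTION:
                output = 1
        trace.extend(t for t in tokens)
        if out_marker != _MAP_DIRECTION and any(
            t.site == out_marker
            and t.direction is Direction.PROTOFILAMENT_PLUS
            for t in tokens
        ):
            output = 1
    return GateRun(output=output, trace=trace, cancellations=cancellations, steps=step)


# ---------------------------------------------------------------------------
# Circuit composition
# ---------------------------------------------------------------------------


class Circuit:
    """A Boolean circuit of lattice gates chained by wiring.

    Sources are input names, gate names, or the constants 0/1.  Evaluation
    topologically orders the acyclic wiring and runs every gate on the
    lattice with :func:`run_gate` — composition never falls back to Boolean
    arithmetic.
    """

    def __init__(self, lattice: MTLattice, base_config: Optional[GateConfig] = None):
        self.lattice = lattice
        self.base_config = base_config or GateConfig(
            gate=GateType.AND,
            io_mode=IOMode.MAPS_AS_INPUT,
            junction=self._default_junction(lattice),
        )
        self._gates: Dict[str, Tuple[GateType, Tuple[object, object]]] = {}
        self.outputs: List[str] = []

    @staticmethod
    def _default_junction(lattice: MTLattice) -> Tuple[int, int]:
        return (
            lattice.spec.n_protofilaments // 2,
            lattice.spec.n_dimer_rings // 2,
        )

    def add_gate(self, name: str, gate, sources: Tuple[object, object]) -> None:
        if name in self._gates:
            raise ParameterError(f"duplicate gate name {name!r}")
        if len(sources) != 2:
            raise ParameterError("every gate has exactly two input sources")
        self._gates[name] = (GateType(gate), tuple(sources))

    def _graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self._gates)
        for name, (_, sources) in self._gates.items():
            for s in sources:
                if isinstance(s, str) and s in self._gates:
                    g.add_edge(s, name)
        return g

    def evaluate(self, inputs: Optional[Dict[str, int]] = None) -> Dict[str, int]:
        """Bit value of every gate for the given named inputs."""
        inputs = inputs or {}
        g = self._graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ParameterError("circuit wiring is cyclic")
        values: Dict[str, int] = {}
        for name in nx.topological_sort(g):
            gate_type, sources = self._gates[name]
            bits = []
            for s in sources:
                if isinstance(s, int):
                    bits.append(int(bool(s)))
                elif s in values:
                    bits.append(values[s])
                elif s in inputs:
                    bits.append(int(bool(inputs[s])))
                else:
                    raise ParameterError(f"unknown signal source {s!r}")
            cfg = replace(self.base_config, gate=gate_type)
            values[name] = run_gate(self.lattice, cfg, tuple(bits)).output
        return values
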