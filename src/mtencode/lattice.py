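"""Cylindrical microtubule A- and B-lattice geometry.

A microtubule is modelled as ``n_protofilaments`` parallel chains of tubulin
dimers wrapped onto a cylinder.  Sites are dimers indexed by 0-based
``(protofilament, axial)`` pairs; each dimer carries two monomer centers
(alpha at the minus side, beta 4 nm toward the plus end).  Lateral packing is
skewed: stepping to the next protofilament raises the dimer by
``lateral_rise`` nm — 0.92 nm for the B lattice (same-monomer lateral
contacts, 3-start monomer helix, one seam) and 4.92 nm for the A lattice
(alpha–beta lateral contacts, no seam).  Wrapping all the way around the
cylinder therefore shifts the axial index by ``ceil(N * rise / dimer_length)``
dimer rings: exactly 8 for a 13-protofilament A lattice, and 2 for the B
lattice, where the physical 1.5-dimer seam mismatch rounds up to the nearest
dimer ring.

Interior sites have exactly six neighbors, one per direction class:
protofilament (axial) +/-, helical +/- (protofilament index increments along
helical+), and anti-helical +/- (protofilament index decrements along
anti-helical+ while advancing one ring toward the plus end).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np

from .errors import BoundaryError, ParameterError

__all__ = [
    "LatticeType",
    "Direction",
    "PatchKind",
    "LatticeSpec",
    "DimerSite",
    "Patch",
    "TracedPath",
    "MTLattice",
    "build_lattice",
    "neighborhood_patch",
    "trace_path",
    "patch_extent",
    "monomer_extent",
]


class LatticeType(str, enum.Enum):
    A = "A"
    B = "B"


class PatchKind(str, enum.Enum):
    A7 = "A7"
    B9 = "B9"


class Direction(str, enum.Enum):
    """Direction classes of lattice neighbors.

    ``PROTOFILAMENT_PLUS`` points toward the beta-exposed plus end; it is the
    "axial+" direction.  ``HELICAL_PLUS`` increments the protofilament index;
    ``ANTI_HELICAL_PLUS`` decrements it while advancing one dimer ring.
    """

    PROTOFILAMENT_PLUS = "protofilament+"
    PROTOFILAMENT_MINUS = "protofilament-"
    HELICAL_PLUS = "helical+"
    HELICAL_MINUS = "helical-"
    ANTI_HELICAL_PLUS = "anti_helical+"
    ANTI_HELICAL_MINUS = "anti_helical-"

    @property
    def opposite(self) -> "Direction":
        return _OPPOSITE[self]


_OPPOSITE = {
    Direction.PROTOFILAMENT_PLUS: Direction.PROTOFILAMENT_MINUS,
    Direction.PROTOFILAMENT_MINUS: Direction.PROTOFILAMENT_PLUS,
    Direction.HELICAL_PLUS: Direction.HELICAL_MINUS,
    Direction.HELICAL_MINUS: Direction.HELICAL_PLUS,
    Direction.ANTI_HELICAL_PLUS: Direction.ANTI_HELICAL_MINUS,
    Direction.ANTI_HELICAL_MINUS: Direction.ANTI_HELICAL_PLUS,
}

# (d_protofilament, d_axial) offsets for interior sites.  Wrapping the
# protofilament index adds/subtracts the lattice wrap offset to the axial
# index (see LatticeSpec.wrap_offset).
_OFFSETS = {
    Direction.PROTOFILAMENT_PLUS: (0, 1),
    Direction.PROTOFILAMENT_MINUS: (0, -1),
    Direction.HELICAL_PLUS: (1, 0),
    Direction.HELICAL_MINUS: (-1, 0),
    Direction.ANTI_HELICAL_PLUS: (-1, 1),
    Direction.ANTI_HELICAL_MINUS: (1, -1),
}

#: canonical lateral rise per protofilament step, nm
DEFAULT_LATERAL_RISE = {LatticeType.A: 4.92, LatticeType.B: 0.92}


@dataclass(frozen=True)
class LatticeSpec:
    """Parameters of a cylindrical microtubule lattice.

    Defaults follow the canonical neuronal microtubule: 13 protofilaments,
    25 nm outer / 15 nm inner diameter, 4 nm monomers (8 nm dimers).
    ``lateral_rise`` defaults by lattice type (B: 0.92 nm, A: 4.92 nm).
    """

    lattice_type: LatticeType
    n_dimer_rings: int
    n_protofilaments: int = 13
    outer_diameter: float = 25.0
    inner_diameter: float = 15.0
    monomer_length: float = 4.0
    lateral_rise: Optional[float] = None
    seam: bool = True

    def __post_init__(self):
        object.__setattr__(self, "lattice_type", LatticeType(self.lattice_type))
        if self.n_protofilaments < 3:
            raise ParameterError("n_protofilaments must be >= 3")
        if self.n_dimer_rings < 1:
            raise ParameterError("n_dimer_rings must be >= 1")
        if not self.outer_diameter > self.inner_diameter > 0:
            raise ParameterError(
                "diameters must satisfy outer_diameter > inner_diameter > 0"
            )
        if self.monomer_length <= 0:
            raise ParameterError("monomer_length must be > 0")
        if self.lateral_rise is None:
            object.__setattr__(
                self, "lateral_rise", DEFAULT_LATERAL_RISE[self.lattice_type]
            )
        if self.lateral_rise < 0:
            raise ParameterError("lateral_rise must be >= 0")

    @property
    def dimer_length(self) -> float:
        return 2.0 * self.monomer_length

    @property
    def radius(self) -> float:
        """Centerline (wall mid-plane) radius: mean of the two wall radii."""
        return (self.outer_diameter + self.inner_diameter) / 4.0

    @property
    def wrap_offset(self) -> int:
        """Axial dimer-ring shift accumulated by one full lateral turn.

        ``ceil(N * lateral_rise / dimer_length)``: exact for the A lattice
        (13 x 4.92 / 8 = 7.995 ~ 8); the B lattice's half-dimer seam mismatch
        (13 x 0.92 / 8 = 1.495) rounds up to 2, the nearest ring for which the
        wrap edges remain nearest-neighbor contacts.
        """
        turns = self.n_protofilaments * self.lateral_rise / self.dimer_length
        return math.ceil(turns - 1e-9)

    @property
    def has_seam(self) -> bool:
        return self.seam and self.lattice_type is LatticeType.B

    def to_json(self) -> str:
        d = {
            "lattice_type": self.lattice_type.value,
            "n_protofilaments": self.n_protofilaments,
            "n_dimer_rings": self.n_dimer_rings,
            "outer_diameter": self.outer_diameter,
            "inner_diameter": self.inner_diameter,
            "monomer_length": self.monomer_length,
            "lateral_rise": self.lateral_rise,
            "seam": self.seam,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LatticeSpec":
        data = json.loads(text)
        allowed = {
            "lattice_type",
            "n_protofilaments",
            "n_dimer_rings",
            "outer_diameter",
            "inner_diameter",
            "monomer_length",
            "lateral_rise",
            "seam",
        }
        unknown = set(data) - allowed
        if unknown:
            raise ParameterError(f"unknown lattice-spec fields: {sorted(unknown)}")
        return cls(**data)


class TailState(str, enum.Enum):
    UP = "up"
    DOWN = "down"


@dataclass(frozen=True)
class DimerSite:
    """One tubulin dimer: a (protofilament, axial) lattice site.

    ``alpha_center``/``beta_center`` are 3D monomer centers in nm; the beta
    monomer sits one monomer length toward the plus end along the
    protofilament axis.
    """

    protofilament_index: int
    axial_index: int
    alpha_center: tuple
    beta_center: tuple
    tail_state_alpha: TailState = TailState.DOWN
    tail_state_beta: TailState = TailState.DOWN

    @property
    def index(self) -> tuple:
        return (self.protofilament_index, self.axial_index)

    @property
    def center(self) -> np.ndarray:
        return (np.asarray(self.alpha_center) + np.asarray(self.beta_center)) / 2.0

    def monomer_centers(self) -> np.ndarray:
        return np.array([self.alpha_center, self.beta_center])


@dataclass(frozen=True)
class Patch:
    """A lattice neighborhood: the 7-dimer A-lattice hexagon or the 9-dimer
    3x3 skewed B-lattice block.  ``members[0]`` is the central (address)
    dimer; the peripheral members follow in canonical clockwise order
    starting from the upper-left dimer (anti-helical-plus neighbor)."""

    center: DimerSite
    members: tuple
    patch_kind: PatchKind

    def __post_init__(self):
        n = {PatchKind.A7: 7, PatchKind.B9: 9}[self.patch_kind]
        if len(self.members) != n:
            raise ParameterError(
                f"{self.patch_kind.value} patch must have {n} members"
            )
        if self.members[0].index != self.center.index:
            raise ParameterError("members[0] must be the central dimer")

    @property
    def peripheral(self) -> tuple:
        return self.members[1:]


# Canonical peripheral orderings, clockwise from the upper-left dimer, as
# (d_protofilament, d_axial) offsets.  Reused by the hexagon target masks
# and the digit numbering of phosphorylation patterns.
A7_PERIPHERAL_OFFSETS = (
    (-1, 1),  # upper-left (anti-helical+)
    (0, 1),   # up (protofilament+)
    (1, 0),   # upper-right (helical+)
    (1, -1),  # lower-right (anti-helical-)
    (0, -1),  # down (protofilament-)
    (-1, 0),  # lower-left (helical-)
)
B9_PERIPHERAL_OFFSETS = (
    (-1, 1),   # upper-left
    (0, 1),    # up
    (1, 1),    # upper-right corner (long diagonal)
    (1, 0),    # right
    (1, -1),   # lower-right
    (0, -1),   # down
    (-1, -1),  # lower-left corner (long diagonal)
    (-1, 0),   # left
)


@dataclass
class TracedPath:
    """Result of a directional path trace; ``truncated`` flags paths that ran
    off the open axial end of the lattice before completing all steps."""

    sites: list
    truncated: bool

    def __iter__(self) -> Iterator[DimerSite]:
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)


class MTLattice:
    """A built lattice: indexed dimer sites plus the labeled neighbor map."""

    def __init__(self, spec: LatticeSpec):
        self.spec = spec
        self._sites = {}
        r = spec.radius
        for p in range(spec.n_protofilaments):
            theta = 2.0 * math.pi * p / spec.n_protofilaments
            x, y = r * math.cos(theta), r * math.sin(theta)
            for a in range(spec.n_dimer_rings):
                z_alpha = a * spec.dimer_length + p * spec.lateral_rise
                self._sites[(p, a)] = DimerSite(
                    protofilament_index=p,
                    axial_index=a,
                    alpha_center=(x, y, z_alpha),
                    beta_center=(x, y, z_alpha + spec.monomer_length),
                )
        self._neighbor_map = {
            idx: {
                d: t
                for d in Direction
                if (t := self._offset_index(idx, *_OFFSETS[d])) is not None
            }
            for idx in self._sites
        }

    def _offset_index(self, idx, dp, da):
        """Apply an index offset with cylinder wrap; None if off the axial end."""
        p, a = idx
        q = p + dp
        if q >= self.spec.n_protofilaments:
            q -= self.spec.n_protofilaments
            a += self.spec.wrap_offset
        elif q < 0:
            q += self.spec.n_protofilaments
            a -= self.spec.wrap_offset
        a += da
        if not 0 <= a < self.spec.n_dimer_rings:
            return None
        return (q, a)

    # -- site access -----------------------------------------------------
    def __len__(self) -> int:
        return len(self._sites)

    def __contains__(self, index) -> bool:
        return tuple(index) in self._sites

    def site(self, protofilament: int, axial: int) -> DimerSite:
        try:
            return self._sites[(protofilament, axial)]
        except KeyError:
            raise ParameterError(
                f"site ({protofilament}, {axial}) outside lattice"
            ) from None

    @property
    def sites(self) -> list:
        return list(self._sites.values())

    @property
    def site_indices(self) -> list:
        return list(self._sites.keys())

    # -- topology --------------------------------------------------------
    def neighbor(self, site, direction: Direction) -> Optional[DimerSite]:
        idx = site.index if isinstance(site, DimerSite) else tuple(site)
        t = self._neighbor_map[idx].get(Direction(direction))
        return self._sites[t] if t is not None else None

    def neighbors(self, site) -> dict:
        idx = site.index if isinstance(site, DimerSite) else tuple(site)
        return {d: self._sites[t] for d, t in self._neighbor_map[idx].items()}

    def degree(self, site) -> int:
        idx = site.index if isinstance(site, DimerSite) else tuple(site)
        return len(self._neighbor_map[idx])

    def is_interior(self, site) -> bool:
        return self.degree(site) == 6

    def offset_site(self, site, dp: int, da: int) -> Optional[DimerSite]:
        """Site at a (protofilament, axial) offset, with cylinder wrap."""
        idx = site.index if isinstance(site, DimerSite) else tuple(site)
        t = self._offset_index(idx, dp, da)
        return self._sites[t] if t is not None else None

    def seam_column_pairs(self):
        """Protofilament index pair across the seam (B lattice) or the
        geometrically seamless wrap line (A lattice)."""
        return (self.spec.n_protofilaments - 1, 0)

    def monomer_coordinates(self) -> np.ndarray:
        """(2 * n_sites, 3) array of all monomer centers, nm."""
        return np.concatenate([s.monomer_centers() for s in self.sites])


def build_lattice(spec: LatticeSpec) -> MTLattice:
    """Construct the cylindrical lattice for ``spec``.

    Site count is ``n_protofilaments * n_dimer_rings``; the neighbor map is
    complete with interior sites having exactly six labeled neighbors.
    """
    return MTLattice(spec)


def neighborhood_patch(lattice: MTLattice, center: DimerSite) -> Patch:
    """The CaMKII-sized neighborhood around ``center``.

    A lattice: the 7-dimer hexagon (center + its six neighbors).  B lattice:
    the 9-dimer 3x3 skewed block (center + eight surrounding sites).
    Raises :class:`BoundaryError` if the neighborhood runs off the open
    axial ends.
    """
    kind = (
        PatchKind.A7
        if lattice.spec.lattice_type is LatticeType.A
        else PatchKind.B9
    )
    offsets = (
        A7_PERIPHERAL_OFFSETS if kind is PatchKind.A7 else B9_PERIPHERAL_OFFSETS
    )
    members = [center]
    for dp, da in offsets:
        s = lattice.offset_site(center, dp, da)
        if s is None:
            raise BoundaryError(
                f"site {center.index} lies too close to the lattice edge for a "
                f"{kind.value} patch"
            )
        members.append(s)
    return Patch(center=center, members=tuple(members), patch_kind=kind)


_TRACE_DIRECTIONS = {
    "protofilament": Direction.PROTOFILAMENT_PLUS,
    "helical": Direction.HELICAL_PLUS,
    "anti_helical": Direction.ANTI_HELICAL_PLUS,
}


def trace_path(
    lattice: MTLattice,
    start: DimerSite,
    direction,
    n_steps: int,
) -> TracedPath:
    """Walk ``n_steps`` lattice steps from ``start`` along a direction class.

    ``direction`` is one of ``"protofilament"``, ``"helical"``,
    ``"anti_helical"`` (plus sense) or any :class:`Direction` member.
    Helical/anti-helical paths wrap around the cylinder; paths leaving the
    lattice axially are truncated and flagged, not an error.
    """
    if isinstance(direction, Direction):
        d = direction
    else:
        try:
            d = _TRACE_DIRECTIONS[str(direction)]
        except KeyError:
            raise ParameterError(f"unknown direction class {direction!r}") from None
    if start.index not in lattice._sites:
        raise ParameterError(f"start site {start.index} not in lattice")
    sites = [lattice.site(*start.index)]
    truncated = False
    for _ in range(n_steps):
        nxt = lattice.neighbor(sites[-1], d)
        if nxt is None:
            truncated = True
            break
        sites.append(nxt)
    return TracedPath(sites=sites, truncated=truncated)


def monomer_extent(sites: Sequence[DimerSite]) -> float:
    """Maximum pairwise monomer-center distance over ``sites``, nm."""
    pts = np.concatenate([s.monomer_centers() for s in sites])
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def patch_extent(patch: Patch) -> float:
    """Maximum pairwise monomer-center distance across the patch, nm.

    For a degenerate single-dimer patch this is the monomer length."""
    return monomer_extent(patch.members)
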