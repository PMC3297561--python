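"""Phosphorylation information states on lattice patches.

One CaMKII face carries six kinases, so at most six dimers of a patch can be
phosphorylated in one encoding event.  Dimer states are ternary digits:
0 = no phosphorylation, 1 = beta-tubulin phosphorylation, 2 = alpha-tubulin
phosphorylation.  Three schemes are counted and enumerated exactly:

* ``binary_A`` — A-lattice 7-dimer patch, beta-only phosphorylation of the
  six peripheral dimers: 2**6 = 64 states.
* ``ternary_A`` — A-lattice patch, ternary states: 3**6 = 729 states.
* ``ternary_B`` — B-lattice 9-dimer patch, ternary states on the eight
  peripheral dimers with at most six non-zero (one kinase face):
  3**8 - 2**8 - 8*2**7 = 5281 states.

The central address dimer is never written.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, Optional, Tuple

from .errors import ConstraintError, ParameterError
from .lattice import DimerSite, MTLattice, Patch, PatchKind

__all__ = [
    "Scheme",
    "EncodingScheme",
    "SCHEMES",
    "PhosphoPattern",
    "LatticePhospho",
    "count_states",
    "enumerate_states",
    "capacity_bits",
    "apply_pattern",
    "read_pattern",
]

STATE_NONE, STATE_BETA, STATE_ALPHA = 0, 1, 2


class Scheme(str, enum.Enum):
    BINARY_A = "binary_A"
    TERNARY_A = "ternary_A"
    TERNARY_B = "ternary_B"


@dataclass(frozen=True)
class EncodingScheme:
    name: Scheme
    n_sites: int
    states_per_site: int
    max_phosphorylated: int
    patch_kind: PatchKind

    def admissible(self, digits: Tuple[int, ...]) -> bool:
        return (
            len(digits) == self.n_sites
            and all(0 <= d < self.states_per_site for d in digits)
            and sum(d != 0 for d in digits) <= self.max_phosphorylated
        )


SCHEMES: Dict[Scheme, EncodingScheme] = {
    Scheme.BINARY_A: EncodingScheme(Scheme.BINARY_A, 6, 2, 6, PatchKind.A7),
    Scheme.TERNARY_A: EncodingScheme(Scheme.TERNARY_A, 6, 3, 6, PatchKind.A7),
    Scheme.TERNARY_B: EncodingScheme(Scheme.TERNARY_B, 8, 3, 6, PatchKind.B9),
}


def get_scheme(scheme) -> EncodingScheme:
    if isinstance(scheme, EncodingScheme):
        return scheme
    return SCHEMES[Scheme(scheme)]


@dataclass(frozen=True)
class PhosphoPattern:
    """An ordered digit string over the numbered peripheral dimers of a
    patch (canonical clockwise numbering from the upper-left dimer)."""

    scheme: EncodingScheme
    site_states: Tuple[int, ...]

    def __post_init__(self):
        scheme = get_scheme(self.scheme)
        object.__setattr__(self, "scheme", scheme)
        digits = tuple(int(d) for d in self.site_states)
        object.__setattr__(self, "site_states", digits)
        if len(digits) != scheme.n_sites:
            raise ConstraintError(
                f"{scheme.name.value} pattern needs {scheme.n_sites} digits, "
                f"got {len(digits)}"
            )
        if any(not 0 <= d < scheme.states_per_site for d in digits):
            raise ConstraintError(
                f"digits must lie in [0, {scheme.states_per_site})"
            )
        n_phos = sum(d != 0 for d in digits)
        if n_phos > scheme.max_phosphorylated:
            raise ConstraintError(
                f"{n_phos} phosphorylated sites exceed the "
                f"{scheme.max_phosphorylated}-kinase limit"
            )

    @classmethod
    def from_digits(cls, scheme, digits: str) -> "PhosphoPattern":
        return cls(get_scheme(scheme), tuple(int(c) for c in str(digits)))

    def digit_string(self) -> str:
        return "".join(str(d) for d in self.site_states)

    @property
    def n_phosphorylated(self) -> int:
        return sum(d != 0 for d in self.site_states)


def count_states(scheme) -> int:
    """Closed-form count of admissible patterns.

    Length-n strings over ``states_per_site`` symbols with at most
    ``max_phosphorylated`` non-zero digits:
    ``sum_k C(n, k) (s-1)**k`` for k up to the limit.
    """
    s = get_scheme(scheme)
    return sum(
        math.comb(s.n_sites, k) * (s.states_per_site - 1) ** k
        for k in range(min(s.max_phosphorylated, s.n_sites) + 1)
    )


def enumerate_states(scheme) -> Iterator[PhosphoPattern]:
    """Yield every admissible pattern exactly once, lexicographically."""
    s = get_scheme(scheme)
    for digits in itertools.product(range(s.states_per_site), repeat=s.n_sites):
        if sum(d != 0 for d in digits) <= s.max_phosphorylated:
            yield PhosphoPattern(s, digits)


def capacity_bits(scheme) -> float:
    """Information capacity, log2 of the admissible state count."""
    return math.log2(count_states(scheme))


class LatticePhospho:
    """Per-dimer phosphorylation state over a whole lattice (default 0)."""

    def __init__(self, lattice: MTLattice, states: Optional[dict] = None):
        self.lattice = lattice
        self._states: Dict[tuple, int] = {}
        if states:
            for idx, v in states.items():
                self.set_state(idx, v)

    def state(self, site) -> int:
        idx = site.index if isinstance(site, DimerSite) else tuple(site)
        return self._states.get(idx, STATE_NONE)

    def set_state(self, site, value: int) -> None:
        idx = site.index if isinstance(site, DimerSite) else tuple(site)
        if idx not in self.lattice:
            raise ParameterError(f"site {idx} not in lattice")
        value = int(value)
        if value not in (STATE_NONE, STATE_BETA, STATE_ALPHA):
            raise ConstraintError(f"invalid phosphorylation state {value}")
        if value == STATE_NONE:
            self._states.pop(idx, None)
        else:
            self._states[idx] = value

    def phosphorylated_indices(self) -> set:
        return set(self._states)

    def is_phosphorylated(self, site) -> bool:
        return self.state(site) != STATE_NONE

    def copy(self) -> "LatticePhospho":
        return LatticePhospho(self.lattice, dict(self._states))


def _check_patch_scheme(patch: Patch, scheme: EncodingScheme) -> None:
    if patch.patch_kind is not scheme.patch_kind:
        raise ConstraintError(
            f"scheme {scheme.name.value} requires a {scheme.patch_kind.value} "
            f"patch, got {patch.patch_kind.value}"
        )


def write_site(
    patch: Patch, state: LatticePhospho, site, value: int
) -> None:
    """Write one dimer state within a patch; the central address dimer is
    never writable."""
    idx = site.index if isinstance(site, DimerSite) else tuple(site)
    if idx == patch.center.index:
        raise ConstraintError(
            "the central address dimer is not available for phosphorylation"
        )
    if idx not in {m.index for m in patch.members}:
        raise ConstraintError(f"site {idx} is not a member of the patch")
    state.set_state(idx, value)


def apply_pattern(
    patch: Patch,
    pattern: PhosphoPattern,
    state: Optional[LatticePhospho] = None,
    lattice: Optional[MTLattice] = None,
) -> LatticePhospho:
    """Write ``pattern`` onto the numbered peripheral dimers of ``patch``.

    Returns the (possibly newly created) lattice state; the central dimer
    stays 0.
    """
    _check_patch_scheme(patch, get_scheme(pattern.scheme))
    if state is None:
        if lattice is None:
            raise ParameterError("apply_pattern needs a state or a lattice")
        state = LatticePhospho(lattice)
    for site, digit in zip(patch.peripheral, pattern.site_states):
        if digit == STATE_NONE:
            state.set_state(site, STATE_NONE)
        else:
            write_site(patch, state, site, digit)
    return state


def read_pattern(
    patch: Patch, state: LatticePhospho, scheme
) -> PhosphoPattern:
    """Read the digit string of ``patch`` back from a lattice state."""
    s = get_scheme(scheme)
    _check_patch_scheme(patch, s)
    digits = tuple(state.state(site) for site in patch.peripheral)
    return PhosphoPattern(s, digits)
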