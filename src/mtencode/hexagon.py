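"""Geometric model of the activated CaMKII kinase hexagon and its alignment
onto microtubule lattice patches.

The activated holoenzyme extends six kinase domains per face in a roughly
planar hexagon about 20 nm in breadth.  Alignment places that hexagon, as a
rigid body, tangent to the microtubule cylinder over a lattice patch and
finds the minimum-cost bijection of kinases onto six target dimers.  The
per-kinase residual distances stand in for linker realignment; an alignment
is feasible when every residual fits within the linker strain allowance.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ConfigurationError, ParameterError
from .lattice import Patch, PatchKind

__all__ = [
    "Configuration",
    "KinaseHexagon",
    "AlignmentResult",
    "target_dimers",
    "align",
    "brute_force_alignment_cost",
    "ANNOTATION_RESIDUES",
]

#: residue-level anchors retained as annotation only (no geometry):
#: the kinase hydrophobic groove, the autoinhibitory threonine, and the two
#: candidate tubulin phosphoacceptor sites.
ANNOTATION_RESIDUES = {
    "kinase_groove": ("Val208", "Trp237"),
    "autoinhibitory": "Thr286",
    "tubulin_cleft_site": "Thr312",
    "beta3_tail_site": "Ser444",
}


class Configuration(str, enum.Enum):
    """Hexagon-to-patch docking configuration.

    ``A`` targets the six peripheral dimers of the A7 hexagon.  ``B1``/``B2``
    are the two fixed 6-of-8 selection masks on the B9 block: B1 drops the two
    long-diagonal corners (the compact selection matching the A7 extent), B2
    drops the two short-diagonal corners (the wider, higher-strain selection).
    """

    A = "A"
    B1 = "B1"
    B2 = "B2"


# Indices into Patch.peripheral (canonical clockwise order).
_TARGET_MASKS = {
    (PatchKind.A7, Configuration.A): (0, 1, 2, 3, 4, 5),
    # B9 peripheral order: UL, U, UR-corner, R, LR, D, LL-corner, L
    (PatchKind.B9, Configuration.B1): (0, 1, 3, 4, 5, 7),
    (PatchKind.B9, Configuration.B2): (1, 2, 3, 5, 6, 7),
}


@dataclass
class KinaseHexagon:
    """Six kinase-domain anchor points (3D, nm) with a breadth and a
    per-kinase linker strain allowance."""

    kinase_positions: np.ndarray
    breadth: float = 20.0
    max_linker_strain: float = 2.0

    def __post_init__(self):
        self.kinase_positions = np.asarray(self.kinase_positions, dtype=float)
        if self.kinase_positions.shape != (6, 3):
            raise ParameterError("kinase_positions must be a (6, 3) array")
        if self.breadth <= 0:
            raise ParameterError("breadth must be > 0")
        if self.max_linker_strain < 0:
            raise ParameterError("max_linker_strain must be >= 0")

    @classmethod
    def regular(cls, breadth: float = 20.0, max_linker_strain: float = 2.0):
        """Planar regular hexagon in the xy-plane with the given breadth
        (max pairwise distance, i.e. twice the circumradius)."""
        r = breadth / 2.0
        ang = np.arange(6) * math.pi / 3.0
        pts = np.stack([r * np.cos(ang), r * np.sin(ang), np.zeros(6)], axis=1)
        return cls(pts, breadth=breadth, max_linker_strain=max_linker_strain)

    def pairwise_breadth(self) -> float:
        d = self.kinase_positions[:, None] - self.kinase_positions[None, :]
        return float(np.sqrt((d**2).sum(-1)).max())


@dataclass
class AlignmentResult:
    """Outcome of a rigid hexagon-to-patch alignment."""

    assignment: tuple  # kinase index -> index into the 6 targets
    per_kinase_displacement: np.ndarray  # nm residuals
    rms_mismatch: float
    configuration: Configuration
    feasible: bool
    target_sites: tuple
    placed_positions: np.ndarray  # kinase positions after the rigid fit


def target_dimers(patch: Patch, configuration) -> tuple:
    """The six dimers a CaMKII face phosphorylates in ``configuration``.

    The central address dimer is never a target.  A7 patches use all six
    peripheral dimers; B9 patches use one of the two fixed 6-of-8 masks.
    """
    configuration = Configuration(configuration)
    try:
        mask = _TARGET_MASKS[(patch.patch_kind, configuration)]
    except KeyError:
        raise ConfigurationError(
            f"configuration {configuration.value} incompatible with "
            f"{patch.patch_kind.value} patch"
        ) from None
    return tuple(patch.peripheral[i] for i in mask)


def _contact_points(targets, contact: str) -> np.ndarray:
    if contact == "beta":
        return np.array([t.beta_center for t in targets], dtype=float)
    if contact == "alpha":
        return np.array([t.alpha_center for t in targets], dtype=float)
    if contact == "midpoint":
        return np.array([t.center for t in targets], dtype=float)
    raise ParameterError(f"unknown contact point {contact!r}")


def _kabsch(P: np.ndarray, Q: np.ndarray):
    """Proper-rotation least-squares superposition of P onto Q.

    Returns (R, t) with ``P @ R.T + t`` the fitted points; reflections are
    excluded (the hexagon is a physical rigid body).
    """
    pc, qc = P.mean(0), Q.mean(0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, qc - R @ pc


def _fit_cost(P, Q, order):
    """RMS residual of the rigid fit of hexagon points P onto Q[order]."""
    Qo = Q[list(order)]
    R, t = _kabsch(P, Qo)
    placed = P @ R.T + t
    res = np.linalg.norm(placed - Qo, axis=1)
    return float(np.sqrt((res**2).mean())), placed, res


def align(
    hexagon: KinaseHexagon,
    patch: Patch,
    configuration,
    contact: str = "beta",
) -> AlignmentResult:
    """Rigid-body least-squares alignment of the kinase hexagon onto the six
    target monomer contact points of ``patch``.

    The hexagon plane is brought tangent to the cylinder over the patch
    center (implicitly, by the least-squares fit over candidate vertex
    correspondences), then the minimum-cost bijective kinase-to-target
    assignment is refined with the Hungarian algorithm.  Candidate starts are
    the 12 dihedral (cyclic x reflection) orderings of the angular target
    sequence, so the search respects the hexagon's symmetry; each start is
    iterated to a fixed point of (rigid fit, reassignment).

    Infeasibility under the linker strain bound is reported in the result,
    not raised.
    """
    configuration = Configuration(configuration)
    targets = target_dimers(patch, configuration)
    Q = _contact_points(targets, contact)
    P = hexagon.kinase_positions

    # Angular ordering of targets around the patch normal gives
    # rotation-consistent starting correspondences.
    centroid = Q.mean(0)
    normal = np.array(
        [patch.center.center[0], patch.center.center[1], 0.0]
    )
    nn = np.linalg.norm(normal)
    normal = normal / nn if nn > 1e-12 else np.array([0.0, 0.0, 1.0])
    axis1 = np.array([0.0, 0.0, 1.0])
    axis2 = np.cross(normal, axis1)
    rel = Q - centroid
    ang = np.arctan2(rel @ axis2, rel @ axis1)
    angular = tuple(int(i) for i in np.argsort(ang))

    best = None
    for flip in (False, True):
        seq = angular[::-1] if flip else angular
        for shift in range(6):
            order = seq[shift:] + seq[:shift]
            cost, placed, res = _fit_cost(P, Q, order)
            # refine: Hungarian reassignment against the placed hexagon,
            # then refit, until the assignment is stable
            for _ in range(10):
                dmat = np.linalg.norm(placed[:, None] - Q[None, :], axis=-1)
                ri, ci = linear_sum_assignment(dmat**2)
                new_order = tuple(int(ci[np.argsort(ri)][k]) for k in range(6))
                if new_order == order:
                    break
                order = new_order
                cost, placed, res = _fit_cost(P, Q, order)
            if best is None or cost < best[0]:
                best = (cost, order, placed, res)

    cost, order, placed, res = best
    return AlignmentResult(
        assignment=order,
        per_kinase_displacement=res,
        rms_mismatch=cost,
        configuration=configuration,
        feasible=bool(np.all(res <= hexagon.max_linker_strain + 1e-12)),
        target_sites=targets,
        placed_positions=placed,
    )


def brute_force_alignment_cost(
    hexagon: KinaseHexagon, patch: Patch, configuration, contact: str = "beta"
) -> float:
    """Exhaustive minimum RMS over all 720 kinase-to-target bijections.

    Independent check of :func:`align`'s assignment optimality; each
    permutation gets its own rigid Kabsch fit.
    """
    targets = target_dimers(patch, Configuration(configuration))
    Q = _contact_points(targets, contact)
    P = hexagon.kinase_positions
    return min(
        _fit_cost(P, Q, perm)[0] for perm in itertools.permutations(range(6))
    )
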