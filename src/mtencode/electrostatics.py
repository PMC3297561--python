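"""Coarse point-charge complementarity model of CaMKII-microtubule binding.

Each activated kinase domain presents a positive potential region taken as
+1 kT/e; each tubulin monomer presents a net surface charge of -10 e.  Their
product gives a 10 kT attraction per kinase-monomer contact at 310 K, linear
in the number of engaged kinases up to the 60 kT six-kinase bound.  This is
deliberately an arithmetic model: no distance dependence, screening or
dielectric — the full Poisson-Boltzmann treatment is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError

__all__ = [
    "ChargeModel",
    "pair_energy",
    "binding_energy",
    "kT_to_kcal_per_mol",
    "kcal_per_mol_to_kT",
    "round_to_int",
    "significance_vs_thermal",
    "KCAL_PER_MOL_PER_KT_310",
]

# CODATA: k_B = 1.380649e-23 J/K, N_A = 6.02214076e23 /mol, 1 kcal = 4184 J
_KB = 1.380649e-23
_NA = 6.02214076e23
_J_PER_KCAL = 4184.0

#: kcal/mol per kT at 310 K (= k_B * 310 * N_A / 4184), ~0.6161
KCAL_PER_MOL_PER_KT_310 = _KB * 310.0 * _NA / _J_PER_KCAL

#: ratio to thermal energy above which an interaction is called significant
SIGNIFICANCE_THRESHOLD = 10.0


@dataclass(frozen=True)
class ChargeModel:
    """Coarse charges: kinase potential in kT/e, monomer charge in e."""

    kinase_potential: float = 1.0
    monomer_surface_charge: float = -10.0
    temperature: float = 310.0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ParameterError("temperature must be > 0")


def pair_energy(model: ChargeModel = ChargeModel()) -> float:
    """Binding magnitude of one kinase-monomer contact, kT.

    |potential x charge|; 10 kT with default charges (attraction reported as
    a positive magnitude).
    """
    return abs(model.kinase_potential * model.monomer_surface_charge)


def binding_energy(model: ChargeModel, n_engaged_kinases: int) -> float:
    """Total binding magnitude for 0..6 engaged kinases, kT.

    Exactly linear: n x pair_energy; 10 kT lower bound (one kinase) to the
    60 kT maximum (all six).
    """
    n = int(n_engaged_kinases)
    if not 0 <= n <= 6:
        raise ParameterError("n_engaged_kinases must lie in [0, 6]")
    return n * pair_energy(model)


def kT_to_kcal_per_mol(x_kT: float, temperature: float = 310.0) -> float:
    """Convert an energy in kT units to kcal/mol at the given temperature."""
    if temperature <= 0:
        raise ParameterError("temperature must be > 0")
    return x_kT * _KB * temperature * _NA / _J_PER_KCAL


def kcal_per_mol_to_kT(x_kcal: float, temperature: float = 310.0) -> float:
    """Inverse of :func:`kT_to_kcal_per_mol` (exact round trip)."""
    if temperature <= 0:
        raise ParameterError("temperature must be > 0")
    return x_kcal * _J_PER_KCAL / (_KB * temperature * _NA)


def round_to_int(x: float) -> int:
    """Round to the nearest integer, for comparison with the headline values
    (10 kT -> 6.16 -> 6 kcal/mol; 20 kT -> 12.32 -> 12 kcal/mol)."""
    return int(round(x))


def significance_vs_thermal(energy_kT: float) -> tuple:
    """Ratio of a binding energy to the 1 kT thermal scale.

    Returns ``(ratio, significant)`` where ``significant`` flags ratios of
    at least 10 — an order of magnitude above thermal vibrational energy.
    """
    if energy_kT < 0:
        raise ParameterError("energy must be >= 0")
    ratio = float(energy_kT)
    return ratio, ratio >= SIGNIFICANCE_THRESHOLD
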