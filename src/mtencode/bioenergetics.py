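"""ATP accounting for CaMKII-microtubule encoding.

Scales one phosphorylation (= one ATP = one written bit) up through synapse,
neuron and whole-brain rates and compares the result with the brain's total
ATP turnover and with the ATP cost of conventional neural signalling.  The
default parameters are the round numbers of the feasibility argument:
2e26 ATP/day whole-body, one fifth to the brain, 100 Hz calcium influx,
100 CaMKII subunits per synapse per influx, 1e4 synapses per neuron and
1e11 neurons.

Every operation reports honest arithmetic; ``rounded`` switches the brain
denominator to its one-significant-figure rounding (5e20 ATP/s) so the
headline 10**8 -> 10**19 -> 2% chain is reproduced exactly alongside the
unrounded values (4.63e20 ATP/s, 2.16%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ParameterError

__all__ = [
    "EnergyBudgetParams",
    "ComparisonConstants",
    "brain_atp_rate",
    "neuron_encoding_rate",
    "brain_encoding_rate",
    "encoding_fraction_of_brain_energy",
    "cost_ratio_vs_conventional",
    "round_one_sig_fig",
    "budget_report",
]


@dataclass(frozen=True)
class EnergyBudgetParams:
    body_atp_per_day: float = 2e26
    brain_fraction: float = 1.0 / 5.0
    influx_frequency: float = 100.0  # Hz
    camkii_per_synapse: float = 100.0
    synapses_per_neuron: float = 1e4
    neurons: float = 1e11
    atp_per_phosphorylation: float = 1.0
    seconds_per_day: float = 86400.0

    def __post_init__(self):
        for name in (
            "body_atp_per_day",
            "influx_frequency",
            "camkii_per_synapse",
            "synapses_per_neuron",
            "neurons",
            "atp_per_phosphorylation",
            "seconds_per_day",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0 < self.brain_fraction <= 1:
            raise ParameterError("brain_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class ComparisonConstants:
    """Reference ATP costs of conventional neural information transfer."""

    atp_per_synaptic_bit: float = 1e4
    atp_per_spike_bit_low: float = 1e6
    atp_per_spike_bit_high: float = 1e7


def round_one_sig_fig(x: float) -> float:
    """Round to one significant figure (4.63e20 -> 5e20)."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x / 10**exp) * 10.0**exp


def brain_atp_rate(
    params: EnergyBudgetParams = EnergyBudgetParams(), rounded: bool = False
) -> float:
    """Brain ATP consumption, ATP/s: the brain fraction of daily body
    turnover.  ``rounded`` returns the one-significant-figure rounding."""
    rate = params.body_atp_per_day / params.seconds_per_day * params.brain_fraction
    return round_one_sig_fig(rate) if rounded else rate


def neuron_encoding_rate(params: EnergyBudgetParams = EnergyBudgetParams()) -> float:
    """Maximal encoding cost of one neuron, ATP/s (= bits/s at 1 ATP/bit)."""
    return (
        params.influx_frequency
        * params.camkii_per_synapse
        * params.synapses_per_neuron
        * params.atp_per_phosphorylation
    )


def brain_encoding_rate(params: EnergyBudgetParams = EnergyBudgetParams()) -> float:
    """Maximal encoding cost of all neurons, ATP/s."""
    return neuron_encoding_rate(params) * params.neurons


def encoding_fraction_of_brain_energy(
    params: EnergyBudgetParams = EnergyBudgetParams(), rounded: bool = True
) -> float:
    """Encoding cost as a percentage of brain ATP turnover.

    With defaults: 2.0% against the rounded 5e20 ATP/s denominator
    (rounded), 2.16% against the unrounded 4.63e20 ATP/s.
    """
    denom = brain_atp_rate(params, rounded=rounded)
    return brain_encoding_rate(params) / denom * 100.0


def cost_ratio_vs_conventional(
    params: EnergyBudgetParams = EnergyBudgetParams(),
    constants: ComparisonConstants = ComparisonConstants(),
) -> dict:
    """ATP-per-bit advantage of phosphorylation encoding over chemical
    synapses and graded/spike coding."""
    per_bit = params.atp_per_phosphorylation
    if per_bit <= 0:
        raise ParameterError("atp_per_phosphorylation must be > 0 for ratios")
    return {
        "vs_synaptic_bit": constants.atp_per_synaptic_bit / per_bit,
        "vs_spike_bit": (
            constants.atp_per_spike_bit_low / per_bit,
            constants.atp_per_spike_bit_high / per_bit,
        ),
    }


def budget_report(
    params: EnergyBudgetParams = EnergyBudgetParams(),
    constants: ComparisonConstants = ComparisonConstants(),
    rounded: bool = False,
) -> dict:
    """All budget quantities in one JSON-serializable mapping."""
    ratios = cost_ratio_vs_conventional(params, constants)
    return {
        "brain_atp_rate_per_s": brain_atp_rate(params, rounded=rounded),
        "brain_atp_rate_per_s_unrounded": brain_atp_rate(params),
        "neuron_encoding_rate_per_s": neuron_encoding_rate(params),
        "brain_encoding_rate_per_s": brain_encoding_rate(params),
        "encoding_fraction_percent": encoding_fraction_of_brain_energy(
            params, rounded=rounded
        ),
        "encoding_fraction_percent_unrounded": encoding_fraction_of_brain_energy(
            params, rounded=False
        ),
        "cost_ratio_vs_synaptic_bit": ratios["vs_synaptic_bit"],
        "cost_ratio_vs_spike_bit": list(ratios["vs_spike_bit"]),
    }
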