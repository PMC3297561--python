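"""Synthetic calcium-influx activity and stochastic phosphorylation patterns.

Emulates the assumed input regime of dendritic memory encoding: periodic
Ca2+-influx event trains with Gaussian timing jitter (LTP-range frequencies,
nominally 50-100 Hz), a frequency/synchrony-dependent CaMKII activation
efficacy peaking near 50 Hz, about 100 activated subunits per influx, and
the phosphorylation patterns those events stamp onto lattice patches.

All sampling flows through one seeded :class:`numpy.random.Generator`, so
every pattern is reproducible bit-for-bit from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .encoding import PhosphoPattern, get_scheme
from .errors import ParameterError, SimulationError

__all__ = [
    "InfluxTrain",
    "ActivationModel",
    "generate_train",
    "activation_efficacy",
    "sample_pattern",
]


@dataclass(frozen=True)
class InfluxTrain:
    """A sorted train of Ca2+-influx event times within [0, duration]."""

    event_times: Tuple[float, ...]
    frequency: float
    jitter_sd: float
    duration: float
    seed: Optional[int]

    @property
    def n_events(self) -> int:
        return len(self.event_times)

    @property
    def empirical_rate(self) -> float:
        return self.n_events / self.duration if self.duration > 0 else 0.0


@dataclass(frozen=True)
class ActivationModel:
    """Frequency/synchrony tuning of CaMKII activation.

    Efficacy is Gaussian in log2(f / optimal_frequency) with a bandwidth in
    octaves, scaled by ``1 - w + w * synchrony`` (w = synchrony_weight), so
    it is unimodal in log-frequency, peaks at the optimum, and is
    non-decreasing in synchrony.
    """

    optimal_frequency: float = 50.0
    bandwidth_octaves: float = 2.0
    synchrony_weight: float = 0.5
    subunits_per_influx: int = 100

    def __post_init__(self):
        if self.optimal_frequency <= 0:
            raise ParameterError("optimal_frequency must be > 0")
        if self.bandwidth_octaves <= 0:
            raise ParameterError("bandwidth_octaves must be > 0")
        if not 0 <= self.synchrony_weight <= 1:
            raise ParameterError("synchrony_weight must lie in [0, 1]")
        if self.subunits_per_influx < 1:
            raise ParameterError("subunits_per_influx must be >= 1")


def generate_train(
    frequency: float,
    duration: float,
    jitter_sd: float = 0.0,
    seed: Optional[int] = None,
) -> InfluxTrain:
    """Periodic influx events at ``frequency`` Hz with Gaussian jitter.

    With zero jitter the train is exactly periodic (events at i/f); jittered
    times are clipped to [0, duration] and sorted.  Reproducible under seed.
    """
    if frequency <= 0:
        raise ParameterError("frequency must be > 0")
    if duration <= 0:
        raise ParameterError("duration must be > 0")
    if jitter_sd < 0:
        raise ParameterError("jitter_sd must be >= 0")
    n = int(math.floor(frequency * duration))
    times = np.arange(n) / frequency
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        times = times + rng.normal(0.0, jitter_sd, size=n)
        times = np.clip(times, 0.0, duration)
        times.sort()
    return InfluxTrain(
        event_times=tuple(float(t) for t in times),
        frequency=frequency,
        jitter_sd=jitter_sd,
        duration=duration,
        seed=seed,
    )


def activation_efficacy(
    model: ActivationModel, frequency: float, synchrony: float = 1.0
) -> float:
    """CaMKII activation efficacy in [0, 1].

    Unimodal in log-frequency with its peak at ``model.optimal_frequency``;
    scaled by synchrony so fully synchronous input at the optimal frequency
    gives exactly 1.
    """
    if frequency <= 0:
        raise ParameterError("frequency must be > 0")
    if not 0 <= synchrony <= 1:
        raise ParameterError("synchrony must lie in [0, 1]")
    octaves = math.log2(frequency / model.optimal_frequency)
    tuning = math.exp(-(octaves**2) / (2.0 * model.bandwidth_octaves**2))
    gain = 1.0 - model.synchrony_weight + model.synchrony_weight * synchrony
    return tuning * gain


def sample_pattern(
    scheme,
    train: InfluxTrain,
    model: ActivationModel = ActivationModel(),
    seed: Optional[int] = None,
    synchrony: float = 1.0,
    efficacy: Optional[float] = None,
    max_attempts: int = 1000,
) -> PhosphoPattern:
    """Draw one stochastic phosphorylation pattern for a patch.

    Each admissible site is independently phosphorylated with probability
    ``p = efficacy * occupancy``.  Occupancy combines two factors: the
    train's delivered event rate relative to its nominal frequency (capped
    at 1), and the kinase-to-site ratio (six kinases over the scheme's
    sites), so a face of six kinases can never saturate an eight-site
    neighborhood.  Ternary sites split evenly between beta (1) and alpha (2)
    phosphorylation.  Schemes limited to six non-zero digits are
    rejection-sampled, with a hard attempt cap.  ``efficacy`` overrides the
    model-derived value when given (e.g. to probe the deterministic limits
    0 and 1).
    """
    s = get_scheme(scheme)
    rng = np.random.default_rng(seed)
    if efficacy is None:
        eff = activation_efficacy(model, train.frequency, synchrony)
    else:
        if not 0 <= efficacy <= 1:
            raise ParameterError("efficacy must lie in [0, 1]")
        eff = efficacy
    delivery = min(1.0, train.empirical_rate / train.frequency)
    kinase_coverage = min(1.0, s.max_phosphorylated / s.n_sites)
    p = eff * delivery * kinase_coverage
    for _ in range(max_attempts):
        hit = rng.random(s.n_sites) < p
        if s.states_per_site == 2:
            digits = hit.astype(int)
        else:
            kind = rng.integers(1, 3, size=s.n_sites)
            digits = np.where(hit, kind, 0)
        if int((digits != 0).sum()) <= s.max_phosphorylated:
            return PhosphoPattern(s, tuple(int(d) for d in digits))
    raise SimulationError(
        f"no admissible pattern found in {max_attempts} rejection attempts"
    )
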