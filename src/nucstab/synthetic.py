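"""Seeded synthetic data emulating the wet-lab measurements.

Two generators stand in for experiments that a stability study would run:

* :func:`gen_decay_series` emulates thermal-degradation time courses —
  first-order decay sampled at discrete times at several elevated
  temperatures, with multiplicative lognormal measurement noise (HPLC
  quantitation error is roughly proportional to the signal, and
  concentrations are positive).
* :func:`gen_speciation_observation` perturbs an exact equilibrium
  speciation the same way, providing inverse-problem fixtures for
  :func:`nucstab.speciation.fit_kdiss`.

Determinism: one global integer seed fixes every output byte-for-byte.
Per-temperature random substreams are derived from (seed, temperature),
so adding or removing a temperature never changes the data generated for
the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .degradation import DecayDataset, celsius_to_kelvin
from .speciation import EquilibriumConstants, SpeciationState, solve_equilibrium
from .thermo import ThermoContext

__all__ = ["DecayGeneratorSpec", "gen_decay_series", "gen_speciation_observation"]

_DEFAULT_TEMPS = (60.0, 65.0, 70.0, 75.0, 80.0)


@dataclass(frozen=True)
class DecayGeneratorSpec:
    """Arrhenius-consistent decay-experiment design.

    Defaults emulate a thermal-degradation study of 6-iodouridine:
    activation energy 26.8 kcal/mol; reference rate chosen so the
    half-life at the hottest point (80 deg C) is one hour; temperatures
    60-80 deg C in 5-degree steps; at each temperature 8 samples spanning
    two local half-lives (the hot-end window is on the order of the
    120-minute conditioning runs such studies use); 2% relative
    measurement noise.
    """

    activation_energy: float = 26.8            # kcal/mol
    reference_rate_s: float = math.log(2.0) / 3600.0
    reference_temperature_K: float = celsius_to_kelvin(80.0)
    temperatures_C: tuple[float, ...] = _DEFAULT_TEMPS
    n_time_points: int = 8
    n_half_lives: float = 2.0
    initial_concentration: float = 1e-3
    noise_sd: float = 0.02
    seed: int = 0
    gas_constant: float = ThermoContext().gas_constant

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.temperatures_C) == 0:
            raise ValueError("at least one temperature is required")
        if self.n_time_points < 3:
            raise ValueError("need >= 3 time points per series")

    def rate_at(self, temperature_C: float) -> float:
        """Arrhenius rate constant (s^-1) implied by the spec at ``T``."""
        T = celsius_to_kelvin(temperature_C)
        ea_over_r = self.activation_energy / self.gas_constant
        return self.reference_rate_s * math.exp(
            -ea_over_r * (1.0 / T - 1.0 / self.reference_temperature_K)
        )

    def time_grid_min(self, temperature_C: float) -> np.ndarray:
        """Sampling times (min): evenly spaced over ``n_half_lives``."""
        half_life_s = math.log(2.0) / self.rate_at(temperature_C)
        t_end_min = self.n_half_lives * half_life_s / 60.0
        return np.linspace(0.0, t_end_min, self.n_time_points)


def _substream(seed: int, *context: int) -> np.random.Generator:
    """Independent deterministic stream for (seed, context...)."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), *context)))


def gen_decay_series(spec: DecayGeneratorSpec) -> list[DecayDataset]:
    """Noisy first-order decay series, one per temperature.

    C(t) = C0 exp(-k(T) t) * exp(sd * Z), Z ~ N(0, 1) i.i.d. per sample;
    the log-scale noise sd equals the relative sd to first order (2%
    default).  Deterministic under a fixed ``spec.seed``.
    """
    out = []
    for temp in spec.temperatures_C:
        rng = _substream(spec.seed, int(round(temp * 1000)))
        t_min = spec.time_grid_min(temp)
        k = spec.rate_at(temp)
        clean = spec.initial_concentration * np.exp(-k * t_min * 60.0)
        noise = np.exp(spec.noise_sd * rng.standard_normal(t_min.size)) \
            if spec.noise_sd > 0 else 1.0
        out.append(DecayDataset(
            temperature_C=float(temp),
            times_min=t_min,
            concentrations=clean * noise,
        ))
    return out


def gen_speciation_observation(
    constants: EquilibriumConstants,
    initial_nucleoside: float,
    perturbation_sd: float,
    seed: int,
) -> SpeciationState:
    """Equilibrium speciation with lognormal observation noise.

    Each observable (non-zero) species is independently multiplied by
    exp(sd * Z).  The perturbed state intentionally violates the exact
    balances — it plays the role of a measured composition, the input to
    robustness studies of the K_diss inverse problem.
    """
    state = solve_equilibrium(constants, initial_nucleoside)
    if perturbation_sd == 0:
        return state
    if perturbation_sd < 0:
        raise ValueError("perturbation_sd must be >= 0")
    rng = _substream(seed, 7)
    perturbed = {}
    for name, value in state.as_dict().items():
        if value > 0:
            perturbed[name] = value * math.exp(
                perturbation_sd * rng.standard_normal())
        else:
            perturbed[name] = value
    return SpeciationState(**perturbed)
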