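"""Thermodynamic primitives: free energies into equilibrium and rate constants.

This module converts the quantities a quantum-chemistry study actually
produces — reaction free energies ΔG, activation free energies ΔG‡, and
proton-exchange free energies ΔΔG against a reference acid — into the
quantities a kinetic model consumes: equilibrium constants, pK values, and
forward/reverse rate constants.

Conventions used throughout the package:

* energies are in kcal/mol (no unit auto-detection);
* equilibrium constants are dimensionless on a 1 mol/dm3 standard state;
* rate constants follow transition-state theory with transmission
  coefficient 1, so a unimolecular barrier gives s^-1 and a bimolecular
  one dm3 mol^-1 s^-1;
* the default temperature is 298.15 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "KCAL_GAS_CONSTANT",
    "ThermoContext",
    "ExchangeRole",
    "ExchangeReaction",
    "BarrierSpec",
    "eyring_prefactor",
    "gibbs_to_K",
    "gibbs_from_K",
    "pk_from_exchange",
    "eyring_rate",
    "reverse_rate",
    "implied_activation_energy",
]

#: Molar gas constant in kcal mol^-1 K^-1.
KCAL_GAS_CONSTANT = 1.98720e-3

# CODATA values; only their ratio times T enters the Eyring prefactor.
_BOLTZMANN_J_PER_K = 1.380649e-23
_PLANCK_J_S = 6.62607015e-34

_LN10 = math.log(10.0)


def eyring_prefactor(temperature: float) -> float:
    """Transition-state-theory frequency factor k_B*T/h in s^-1."""
    if not (math.isfinite(temperature) and temperature > 0):
        raise ValueError(f"temperature must be positive and finite, got {temperature!r}")
    return _BOLTZMANN_J_PER_K * temperature / _PLANCK_J_S


@dataclass(frozen=True)
class ThermoContext:
    """Shared thermodynamic state for one analysis.

    Parameters
    ----------
    temperature : float
        Absolute temperature in K.  Default 298.15 K (25 deg C); every
        printed comparison value in the bundled presets refers to ambient
        temperature, where the 0.15 K difference from a nominal 298 K is
        far below the rounding of the inputs.
    gas_constant : float
        Gas constant in kcal mol^-1 K^-1.
    eyring_prefactor_s : float, optional
        k_B*T/h in s^-1.  Computed from ``temperature`` when omitted; if
        supplied it must agree with the recomputed value to 0.1%.
    pKw : float
        Negative decimal logarithm of the water ion product.  Default 14.0.
    water_concentration : float
        Bulk water concentration in mol/dm3, held constant by every model
        in this package.  Default 55.5.
    """

    temperature: float = 298.15
    gas_constant: float = KCAL_GAS_CONSTANT
    eyring_prefactor_s: float = field(default=None)  # type: ignore[assignment]
    pKw: float = 14.0
    water_concentration: float = 55.5

    def __post_init__(self):
        if not (math.isfinite(self.temperature) and self.temperature > 0):
            raise ValueError(f"temperature must be > 0, got {self.temperature!r}")
        recomputed = eyring_prefactor(self.temperature)
        if self.eyring_prefactor_s is None:
            object.__setattr__(self, "eyring_prefactor_s", recomputed)
        elif abs(self.eyring_prefactor_s - recomputed) > 1e-3 * recomputed:
            raise ValueError(
                "eyring_prefactor_s disagrees with k_B*T/h at "
                f"T={self.temperature} K by more than 0.1%: "
                f"{self.eyring_prefactor_s:.6e} vs {recomputed:.6e}"
            )
        if self.water_concentration <= 0:
            raise ValueError("water_concentration must be positive")

    @property
    def RT(self) -> float:
        """Thermal energy R*T in kcal/mol."""
        return self.gas_constant * self.temperature

    @property
    def Kw(self) -> float:
        """Water ion product (mol/dm3)^2."""
        return 10.0 ** (-self.pKw)


class ExchangeRole(str, Enum):
    """Which acid/base constant a proton-exchange reaction defines.

    ``ANIONIC_BASE``
        The target species is a base anion (a deprotonated nucleobase);
        the exchange against the reference acid yields its K_b, and the
        reference pK entering the cycle is the reference *base* strength
        pKw - pKa(reference acid).
    ``CATIONIC_ACID``
        The target species is a cation acting as an acid (a sugar
        oxocarbenium); the exchange yields its K_a against the reference
        cation's pKa directly.
    """

    ANIONIC_BASE = "anionic_base"
    CATIONIC_ACID = "cationic_acid"


@dataclass(frozen=True)
class ExchangeReaction:
    """A proton-exchange reaction defining a pK through a thermodynamic cycle.

    ``ddG`` is the free-energy change (kcal/mol) of the exchange written
    with the target ion on the left; ``reference_pK`` is the pK of the
    reference species on the same (acid or base) scale as the result.
    """

    ddG: float
    reference_pK: float
    role: ExchangeRole = ExchangeRole.ANIONIC_BASE

    def __post_init__(self):
        if not math.isfinite(self.ddG):
            raise ValueError(f"ddG must be finite, got {self.ddG!r}")
        if not math.isfinite(self.reference_pK):
            raise ValueError(f"reference_pK must be finite, got {self.reference_pK!r}")
        # accept plain strings for convenience, normalise to the enum
        object.__setattr__(self, "role", ExchangeRole(self.role))


@dataclass(frozen=True)
class BarrierSpec:
    """An activation free energy with its molecularity.

    ``molecularity`` only fixes the units of the resulting rate constant
    (1: s^-1; 2: dm3 mol^-1 s^-1 on a 1 M standard state).
    """

    dG_act: float
    molecularity: int = 1

    def __post_init__(self):
        if not math.isfinite(self.dG_act):
            raise ValueError(f"dG_act must be finite, got {self.dG_act!r}")
        if self.molecularity not in (1, 2):
            raise ValueError(f"molecularity must be 1 or 2, got {self.molecularity!r}")


def gibbs_to_K(dG: float, ctx: ThermoContext | None = None) -> float:
    """Equilibrium constant K = exp(-dG / RT).

    Strictly decreasing in ``dG``; K(0) = 1.  Very negative ``dG`` may
    return ``inf`` (the reaction is then treated as irreversible by
    :func:`reverse_rate` callers).
    """
    ctx = ctx or ThermoContext()
    if not math.isfinite(dG):
        raise ValueError(f"dG must be finite, got {dG!r}")
    try:
        return math.exp(-dG / ctx.RT)
    except OverflowError:
        return math.inf


def gibbs_from_K(K: float, ctx: ThermoContext | None = None) -> float:
    """Inverse of :func:`gibbs_to_K`: dG = -RT ln K (kcal/mol)."""
    ctx = ctx or ThermoContext()
    if not (K > 0 and math.isfinite(K)):
        raise ValueError(f"K must be positive and finite, got {K!r}")
    return -ctx.RT * math.log(K)


def pk_from_exchange(rxn: ExchangeReaction, ctx: ThermoContext | None = None) -> float:
    """pK of the target ion from a proton-exchange thermodynamic cycle.

    pK = pK_ref + s * ddG / (RT ln 10), with s = +1 for an anionic base
    (its pK_b grows as the exchange becomes less favourable) and s = -1
    for a cationic acid (its pK_a falls).  The sign convention matches
    exchanges written with the target ion on the left-hand side.
    """
    ctx = ctx or ThermoContext()
    if rxn.role is ExchangeRole.ANIONIC_BASE:
        sign = 1.0
    elif rxn.role is ExchangeRole.CATIONIC_ACID:
        sign = -1.0
    else:  # pragma: no cover - enum already validates
        raise ValueError(f"unknown exchange role {rxn.role!r}")
    return rxn.reference_pK + sign * rxn.ddG / (ctx.RT * _LN10)


def eyring_rate(barrier: BarrierSpec | float, ctx: ThermoContext | None = None) -> float:
    """Rate constant k = (k_B T / h) * exp(-dG_act / RT).

    Accepts either a :class:`BarrierSpec` or a bare barrier height in
    kcal/mol (unimolecular assumed).  Transmission coefficient is 1.
    """
    ctx = ctx or ThermoContext()
    if not isinstance(barrier, BarrierSpec):
        barrier = BarrierSpec(float(barrier))
    return ctx.eyring_prefactor_s * math.exp(-barrier.dG_act / ctx.RT)


def reverse_rate(k_forward: float, K: float) -> float:
    """Reverse rate constant from detailed balance: k_rev = k_fwd / K.

    ``K = 0`` is rejected: a vanishing equilibrium constant means the
    forward reaction was written the wrong way round (an irreversible
    step should simply omit its reverse reaction).  ``K = inf`` returns 0.
    """
    if not (k_forward >= 0 and math.isfinite(k_forward)):
        raise ValueError(f"k_forward must be finite and >= 0, got {k_forward!r}")
    if K == 0:
        raise ValueError(
            "K = 0 passed to reverse_rate; an irreversible reaction has no "
            "reverse rate constant"
        )
    if math.isinf(K):
        return 0.0
    if not K > 0:
        raise ValueError(f"K must be positive, got {K!r}")
    return k_forward / K


def implied_activation_energy(k: float, ctx: ThermoContext | None = None) -> float:
    """Eyring-equivalent barrier dG_act = RT ln(k_B T / (h k)) in kcal/mol.

    Inverts :func:`eyring_rate`; used to express an experimentally fitted
    rate constant on the same scale as a computed activation free energy.
    """
    ctx = ctx or ThermoContext()
    if not (k > 0 and math.isfinite(k)):
        raise ValueError(f"rate constant must be positive and finite, got {k!r}")
    return ctx.RT * math.log(ctx.eyring_prefactor_s / k)
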