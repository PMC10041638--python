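"""Bundled compound presets and the config -> model pipeline.

The presets ship the published thermochemistry for the three iodinated
pyrimidine nucleosides (5IdU, 6IdU, 6IUrd).  :func:`build_model` is the
single place where a configuration becomes numbers: pK values via the
thermodynamic cycle, equilibrium constants, a calibrated K_diss, and a
ready-to-integrate reaction network.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .config import CompoundConfig, load_config
from .errors import ConfigError
from .kinetics import ReactionNetwork, build_network
from .speciation import EquilibriumConstants, fit_kdiss
from .thermo import (
    BarrierSpec,
    ExchangeRole,
    ThermoContext,
    gibbs_to_K,
    pk_from_exchange,
)

__all__ = ["PRESET_NAMES", "load_preset", "resolve_compound",
           "CompoundModel", "build_model"]

PRESET_NAMES = ("5IdU", "6IdU", "6IUrd")
_FILES = {"5IdU": "5idu.yaml", "6IdU": "6idu.yaml", "6IUrd": "6iurd.yaml"}


def load_preset(name: str) -> CompoundConfig:
    """Load one of the bundled compound presets by name (case-insensitive)."""
    key = {n.lower(): n for n in PRESET_NAMES}.get(name.lower())
    if key is None:
        raise ConfigError(
            f"unknown compound {name!r}; presets: {', '.join(PRESET_NAMES)}")
    ref = resources.files("nucstab.data") / _FILES[key]
    with resources.as_file(ref) as path:
        return load_config(path)


def resolve_compound(name_or_path: str) -> CompoundConfig:
    """Interpret a CLI argument as a preset name or a config file path."""
    if name_or_path.lower() in {n.lower() for n in PRESET_NAMES}:
        return load_preset(name_or_path)
    path = Path(name_or_path)
    if path.exists():
        return load_config(path)
    raise ConfigError(
        f"{name_or_path!r} is neither a preset ({', '.join(PRESET_NAMES)}) "
        "nor an existing config file")


@dataclass(frozen=True)
class CompoundModel:
    """Fully derived model for one compound."""

    config: CompoundConfig
    ctx: ThermoContext
    pK_base: float          # pK_b of the nucleobase anion
    pK_sugar: float         # pK_a of the sugar oxocarbenium
    constants: EquilibriumConstants
    network: ReactionNetwork

    @property
    def K_b(self) -> float:
        return self.constants.K_b

    @property
    def K_a(self) -> float:
        return self.constants.K_a

    @property
    def K_diss(self) -> float:
        return self.constants.K_diss


def thermo_context(config: CompoundConfig) -> ThermoContext:
    return ThermoContext(**config.thermo)


def build_model(config: CompoundConfig,
                ctx: ThermoContext | None = None) -> CompoundModel:
    """Derive pK values, equilibrium constants, and the reaction network.

    The dissociation constant is calibrated so that the equilibrium solve
    reproduces the configured residual nucleoside concentration; K_a and
    K_b come from the proton-exchange thermodynamic cycles; all kinetic
    reverse rates then follow from detailed balance.
    """
    ctx = ctx or thermo_context(config)
    base_rxn = config.base_exchange.to_reaction(pKw=ctx.pKw)
    sugar_rxn = config.sugar_exchange.to_reaction(pKw=ctx.pKw)
    if base_rxn.role is not ExchangeRole.ANIONIC_BASE:
        raise ConfigError("base_exchange must have role 'anionic_base'")
    if sugar_rxn.role is not ExchangeRole.CATIONIC_ACID:
        raise ConfigError("sugar_exchange must have role 'cationic_acid'")
    pk_b = pk_from_exchange(base_rxn, ctx)
    pk_a = pk_from_exchange(sugar_rxn, ctx)
    constants = EquilibriumConstants(
        K_a=10.0 ** (-pk_a),
        K_b=10.0 ** (-pk_b),
        K_w=ctx.Kw,
        K_sn2=(gibbs_to_K(config.sn2_channel.dG_kcal_per_mol, ctx)
               if config.sn2_channel else None),
    )
    k_diss = fit_kdiss(config.residual_nucleoside_M, constants,
                       config.initial_concentration_M)
    constants = constants.with_kdiss(k_diss)
    network = build_network(
        config.compound,
        BarrierSpec(config.dissociation_dG_act_kcal_per_mol),
        constants,
        ctx,
        sn2_barrier=(BarrierSpec(config.sn2_channel.dG_act_kcal_per_mol,
                                 molecularity=2)
                     if config.sn2_channel else None),
        sn2_dG=(config.sn2_channel.dG_kcal_per_mol
                if config.sn2_channel else None),
    )
    return CompoundModel(config=config, ctx=ctx, pK_base=pk_b, pK_sugar=pk_a,
                         constants=constants, network=network)
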