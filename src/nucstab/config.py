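"""Compound configuration: strict, unit-explicit, round-trippable.

Every number the pipeline consumes for a compound lives in one structured
YAML document with units spelled out in the key names (the analysis is
unit-fragile, so implicit units are banned).  Loading rejects unknown keys
at every level, and load -> save -> load is lossless.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .thermo import ExchangeReaction, ExchangeRole

__all__ = [
    "ExchangeEntry",
    "Sn2Channel",
    "ClassificationThresholds",
    "CompoundConfig",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class ExchangeEntry:
    """One proton-exchange row: the printed ddG plus its reference acid.

    ``reference_pKa`` is always the *acid* pKa of the reference compound;
    for an anionic base the cycle itself uses the conjugate base strength
    pKw - pKa, which :meth:`to_reaction` applies.
    """

    species: str
    ddG_kcal_per_mol: float
    reference_species: str
    reference_pKa: float
    role: str  # "anionic_base" | "cationic_acid"

    def to_reaction(self, pKw: float = 14.0) -> ExchangeReaction:
        role = ExchangeRole(self.role)
        ref = (pKw - self.reference_pKa
               if role is ExchangeRole.ANIONIC_BASE else self.reference_pKa)
        return ExchangeReaction(ddG=self.ddG_kcal_per_mol,
                                reference_pK=ref, role=role)


@dataclass(frozen=True)
class Sn2Channel:
    """Hydroxide SN2 side channel (reaction and activation free energies)."""

    dG_kcal_per_mol: float
    dG_act_kcal_per_mol: float


@dataclass(frozen=True)
class ClassificationThresholds:
    """Half-life cutoffs (s) for the qualitative stability verdict."""

    unstable_below_s: float = 60.0
    moderately_stable_below_s: float = 7 * 24 * 3600.0

    def classify(self, half_life_s: float | None) -> str:
        if half_life_s is None:
            # no half-life: the equilibrium keeps most of the substrate
            return "stable"
        if half_life_s < self.unstable_below_s:
            return "unstable"
        if half_life_s < self.moderately_stable_below_s:
            return "moderately stable"
        return "stable"


@dataclass(frozen=True)
class CompoundConfig:
    """Everything needed to analyse one nucleoside."""

    compound: str
    full_name: str
    initial_concentration_M: float
    residual_nucleoside_M: float
    base_exchange: ExchangeEntry
    sugar_exchange: ExchangeEntry
    dissociation_dG_act_kcal_per_mol: float
    sn2_channel: Sn2Channel | None = None
    thermo: dict = field(default_factory=dict)
    classification: ClassificationThresholds = field(
        default_factory=ClassificationThresholds)

    def __post_init__(self):
        if not 0 < self.residual_nucleoside_M < self.initial_concentration_M:
            raise ConfigError(
                "residual_nucleoside_M must lie strictly between 0 and "
                "initial_concentration_M"
            )
        if not (math.isfinite(self.dissociation_dG_act_kcal_per_mol)
                and self.dissociation_dG_act_kcal_per_mol >= 0):
            raise ConfigError("dissociation_dG_act_kcal_per_mol must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.sn2_channel is None:
            d["sn2_channel"] = None
        return d


def _require_keys(mapping: dict, allowed: set[str], required: set[str],
                  where: str) -> None:
    if not isinstance(mapping, dict):
        raise ConfigError(f"{where}: expected a mapping, got {type(mapping).__name__}")
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")
    missing = required - set(mapping)
    if missing:
        raise ConfigError(f"{where}: missing required key(s) {sorted(missing)}")


def _parse_exchange(d: dict, where: str) -> ExchangeEntry:
    keys = {"species", "ddG_kcal_per_mol", "reference_species",
            "reference_pKa", "role"}
    _require_keys(d, keys, keys, where)
    if d["role"] not in ("anionic_base", "cationic_acid"):
        raise ConfigError(f"{where}: role must be 'anionic_base' or "
                          f"'cationic_acid', got {d['role']!r}")
    return ExchangeEntry(**d)


def config_from_dict(data: dict, source: str = "<dict>") -> CompoundConfig:
    top_required = {
        "compound", "full_name", "initial_concentration_M",
        "residual_nucleoside_M", "base_exchange", "sugar_exchange",
        "dissociation_dG_act_kcal_per_mol",
    }
    top_allowed = top_required | {"sn2_channel", "thermo", "classification"}
    _require_keys(data, top_allowed, top_required, source)

    sn2 = data.get("sn2_channel")
    if sn2 is not None:
        keys = {"dG_kcal_per_mol", "dG_act_kcal_per_mol"}
        _require_keys(sn2, keys, keys, f"{source}.sn2_channel")
        sn2 = Sn2Channel(**sn2)

    thermo = data.get("thermo") or {}
    allowed_thermo = {"temperature", "gas_constant", "pKw", "water_concentration"}
    _require_keys(thermo, allowed_thermo, set(), f"{source}.thermo")

    cls = data.get("classification")
    if cls is not None:
        keys = {"unstable_below_s", "moderately_stable_below_s"}
        _require_keys(cls, keys, set(), f"{source}.classification")
        cls = ClassificationThresholds(**cls)
    else:
        cls = ClassificationThresholds()

    try:
        return CompoundConfig(
            compound=data["compound"],
            full_name=data["full_name"],
            initial_concentration_M=float(data["initial_concentration_M"]),
            residual_nucleoside_M=float(data["residual_nucleoside_M"]),
            base_exchange=_parse_exchange(data["base_exchange"],
                                          f"{source}.base_exchange"),
            sugar_exchange=_parse_exchange(data["sugar_exchange"],
                                           f"{source}.sugar_exchange"),
            dissociation_dG_act_kcal_per_mol=float(
                data["dissociation_dG_act_kcal_per_mol"]),
            sn2_channel=sn2,
            thermo=dict(thermo),
            classification=cls,
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{source}: {exc}") from exc


def load_config(path) -> CompoundConfig:
    """Load and validate a compound configuration from YAML."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return config_from_dict(data, source=str(path))


def save_config(config: CompoundConfig, path) -> None:
    """Write a configuration back to YAML (lossless round trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True,
                       default_flow_style=False)
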