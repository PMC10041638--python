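"""Experimental-style degradation kinetics: first-order fits and Arrhenius analysis.

This module reproduces the classical accelerated-stability workflow for a
compound followed by HPLC at several elevated temperatures:

1. at each temperature, ln(concentration) vs time is fit by ordinary
   least squares and the negated slope is the first-order rate constant;
2. ln k vs 1/T across temperatures gives the Arrhenius activation energy
   E_a = -slope * R and the log prefactor;
3. the fit is extrapolated to 25 deg C to predict the ambient rate
   constant and shelf half-life.

E_a (an Arrhenius empirical slope) and an Eyring activation free energy
dG_act are different conventions for "the barrier"; :func:`compare_barriers`
reports both side by side, converting the extrapolated ambient rate into
its Eyring-equivalent barrier so a computed dG_act can be compared with
experiment on one scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .thermo import BarrierSpec, ThermoContext, implied_activation_energy

__all__ = [
    "DecayDataset",
    "FirstOrderFit",
    "ArrheniusFit",
    "fit_first_order",
    "fit_arrhenius",
    "compare_barriers",
    "read_decay_table",
    "write_decay_table",
    "celsius_to_kelvin",
]

_AMBIENT_K = 298.15


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + 273.15


@dataclass
class DecayDataset:
    """One concentration-time series at a single temperature.

    Times are in minutes (the bench convention); concentrations may be in
    any consistent unit (mol/dm3 or raw peak area) since only their
    logarithmic slope matters.
    """

    temperature_C: float
    times_min: np.ndarray
    concentrations: np.ndarray
    replicate: int = 0

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times_min.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must have equal length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("time points must be strictly increasing")

    @property
    def temperature_K(self) -> float:
        return celsius_to_kelvin(self.temperature_C)


@dataclass(frozen=True)
class FirstOrderFit:
    """Rate constant (s^-1) from a log-linear decay fit, with diagnostics."""

    rate_s: float
    stderr_s: float
    intercept_ln: float
    r_squared: float
    n_points: int
    temperature_C: float


@dataclass(frozen=True)
class ArrheniusFit:
    """ln k vs 1/T regression result.

    ``activation_energy`` is in kcal/mol (E_a = -slope * R);
    ``log_prefactor`` is the natural log of the extrapolated prefactor in
    s^-1.  ``rate_constants`` maps temperature (K) to the fitted k (s^-1).
    """

    activation_energy: float
    activation_energy_stderr: float
    log_prefactor: float
    r_squared: float
    rate_constants: dict[float, float] = field(default_factory=dict)
    gas_constant: float = ThermoContext().gas_constant

    def rate_at(self, temperature_K: float) -> float:
        return math.exp(self.log_prefactor
                        - self.activation_energy / (self.gas_constant * temperature_K))

    @property
    def rate_25C(self) -> float:
        """Extrapolated ambient (298.15 K) rate constant in s^-1."""
        return self.rate_at(_AMBIENT_K)

    @property
    def half_life_25C_s(self) -> float:
        """Predicted ambient first-order half-life ln2/k in s."""
        return math.log(2.0) / self.rate_25C


def fit_first_order(dataset: DecayDataset) -> FirstOrderFit:
    """Least-squares first-order rate constant from one decay series.

    Fits ln C = ln C0 - k t by ordinary least squares (times converted to
    seconds) and returns the negated slope with its standard error.
    """
    if dataset.times_min.size < 3:
        raise ValueError("need at least 3 time points for a rate fit")
    if np.any(dataset.concentrations <= 0):
        raise ValueError(
            "non-positive concentrations cannot enter a log-linear fit; "
            "censor points at or below the detection limit first"
        )
    t_s = dataset.times_min * 60.0
    res = stats.linregress(t_s, np.log(dataset.concentrations))
    return FirstOrderFit(
        rate_s=-res.slope,
        stderr_s=res.stderr,
        intercept_ln=res.intercept,
        r_squared=res.rvalue ** 2,
        n_points=int(t_s.size),
        temperature_C=dataset.temperature_C,
    )


def fit_arrhenius(
    rates: list[tuple[float, float]],
    gas_constant: float | None = None,
) -> ArrheniusFit:
    """Arrhenius regression over (temperature K, rate constant s^-1) pairs.

    Unweighted OLS on ln k vs 1/T.  Replicate temperatures are pooled into
    the single regression.  At exactly two distinct temperatures the fit
    is the two-point analytic solution (R^2 = 1 by construction).
    """
    R = gas_constant if gas_constant is not None else ThermoContext().gas_constant
    if len(rates) < 2:
        raise ValueError("need rate constants at >= 2 temperatures")
    T = np.array([t for t, _ in rates], dtype=float)
    k = np.array([r for _, r in rates], dtype=float)
    if np.unique(T).size < 2:
        raise ValueError("all rate constants are at one temperature; "
                         "an Arrhenius slope needs >= 2 distinct temperatures")
    if np.any(k <= 0):
        raise ValueError("rate constants must be positive")
    res = stats.linregress(1.0 / T, np.log(k))
    slope_se = 0.0 if math.isnan(res.stderr) else res.stderr
    return ArrheniusFit(
        activation_energy=-res.slope * R,
        activation_energy_stderr=slope_se * R,
        log_prefactor=res.intercept,
        r_squared=res.rvalue ** 2,
        rate_constants={float(t): float(r) for t, r in rates},
        gas_constant=R,
    )


def compare_barriers(
    fit: ArrheniusFit,
    computed: BarrierSpec | float,
    ctx: ThermoContext | None = None,
) -> dict[str, float]:
    """Side-by-side report of experimental and computed activation measures.

    Returns the Arrhenius ``activation_energy_kcal`` (an empirical slope),
    the ``implied_dG_act_kcal`` obtained by pushing the extrapolated
    ambient rate constant through the Eyring relation, the externally
    ``computed_dG_act_kcal``, and their differences.  The two "energies"
    follow different conventions and are labelled accordingly; the
    difference fields quantify, not hide, that gap.
    """
    ctx = ctx or ThermoContext()
    if not isinstance(computed, BarrierSpec):
        computed = BarrierSpec(float(computed))
    implied = implied_activation_energy(fit.rate_25C, ctx)
    return {
        "activation_energy_kcal": fit.activation_energy,
        "activation_energy_stderr_kcal": fit.activation_energy_stderr,
        "implied_dG_act_kcal": implied,
        "computed_dG_act_kcal": computed.dG_act,
        "arrhenius_minus_computed_kcal": fit.activation_energy - computed.dG_act,
        "implied_minus_computed_kcal": implied - computed.dG_act,
        "rate_25C_s": fit.rate_25C,
        "half_life_25C_s": fit.half_life_25C_s,
    }


# -- delimited I/O ------------------------------------------------------

_COLUMNS = ["temperature_C", "time_min", "concentration", "replicate"]


def write_decay_table(datasets: list[DecayDataset], path) -> None:
    """Write decay series as tab-separated text (one row per observation)."""
    rows = []
    for d in datasets:
        for t, c in zip(d.times_min, d.concentrations):
            rows.append((d.temperature_C, t, c, d.replicate))
    frame = pd.DataFrame(rows, columns=_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10e")


def read_decay_table(path) -> list[DecayDataset]:
    """Read the tab-separated decay format back into datasets.

    Rows are grouped by (temperature, replicate); a missing replicate
    column is treated as a single replicate 0.
    """
    frame = pd.read_csv(path, sep="\t")
    missing = set(_COLUMNS[:3]) - set(frame.columns)
    if missing:
        raise ValueError(f"decay table missing column(s): {sorted(missing)}")
    if "replicate" not in frame.columns:
        frame["replicate"] = 0
    out = []
    for (temp, rep), grp in frame.groupby(["temperature_C", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        out.append(DecayDataset(
            temperature_C=float(temp),
            times_min=grp["time_min"].to_numpy(),
            concentrations=grp["concentration"].to_numpy(),
            replicate=int(rep),
        ))
    return out


def fit_report(datasets: list[DecayDataset],
               ctx: ThermoContext | None = None) -> dict:
    """End-to-end fit of a decay corpus: per-temperature rates + Arrhenius.

    Replicates at one temperature are pooled into a single log-linear
    regression before the Arrhenius stage.
    """
    by_temp: dict[float, list[DecayDataset]] = {}
    for d in datasets:
        by_temp.setdefault(d.temperature_C, []).append(d)
    per_temperature = {}
    pairs = []
    for temp in sorted(by_temp):
        group = by_temp[temp]
        if len(group) > 1:
            # replicates share time points, so pool the raw observations
            # into one regression rather than a (strictly-increasing)
            # DecayDataset
            t_s = np.concatenate([g.times_min for g in group]) * 60.0
            lnc = np.log(np.concatenate([g.concentrations for g in group]))
            if np.any(~np.isfinite(lnc)):
                raise ValueError("non-positive concentrations in pooled fit")
            res = stats.linregress(t_s, lnc)
            fit = FirstOrderFit(-res.slope, res.stderr, res.intercept,
                                res.rvalue ** 2, t_s.size, temp)
        else:
            fit = fit_first_order(group[0])
        per_temperature[temp] = fit
        pairs.append((celsius_to_kelvin(temp), fit.rate_s))
    arr = fit_arrhenius(pairs)
    return {
        "per_temperature": {
            f"{temp:g}": {"rate_s": f.rate_s, "stderr_s": f.stderr_s,
                          "r_squared": f.r_squared, "n_points": f.n_points}
            for temp, f in per_temperature.items()
        },
        "activation_energy_kcal": arr.activation_energy,
        "activation_energy_stderr_kcal": arr.activation_energy_stderr,
        "ln_prefactor": arr.log_prefactor,
        "r_squared": arr.r_squared,
        "rate_25C_s": arr.rate_25C,
        "half_life_25C_s": arr.half_life_25C_s,
        "_fit": arr,
    }


def report_to_json(report: dict, path) -> None:
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    with open(path, "w") as fh:
        json.dump(clean, fh, indent=2, sort_keys=True)
        fh.write("\n")
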