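"""Equilibrium speciation of the nucleoside hydrolysis network.

A nucleoside Nuc dissolved in water partitions, at equilibrium, among the
species of the coupled system

    Nuc        <=>  A-  +  R+          K_diss = [A-][R+]/[Nuc]
    R+ + 2H2O  <=>  R   +  H3O+        K_a    = [R][H3O+]/[R+]
    A- +  H2O  <=>  A   +  OH-         K_b    = [A][OH-]/[A-]
    2H2O       <=>  H3O+ + OH-         K_w    = [H3O+][OH-]

(water activity folded into the constants), subject to conservation of the
nucleobase and sugar units and to electroneutrality.  Species span more
than twenty orders of magnitude in concentration, so the solver works on
logarithmic variables throughout: an outer scalar root-find on ln[Nuc]
(the dissociation equilibrium) wraps an inner root-find on log10[H3O+]
(charge balance), with every other species given in closed form.  Both
scalar problems are strictly monotone, so the physical root is unique and
bracketing cannot fail.

The hydroxide SN2 side channel of 6-iodouridine is deliberately *not*
part of the equilibrium system: its reaction free energy (about
-72 kcal/mol) would predict quantitative conversion to 6-hydroxyuridine,
which is not what either the long-time kinetics or the observations show
on any relevant timescale.  The channel is treated kinetically only (see
:mod:`nucstab.kinetics`), and the 6-hydroxyuridine/iodide fields of
:class:`SpeciationState` stay at zero in equilibrium output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd
from scipy.optimize import brentq

from .errors import ConvergenceError
from .thermo import ThermoContext

__all__ = [
    "EquilibriumConstants",
    "SpeciationState",
    "solve_equilibrium",
    "fit_kdiss",
    "decomposed_fraction",
    "speciation_table",
    "SPECIES_LABELS",
]


@dataclass(frozen=True)
class EquilibriumConstants:
    """Equilibrium constants of the hydrolysis network (1 M standard state).

    ``K_diss`` may be ``None`` while the dissociation constant is still to
    be calibrated (see :func:`fit_kdiss`); every other constant must be a
    positive number.  ``K_sn2`` is the (huge) constant of the hydroxide
    SN2 channel, carried for kinetic use only.
    """

    K_a: float
    K_b: float
    K_w: float = 1e-14
    K_diss: float | None = None
    K_sn2: float | None = None

    def __post_init__(self):
        for name in ("K_a", "K_b", "K_w"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")
        if self.K_diss is not None and not self.K_diss >= 0:
            raise ValueError(f"K_diss must be >= 0, got {self.K_diss!r}")
        if self.K_sn2 is not None and not self.K_sn2 > 0:
            raise ValueError(f"K_sn2 must be positive, got {self.K_sn2!r}")

    def with_kdiss(self, K_diss: float) -> "EquilibriumConstants":
        return replace(self, K_diss=K_diss)


@dataclass
class SpeciationState:
    """Concentrations (mol/dm3) of every species in the network.

    ``hydr_nucleoside`` (the SN2 product 6-hydroxyuridine) and ``iodide``
    are only populated by kinetic simulations of 6-iodouridine; the
    equilibrium solver leaves them at zero.
    """

    nucleoside: float
    base: float
    base_anion: float
    sugar: float
    sugar_cation: float
    hydronium: float
    hydroxide: float
    hydr_nucleoside: float = 0.0
    iodide: float = 0.0

    _FIELDS = (
        "nucleoside", "base", "base_anion", "sugar", "sugar_cation",
        "hydronium", "hydroxide", "hydr_nucleoside", "iodide",
    )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self._FIELDS}

    def base_balance(self, initial: float) -> float:
        """Relative error of the nucleobase-unit balance."""
        total = self.nucleoside + self.base + self.base_anion + self.hydr_nucleoside
        return (total - initial) / initial

    def sugar_balance(self, initial: float) -> float:
        """Relative error of the sugar-unit balance."""
        total = self.nucleoside + self.sugar + self.sugar_cation + self.hydr_nucleoside
        return (total - initial) / initial

    def charge_balance(self) -> float:
        """Charge imbalance relative to the total ionic content."""
        positive = self.hydronium + self.sugar_cation
        negative = self.base_anion + self.hydroxide + self.iodide
        total = positive + negative
        return (positive - negative) / total if total > 0 else 0.0

    def ion_product(self) -> float:
        return self.hydronium * self.hydroxide

    def validate(self, initial: float, K_w: float | None = None,
                 rel_tol: float = 1e-6) -> None:
        """Raise if a balance is violated beyond ``rel_tol``."""
        residuals = {
            "base_balance": self.base_balance(initial),
            "sugar_balance": self.sugar_balance(initial),
            "charge_balance": self.charge_balance(),
        }
        if any(c < 0 for c in self.as_dict().values()):
            raise ConvergenceError("negative concentration in state", residuals)
        if K_w is not None:
            residuals["ion_product"] = self.ion_product() / K_w - 1.0
        bad = {k: v for k, v in residuals.items()
               if abs(v) > (1e-4 if k == "ion_product" else rel_tol)}
        if bad:
            raise ConvergenceError(f"speciation balances violated: {bad}", residuals)


#: Row labels used by the tabular report, matching the field order of
#: :class:`SpeciationState`.
SPECIES_LABELS = {
    "nucleoside": "nucleoside [Nuc]",
    "base": "base [A]",
    "base_anion": "base anion [A-]",
    "sugar": "sugar moiety [R]",
    "sugar_cation": "sugar moiety cation [R+]",
    "hydroxide": "[OH-]",
    "hydronium": "[H3O+]",
    "hydr_nucleoside": "6OHUrd [hydrNuc]",
    "iodide": "iodide anion [I-]",
}


def _charge_balance_hydronium(D: float, K_a: float, K_b: float, K_w: float) -> float:
    """Hydronium concentration for a fixed dissociated amount ``D``.

    Given D = [A]+[A-] = [R]+[R+], electroneutrality
    h + R+(h) - A-(h) - K_w/h = 0 is strictly increasing in h, so a
    bracketed root-find on log10 h is exact and cannot diverge.
    """
    if D <= 0:
        return math.sqrt(K_w)

    def residual(log_h: float) -> float:
        h = 10.0 ** log_h
        a_minus = D / (1.0 + K_b * h / K_w)
        r_plus = D * (h / K_a) / (1.0 + h / K_a)
        return h + r_plus - a_minus - K_w / h

    sqrt_kw = math.sqrt(K_w)
    hi = math.log10(D + 10.0 * sqrt_kw) + 2.0
    lo = math.log10(K_w / (D + 10.0 * sqrt_kw)) - 2.0
    log_h = brentq(residual, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    return 10.0 ** log_h


def _state_for(D: float, C0: float, c: EquilibriumConstants) -> SpeciationState:
    """Closed-form state once the dissociated amount and pH are known."""
    h = _charge_balance_hydronium(D, c.K_a, c.K_b, c.K_w)
    a_minus = D / (1.0 + c.K_b * h / c.K_w)
    r_plus = D * (h / c.K_a) / (1.0 + h / c.K_a)
    return SpeciationState(
        nucleoside=C0 - D,
        base=D - a_minus,
        base_anion=a_minus,
        sugar=D - r_plus,
        sugar_cation=r_plus,
        hydronium=h,
        hydroxide=c.K_w / h,
    )


def solve_equilibrium(
    constants: EquilibriumConstants,
    initial_nucleoside: float,
    ctx: ThermoContext | None = None,
) -> SpeciationState:
    """Solve the coupled equilibrium system for all species.

    Parameters
    ----------
    constants : EquilibriumConstants
        Must carry a calibrated ``K_diss`` (possibly 0 for the
        no-dissociation limit).
    initial_nucleoside : float
        Total nucleoside concentration C0 in mol/dm3.
    ctx : ThermoContext, optional
        Accepted for interface symmetry; the solve is fully determined by
        ``constants``.

    Returns
    -------
    SpeciationState
        The unique physically admissible root; mass balances and the ion
        product hold by construction, charge balance and the dissociation
        equilibrium to the scalar-solver tolerance (~1e-13 relative).
    """
    del ctx  # the equilibrium is fixed by the constants alone
    C0 = initial_nucleoside
    if not (C0 > 0 and math.isfinite(C0)):
        raise ValueError(f"initial_nucleoside must be positive, got {C0!r}")
    if constants.K_diss is None:
        raise ValueError("constants.K_diss is not set; calibrate it first "
                         "(see fit_kdiss) or construct it explicitly")
    K = constants.K_diss
    if K == 0:
        sqrt_kw = math.sqrt(constants.K_w)
        return SpeciationState(C0, 0.0, 0.0, 0.0, 0.0, sqrt_kw, sqrt_kw)

    def log_residual(ln_nuc: float) -> float:
        nuc = math.exp(ln_nuc)
        st = _state_for(C0 - nuc, C0, constants)
        # strictly decreasing in ln_nuc
        return math.log(st.base_anion * st.sugar_cation) - ln_nuc - math.log(K)

    lo = math.log(C0) - 80.0          # Nuc down to ~1e-38 of C0
    hi = math.log(C0) + math.log1p(-1e-13)
    f_lo, f_hi = log_residual(lo), log_residual(hi)
    if f_hi > 0:
        # dissociation so weak that Nuc ~ C0 within 1e-13: treat the
        # remaining extent in closed form (A- ~ R+ ~ sqrt regime).
        st = _state_for(C0 - math.exp(hi), C0, constants)
        return st
    if f_lo < 0:
        raise ConvergenceError(
            "equilibrium root outside bracket: nucleoside residual below "
            "1e-38 of the initial concentration",
            residuals={"f_lo": f_lo, "f_hi": f_hi},
        )
    ln_nuc = brentq(log_residual, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    state = _state_for(C0 - math.exp(ln_nuc), C0, constants)
    state.validate(C0, K_w=constants.K_w)
    return state


def fit_kdiss(
    observed_residual_nucleoside: float,
    constants: EquilibriumConstants,
    initial_nucleoside: float,
) -> float:
    """Dissociation constant reproducing an observed residual nucleoside.

    The observed residual fixes the dissociated amount D = C0 - [Nuc]
    exactly; charge balance then yields the pH and the ion concentrations,
    and K_diss follows from its defining ratio.  The round trip through
    :func:`solve_equilibrium` reproduces the observation to the solver
    tolerance.
    """
    C0 = initial_nucleoside
    obs = observed_residual_nucleoside
    if not (0.0 < obs < C0):
        raise ValueError(
            f"observed residual nucleoside must lie strictly between 0 and the "
            f"initial concentration ({C0!r}), got {obs!r}"
        )
    st = _state_for(C0 - obs, C0, constants)
    return st.base_anion * st.sugar_cation / obs


def decomposed_fraction(state: SpeciationState, initial: float) -> float:
    """Fraction of the substrate decomposed: 1 - [Nuc]/C0, clipped to [0, 1]."""
    if initial <= 0:
        raise ValueError("initial concentration must be positive")
    return min(max(1.0 - state.nucleoside / initial, 0.0), 1.0)


def speciation_table(
    state: SpeciationState,
    initial: float | None = None,
    column: str = "equilibrium",
) -> pd.DataFrame:
    """One-column concentration table with the conventional row labels.

    Rows for the SN2 products are dropped when both are zero (compounds
    without that channel), mirroring the usual presentation.
    """
    rows = {}
    for attr, label in SPECIES_LABELS.items():
        value = getattr(state, attr)
        if attr in ("hydr_nucleoside", "iodide") and state.hydr_nucleoside == 0 \
                and state.iodide == 0:
            continue
        rows[label] = value
    df = pd.DataFrame({column: pd.Series(rows, dtype=float)})
    if initial is not None:
        df.attrs["initial_concentration_M"] = float(initial)
        df.attrs["decomposed_fraction"] = decomposed_fraction(state, initial)
    return df
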