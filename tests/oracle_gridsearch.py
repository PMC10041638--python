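"""Independent brute-force oracle for the equilibrium speciation solve.

Searches reaction-extent space directly.  The three extents are

    xi1  nucleoside dissociation      Nuc -> A- + R+
    xi2  oxocarbenium solvolysis      R+  -> R  + H3O+
    xi3  base-anion protonation       A-  -> A  + OH-

but because the interesting species span many decades, the grid runs over
the equivalent log-space coordinates (log10 [Nuc], log10 [A-], log10 [R+])
with [Nuc] = C0 - xi1, [A-] = xi1 - xi3 and [R+] = xi1 - xi2, so the
residual nucleoside and both trace ions are resolved directly.  For any grid point the
water-autoionization extent w follows in closed form from the ion product
(the quadratic ([H3O+])([OH-]) = (xi2 + w)(xi3 + w) = K_w has exactly one
root keeping both ions positive), so both mass balances, charge balance,
and K_w hold identically everywhere on the grid, and the objective is the
sum of squared log-residuals of the three remaining equilibrium
conditions.  Iterative refinement shrinks the box around the running
minimum.  Nothing here reuses the production solver's structure (no
nested 1-D root-finds, no closed-form speciation given a pH), which is
what makes it an independent check.
"""

from __future__ import annotations

import numpy as np

from nucstab.speciation import EquilibriumConstants, SpeciationState

_FLOOR = 1e-300


def _water_extent(xi2: np.ndarray, xi3: np.ndarray, K_w: float) -> np.ndarray:
    # (xi2 + w)(xi3 + w) = K_w, root with xi2 + w > 0 and xi3 + w > 0
    s = xi2 + xi3
    return 0.5 * (-s + np.sqrt((xi2 - xi3) ** 2 + 4.0 * K_w))


def _objective(u: tuple[np.ndarray, np.ndarray, np.ndarray],
               constants: EquilibriumConstants, C0: float) -> np.ndarray:
    nuc = 10.0 ** u[0]
    a_minus = 10.0 ** u[1]
    r_plus = 10.0 ** u[2]
    xi1 = C0 - nuc
    xi3 = xi1 - a_minus
    xi2 = xi1 - r_plus
    bad = (a_minus > xi1) | (r_plus > xi1) | (nuc > C0)
    xi2c = np.maximum(xi2, _FLOOR)
    xi3c = np.maximum(xi3, _FLOOR)
    w = _water_extent(xi2c, xi3c, constants.K_w)
    h = np.maximum(xi2c + w, _FLOOR)
    oh = np.maximum(xi3c + w, _FLOOR)
    with np.errstate(divide="ignore", over="ignore"):
        r1 = np.log(a_minus * r_plus / (nuc * constants.K_diss))
        r2 = np.log(xi2c * h / (r_plus * constants.K_a))
        r3 = np.log(xi3c * oh / (a_minus * constants.K_b))
        obj = r1 ** 2 + r2 ** 2 + r3 ** 2
    return np.where(bad, np.inf, obj)


def brute_force_equilibrium(
    constants: EquilibriumConstants,
    C0: float,
    n_grid: int = 13,
    n_rounds: int = 80,
) -> SpeciationState:
    """Dense log-space grid search with local refinement."""
    top = np.log10(C0)
    lo = np.array([top - 18.0, top - 18.0, top - 18.0])
    hi = np.array([top, top, top])
    best = None
    for _ in range(n_rounds):
        axes = [np.linspace(lo[d], hi[d], n_grid) for d in range(3)]
        grids = np.meshgrid(*axes, indexing="ij")
        obj = _objective(tuple(grids), constants, C0)
        idx = np.unravel_index(np.argmin(obj), obj.shape)
        best = np.array([g[idx] for g in grids])
        span = (hi - lo) * (2.0 / (n_grid - 1))
        lo = best - span
        hi = np.minimum(best + span, np.array([top, top, top]))
    nuc, a_minus, r_plus = 10.0 ** best
    xi1 = C0 - nuc
    xi2, xi3 = xi1 - r_plus, xi1 - a_minus
    w = float(_water_extent(np.asarray(xi2), np.asarray(xi3), constants.K_w))
    return SpeciationState(
        nucleoside=nuc,
        base=xi3,
        base_anion=a_minus,
        sugar=xi2,
        sugar_cation=r_plus,
        hydronium=xi2 + w,
        hydroxide=xi3 + w,
    )


def random_moderate_constants(rng: np.random.Generator) -> EquilibriumConstants:
    """Random admissible systems spanning several decades per constant."""
    return EquilibriumConstants(
        K_diss=10.0 ** rng.uniform(-12.0, -11.0),
        K_a=10.0 ** rng.uniform(2.0, 3.0),
        K_b=10.0 ** rng.uniform(-7.0, -5.0),
        K_w=1e-14,
    )
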