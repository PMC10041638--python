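"""End-to-end stability report for one compound.

Chains the whole pipeline — thermodynamic-cycle pK values, calibrated
equilibrium constants, equilibrium speciation, kinetic simulation,
half-life and time-to-equilibrium — into one structured report with a
qualitative stability verdict.  Every number in the report is computed by
a module operation from the configuration; the reporting layer itself
contains no constants.
"""

from __future__ import annotations

import json
import math

from .config import CompoundConfig
from .kinetics import half_life, simulate, time_to_equilibrium
from .presets import CompoundModel, build_model
from .speciation import decomposed_fraction, solve_equilibrium
from .thermo import ThermoContext, eyring_rate

__all__ = ["run_stability_report", "report_to_json", "format_report"]

_YEAR_S = 365.25 * 24 * 3600.0


def _auto_t_end(model: CompoundModel, relaxation_multiples: float = 30.0) -> float:
    """Integration horizon: ~30 relaxation times of the slow dissociation."""
    k1 = eyring_rate(model.config.dissociation_dG_act_kcal_per_mol, model.ctx)
    return max(relaxation_multiples / k1, 1e3)


def run_stability_report(
    config: CompoundConfig,
    ctx: ThermoContext | None = None,
    *,
    t_end: float | None = None,
    equilibration_rel_tol: float = 0.05,
) -> dict:
    """Full stability analysis of one compound configuration.

    Returns a JSON-serialisable dict with the pK/K table, the equilibrium
    speciation, kinetic half-life and time-to-equilibrium, and a
    classification by the configured half-life thresholds.
    """
    model = build_model(config, ctx)
    C0 = config.initial_concentration_M
    eq = solve_equilibrium(model.constants, C0)
    horizon = t_end if t_end is not None else _auto_t_end(model)
    traj = simulate(model.network, C0, horizon)
    hl = half_life(traj)
    teq = time_to_equilibrium(traj, eq, rel_tol=equilibration_rel_tol)
    classification = config.classification.classify(hl)

    notes = []
    if config.sn2_channel is not None:
        notes.append(
            "the hydroxide SN2 side channel is modelled kinetically only; "
            "its huge reaction free energy would otherwise predict "
            "quantitative conversion, so the printed equilibrium column "
            "excludes the SN2 products and published long-time speciation "
            "tables for this compound are not mass-consistent with the "
            "equilibrium-only system"
        )

    report = {
        "compound": config.compound,
        "full_name": config.full_name,
        "temperature_K": model.ctx.temperature,
        "initial_concentration_M": C0,
        "pk_table": {
            "pK_b_base_anion": model.pK_base,
            "pK_a_sugar_cation": model.pK_sugar,
            "K_b": model.K_b,
            "K_a": model.K_a,
            "K_diss": model.K_diss,
            "K_w": model.constants.K_w,
        },
        "equilibrium": {
            "concentrations_M": eq.as_dict(),
            "decomposed_fraction": decomposed_fraction(eq, C0),
            "pH": -math.log10(eq.hydronium),
        },
        "kinetics": {
            "t_end_s": horizon,
            "half_life_s": hl,
            "half_life_defined": hl is not None,
            "equilibration_time_s": teq.time_s,
            "equilibration_reached": teq.reached,
            "equilibration_rel_tol": equilibration_rel_tol,
            "equilibration_time_years":
                None if teq.time_s is None else teq.time_s / _YEAR_S,
            "terminal_concentrations_M": traj.terminal_state().as_dict(),
        },
        "classification": classification,
        "notes": notes,
    }
    return report


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _fmt_seconds(seconds: float | None) -> str:
    if seconds is None:
        return "not defined"
    if seconds < 120:
        return f"{seconds:.3g} s"
    if seconds < 2 * 3600:
        return f"{seconds / 60:.3g} min"
    if seconds < 3 * 86400:
        return f"{seconds / 3600:.3g} h"
    if seconds < 3 * _YEAR_S:
        return f"{seconds / 86400:.3g} d"
    return f"{seconds / _YEAR_S:.3g} years"


def format_report(report: dict) -> str:
    """Human-readable rendering of :func:`run_stability_report` output."""
    pk = report["pk_table"]
    eq = report["equilibrium"]
    kin = report["kinetics"]
    lines = [
        f"Stability report: {report['compound']} ({report['full_name']})",
        f"  T = {report['temperature_K']:.2f} K, "
        f"C0 = {report['initial_concentration_M']:.2e} M",
        "",
        "  acid/base constants (thermodynamic cycle):",
        f"    pK_b(base anion)   = {pk['pK_b_base_anion']:8.3f}"
        f"   (K_b = {pk['K_b']:.2e})",
        f"    pK_a(sugar cation) = {pk['pK_a_sugar_cation']:8.3f}"
        f"   (K_a = {pk['K_a']:.2e})",
        f"    K_diss (calibrated) = {pk['K_diss']:.2e}",
        "",
        "  equilibrium speciation:",
    ]
    for name, value in eq["concentrations_M"].items():
        if value > 0:
            lines.append(f"    {name:16s} = {value:.2e} M")
    lines += [
        f"    decomposed fraction = {eq['decomposed_fraction'] * 100:.1f}%"
        f"   (pH {eq['pH']:.2f})",
        "",
        "  kinetics:",
        f"    half-life          = {_fmt_seconds(kin['half_life_s'])}",
        f"    time to equilibrium ({kin['equilibration_rel_tol']:.0%}) = "
        f"{_fmt_seconds(kin['equilibration_time_s'])}",
        "",
        f"  classification: {report['classification'].upper()}",
    ]
    for note in report["notes"]:
        lines.append(f"  note: {note}")
    return "\n".join(lines) + "\n"
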