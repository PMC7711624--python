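"""Steady-state pharmacokinetic bridging between a mucosal film and oral
prolonged-release (PR) dosing.

One-compartment steady-state algebra: from a dose-normalized steady-state
plasma concentration [Cp]ss, an elimination half-life and a volume of
distribution, compute

    Ke  = 0.693 / t_half                    (elimination rate constant, 1/h)
    Cp_ss = cp_ss_per_mg * dose             (ng/mL)
    D_E = Cp_ss * Ke                        (drug elimination rate, ng/(mL h))
    D_A = D_E * V_D                         (drug absorption rate, mg/h)

and compare D_A with the film's mucosal input rate Js (and Js * area).  The
0.693 constant (rather than exact ln 2) is the conventional rounding used in
the source PK literature; an exact-ln2 mode is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .permeation import FluxEstimate

__all__ = [
    "PKParams",
    "EquivalenceReport",
    "ke_from_half_life",
    "css_for_dose",
    "elimination_rate",
    "absorption_rate",
    "equivalence_report",
    "area_for_target_rate",
]

LN2_CONVENTION = 0.693


def ke_from_half_life(t_half: float, exact_ln2: bool = False) -> float:
    """Elimination rate constant (1/h) from the half-life (h)."""
    if t_half <= 0:
        raise ValueError("t_half must be > 0")
    return (math.log(2.0) if exact_ln2 else LN2_CONVENTION) / t_half


@dataclass(frozen=True)
class PKParams:
    """Constants of the steady-state bridge.

    Defaults are the literature values for ropinirole: [Cp]ss of 1 ng/mL per
    mg of daily PR dose, 6-h half-life, 7.5 L/kg distribution volume, 70-kg
    reference adult.
    """

    cp_ss_per_mg: float = 1.0   # ng/mL per mg dose
    t_half: float = 6.0         # h
    v_d_per_kg: float = 7.5     # L/kg
    body_mass: float = 70.0     # kg
    exact_ln2: bool = False

    def __post_init__(self) -> None:
        if min(self.cp_ss_per_mg, self.t_half, self.v_d_per_kg,
               self.body_mass) <= 0:
            raise ValueError("all PK constants must be > 0")

    @property
    def ke(self) -> float:
        return ke_from_half_life(self.t_half, self.exact_ln2)

    @property
    def v_d(self) -> float:
        return self.v_d_per_kg * self.body_mass


def css_for_dose(pk: PKParams, dose: float) -> float:
    """Steady-state plasma concentration (ng/mL) for an oral PR dose (mg)."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    return pk.cp_ss_per_mg * dose


def elimination_rate(cp_ss: float, ke: float) -> float:
    """Drug elimination rate D_E = Cp_ss * Ke, in ng/(mL h)."""
    if cp_ss < 0 or ke < 0:
        raise ValueError("cp_ss and ke must be >= 0")
    return cp_ss * ke


def absorption_rate(d_e: float, v_d: float) -> float:
    """Drug absorption rate D_A = D_E * V_D, converted to mg/h.

    ng/mL * L = ug, hence the /1000 to mg.  The value is returned unrounded;
    round only for display."""
    if d_e < 0 or v_d < 0:
        raise ValueError("d_e and v_d must be >= 0")
    return d_e * v_d / 1000.0


def area_for_target_rate(target_da: float, js: float) -> float:
    """Film area (cm^2) whose input rate Js * area meets a target absorption
    rate (mg/h): the dose-modulation knob of the film format."""
    if js <= 0:
        raise ValueError("Js must be > 0")
    if target_da < 0:
        raise ValueError("target rate must be >= 0")
    return target_da / js


@dataclass
class EquivalenceReport:
    """Film-vs-oral steady-state comparison.

    ``per_cm2_ratio`` compares Js (mg cm^-2 h^-1) directly against D_A (mg/h)
    -- the per-cm^2 basis presentation -- while ``input_rate_ratio`` compares
    the dimensionally homogeneous film input rate Js * area against D_A."""

    dose: float
    cp_ss: float
    ke: float
    v_d: float
    d_e: float
    d_a: float
    Js: float
    film_area: float
    area_multiplier: float
    film_input_rate: float
    per_cm2_ratio: float
    input_rate_ratio: float
    lag_h: float | None = None
    area_matching_da: float | None = None

    def render_text(self) -> str:
        def row(label: str, value: str) -> str:
            return f"  {label:<24s}  {value}"

        lines = [
            "Steady-state equivalence (film vs oral PR)",
            row("oral PR dose", f"{self.dose:.3f} mg"),
            row("Cp_ss", f"{self.cp_ss:.3f} ng/mL"),
            row("Ke", f"{self.ke:.4f} 1/h"),
            row("V_D", f"{self.v_d:.1f} L"),
            row("D_E", f"{self.d_e:.3f} ng/(mL h)"),
            row("D_A", f"{self.d_a:.3f} mg/h"),
            row("Js", f"{self.Js:.3f} mg/(cm^2 h)"),
            row(f"film area (x{self.area_multiplier:g})",
                f"{self.film_area:.3f} cm^2"),
            row("film input rate Js*A", f"{self.film_input_rate:.3f} mg/h"),
            row("Js vs D_A (per-cm^2)", f"{self.per_cm2_ratio:.3f}"),
            row("Js*A vs D_A", f"{self.input_rate_ratio:.3f}"),
        ]
        if self.lag_h is not None:
            lines.insert(8, row("lag time", f"{self.lag_h:.2f} h"))
        if self.area_matching_da is not None:
            lines.append(row("area matching D_A",
                             f"{self.area_matching_da:.3f} cm^2"))
        return "\n".join(lines)


def equivalence_report(pk: PKParams, oral_dose: float,
                       flux: "FluxEstimate | float", film_area: float,
                       area_multiplier: float = 1.0) -> EquivalenceReport:
    """Assemble the full steady-state comparison for one oral reference dose.

    ``area_multiplier`` scales the effective absorbing area (e.g. 2 if both
    film faces contact mucosa); default 1.
    """
    if film_area <= 0 or area_multiplier <= 0:
        raise ValueError("film_area and area_multiplier must be > 0")
    js = flux.Js if isinstance(flux, FluxEstimate) else float(flux)
    lag = flux.lag_h if isinstance(flux, FluxEstimate) else None
    if js < 0:
        raise ValueError("Js must be >= 0")
    cp_ss = css_for_dose(pk, oral_dose)
    d_e = elimination_rate(cp_ss, pk.ke)
    d_a = absorption_rate(d_e, pk.v_d)
    area_eff = film_area * area_multiplier
    input_rate = js * area_eff
    return EquivalenceReport(
        dose=oral_dose, cp_ss=cp_ss, ke=pk.ke, v_d=pk.v_d, d_e=d_e, d_a=d_a,
        Js=js, film_area=film_area, area_multiplier=area_multiplier,
        film_input_rate=input_rate,
        per_cm2_ratio=js / d_a if d_a > 0 else 0.0,
        input_rate_ratio=input_rate / d_a if d_a > 0 else 0.0,
        lag_h=lag,
        area_matching_da=area_for_target_rate(d_a, js) if js > 0 else None,
    )
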