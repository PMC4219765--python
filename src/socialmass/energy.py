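"""Dynamic caloric intake and total-energy-expenditure decomposition.

Intake follows a power law in relative body mass,

    I(t) = I(t0) * (m(t) / m(t0)) ** gamma,

where the per-individual responsiveness ``gamma`` in [0, 1] sets how
strongly intake tracks mass: gamma = 0 decouples intake from mass, larger
gamma slows the approach to energy balance.  Total expenditure is the
FAO-style decomposition

    E(t) = B(sex, age, m) + beta * I(t) + delta * m(t)

with B the basal (resting) expenditure, linear in mass within sex- and
age-bracket-specific coefficients (FAO/WHO/UNU Schofield adult weight
equations), thermogenesis a fixed fraction ``beta`` of intake, and
activity costed at ``delta`` kcal per kg per day.  ``delta`` is not a free
parameter: it is calibrated once from the individual's printed initial
conditions so that E(t0) reproduces the given E0 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "DEFAULT_BETA_THERMO",
    "DEFAULT_GAMMA_RANGE",
    "BMRBracket",
    "DEFAULT_BMR_TABLE",
    "IntakeParams",
    "ExpenditureParams",
    "intake_update",
    "basal_expenditure",
    "thermogenesis",
    "calibrate_activity",
    "total_expenditure",
]

#: Diet-induced thermogenesis as a fraction of intake.
DEFAULT_BETA_THERMO = 0.10
#: Interval the per-individual gamma is drawn from; its mean (0.3) is the
#: value used in every social-interaction scenario.
DEFAULT_GAMMA_RANGE = (0.1, 0.5)


@dataclass(frozen=True)
class BMRBracket:
    """One row of the basal-metabolic-rate table: BMR = slope*W + intercept."""

    sex: str
    age_min: float
    age_max: float
    slope: float  # kcal per kg per day
    intercept: float  # kcal per day


#: FAO/WHO/UNU (Schofield) adult weight-based equations, kcal/day.
DEFAULT_BMR_TABLE: tuple[BMRBracket, ...] = (
    BMRBracket("male", 18.0, 30.0, 15.057, 692.2),
    BMRBracket("male", 30.0, 60.0, 11.472, 873.1),
    BMRBracket("male", 60.0, float("inf"), 11.711, 587.7),
    BMRBracket("female", 18.0, 30.0, 14.818, 486.6),
    BMRBracket("female", 30.0, 60.0, 8.126, 845.6),
    BMRBracket("female", 60.0, float("inf"), 9.082, 658.5),
)


@dataclass(frozen=True)
class IntakeParams:
    """Parameters of the dynamic-intake law."""

    gamma: float
    intake0_kcal: float
    mass0_kg: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")
        if self.intake0_kcal < 0.0:
            raise ValueError(f"initial intake must be >= 0, got {self.intake0_kcal}")
        if self.mass0_kg <= 0.0:
            raise ValueError(f"initial mass must be > 0, got {self.mass0_kg}")


@dataclass(frozen=True)
class ExpenditureParams:
    """Coefficients of the expenditure decomposition.

    ``activity_mode`` selects how the activity term scales once the
    per-kg cost delta has been calibrated at t0: ``"per_kg"`` (default)
    uses A(t) = delta*m(t); ``"constant"`` freezes A at its t0 value
    delta*m0.
    """

    beta_thermo: float = DEFAULT_BETA_THERMO
    bmr_table: tuple[BMRBracket, ...] = DEFAULT_BMR_TABLE
    activity_mode: str = "per_kg"

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta_thermo < 0.3:
            raise ValueError(f"beta_thermo must lie in [0, 0.3), got {self.beta_thermo}")
        if self.activity_mode not in ("per_kg", "constant"):
            raise ValueError(f"activity_mode must be 'per_kg' or 'constant', got {self.activity_mode!r}")


def intake_update(params: IntakeParams, mass_kg: float) -> float:
    """Daily intake at the current mass: I0 * (m/m0)**gamma (kcal/day)."""
    if mass_kg <= 0.0:
        raise ValueError(f"mass must be positive, got {mass_kg}")
    return params.intake0_kcal * (mass_kg / params.mass0_kg) ** params.gamma


def _find_bracket(sex: str, age_years: float, table: tuple[BMRBracket, ...]) -> BMRBracket:
    for row in table:
        if row.sex == sex and row.age_min <= age_years < row.age_max:
            return row
    supported = ", ".join(
        f"{r.sex} [{r.age_min:g}, {r.age_max:g})" for r in table
    )
    raise ValueError(
        f"no basal-expenditure bracket for sex={sex!r}, age={age_years}; "
        f"supported brackets: {supported}"
    )


def basal_expenditure(
    sex: str,
    age_years: float,
    mass_kg: float,
    coeffs: ExpenditureParams | None = None,
) -> float:
    """Basal metabolic rate from the sex/age bracket table (kcal/day)."""
    coeffs = coeffs or ExpenditureParams()
    row = _find_bracket(sex, age_years, coeffs.bmr_table)
    return row.slope * mass_kg + row.intercept


def thermogenesis(intake_kcal: float, beta: float = DEFAULT_BETA_THERMO) -> float:
    """Diet-induced thermogenesis: beta * intake (kcal/day)."""
    if intake_kcal < 0.0:
        raise ValueError(f"intake must be >= 0, got {intake_kcal}")
    return beta * intake_kcal


def calibrate_activity(
    sex: str,
    age_years: float,
    mass0_kg: float,
    intake0_kcal: float,
    expend0_kcal: float,
    coeffs: ExpenditureParams | None = None,
) -> float:
    """Per-kg activity cost delta implied by the initial conditions.

    delta = (E0 - B0 - beta*I0) / m0, so that ``total_expenditure``
    evaluated at t0 returns E0 exactly.

    Raises
    ------
    ValueError
        If the initial conditions imply a negative activity cost
        (E0 < B0 + beta*I0), i.e. they are physically inconsistent.
    """
    coeffs = coeffs or ExpenditureParams()
    b0 = basal_expenditure(sex, age_years, mass0_kg, coeffs)
    resid = expend0_kcal - b0 - thermogenesis(intake0_kcal, coeffs.beta_thermo)
    if resid < 0.0:
        raise ValueError(
            "initial conditions imply negative activity expenditure: "
            f"E0={expend0_kcal} < B0 + beta*I0 = {b0 + coeffs.beta_thermo * intake0_kcal:.2f}"
        )
    return resid / mass0_kg


def total_expenditure(
    sex: str,
    age_years: float,
    mass_kg: float,
    intake_kcal: float,
    activity_per_kg: float,
    coeffs: ExpenditureParams | None = None,
    mass0_kg: float | None = None,
) -> float:
    """Total daily expenditure E = B + beta*I + A (kcal/day).

    With ``activity_mode == "constant"`` the activity term is frozen at
    its t0 value ``activity_per_kg * mass0_kg`` (``mass0_kg`` required).
    """
    coeffs = coeffs or ExpenditureParams()
    b = basal_expenditure(sex, age_years, mass_kg, coeffs)
    t = thermogenesis(intake_kcal, coeffs.beta_thermo)
    if coeffs.activity_mode == "constant":
        if mass0_kg is None:
            raise ValueError("activity_mode='constant' requires mass0_kg")
        a = activity_per_kg * mass0_kg
    else:
        a = activity_per_kg * mass_kg
    return b + t + a
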