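"""Two-compartment (fat / lean) energy partitioning.

The daily energy imbalance ``I - E`` (kcal/day) is split between a fat
compartment with energy density ``rho_F`` and a lean compartment with
energy density ``rho_L``.  A partition fraction ``p`` routes the fraction
``p`` of the imbalance energy into lean tissue and ``1 - p`` into fat::

    dL = p       * (I - E) * dt / rho_L
    dF = (1 - p) * (I - E) * dt / rho_F

so that the energy budget ``rho_F * dF + rho_L * dL = (I - E) * dt`` closes
identically (first law).  Two partition rules are provided:

* **Forbes** — ``p = C / (C + F)``: the partition responds to the current
  fat store.  As fat is depleted ``p`` rises toward 1 and the remaining
  loss is taken from lean tissue, so fat mass can never cross zero.
* **Hall** — ``p`` derived from the previously *realized* lean-to-total
  mass-change ratio ``dL/dM``.  This rule has no feedback from the fat
  level: the split it reproduces is whatever seeded it, and under a
  sustained deficit larger than the fat store it drives fat mass negative.
  The simulator records that pathology instead of hiding it.

Masses in kg, energies in kcal, time in days throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "DEFAULT_RHO_F",
    "DEFAULT_RHO_L",
    "FORBES_LEAN_FAT_KG",
    "EnergyDensities",
    "BodyState",
    "PartitionModel",
    "forbes_p",
    "hall_p",
    "lean_energy_share",
    "lean_mass_share",
    "partition_step",
]

#: Energy density of body fat, kcal per kg (Chow--Hall convention).
DEFAULT_RHO_F = 9400.0
#: Energy density of lean tissue, kcal per kg.
DEFAULT_RHO_L = 1800.0
#: Forbes lean--fat companionship constant, kg (dL/dF = 10.4 / F).
FORBES_LEAN_FAT_KG = 10.4


@dataclass(frozen=True)
class EnergyDensities:
    """Energy densities of the two tissue compartments (kcal/kg)."""

    rho_F: float = DEFAULT_RHO_F
    rho_L: float = DEFAULT_RHO_L

    def __post_init__(self) -> None:
        if not (self.rho_F > self.rho_L > 0.0):
            raise ValueError(
                f"require rho_F > rho_L > 0, got rho_F={self.rho_F}, rho_L={self.rho_L}"
            )


@dataclass(frozen=True)
class BodyState:
    """Fat and lean mass of one individual at one time point (kg).

    Total mass is derived, never stored.  Lean mass must stay positive;
    fat mass may be negative only under the Hall partition rule, where a
    negative value is itself a model result that is recorded downstream.
    """

    fat_kg: float
    lean_kg: float

    @property
    def mass_kg(self) -> float:
        return self.fat_kg + self.lean_kg

    def bmi(self, height_m: float) -> float:
        """Body-mass index, kg/m^2."""
        return self.mass_kg / height_m**2


@dataclass(frozen=True)
class PartitionModel:
    """Partition rule and its constants.

    ``forbes_C_kg`` is the Forbes constant expressed on the energy-share
    scale: ``C = 10.4 * rho_L / rho_F`` kg, so that ``p = C/(C+F)`` is the
    lean share of the *energy* imbalance and the implied mass split
    matches Forbes' companionship curve ``dL/dM = 10.4/(10.4 + F)``.
    """

    densities: EnergyDensities = field(default_factory=EnergyDensities)
    forbes_C_kg: float | None = None
    p_kind: str = "forbes"

    def __post_init__(self) -> None:
        if self.forbes_C_kg is None:
            object.__setattr__(
                self,
                "forbes_C_kg",
                FORBES_LEAN_FAT_KG * self.densities.rho_L / self.densities.rho_F,
            )
        if self.forbes_C_kg <= 0.0:
            raise ValueError(f"forbes_C_kg must be positive, got {self.forbes_C_kg}")
        if self.p_kind not in ("forbes", "hall"):
            raise ValueError(f"p_kind must be 'forbes' or 'hall', got {self.p_kind!r}")


def forbes_p(fat_kg: float, model: PartitionModel) -> float:
    """Forbes partition fraction ``p = C / (C + F)``.

    Strictly decreasing in fat mass; tends to 0 as ``F`` grows and to 1 as
    the fat store empties.

    Raises
    ------
    ValueError
        If ``fat_kg`` is not strictly positive.
    """
    if not fat_kg > 0.0:
        raise ValueError(f"Forbes p requires fat mass > 0 kg, got {fat_kg}")
    C = model.forbes_C_kg
    return C / (C + fat_kg)


def hall_p(
    delta_L: float,
    delta_M: float,
    fallback_p: float,
    tol: float = 1e-9,
) -> float:
    """Hall partition fraction: the realized ratio ``dL / dM``.

    ``delta_L`` and ``delta_M`` are the lean and total mass increments of
    the *previous* step.  When ``|delta_M|`` is below ``tol`` (first step,
    or a step at exact balance) the recursion is seeded with
    ``fallback_p`` instead.  The ratio is deliberately not clamped to
    [0, 1]: out-of-range values are part of what this rule can produce.
    """
    if abs(delta_M) < tol:
        return fallback_p
    return delta_L / delta_M


def lean_energy_share(q_mass: float, densities: EnergyDensities) -> float:
    """Energy share p implied by a lean *mass*-change fraction ``q``.

    Inverse of :func:`lean_mass_share`: a step taken with energy share
    ``p = q*rho_L / (q*rho_L + (1-q)*rho_F)`` realizes exactly the mass
    split ``dL/dM = q``.
    """
    num = q_mass * densities.rho_L
    den = num + (1.0 - q_mass) * densities.rho_F
    return num / den


def lean_mass_share(p_energy: float, densities: EnergyDensities) -> float:
    """Lean fraction of the mass change realized by energy share ``p``."""
    num = p_energy * densities.rho_F
    den = num + (1.0 - p_energy) * densities.rho_L
    return num / den


def partition_step(
    state: BodyState,
    imbalance_kcal: float,
    p: float,
    model: PartitionModel,
    dt_days: float = 1.0,
) -> BodyState:
    """Advance the body state by one Euler step of length ``dt_days``.

    ``imbalance_kcal`` is the effective daily energy imbalance I - E
    (kcal/day), already including any social perturbation.  Conservation
    ``rho_F*dF + rho_L*dL = imbalance*dt`` holds to machine precision by
    construction.

    Raises
    ------
    ValueError
        If the imbalance is NaN or infinite.
    """
    if not math.isfinite(imbalance_kcal):
        raise ValueError(f"energy imbalance must be finite, got {imbalance_kcal}")
    d = model.densities
    e = imbalance_kcal * dt_days
    dL = p * e / d.rho_L
    dF = (1.0 - p) * e / d.rho_F
    return BodyState(fat_kg=state.fat_kg + dF, lean_kg=state.lean_kg + dL)
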