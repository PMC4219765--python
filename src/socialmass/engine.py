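"""Day-stepping simulation engine, scenario suite and trajectory I/O.

``simulate`` advances one individual with a one-day explicit Euler step:
each day it draws the social term (if enabled), updates intake from the
current mass, recomputes expenditure, forms the effective imbalance and
partitions it into the fat and lean compartments.  The per-day record of
masses, energies and the social term is a :class:`Trajectory`.

``run_scenario_suite`` packages the parameter sweeps used in the study
(Forbes-vs-Hall comparison, gamma sweeps, the three social cases) as
named presets fig1..fig12 and returns trajectories plus a summary table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from . import __version__ as _version
from .energy import (
    ExpenditureParams,
    IntakeParams,
    calibrate_activity,
    intake_update,
    total_expenditure,
)
from .partition import (
    BodyState,
    PartitionModel,
    forbes_p,
    hall_p,
    lean_energy_share,
    lean_mass_share,
    partition_step,
)
from .population import IndividualProfile, profile_from_caption
from .social import SocialParams, perturbed_balance, social_term

__all__ = [
    "RunConfig",
    "Trajectory",
    "simulate",
    "run_scenario_suite",
    "scenario_names",
    "time_to_stability",
    "final_energy_gap",
    "tail_increment_variance",
    "estimate_gamma",
    "DEFAULT_GAMMA_GRID",
]

#: gamma sweep grid: 0.10 to 0.50 in steps of 0.05.
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(round(0.10 + 0.05 * k, 2) for k in range(9))

_HALL_DM_TOL = 1e-9  # kg; below this the partition ratio is re-seeded


@dataclass(frozen=True)
class RunConfig:
    """Everything one simulation run needs."""

    profile: IndividualProfile
    horizon_days: int = 1500
    partition: PartitionModel = field(default_factory=PartitionModel)
    expenditure: ExpenditureParams = field(default_factory=ExpenditureParams)
    social: SocialParams = field(default_factory=SocialParams)
    seed: int | None = None
    dt_days: float = 1.0

    def __post_init__(self) -> None:
        if self.horizon_days < 1:
            raise ValueError(f"horizon_days must be >= 1, got {self.horizon_days}")
        if not 0.0 < self.dt_days <= 1.0:
            raise ValueError(f"dt_days must lie in (0, 1], got {self.dt_days}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        """Build a config from a plain (YAML-friendly) dictionary."""
        d = dict(d)
        prof = d.pop("profile")
        if isinstance(prof, str):
            profile = profile_from_caption(prof)
        else:
            profile = IndividualProfile(**prof)
        if "gamma" in d:  # convenience override
            profile = replace(profile, gamma=float(d.pop("gamma")))
        kw: dict = {"profile": profile}
        if "p_kind" in d:
            kw["partition"] = PartitionModel(p_kind=d.pop("p_kind"))
        if "social" in d:
            kw["social"] = SocialParams(**d.pop("social"))
        for key in ("horizon_days", "seed", "dt_days"):
            if key in d:
                kw[key] = d.pop(key)
        if d:
            raise ValueError(f"unknown run-config keys: {sorted(d)}")
        return cls(**kw)


_TRAJ_COLUMNS = [
    "day", "fat_kg", "lean_kg", "mass_kg", "intake_kcal", "expend_kcal",
    "social_kcal", "flags",
]


@dataclass
class Trajectory:
    """Per-day record of one simulation run."""

    data: pd.DataFrame
    profile: IndividualProfile
    p_kind: str
    seed: int | None = None
    clamped: bool = False
    negative_fat: bool = False

    @property
    def final_mass_kg(self) -> float:
        return float(self.data["mass_kg"].iloc[-1])

    @property
    def mass_kg(self) -> np.ndarray:
        return self.data["mass_kg"].to_numpy()

    def to_csv(self, path, metadata_path=None) -> None:
        """Write the per-day table; optionally a JSON metadata sidecar."""
        self.data.to_csv(path, index=False, float_format="%.10g")
        if metadata_path is not None:
            meta = {
                "version": _version,
                "profile": asdict(self.profile),
                "p_kind": self.p_kind,
                "seed": self.seed,
                "clamped": self.clamped,
                "negative_fat": self.negative_fat,
            }
            with open(metadata_path, "w") as fh:
                json.dump(meta, fh, indent=1)


def simulate(config: RunConfig) -> Trajectory:
    """Run one individual forward; deterministic given the seed.

    Daily order of operations: social draw -> intake from current mass ->
    expenditure -> effective imbalance -> partition fraction (Forbes from
    the fat level, Hall from the previous realized mass split) -> Euler
    step.  Under Forbes the compartments are clamped at zero and the run
    stops with ``clamped`` set; under Hall negative fat is recorded via
    ``negative_fat`` and the run continues.
    """
    prof = config.profile
    model = config.partition
    dens = model.densities
    rng = np.random.default_rng(config.seed)

    delta = calibrate_activity(
        prof.sex, prof.age_years, prof.mass0_kg, prof.intake0_kcal,
        prof.expend0_kcal, config.expenditure,
    )
    intake_params = IntakeParams(prof.gamma, prof.intake0_kcal, prof.mass0_kg)

    n_steps = int(round(config.horizon_days / config.dt_days))
    state = BodyState(fat_kg=prof.fat0_kg, lean_kg=prof.lean0_kg)

    day = np.empty(n_steps + 1)
    fat = np.empty(n_steps + 1)
    lean = np.empty(n_steps + 1)
    intake = np.empty(n_steps + 1)
    expend = np.empty(n_steps + 1)
    soc = np.empty(n_steps + 1)
    flags: list[str] = [""]

    day[0], fat[0], lean[0] = 0.0, state.fat_kg, state.lean_kg
    intake[0], expend[0], soc[0] = prof.intake0_kcal, prof.expend0_kcal, 0.0

    prev_dL = 0.0
    prev_dM = 0.0
    prev_q = lean_mass_share(forbes_p(max(state.fat_kg, 1e-12), model), dens)
    clamped = False
    negative_fat = False
    n_recorded = 0

    for k in range(1, n_steps + 1):
        try:
            s = social_term(config.social, rng)
            i_t = intake_update(intake_params, state.mass_kg)
            e_t = total_expenditure(
                prof.sex, prof.age_years, state.mass_kg, i_t, delta,
                config.expenditure, mass0_kg=prof.mass0_kg,
            )
        except ValueError as err:
            raise ValueError(f"day {k}: {err}") from err
        imbalance = perturbed_balance(i_t, e_t, s)

        if model.p_kind == "forbes":
            p = forbes_p(state.fat_kg, model)
        else:
            if state.fat_kg > 0.0:
                fallback_q = lean_mass_share(forbes_p(state.fat_kg, model), dens)
            else:
                fallback_q = prev_q  # fat store exhausted: keep last split
            q = hall_p(prev_dL, prev_dM, fallback_q, tol=_HALL_DM_TOL)
            prev_q = q
            p = lean_energy_share(q, dens)

        new = partition_step(state, imbalance, p, model, config.dt_days)

        flag = ""
        if model.p_kind == "forbes" and (new.fat_kg < 0.0 or new.lean_kg <= 0.0):
            new = BodyState(fat_kg=max(new.fat_kg, 0.0), lean_kg=max(new.lean_kg, 0.0))
            clamped = True
            flag = "clamped"
        elif new.fat_kg < 0.0:
            negative_fat = True
            flag = "negative_fat"

        prev_dL = new.lean_kg - state.lean_kg
        prev_dM = new.mass_kg - state.mass_kg
        state = new

        day[k], fat[k], lean[k] = k * config.dt_days, state.fat_kg, state.lean_kg
        intake[k], expend[k], soc[k] = i_t, e_t, s
        flags.append(flag)
        n_recorded = k
        if clamped:
            break

    end = n_recorded + 1
    df = pd.DataFrame(
        {
            "day": day[:end],
            "fat_kg": fat[:end],
            "lean_kg": lean[:end],
            "mass_kg": fat[:end] + lean[:end],
            "intake_kcal": intake[:end],
            "expend_kcal": expend[:end],
            "social_kcal": soc[:end],
            "flags": flags[:end],
        },
        columns=_TRAJ_COLUMNS,
    )
    return Trajectory(
        data=df, profile=prof, p_kind=model.p_kind, seed=config.seed,
        clamped=clamped, negative_fat=negative_fat,
    )


# ---------------------------------------------------------------------------
# Summary statistics


def final_energy_gap(traj: Trajectory) -> float:
    """Intake minus expenditure on the last simulated day, kcal/day."""
    row = traj.data.iloc[-1]
    return float(row["intake_kcal"] - row["expend_kcal"])


def time_to_stability(
    traj: Trajectory, target_mass_kg: float | None = None, tol_kg: float = 0.1
) -> float:
    """First day whose mass is within ``tol_kg`` of the stable mass.

    The stable mass defaults to the run's final mass.  Returns inf if the
    trajectory never enters the band.
    """
    target = traj.final_mass_kg if target_mass_kg is None else target_mass_kg
    within = np.abs(traj.mass_kg - target) < tol_kg
    idx = np.argmax(within)
    if not within[idx]:
        return float("inf")
    return float(traj.data["day"].iloc[int(idx)])


def tail_increment_variance(traj: Trajectory, tail_fraction: float = 0.2) -> float:
    """Sample variance of day-over-day mass increments in the final tail."""
    inc = np.diff(traj.mass_kg)
    k = max(2, int(round(len(inc) * tail_fraction)))
    return float(np.var(inc[-k:], ddof=1))


def estimate_gamma(
    observed_mass: np.ndarray,
    config: RunConfig,
    grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
) -> float:
    """Recover gamma from a mass trajectory by least squares over a grid.

    Re-simulates ``config`` (social noise off) with each candidate gamma
    and returns the grid value minimizing the sum of squared deviations
    from ``observed_mass``.
    """
    observed = np.asarray(observed_mass, dtype=float)
    base = replace(config, social=SocialParams(case="off"))
    best_gamma, best_sse = None, np.inf
    for g in grid:
        cand = replace(base, profile=replace(base.profile, gamma=g))
        m = simulate(cand).mass_kg
        k = min(len(m), len(observed))
        sse = float(np.sum((m[:k] - observed[:k]) ** 2))
        if sse < best_sse:
            best_gamma, best_sse = g, sse
    return float(best_gamma)


# ---------------------------------------------------------------------------
# Scenario suite

_EPS_SWEEP = (20.0, 50.0, 100.0, 150.0)
_ALPHA_SWEEP = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def _social(case, **kw):
    return SocialParams(case=case, **kw)


def _suite_runs(name: str, seed: int | None) -> list[tuple[str, RunConfig]]:
    """Expand a scenario preset into named run configs."""
    long = 5000   # horizons long enough for the slow-gamma runs to settle
    mid = 1500
    if name in ("fig1", "fig2"):
        prof = profile_from_caption(name)
        return [
            (f"{name}_{kind}", RunConfig(profile=prof, horizon_days=mid,
                                         partition=PartitionModel(p_kind=kind)))
            for kind in ("forbes", "hall")
        ]
    if name in ("fig3", "fig4"):
        prof = profile_from_caption(name)
        return [
            (f"{name}_gamma{g:.2f}",
             RunConfig(profile=replace(prof, gamma=g), horizon_days=long))
            for g in DEFAULT_GAMMA_GRID
        ]
    if name in ("fig5", "fig7"):  # case i: fixed proximity, epsilon sweep
        prof = profile_from_caption("fig3" if name == "fig5" else "fig4")
        sign = "positive" if name == "fig5" else "negative"
        return [
            (f"{name}_eps{int(eps)}",
             RunConfig(profile=prof, horizon_days=long,
                       social=_social("fixed_proximity", alpha_s=0.5,
                                      epsilon_kcal=eps, sign_policy=sign)))
            for eps in _EPS_SWEEP
        ]
    if name in ("fig6", "fig8"):  # case ii: fixed influence, alpha sweep
        prof = profile_from_caption("fig3" if name == "fig6" else "fig4")
        sign = "positive" if name == "fig6" else "negative"
        return [
            (f"{name}_alpha{a:.1f}",
             RunConfig(profile=prof, horizon_days=long,
                       social=_social("fixed_influence", alpha_s=a,
                                      epsilon_kcal=50.0, sign_policy=sign)))
            for a in _ALPHA_SWEEP
        ]
    if name in ("fig9", "fig10"):  # case iii: fully random noise
        prof = profile_from_caption("fig3" if name == "fig9" else "fig4")
        return [
            (f"{name}_random",
             RunConfig(profile=prof, horizon_days=mid, seed=seed,
                       social=_social("random", sign_policy="random")))
        ]
    if name in ("fig11", "fig12"):  # matched-seed pair: noise on vs off
        prof = profile_from_caption("fig3" if name == "fig11" else "fig4")
        return [
            (f"{name}_nonoise", RunConfig(profile=prof, horizon_days=mid, seed=seed)),
            (f"{name}_noise",
             RunConfig(profile=prof, horizon_days=mid, seed=seed,
                       social=_social("random", sign_policy="random"))),
        ]
    raise ValueError(f"unknown scenario {name!r}; available: {scenario_names()}")


def scenario_names() -> list[str]:
    return [f"fig{i}" for i in range(1, 13)]


def run_scenario_suite(name: str, outdir=None, seed: int | None = 0):
    """Execute one scenario preset.

    Returns ``(trajectories, summary)``: a dict of run-id -> Trajectory
    and a summary DataFrame (final mass, time to stability, tail increment
    variance, flags).  If ``outdir`` is given, per-run trajectory CSVs and
    ``summary.csv`` are written there.
    """
    runs = _suite_runs(name, seed)
    trajectories: dict[str, Trajectory] = {}
    rows = []
    for run_id, cfg in runs:
        traj = simulate(cfg)
        trajectories[run_id] = traj
        rows.append(
            {
                "run_id": run_id,
                "p_kind": traj.p_kind,
                "gamma": cfg.profile.gamma,
                "social_case": cfg.social.case,
                "alpha_s": cfg.social.alpha_s,
                "epsilon_kcal": cfg.social.epsilon_kcal,
                "sign_policy": cfg.social.sign_policy,
                "seed": cfg.seed,
                "final_mass_kg": traj.final_mass_kg,
                "final_gap_kcal": final_energy_gap(traj),
                "time_to_stability_days": time_to_stability(traj),
                "tail_increment_var": tail_increment_variance(traj),
                "clamped": traj.clamped,
                "negative_fat": traj.negative_fat,
            }
        )
    summary = pd.DataFrame(rows)
    if outdir is not None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for run_id, traj in trajectories.items():
            traj.to_csv(out / f"{run_id}.csv", metadata_path=out / f"{run_id}.meta.json")
        summary.to_csv(out / "summary.csv", index=False, float_format="%.10g")
    return trajectories, summary
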