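"""Simulation engine: stepping order, flags, scenario suite, I/O, estimation."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from socialmass import (
    IndividualProfile,
    PartitionModel,
    RunConfig,
    SocialParams,
    estimate_gamma,
    final_energy_gap,
    profile_from_caption,
    run_scenario_suite,
    simulate,
)


def _balanced_profile():
    """An individual whose initial intake equals initial expenditure."""
    return IndividualProfile(
        id="bal", sex="male", age_years=40.0, height_m=1.78, mass0_kg=80.0,
        fat0_kg=18.0, lean0_kg=62.0, intake0_kcal=3000.0, expend0_kcal=3000.0,
        gamma=0.3,
    )


class TestSimulate:
    def test_balanced_individual_keeps_mass(self):
        traj = simulate(RunConfig(profile=_balanced_profile(), horizon_days=30))
        assert traj.final_mass_kg == pytest.approx(80.0, abs=1e-9)
        assert np.allclose(traj.data["intake_kcal"], 3000.0)

    def test_first_record_is_the_initial_condition(self, fig3_run):
        row0 = fig3_run.data.iloc[0]
        prof = fig3_run.profile
        assert row0["day"] == 0
        assert row0["mass_kg"] == pytest.approx(prof.mass0_kg)
        assert row0["intake_kcal"] == prof.intake0_kcal
        assert row0["expend_kcal"] == prof.expend0_kcal

    def test_mass_closure_every_day(self, fig3_run):
        df = fig3_run.data
        assert np.allclose(df["mass_kg"], df["fat_kg"] + df["lean_kg"], atol=1e-9)

    def test_slow_loser_reaches_balance_below_start(self, fig3_run):
        assert fig3_run.final_mass_kg < 99.52
        assert abs(final_energy_gap(fig3_run)) < 0.5

    def test_slow_gainer_reaches_balance_above_start(self, fig4_run):
        assert fig4_run.final_mass_kg > 50.01
        assert abs(final_energy_gap(fig4_run)) < 0.5

    def test_negative_fat_flagged_not_hidden(self):
        traj = simulate(
            RunConfig(
                profile=profile_from_caption("fig1"), horizon_days=1500,
                partition=PartitionModel(p_kind="hall"),
            )
        )
        assert traj.negative_fat
        flagged = traj.data.loc[traj.data["flags"] == "negative_fat"]
        assert (flagged["fat_kg"] < 0.0).all() and len(flagged) > 0

    def test_forbes_clamps_and_stops_at_emaciation(self):
        # gamma 0 pins intake below the expenditure intercept, so no
        # positive-mass equilibrium exists and the deficit never closes
        prof = IndividualProfile(
            id="x", sex="male", age_years=40.0, height_m=1.8, mass0_kg=60.0,
            fat0_kg=3.0, lean0_kg=57.0, intake0_kcal=700.0, expend0_kcal=3500.0,
            gamma=0.0,
        )
        traj = simulate(RunConfig(profile=prof, horizon_days=20000))
        assert traj.clamped
        assert traj.data["flags"].iloc[-1] == "clamped"
        assert len(traj.data) < 20001  # run stopped early
        assert traj.data["fat_kg"].iloc[-1] >= 0.0

    def test_cumulative_energy_audit(self, fig3_run):
        """Total stored-energy change equals the summed effective imbalance."""
        df = fig3_run.data
        stored = 9400.0 * (df["fat_kg"].iloc[-1] - df["fat_kg"].iloc[0]) + 1800.0 * (
            df["lean_kg"].iloc[-1] - df["lean_kg"].iloc[0]
        )
        imb = (df["intake_kcal"] - df["expend_kcal"] + df["social_kcal"]).iloc[1:].sum()
        assert stored == pytest.approx(imb, rel=1e-8)

    def test_seed_reproducibility(self):
        cfg = RunConfig(
            profile=profile_from_caption("fig3"), horizon_days=200, seed=5,
            social=SocialParams(case="random", sign_policy="random"),
        )
        a, b = simulate(cfg), simulate(cfg)
        pd.testing.assert_frame_equal(a.data, b.data)
        c = simulate(replace(cfg, seed=6))
        assert not a.data["mass_kg"].equals(c.data["mass_kg"])

    def test_day_index_attached_to_errors(self):
        prof = replace(_balanced_profile(), expend0_kcal=5000.0, intake0_kcal=5000.0)
        # beta*I0 + B0 exceeds E0 only if we corrupt expenditure mid-run;
        # instead check the calibration error path surfaces cleanly
        bad = replace(prof, expend0_kcal=1000.0)
        with pytest.raises(ValueError, match="negative activity"):
            simulate(RunConfig(profile=bad, horizon_days=5))


class TestScenarioSuite:
    def test_case_i_final_mass_monotone_in_epsilon(self):
        _, s5 = run_scenario_suite("fig5")
        assert s5["final_mass_kg"].is_monotonic_increasing
        _, s7 = run_scenario_suite("fig7")
        assert s7["final_mass_kg"].is_monotonic_decreasing

    def test_case_ii_final_mass_monotone_in_alpha(self):
        _, s6 = run_scenario_suite("fig6")
        assert s6["final_mass_kg"].is_monotonic_increasing
        _, s8 = run_scenario_suite("fig8")
        assert s8["final_mass_kg"].is_monotonic_decreasing

    def test_matched_seed_pair_reports_noise_amplification(self):
        _, s11 = run_scenario_suite("fig11", seed=3)
        v = s11.set_index("run_id")["tail_increment_var"]
        assert v["fig11_noise"] > v["fig11_nonoise"]

    def test_unknown_scenario_lists_presets(self):
        with pytest.raises(ValueError, match="fig1"):
            run_scenario_suite("fig99")

    def test_summary_csv_byte_identical_under_same_seed(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        run_scenario_suite("fig11", outdir=d1, seed=7)
        run_scenario_suite("fig11", outdir=d2, seed=7)
        assert (d1 / "summary.csv").read_bytes() == (d2 / "summary.csv").read_bytes()


class TestTrajectoryIO:
    def test_csv_and_metadata_sidecar(self, tmp_path):
        traj = simulate(RunConfig(profile=profile_from_caption("fig4"), horizon_days=50))
        csv = tmp_path / "t.csv"
        meta = tmp_path / "t.meta.json"
        traj.to_csv(csv, metadata_path=meta)
        df = pd.read_csv(csv)
        assert list(df.columns) == [
            "day", "fat_kg", "lean_kg", "mass_kg", "intake_kcal",
            "expend_kcal", "social_kcal", "flags",
        ]
        assert len(df) == 51
        import json

        m = json.loads(meta.read_text())
        assert m["profile"]["id"] == "fig4" and m["p_kind"] == "forbes"


class TestGammaEstimation:
    @pytest.mark.parametrize("gamma_true", [0.15, 0.30, 0.45])
    def test_recovers_generating_gamma_from_noise_free_trajectory(self, gamma_true):
        prof = replace(profile_from_caption("fig3"), gamma=gamma_true)
        cfg = RunConfig(profile=prof, horizon_days=1500)
        observed = simulate(cfg).mass_kg
        g_hat = estimate_gamma(observed, cfg)
        assert abs(g_hat - gamma_true) <= 0.05
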