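"""Simulation loop: inoculation, step ordering, conservation, determinism."""

import numpy as np
import pandas as pd
import pytest

from colonysim.agents import StrainParams
from colonysim.config_io import NutrientConfig, RunConfig
from colonysim.engine import InoculationSpec, ParamSwitchEvent, Simulation
from colonysim.environment import NutrientLayers, PlateGeometry, RefeedEvent
from colonysim.measurement import inhibition_zone_ratio

from conftest import small_run_config


def doubling_oracle(params: StrainParams, n_steps: int) -> list[int]:
    """Independent cohort recursion for one founder with unlimited nutrient.

    Tracks (energy, count) cohorts; each step every cohort gains
    uptake - cost, divides when it reaches the division threshold
    (daughters act from the next step), never dies, never enters G0.
    """
    gain = params.uptake_rate_active - params.metabolic_cost_active
    cohorts = [(params.initial_energy, 1)]
    counts = []
    for _ in range(n_steps):
        new_cohorts = []
        born = []
        for energy, count in cohorts:
            energy += gain
            if energy >= params.division_threshold:
                born.append((params.initial_energy, count))
                energy -= params.initial_energy
            new_cohorts.append((energy, count))
        cohorts = new_cohorts + born
        counts.append(sum(c for _, c in cohorts))
    return counts


class TestInoculation:
    def test_single_founder_at_center(self):
        cfg = small_run_config(
            inoculations=[InoculationSpec((30.0, 30.0), 0.0, 1, "wt", "c0")]
        )
        sim = cfg.build(seed=1)
        assert len(sim.population) == 1
        assert sim.population.x[0] == 30.0 and sim.population.y[0] == 30.0

    def test_all_founders_within_disc(self):
        cfg = small_run_config(
            inoculations=[InoculationSpec((30.0, 30.0), 5.0, 200, "wt", "c0")]
        )
        sim = cfg.build(seed=1)
        r = np.hypot(sim.population.x - 30.0, sim.population.y - 30.0)
        assert (r <= 5.0 + 1e-9).all()

    def test_initial_area_scales_with_radius_squared(self):
        areas = {}
        for radius in (2.0, 6.0):
            cfg = small_run_config(
                n=80,
                inoculations=[InoculationSpec((40.0, 40.0), radius, 2000, "wt", "c0")],
            )
            areas[radius] = cfg.build(seed=3).colony_area_px(0)
        ratio = areas[6.0] / areas[2.0]
        assert 6.0 < ratio < 12.0  # saturated discs: ~(6/2)^2 up to grid effects

    def test_center_outside_plate_rejected(self):
        cfg = small_run_config(
            inoculations=[InoculationSpec((1.0, 1.0), 0.0, 1, "wt", "c0")]
        )
        with pytest.raises(ValueError, match="outside"):
            cfg.build(seed=0)


class TestStepLoop:
    def test_zero_steps_records_initial_state_only(self):
        sim = small_run_config(n_steps=0).run(seed=1)
        df = sim.trajectory.to_frame()
        assert len(df) == 1 and df["step"].iloc[0] == 0

    def test_empty_plate_conserves_nutrient(self):
        geom = PlateGeometry(30, 30, "circular")
        layers = NutrientLayers.uniform(geom, 2.0, 4.0, sigma_top=1.0, sigma_deep=1.0)
        sim = Simulation(
            geom, layers, {"wt": StrainParams("wt")},
            [InoculationSpec((15.0, 15.0), 0.0, 1, "wt", "c0")], seed=0,
        )
        sim.population.keep(np.zeros(1, dtype=bool))  # remove the founder
        total0 = sim.layers.total()
        sim.run(50)
        assert sim.layers.total() == pytest.approx(total0, rel=1e-9)

    def test_population_follows_doubling_recursion(self):
        strain = StrainParams("wt")  # uptake 1, cost 0.2, threshold 2, E0 1
        cfg = small_run_config(
            n=40,
            strain=strain,
            inoculations=[InoculationSpec((20.0, 20.0), 0.0, 1, "wt", "c0")],
            init_top=1e6,
            init_deep=1e6,
            n_steps=18,
        )
        sim = cfg.run(seed=7)
        counts = sim.trajectory.to_frame()["n_agents"].to_numpy()[1:]
        assert list(counts) == doubling_oracle(strain, 18)

    def test_deterministic_under_fixed_seed(self):
        cfg = small_run_config(n_steps=60)
        df1 = cfg.run(seed=9).trajectory.to_frame()
        df2 = cfg.run(seed=9).trajectory.to_frame()
        pd.testing.assert_frame_equal(df1, df2)

    def test_different_seeds_diverge(self):
        cfg = small_run_config(n_steps=60)
        df1 = cfg.run(seed=1).trajectory.to_frame()
        df2 = cfg.run(seed=2).trajectory.to_frame()
        assert not df1.equals(df2)

    def test_energy_ledger_closes_with_deaths_and_refeed(self):
        # starvation-prone strain on a poor plate, plus a mid-run refeed:
        # deaths, G0 cycling and the refeed all enter the ledger
        strain = StrainParams(
            "wt", uptake_rate_g0=0.0, metabolic_cost_g0=0.02,
            metabolic_cost_active=0.4, death_threshold=0.3,
            g0_threshold=0.7, division_threshold=2.0,
        )
        cfg = small_run_config(
            n=40, strain=strain, init_top=0.5, init_deep=1.0, n_steps=120,
            inoculations=[InoculationSpec((20.0, 20.0), 3.0, 80, "wt", "c0")],
        )
        cfg.events = [RefeedEvent(step=60, amount=1.0, region="all", layer="top")]
        sim = cfg.build(seed=5)
        ledger0 = sim.energy_ledger()
        n0 = len(sim.population)
        sim.run(cfg.n_steps)
        assert sim.energy_ledger() == pytest.approx(ledger0, rel=1e-6)
        assert len(sim.population) < n0  # starvation actually removed agents

    def test_g0_energy_frozen_when_fully_dormant(self):
        strain = StrainParams("wt")  # G0 uptake and cost are zero
        cfg = small_run_config(
            n=30, strain=strain, init_top=0.3, init_deep=0.6, n_steps=40,
            sigma_top=0.0, sigma_deep=0.0, flowrate=0.0,
            inoculations=[InoculationSpec((15.0, 15.0), 0.0, 1, "wt", "c0")],
        )
        sim = cfg.run(seed=1)
        from colonysim.agents import AgentState

        assert (sim.population.state == AgentState.G0).all()
        energy_then = sim.population.energy.copy()
        sim.run(20)
        np.testing.assert_array_equal(sim.population.energy, energy_then)


class TestEvents:
    def test_param_switch_changes_strain_and_sigmas(self):
        cfg = small_run_config(n_steps=10)
        cfg.events = [
            ParamSwitchEvent(
                step=5,
                strain_updates={"wt": {"division_distance": 2.5}},
                sigma_top=0.1,
            )
        ]
        sim = cfg.build(seed=0)
        sim.run(4)
        assert sim.strains["wt"].division_distance == 1.0
        sim.run(1)
        assert sim.strains["wt"].division_distance == 2.5
        assert sim.layers.sigma_top == 0.1

    def test_reinoculation_fires_at_its_step(self):
        cfg = small_run_config(n_steps=20)
        cfg.inoculations.append(
            InoculationSpec((20.0, 20.0), 0.0, 30, "wt", "late", at_step=10)
        )
        sim = cfg.build(seed=0)
        sim.run(9)
        df = sim.trajectory.to_frame()
        assert df["area_px_late"].iloc[-1] == 0
        sim.run(1)
        assert sim.trajectory.to_frame()["area_px_late"].iloc[-1] > 0


class TestColonyInteraction:
    def test_close_colonies_form_inhibition_zone(self):
        # two droplets 30 cells apart: rims approach but a low-density
        # boundary strip persists between them
        cfg = small_run_config(
            n=120,
            n_steps=360,
            inoculations=[
                InoculationSpec((45.0, 60.0), 4.0, 100, "wt", "A"),
                InoculationSpec((75.0, 60.0), 4.0, 100, "wt", "B"),
            ],
        )
        ratios = []
        for seed in range(3):
            sim = cfg.run(seed=seed)
            ratios.append(
                inhibition_zone_ratio(sim.density_grid("A"), sim.density_grid("B"))
            )
        assert all(r < 0.5 for r in ratios)

    def test_shared_plate_reduces_per_colony_area(self):
        def mean_final_area(n_colonies, seed):
            specs = []
            for k in range(n_colonies):
                angle = 2 * np.pi * k / max(n_colonies, 1)
                x = 60 + 33 * np.cos(angle) if n_colonies > 1 else 60.0
                y = 60 + 33 * np.sin(angle) if n_colonies > 1 else 60.0
                specs.append(InoculationSpec((x, y), 4.0, 100, "wt", f"c{k}"))
            cfg = small_run_config(n=120, n_steps=240, inoculations=specs)
            sim = cfg.run(seed=seed)
            return np.mean([sim.colony_area_px(i) for i in range(n_colonies)])

        lone = np.mean([mean_final_area(1, s) for s in range(3)])
        crowded = np.mean([mean_final_area(6, s) for s in range(3)])
        assert crowded < lone
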