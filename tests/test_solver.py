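"""0D network solver: closed forms, conservation, convergence."""

import dataclasses

import numpy as np
import pytest

from coroflow import anatomy as ana
from coroflow import pipeline as pl
from coroflow import solver as sol
from coroflow.units import cgs_to_mmhg
from coroflow.waveforms import constant_waveform


def _uniform_tube(radius: float, length: float) -> ana.CenterlineSegment:
    return ana.CenterlineSegment(
        "T", "LAD", np.linspace(0.0, length, 11), np.full(11, radius)
    )


def _healthy_model(cfg: pl.StudyConfig) -> sol.NetworkModel:
    lib = pl.make_study_library(cfg)
    spec = pl.case_specs(["healthy"])[0]
    tree = pl.build_case_tree(spec, cfg)
    bcs, _ = pl.calibrate_outlets(tree, cfg, lib)
    return sol.assemble(tree, bcs, lib, cfg.fluid)


# ---------------------------------------------------------------------------
# Poiseuille segment resistance
# ---------------------------------------------------------------------------

def test_segment_resistance_matches_poiseuille_closed_form():
    fluid = sol.FluidProperties(mu=0.04)
    r = sol.segment_resistance(_uniform_tube(0.1, 1.0), fluid)
    expected = 8.0 * 0.04 * 1.0 / (np.pi * 0.1**4)
    assert r == pytest.approx(expected, rel=1e-3)
    # linear in length, r^-4 in radius
    assert sol.segment_resistance(_uniform_tube(0.1, 2.0), fluid) == pytest.approx(2 * r, rel=1e-9)
    assert sol.segment_resistance(_uniform_tube(0.05, 1.0), fluid) == pytest.approx(16 * r, rel=1e-9)


def test_poiseuille_pressure_drop_closed_form():
    # steady flow Q through a uniform tube: dP = 8 mu L Q / (pi r^4)
    fluid = sol.FluidProperties(mu=0.04)
    q, radius, length = 2.0, 0.12, 3.0
    model = sol.NetworkModel(
        n_nodes=1,
        elements=[
            sol.Resistor(0, sol.GROUND, sol.segment_resistance(_uniform_tube(radius, length), fluid), "tube"),
            sol.FlowSource(0, constant_waveform(q, 1.0), "inflow"),
        ],
        node_names=["in"],
    )
    res = sol.solve(model, sol.SimConfig(n_cycles=1))
    expected = cgs_to_mmhg(8.0 * fluid.mu * length * q / (np.pi * radius**4))
    assert res.node_pressure[0, -1] == pytest.approx(expected, rel=1e-3)


# ---------------------------------------------------------------------------
# solve(): Ohmic and RC closed forms
# ---------------------------------------------------------------------------

def test_pure_resistive_network_is_ohmic_at_every_step():
    q, r = 5.0, 2000.0
    model = sol.NetworkModel(
        n_nodes=1,
        elements=[
            sol.Resistor(0, sol.GROUND, r, "r"),
            sol.FlowSource(0, constant_waveform(q, 1.0), "inflow"),
        ],
        node_names=["in"],
    )
    res = sol.solve(model, sol.SimConfig(n_cycles=2))
    assert np.allclose(res.node_pressure[0], cgs_to_mmhg(q * r), rtol=1e-12)
    assert np.allclose(res.flow("r"), q, rtol=1e-12)


def _rcr_model(q, rp, c, rd):
    return sol.NetworkModel(
        n_nodes=2,
        elements=[
            sol.Resistor(0, 1, rp, "rcr:rp"),
            sol.Capacitor(1, c, "rcr:c"),
            sol.Resistor(1, sol.GROUND, rd, "rcr:rd"),
            sol.FlowSource(0, constant_waveform(q, 1.0), "inflow"),
        ],
        node_names=["in", "mid"],
    )


def test_rcr_step_response_matches_exponential():
    # uncharged RCR block with a flow step: P(t) = Q Rp + Q Rd (1 - exp(-t / Rd C))
    q, rp, c, rd = 10.0, 100.0, 0.001, 1000.0
    tau = rd * c  # 1.0 s
    res = sol.solve(_rcr_model(q, rp, c, rd), sol.SimConfig(n_cycles=4), init="zero")
    for t_probe in (0.5, 1.0, 2.0):
        k = int(round(t_probe / 0.002)) - 1
        expected = cgs_to_mmhg(q * rp + q * rd * (1.0 - np.exp(-res.time[k] / tau)))
        assert res.node_pressure[0, k] == pytest.approx(expected, rel=1e-3)


def test_rcr_terminal_pressure_relaxes_to_total_resistance():
    q, rp, c, rd = 10.0, 100.0, 0.001, 1000.0
    res = sol.solve(_rcr_model(q, rp, c, rd), sol.SimConfig(n_cycles=12), init="zero")
    assert res.node_pressure[0, -1] == pytest.approx(cgs_to_mmhg(q * (rp + rd)), rel=1e-3)


# ---------------------------------------------------------------------------
# assembly structure and errors
# ---------------------------------------------------------------------------

def test_assembled_circuit_has_one_rcr_and_three_lpn_blocks(study_cfg):
    model = _healthy_model(study_cfg)
    labels = [el.label for el in model.elements]
    assert {"rcr:rp", "rcr:c", "rcr:rd", "inflow"} <= set(labels)
    lpn_blocks = {lbl.split(":")[1] for lbl in labels if lbl.startswith("lpn:")}
    assert lpn_blocks == {"LAD", "LCX", "RCA"}
    assert sum(lbl.startswith("seg:") for lbl in labels) == 5  # one resistor per segment


def test_plaque_strictly_increases_lad_resistance(study_cfg):
    tree = ana.build_tree(ana.VARIANT_NORMAL, study_cfg.geometry)
    narrowed = ana.insert_stenosis(tree, study_cfg.plaque)
    assert sol.segment_resistance(narrowed.segment("LAD"), study_cfg.fluid) > sol.segment_resistance(
        tree.segment("LAD"), study_cfg.fluid
    )


def test_missing_coronary_bc_is_rejected(study_cfg):
    lib = pl.make_study_library(study_cfg)
    tree = ana.build_tree(ana.VARIANT_NORMAL, study_cfg.geometry)
    bcs, _ = pl.calibrate_outlets(tree, study_cfg, lib)
    del bcs["LCX"]
    with pytest.raises(sol.SolverError, match="LCX"):
        sol.assemble(tree, bcs, lib, study_cfg.fluid)


def test_period_mismatch_is_rejected(study_cfg):
    model = _healthy_model(study_cfg)
    with pytest.raises(sol.SolverError, match="period"):
        sol.solve(model, sol.SimConfig(dt=0.002, steps_per_cycle=400))


def test_prescribed_flow_mode_imposes_the_branch_flow(study_cfg):
    lib = pl.make_study_library(study_cfg)
    tree = pl.build_case_tree(pl.case_specs(["healthy"])[0], study_cfg)
    bcs, _ = pl.calibrate_outlets(tree, study_cfg, lib)
    prescribed = {"LAD": lib.right_shape.scaled(1.5)}
    model = sol.assemble(tree, bcs, lib, study_cfg.fluid, prescribed_flows=prescribed)
    assert "presc:LAD" in [el.label for el in model.elements]
    res = sol.solve(model, study_cfg.sim)
    expected = np.asarray(prescribed["LAD"](res.time))
    assert np.max(np.abs(res.flow("seg:LAD") - expected)) < 1e-8


# ---------------------------------------------------------------------------
# conservation and convergence on the calibrated model
# ---------------------------------------------------------------------------

def test_instantaneous_mass_balance(healthy_case):
    assert sol.mass_residual(healthy_case.sim) < 1e-8


def test_capacitors_carry_no_net_cycle_charge(study_cfg):
    # long run so the start-up transient is fully decayed
    model = _healthy_model(study_cfg)
    res = sol.solve(model, dataclasses.replace(study_cfg.sim, n_cycles=30))
    q_in = float(np.mean(res.flow("inflow")[res.last_cycle]))
    for label in res.element_labels:
        if label == "rcr:c" or label.endswith(":ca") or label.endswith(":cim"):
            net = abs(float(np.mean(res.flow(label)[res.last_cycle])))
            assert net / q_in < 1e-6, label


def test_periodic_convergence_below_tolerance_and_monotone(study_cfg, healthy_case):
    assert healthy_case.convergence < study_cfg.sim.convergence_tol
    model = _healthy_model(study_cfg)
    short = sol.solve(model, dataclasses.replace(study_cfg.sim, n_cycles=2))
    assert sol.periodic_convergence(short) > healthy_case.convergence
    with pytest.raises(sol.SolverError):
        sol.periodic_convergence(
            sol.solve(model, dataclasses.replace(study_cfg.sim, n_cycles=1))
        )


def test_halving_dt_barely_changes_mean_pressures(study_cfg, healthy_case):
    fine_cfg = dataclasses.replace(
        study_cfg, sim=sol.SimConfig(dt=0.001, steps_per_cycle=1000, n_cycles=12)
    )
    fine = pl.run_case(pl.case_specs(["healthy"])[0], fine_cfg)
    for name in healthy_case.sim.node_names:
        coarse_mean = float(np.mean(healthy_case.sim.pressure(name)[healthy_case.sim.last_cycle]))
        fine_mean = float(np.mean(fine.sim.pressure(name)[fine.sim.last_cycle]))
        assert abs(fine_mean - coarse_mean) / abs(coarse_mean) < 0.005, name


def test_branch_pressure_drop_equals_series_resistive_drop(study_cfg, healthy_case):
    # no capacitors sit inside the arterial tree, so the mean ostium-to-outlet
    # drop is exactly the sum of mean flow x resistance over the path
    tree = pl.build_case_tree(pl.case_specs(["healthy"])[0], study_cfg)
    res = healthy_case.sim
    r_lm = sol.segment_resistance(tree.segment("LM"), study_cfg.fluid)
    r_lad = sol.segment_resistance(tree.segment("LAD"), study_cfg.fluid)
    q_lm = float(np.mean(res.flow("seg:LM")[res.last_cycle]))
    q_lad = float(np.mean(res.flow("seg:LAD")[res.last_cycle]))
    expected = cgs_to_mmhg(q_lm * r_lm + q_lad * r_lad)
    assert sol.pressure_drop(res, "LAD") == pytest.approx(expected, rel=1e-9)
    with pytest.raises(sol.SolverError):
        sol.pressure_drop(res, "OM2")


def test_flow_fractions_sum_to_one_hundred(healthy_case):
    fractions = sol.flow_fractions(healthy_case.sim)
    assert sum(fractions.values()) == pytest.approx(100.0, abs=0.1)
    assert set(fractions) == {"AORTA", "LAD", "LCX", "RCA"}
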