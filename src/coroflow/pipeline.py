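"""Six-case study orchestration.

The study matrix crosses anatomy (normal vs. anomalous LCX origin),
plaque (with / without the mild LAD stenosis) and coronary waveform
assignment (default vs. left/right swap):

========================  =========================  ======  =======
case                      anatomy                    plaque  swapped
========================  =========================  ======  =======
patient                   aoca_lcx_right_sinus       yes     no
patient_no_plaque         aoca_lcx_right_sinus       no      no
healthy                   normal                     no      no
healthy_with_plaque       normal                     yes     no
patient_adjusted          aoca_lcx_right_sinus       yes     yes
healthy_adjusted          normal                     no      yes
========================  =========================  ======  =======

Unswapped cases are driven through the calibrated coronary outlet
circuits.  In the swapped ("adjusted") cases the coronary branch flows
are prescribed directly at the coronary outlets -- the left branches
carry the (swapped-in) double-peak shape and the right branch the
single-peak shape, each scaled to the branch's Murray-calibrated mean
flow -- which is the literal reading of exchanging the coronary inlet
flow waveforms.

The module computes, per case and branch: flow fraction of the aortic
inflow, mean branch pressure, ostium-to-outlet pressure drop, and the
spatial mean +/- SD of TAWSS / OSI / ECAP from Poiseuille wall-shear
series; and between baseline/adjusted pairs the normalized flow change
per branch.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anatomy as ana
from . import calibration as cal
from . import indices as idx
from . import solver as sol
from . import waveforms as wf

__all__ = [
    "CASE_NAMES",
    "CaseSpec",
    "StudyConfig",
    "CaseResult",
    "ComparisonReport",
    "case_specs",
    "default_plaque",
    "build_case_tree",
    "calibrate_outlets",
    "run_case",
    "run_case_matrix",
    "normalized_flow_change",
    "compare_report",
    "write_signals_csv",
]

logger = logging.getLogger(__name__)

CASE_NAMES = (
    "patient",
    "patient_no_plaque",
    "healthy",
    "healthy_with_plaque",
    "patient_adjusted",
    "healthy_adjusted",
)

_CASE_TABLE = {
    "patient": (ana.VARIANT_AOCA, True, False),
    "patient_no_plaque": (ana.VARIANT_AOCA, False, False),
    "healthy": (ana.VARIANT_NORMAL, False, False),
    "healthy_with_plaque": (ana.VARIANT_NORMAL, True, False),
    "patient_adjusted": (ana.VARIANT_AOCA, True, True),
    "healthy_adjusted": (ana.VARIANT_NORMAL, False, True),
}

#: which intramyocardial pressure source a branch's outlet uses; territory
#: follows the branch identity, not the sinus of origin.
_PIM_SIDE = {"LAD": "left", "LCX": "left", "LM": "left", "RCA": "right"}


@dataclass(frozen=True)
class CaseSpec:
    name: str
    variant: str
    plaque: bool
    swapped: bool

    def __post_init__(self) -> None:
        expected = _CASE_TABLE.get(self.name)
        if expected is None:
            raise ValueError(f"unknown case {self.name!r}; expected one of {CASE_NAMES}")
        if expected != (self.variant, self.plaque, self.swapped):
            raise ValueError(
                f"case {self.name!r} must map to (variant, plaque, swapped) = {expected}"
            )


def case_specs(names=CASE_NAMES) -> list[CaseSpec]:
    return [CaseSpec(n, *_CASE_TABLE[n]) for n in names]


def default_plaque() -> ana.StenosisSpec:
    """The packaged patient plaque: mild 14% focal LAD stenosis.

    Centered 1.2 cm downstream of the left coronary ostium along the
    LM + LAD path; with the default 1.0 cm LM this is 0.2 cm into the
    LAD in segment-local coordinates.
    """
    return ana.StenosisSpec(segment_id="LAD", center_s=0.2, length=0.4, degree=14.0)


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to reproduce the six-case matrix."""

    geometry: ana.GeometryParams = field(default_factory=ana.GeometryParams)
    calibration: cal.CalibrationInputs = field(default_factory=cal.CalibrationInputs)
    sim: sol.SimConfig = field(default_factory=sol.SimConfig)
    fluid: sol.FluidProperties = field(default_factory=sol.FluidProperties)
    plaque: ana.StenosisSpec = field(default_factory=default_plaque)
    pim_left_peak: float | None = None
    pim_right_peak: float | None = None
    #: total compliance of each coronary outlet circuit (cm^5/dyn)
    c_total_per_outlet: float = 1e-6
    murray_exponent: float = cal.MURRAY_EXPONENT
    resistance_mode: str = "parallel"
    #: arc spacing of the wall-shear sampling locations (cm)
    wss_spacing: float = 0.25

    @property
    def period(self) -> float:
        return self.sim.period

    # -- YAML interchange ------------------------------------------------
    @classmethod
    def from_dict(cls, doc: dict) -> "StudyConfig":
        kwargs = {}
        if "geometry" in doc:
            kwargs["geometry"] = ana.GeometryParams(**doc["geometry"])
        if "calibration" in doc:
            kwargs["calibration"] = cal.CalibrationInputs(**doc["calibration"])
        if "sim" in doc:
            kwargs["sim"] = sol.SimConfig(**doc["sim"])
        if "fluid" in doc:
            kwargs["fluid"] = sol.FluidProperties(**doc["fluid"])
        if "plaque" in doc:
            kwargs["plaque"] = ana.StenosisSpec(**doc["plaque"])
        for key in (
            "pim_left_peak",
            "pim_right_peak",
            "c_total_per_outlet",
            "murray_exponent",
            "resistance_mode",
            "wss_spacing",
        ):
            if key in doc:
                kwargs[key] = doc[key]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        doc = {
            "geometry": dataclasses.asdict(self.geometry),
            "calibration": dataclasses.asdict(self.calibration),
            "sim": dataclasses.asdict(self.sim),
            "fluid": dataclasses.asdict(self.fluid),
            "plaque": dataclasses.asdict(self.plaque),
            "pim_left_peak": self.pim_left_peak,
            "pim_right_peak": self.pim_right_peak,
            "c_total_per_outlet": self.c_total_per_outlet,
            "murray_exponent": self.murray_exponent,
            "resistance_mode": self.resistance_mode,
            "wss_spacing": self.wss_spacing,
        }
        return doc


def build_case_tree(spec: CaseSpec, cfg: StudyConfig) -> ana.CoronaryTree:
    tree = ana.build_tree(spec.variant, cfg.geometry)
    if spec.plaque:
        tree = ana.insert_stenosis(tree, cfg.plaque)
    return tree


def make_study_library(cfg: StudyConfig) -> wf.WaveformLibrary:
    return wf.make_library(
        period_T=cfg.period,
        cardiac_output=cfg.calibration.cardiac_output,
        pim_left_peak=cfg.pim_left_peak,
        pim_right_peak=cfg.pim_right_peak,
        n_samples=cfg.sim.steps_per_cycle,
    )


def calibrate_outlets(
    tree: ana.CoronaryTree, cfg: StudyConfig, lib: wf.WaveformLibrary
) -> tuple[dict, dict[str, float]]:
    """Estimate and split the outlet boundary conditions for one tree.

    Returns the per-outlet BC map and the Murray conductance shares of
    the coronary outlets (fraction of coronary flow each outlet is
    calibrated to carry).
    """
    est = cal.estimate_resistances(cfg.calibration, mode=cfg.resistance_mode)
    coronary = sorted(s.name for s in tree.leaves if s.name != "AORTA")
    outlets = [(name, float(tree.segment(name).radius[-1])) for name in coronary]
    allocation = cal.allocate_murray(est.r_cor, outlets, exponent=cfg.murray_exponent)
    weights = {name: r**cfg.murray_exponent for name, r in outlets}
    total_w = sum(weights.values())
    shares = {name: w / total_w for name, w in weights.items()}
    bcs: dict = {"AORTA": cal.split_rcr(est.r_aorta)}
    for name in coronary:
        pim = lib.pim_left if _PIM_SIDE[name] == "left" else lib.pim_right
        bcs[name] = cal.split_lpn(allocation[name], cfg.c_total_per_outlet, pim)
    return bcs, shares


@dataclass
class CaseResult:
    case: CaseSpec
    sim: sol.SimResult
    indices: idx.IndexReport
    fractions: dict[str, float]
    pressure_drops: dict[str, float]
    mean_pressures: dict[str, float]
    branch_flows: dict[str, float]
    convergence: float
    runtime_s: float


def _branch_mean_pressures(result: sol.SimResult) -> dict[str, float]:
    """Time-average of the branch midpoint pressure over the last cycle.

    The 0D analogue of a branch's wall pressure: the mean of its inlet
    and outlet node pressures.
    """
    out = {}
    for branch in result.meta["terminal_branches"]:
        p_in = result.node_pressure[result.meta["branch_inlet_node"][branch], result.last_cycle]
        p_out = result.node_pressure[result.meta["branch_outlet_node"][branch], result.last_cycle]
        out[branch] = float(np.mean(0.5 * (p_in + p_out)))
    return out


def _wss_report(
    tree: ana.CoronaryTree, result: sol.SimResult, cfg: StudyConfig
) -> idx.IndexReport:
    spc = cfg.sim.steps_per_cycle
    t = np.arange(spc) * cfg.sim.dt
    series = []
    grouping = {}
    for branch in result.meta["coronary_branches"]:
        seg = tree.segment(branch)
        q_last = result.flow(f"seg:{branch}")[result.last_cycle]
        positions = np.arange(0.0, seg.length + 1e-9, cfg.wss_spacing)
        for s_pos in positions:
            loc = f"{branch}@{s_pos:.2f}"
            r_local = float(seg.radius_at(s_pos))
            series.append(
                idx.wss_from_flow(q_last, r_local, cfg.fluid.mu, t, cfg.period, loc)
            )
            grouping[loc] = branch
    return idx.IndexReport.from_series(series, grouping)


def run_case(spec: CaseSpec, cfg: StudyConfig, lib: wf.WaveformLibrary | None = None) -> CaseResult:
    """Build, calibrate, simulate and post-process one study case."""
    started = _time.perf_counter()
    lib = lib or make_study_library(cfg)
    tree = build_case_tree(spec, cfg)
    bcs, shares = calibrate_outlets(tree, cfg, lib)

    prescribed = None
    if spec.swapped:
        swapped_lib = wf.swap_left_right(lib)
        q_cor = cfg.calibration.coronary_fraction * cfg.calibration.cardiac_output
        prescribed = {}
        for branch, share in shares.items():
            shape = (
                swapped_lib.left_shape
                if _PIM_SIDE[branch] == "left"
                else swapped_lib.right_shape
            )
            prescribed[branch] = shape.scaled(q_cor * share)
        lib_used = swapped_lib
    else:
        lib_used = lib

    model = sol.assemble(tree, bcs, lib_used, cfg.fluid, prescribed_flows=prescribed)
    result = sol.solve(model, cfg.sim)
    conv = sol.periodic_convergence(result)
    if conv > cfg.sim.convergence_tol:
        raise sol.SolverError(
            f"case {spec.name!r} failed periodic convergence: "
            f"{conv:.3e} > {cfg.sim.convergence_tol:.1e}"
        )
    report = _wss_report(tree, result, cfg)
    fractions = sol.flow_fractions(result)
    drops = {b: sol.pressure_drop(result, b) for b in result.meta["terminal_branches"]}
    flows = sol.branch_mean_flows(result)
    runtime = _time.perf_counter() - started
    logger.info(
        "case=%s convergence=%.3e coronary_share=%.3f%% runtime=%.2fs",
        spec.name,
        conv,
        sum(fractions[b] for b in result.meta["coronary_branches"]),
        runtime,
    )
    return CaseResult(
        case=spec,
        sim=result,
        indices=report,
        fractions=fractions,
        pressure_drops=drops,
        mean_pressures=_branch_mean_pressures(result),
        branch_flows=flows,
        convergence=conv,
        runtime_s=runtime,
    )


def run_case_matrix(
    cfg: StudyConfig | None = None, names=CASE_NAMES
) -> dict[str, CaseResult]:
    """Simulate the study matrix; deterministic for a fixed configuration."""
    cfg = cfg or StudyConfig()
    lib = make_study_library(cfg)
    return {spec.name: run_case(spec, cfg, lib) for spec in case_specs(names)}


def normalized_flow_change(
    before: dict[str, float], after: dict[str, float]
) -> dict[str, float]:
    """Per-branch relative absolute change of mean flow, in percent.

    100 * |Q_after - Q_before| / Q_before, with the unswapped case as
    the baseline.
    """
    if set(before) != set(after):
        raise ValueError("before/after must cover the same branches")
    out = {}
    for branch, q0 in before.items():
        if q0 == 0.0:
            raise ValueError(f"zero baseline flow in branch {branch!r}")
        out[branch] = 100.0 * abs(after[branch] - q0) / abs(q0)
    return out


#: baseline -> adjusted pairings for the waveform-swap comparison
SWAP_PAIRS = (("patient", "patient_adjusted"), ("healthy", "healthy_adjusted"))


@dataclass
class ComparisonReport:
    """Machine-readable summary of the study matrix."""

    table: pd.DataFrame  # per case x branch metrics
    flow_changes: pd.DataFrame  # per pair x branch normalized flow change

    def to_json(self, path=None) -> str:
        doc = {
            "cases": self.table.to_dict(orient="records"),
            "flow_changes": self.flow_changes.to_dict(orient="records"),
        }
        text = json.dumps(doc, sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "ComparisonReport":
        doc = json.loads(Path(path).read_text())
        return cls(
            table=pd.DataFrame.from_records(doc["cases"]),
            flow_changes=pd.DataFrame.from_records(doc["flow_changes"]),
        )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_report(results: dict[str, CaseResult]) -> ComparisonReport:
    """Aggregate a completed case matrix into the comparison report."""
    rows = []
    for name, res in results.items():
        coronary = set(res.sim.meta["coronary_branches"])
        for branch in res.sim.meta["terminal_branches"]:
            row = {
                "case": name,
                "branch": branch,
                "flow_fraction_pct": res.fractions[branch],
                "mean_flow_ml_s": res.branch_flows[branch],
                "mean_pressure_mmhg": res.mean_pressures[branch],
                "pressure_drop_mmhg": res.pressure_drops[branch],
            }
            if branch in coronary:
                for metric in ("tawss", "osi", "ecap"):
                    row[f"{metric}_mean"] = res.indices.branch_mean(metric, branch)
                row["tawss_sd"] = float(
                    res.indices.branches.loc[
                        res.indices.branches["branch"] == branch, "tawss_sd"
                    ].iloc[0]
                )
            rows.append(row)
    table = pd.DataFrame(rows).sort_values(["case", "branch"]).reset_index(drop=True)

    change_rows = []
    for base, adjusted in SWAP_PAIRS:
        if base not in results or adjusted not in results:
            continue
        before = {
            b: results[base].branch_flows[b]
            for b in results[base].sim.meta["coronary_branches"]
        }
        after = {
            b: results[adjusted].branch_flows[b]
            for b in results[adjusted].sim.meta["coronary_branches"]
        }
        for branch, pct in normalized_flow_change(before, after).items():
            change_rows.append(
                {"baseline": base, "adjusted": adjusted, "branch": branch,
                 "flow_change_pct": pct}
            )
    changes = pd.DataFrame(change_rows)
    if not changes.empty:
        changes = changes.sort_values(["baseline", "branch"]).reset_index(drop=True)
    return ComparisonReport(table=table, flow_changes=changes)


def write_signals_csv(result: sol.SimResult, case_name: str, path) -> None:
    """Long-format per-case signal dump (case, signal, t, value)."""
    frames = []
    for i, name in enumerate(result.node_names):
        frames.append(
            pd.DataFrame(
                {
                    "case": case_name,
                    "signal": f"pressure:{name}",
                    "t": result.time,
                    "value": result.node_pressure[i],
                }
            )
        )
    for i, label in enumerate(result.element_labels):
        frames.append(
            pd.DataFrame(
                {
                    "case": case_name,
                    "signal": f"flow:{label}",
                    "t": result.time,
                    "value": result.element_flow[i],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
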