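"""Lumped-parameter (0D) pulsatile network solver.

The coronary tree is reduced to an electrical-analog circuit: each
vessel segment becomes a Poiseuille resistor (R = integral of
8 mu / (pi r(s)^4) ds along the centerline), the aortic outlet carries a
three-element Windkessel, and each coronary outlet carries the
five-element coronary circuit whose intramyocardial capacitor is
referenced to the time-varying myocardial pressure P_im.  The aortic
inflow is a prescribed periodic flow source; the venous/reference
pressure is the 0 mmHg ground.

The circuit is linear with time-varying sources only, so the system is
integrated with a fixed-step implicit scheme (trapezoidal rule with a
backward-Euler starting step) using companion models for the
capacitors; the constant conductance matrix is LU-factorized once.
Simulations are started from the DC (cycle-mean) operating point so the
periodic regime is reached well within the simulated cycles.  There is
no randomness anywhere: results are bitwise reproducible for a fixed
configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .anatomy import CenterlineSegment, CoronaryTree
from .calibration import CoronaryLPNParams, RCRParams
from .units import cgs_to_mmhg, mmhg_to_cgs
from .waveforms import Waveform, WaveformLibrary

__all__ = [
    "GROUND",
    "SolverError",
    "FluidProperties",
    "Resistor",
    "Capacitor",
    "FlowSource",
    "NetworkModel",
    "SimConfig",
    "SimResult",
    "segment_resistance",
    "assemble",
    "solve",
    "periodic_convergence",
    "pressure_drop",
    "branch_mean_flows",
    "flow_fractions",
    "coronary_share",
    "mass_residual",
]

GROUND = -1
"""Reference node index (venous pressure, 0 mmHg)."""


class SolverError(RuntimeError):
    """Raised on inconsistent networks or failed integrations."""


@dataclass(frozen=True)
class FluidProperties:
    """Blood treated as an incompressible Newtonian fluid.

    rho in g/cm^3, mu in g/(cm s) (poise).
    """

    rho: float = 1.04
    mu: float = 0.04

    def __post_init__(self) -> None:
        if self.rho <= 0.0 or self.mu <= 0.0:
            raise ValueError("density and viscosity must be positive")


def segment_resistance(seg: CenterlineSegment, fluid: FluidProperties | None = None) -> float:
    """Poiseuille resistance of a segment (dyn*s/cm^5).

    R = integral of 8 mu / (pi r(s)^4) ds, evaluated by the trapezoidal
    rule over the segment's samples, so a focal narrowing raises the
    resistance through the local r^-4 factor.
    """
    fluid = fluid or FluidProperties()
    if seg.arc_s.size < 2:
        raise SolverError("segment needs at least 2 samples")
    integrand = 8.0 * fluid.mu / (np.pi * seg.radius**4)
    return float(np.trapezoid(integrand, seg.arc_s))


# ---------------------------------------------------------------------------
# circuit elements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Resistor:
    a: int
    b: int  # GROUND allowed
    r: float
    label: str


@dataclass(frozen=True)
class Capacitor:
    """Capacitor from node ``a`` to ground or to an external pressure source.

    If ``p_ext`` is given, the far plate rides the external pressure
    waveform (in mmHg) instead of ground -- this is the intramyocardial
    compliance driven by P_im.
    """

    a: int
    c: float
    label: str
    p_ext: Waveform | None = None


@dataclass(frozen=True)
class FlowSource:
    """Prescribed periodic flow into (+1) or out of (-1) a node."""

    node: int
    q: Waveform
    label: str
    sign: float = 1.0


@dataclass
class NetworkModel:
    n_nodes: int
    elements: list
    node_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for el in self.elements:
            nodes = []
            if isinstance(el, Resistor):
                nodes = [el.a, el.b]
            elif isinstance(el, Capacitor):
                nodes = [el.a]
            elif isinstance(el, FlowSource):
                nodes = [el.node]
            for n in nodes:
                if n != GROUND and not (0 <= n < self.n_nodes):
                    raise SolverError(f"element {el.label!r} references missing node {n}")


@dataclass(frozen=True)
class SimConfig:
    """Fixed-step integration settings; dt * steps_per_cycle is the period."""

    dt: float = 0.002
    steps_per_cycle: int = 500
    n_cycles: int = 12
    convergence_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.dt <= 0.0 or self.steps_per_cycle < 2 or self.n_cycles < 1:
            raise ValueError("invalid simulation configuration")

    @property
    def period(self) -> float:
        return self.dt * self.steps_per_cycle


@dataclass
class SimResult:
    """Trajectories of all node pressures (mmHg) and element flows (mL/s)."""

    time: np.ndarray
    node_pressure: np.ndarray  # (n_nodes, n_steps)
    element_flow: np.ndarray  # (n_elements, n_steps)
    node_names: list[str]
    element_labels: list[str]
    config: SimConfig
    meta: dict

    @property
    def last_cycle(self) -> slice:
        """Slice selecting the final simulated cycle (steps_per_cycle samples)."""
        n = self.time.size
        return slice(n - self.config.steps_per_cycle, n)

    def cycle(self, k: int) -> slice:
        spc = self.config.steps_per_cycle
        return slice(k * spc, (k + 1) * spc)

    def pressure(self, node_name: str) -> np.ndarray:
        return self.node_pressure[self.node_names.index(node_name)]

    def flow(self, label: str) -> np.ndarray:
        return self.element_flow[self.element_labels.index(label)]


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

CORONARY_BRANCHES = ("LAD", "LCX", "RCA")


def assemble(
    tree: CoronaryTree,
    bcs: dict[str, RCRParams | CoronaryLPNParams],
    lib: WaveformLibrary,
    fluid: FluidProperties | None = None,
    prescribed_flows: dict[str, Waveform] | None = None,
) -> NetworkModel:
    """Build the circuit for a coronary tree with calibrated outlet BCs.

    ``bcs`` maps terminal branch names to outlet parameter sets: the
    AORTA entry must be :class:`RCRParams`; coronary leaves must be
    :class:`CoronaryLPNParams`.  If ``prescribed_flows`` names coronary
    branches, their outlet circuits are replaced by prescribed-flow
    sinks (the waveform-swap experiment's literal reading, where the
    coronary flow shapes are imposed directly).

    Branch junctions are lumped to the nearest endpoint node of the
    parent segment; for the packaged geometries this places the
    coronary ostia at the aortic root.
    """
    fluid = fluid or FluidProperties()
    prescribed_flows = prescribed_flows or {}
    node_names = ["root"]
    inlet: dict[str, int] = {}
    outlet: dict[str, int] = {}

    def new_node(name: str) -> int:
        node_names.append(name)
        return len(node_names) - 1

    by_name = {s.name: s for s in tree.segments}
    aorta = tree.segment("AORTA")
    inlet["AORTA"] = 0
    outlet["AORTA"] = new_node("AORTA:out")
    pending = [s for s in tree.segments if s.parent is not None]
    while pending:
        progressed = False
        remaining = []
        for seg in pending:
            if seg.parent in outlet:
                parent = by_name[seg.parent]
                attach = inlet[seg.parent] if seg.attach_s <= parent.length / 2.0 else outlet[seg.parent]
                inlet[seg.name] = attach
                outlet[seg.name] = new_node(f"{seg.name}:out")
                progressed = True
            else:
                remaining.append(seg)
        if not progressed:
            raise SolverError(f"disconnected segments: {[s.name for s in remaining]}")
        pending = remaining

    elements: list = []
    for seg in tree.segments:
        elements.append(
            Resistor(inlet[seg.name], outlet[seg.name], segment_resistance(seg, fluid),
                     label=f"seg:{seg.name}")
        )

    terminal = [s.name for s in tree.leaves]
    if "AORTA" not in terminal:
        terminal.append("AORTA")  # the aortic outlet is always a terminal

    for branch in terminal:
        node = outlet[branch]
        if branch == "AORTA":
            bc = bcs.get("AORTA")
            if not isinstance(bc, RCRParams):
                raise SolverError("AORTA outlet requires RCRParams")
            n1 = new_node("rcr:mid")
            elements.append(Resistor(node, n1, bc.r_p, label="rcr:rp"))
            elements.append(Capacitor(n1, bc.c, label="rcr:c"))
            elements.append(Resistor(n1, GROUND, bc.r_d, label="rcr:rd"))
        elif branch in prescribed_flows:
            elements.append(
                FlowSource(node, prescribed_flows[branch], label=f"presc:{branch}", sign=-1.0)
            )
        else:
            bc = bcs.get(branch)
            if not isinstance(bc, CoronaryLPNParams):
                raise SolverError(f"coronary outlet {branch!r} is missing a CoronaryLPNParams BC")
            n1 = new_node(f"lpn:{branch}:a")
            n2 = new_node(f"lpn:{branch}:im")
            elements.append(Resistor(node, n1, bc.r_a, label=f"lpn:{branch}:ra"))
            elements.append(Capacitor(n1, bc.c_a, label=f"lpn:{branch}:ca"))
            elements.append(Resistor(n1, n2, bc.r_a_micro, label=f"lpn:{branch}:ramicro"))
            elements.append(Capacitor(n2, bc.c_im, label=f"lpn:{branch}:cim", p_ext=bc.pim))
            elements.append(Resistor(n2, GROUND, bc.r_v, label=f"lpn:{branch}:rv"))

    elements.append(FlowSource(0, lib.aortic_inflow, label="inflow", sign=1.0))

    meta = {
        "root_node": 0,
        "inflow_label": "inflow",
        "terminal_branches": sorted(terminal),
        "coronary_branches": sorted(b for b in terminal if b != "AORTA"),
        "branch_inlet_node": dict(inlet),
        "branch_outlet_node": dict(outlet),
    }
    return NetworkModel(
        n_nodes=len(node_names), elements=elements, node_names=node_names, meta=meta
    )


# ---------------------------------------------------------------------------
# time integration
# ---------------------------------------------------------------------------

def _conductance_matrix(model: NetworkModel, cap_coef: float, dt: float) -> np.ndarray:
    n = model.n_nodes
    g = np.zeros((n, n))
    for el in model.elements:
        if isinstance(el, Resistor):
            if el.r <= 0.0:
                raise SolverError(f"non-positive resistance in {el.label!r}")
            cond = 1.0 / el.r
            g[el.a, el.a] += cond
            if el.b != GROUND:
                g[el.b, el.b] += cond
                g[el.a, el.b] -= cond
                g[el.b, el.a] -= cond
        elif isinstance(el, Capacitor):
            g[el.a, el.a] += cap_coef * el.c / dt
    return g


def _dc_state(model: NetworkModel) -> np.ndarray:
    """Resistive operating point with all sources at their cycle means."""
    n = model.n_nodes
    g = np.zeros((n, n))
    b = np.zeros(n)
    for el in model.elements:
        if isinstance(el, Resistor):
            cond = 1.0 / el.r
            g[el.a, el.a] += cond
            if el.b != GROUND:
                g[el.b, el.b] += cond
                g[el.a, el.b] -= cond
                g[el.b, el.a] -= cond
        elif isinstance(el, FlowSource):
            b[el.node] += el.sign * el.q.mean()
    try:
        return scipy.linalg.solve(g, b)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise SolverError(f"singular DC system: {exc}") from exc


def solve(
    model: NetworkModel, config: SimConfig | None = None, init: str = "dc"
) -> SimResult:
    """Integrate the network over ``config.n_cycles`` cardiac cycles.

    ``init`` selects the initial state: ``"dc"`` (default) starts from
    the resistive cycle-mean operating point, which shortens the
    start-up transient; ``"zero"`` starts from zero pressures and
    uncharged capacitors (used e.g. to observe step responses).

    Raises :class:`SolverError` for period-inconsistent sources,
    singular systems (with the offending node named) and non-finite
    states.
    """
    if init not in ("dc", "zero"):
        raise ValueError("init must be 'dc' or 'zero'")
    config = config or SimConfig()
    period = config.period
    for el in model.elements:
        w = el.q if isinstance(el, FlowSource) else getattr(el, "p_ext", None)
        if w is not None and abs(w.period - period) > 1e-12:
            raise SolverError(
                f"element {el.label!r}: waveform period {w.period} != dt*steps {period}"
            )

    n_steps = config.steps_per_cycle * config.n_cycles
    times = np.arange(1, n_steps + 1) * config.dt

    caps = [el for el in model.elements if isinstance(el, Capacitor)]
    sources = [el for el in model.elements if isinstance(el, FlowSource)]
    resistors = [el for el in model.elements if isinstance(el, Resistor)]

    # precompute source trajectories (CGS)
    q_vals = {el.label: np.asarray(el.q(times), dtype=float) for el in sources}
    pext_vals = {}
    pext_zero = {}
    for el in caps:
        if el.p_ext is not None:
            pext_vals[el.label] = mmhg_to_cgs(np.asarray(el.p_ext(times), dtype=float))
            pext_zero[el.label] = mmhg_to_cgs(float(el.p_ext(0.0)))

    lu = {}
    for scheme, coef in (("be", 1.0), ("tr", 2.0)):
        g = _conductance_matrix(model, coef, config.dt)
        try:
            lu[scheme] = scipy.linalg.lu_factor(g)
        except scipy.linalg.LinAlgError as exc:
            raise SolverError(f"singular conductance matrix: {exc}") from exc
        probe = scipy.linalg.lu_solve(lu[scheme], np.ones(model.n_nodes))
        if not np.all(np.isfinite(probe)):
            bad = model.node_names[int(np.argmax(~np.isfinite(probe)))]
            raise SolverError(f"singular system at node {bad!r}")

    p = _dc_state(model) if init == "dc" else np.zeros(model.n_nodes)
    v_cap = np.zeros(len(caps))
    i_cap = np.zeros(len(caps))
    if init == "dc":
        for j, el in enumerate(caps):
            far = pext_zero.get(el.label, 0.0)
            v_cap[j] = p[el.a] - far

    pressures = np.empty((model.n_nodes, n_steps))
    flows = np.empty((len(model.elements), n_steps))
    el_index = {el.label: k for k, el in enumerate(model.elements)}

    for k in range(n_steps):
        scheme = "be" if k == 0 else "tr"
        coef_fac = 1.0 if scheme == "be" else 2.0
        b = np.zeros(model.n_nodes)
        for el in sources:
            b[el.node] += el.sign * q_vals[el.label][k]
        for j, el in enumerate(caps):
            coef = coef_fac * el.c / config.dt
            hist = coef * v_cap[j] + (i_cap[j] if scheme == "tr" else 0.0)
            b[el.a] += hist
            if el.p_ext is not None:
                b[el.a] += coef * pext_vals[el.label][k]
        p = scipy.linalg.lu_solve(lu[scheme], b)
        if not np.all(np.isfinite(p)):
            bad = model.node_names[int(np.argmax(~np.isfinite(p)))]
            raise SolverError(f"non-finite pressure at node {bad!r}, step {k}")
        for j, el in enumerate(caps):
            coef = coef_fac * el.c / config.dt
            far = pext_vals[el.label][k] if el.p_ext is not None else 0.0
            v_new = p[el.a] - far
            i_new = coef * (v_new - v_cap[j]) - (i_cap[j] if scheme == "tr" else 0.0)
            v_cap[j], i_cap[j] = v_new, i_new
            flows[el_index[el.label], k] = i_new
        pressures[:, k] = p
        for el in resistors:
            pb = 0.0 if el.b == GROUND else p[el.b]
            flows[el_index[el.label], k] = (p[el.a] - pb) / el.r
        for el in sources:
            flows[el_index[el.label], k] = el.sign * q_vals[el.label][k]

    return SimResult(
        time=times,
        node_pressure=cgs_to_mmhg(pressures),
        element_flow=flows,
        node_names=list(model.node_names),
        element_labels=[el.label for el in model.elements],
        config=config,
        meta=dict(model.meta),
    )


# ---------------------------------------------------------------------------
# diagnostics & derived quantities
# ---------------------------------------------------------------------------

def periodic_convergence(result: SimResult) -> float:
    """Cycle-to-cycle relative difference of the final two cycles.

    max over signals of RMS(last - previous) / RMS(last); small values
    justify analyzing the final cycle as the periodic regime.
    """
    if result.config.n_cycles < 2:
        raise SolverError("need at least two simulated cycles")
    last = result.last_cycle
    prev = result.cycle(result.config.n_cycles - 2)
    signals = np.vstack([result.node_pressure, result.element_flow])
    x_last = signals[:, last]
    x_prev = signals[:, prev]
    rms_last = np.sqrt(np.mean(x_last**2, axis=1))
    scale = float(np.max(rms_last))
    worst = 0.0
    for i in range(signals.shape[0]):
        if rms_last[i] < 1e-12 * scale:
            continue
        diff = np.sqrt(np.mean((x_last[i] - x_prev[i]) ** 2))
        worst = max(worst, float(diff / rms_last[i]))
    return worst


def pressure_drop(result: SimResult, branch: str) -> float:
    """Last-cycle mean of (ostial pressure - branch outlet pressure), mmHg."""
    nodes = result.meta["branch_outlet_node"]
    if branch not in nodes:
        raise SolverError(f"unknown branch {branch!r}")
    root = result.node_pressure[result.meta["root_node"], result.last_cycle]
    out = result.node_pressure[nodes[branch], result.last_cycle]
    return float(np.mean(root - out))


def branch_mean_flows(result: SimResult) -> dict[str, float]:
    """Last-cycle mean flow through each terminal branch (mL/s)."""
    return {
        b: float(np.mean(result.flow(f"seg:{b}")[result.last_cycle]))
        for b in result.meta["terminal_branches"]
    }


def flow_fractions(result: SimResult) -> dict[str, float]:
    """Mean last-cycle branch flow as a percentage of mean aortic inflow."""
    q_in = float(np.mean(result.flow(result.meta["inflow_label"])[result.last_cycle]))
    if abs(q_in) < 1e-12:
        raise SolverError("zero mean inflow")
    return {b: 100.0 * q / q_in for b, q in branch_mean_flows(result).items()}


def coronary_share(result: SimResult) -> float:
    """Summed coronary outlet flow as a percentage of mean aortic inflow."""
    fractions = flow_fractions(result)
    return float(sum(fractions[b] for b in result.meta["coronary_branches"]))


def mass_residual(result: SimResult) -> float:
    """Worst-case instantaneous mass-balance residual, relative to peak inflow.

    At every step the prescribed inflow must equal the sum of flows to
    ground plus all capacitor charging currents.
    """
    inflow = result.flow(result.meta["inflow_label"])
    balance = np.zeros_like(inflow)
    # reconstruct the KCL sum over all node equations: sources minus
    # ground-sink resistor currents minus capacitor charging currents
    for label in result.element_labels:
        series = result.flow(label)
        if label == result.meta["inflow_label"]:
            balance += series
        elif label.startswith("presc:"):
            balance += series
        elif label in ("rcr:rd",) or label.endswith(":rv"):
            balance -= series
        elif label == "rcr:c" or label.endswith(":ca") or label.endswith(":cim"):
            balance -= series
    scale = float(np.max(np.abs(inflow)))
    return float(np.max(np.abs(balance)) / scale)
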