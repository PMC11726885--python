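"""Boundary-condition parameter estimation.

Outlet boundary conditions are calibrated from cuff blood pressure and
cardiac output.  The total peripheral resistance is the mean arterial
pressure over the cardiac output; the coronary bed is assumed to carry
a fixed small fraction f of the cardiac output (default 4%), which
fixes the total coronary resistance.  The coronary resistance is then
distributed over the coronary outlets by Murray's law (outlet
conductance proportional to radius^2.6) and each outlet's lump is split
into either a three-element Windkessel (RCR, for the aortic outlet) or
a five-element coronary circuit (R_a - C_a - R_a-micro - C_im(P_im) -
R_v) using fixed literature ratios.

Two estimation modes are provided because the series decomposition
``R_total = R_cor + R_aorta`` combined with the flow-ratio rule
``R_cor : R_aorta = Q_aorta : Q_cor`` does not, taken literally, route
the stated fraction f of the cardiac output through the coronary bed.
The default ``parallel`` mode treats the coronary and aortic beds as
parallel conductances (R_cor = P_mean / Q_cor), which closes the loop
on the f calibration; ``as_printed`` applies the series formula
literally and is retained for fidelity experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import mmhg_to_cgs
from .waveforms import Waveform

__all__ = [
    "CalibrationError",
    "CalibrationInputs",
    "ResistanceEstimate",
    "RCRParams",
    "CoronaryLPNParams",
    "RCR_SPLIT",
    "LPN_RESISTANCE_SPLIT",
    "LPN_COMPLIANCE_SPLIT",
    "MURRAY_EXPONENT",
    "mean_pressure",
    "estimate_resistances",
    "allocate_murray",
    "split_rcr",
    "split_lpn",
]


class CalibrationError(ValueError):
    """Raised for invalid calibration inputs."""


#: proximal : distal split of an RCR outlet resistance
RCR_SPLIT = (0.09, 0.91)
#: arterial : microcirculatory : venous split of a coronary outlet resistance
LPN_RESISTANCE_SPLIT = (0.35, 0.50, 0.15)
#: arterial : intramyocardial split of a coronary outlet compliance
LPN_COMPLIANCE_SPLIT = (0.11, 0.89)
#: radius exponent of the Murray-law conductance allocation
MURRAY_EXPONENT = 2.6
#: default compliance of the aortic RCR outlet (cm^5/dyn)
RCR_COMPLIANCE = 0.001


def mean_pressure(sbp: float, dbp: float) -> float:
    """Mean arterial pressure (mmHg): DBP + pulse pressure / 3.

    The standard clinical estimate for the time-average of the arterial
    pressure waveform from cuff systolic/diastolic readings.
    """
    if not (sbp > dbp > 0.0):
        raise CalibrationError(f"require sbp > dbp > 0, got sbp={sbp}, dbp={dbp}")
    return dbp + (sbp - dbp) / 3.0


@dataclass(frozen=True)
class CalibrationInputs:
    """Clinical inputs of the resistance estimation.

    ``cardiac_output`` is the mean systemic flow Q_total in mL/s;
    ``coronary_fraction`` is f = Q_cor / Q_total.
    """

    sbp: float = 122.0
    dbp: float = 75.0
    cardiac_output: float = 83.3
    coronary_fraction: float = 0.04

    def __post_init__(self) -> None:
        if not (self.sbp > self.dbp > 0.0):
            raise CalibrationError("require sbp > dbp > 0")
        if not (0.0 < self.coronary_fraction < 1.0):
            raise CalibrationError("coronary fraction must lie in (0, 1)")
        if self.cardiac_output <= 0.0:
            raise CalibrationError("cardiac output must be positive")

    @property
    def p_mean(self) -> float:
        """Mean arterial pressure (mmHg)."""
        return mean_pressure(self.sbp, self.dbp)


@dataclass(frozen=True)
class ResistanceEstimate:
    """Total, coronary and aortic resistances in CGS (dyn*s/cm^5)."""

    r_total: float
    r_cor: float
    r_aorta: float
    p_mean: float  # mmHg
    mode: str

    def __post_init__(self) -> None:
        if min(self.r_total, self.r_cor, self.r_aorta) <= 0.0:
            raise CalibrationError("all resistances must be positive")


def estimate_resistances(inputs: CalibrationInputs, mode: str = "parallel") -> ResistanceEstimate:
    """Split the total peripheral resistance into coronary and aortic lumps.

    ``parallel`` (default): the two beds are parallel conductances fed
    at P_mean, so R_cor = P_mean / (f Q) and R_aorta = P_mean / ((1-f) Q).
    ``as_printed``: the series decomposition R_total = R_cor + R_aorta
    with R_cor = (1-f) R_total and R_aorta = f R_total.  Both satisfy
    the flow-ratio rule R_cor : R_aorta = (1-f) : f.
    """
    if mode not in ("parallel", "as_printed"):
        raise CalibrationError(f"unknown mode {mode!r}")
    f = inputs.coronary_fraction
    p_cgs = mmhg_to_cgs(inputs.p_mean)
    q = inputs.cardiac_output
    r_total = p_cgs / q
    if mode == "parallel":
        r_cor = p_cgs / (f * q)
        r_aorta = p_cgs / ((1.0 - f) * q)
    else:
        r_cor = (1.0 - f) * r_total
        r_aorta = f * r_total
    return ResistanceEstimate(r_total=r_total, r_cor=r_cor, r_aorta=r_aorta,
                              p_mean=inputs.p_mean, mode=mode)


def allocate_murray(
    r_cor: float,
    outlets: list[tuple[str, float]],
    exponent: float = MURRAY_EXPONENT,
) -> dict[str, float]:
    """Distribute the coronary resistance over outlets by Murray's law.

    Outlet conductance is proportional to radius**exponent and the
    parallel combination of the returned resistances equals ``r_cor``.
    """
    if not outlets:
        raise CalibrationError("need at least one outlet")
    if r_cor <= 0.0:
        raise CalibrationError("total coronary resistance must be positive")
    radii = np.asarray([r for _, r in outlets], dtype=float)
    if np.any(radii <= 0.0):
        raise CalibrationError("outlet radii must be positive")
    weights = radii**exponent
    total = weights.sum()
    return {name: float(r_cor * total / w) for (name, _), w in zip(outlets, weights)}


@dataclass(frozen=True)
class RCRParams:
    """Three-element Windkessel: proximal R, compliance, distal R (CGS)."""

    r_p: float
    c: float
    r_d: float

    def __post_init__(self) -> None:
        if min(self.r_p, self.c, self.r_d) <= 0.0:
            raise CalibrationError("RCR parameters must be positive")


def split_rcr(r_outlet: float, compliance: float = RCR_COMPLIANCE) -> RCRParams:
    """Split an outlet resistance into the fixed proximal:distal RCR ratio."""
    if r_outlet <= 0.0:
        raise CalibrationError("outlet resistance must be positive")
    fp, fd = RCR_SPLIT
    return RCRParams(r_p=fp * r_outlet, c=compliance, r_d=fd * r_outlet)


@dataclass(frozen=True)
class CoronaryLPNParams:
    """Coronary outlet circuit parameters (CGS) with its P_im source."""

    r_a: float
    r_a_micro: float
    r_v: float
    c_a: float
    c_im: float
    pim: Waveform = field(compare=False)

    def __post_init__(self) -> None:
        if min(self.r_a, self.r_a_micro, self.r_v, self.c_a, self.c_im) <= 0.0:
            raise CalibrationError("LPN parameters must be positive")
        r_tot = self.r_a + self.r_a_micro + self.r_v
        target = np.asarray(LPN_RESISTANCE_SPLIT)
        actual = np.asarray([self.r_a, self.r_a_micro, self.r_v]) / r_tot
        if np.max(np.abs(actual - target) / target) > 1e-9:
            raise CalibrationError("resistances must be in the 0.35:0.50:0.15 ratio")
        c_tot = self.c_a + self.c_im
        target_c = np.asarray(LPN_COMPLIANCE_SPLIT)
        actual_c = np.asarray([self.c_a, self.c_im]) / c_tot
        if np.max(np.abs(actual_c - target_c) / target_c) > 1e-9:
            raise CalibrationError("compliances must be in the 0.11:0.89 ratio")
        if self.pim.kind != "pressure":
            raise CalibrationError("P_im must be a pressure waveform")


def split_lpn(r_outlet: float, c_total: float, pim: Waveform) -> CoronaryLPNParams:
    """Split a coronary outlet resistance/compliance into the fixed LPN ratios."""
    if r_outlet <= 0.0 or c_total <= 0.0:
        raise CalibrationError("outlet resistance and total compliance must be positive")
    fa, fm, fv = LPN_RESISTANCE_SPLIT
    ca, cim = LPN_COMPLIANCE_SPLIT
    return CoronaryLPNParams(
        r_a=fa * r_outlet,
        r_a_micro=fm * r_outlet,
        r_v=fv * r_outlet,
        c_a=ca * c_total,
        c_im=cim * c_total,
        pim=pim,
    )
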