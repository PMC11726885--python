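"""Pulsatile drivers for the coronary network.

The module provides the periodic signals the simulation is driven by:

* an idealized aortic inflow (a non-negative systolic pulse whose
  time-mean equals the cardiac output),
* the characteristic coronary flow shapes -- the left coronary artery
  carries a single, diastole-dominant peak per cycle while the right
  coronary artery carries a double (systolic + diastolic) peak,
* intramyocardial pressure sources (P_im) for the coronary outlet
  circuits, peaking in systole, with the left peak above the right peak
  to reflect the left/right ventricular pressure asymmetry,

together with the left/right waveform swap experiment.

All functional forms are smooth piecewise-cosine constructions: only
the qualitative shapes are physiologically constrained, so the package
uses the simplest C^1 signals with the right peak structure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Waveform",
    "WaveformLibrary",
    "WaveformError",
    "DEFAULT_PIM_PEAKS",
    "constant_waveform",
    "make_aortic_inflow",
    "make_coronary_shape",
    "make_pim",
    "make_library",
    "swap_left_right",
    "count_peaks",
    "write_waveform_csv",
    "read_waveform_csv",
    "write_library",
    "read_library",
]


class WaveformError(ValueError):
    """Raised for malformed or inconsistent waveforms."""


#: default P_im peak pressures (mmHg); left ventricular systolic pressure
#: far exceeds right ventricular systolic pressure.
DEFAULT_PIM_PEAKS = {"left": 120.0, "right": 25.0}


@dataclass(frozen=True)
class Waveform:
    """A periodic sampled signal over one cycle.

    ``t`` holds sample times in [0, period); evaluation outside the
    cycle wraps periodically with linear interpolation between samples
    (and between the last sample and the first sample of the next
    cycle).
    """

    period: float
    t: np.ndarray
    value: np.ndarray
    kind: str = "flow"  # "flow" (mL/s) or "pressure" (mmHg)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "value", v)
        if self.kind not in ("flow", "pressure"):
            raise WaveformError(f"kind must be 'flow' or 'pressure', got {self.kind!r}")
        if self.period <= 0.0:
            raise WaveformError("period must be positive")
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size or t.size < 2:
            raise WaveformError("t and value must be equal-length 1D arrays with >= 2 samples")
        if t[0] != 0.0 or np.any(np.diff(t) <= 0.0) or t[-1] >= self.period:
            raise WaveformError("t must be strictly increasing with t[0]=0 and t[-1] < period")

    def __call__(self, times) -> np.ndarray | float:
        tau = np.mod(times, self.period)
        tp = np.append(self.t, self.period)
        vp = np.append(self.value, self.value[0])
        return np.interp(tau, tp, vp)

    def mean(self) -> float:
        """Cycle-average computed by trapezoidal quadrature with periodic closure."""
        tp = np.append(self.t, self.period)
        vp = np.append(self.value, self.value[0])
        return float(np.trapezoid(vp, tp) / self.period)

    def resample(self, n: int) -> "Waveform":
        tt = np.arange(n) * (self.period / n)
        return Waveform(self.period, tt, np.asarray(self(tt)), self.kind)

    def scaled(self, factor: float) -> "Waveform":
        return dataclasses.replace(self, value=self.value * factor)


def constant_waveform(value: float, period: float, kind: str = "flow") -> Waveform:
    return Waveform(period, np.array([0.0, period / 2.0]), np.array([value, value]), kind)


def _bump(t: np.ndarray, start: float, width: float, period: float) -> np.ndarray:
    """sin^2 pulse on [start, start+width) of the cycle, periodic, zero elsewhere."""
    x = np.mod(t - start, period) / width
    out = np.zeros_like(t)
    inside = x < 1.0
    out[inside] = np.sin(np.pi * x[inside]) ** 2
    return out


def make_aortic_inflow(
    period_T: float,
    cardiac_output: float,
    systole_fraction: float = 0.35,
    n_samples: int = 500,
) -> Waveform:
    """Idealized aortic inflow: a systolic pulse normalized to the cardiac output.

    Parameters
    ----------
    period_T:
        Cardiac cycle duration (s).
    cardiac_output:
        Target time-mean flow (mL/s).
    systole_fraction:
        Fraction of the cycle occupied by the ejection pulse (~1/3).
    """
    if period_T <= 0.0:
        raise WaveformError("period must be positive")
    if cardiac_output <= 0.0:
        raise WaveformError("cardiac output must be positive")
    if not (0.05 < systole_fraction < 0.9):
        raise WaveformError("systole_fraction must lie in (0.05, 0.9)")
    t = np.arange(n_samples) * (period_T / n_samples)
    raw = _bump(t, 0.0, systole_fraction * period_T, period_T)
    wave = Waveform(period_T, t, raw, "flow")
    return wave.scaled(cardiac_output / wave.mean())


def make_coronary_shape(side: str, period_T: float, n_samples: int = 500) -> Waveform:
    """Unit-mean coronary flow shape.

    ``left``: one diastole-dominant peak per cycle (systolic compression
    of the left coronary bed suppresses systolic flow).  ``right``: a
    double peak, one systolic and one diastolic, reflecting the more
    uniform perfusion of the right coronary artery.
    """
    if side not in ("left", "right"):
        raise WaveformError("side must be 'left' or 'right'")
    if period_T <= 0.0:
        raise WaveformError("period must be positive")
    t = np.arange(n_samples) * (period_T / n_samples)
    if side == "left":
        raw = _bump(t, 0.40 * period_T, 0.55 * period_T, period_T)
        raw = raw + 0.05  # small baseline perfusion, keeps the shape strictly positive
    else:
        raw = 0.75 * _bump(t, 0.03 * period_T, 0.30 * period_T, period_T)
        raw += _bump(t, 0.42 * period_T, 0.50 * period_T, period_T)
        raw = raw + 0.05
    wave = Waveform(period_T, t, raw, "flow")
    return wave.scaled(1.0 / wave.mean())


def make_pim(
    side: str,
    period_T: float,
    peak_pressure: float | None = None,
    n_samples: int = 500,
) -> Waveform:
    """Intramyocardial pressure source: a smooth systolic pressure pulse (mmHg)."""
    if side not in ("left", "right"):
        raise WaveformError("side must be 'left' or 'right'")
    if period_T <= 0.0:
        raise WaveformError("period must be positive")
    peak = DEFAULT_PIM_PEAKS[side] if peak_pressure is None else float(peak_pressure)
    if peak < 0.0:
        raise WaveformError("peak pressure must be non-negative")
    t = np.arange(n_samples) * (period_T / n_samples)
    raw = peak * _bump(t, 0.02 * period_T, 0.40 * period_T, period_T)
    return Waveform(period_T, t, raw, "pressure")


@dataclass(frozen=True)
class WaveformLibrary:
    """The five pulsatile drivers of one study configuration."""

    aortic_inflow: Waveform
    left_shape: Waveform
    right_shape: Waveform
    pim_left: Waveform
    pim_right: Waveform
    swapped: bool = False

    def __post_init__(self) -> None:
        periods = {
            self.aortic_inflow.period,
            self.left_shape.period,
            self.right_shape.period,
            self.pim_left.period,
            self.pim_right.period,
        }
        if len(periods) != 1:
            raise WaveformError(f"library members must share one period, got {sorted(periods)}")

    @property
    def period(self) -> float:
        return self.aortic_inflow.period


def make_library(
    period_T: float = 1.0,
    cardiac_output: float = 83.3,
    pim_left_peak: float | None = None,
    pim_right_peak: float | None = None,
    n_samples: int = 500,
) -> WaveformLibrary:
    """Assemble the default waveform library (unswapped)."""
    return WaveformLibrary(
        aortic_inflow=make_aortic_inflow(period_T, cardiac_output, n_samples=n_samples),
        left_shape=make_coronary_shape("left", period_T, n_samples),
        right_shape=make_coronary_shape("right", period_T, n_samples),
        pim_left=make_pim("left", period_T, pim_left_peak, n_samples),
        pim_right=make_pim("right", period_T, pim_right_peak, n_samples),
        swapped=False,
    )


def swap_left_right(lib: WaveformLibrary, swap_pim: bool = False) -> WaveformLibrary:
    """Exchange the left and right coronary members; involution.

    The coronary flow shapes are always exchanged; with ``swap_pim``
    the intramyocardial pressure pair is exchanged as well, so that the
    outlet circuits themselves produce swapped flow shapes.
    """
    return WaveformLibrary(
        aortic_inflow=lib.aortic_inflow,
        left_shape=lib.right_shape,
        right_shape=lib.left_shape,
        pim_left=lib.pim_right if swap_pim else lib.pim_left,
        pim_right=lib.pim_left if swap_pim else lib.pim_right,
        swapped=not lib.swapped,
    )


def count_peaks(w: Waveform) -> int:
    """Number of local maxima per cycle above a 10%-of-range noise guard.

    The signal is treated circularly; a plateau of equal samples at an
    apex (e.g. a smooth peak sampled symmetrically about its maximum)
    counts as a single peak.
    """
    v = w.value
    n = v.size
    if n < 50:
        raise WaveformError("need >= 50 samples per cycle to count peaks")
    rng = float(v.max() - v.min())
    if rng == 0.0:
        return 0
    threshold = float(v.min()) + 0.1 * rng
    d = np.diff(np.append(v, v[0]))  # circular edge slopes, d[i] = v[i+1] - v[i]
    s = np.sign(d).astype(int)
    if not np.any(s):
        return 0
    # forward-fill zero slopes (plateaus inherit the preceding direction)
    filled = s.copy()
    last = filled[np.nonzero(filled)[0][-1]]  # wrap-around initialization
    for i in range(n):
        if filled[i] == 0:
            filled[i] = last
        else:
            last = filled[i]
    count = 0
    for i in range(n):
        if filled[i] == -1 and filled[i - 1] == 1 and v[i] > threshold:
            count += 1
    return count


# ---------------------------------------------------------------------------
# CSV / YAML interchange
# ---------------------------------------------------------------------------

def write_waveform_csv(w: Waveform, path) -> None:
    pd.DataFrame({"t_seconds": w.t, "value": w.value}).to_csv(path, index=False)


def read_waveform_csv(path, period: float, kind: str = "flow") -> Waveform:
    df = pd.read_csv(path)
    t = df["t_seconds"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0.0):
        raise WaveformError(f"{path}: t_seconds must be strictly increasing")
    return Waveform(period, t, df["value"].to_numpy(dtype=float), kind)


_MEMBER_KINDS = {
    "aortic_inflow": "flow",
    "left_shape": "flow",
    "right_shape": "flow",
    "pim_left": "pressure",
    "pim_right": "pressure",
}


def write_library(lib: WaveformLibrary, directory, name: str = "library.yaml") -> Path:
    """Write the five member CSVs plus a YAML manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    for member in _MEMBER_KINDS:
        fname = f"{member}.csv"
        write_waveform_csv(getattr(lib, member), directory / fname)
        files[member] = fname
    manifest = {"period": lib.period, "swapped": lib.swapped, "files": files}
    path = directory / name
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh)
    return path


def read_library(manifest_path) -> WaveformLibrary:
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    period = float(manifest["period"])
    members = {
        member: read_waveform_csv(
            manifest_path.parent / manifest["files"][member], period, kind
        )
        for member, kind in _MEMBER_KINDS.items()
    }
    return WaveformLibrary(swapped=bool(manifest.get("swapped", False)), **members)
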