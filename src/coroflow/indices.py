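"""Wall-shear and velocity-field hemodynamic indices.

From wall-shear time series over one cardiac cycle the module computes

* TAWSS, the time-average of |WSS| (dyne/cm^2) -- the magnitude
  convention makes the index comparable with reported positive
  mean +/- SD values; the signed integral lives inside OSI;
* OSI = 1/2 (1 - |int WSS dt| / int |WSS| dt), in [0, 0.5]: 0 for
  unidirectional shear, 0.5 for perfectly reversing shear;
* ECAP = OSI / TAWSS (cm^2/dyne), a thrombosis-propensity surrogate.

At reduced order, the wall shear of a branch is obtained from the
Poiseuille surrogate tau(t) = 4 mu q(t) / (pi r^3) at sampled arc
positions.  For gridded 3D velocity fields the module provides
pointwise helicity v . (curl v) and the Q-criterion
Q = 1/2 (||Omega||_F^2 - ||S||_F^2), both with second-order central
differences (one-sided second order at boundaries).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IndexError_",
    "WSSSeries",
    "VectorField3D",
    "IndexReport",
    "wss_from_flow",
    "tawss",
    "osi",
    "ecap",
    "helicity",
    "q_criterion",
    "spatial_stats",
]


class IndexError_(ValueError):
    """Raised for malformed index inputs (named to avoid the builtin)."""


@dataclass(frozen=True)
class WSSSeries:
    """Signed wall-shear samples over exactly one cycle at one wall location."""

    location_id: str
    t: np.ndarray
    wss: np.ndarray
    period: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        w = np.asarray(self.wss, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "wss", w)
        if t.ndim != 1 or t.size != w.size or t.size < 2:
            raise IndexError_("t and wss must be equal-length 1D arrays with >= 2 samples")
        if self.period <= 0.0 or np.any(np.diff(t) <= 0.0):
            raise IndexError_("t must be strictly increasing within a positive period")
        if t[-1] - t[0] >= self.period:
            raise IndexError_("samples must span exactly one period (t[-1]-t[0] < T)")


def wss_from_flow(
    q: np.ndarray, radius: float, mu: float, t: np.ndarray, period: float,
    location_id: str = "",
) -> WSSSeries:
    """Poiseuille wall-shear surrogate: tau(t) = 4 mu q(t) / (pi r^3)."""
    if radius <= 0.0:
        raise IndexError_("radius must be positive")
    q = np.asarray(q, dtype=float)
    wss = 4.0 * mu * q / (np.pi * radius**3)
    return WSSSeries(location_id=location_id, t=np.asarray(t, dtype=float),
                     wss=wss, period=period)


def _periodic_integrals(s: WSSSeries) -> tuple[float, float]:
    """Signed and absolute trapezoidal integrals with periodic closure."""
    tp = np.append(s.t, s.t[0] + s.period)
    wp = np.append(s.wss, s.wss[0])
    signed = float(np.trapezoid(wp, tp))
    absolute = float(np.trapezoid(np.abs(wp), tp))
    return signed, absolute


def tawss(s: WSSSeries) -> float:
    """Time-averaged magnitude of wall shear stress over one cycle (dyne/cm^2)."""
    _, absolute = _periodic_integrals(s)
    return absolute / s.period


def osi(s: WSSSeries) -> float:
    """Oscillatory shear index in [0, 0.5]; 0 for a series that never reverses."""
    signed, absolute = _periodic_integrals(s)
    if absolute == 0.0:
        warnings.warn("OSI of an identically zero shear series is defined as 0",
                      stacklevel=2)
        return 0.0
    value = 0.5 * (1.0 - abs(signed) / absolute)
    return float(min(max(value, 0.0), 0.5))


def ecap(tawss_val: float, osi_val: float) -> float:
    """Endothelial cell activation potential OSI / TAWSS (cm^2/dyne)."""
    if tawss_val <= 0.0:
        raise IndexError_("ECAP undefined where TAWSS is zero (degenerate location)")
    return osi_val / tawss_val


# ---------------------------------------------------------------------------
# gridded velocity fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VectorField3D:
    """A 3-component velocity field on a regular lattice.

    ``velocity`` has shape (nx, ny, nz, 3), coordinates in cm,
    velocities in cm/s.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    velocity: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        z = np.asarray(self.z, dtype=float)
        v = np.asarray(self.velocity, dtype=float)
        for name, axis in (("x", x), ("y", y), ("z", z)):
            if axis.ndim != 1 or axis.size < 3:
                raise IndexError_(f"axis {name} needs >= 3 points")
            spacing = np.diff(axis)
            if np.any(spacing <= 0.0) or not np.allclose(spacing, spacing[0]):
                raise IndexError_(f"axis {name} must be uniformly increasing")
        if v.shape != (x.size, y.size, z.size, 3):
            raise IndexError_(
                f"velocity shape {v.shape} != {(x.size, y.size, z.size, 3)}"
            )
        if not np.all(np.isfinite(v)):
            raise IndexError_("velocity must be finite everywhere")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "velocity", v)


def _velocity_gradient(f: VectorField3D) -> np.ndarray:
    """grad[i, j] = d v_i / d x_j on the lattice, shape (nx,ny,nz,3,3)."""
    shape = f.velocity.shape[:3]
    grad = np.empty(shape + (3, 3))
    axes = (f.x, f.y, f.z)
    for i in range(3):
        for j in range(3):
            grad[..., i, j] = np.gradient(
                f.velocity[..., i], axes[j], axis=j, edge_order=2
            )
    return grad


def helicity(f: VectorField3D) -> np.ndarray:
    """Pointwise helicity density v . (curl v), shape (nx, ny, nz)."""
    g = _velocity_gradient(f)
    curl = np.stack(
        [
            g[..., 2, 1] - g[..., 1, 2],
            g[..., 0, 2] - g[..., 2, 0],
            g[..., 1, 0] - g[..., 0, 1],
        ],
        axis=-1,
    )
    return np.einsum("...i,...i->...", f.velocity, curl)


def q_criterion(f: VectorField3D) -> np.ndarray:
    """Q = 1/2 (||Omega||_F^2 - ||S||_F^2); positive where rotation dominates."""
    g = _velocity_gradient(f)
    s = 0.5 * (g + np.swapaxes(g, -1, -2))
    omega = 0.5 * (g - np.swapaxes(g, -1, -2))
    return 0.5 * (
        np.einsum("...ij,...ij->...", omega, omega)
        - np.einsum("...ij,...ij->...", s, s)
    )


# ---------------------------------------------------------------------------
# spatial statistics and reports
# ---------------------------------------------------------------------------

def spatial_stats(values: dict[str, float], grouping: dict[str, str]) -> pd.DataFrame:
    """Per-branch arithmetic mean and population SD of per-location values.

    ``values`` maps location ids to index values; ``grouping`` maps
    location ids to branch names.  Every branch must contribute at
    least one location.
    """
    if not values:
        raise IndexError_("no values to aggregate")
    rows = []
    for loc, val in values.items():
        if loc not in grouping:
            raise IndexError_(f"location {loc!r} has no branch assignment")
        rows.append((grouping[loc], val))
    df = pd.DataFrame(rows, columns=["branch", "value"])
    out = df.groupby("branch")["value"].agg(mean="mean", sd=lambda v: float(np.std(v)))
    return out.reset_index()


@dataclass
class IndexReport:
    """Per-location indices plus per-branch spatial mean +/- SD."""

    locations: pd.DataFrame  # location_id, branch, tawss, osi, ecap
    branches: pd.DataFrame  # branch, tawss_mean, tawss_sd, osi_mean, osi_sd, ecap_mean, ecap_sd

    @classmethod
    def from_series(
        cls, series: list[WSSSeries], grouping: dict[str, str]
    ) -> "IndexReport":
        records = []
        for s in series:
            t_val = tawss(s)
            o_val = osi(s)
            e_val = ecap(t_val, o_val) if t_val > 0.0 else np.nan
            records.append(
                {
                    "location_id": s.location_id,
                    "branch": grouping[s.location_id],
                    "tawss": t_val,
                    "osi": o_val,
                    "ecap": e_val,
                }
            )
        locations = pd.DataFrame.from_records(records)
        parts = []
        for metric in ("tawss", "osi", "ecap"):
            stats = spatial_stats(
                dict(zip(locations["location_id"], locations[metric])), grouping
            ).rename(columns={"mean": f"{metric}_mean", "sd": f"{metric}_sd"})
            parts.append(stats.set_index("branch"))
        branches = pd.concat(parts, axis=1).reset_index()
        return cls(locations=locations, branches=branches)

    def branch_mean(self, metric: str, branch: str) -> float:
        row = self.branches.loc[self.branches["branch"] == branch]
        if row.empty:
            raise IndexError_(f"no branch {branch!r} in report")
        return float(row[f"{metric}_mean"].iloc[0])

    def overall_mean(self, metric: str) -> float:
        """Spatial average of a metric across all locations of all branches."""
        return float(self.locations[metric].mean())
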