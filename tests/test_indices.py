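"""Wall-shear and velocity-field indices: closed forms and invariants."""

import numpy as np
import pytest
import scipy.integrate
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from coroflow import indices as idx


def _series(values, period=1.0, loc="x"):
    values = np.asarray(values, dtype=float)
    t = np.arange(values.size) * (period / values.size)
    return idx.WSSSeries(loc, t, values, period)


def _sin_series(n=500, offset=0.0):
    t = np.arange(n) / n
    return _series(offset + np.sin(2.0 * np.pi * t))


# ---------------------------------------------------------------------------
# TAWSS / OSI / ECAP
# ---------------------------------------------------------------------------

def test_tawss_of_constant_series_is_the_constant():
    assert idx.tawss(_series(np.full(100, 7.5))) == pytest.approx(7.5, rel=1e-12)


def test_tawss_of_sine_is_mean_of_absolute_sine():
    assert idx.tawss(_sin_series()) == pytest.approx(2.0 / np.pi, abs=1e-4)


def test_tawss_is_homogeneous_in_magnitude():
    s = _sin_series(offset=0.3)
    scaled = _series(-4.0 * s.wss)
    assert idx.tawss(scaled) == pytest.approx(4.0 * idx.tawss(s), rel=1e-12)


def test_osi_of_unidirectional_series_is_zero():
    assert idx.osi(_series(np.abs(np.sin(2 * np.pi * np.arange(200) / 200)) + 0.1)) == 0.0


def test_osi_of_zero_mean_sine_is_half():
    assert idx.osi(_sin_series()) == pytest.approx(0.5, abs=1e-12)


def test_osi_of_offset_sine_matches_quadrature_oracle():
    # independent oracle: adaptive quadrature of the defining integrals
    f = lambda t: 0.5 + np.sin(2.0 * np.pi * t)
    signed = scipy.integrate.quad(f, 0.0, 1.0)[0]
    absolute = scipy.integrate.quad(lambda t: abs(f(t)), 0.0, 1.0, limit=200)[0]
    expected = 0.5 * (1.0 - abs(signed) / absolute)
    assert idx.osi(_sin_series(n=2000, offset=0.5)) == pytest.approx(expected, abs=1e-4)


def test_osi_of_identically_zero_series_warns_and_returns_zero():
    with pytest.warns(UserWarning):
        assert idx.osi(_series(np.zeros(100))) == 0.0


@settings(derandomize=True, deadline=None, max_examples=60)
@given(st.lists(st.floats(-100.0, 100.0), min_size=4, max_size=60))
def test_osi_is_bounded_for_arbitrary_series(values):
    assume(any(abs(v) > 1e-9 for v in values))
    val = idx.osi(_series(values))
    assert 0.0 <= val <= 0.5


def test_ecap_identity_and_errors():
    assert idx.ecap(5.0, 0.25) == pytest.approx(0.05, rel=1e-12)
    assert idx.ecap(3.7, 0.0) == 0.0
    s = _sin_series(offset=0.2)
    t_val, o_val = idx.tawss(s), idx.osi(s)
    assert idx.ecap(t_val, o_val) * t_val == pytest.approx(o_val, rel=1e-12)
    with pytest.raises(idx.IndexError_):
        idx.ecap(0.0, 0.1)


def test_wss_from_flow_poiseuille_surrogate():
    t = np.arange(100) / 100.0
    s = idx.wss_from_flow(np.full(100, 10.0), 0.15, 0.04, t, 1.0, "LAD@0")
    expected = 4.0 * 0.04 * 10.0 / (np.pi * 0.15**3)
    assert np.allclose(s.wss, expected, rtol=1e-12)
    zero = idx.wss_from_flow(np.zeros(100), 0.15, 0.04, t, 1.0)
    assert np.all(zero.wss == 0.0)
    doubled = idx.wss_from_flow(np.full(100, 10.0), 0.30, 0.04, t, 1.0)
    assert np.allclose(doubled.wss, expected / 8.0, rtol=1e-12)
    with pytest.raises(idx.IndexError_):
        idx.wss_from_flow(np.ones(100), -0.1, 0.04, t, 1.0)


# ---------------------------------------------------------------------------
# helicity and Q-criterion
# ---------------------------------------------------------------------------

def _lattice(n, lo=-1.0, hi=1.0):
    ax = np.linspace(lo, hi, n)
    return ax, np.meshgrid(ax, ax, ax, indexing="ij")


def test_helicity_vanishes_for_axial_poiseuille_flow():
    ax, (x, y, z) = _lattice(9)
    v = np.zeros(x.shape + (3,))
    v[..., 2] = 2.0 * (1.0 - x**2 - y**2)
    field = idx.VectorField3D(ax, ax, ax, v)
    assert np.max(np.abs(idx.helicity(field))) == 0.0


def test_helicity_of_beltrami_field_equals_speed_squared():
    # ABC flow: curl v = v, so helicity = |v|^2
    ax = np.linspace(0.0, 2.0 * np.pi, 41)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    v = np.stack([np.sin(z) + np.cos(y), np.sin(x) + np.cos(z), np.sin(y) + np.cos(x)], axis=-1)
    field = idx.VectorField3D(ax, ax, ax, v)
    expected = np.einsum("...i,...i->...", v, v)
    assert np.max(np.abs(idx.helicity(field) - expected)) < 5e-2


def test_helicity_scales_quadratically_with_velocity():
    ax = np.linspace(0.0, 2.0 * np.pi, 17)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    v = np.stack([np.sin(z), np.sin(x), np.sin(y)], axis=-1)
    h1 = idx.helicity(idx.VectorField3D(ax, ax, ax, v))
    h3 = idx.helicity(idx.VectorField3D(ax, ax, ax, 3.0 * v))
    assert np.allclose(h3, 9.0 * h1, rtol=1e-12, atol=1e-12)


def test_q_criterion_closed_forms():
    ax, (x, y, z) = _lattice(9)
    omega, gamma = 2.0, 3.0
    rot = np.stack([-omega * y, omega * x, np.zeros_like(x)], axis=-1)
    q_rot = idx.q_criterion(idx.VectorField3D(ax, ax, ax, rot))
    assert np.allclose(q_rot, omega**2, rtol=1e-10)  # rotation dominates everywhere
    shear = np.stack([gamma * y, np.zeros_like(x), np.zeros_like(x)], axis=-1)
    q_shear = idx.q_criterion(idx.VectorField3D(ax, ax, ax, shear))
    assert np.max(np.abs(q_shear)) < 1e-12
    uniform = np.ones(x.shape + (3,))
    assert np.max(np.abs(idx.q_criterion(idx.VectorField3D(ax, ax, ax, uniform)))) < 1e-12


@pytest.mark.parametrize(
    "compute, exact",
    [
        (
            idx.helicity,
            lambda x, y, z: (np.sin(z) + np.cos(y)) ** 2
            + (np.sin(x) + np.cos(z)) ** 2
            + (np.sin(y) + np.cos(x)) ** 2,
        ),
        (idx.q_criterion, lambda x, y, z: -np.cos(x) * np.cos(y)),
    ],
)
def test_field_operators_converge_at_second_order(compute, exact):
    errors = []
    for n in (17, 33):
        ax = np.linspace(0.0, 2.0 * np.pi, n)
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        if compute is idx.helicity:
            v = np.stack(
                [np.sin(z) + np.cos(y), np.sin(x) + np.cos(z), np.sin(y) + np.cos(x)],
                axis=-1,
            )
        else:
            v = np.stack([np.sin(y), np.sin(x), np.zeros_like(x)], axis=-1)
        field = idx.VectorField3D(ax, ax, ax, v)
        errors.append(np.max(np.abs(compute(field) - exact(x, y, z))))
    observed_order = np.log2(errors[0] / errors[1])
    assert observed_order >= 1.8


def test_grid_too_small_is_rejected():
    ax = np.array([0.0, 1.0])
    with pytest.raises(idx.IndexError_):
        idx.VectorField3D(ax, ax, ax, np.zeros((2, 2, 2, 3)))


# ---------------------------------------------------------------------------
# spatial statistics
# ---------------------------------------------------------------------------

def test_spatial_stats_mean_and_population_sd():
    stats = idx.spatial_stats(
        {"a": 1.0, "b": 3.0, "c": 9.0},
        {"a": "LAD", "b": "LAD", "c": "RCA"},
    )
    lad = stats.loc[stats["branch"] == "LAD"].iloc[0]
    assert lad["mean"] == pytest.approx(2.0)
    assert lad["sd"] == pytest.approx(1.0)  # population SD
    rca = stats.loc[stats["branch"] == "RCA"].iloc[0]
    assert rca["sd"] == 0.0  # single location


def test_spatial_stats_is_permutation_invariant():
    values = {"a": 1.0, "b": 3.0, "c": 9.0}
    grouping = {"a": "LAD", "b": "LAD", "c": "LAD"}
    forward = idx.spatial_stats(values, grouping)
    reversed_ = idx.spatial_stats(dict(reversed(values.items())), grouping)
    assert forward.equals(reversed_)


def test_spatial_stats_rejects_unassigned_locations():
    with pytest.raises(idx.IndexError_):
        idx.spatial_stats({"a": 1.0}, {})
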