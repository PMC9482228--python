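"""Bateman curve and first-order cascade against independent oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from volnorm.kinetics import (
    KineticParams,
    SubnetworkParams,
    bateman_array,
    bateman_concentration,
    subnetwork_concentrations,
)


def bateman_direct(t, k_a, k_e, c_0, lag, d):
    """High-precision scalar evaluation of the two-exponential form."""
    b = c_0 * k_a / (k_e - k_a) * (
        np.exp(-k_a * (t - lag)) - np.exp(-k_e * (t - lag)))
    return b + d if b >= 0 else d


@pytest.mark.parametrize("params, t, expected", [
    # core vanishes at t = lag
    (dict(k_a=1, k_e=2, c_0=1, lag=5, d=0.3), 5.0, 0.3),
    # c_0 = 0 forces the core to zero everywhere
    (dict(k_a=0.7, k_e=1.3, c_0=0, lag=0, d=0.7), 3.0, 0.7),
    (dict(k_a=0.7, k_e=1.3, c_0=0, lag=0, d=0.7), 11.0, 0.7),
    # direct evaluation of the closed form
    (dict(k_a=2, k_e=1, c_0=1, lag=0, d=0), 1.0,
     bateman_direct(1.0, 2, 1, 1, 0, 0)),
])
def test_bateman_point_values(params, t, expected):
    p = KineticParams(**params)
    assert bateman_concentration(t, p) == pytest.approx(expected, abs=1e-12)
    assert bateman_concentration(1.0, KineticParams(k_a=2, k_e=1, c_0=1)
                                 ) == pytest.approx(0.46509, abs=1e-5)


def test_bateman_baseline_before_lag():
    """F(t) = d for all t < lag: the core is negative there."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        k_a, k_e = rng.uniform(0.05, 3, 2)
        if abs(k_a - k_e) < 1e-3:
            k_e += 0.01
        p = KineticParams(k_a=k_a, k_e=k_e, c_0=rng.uniform(0.1, 5),
                          lag=rng.uniform(1, 15), d=rng.uniform(0, 3))
        t = np.linspace(-5, p.lag - 1e-6, 23)
        assert np.allclose(bateman_concentration(t, p), p.d)


def test_bateman_equal_rates_limit_matches_two_exponential_form():
    """The analytic k_a == k_e limit joins the two-exponential branch
    continuously: the deviation shrinks first-order in |k_e - k_a|."""
    t = np.linspace(0, 15, 40)
    k = 1.3

    def gap(dk):
        near = KineticParams(k_a=k, k_e=k + dk, c_0=2.0, lag=1.0, d=0.5)
        limit = KineticParams(k_a=k, k_e=k, c_0=2.0, lag=1.0, d=0.5)
        return np.max(np.abs(bateman_concentration(t, near)
                             - bateman_concentration(t, limit)))

    assert gap(1e-4) <= 1e-4
    assert gap(1e-6) <= 1e-6
    # near the switch threshold cancellation noise dominates the gap
    assert gap(1e-8) <= 1e-7


def test_bateman_array_matches_scalar_api():
    rng = np.random.default_rng(11)
    t = np.linspace(0, 15, 20)
    params = rng.uniform((0, 0, 0, 0, 0), (3, 3, 5, 15, 3), size=(8, 5))
    C = bateman_array(t, params)
    for j in range(8):
        p = KineticParams(*params[j])
        assert np.allclose(C[:, j], bateman_concentration(t, p), atol=1e-12)


def test_bateman_rejects_bad_parameters():
    with pytest.raises(ValueError):
        KineticParams(k_a=np.nan, k_e=1, c_0=1)
    with pytest.raises(ValueError):
        KineticParams(k_a=5.0, k_e=1, c_0=1)  # outside default bounds
    with pytest.raises(ValueError):
        bateman_concentration(np.inf, KineticParams(k_a=1, k_e=2, c_0=1))


def _ode_oracle(t_eval, p: SubnetworkParams, rtol=1e-11):
    """Adaptive-step integration of the cascade, tracking elimination."""
    def rhs(_, y):
        A, caf, met, elim = y
        return [-p.k1p * A,
                p.k1p * A - (p.k2p + p.k3p) * caf,
                p.k2p * caf - p.k4p * met,
                p.k3p * caf + p.k4p * met]
    sol = solve_ivp(rhs, (0, max(t_eval.max(), 1e-9)), [p.c0, 0, 0, 0],
                    t_eval=t_eval, rtol=rtol, atol=1e-13, method="LSODA")
    return sol.y


def test_subnetwork_zero_rates_give_zero_concentrations():
    t = np.linspace(0, 15, 10)
    caf, met = subnetwork_concentrations(t, SubnetworkParams(0, 0, 0, 0, 1))
    assert np.allclose(caf, 0) and np.allclose(met, 0)


def test_subnetwork_closed_form_matches_ode_oracle_point():
    p = SubnetworkParams(k1p=1.0, k2p=0.3, k3p=0.2, k4p=0.4, c0=1.0)
    t = np.array([2.0])
    caf, met = subnetwork_concentrations(t, p)
    _, caf_o, met_o, _ = _ode_oracle(t, p)
    assert abs(caf[0] - caf_o[0]) <= 1e-8
    assert abs(met[0] - met_o[0]) <= 1e-8


def test_subnetwork_closed_form_matches_ode_oracle_random_draws():
    rng = np.random.default_rng(3)
    t = np.linspace(0.25, 15, 12)
    worst = 0.0
    for _ in range(100):
        p = SubnetworkParams(*rng.uniform(0.05, 3, 4), c0=rng.uniform(0.2, 5))
        caf, met = subnetwork_concentrations(t, p)
        _, caf_o, met_o, _ = _ode_oracle(t, p)
        worst = max(worst, np.max(np.abs(caf - caf_o)),
                    np.max(np.abs(met - met_o)))
        assert np.all(caf >= -1e-12) and np.all(met >= -1e-12)
    assert worst <= 1e-7


def test_subnetwork_mass_balance():
    """A + Caf + M + eliminated = c0 along the whole trajectory."""
    p = SubnetworkParams(k1p=0.9, k2p=0.5, k3p=0.3, k4p=0.7, c0=2.0)
    t = np.linspace(0.5, 12, 8)
    A, caf, met, elim = _ode_oracle(t, p)
    assert np.allclose(A + caf + met + elim, p.c0, atol=1e-9)
    caf_c, met_c = subnetwork_concentrations(t, p)
    assert np.allclose(caf_c, caf, atol=1e-8)
    assert np.allclose(met_c, met, atol=1e-8)


def test_subnetwork_derived_rate_identities_and_validation():
    p = SubnetworkParams(k1p=1.1, k2p=0.4, k3p=0.25, k4p=0.6)
    assert p.k_a_caf == 1.1
    assert p.k_e_caf == pytest.approx(0.65)
    with pytest.raises(ValueError):
        SubnetworkParams(-0.1, 0.2, 0.3, 0.4)
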