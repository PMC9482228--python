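"""Loss building blocks and the PKM / MIX estimators."""

import numpy as np
import pytest

from volnorm import synthetic as syn
from volnorm.metrics import rrmse
from volnorm.models import (
    MIXNormalizer,
    PKMNormalizer,
    lambda_weight,
    loss_pkm,
    loss_pqn,
    scale,
    transform,
)

# --------------------------------------------------------------------------
# transforms / scalings / lambda


def test_transform_identity_and_log10():
    assert np.allclose(transform([3.0, 7.0], "none"), [3.0, 7.0])
    assert transform(0.0, "log10") == pytest.approx(-8.0)
    assert transform(1.0, "log10") == pytest.approx(4.342944e-9, rel=1e-4)
    with pytest.raises(ValueError):
        transform([-1.0], "log10")


def test_scale_standard_and_mean():
    z = scale([1.0, 2.0, 3.0], "standard")
    assert np.allclose(z, [-1.22474487, 0.0, 1.22474487])
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std() == pytest.approx(1.0)
    assert np.allclose(scale([1.0, 2.0, 3.0], "mean", "log10"), [-1, 0, 1])
    assert np.allclose(scale([1.0, 2.0, 3.0], "mean", "none"),
                       np.array([1, 2, 3]) / 2.0)
    with pytest.raises(ValueError):
        scale([2.0, 2.0], "standard")
    with pytest.raises(ValueError):
        scale([1.0], "standard")


def test_lambda_weight_values_and_monotonicity():
    assert lambda_weight(4) == pytest.approx(0.2)
    assert lambda_weight(1) == pytest.approx(0.5)
    ells = np.arange(1, 200)
    lams = np.array([lambda_weight(e) for e in ells])
    assert np.all(np.diff(lams) < 0) and lams[-1] < 0.01
    with pytest.raises(ValueError):
        lambda_weight(0)


# --------------------------------------------------------------------------
# loss terms


def test_loss_pkm_zero_at_exact_reproduction():
    C = np.array([[1.0, 2.0], [3.0, 4.0]])
    V = np.array([0.5, 2.0])
    M = C * V[:, None]
    for loss in ("cauchy", "max_cauchy", "max_linear"):
        assert loss_pkm(M, C, V, loss=loss) == 0.0


def test_loss_pkm_single_cauchy_residual():
    # one entry, residual r = 1, lambda = 1 -> ln(1 + r^2) = ln 2
    M = np.array([[2.0]])
    C = np.array([[1.0]])
    V = np.array([1.0])
    assert loss_pkm(M, C, V, lam=1.0, loss="cauchy") == pytest.approx(np.log(2))


def test_loss_pkm_matches_brute_force_sum():
    """2x2 toy case against an independent elementwise summation."""
    M = np.array([[1.0, 4.0], [2.0, 0.5]])
    C = np.array([[0.8, 3.0], [2.5, 1.0]])
    V = np.array([1.2, 0.4])
    lam = 0.3
    expected = 0.0
    for i in range(2):
        for j in range(2):
            r = M[i, j] - C[i, j] * V[i]
            expected += np.log(1 + lam * r * r)
    assert loss_pkm(M, C, V, lam=lam, loss="cauchy") == pytest.approx(expected)
    # max_cauchy: maximum of absolute and relative residual, squared
    expected_max = 0.0
    for i in range(2):
        for j in range(2):
            r = M[i, j] - C[i, j] * V[i]
            rr = max(abs(r), abs(r / M[i, j]))
            expected_max += np.log(1 + lam * rr * rr)
    assert loss_pkm(M, C, V, lam=lam, loss="max_cauchy"
                    ) == pytest.approx(expected_max)


def test_loss_pqn_zero_cases():
    q = np.array([0.5, 1.0, 2.0, 1.5])
    # V proportional to q: standard scaling removes scale and location
    assert loss_pqn(3.0 * q, q, lam=0.2) == pytest.approx(0.0, abs=1e-12)
    # lambda = 1: the PQN term vanishes and MIX reduces to PKM
    assert loss_pqn(np.array([1.0, 4.0, 2.0, 0.3]), q, lam=1.0) == 0.0
    # constant V candidate: Var(T(V)) = 0 kills the term smoothly
    assert loss_pqn(np.full(4, 0.7), q, lam=0.2) == pytest.approx(0.0)


def test_loss_pqn_matches_brute_force():
    V = np.array([0.2, 0.9, 0.4])
    q = np.array([0.6, 1.4, 1.1])
    lam = 0.25
    tV, tq = np.log10(V + 1e-8), np.log10(q + 1e-8)
    zV = (tV - tV.mean()) / tV.std()
    zq = (tq - tq.mean()) / tq.std()
    expected = np.sum(np.log1p((1 - lam) * (zV - zq) ** 2 * tV.var()))
    assert loss_pqn(V, q, lam=lam) == pytest.approx(expected)


# --------------------------------------------------------------------------
# fitting


def test_pkm_recovers_volumes_on_noise_free_data(toy_known):
    """ell = n_metabolites = 4, no error: volumes come back essentially
    exactly (rRMSE well under 0.05)."""
    ds = syn.simulate_v1(n_metabolites=4, n_timepoints=20, seed=5,
                         epsilon=1.0)
    est = PKMNormalizer(ell=4, known_params=toy_known, n_starts=10,
                        random_state=9).fit(ds.M, t=ds.t)
    assert rrmse(ds.V, est.V_) < 0.05


def test_mix_with_lambda_one_reduces_to_pkm_bitwise(small_noisy_v1, toy_known):
    ds = small_noisy_v1
    kwargs = dict(ell=4, known_params=toy_known, n_starts=4, random_state=42,
                  loss="max_cauchy", transform="none")
    pkm = PKMNormalizer(**kwargs).fit(ds.M, t=ds.t)
    mix = MIXNormalizer(lam=1.0, **kwargs).fit(ds.M, t=ds.t)
    assert np.array_equal(pkm.V_, mix.V_)
    assert pkm.loss_ == mix.loss_
    assert all(np.array_equal(a.values, b.values) for a, b in
               zip(pkm.kinetic_params_, mix.kinetic_params_))


def test_fit_respects_bounds(small_noisy_v1, toy_known):
    ds = small_noisy_v1
    est = MIXNormalizer(ell=4, known_params=toy_known, n_starts=6,
                        random_state=3, v_bounds=(0.05, 4.0)).fit(ds.M, t=ds.t)
    assert np.all(est.V_ >= 0.05) and np.all(est.V_ <= 4.0)
    for p in est.kinetic_params_:
        assert np.all(p.values >= np.asarray(p.lower) - 1e-9)
        assert np.all(p.values <= np.asarray(p.upper) + 1e-9)


def test_multistart_best_loss_is_monotone_in_starts(small_noisy_v1, toy_known):
    """Nested seed streams: more starts can only improve the best loss."""
    ds = small_noisy_v1
    losses = [PKMNormalizer(ell=4, known_params=toy_known, n_starts=n,
                            random_state=7).fit(ds.M, t=ds.t).loss_
              for n in (2, 5, 9)]
    assert losses[1] <= losses[0] and losses[2] <= losses[1]


def test_duplicated_columns_get_matching_kinetics():
    t = np.linspace(0, 15, 20)
    C = syn.toy_base_concentrations(t)[:, :2]
    V = np.linspace(0.3, 1.2, 20)
    M = C * V[:, None]
    M = np.hstack([M, M])  # metabolites 2,3 duplicate 0,1
    est = PKMNormalizer(ell=4, n_starts=8, random_state=1).fit(M, t=t)
    for j in (0, 1):
        a, b = est.kinetic_params_[j], est.kinetic_params_[j + 2]
        ca = est.predict_concentrations()[:, j]
        cb = est.predict_concentrations()[:, j + 2]
        assert np.allclose(ca, cb, rtol=1e-3, atol=1e-6)


def test_fit_input_validation(toy_known):
    ds = syn.simulate_v1(n_metabolites=6, seed=1)
    with pytest.raises(ValueError):
        PKMNormalizer(ell=1).fit(ds.M, t=ds.t)  # PKM needs >= 2
    with pytest.raises(ValueError):
        MIXNormalizer(ell=4, lam=1.5).fit(ds.M, t=ds.t)
    with pytest.raises(ValueError):
        MIXNormalizer(ell=4).fit(ds.M, t=ds.t[:-1])
    with pytest.raises(ValueError):
        MIXNormalizer(ell=4).fit(ds.M, t=ds.t, q=np.ones(3))
    with pytest.raises(ValueError):
        PKMNormalizer(ell=4, v_bounds=(4.0, 0.05)).fit(ds.M, t=ds.t)


def test_no_size_effect_warning_on_constant_volumes(toy_known):
    """Constant true volumes: the fitter flags that it saw no size
    effect instead of failing."""
    ds = syn.simulate_v1(n_metabolites=6, seed=13, epsilon=1.0,
                         volumes=np.full(20, 1.0))
    with pytest.warns(UserWarning, match="no size effect"):
        est = PKMNormalizer(ell=4, known_params=toy_known, n_starts=6,
                            random_state=2).fit(ds.M, t=ds.t)
    assert est.size_effect_detected_ is False


def test_subnetwork_model_fits_cascade_data():
    """The two-metabolite cascade model (shared rate constants)
    reproduces noise-free cascade data essentially exactly.  Volumes and
    rates are only identified jointly (absorption/elimination can swap
    with a compensating volume rescale), so the check is on the fit, the
    bounds and the derived rate identities, not on parameter equality."""
    from volnorm.kinetics import SubnetworkParams, subnetwork_concentrations
    t = np.linspace(0.5, 15, 20)
    p = SubnetworkParams(k1p=1.0, k2p=0.4, k3p=0.2, k4p=0.5, c0=2.0)
    caf, met = subnetwork_concentrations(t, p)
    V = np.linspace(0.2, 1.5, 20)
    M = np.column_stack([caf, met]) * V[:, None]
    est = PKMNormalizer(ell=2, kinetic_model="subnetwork",
                        known_params={"c0": 2.0}, n_starts=15,
                        random_state=4).fit(M, t=t)
    assert est.loss_ < 1e-10  # exact reproduction of the data
    C_hat = est.predict_concentrations(t)
    assert np.allclose(C_hat * est.V_[:, None], M, rtol=1e-4, atol=1e-8)
    fitted = est.kinetic_params_[0]
    assert fitted.k_a_caf == fitted.k1p
    assert fitted.k_e_caf == pytest.approx(fitted.k2p + fitted.k3p)


def test_prescale_folds_factor_back_into_c0():
    """Unit-max column scaling: fitting happens on M / max, known fixed
    parameters are supplied in scaled units, and the reported kinetics
    carry the factor folded back into c_0 and d (measured-abundance
    scale)."""
    ds = syn.simulate_v1(n_metabolites=4, seed=31, epsilon=1.0)
    factors = ds.M.max(axis=0)
    known = {j: {"c_0": p.c_0 / factors[j], "lag": p.lag,
                 "d": p.d / factors[j]}
             for j, p in enumerate(syn.TOY_PARAMS)}
    est = PKMNormalizer(ell=4, known_params=known, n_starts=10,
                        random_state=6, prescale=True).fit(ds.M, t=ds.t)
    assert np.allclose(est.column_scale_, factors)
    assert rrmse(ds.V, est.V_) < 0.05
    # folded-back c_0 returns to the generating scale
    for j, p in enumerate(syn.TOY_PARAMS):
        assert est.kinetic_params_[j].c_0 == pytest.approx(p.c_0, rel=1e-6)
    C = est.predict_concentrations()
    assert np.allclose(C * est.V_[:, None], ds.M, rtol=0.05, atol=0.02)


def test_estimator_follows_sklearn_param_protocol():
    est = MIXNormalizer(ell=7, n_starts=12)
    params = est.get_params()
    assert params["ell"] == 7 and params["n_starts"] == 12
    est.set_params(ell=5)
    assert est.ell == 5
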