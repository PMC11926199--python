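"""Tensor signal model, log-linear fitting, metrics, and phantoms."""

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from rp2gauge.dti import (PhantomConfig, delta_theta, design_matrix,
                          fit_tensor, mad_metric, make_phantom, make_scheme,
                          metrics_of, simulate_signal)
from rp2gauge.qspace import GradientScheme


def random_psd_tensor(rng, scale=1e-3):
    A = rng.normal(size=(3, 3))
    return (A @ A.T) * scale / 3


def test_simulate_signal_basics():
    sch = make_scheme(10)
    iso = simulate_signal(0.7e-3 * np.eye(3), sch, S0=100.0)
    assert np.allclose(iso, 100.0 * np.exp(-1000.0 * 0.7e-3))
    b0 = GradientScheme(sch.directions, np.zeros(10))
    assert np.allclose(simulate_signal(np.diag([1e-3, 2e-3, 3e-4]), b0, 7.0), 7.0)


def test_signal_antipodally_symmetric(rng):
    D = random_psd_tensor(rng)
    sch = make_scheme(12)
    neg = GradientScheme(-sch.directions, sch.bvalues)
    assert np.allclose(simulate_signal(D, sch), simulate_signal(D, neg))


def test_fit_recovers_tensor_from_six_directions(rng):
    sch = make_scheme(6)
    for _ in range(10):
        D = random_psd_tensor(rng)
        s = simulate_signal(D, sch, 1000.0)
        Df = fit_tensor(s, sch, 1000.0)
        assert np.abs(Df - D).max() < 1e-10


def test_fit_unique_with_six_directions(rng):
    sch = make_scheme(6)
    assert np.linalg.matrix_rank(design_matrix(sch)) == 6
    D = random_psd_tensor(rng)
    s = simulate_signal(D, sch, 1.0)
    # uniqueness: lstsq solution equals the exact solve of the 6x6 system
    B = design_matrix(sch)
    d = np.linalg.solve(B, -np.log(s))
    Df = fit_tensor(s, sch, 1.0)
    assert np.allclose([Df[0, 0], Df[1, 1], Df[2, 2],
                        Df[0, 1], Df[0, 2], Df[1, 2]], d, atol=1e-12)


def test_fit_rank_deficiency_raises():
    sch5 = make_scheme(6).subset(5)
    with pytest.raises(np.linalg.LinAlgError):
        fit_tensor(np.ones(5), sch5, 1.0)
    # six coplanar directions are also rank deficient
    ang = np.linspace(0, np.pi, 6, endpoint=False)
    plane = np.stack([np.cos(ang), np.sin(ang), np.zeros(6)], axis=1)
    with pytest.raises(np.linalg.LinAlgError):
        fit_tensor(np.ones(6), GradientScheme(plane, np.full(6, 1e3)), 1.0)


def test_nonpositive_signal_clamped_with_warning():
    sch = make_scheme(6)
    vals = simulate_signal(0.7e-3 * np.eye(3), sch, 1.0)
    vals[0] = -0.1
    with pytest.warns(UserWarning):
        fit_tensor(vals, sch, 1.0)


def test_fa_extremes_and_oracle(rng):
    assert metrics_of(np.eye(3) * 1e-3).fa == pytest.approx(0.0, abs=1e-12)
    assert metrics_of(np.diag([1.0, 0.0, 0.0])).fa == pytest.approx(1.0)
    for _ in range(10):
        D = random_psd_tensor(rng)
        m = metrics_of(D)
        lam = np.sort(np.linalg.eigvalsh(D))[::-1]
        fa_ref = np.sqrt(1.5 * ((lam - lam.mean()) ** 2).sum() / (lam ** 2).sum())
        assert np.isclose(m.fa, fa_ref, atol=1e-12)
        assert (m.eigenvalues == np.sort(m.eigenvalues)[::-1]).all()


def test_metrics_rotation_invariance_and_v1_covariance(rng):
    D = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
    for _ in range(5):
        R = special_ortho_group.rvs(3, random_state=rng.integers(2 ** 31))
        m0, m1 = metrics_of(D), metrics_of(R @ D @ R.T)
        assert np.isclose(m0.fa, m1.fa, atol=1e-12)
        assert np.allclose(m0.eigenvalues, m1.eigenvalues, atol=1e-15)
        assert delta_theta(m1.v1, R @ m0.v1 / np.linalg.norm(R @ m0.v1)) < 1e-5


def test_degenerate_leading_pair_flagged():
    m = metrics_of(np.diag([1e-3, 1e-3, 0.3e-3]))
    assert not m.v1_stable[()] if m.v1_stable.ndim else not m.v1_stable


def test_delta_theta_identities():
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([0.0, 1.0, 0.0])
    assert delta_theta(e1, e1) == 0.0
    assert delta_theta(e1, -e1) == 0.0
    assert delta_theta(e1, e2) == pytest.approx(90.0)
    with pytest.raises(ValueError):
        delta_theta(e1, 2 * e2)


def test_mad_metric_against_loop_oracle(rng):
    truth = rng.normal(size=(4, 4, 4))
    pred = rng.normal(size=(4, 4, 4))
    mask = rng.random((4, 4, 4)) > 0.4
    got = mad_metric(truth, pred, mask)
    acc = [abs(truth[i] - pred[i]) for i in np.ndindex(4, 4, 4) if mask[i]]
    assert np.isclose(got, np.mean(acc))
    assert mad_metric(truth, truth, mask) == 0.0
    assert mad_metric(truth, truth + 0.1, mask) == pytest.approx(0.1)
    with pytest.raises(ValueError):
        mad_metric(truth, pred, np.zeros_like(mask))


def test_rotation_covariance_of_signal(rng):
    D = random_psd_tensor(rng)
    sch = make_scheme(20)
    R = special_ortho_group.rvs(3, random_state=7)
    rot = GradientScheme(sch.directions @ R.T, sch.bvalues)
    assert np.allclose(simulate_signal(R @ D @ R.T, rot),
                       simulate_signal(D, sch), atol=1e-12)


def test_scheme_first_six_are_icosahedral():
    sch = make_scheme(90)
    six = sch.directions[:6]
    # icosahedral 6-direction scheme: pairwise folded angles all equal
    dots = np.abs(six @ six.T)
    off = dots[~np.eye(6, dtype=bool)]
    assert np.allclose(off, off[0], atol=1e-9)
    assert np.allclose(np.linalg.norm(sch.directions, axis=1), 1.0, atol=1e-9)


def test_phantom_determinism_and_noiseless_exactness():
    cfg = PhantomConfig(shape=(8, 8, 8), noise="none")
    ph = make_phantom(cfg, seed=3)
    assert np.array_equal(ph.signal, ph.clean_signal)
    ph1 = make_phantom(PhantomConfig(shape=(8, 8, 8)), seed=5)
    ph2 = make_phantom(PhantomConfig(shape=(8, 8, 8)), seed=5)
    assert np.array_equal(ph1.signal, ph2.signal)
    assert not np.array_equal(ph1.signal,
                              make_phantom(PhantomConfig(shape=(8, 8, 8)),
                                           seed=6).signal)


def test_phantom_config_validation():
    with pytest.raises(ValueError):
        PhantomConfig(shape=(2, 2, 2)).validate()
    with pytest.raises(ValueError):
        PhantomConfig(noise="poisson").validate()
    with pytest.raises(ValueError):
        PhantomConfig(snr=-1.0).validate()


def test_noiseless_phantom_fa_recovery():
    ph = make_phantom(PhantomConfig(shape=(8, 8, 8), noise="none"), seed=1)
    Df = fit_tensor(ph.signal, ph.scheme, ph.s0)
    fa_err = np.abs(metrics_of(Df).fa - metrics_of(ph.tensors).fa)
    assert fa_err.max() < 1e-8


def test_noise_reduces_with_more_directions():
    """Tensor-estimate error shrinks from 6 to 90 directions at fixed SNR."""
    cfg = PhantomConfig(shape=(8, 8, 8), snr=20.0)
    ph = make_phantom(cfg, seed=11)
    D90 = fit_tensor(ph.signal, ph.scheme, ph.s0)
    D6 = fit_tensor(ph.signal[..., :6], ph.scheme.subset(6), ph.s0)
    rmse90 = np.sqrt(((D90 - ph.tensors) ** 2).mean())
    rmse6 = np.sqrt(((D6 - ph.tensors) ** 2).mean())
    assert rmse90 < rmse6
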