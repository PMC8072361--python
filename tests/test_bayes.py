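"""Bayesian deconvolution: operator, prior, evidence oracle, estimates."""

import numpy as np
import pytest
import scipy.linalg as sla

from mbfdecon import (BayesConfig, Curve, KineticParams,
                      build_delayed_convolution_operator, estimate_bayesian,
                      estimate_bayesian_stack, generate_tissue_curve,
                      log_evidence, posterior_over_grid,
                      second_difference_precision)
from mbfdecon.bayes import _DATA_SCALE, _RIDGE, _n_nodes


# ------------------------------------------------------------- operator

def test_operator_impulse_reproduces_delayed_aif(aif):
    delay = 1.4
    M = build_delayed_convolution_operator(aif, delay)
    k = np.zeros(M.shape[1])
    k[0] = 1.0 / aif.dt
    out = M @ k
    expected = aif.shifted(2).values
    assert np.allclose(out, expected, atol=1e-15)


def test_operator_causality(aif):
    M = build_delayed_convolution_operator(aif, 0.0, n_nodes=30)
    assert np.allclose(np.triu(M, k=1), 0.0)


def test_operator_matches_oversampled_convolution(aif):
    """Staircase operator vs x20 sample-held convolution on a smooth k.

    The operator uses a left-endpoint rule for the AIF, so the two differ
    by at most a half-sample lag of C_a; on the default AIF that bounds
    the disagreement at a few percent of peak.
    """
    nodes = _n_nodes(aif, 0.0, 40.0)
    t_nodes = aif.dt * np.arange(nodes)
    k = np.exp(-t_nodes / 8.0) / 60.0
    M = build_delayed_convolution_operator(aif, 0.0, nodes)
    coarse = M @ k
    os = 20
    dtf = aif.dt / os
    nf = (len(aif) - 1) * os + 1
    tf = dtf * np.arange(nf)
    ca_f = np.interp(tf, aif.times, aif.values)
    k_f = np.repeat(k, os)[:nf]
    fine = (np.convolve(ca_f, k_f)[:nf] * dtf)[::os]
    scale = np.max(np.abs(fine))
    assert np.max(np.abs(coarse - fine)) / scale < 0.07


def test_operator_delay_bounds(aif):
    with pytest.raises(ValueError):
        build_delayed_convolution_operator(aif, -0.1)
    with pytest.raises(ValueError):
        build_delayed_convolution_operator(aif, aif.duration + 1.0)


# ------------------------------------------------------ smoothness prior

def test_second_difference_annihilates_linear_sequences():
    P = second_difference_precision(12, 3.7)
    r = 0.4 + 1.3 * np.arange(12)
    assert r @ P @ r == pytest.approx(0.0, abs=1e-9)


def test_second_difference_minimal_and_linear_in_eps():
    P3 = second_difference_precision(3, 1.0)
    d2 = np.array([1.0, -2.0, 1.0])
    assert np.allclose(P3, np.outer(d2, d2))
    assert np.allclose(second_difference_precision(7, 4.0),
                       2 * second_difference_precision(7, 2.0))
    with pytest.raises(ValueError):
        second_difference_precision(2, 1.0)
    with pytest.raises(ValueError):
        second_difference_precision(5, 0.0)


# ------------------------------------------------------ evidence oracle

def _small_instance(bf, delay, eps, seed=0):
    """An 8-sample curve pair with a 4-node residue support."""
    t = 0.7 * np.arange(8)
    ca = np.array([0.0, 1.0, 4.0, 5.5, 3.5, 1.5, 0.6, 0.2]) * 1e-3
    aif = Curve(t, ca)
    cfg = BayesConfig(residue_support_max=2.2)
    m = _n_nodes(aif, delay, cfg.residue_support_max)
    M = build_delayed_convolution_operator(aif, delay, m)
    residue = np.array([1.0, 0.7, 0.45, 0.3])[:m]
    rng = np.random.default_rng(seed)
    beta = bf / 60.0
    y = beta * M @ residue + rng.normal(0.0, 2e-4, size=8)
    return Curve(t, y), aif, cfg


def _brute_force_log_evidence(tissue, aif, bf, delay, eps, cfg,
                              n_r=41, n_sigma=160):
    """Tensor-grid quadrature over the free residue nodes and sigma.

    Replicates the model definition (operator, ridge-stabilized prior,
    Jeffreys sigma prior) but integrates numerically instead of using the
    closed form under test.
    """
    m = _n_nodes(aif, delay, cfg.residue_support_max)
    M = build_delayed_convolution_operator(aif, delay, m) * _DATA_SCALE
    y = tissue.values * _DATA_SCALE
    n = y.size
    m0, N = M[:, 0], M[:, 1:]
    K = second_difference_precision(m, 1.0)
    K11 = K[1:, 1:] + _RIDGE * np.trace(K[1:, 1:]) * np.eye(m - 1)
    k10 = K[1:, 0]
    mu_p = -sla.solve(K11, k10, assume_a="pos")
    Q = eps * K11
    beta = bf / 60.0
    z = y - beta * m0

    # quadrature coordinates: center on the penalized least-squares point
    # and decorrelate with the local curvature's Cholesky factor (the
    # posterior is strongly correlated, so an axis-aligned grid aliases)
    H = beta ** 2 * (N.T @ N) + Q
    r_hat = sla.solve(H, beta * N.T @ z + Q @ mu_p, assume_a="pos")
    sse = float(np.sum((z - beta * N @ r_hat) ** 2)
                + (r_hat - mu_p) @ Q @ (r_hat - mu_p))
    sigma_hat = np.sqrt(sse / n)
    L = np.linalg.cholesky(sla.inv(H))
    sign_l, logdet_l = np.linalg.slogdet(L)

    sign_q, logdet_q = np.linalg.slogdet(Q)
    sigmas = np.geomspace(sigma_hat / 15, sigma_hat * 15, n_sigma)
    log_f = np.full(n_sigma, -np.inf)
    axes1d = np.linspace(-7.0, 7.0, n_r)
    step = axes1d[1] - axes1d[0]
    U = np.stack(np.meshgrid(*([axes1d] * (m - 1)), indexing="ij"),
                 axis=-1).reshape(-1, m - 1)
    for i, s in enumerate(sigmas):
        flat = r_hat[None, :] + s * (U @ L.T)
        resid = z[None, :] - beta * flat @ N.T
        quad = np.einsum("ij,ij->i", resid, resid)
        dr = flat - mu_p
        quad += np.einsum("ij,jk,ik->i", dr, Q, dr)
        integrand = np.exp(-(quad - quad.min()) / (2 * s * s))
        val = integrand.reshape((n_r,) * (m - 1))
        for _ in range(m - 1):
            val = np.trapezoid(val, dx=step, axis=0)
        # du volume element: |det(s L)|
        log_ir = (np.log(val) - quad.min() / (2 * s * s)
                  + (m - 1) * np.log(s) + logdet_l)
        # Gaussian prior normalization |Q|^(1/2) (2 pi s^2)^-(m-1)/2,
        # likelihood (2 pi s^2)^(-n/2), Jeffreys 1/s
        log_f[i] = (log_ir + 0.5 * logdet_q
                    - 0.5 * (n + m - 1) * np.log(2 * np.pi * s * s)
                    - np.log(s))
    # trapezoid in sigma via shifted exponentials
    top = log_f.max()
    total = np.trapezoid(np.exp(log_f - top), x=sigmas)
    return float(top + np.log(total))


@pytest.mark.parametrize("bf,delay,eps", [
    (2.4, 0.35, 0.8),
    (1.0, 0.0, 10.0),
    (4.0, 0.7, 0.05),
])
def test_log_evidence_matches_quadrature_oracle(bf, delay, eps):
    tissue, aif, cfg = _small_instance(bf, delay, eps)
    closed = log_evidence(tissue, aif, bf, delay, eps, cfg)
    brute = _brute_force_log_evidence(tissue, aif, bf, delay, eps, cfg)
    assert closed == pytest.approx(brute, abs=1e-3)


def test_evidence_prefers_generating_flow():
    tissue, aif, cfg = _small_instance(2.4, 0.35, 0.8, seed=3)
    le_true = log_evidence(tissue, aif, 2.4, 0.35, 0.8, cfg)
    le_double = log_evidence(tissue, aif, 4.8, 0.35, 0.8, cfg)
    assert le_true >= le_double


def test_evidence_translation_invariant():
    # compactly supported curves: shifting both by s samples is exact
    t = 0.7 * np.arange(24)
    ca = np.zeros(24)
    ca[2:9] = np.array([0.5, 2.0, 4.0, 3.0, 1.5, 0.6, 0.2]) * 1e-3
    aif = Curve(t, ca)
    cfg = BayesConfig(residue_support_max=2.2)
    m = _n_nodes(aif, 0.0, cfg.residue_support_max)
    M = build_delayed_convolution_operator(aif, 0.0, m)
    y = (2.0 / 60.0) * M @ np.array([1.0, 0.6, 0.4, 0.25])
    tissue = Curve(t, y)
    shift = 3
    aif_s = aif.shifted(shift)
    tissue_s = tissue.shifted(shift)
    for eps in (0.1, 10.0):
        a = log_evidence(tissue, aif, 2.0, 0.0, eps, cfg)
        b = log_evidence(tissue_s, aif_s, 2.0, 0.0, eps, cfg)
        assert a == pytest.approx(b, abs=1e-6)


# ---------------------------------------------------------- posterior

def test_posterior_normalization(aif, tissue):
    post = posterior_over_grid(tissue, aif)
    total = (post.posterior * post.weights).sum()
    assert total == pytest.approx(1.0, abs=1e-8)
    assert np.all(post.posterior >= 0)


def test_posterior_mode_at_generating_cell(aif):
    # noiseless single-compartment curve at bf = 2, delay = 1.4 s
    k = KineticParams(Fp=2.0, Vp=0.1, PS=0.0)
    ct = generate_tissue_curve(aif, k, delay=1.4)
    cfg = BayesConfig()
    post = posterior_over_grid(ct, aif, cfg)
    mode_bf, mode_delay, _ = post.mode()
    assert mode_bf == pytest.approx(
        cfg.bf_grid[np.argmin(np.abs(cfg.bf_grid - 2.0))])
    assert mode_delay == pytest.approx(1.4)


def test_posterior_means_inside_grid_hull(aif, tissue):
    post = posterior_over_grid(tissue, aif)
    cfg = post.config
    for name, grid in (("bf", cfg.bf_grid), ("delay", cfg.delay_grid),
                       ("eps", cfg.eps_grid)):
        mean = post.mean(name)
        assert grid[0] <= mean <= grid[-1]


# ----------------------------------------------------------- estimates

def test_estimate_small_bias_on_noiseless_midrange_tile(aif):
    ct = generate_tissue_curve(aif, KineticParams(Fp=2.0, Vp=0.1))
    est = estimate_bayesian(ct, aif)
    assert abs(est.mbf - 2.0) < 0.5


def test_estimate_stable_under_bolus_delay(aif):
    ct0 = generate_tissue_curve(aif, KineticParams(Fp=2.0, Vp=0.1))
    ct28 = generate_tissue_curve(aif, KineticParams(Fp=2.0, Vp=0.1),
                                 delay=2.8)
    e0 = estimate_bayesian(ct0, aif)
    e28 = estimate_bayesian(ct28, aif)
    assert abs(e28.mbf - e0.mbf) / e0.mbf < 0.05


def test_estimate_central_volume_identity(aif, tissue):
    est = estimate_bayesian(tissue, aif)
    assert est.mbv == pytest.approx(est.mbf * est.mtt / 60.0, rel=1e-12)
    assert est.residue_mean[0] == 1.0
    assert est.residue_times[-1] <= 40.0 + 1e-9


def test_estimate_delay_recovery_with_noise(aif):
    rng = np.random.default_rng(3)
    cases = [(2.0, 0.08, 3.5), (3.9, 0.1, 2.8), (1.24, 0.08, 0.0)]
    for fp, vp, d in cases:
        ct = generate_tissue_curve(aif, KineticParams(Fp=fp, Vp=vp), delay=d)
        y = ct.values + rng.normal(0, 7.57e-6, len(ct))
        out = estimate_bayesian_stack(y[None, :], aif)
        assert abs(out["delay"][0] - d) <= 0.7 + 1e-9


def test_estimate_approximate_scale_equivariance(aif, tissue):
    rng = np.random.default_rng(9)
    y = tissue.values + rng.normal(0, 7.57e-6, len(tissue))
    out1 = estimate_bayesian_stack(y[None, :], aif)
    out2 = estimate_bayesian_stack(1.5 * y[None, :], aif)
    assert out2["mbf"][0] == pytest.approx(1.5 * out1["mbf"][0], rel=0.05)


def test_stack_matches_single_curve_path(aif, tissue):
    rng = np.random.default_rng(4)
    y = tissue.values + rng.normal(0, 7.57e-6, len(tissue))
    est = estimate_bayesian(Curve(aif.times, y), aif)
    out = estimate_bayesian_stack(y[None, :], aif)
    assert out["mbf"][0] == pytest.approx(est.mbf, rel=1e-9)
    assert out["delay"][0] == pytest.approx(est.delay, abs=1e-9)
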