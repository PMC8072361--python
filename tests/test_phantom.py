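"""Phantom generation: AIF shape, 2CXM kinetics, noise and containers."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import mbfdecon as mb
from mbfdecon import (AIFParams, Curve, KineticParams, PhantomSpec,
                      build_phantom, generate_tissue_curve, load_phantom,
                      save_phantom, synthesize_aif)
from mbfdecon.phantom import _tcxm_rate_system, tcxm_impulse_response


# ---------------------------------------------------------------------- AIF

def test_aif_peak_matches_clinical_calibration(aif):
    # stress peak arterial concentration ~5.86 mmol/L
    assert aif.values.max() == pytest.approx(5.86e-3, rel=0.01)
    assert np.all(aif.values >= 0)


def test_aif_quiet_during_early_baseline(aif, aif_params):
    # the first-pass Gaussian is ~1e-10 of peak here; the floor is set by
    # the broad recirculation Gaussian's left tail (~4e-5 of peak)
    early = aif.values[aif.times <= aif_params.baseline_duration - 3 * aif_params.first_pass_sd]
    assert early.size > 0
    assert np.all(early < 1e-4 * aif.values.max())


def test_aif_single_gaussian_closed_form():
    p = AIFParams(recirc_amplitude_fraction=0.0)
    aif = synthesize_aif(p, duration=60.0, dt=0.1)
    # value at time_to_peak + 2 sd equals peak * exp(-2)
    idx = int(round((p.time_to_peak + 2 * p.first_pass_sd) / 0.1))
    expected = p.peak_concentration * np.exp(-2.0)
    assert aif.values[idx] == pytest.approx(expected, abs=1e-12)


def test_aif_invalid_parameters():
    with pytest.raises(ValueError):
        AIFParams(first_pass_sd=-1.0)
    with pytest.raises(ValueError):
        synthesize_aif(AIFParams(), duration=60.0, dt=-0.7)
    with pytest.raises(ValueError):
        synthesize_aif(AIFParams(), duration=3.0, dt=0.7)  # < 10 samples


# ------------------------------------------------------------------- 2CXM

def test_impulse_response_single_compartment_limit():
    k = KineticParams(Fp=2.0, Vp=0.1, PS=0.0)
    t = np.arange(0, 60, 0.7)
    h = tcxm_impulse_response(k, t)
    expected = (2.0 / 60.0) * np.exp(-(2.0 / 0.1 / 60.0) * t)
    assert np.allclose(h, expected, rtol=1e-12)


_PULSE_WIDTH = 1e-3  # s; narrow rectangular unit-area input


def _ode_impulse_oracle(k: KineticParams, times: np.ndarray) -> np.ndarray:
    """Stiff ODE integration of the exchange system with a narrow pulse.

    The response to a width-w unit pulse sampled at t+w equals the average
    of the true impulse response over [t, t+w], i.e. h(t + w/2) + O(w^2),
    so callers should compare against h evaluated at times + w/2.
    """
    A, b, c = _tcxm_rate_system(k)
    w = _PULSE_WIDTH

    def rhs_pulse(t, x):
        return A @ x + b / w

    def rhs_free(t, x):
        return A @ x

    s1 = solve_ivp(rhs_pulse, (0.0, w), [0.0, 0.0], method="LSODA",
                   rtol=1e-10, atol=1e-16, max_step=w / 10)
    s2 = solve_ivp(rhs_free, (w, float(times[-1]) + 1.0), s1.y[:, -1],
                   method="LSODA", rtol=1e-10, atol=1e-16,
                   t_eval=np.asarray(times) + w)
    return c @ s2.y


def test_impulse_response_matches_ode_oracle():
    k = KineticParams(Fp=1.0, Vp=0.1, PS=0.95, Visf=0.2)
    t = np.arange(0, 60, 0.7)
    h = tcxm_impulse_response(k, t + _PULSE_WIDTH / 2)
    oracle = _ode_impulse_oracle(k, t)
    assert np.max(np.abs(h - oracle)) / h.max() < 1e-5


def test_impulse_response_random_draws_match_ode_oracle():
    rng = np.random.default_rng(42)
    t = np.arange(0, 60, 0.7)
    for _ in range(20):
        k = KineticParams(Fp=float(rng.uniform(0.48, 3.9)),
                          Vp=float(rng.uniform(0.04, 0.1)),
                          PS=float(rng.uniform(0.3, 2.0)),
                          Visf=float(rng.uniform(0.1, 0.4)))
        h = tcxm_impulse_response(k, t + _PULSE_WIDTH / 2)
        oracle = _ode_impulse_oracle(k, t)
        assert np.max(np.abs(h - oracle)) / h.max() < 1e-4


def test_impulse_response_area_is_distribution_volume():
    # central volume: integral of h = Vp + Visf, so MTT = (Vp+Visf)/Fp
    k = KineticParams(Fp=2.0, Vp=0.07, PS=0.95, Visf=0.2)
    t = np.arange(0, 3000, 0.01)
    area = np.trapezoid(tcxm_impulse_response(k, t), dx=0.01)
    assert area == pytest.approx(k.Vp + k.Visf, rel=1e-6)


def test_impulse_response_initial_value_and_shape(aif):
    k = KineticParams(Fp=3.9, Vp=0.04)
    h = tcxm_impulse_response(k, aif.times)
    assert h[0] == pytest.approx(3.9 / 60.0, rel=1e-12)
    assert np.all(h >= 0)
    assert np.all(np.diff(h[5:]) <= 1e-18)  # eventually decreasing


def test_kinetic_params_validation():
    with pytest.raises(ValueError):
        KineticParams(Fp=0.0, Vp=0.1)
    with pytest.raises(ValueError):
        KineticParams(Fp=1.0, Vp=0.9, Visf=0.2)  # Vp + Visf >= 1
    with pytest.raises(ValueError):
        KineticParams(Fp=1.0, Vp=0.1, PS=-0.1)


# ---------------------------------------------------------- tissue curves

def test_tissue_curve_zero_aif_gives_zero(midrange_kinetics):
    aif0 = Curve(np.arange(20) * 0.7, np.zeros(20))
    ct = generate_tissue_curve(aif0, midrange_kinetics)
    assert np.all(ct.values == 0)


def test_tissue_curve_delay_is_integer_shift(aif, midrange_kinetics):
    base = generate_tissue_curve(aif, midrange_kinetics, delay=0.0)
    delayed = generate_tissue_curve(aif, midrange_kinetics, delay=1.4)
    assert np.allclose(delayed.values, base.shifted(2).values, rtol=0,
                       atol=1e-18)
    with pytest.raises(ValueError):
        generate_tissue_curve(aif, midrange_kinetics, delay=1.0)
    with pytest.raises(ValueError):
        generate_tissue_curve(aif, midrange_kinetics, delay=-0.7)


def test_tissue_curve_oversampling_converges(aif, midrange_kinetics):
    c20 = generate_tissue_curve(aif, midrange_kinetics, oversample=20)
    c200 = generate_tissue_curve(aif, midrange_kinetics, oversample=200)
    assert abs(c20.values.max() - c200.values.max()) / c200.values.max() < 0.01


def test_tissue_curve_causal(aif, midrange_kinetics):
    ct = generate_tissue_curve(aif, midrange_kinetics, delay=2.8)
    onset = np.argmax(aif.values > 1e-3 * aif.values.max())
    assert np.all(np.abs(ct.values[:onset + 4]) < 1e-3 * ct.values.max())


# --------------------------------------------------------------- phantom

def test_phantom_structure_and_determinism():
    spec = PhantomSpec(realizations_per_tile=3, seed=5)
    ds = build_phantom(spec)
    assert ds.n_tiles == 100
    assert ds.curves.shape == (10, 10, 3, 86)
    assert ds.truth_mbf_map.shape == ds.truth_vp_map.shape
    ds2 = build_phantom(spec)
    assert np.array_equal(ds.curves, ds2.curves)


def test_phantom_truth_equals_plasma_flow(small_phantom):
    truth = small_phantom.truth_mbf_flat()
    fp = np.asarray(small_phantom.spec.fp_values)
    assert set(np.unique(truth)) == set(fp)
    # flattened stack aligns with tile order
    nf, nv, nr, _ = small_phantom.curves.shape
    assert truth[0] == fp[0] and truth[-1] == fp[-1]
    assert len(truth) == nf * nv * nr


def test_phantom_zero_noise_realizations_identical():
    spec = PhantomSpec(fp_values=[1.0, 2.0], vp_values=[0.05, 0.08],
                       noise_sigma=0.0, realizations_per_tile=3, seed=1)
    ds = build_phantom(spec)
    assert np.all(ds.curves == ds.curves[:, :, :1, :])


def test_phantom_noise_statistics():
    spec = PhantomSpec(fp_values=[2.0], vp_values=[0.07],
                       realizations_per_tile=10_000, seed=2)
    ds = build_phantom(spec)
    noise = ds.curves[0, 0] - ds.clean[0, 0]
    sigma = spec.noise_sigma
    n = noise.size
    assert abs(noise.mean()) < 3 * sigma / np.sqrt(n)
    assert abs(noise.std() - sigma) < 3 * sigma / np.sqrt(2 * n)


def test_phantom_delay_validation():
    with pytest.raises(ValueError):
        PhantomSpec(delay_s=1.0)  # not a multiple of 0.7


def test_phantom_hdf5_round_trip(tmp_path, small_phantom):
    p = tmp_path / "phantom.h5"
    save_phantom(small_phantom, p)
    ds = load_phantom(p)
    assert np.array_equal(ds.curves, small_phantom.curves)
    assert np.array_equal(ds.aif.values, small_phantom.aif.values)
    assert ds.spec == small_phantom.spec


def test_noise_scale_constants():
    assert mb.NOISE_SCALES["myocardium"] == 7.57e-6
    assert mb.NOISE_SCALES["segment"] == 7.83e-6
    assert mb.NOISE_SCALES["voxel"] == 1.33e-5
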