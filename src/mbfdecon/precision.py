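"""Wild-bootstrap precision of MBF estimates.

Because a single in-vivo curve has no ground truth, precision is measured
by resampling: residuals e* = C_t - C_t_hat are sign-flipped pointwise
with Rademacher draws (optionally scaled by heteroscedasticity-consistent
leverage weights a_i), added back to the fitted curve, and the estimator
is re-run on each perturbed curve.  The sample SD of the replicate MBFs is
the reported precision.  The representative curve of a region is the
member closest (in summed squared difference) to the region-mean curve.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np

from . import bayes as _bayes
from . import fermi as _fermi
from .curves import Curve

__all__ = [
    "BootstrapConfig",
    "PrecisionResult",
    "representative_curve",
    "wild_bootstrap_replicates",
    "bootstrap_precision",
]


@dataclasses.dataclass(frozen=True)
class BootstrapConfig:
    """Wild-bootstrap settings.

    weight_scheme : 'hc2', 'hc3' or 'unit'.  The leverage-based schemes
    need a model Jacobian (available for the Fermi fits) and fall back to
    unit weights otherwise.
    """

    n_rep: int = 1000
    weight_scheme: str = "hc3"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rep < 2:
            raise ValueError("n_rep must be >= 2")
        if self.weight_scheme not in ("hc2", "hc3", "unit"):
            raise ValueError("weight_scheme must be hc2, hc3 or unit")


@dataclasses.dataclass
class PrecisionResult:
    """Replicate summary: the reported precision is ``mbf_sd``."""

    mbf_mean: float
    mbf_sd: float
    replicate_mbfs: np.ndarray
    n_failed: int = 0
    warning: Optional[str] = None


def representative_curve(region_curves: Sequence[Curve]) -> tuple:
    """Index and member curve minimizing sum_t (mean(t) - C_t(t))^2.

    Ties break toward the lowest index.
    """
    curves = list(region_curves)
    if not curves:
        raise ValueError("empty region")
    t0 = curves[0].times
    for c in curves[1:]:
        if np.max(np.abs(c.times - t0)) > 1e-9:
            raise ValueError("region curves must share the time grid")
    stack = np.array([c.values for c in curves])
    mean = stack.mean(axis=0)
    scores = ((mean[None, :] - stack) ** 2).sum(axis=1)
    idx = int(np.argmin(scores))
    return idx, curves[idx]


def _leverage_weights(jac: np.ndarray, scheme: str) -> np.ndarray:
    """HC2/HC3 weights 1/sqrt(1-h) or 1/(1-h) from a model Jacobian."""
    q, _ = np.linalg.qr(jac)
    h = np.clip((q * q).sum(axis=1), 0.0, 1.0 - 1e-8)
    if scheme == "hc2":
        return 1.0 / np.sqrt(1.0 - h)
    return 1.0 / (1.0 - h)


def wild_bootstrap_replicates(fitted: Curve, residuals: np.ndarray,
                              config: BootstrapConfig,
                              weights: Optional[np.ndarray] = None
                              ) -> np.ndarray:
    """Generate n_rep perturbed curves fitted + a * lambda * e*.

    lambda is i.i.d. Rademacher (+/-1 with p = 1/2) per time point and
    replicate; ``weights`` (a_i) defaults to 1.  Returns an array of shape
    (n_rep, n_times) aligned with ``fitted``.
    """
    e = np.asarray(residuals, dtype=float)
    if e.size != len(fitted):
        raise ValueError("residuals must match the fitted curve length")
    a = np.ones_like(e) if weights is None else np.asarray(weights, float)
    rng = np.random.default_rng(config.seed)
    lam = rng.integers(0, 2, size=(config.n_rep, e.size)) * 2 - 1
    return fitted.values[None, :] + lam * (a * e)[None, :]


def bootstrap_precision(tissue: Curve, aif: Curve, estimator: str,
                        config: Optional[BootstrapConfig] = None,
                        fermi_config: Optional[_fermi.FermiFitConfig] = None,
                        bayes_config: Optional[_bayes.BayesConfig] = None
                        ) -> PrecisionResult:
    """Wild-bootstrap precision of one curve under a chosen estimator.

    ``estimator`` is 'fermi', 'fermi_delta' or 'bayes'.  The estimator is
    fit once to the original curve; replicates perturb the fitted curve by
    sign-flipped (weighted) residuals and are re-estimated.  Replicate
    fits that fail are dropped and counted; more than 10% failures sets a
    warning on the result.
    """
    cfg = config or BootstrapConfig()
    if estimator in ("fermi", "fermi_delta"):
        fit = _fermi.fit_fermi(tissue, aif, estimator, fermi_config)
        if not fit.converged:
            raise RuntimeError("estimator failed on the original curve")
        end = fit.window_end_index
        fitted_win = Curve(tissue.times[:end + 1],
                           fit.fitted_curve.values[:end + 1])
        weights = None
        if cfg.weight_scheme in ("hc2", "hc3"):
            jac = _numeric_fermi_jacobian(fit, aif, end)
            weights = _leverage_weights(jac, cfg.weight_scheme)
        reps = wild_bootstrap_replicates(fitted_win, fit.residuals, cfg,
                                         weights)
        full = np.tile(tissue.values, (cfg.n_rep, 1))
        full[:, :end + 1] = reps
        fcfg = fermi_config or _fermi.FermiFitConfig()
        fcfg = dataclasses.replace(fcfg, window_end=end)
        out = _fermi.fit_fermi_stack(full, aif, estimator, fcfg)
        ok = out["converged"]
        mbfs = out["mbf"][ok]
        n_failed = int((~ok).sum())
    elif estimator == "bayes":
        est = _bayes.estimate_bayesian(tissue, aif, bayes_config)
        resid = tissue.values - est.fitted_curve.values
        reps = wild_bootstrap_replicates(est.fitted_curve, resid, cfg)
        out = _bayes.estimate_bayesian_stack(reps, aif, bayes_config)
        mbfs = out["mbf"]
        n_failed = 0
    else:
        raise ValueError("estimator must be fermi, fermi_delta or bayes")
    if mbfs.size < 2:
        raise RuntimeError("too few successful replicates")
    warning = None
    if n_failed > 0.1 * cfg.n_rep:
        warning = f"{n_failed}/{cfg.n_rep} replicate fits failed"
        warnings.warn(warning, stacklevel=2)
    return PrecisionResult(
        mbf_mean=float(mbfs.mean()), mbf_sd=float(mbfs.std(ddof=1)),
        replicate_mbfs=mbfs, n_failed=n_failed, warning=warning)


def _numeric_fermi_jacobian(fit, aif: Curve, end: int) -> np.ndarray:
    """Forward-difference Jacobian of the Fermi model on the fit window."""
    p = fit.params
    x = [p.A, p.k, p.tau0] + ([p.tau_d] if p.tau_d is not None else [])
    x = np.asarray(x, dtype=float)

    def model(xv):
        kw = dict(A=xv[0], k=xv[1], tau0=xv[2], variant=p.variant)
        if p.variant == "fermi_delta":
            kw["tau_d"] = xv[3]
        return _fermi.convolve_model(aif, _fermi.FermiParams(**kw)).values[:end + 1]

    base = model(x)
    jac = np.empty((base.size, x.size))
    for i in range(x.size):
        step = 1e-6 * max(abs(x[i]), 1e-3)
        xp = x.copy()
        xp[i] += step
        jac[:, i] = (model(xp) - base) / step
    return jac
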