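"""Digital perfusion phantom: AIF synthesis, 2CXM tissue curves, noise.

The phantom emulates a first-pass contrast-enhanced myocardial perfusion
experiment in concentration space.  A dual-Gaussian arterial input function
(first pass + recirculation) drives a two-compartment exchange model (2CXM)
whose plasma flow F_p and plasma volume V_p vary over a 10 x 10 grid of
tiles; each tile holds many noisy realizations of the same noiseless tissue
curve.  Ground-truth MBF equals F_p (no hematocrit in the simulation).

Units
-----
Flows (F_p, PS) are ml/min/g; volumes (V_p, V_isf) ml/g; concentrations
mol/L; times seconds.  Internally flows are converted to per-second by
dividing by 60, so the tissue impulse response h(t) = (F_p/60)*R(t) has
units 1/s and C_t = h (*) C_a stays in mol/L.
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np

from .curves import Curve

__all__ = [
    "AIFParams",
    "KineticParams",
    "PhantomSpec",
    "PhantomDataset",
    "synthesize_aif",
    "tcxm_impulse_response",
    "generate_tissue_curve",
    "build_phantom",
    "save_phantom",
    "load_phantom",
    "SIGMA_MYO",
    "SIGMA_SEGMENT",
    "SIGMA_VOXEL",
    "NOISE_SCALES",
]

# Gaussian noise SD at the three clinical observation scales (mol/L):
# whole-myocardium, AHA segment, and single voxel.
SIGMA_MYO = 7.57e-6
SIGMA_SEGMENT = 7.83e-6
SIGMA_VOXEL = 1.33e-5
NOISE_SCALES = {
    "myocardium": SIGMA_MYO,
    "segment": SIGMA_SEGMENT,
    "voxel": SIGMA_VOXEL,
}


@dataclasses.dataclass(frozen=True)
class AIFParams:
    """Dual-Gaussian arterial input function parameters.

    The first Gaussian is the first pass of the bolus, the second its
    recirculation.  The mixture is scaled so its maximum equals
    ``peak_concentration``.  Defaults are calibrated to clinically observed
    stress features: a ~5.9 mmol/L peak, a quiet baseline of ~8 s, and a
    recirculation bump ~12.6 s after the first-pass peak.
    """

    baseline_duration: float = 8.4      # s, pre-bolus quiet period
    peak_concentration: float = 5.86e-3  # mol/L
    time_to_peak: float = 16.8          # s, first-pass peak position
    first_pass_sd: float = 2.5          # s
    recirc_amplitude_fraction: float = 0.3
    recirc_delay: float = 12.6          # s after the first-pass peak
    recirc_sd: float = 7.0              # s

    def __post_init__(self) -> None:
        if self.peak_concentration <= 0:
            raise ValueError("peak_concentration must be > 0")
        if self.first_pass_sd <= 0 or self.recirc_sd <= 0:
            raise ValueError("Gaussian widths must be > 0")
        if not 0 <= self.recirc_amplitude_fraction < 1:
            raise ValueError("recirc_amplitude_fraction must be in [0, 1)")


@dataclasses.dataclass(frozen=True)
class KineticParams:
    """2CXM ground-truth parameters for one phantom tile.

    Fp : plasma flow, ml/min/g (equals the true MBF).
    Vp : plasma volume, ml/g.
    PS : permeability-surface product, ml/min/g.
    Visf : interstitial fluid volume, ml/g.
    """

    Fp: float
    Vp: float
    PS: float = 0.95
    Visf: float = 0.2

    def __post_init__(self) -> None:
        if self.Fp <= 0 or self.Vp <= 0 or self.Visf <= 0:
            raise ValueError("Fp, Vp, Visf must be > 0")
        if self.PS < 0:
            raise ValueError("PS must be >= 0")
        if self.Vp + self.Visf >= 1.0:
            raise ValueError("Vp + Visf must be < 1 ml/g")


def _default_fp() -> np.ndarray:
    return np.linspace(0.48, 3.9, 10)


def _default_vp() -> np.ndarray:
    return np.linspace(0.04, 0.1, 10)


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom condition.

    ``fp_values`` x ``vp_values`` defines the tile grid (10 x 10 by
    default, flows 0.48-3.9 ml/min/g, volumes 0.04-0.1 ml/g); ``delay_s``
    must be an integer multiple of ``dt``; ``noise_sigma`` is the SD of the
    centered Gaussian noise added per sample (mol/L).
    """

    fp_values: tuple = dataclasses.field(default_factory=lambda: tuple(_default_fp()))
    vp_values: tuple = dataclasses.field(default_factory=lambda: tuple(_default_vp()))
    PS: float = 0.95
    Visf: float = 0.2
    delay_s: float = 0.0
    noise_sigma: float = SIGMA_MYO
    duration: float = 60.0
    dt: float = 0.7
    realizations_per_tile: int = 100
    oversample: int = 1
    seed: int = 0
    aif: AIFParams = dataclasses.field(default_factory=AIFParams)

    def __post_init__(self) -> None:
        object.__setattr__(self, "fp_values", tuple(float(f) for f in self.fp_values))
        object.__setattr__(self, "vp_values", tuple(float(v) for v in self.vp_values))
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be > 0")
        if self.delay_s < 0:
            raise ValueError("delay must be non-negative")
        ratio = self.delay_s / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("delay must be an integer multiple of dt")
        if self.realizations_per_tile < 1:
            raise ValueError("realizations_per_tile must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def delay_samples(self) -> int:
        return int(round(self.delay_s / self.dt))

    @property
    def times(self) -> np.ndarray:
        n = int(np.floor(self.duration / self.dt + 1e-9)) + 1
        return self.dt * np.arange(n)

    def kinetic_params(self, i: int, j: int) -> KineticParams:
        """Ground truth of tile (fp index i, vp index j)."""
        return KineticParams(self.fp_values[i], self.vp_values[j],
                             self.PS, self.Visf)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["aif"] = dataclasses.asdict(self.aif)
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        d["aif"] = AIFParams(**d["aif"])
        d["fp_values"] = tuple(d["fp_values"])
        d["vp_values"] = tuple(d["vp_values"])
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class PhantomDataset:
    """One generated phantom condition.

    ``curves`` has shape (n_fp, n_vp, realizations, n_times); index
    ``[i, j]`` is the tile with flow ``fp_values[i]`` and volume
    ``vp_values[j]``.  ``clean`` holds the noiseless curve per tile.
    ``truth_mbf_map``/``truth_vp_map`` are tile-expanded 2-D maps with one
    pixel per realization (tiles laid out as close to square as possible).
    """

    spec: PhantomSpec
    aif: Curve
    curves: np.ndarray
    clean: np.ndarray
    truth_mbf_map: np.ndarray
    truth_vp_map: np.ndarray

    @property
    def n_tiles(self) -> int:
        return len(self.spec.fp_values) * len(self.spec.vp_values)

    def truth_mbf_flat(self) -> np.ndarray:
        """True MBF repeated per realization, aligned with curves_flat."""
        nf, nv, nr, _ = self.curves.shape
        fp = np.asarray(self.spec.fp_values)
        return np.repeat(np.repeat(fp, nv), nr)

    def curves_flat(self) -> np.ndarray:
        """All realizations as a (n_curves, n_times) stack."""
        nf, nv, nr, nt = self.curves.shape
        return self.curves.reshape(nf * nv * nr, nt)


# ---------------------------------------------------------------------------
# AIF


def synthesize_aif(params: AIFParams, duration: float = 60.0,
                   dt: float = 0.7) -> Curve:
    """Dual-Gaussian arterial input function on a uniform grid.

    The first-pass Gaussian sits at ``time_to_peak``; the recirculation
    Gaussian follows ``recirc_delay`` later at a fraction of the amplitude.
    The mixture is rescaled so its maximum equals ``peak_concentration``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if duration / dt < 10:
        raise ValueError("need at least 10 samples of AIF")
    n = int(np.floor(duration / dt + 1e-9)) + 1
    t = dt * np.arange(n)
    raw = _aif_shape(t, params)
    peak = raw.max()
    if peak <= 0:
        raise ValueError("degenerate AIF")
    return Curve(t, params.peak_concentration * raw / peak)


def _aif_shape(t: np.ndarray, p: AIFParams) -> np.ndarray:
    """Unnormalized dual-Gaussian mixture (unit first-pass amplitude)."""
    g1 = np.exp(-0.5 * ((t - p.time_to_peak) / p.first_pass_sd) ** 2)
    t2 = p.time_to_peak + p.recirc_delay
    g2 = p.recirc_amplitude_fraction * np.exp(
        -0.5 * ((t - t2) / p.recirc_sd) ** 2)
    return g1 + g2


# ---------------------------------------------------------------------------
# 2CXM closed form

_MIN_TO_S = 1.0 / 60.0


def _tcxm_rate_system(k: KineticParams):
    """Rate matrix A (1/s), input vector b, readout vector c.

    State x = [Cp, Cisf]; dx/dt = A x + b Ca; tissue concentration per
    gram is c . x, so the Dirac-input impulse response is h(t) = c e^{At} b.
    """
    fp = k.Fp * _MIN_TO_S
    ps = k.PS * _MIN_TO_S
    A = np.array([
        [-(fp + ps) / k.Vp, ps / k.Vp],
        [ps / k.Visf, -ps / k.Visf],
    ])
    b = np.array([fp / k.Vp, 0.0])
    c = np.array([k.Vp, k.Visf])
    return A, b, c


def tcxm_impulse_response(k: KineticParams, times: np.ndarray) -> np.ndarray:
    """Closed-form 2CXM impulse response h(t) in 1/s.

    Bi-exponential solution of the two-ODE exchange system driven by a
    Dirac arterial input; h(0+) = Fp/60 and the area under h over [0, inf)
    is Vp + Visf (so MTT = (Vp+Visf)/Fp with consistent units).  Degenerate
    (equal) eigenvalues fall back to the confluent t*exp limit form.
    """
    t = np.asarray(times, dtype=float)
    if t.size and t[0] < -1e-12:
        raise ValueError("times must start at 0")
    A, b, c = _tcxm_rate_system(k)
    tr = A[0, 0] + A[1, 1]
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    disc = tr * tr - 4.0 * det
    if disc > max(1e-24, 1e-12 * tr * tr):
        sq = np.sqrt(disc)
        lam1, lam2 = 0.5 * (tr + sq), 0.5 * (tr - sq)
        # e^{At} = e^{l1 t} (A - l2)/(l1 - l2) + e^{l2 t} (A - l1)/(l2 - l1)
        alpha1 = c @ ((A - lam2 * np.eye(2)) @ b) / (lam1 - lam2)
        alpha2 = c @ ((A - lam1 * np.eye(2)) @ b) / (lam2 - lam1)
        h = alpha1 * np.exp(lam1 * t) + alpha2 * np.exp(lam2 * t)
    else:
        lam = 0.5 * tr
        h = np.exp(lam * t) * (c @ b + t * (c @ ((A - lam * np.eye(2)) @ b)))
    return np.maximum(h, 0.0)


# ---------------------------------------------------------------------------
# Tissue curve generation


def generate_tissue_curve(aif: Curve, k: KineticParams, delay: float = 0.0,
                          oversample: int = 1) -> Curve:
    """Noiseless 2CXM tissue curve: C_t = (h (*) C_a), shifted by the delay.

    The impulse response is sampled on the acquisition grid and convolved
    discretely with the AIF: the phantom's ground truth is defined at the
    resolution the scanner (and hence every estimator) sees, so the
    sampled residue itself -- with h(0) = Fp/60 -- is what a perfect
    deconvolution would recover.  With ``oversample`` > 1 the quadrature
    is refined on a grid that much finer (AIF linearly interpolated,
    residue sample-and-hold), which conserves the per-sample residue mass;
    useful as a convergence check.  The result is shifted right by
    ``delay/dt`` samples with zero fill (the integer-sample bolus delay).
    """
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    if delay < 0:
        raise ValueError("delay must be non-negative")
    dt = aif.dt
    ratio = delay / dt
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("phantom delays must be integer multiples of dt")
    shift = int(round(ratio))
    n = len(aif)
    t0 = aif.times - aif.times[0]
    h_c = tcxm_impulse_response(k, t0)
    if oversample == 1:
        ct = np.convolve(aif.values, h_c)[:n] * dt
    else:
        dtf = dt / oversample
        nf = (n - 1) * oversample + 1
        tf = dtf * np.arange(nf)
        ca_f = np.interp(tf, t0, aif.values)
        h_f = np.repeat(h_c, oversample)[:nf]   # zero-order hold
        ct = (np.convolve(ca_f, h_f)[:nf] * dtf)[::oversample]
    return Curve(aif.times, ct).shifted(shift)


def _tile_shape(n: int) -> tuple:
    """Near-square tile layout for n realizations (10x10 for n=100)."""
    r = int(np.sqrt(n))
    while r > 1 and n % r:
        r -= 1
    return (r, n // r)


def build_phantom(spec: PhantomSpec) -> PhantomDataset:
    """Generate the tiled phantom for one (delay, noise) condition.

    One noiseless curve per (Fp, Vp) pair; each realization adds i.i.d.
    centered Gaussian noise of SD ``spec.noise_sigma``.  All randomness
    comes from ``spec.seed``, so regeneration is bit-identical.
    """
    aif = synthesize_aif(spec.aif, spec.duration, spec.dt)
    nf, nv = len(spec.fp_values), len(spec.vp_values)
    nt = len(aif)
    nr = spec.realizations_per_tile
    clean = np.empty((nf, nv, nt))
    for i in range(nf):
        for j in range(nv):
            clean[i, j] = generate_tissue_curve(
                aif, spec.kinetic_params(i, j), spec.delay_s,
                spec.oversample).values
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sigma, size=(nf, nv, nr, nt)) \
        if spec.noise_sigma > 0 else np.zeros((nf, nv, nr, nt))
    curves = clean[:, :, None, :] + noise
    th, tw = _tile_shape(nr)
    fp_grid = np.asarray(spec.fp_values)[:, None] * np.ones((1, nv))
    vp_grid = np.ones((nf, 1)) * np.asarray(spec.vp_values)[None, :]
    mbf_map = np.kron(fp_grid, np.ones((th, tw)))
    vp_map = np.kron(vp_grid, np.ones((th, tw)))
    return PhantomDataset(spec=spec, aif=aif, curves=curves, clean=clean,
                          truth_mbf_map=mbf_map, truth_vp_map=vp_map)


# ---------------------------------------------------------------------------
# HDF5 container


def save_phantom(dataset: PhantomDataset, path) -> None:
    """Write a phantom to HDF5 (/aif, /curves, /truth/*, /meta)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("aif")
        g.create_dataset("times", data=dataset.aif.times)
        g.create_dataset("values", data=dataset.aif.values)
        f.create_dataset("curves", data=dataset.curves)
        f.create_dataset("clean", data=dataset.clean)
        t = f.create_group("truth")
        t.create_dataset("mbf", data=dataset.truth_mbf_map)
        t.create_dataset("vp", data=dataset.truth_vp_map)
        f.create_dataset("meta", data=dataset.spec.to_json())


def load_phantom(path) -> PhantomDataset:
    with h5py.File(path, "r") as f:
        spec = PhantomSpec.from_json(f["meta"][()].decode())
        aif = Curve(f["aif/times"][:], f["aif/values"][:])
        return PhantomDataset(
            spec=spec, aif=aif, curves=f["curves"][:], clean=f["clean"][:],
            truth_mbf_map=f["truth/mbf"][:], truth_vp_map=f["truth/vp"][:])
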