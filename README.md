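# mbfdecon

Myocardial blood-flow (MBF) quantification from first-pass
contrast-enhanced perfusion curves by tracer-kinetic deconvolution — with
the digital phantom needed to validate the estimators against a known
ground truth.

The package is for researchers working on quantitative cardiac perfusion
(CMR first-pass imaging in particular) who need (a) reference
implementations of the two deconvolution families used clinically, (b) a
reproducible in-silico test bed for them, and (c) per-curve precision
estimates for in-vivo use where no ground truth exists.

## What it computes

Indicator-dilution theory models the tissue concentration curve as

    C_t(t) = MBF · ( C_a(· − τ_d) ⊛ R )(t)

with arterial input C_a, residue function R (R(arrival) = 1, decaying),
bolus-arrival delay τ_d, MTT = ∫R dt and MBV = MBF·MTT. Three estimators
invert this:

- **Fermi** — the residue constrained to a Fermi sigmoid
  r(t) = A/(1 + e^{(t−τ0)k}), fitted by bounded variable-projection least
  squares over the first-pass window; MBF is the maximum of the fitted
  residue on the window.
- **Fermi-δ** — the same with a causal arrival delay τ_d, selected on the
  sample grid and polished.
- **Bayesian** — nonparametric residue (one node per sample, 40 s
  support) with a Dirac prior R(τ_d) = 1 and a second-difference
  smoothness prior; the residue and the noise level integrate out
  analytically, and MBF, τ_d and the smoothness weight are posterior
  means over a deterministic 3-D grid. Returns the full MBF posterior,
  the residue with a 95% band, MTT and MBV.

The synthetic-data module generates tiled two-compartment-exchange (2CXM)
phantoms — 10 flows × 10 plasma volumes, clinically calibrated
dual-Gaussian AIF, three measured noise scales, integer-sample bolus
delays — and the evaluation module produces the agreement statistics
(regression, Lin's concordance, per-tile relative error, bolus-arrival
measurement, comparison tables). A wild bootstrap (Rademacher sign-flips
of the fit residuals) quotes per-curve precision. See `docs/methods.md`
for the models, priors, numerical choices and limitations.

## Worked example

Estimate flow on one noisy phantom curve (true MBF 2.0 ml/min/g, true
delay 1.4 s, whole-myocardium noise):

```python
import numpy as np
import mbfdecon as mb

aif = mb.synthesize_aif(mb.AIFParams())
truth = mb.KineticParams(Fp=2.0, Vp=0.07)
clean = mb.generate_tissue_curve(aif, truth, delay=1.4)
rng = np.random.default_rng(7)
tissue = clean.with_values(clean.values + rng.normal(0, mb.SIGMA_MYO, len(clean)))

est = mb.estimate_bayesian(tissue, aif)
print(f"Bayes    : MBF={est.mbf:.2f} ml/min/g  delay={est.delay:.2f} s  "
      f"MTT={est.mtt:.1f} s  MBV={est.mbv:.3f} ml/g")
fit = mb.fit_fermi(tissue, aif, "fermi_delta")
print(f"Fermi-d  : MBF={fit.mbf:.2f} ml/min/g  tau_d={fit.params.tau_d:.2f} s")
prec = mb.bootstrap_precision(tissue, aif, "fermi_delta",
                              mb.BootstrapConfig(n_rep=200, seed=1))
print(f"precision: SD(MBF)={prec.mbf_sd:.3f} ml/min/g")
```

prints

```
Bayes    : MBF=1.65 ml/min/g  delay=1.33 s  MTT=8.8 s  MBV=0.242 ml/g
Fermi-d  : MBF=1.39 ml/min/g  tau_d=0.70 s
precision: SD(MBF)=0.140 ml/min/g
```

The Bayesian estimate sits below the true 2.0 ml/min/g — the smoothness
prior shrinks flow amplitudes by 15–25% at clinical noise (see the
methods note) — but locates the 1.4 s bolus delay to within a tenth of a
second; MBV ≈ 0.24 ml/g reflects the true distribution volume
V_p + V_isf = 0.27 ml/g truncated at the 40 s residue support. The
precision SD (±0.14) is the wild-bootstrap spread a clinical reader would
quote for this curve.

The full simulate → estimate → evaluate → report pipeline runs from the
command line:

```bash
mbfdecon run --out results/demo --seed 7      # tables + manifest
mbfdecon estimate --method bayes --curve ct.csv --aif aif.csv
mbfdecon bootstrap --curve ct.csv --aif aif.csv --estimator fermi-delta
```

Curves travel as 2-column CSV (`time_s,conc_mol_per_L`); phantoms as HDF5.

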