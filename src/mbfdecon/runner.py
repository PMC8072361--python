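"""Pipeline orchestration: simulate -> estimate -> evaluate -> report.

One :class:`RunConfig` (JSON round-trippable) drives the whole in-silico
study: phantom generation per (noise scale, delay) condition, per-curve
MBF estimation with the enabled methods, agreement statistics against the
ground truth, and a report bundle (tables + manifest with content
checksums).  A single master seed deterministically derives every stage
seed, so two runs with the same config differ only in manifest timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import bayes as _bayes
from . import fermi as _fermi
from .curves import Curve
from .evalreport import (compile_comparison_tables, lin_ccc,
                         regression_stats, relative_error_summary)
from .phantom import (AIFParams, NOISE_SCALES, PhantomDataset, PhantomSpec,
                      build_phantom, save_phantom)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "load_curves",
           "save_estimates", "condition_seed"]

log = logging.getLogger("mbfdecon")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Configuration of one full in-silico run (JSON serializable)."""

    fp_values: tuple = dataclasses.field(
        default_factory=lambda: tuple(np.linspace(0.48, 3.9, 10)))
    vp_values: tuple = dataclasses.field(
        default_factory=lambda: tuple(np.linspace(0.04, 0.1, 10)))
    PS: float = 0.95
    Visf: float = 0.2
    dt: float = 0.7
    duration: float = 60.0
    realizations_per_tile: int = 16
    delays: tuple = (0.0, 1.4, 2.8)
    noise_scales: tuple = tuple(NOISE_SCALES.items())
    methods: tuple = ("bayes", "fermi", "fermi_delta")
    aif: AIFParams = dataclasses.field(default_factory=AIFParams)
    out_dir: str = "mbfdecon_run"
    master_seed: int = 0
    save_phantoms: bool = False
    figures: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "fp_values", tuple(float(x) for x in self.fp_values))
        object.__setattr__(self, "vp_values", tuple(float(x) for x in self.vp_values))
        object.__setattr__(self, "delays", tuple(float(x) for x in self.delays))
        ns = tuple((str(k), float(v)) for k, v in self.noise_scales)
        object.__setattr__(self, "noise_scales", ns)
        object.__setattr__(self, "methods", tuple(self.methods))
        for m in self.methods:
            if m not in ("bayes", "fermi", "fermi_delta"):
                raise ValueError(f"unknown method {m!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["aif"] = dataclasses.asdict(self.aif)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["aif"] = AIFParams(**d["aif"])
        d["noise_scales"] = tuple((k, v) for k, v in d["noise_scales"])
        return cls(**d)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        text = Path(source).read_text(encoding="utf-8") \
            if not str(source).lstrip().startswith("{") else str(source)
        return cls.from_dict(json.loads(text))

    def phantom_spec(self, sigma: float, delay: float, seed: int) -> PhantomSpec:
        return PhantomSpec(
            fp_values=self.fp_values, vp_values=self.vp_values, PS=self.PS,
            Visf=self.Visf, delay_s=delay, noise_sigma=sigma,
            duration=self.duration, dt=self.dt,
            realizations_per_tile=self.realizations_per_tile,
            seed=seed, aif=self.aif)


def condition_seed(master_seed: int, *key) -> int:
    """Deterministic sub-2^31 stage seed derived from the master seed."""
    text = json.dumps([int(master_seed), *map(str, key)])
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclasses.dataclass
class ReportBundle:
    """Everything one pipeline run produced."""

    manifest: dict
    table_path: Optional[Path]
    report: object  # ComparisonReport


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _estimate_condition(ds: PhantomDataset, method: str) -> dict:
    """Run one estimator over every curve of one phantom condition."""
    Y = ds.curves_flat()
    t0 = time.perf_counter()
    if method == "bayes":
        out = _bayes.estimate_bayesian_stack(Y, ds.aif)
    else:
        out = _fermi.fit_fermi_stack(Y, ds.aif, method)
    out["proc_time_s"] = time.perf_counter() - t0
    return out


def _condition_stats(ds: PhantomDataset, mbf: np.ndarray) -> dict:
    """Agreement statistics of one condition.

    Wall time is deliberately not part of the returned cell: the written
    tables are byte-reproducible for a fixed config, so hardware-bound
    runtimes live in the manifest instead.
    """
    truth = ds.truth_mbf_flat()
    reg = regression_stats(mbf, truth)
    agr = lin_ccc(mbf, truth)
    nf, nv, nr, _ = ds.curves.shape
    tiles = mbf.reshape(nf * nv, nr)
    truth_tiles = truth.reshape(nf * nv, nr)[:, 0]
    rel = relative_error_summary(tiles, truth_tiles)
    return {
        "r2": reg.r2, "slope": reg.slope, "intercept": reg.intercept,
        "ccc": agr.ccc, "ccc_ci_low": agr.ccc_ci_low,
        "ccc_ci_high": agr.ccc_ci_high, "rho": agr.rho, "cb": agr.cb,
        "relerr_avg_pct": rel.avg, "relerr_max_pct": rel.max,
    }


def save_estimates(path, ds: PhantomDataset, out: dict) -> None:
    """Write per-curve estimates of one condition as CSV."""
    nf, nv, nr, _ = ds.curves.shape
    idx = np.arange(nf * nv * nr)
    df = pd.DataFrame({
        "fp_index": idx // (nv * nr),
        "vp_index": (idx // nr) % nv,
        "realization": idx % nr,
        "truth_mbf": ds.truth_mbf_flat(),
        "mbf": out["mbf"],
    })
    if "delay" in out:
        df["delay_s"] = out["delay"]
    if "tau_d" in out:
        df["tau_d_s"] = out["tau_d"]
    if "converged" in out:
        df["converged"] = out["converged"].astype(int)
    df.to_csv(path, index=False, float_format="%.10g")


def load_curves(path) -> List[Curve]:
    """Read curve CSV file(s); a directory loads every ``*.csv`` inside."""
    p = Path(path)
    if p.is_dir():
        return [Curve.from_csv(f) for f in sorted(p.glob("*.csv"))]
    return [Curve.from_csv(p)]


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute simulate -> estimate -> evaluate -> report.

    Idempotent for a fixed config: rerunning rewrites byte-identical
    tables.  A stage failure aborts with the manifest recording the
    stages completed so far.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "estimates").mkdir(exist_ok=True)
    (out_dir / "tables").mkdir(exist_ok=True)
    manifest: dict = {"config_sha256": hashlib.sha256(
        config.to_json().encode()).hexdigest(), "stages": {}, "files": {}}
    config.to_json(out_dir / "config.json")

    handler = logging.FileHandler(out_dir / "run.log")
    log.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler)
               for h in log.handlers):
        log.addHandler(logging.StreamHandler())  # stderr
    log.setLevel(logging.INFO)
    try:
        results: Dict[tuple, Optional[dict]] = {}
        t_stage = time.perf_counter()
        for scale_name, sigma in config.noise_scales:
            for delay in config.delays:
                seed = condition_seed(config.master_seed, scale_name, delay)
                spec = config.phantom_spec(sigma, delay, seed)
                log.info("simulate %s delay=%.1f seed=%d", scale_name,
                         delay, seed)
                ds = build_phantom(spec)
                if config.save_phantoms:
                    (out_dir / "phantoms").mkdir(exist_ok=True)
                    h5 = out_dir / "phantoms" / f"{scale_name}_d{delay:g}.h5"
                    save_phantom(ds, h5)
                for method in ("bayes", "fermi", "fermi_delta"):
                    key = (method, scale_name, delay)
                    if method not in config.methods:
                        results[key] = None
                        continue
                    log.info("estimate %s %s delay=%.1f", method,
                             scale_name, delay)
                    out = _estimate_condition(ds, method)
                    csv = out_dir / "estimates" / \
                        f"{method}_{scale_name}_d{delay:g}.csv"
                    save_estimates(csv, ds, out)
                    manifest["files"][str(csv.relative_to(out_dir))] = \
                        _file_checksum(csv)
                    manifest.setdefault("proc_times_s", {})[
                        f"{method}/{scale_name}/{delay:g}"] = \
                        round(out["proc_time_s"], 3)
                    results[key] = _condition_stats(ds, out["mbf"])
        manifest["stages"]["simulate+estimate"] = \
            time.perf_counter() - t_stage

        t_stage = time.perf_counter()
        report = compile_comparison_tables(results)
        table_path = out_dir / "tables" / "comparison_tables.csv"
        report.to_csv(table_path)
        report.to_json(out_dir / "tables" / "agreement.json")
        for f in ("tables/comparison_tables.csv", "tables/agreement.json"):
            manifest["files"][f] = _file_checksum(out_dir / f)
        if config.figures:
            _render_figures(out_dir, results)
        manifest["stages"]["evaluate+report"] = time.perf_counter() - t_stage
        manifest["completed"] = True
    except Exception:
        manifest["completed"] = False
        raise
    finally:
        manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        log.removeHandler(handler)
        handler.close()
    return ReportBundle(manifest=manifest, table_path=table_path,
                        report=report)


def _render_figures(out_dir: Path, results: dict) -> None:
    """Regression-slope summary figure (optional, matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    methods = sorted({k[0] for k in results})
    for method in methods:
        pts = [(k[2], v["slope"]) for k, v in results.items()
               if k[0] == method and v is not None and k[1] == "myocardium"]
        if pts:
            pts.sort()
            ax.plot(*zip(*pts), marker="o", label=method)
    ax.set_xlabel("bolus delay (s)")
    ax.set_ylabel("regression slope vs truth")
    ax.axhline(1.0, color="k", ls="--", lw=0.8)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "tables" / "slopes.png", dpi=120)
    plt.close(fig)
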