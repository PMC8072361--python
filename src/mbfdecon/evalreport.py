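"""Agreement statistics and summary tables for MBF estimation maps.

Estimated-vs-true MBF is summarized three ways, mirroring common practice
in perfusion phantom validation: ordinary least-squares regression (slope,
intercept, r^2), Lin's concordance correlation coefficient (CCC = rho *
C_b, splitting agreement into Pearson precision rho and an accuracy factor
C_b), and per-tile relative error (within-tile SD of estimates divided by
the true MBF).  The module also provides the 10%-of-peak bolus-arrival
measurement, fixed-width MBF histograms, and the method x noise-scale x
delay comparison table assembly.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Dict, Optional

import numpy as np
import pandas as pd
import scipy.stats as st

from .curves import Curve

__all__ = [
    "RegressionStats",
    "AgreementStats",
    "RelativeErrorSummary",
    "regression_stats",
    "lin_ccc",
    "relative_error_summary",
    "measure_bat_10pct",
    "mbf_histogram",
    "compile_comparison_tables",
    "ComparisonReport",
]


@dataclasses.dataclass(frozen=True)
class RegressionStats:
    slope: float
    intercept: float
    r2: float


@dataclasses.dataclass(frozen=True)
class AgreementStats:
    ccc: float
    ccc_ci_low: float
    ccc_ci_high: float
    rho: float
    cb: float


@dataclasses.dataclass(frozen=True)
class RelativeErrorSummary:
    per_tile: np.ndarray   # % per tile
    avg: float             # %
    max: float             # %


def regression_stats(estimates, truth) -> RegressionStats:
    """OLS of estimates on truth; r^2 is the squared Pearson correlation."""
    x = np.asarray(truth, dtype=float)
    y = np.asarray(estimates, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("truth is constant; regression undefined")
    res = st.linregress(x, y)
    return RegressionStats(slope=float(res.slope),
                           intercept=float(res.intercept),
                           r2=float(res.rvalue ** 2))


def lin_ccc(estimates, truth) -> AgreementStats:
    """Lin's concordance correlation coefficient with population moments.

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2) using 1/n moments;
    rho is the Pearson correlation and C_b = CCC / rho the accuracy
    factor.  The 95% CI uses the Fisher z transform with SE 1/sqrt(n-3).
    """
    x = np.asarray(estimates, dtype=float)
    y = np.asarray(truth, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 points")
    sx2 = x.var()
    sy2 = y.var()
    if sx2 == 0 or sy2 == 0:
        raise ValueError("zero variance; CCC undefined")
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    ccc = 2.0 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2)
    rho = sxy / np.sqrt(sx2 * sy2)
    cb = ccc / rho
    if abs(ccc) >= 1.0 or x.size <= 3:
        # perfect agreement or too few points: the z-transform interval
        # degenerates; report the point estimate as its own bounds
        lo = hi = float(ccc)
    else:
        z = np.arctanh(ccc)
        half = 1.959963984540054 / np.sqrt(x.size - 3)
        lo, hi = float(np.tanh(z - half)), float(np.tanh(z + half))
    return AgreementStats(ccc=float(ccc), ccc_ci_low=lo, ccc_ci_high=hi,
                          rho=float(rho), cb=float(cb))


def relative_error_summary(tile_estimates: np.ndarray,
                           truth_mbf: np.ndarray) -> RelativeErrorSummary:
    """Per-tile relative error: sample SD of estimates / true MBF, in %.

    ``tile_estimates`` has shape (..., n_realizations) with one leading
    cell per tile; ``truth_mbf`` the matching true MBF per tile.
    """
    est = np.asarray(tile_estimates, dtype=float)
    truth = np.asarray(truth_mbf, dtype=float)
    if est.shape[:-1] != truth.shape:
        raise ValueError("tile_estimates and truth_mbf shapes disagree")
    if est.shape[-1] < 2:
        raise ValueError("need >= 2 estimates per tile")
    sd = est.std(axis=-1, ddof=1)
    rel = 100.0 * sd / truth
    return RelativeErrorSummary(per_tile=rel, avg=float(rel.mean()),
                                max=float(rel.max()))


def _first_crossing(curve: Curve, level: float) -> float:
    """Time of the first up-crossing of ``level``, linearly interpolated."""
    v = curve.values
    above = v >= level
    if not above.any():
        raise ValueError("curve never reaches the threshold")
    i = int(np.argmax(above))
    if i == 0:
        return float(curve.times[0])
    t0, t1 = curve.times[i - 1], curve.times[i]
    v0, v1 = v[i - 1], v[i]
    return float(t0 + (level - v0) / (v1 - v0) * (t1 - t0))


def measure_bat_10pct(aif: Curve, tissue: Curve) -> float:
    """Bolus-arrival delay from the 10%-of-peak crossing times.

    The delay is the time at which the tissue curve first reaches 10% of
    its own peak minus the time the AIF reaches 10% of its peak; both
    crossings are located by linear interpolation between samples.
    """
    pa = float(np.max(aif.values))
    pt = float(np.max(tissue.values))
    if pa <= 0 or pt <= 0:
        raise ValueError("both curves need positive peaks")
    return _first_crossing(tissue, 0.1 * pt) - _first_crossing(aif, 0.1 * pa)


def mbf_histogram(mbf_map: np.ndarray, region_masks: Optional[np.ndarray] = None,
                  bin_width: float = 0.2) -> Dict:
    """Per-region histograms of MBF with bins anchored at 0.

    ``region_masks`` is an integer label map aligned with ``mbf_map``
    (label 0 = background, ignored); ``None`` treats the whole map as one
    region labeled 1.  Empty regions yield empty histograms.
    """
    vals = np.asarray(mbf_map, dtype=float)
    labels = (np.ones(vals.shape, dtype=int) if region_masks is None
              else np.asarray(region_masks))
    if labels.shape != vals.shape:
        raise ValueError("region mask must match the map shape")
    out = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        x = vals[labels == lab]
        if x.size == 0:
            out[int(lab)] = {"edges": np.array([0.0]), "counts": np.array([], int)}
            continue
        n_bins = int(np.floor(x.max() / bin_width)) + 1
        edges = bin_width * np.arange(n_bins + 1)
        counts, _ = np.histogram(x, bins=edges)
        out[int(lab)] = {"edges": edges, "counts": counts}
    return out


GAP = "missing"


@dataclasses.dataclass
class ComparisonReport:
    """Method x noise-scale x delay comparison table.

    ``table`` is a DataFrame with one row per cell; absent cells are kept
    with an explicit gap marker in the ``status`` column rather than
    silently dropped.
    """

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")

    def to_json(self, path) -> None:
        records = self.table.to_dict(orient="records")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(records, fh, indent=1, sort_keys=True, allow_nan=True)


_CELL_FIELDS = [
    "r2", "slope", "intercept", "proc_time_s",
    "ccc", "ccc_ci_low", "ccc_ci_high", "rho", "cb",
    "relerr_avg_pct", "relerr_max_pct",
]


def compile_comparison_tables(results: Dict[tuple, Optional[dict]]
                              ) -> ComparisonReport:
    """Assemble per-condition statistics into one tidy table.

    ``results`` maps (method, noise_scale, delay_s) to a dict with any of
    the cell fields (regression, agreement, relative error, runtime); a
    ``None`` value or missing field becomes an explicit gap.
    """
    rows = []
    for (method, scale, delay), cell in sorted(results.items()):
        row = {"method": method, "noise_scale": scale, "delay_s": delay}
        if cell is None:
            row["status"] = GAP
            row.update({f: np.nan for f in _CELL_FIELDS})
        else:
            row["status"] = "ok"
            for f in _CELL_FIELDS:
                row[f] = cell.get(f, np.nan)
        rows.append(row)
    cols = ["method", "noise_scale", "delay_s", "status"] + _CELL_FIELDS
    return ComparisonReport(table=pd.DataFrame(rows, columns=cols))
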