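"""Uniformly sampled concentration-time curves.

Every quantity in the package that varies over time -- the arterial input
function C_a(t), tissue curves C_t(t), fitted model curves -- is held as a
:class:`Curve`: a strictly uniform time grid plus one value per sample.
Concentrations are in mol/L unless stated otherwise; times in seconds.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

__all__ = ["Curve", "CurveFormatError"]

#: canonical 2-column CSV header for curve files
CSV_HEADER = "time_s,conc_mol_per_L"

_GRID_TOL = 1e-9


class CurveFormatError(ValueError):
    """Raised when a curve file or array violates the curve contract."""


@dataclasses.dataclass(frozen=True)
class Curve:
    """A uniformly sampled time series.

    Parameters
    ----------
    times : array of float
        Sample times in seconds, strictly increasing with constant step.
    values : array of float
        One finite value per sample (concentration in mol/L by convention).
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise CurveFormatError("times and values must be 1-D")
        if times.size != values.size:
            raise CurveFormatError("times and values must have equal length")
        if times.size < 2:
            raise CurveFormatError("a curve needs at least 2 samples")
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise CurveFormatError("times must be strictly increasing")
        if np.max(np.abs(steps - steps[0])) > _GRID_TOL:
            raise CurveFormatError("time grid must be uniform")
        if not np.all(np.isfinite(values)) or not np.all(np.isfinite(times)):
            raise CurveFormatError("times and values must be finite")

    # -- basic properties -------------------------------------------------

    @property
    def dt(self) -> float:
        """Sampling period in seconds."""
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        """Time spanned by the grid (last minus first sample), seconds."""
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return int(self.times.size)

    # -- derived curves ---------------------------------------------------

    def with_values(self, values: np.ndarray) -> "Curve":
        """Same grid, new values."""
        return Curve(self.times, np.asarray(values, dtype=float))

    def shifted(self, n_samples: int) -> "Curve":
        """Shift values right by ``n_samples`` grid steps, zero-filling.

        This is the integer-sample bolus-delay mechanism used by the
        phantom: the time grid is unchanged, the signal arrives later.
        """
        if n_samples < 0:
            raise ValueError("shift must be non-negative")
        out = np.zeros_like(self.values)
        if n_samples == 0:
            out[:] = self.values
        elif n_samples < len(self):
            out[n_samples:] = self.values[: len(self) - n_samples]
        return self.with_values(out)

    # -- CSV round trip ---------------------------------------------------

    def to_csv(self, path) -> None:
        """Write the curve as 2-column CSV with a one-line units header."""
        data = np.column_stack([self.times, self.values])
        np.savetxt(path, data, delimiter=",", header=CSV_HEADER, comments="",
                   fmt="%.17g")

    @classmethod
    def from_csv(cls, path) -> "Curve":
        """Read a 2-column (time_s, conc) CSV.

        A missing or unrecognized units header is tolerated with a warning
        (mol/L assumed).  Non-uniform or non-monotone time grids and NaN
        values raise :class:`CurveFormatError` naming the offending row.
        """
        with open(path, "r", encoding="utf-8") as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        if not lines:
            raise CurveFormatError(f"{path}: empty curve file")
        start = 0
        first = lines[0].split(",")[0].strip()
        try:
            float(first)
        except ValueError:
            if lines[0].replace(" ", "") != CSV_HEADER:
                warnings.warn(
                    f"{path}: unrecognized header {lines[0]!r}; "
                    "assuming columns are time_s, conc_mol_per_L",
                    stacklevel=2,
                )
            start = 1
        else:
            warnings.warn(
                f"{path}: no units header; assuming mol/L", stacklevel=2
            )
        times, values = [], []
        for i, ln in enumerate(lines[start:], start=start + 1):
            parts = ln.split(",")
            if len(parts) != 2:
                raise CurveFormatError(f"{path}: row {i}: expected 2 columns")
            try:
                t, v = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise CurveFormatError(f"{path}: row {i}: {exc}") from exc
            if not (np.isfinite(t) and np.isfinite(v)):
                raise CurveFormatError(f"{path}: row {i}: non-finite entry")
            times.append(t)
            values.append(v)
        t = np.asarray(times)
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            row = int(np.argmax(np.diff(t) <= 0)) + start + 2
            raise CurveFormatError(f"{path}: row {row}: time not increasing")
        try:
            return cls(t, np.asarray(values))
        except CurveFormatError as exc:
            raise CurveFormatError(f"{path}: {exc}") from exc
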