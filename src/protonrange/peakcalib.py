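"""Offset calibration against beam energy (the PeakCalib reimplementation).

Interpolates the swept offset table — Bragg depth, 13N depth and their
offset, each independently — against energy, with either piecewise-linear
or natural cubic-spline interpolants, and evaluates them on a 0.1 MeV grid.
Given a measured 13N-peak depth and the beam energy, the estimated Bragg
depth is the measured depth plus the interpolated offset.

No extrapolation: offsets outside the swept band are unvalidated, so
queries outside the knot range raise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, interp1d

from .rangefinder import OffsetTable

__all__ = ["CalibrationCurve", "fit_interpolant", "offset_at", "estimate_bragg"]

_QUANTITIES = ("bragg_mm", "n13_mm", "offset_mm")


@dataclass(frozen=True)
class CalibrationCurve:
    """Interpolants for bragg/n13/offset vs energy; passes through every knot."""

    method: str
    knots: OffsetTable
    _interp: dict

    @property
    def energy_range(self) -> tuple[float, float]:
        e = self.knots.energies
        return float(e[0]), float(e[-1])

    def _check(self, energy_MeV) -> np.ndarray:
        e = np.asarray(energy_MeV, float)
        lo, hi = self.energy_range
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"energy outside the calibrated range [{lo}, {hi}] MeV; "
                "extrapolation is not supported")
        return e

    def offset_at(self, energy_MeV):
        e = self._check(energy_MeV)
        out = self._interp["offset_mm"](e)
        return float(out) if np.isscalar(energy_MeV) else np.asarray(out, float)

    def bragg_at(self, energy_MeV):
        e = self._check(energy_MeV)
        out = self._interp["bragg_mm"](e)
        return float(out) if np.isscalar(energy_MeV) else np.asarray(out, float)

    def n13_at(self, energy_MeV):
        e = self._check(energy_MeV)
        out = self._interp["n13_mm"](e)
        return float(out) if np.isscalar(energy_MeV) else np.asarray(out, float)

    def estimate_bragg(self, measured_n13_mm: float, energy_MeV: float) -> float:
        """Bragg-depth estimate = measured 13N depth + interpolated offset."""
        return float(measured_n13_mm + self.offset_at(energy_MeV))

    def export_grid(self, step_MeV: float = 0.1) -> pd.DataFrame:
        """Dense table on [E_min, E_max] at ``step_MeV`` (2051 rows for the
        default 45-250 MeV knots at 0.1 MeV)."""
        lo, hi = self.energy_range
        n = int(round((hi - lo) / step_MeV))
        e = lo + np.arange(n + 1) * step_MeV
        e[-1] = hi
        return pd.DataFrame({
            "energy_MeV": e,
            "bragg_mm": self.bragg_at(e),
            "n13_mm": self.n13_at(e),
            "offset_mm": self.offset_at(e),
        })


def fit_interpolant(table: OffsetTable, method: str = "linear",
                    cubic_bc: str = "natural") -> CalibrationCurve:
    """Build the calibration curve from an offset table.

    ``linear`` needs >= 2 knots; ``cubic_spline`` (natural boundary
    conditions by default, ``clamped`` optional) needs >= 4.
    """
    e = table.energies
    if np.unique(e).size != e.size:
        raise ValueError("duplicate knot energies")
    if method == "linear":
        if e.size < 2:
            raise ValueError("linear interpolation needs at least 2 knots")
        mk = lambda y: interp1d(e, y, kind="linear", assume_sorted=True)
    elif method == "cubic_spline":
        if e.size < 4:
            raise ValueError("cubic spline needs at least 4 knots")
        mk = lambda y: CubicSpline(e, y, bc_type=cubic_bc)
    else:
        raise ValueError(f"unknown method {method!r}")
    interp = {q: mk(table.df[q].to_numpy(float)) for q in _QUANTITIES}
    return CalibrationCurve(method, table, interp)


def offset_at(curve: CalibrationCurve, energy_MeV):
    return curve.offset_at(energy_MeV)


def estimate_bragg(measured_n13_mm: float, energy_MeV: float,
                   curve: CalibrationCurve) -> float:
    return curve.estimate_bragg(measured_n13_mm, energy_MeV)
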