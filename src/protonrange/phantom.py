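"""Analytic proton-beam / phantom physics.

The stand-in for a Monte Carlo transport engine: a range–energy relation
(Bragg–Kleeman closed form or numerical integration of a stopping-power
table), the residual-energy-vs-depth inversion, and a depth-dose profile
with Gaussian range straggling.  Everything downstream (activation, dynamic
frames, spectral analysis) is built on these three primitives.

Units: energies in MeV, depths in mm, densities in g/cm^3, mass stopping
power in MeV cm^2/g.  Ranges follow the usual 1/rho density scaling at
fixed composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "MaterialComposition",
    "WATER_GEL",
    "PhantomSpec",
    "BeamSpec",
    "StoppingModel",
    "DepthProfile",
    "range_from_energy",
    "energy_at_depth",
    "depth_dose_profile",
    "range_straggling_sigma_mm",
]

# Bragg-Kleeman constants for water, R[cm] = alpha * E[MeV]**p
BK_ALPHA_CM = 0.0022
BK_P = 1.77

# Gaussian range-straggling parameterization, sigma[cm] = a * R[cm]**b
STRAGGLE_A = 0.012
STRAGGLE_B = 0.935


@dataclass(frozen=True)
class MaterialComposition:
    """Elemental composition by mass fraction plus bulk density."""

    density_g_cm3: float
    mass_fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.density_g_cm3 <= 0:
            raise ValueError("density must be positive")
        fr = dict(self.mass_fractions)
        if any(v < 0 for v in fr.values()):
            raise ValueError("mass fractions must be non-negative")
        total = sum(fr.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mass fractions sum to {total}, expected 1.0")
        object.__setattr__(self, "mass_fractions", fr)

    def fraction(self, element: str) -> float:
        return self.mass_fractions.get(element, 0.0)


#: Agar water-gel: 1% agar in water, no nitrogen. H/C/O by weight.
WATER_GEL = MaterialComposition(1.010, {"H": 0.1100, "C": 0.0465, "O": 0.8435})


@dataclass(frozen=True)
class PhantomSpec:
    """Rectangular homogeneous phantom, beam entering the z=0 face."""

    size_mm: tuple[float, float, float] = (100.0, 100.0, 400.0)
    voxel_mm: tuple[float, float, float] = (2.0, 2.0, 0.5)
    material: MaterialComposition = WATER_GEL

    def __post_init__(self) -> None:
        for s, v in zip(self.size_mm, self.voxel_mm):
            if s <= 0 or v <= 0:
                raise ValueError("phantom extents and voxel sizes must be positive")
            n = s / v
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"voxel size {v} mm does not divide extent {s} mm")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(int(round(s / v)) for s, v in zip(self.size_mm, self.voxel_mm))

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        dv = self.voxel_mm[axis]
        return (np.arange(n) + 0.5) * dv - (self.size_mm[axis] / 2 if axis < 2 else 0.0)


@dataclass(frozen=True)
class BeamSpec:
    """Monoenergetic pencil beam along +z, uniform circular footprint."""

    energy_MeV: float
    diameter_mm: float = 10.0
    entry_xy_mm: tuple[float, float] = (0.0, 0.0)  # relative to face center

    def __post_init__(self) -> None:
        if self.energy_MeV < 0:
            raise ValueError("beam energy must be non-negative")
        if self.diameter_mm <= 0:
            raise ValueError("beam diameter must be positive")
        if not (45.0 <= self.energy_MeV <= 250.0):
            import warnings

            warnings.warn(
                f"beam energy {self.energy_MeV} MeV outside the validated "
                "45-250 MeV band",
                stacklevel=2,
            )


class StoppingModel:
    """Range-energy relation for protons in a light material.

    Two modes:

    ``bragg_kleeman``
        The closed form R = alpha * E**p (water constants by default),
        analytically invertible.  This is the package default.
    ``table``
        Numerical integration of a (energy, mass stopping power) table,
        R(E) = integral dE' / S(E'); used as the independent oracle for the
        closed form and as the higher-fidelity alternative.

    Both modes express the range in g/cm^2 internally so that the 1/rho
    density scaling is exact.
    """

    def __init__(self, mode: str = "bragg_kleeman", *,
                 bk_alpha_cm: float = BK_ALPHA_CM, bk_p: float = BK_P,
                 energies_MeV: np.ndarray | None = None,
                 mass_stopping: np.ndarray | None = None) -> None:
        if mode not in ("bragg_kleeman", "table"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.bk_alpha_cm = float(bk_alpha_cm)
        self.bk_p = float(bk_p)
        if mode == "table":
            if energies_MeV is None or mass_stopping is None:
                raise ValueError("table mode requires a stopping-power table")
            e = np.asarray(energies_MeV, float)
            s = np.asarray(mass_stopping, float)
            if e.ndim != 1 or e.size < 4 or np.any(np.diff(e) <= 0):
                raise ValueError("table energies must be strictly increasing")
            if np.any(s <= 0):
                raise ValueError("stopping powers must be positive")
            # dense log-grid resample for a smooth integrand, then integrate
            eg = np.geomspace(e[0], e[-1], 4000)
            sg = np.exp(PchipInterpolator(np.log(e), np.log(s))(np.log(eg)))
            r = eg[0] / sg[0] + cumulative_trapezoid(1.0 / sg, eg, initial=0.0)
            self._e_grid, self._s_grid, self._r_grid = eg, sg, r
            self._range_of_e = PchipInterpolator(eg, r)        # g/cm^2
            self._energy_of_r = PchipInterpolator(r, eg)
            self._s_of_e = PchipInterpolator(eg, sg)

    # -- factories -------------------------------------------------------

    @classmethod
    def bragg_kleeman(cls, alpha_cm: float = BK_ALPHA_CM, p: float = BK_P) -> "StoppingModel":
        return cls("bragg_kleeman", bk_alpha_cm=alpha_cm, bk_p=p)

    @classmethod
    def from_table(cls, energies_MeV, mass_stopping) -> "StoppingModel":
        return cls("table", energies_MeV=energies_MeV, mass_stopping=mass_stopping)

    @classmethod
    def from_csv(cls, path) -> "StoppingModel":
        import pandas as pd

        df = pd.read_csv(path)
        return cls.from_table(df["energy_MeV"].to_numpy(),
                              df["mass_stopping_MeV_cm2_g"].to_numpy())

    def fit_bragg_kleeman(self, e_lo: float = 45.0, e_hi: float = 250.0,
                          n: int = 64) -> "StoppingModel":
        """Least-squares fit of (alpha, p) to this model's ranges on [e_lo, e_hi]."""
        e = np.geomspace(e_lo, e_hi, n)
        r_cm = np.array([self.range_g_cm2(x) for x in e])  # rho=1 reference
        coeff = np.polyfit(np.log(e), np.log(r_cm), 1)
        return StoppingModel.bragg_kleeman(alpha_cm=float(np.exp(coeff[1])),
                                           p=float(coeff[0]))

    # -- core relations --------------------------------------------------

    def range_g_cm2(self, energy_MeV: float) -> float:
        """CSDA range in areal density (material-density independent)."""
        if energy_MeV < 0:
            raise ValueError("energy must be non-negative")
        if energy_MeV == 0:
            return 0.0
        if self.mode == "bragg_kleeman":
            return self.bk_alpha_cm * energy_MeV**self.bk_p
        e = min(max(energy_MeV, self._e_grid[0]), self._e_grid[-1])
        if energy_MeV > self._e_grid[-1]:
            raise ValueError(
                f"energy {energy_MeV} MeV above the table maximum {self._e_grid[-1]}")
        return float(self._range_of_e(e))

    def range_mm(self, energy_MeV: float, material: MaterialComposition) -> float:
        return self.range_g_cm2(energy_MeV) / material.density_g_cm3 * 10.0

    def energy_at_depth(self, energy_MeV: float, z_mm,
                        material: MaterialComposition) -> np.ndarray | float:
        """Residual energy at depth z; 0 at and beyond the range."""
        z = np.asarray(z_mm, float)
        if np.any(z < 0):
            raise ValueError("depth must be non-negative")
        rr = self.range_g_cm2(energy_MeV) - z * material.density_g_cm3 / 10.0
        if self.mode == "bragg_kleeman":
            out = np.where(rr <= 0.0, 0.0,
                           (np.clip(rr, 0.0, None) / self.bk_alpha_cm) ** (1.0 / self.bk_p))
        else:
            floor = self._r_grid[0]
            e0 = self._energy_of_r(np.clip(rr, floor, self._r_grid[-1]))
            # two Newton refinements: dR/dE = 1/S, so dE = (R(E)-rr) * S(E)
            for _ in range(2):
                e0 = e0 - (self._range_of_e(e0) - np.clip(rr, floor, None)) * self._s_of_e(e0)
                e0 = np.clip(e0, self._e_grid[0], self._e_grid[-1])
            out = np.where(rr <= floor, 0.0, e0)
        return float(out) if np.isscalar(z_mm) else out


@dataclass(frozen=True)
class DepthProfile:
    """Uniformly binned 1D quantity vs depth (bin centers at (k+1/2)dz)."""

    depth_mm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.depth_mm, float)
        v = np.asarray(self.values, float)
        if d.ndim != 1 or d.size < 1 or d.size != v.size:
            raise ValueError("depth and value arrays must be 1D and equal length")
        if d.size > 1:
            steps = np.diff(d)
            if np.any(steps <= 0) or np.ptp(steps) > 1e-9 * steps[0]:
                raise ValueError("depth bins must be uniform and increasing")
        if np.any(v < -1e-12):
            raise ValueError("profile values must be non-negative")
        object.__setattr__(self, "depth_mm", d)
        object.__setattr__(self, "values", np.clip(v, 0.0, None))

    @property
    def step_mm(self) -> float:
        return float(self.depth_mm[1] - self.depth_mm[0]) if self.depth_mm.size > 1 else np.nan

    def to_csv(self, path, value_name: str = "value") -> None:
        import pandas as pd

        pd.DataFrame({"depth_mm": self.depth_mm,
                      value_name: self.values}).to_csv(path, index=False)


def range_straggling_sigma_mm(range_mm: float) -> float:
    """Gaussian range-straggling width, sigma = 0.012 R^0.935 (cm in, cm out)."""
    return STRAGGLE_A * (range_mm / 10.0) ** STRAGGLE_B * 10.0


def range_from_energy(energy_MeV: float, model: StoppingModel,
                      material: MaterialComposition = WATER_GEL) -> float:
    """Proton range in mm for entrance energy ``energy_MeV``."""
    return model.range_mm(energy_MeV, material)


def energy_at_depth(energy_MeV: float, z_mm, model: StoppingModel,
                    material: MaterialComposition = WATER_GEL):
    """Residual proton energy at depth; clamps to 0 beyond the range."""
    return model.energy_at_depth(energy_MeV, z_mm, material)


def _fine_edges(z_max_mm: float, dz_mm: float, substeps: int) -> np.ndarray:
    n = int(round(z_max_mm / dz_mm)) * substeps
    return np.linspace(0.0, z_max_mm, n + 1)


def _rebin(fine_mid: np.ndarray, fine_val: np.ndarray, dz_mm: float) -> np.ndarray:
    idx = np.floor(fine_mid / dz_mm).astype(int)
    return np.bincount(idx, weights=fine_val)


def required_extent_mm(energy_MeV: float, model: StoppingModel,
                       material: MaterialComposition = WATER_GEL) -> float:
    """Depth the profile grid must cover: range + 5 sigma + 1 mm margin."""
    r = model.range_mm(energy_MeV, material)
    return r + 5.0 * range_straggling_sigma_mm(r) + 1.0


def depth_dose_profile(energy_MeV: float, model: StoppingModel,
                       material: MaterialComposition = WATER_GEL, *,
                       z_max_mm: float | None = None, dz_mm: float = 0.5,
                       straggle: bool = True,
                       fluence_lambda_mm: float | None = 1000.0,
                       substeps: int = 10) -> DepthProfile:
    """Depth-dose curve of a pencil beam, per primary proton.

    Dose in a bin is the energy lost there (difference of residual energies
    at the bin edges) weighted by the surviving primary fluence
    Phi(z) = exp(-z / fluence_lambda_mm).  With ``straggle`` the curve is
    convolved with a Gaussian of width sigma_R, producing the finite-width
    Bragg peak slightly proximal of the nominal range.
    """
    if energy_MeV < 0:
        raise ValueError("energy must be non-negative")
    need = required_extent_mm(energy_MeV, model, material)
    if z_max_mm is None:
        z_max_mm = np.ceil(need / dz_mm) * dz_mm
    if z_max_mm < need - 1e-9:
        raise ValueError(
            f"profile grid must cover at least {need:.1f} mm "
            f"(range + straggle margin), got {z_max_mm} mm")
    edges = _fine_edges(z_max_mm, dz_mm, substeps)
    e_edges = model.energy_at_depth(energy_MeV, edges, material)
    mid = 0.5 * (edges[:-1] + edges[1:])
    dose = e_edges[:-1] - e_edges[1:]
    if fluence_lambda_mm is not None:
        dose = dose * np.exp(-mid / fluence_lambda_mm)
    if straggle:
        sigma = range_straggling_sigma_mm(model.range_mm(energy_MeV, material))
        dose = gaussian_filter1d(dose, sigma / (edges[1] - edges[0]), mode="constant")
    values = _rebin(mid, dose, dz_mm)
    centers = (np.arange(values.size) + 0.5) * dz_mm
    return DepthProfile(centers, values)
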