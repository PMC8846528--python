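"""Positron-emitter production: nuclide registry, cross sections, yield profiles.

Production along the beam follows the thin-target activation form

    Y(z) = n_target(rho, w) * sigma(E(z)) * Phi(z),

gated by each reaction's threshold energy.  Because the reaction thresholds
are ordered (13N at 5.660 MeV well below 15O at 16.79 and 11C at 20.61 MeV),
13N production persists closest to the end of range and forms the peak used
for range verification.

Yields are relative (per primary proton, arbitrary normalization): the
target number density folds the mass fraction and atomic mass into a
constant that cancels in every peak-position question.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .phantom import (
    BeamSpec,
    DepthProfile,
    MaterialComposition,
    PhantomSpec,
    StoppingModel,
    WATER_GEL,
    _fine_edges,
    _rebin,
    range_straggling_sigma_mm,
    required_extent_mm,
)

__all__ = [
    "NuclideSpec",
    "NUCLIDES",
    "CrossSection",
    "load_cross_section",
    "YieldMap",
    "production_profile",
    "yield_map_3d",
]

_ATOMIC_MASS = {"H": 1.008, "C": 12.011, "O": 15.999}

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class NuclideSpec:
    """A positron emitter with its production channel."""

    name: str
    half_life_min: float
    reaction: str
    threshold_MeV: float
    target_element: str

    def __post_init__(self) -> None:
        if self.half_life_min <= 0 or self.threshold_MeV <= 0:
            raise ValueError("half-life and threshold must be positive")

    @property
    def half_life_s(self) -> float:
        return self.half_life_min * 60.0

    @property
    def decay_constant_s(self) -> float:
        """lambda = ln 2 / T_1/2 in s^-1."""
        return LN2 / self.half_life_s


#: The three channels of the water-gel study. (p,2p2n) is inclusive of (p,a).
NUCLIDES: Mapping[str, NuclideSpec] = {
    "C11": NuclideSpec("C11", 20.39, "12C(p,pn)11C", 20.61, "C"),
    "O15": NuclideSpec("O15", 2.037, "16O(p,pn)15O", 16.79, "O"),
    "N13": NuclideSpec("N13", 9.965, "16O(p,2p2n)13N", 5.660, "O"),
}

_XS_FILES = {
    "N13": "xs_o16_p2p2n_n13_synthetic.csv",
    "O15": "xs_o16_ppn_o15_synthetic.csv",
    "C11": "xs_c12_ppn_c11_synthetic.csv",
}


@dataclass(frozen=True)
class CrossSection:
    """Threshold-gated excitation function, linear between knots.

    sigma(E) = 0 strictly below the threshold, linear interpolation between
    knots, constant extrapolation above the last knot.
    """

    energies_MeV: np.ndarray
    sigma_mb: np.ndarray
    threshold_MeV: float

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_MeV, float)
        s = np.asarray(self.sigma_mb, float)
        if e.ndim != 1 or e.size < 2 or e.size != s.size:
            raise ValueError("cross section needs matching 1D energy/sigma arrays")
        if np.any(np.diff(e) <= 0):
            raise ValueError("cross-section energies must be strictly increasing")
        if np.any(s < 0):
            raise ValueError("cross sections must be non-negative")
        if np.any(s[e < self.threshold_MeV] > 0):
            raise ValueError("sigma must vanish below the threshold")
        object.__setattr__(self, "energies_MeV", e)
        object.__setattr__(self, "sigma_mb", s)

    def __call__(self, energy_MeV) -> np.ndarray:
        e = np.asarray(energy_MeV, float)
        out = np.interp(e, self.energies_MeV, self.sigma_mb,
                        left=0.0, right=float(self.sigma_mb[-1]))
        return np.where(e < self.threshold_MeV, 0.0, out)

    def scaled(self, factor: float) -> "CrossSection":
        return CrossSection(self.energies_MeV, self.sigma_mb * factor,
                            self.threshold_MeV)


def load_cross_section(nuclide: str) -> CrossSection:
    """Packaged excitation-function fixture for C11 / O15 / N13."""
    if nuclide not in _XS_FILES:
        raise KeyError(f"no cross-section fixture for {nuclide!r}")
    import pandas as pd

    with resources.files("protonrange.data").joinpath(_XS_FILES[nuclide]).open() as fh:
        df = pd.read_csv(fh)
    return CrossSection(df["energy_MeV"].to_numpy(), df["sigma_mb"].to_numpy(),
                        NUCLIDES[nuclide].threshold_MeV)


def _target_density_rel(material: MaterialComposition, element: str) -> float:
    """Relative target nuclei density (arbitrary normalization constant)."""
    return material.density_g_cm3 * material.fraction(element) / _ATOMIC_MASS[element]


def production_profile(energy_MeV: float, nuclide: NuclideSpec, xs: CrossSection,
                       model: StoppingModel,
                       material: MaterialComposition = WATER_GEL, *,
                       z_max_mm: float | None = None, dz_mm: float = 0.5,
                       straggle: bool = True,
                       fluence_lambda_mm: float | None = 1000.0,
                       substeps: int = 10) -> DepthProfile:
    """Per-nuclide production density vs depth, n * sigma(E(z)) * Phi(z).

    With ``straggle`` the profile is convolved with the same Gaussian
    sigma_R as the dose curve (stopping depths straggle, so production
    cutoffs do too).  In straggle-off mode the profile is identically zero
    wherever the residual energy is below the reaction threshold.
    """
    if abs(xs.threshold_MeV - nuclide.threshold_MeV) > 1e-6:
        raise ValueError(
            f"cross-section threshold {xs.threshold_MeV} MeV does not match "
            f"{nuclide.name} threshold {nuclide.threshold_MeV} MeV")
    need = required_extent_mm(energy_MeV, model, material)
    if z_max_mm is None:
        z_max_mm = np.ceil(need / dz_mm) * dz_mm
    if z_max_mm < need - 1e-9:
        raise ValueError(
            f"profile grid must cover at least {need:.1f} mm, got {z_max_mm} mm")
    edges = _fine_edges(z_max_mm, dz_mm, substeps)
    mid = 0.5 * (edges[:-1] + edges[1:])
    e_mid = model.energy_at_depth(energy_MeV, mid, material)
    dz_fine = edges[1] - edges[0]
    y = _target_density_rel(material, nuclide.target_element) * xs(e_mid) * dz_fine
    if fluence_lambda_mm is not None:
        y = y * np.exp(-mid / fluence_lambda_mm)
    y[e_mid < nuclide.threshold_MeV] = 0.0
    if straggle:
        sigma = range_straggling_sigma_mm(model.range_mm(energy_MeV, material))
        y = gaussian_filter1d(y, sigma / dz_fine, mode="constant")
    values = _rebin(mid, y, dz_mm)
    centers = (np.arange(values.size) + 0.5) * dz_mm
    return DepthProfile(centers, values)


@dataclass(frozen=True)
class YieldMap:
    """3D production map of one nuclide on the phantom voxel grid."""

    values: np.ndarray  # (nx, ny, nz)
    voxel_mm: tuple[float, float, float]
    nuclide: str
    beam_energy_MeV: float

    def depth_profile(self) -> DepthProfile:
        dz = self.voxel_mm[2]
        centers = (np.arange(self.values.shape[2]) + 0.5) * dz
        return DepthProfile(centers, self.values.sum(axis=(0, 1)))


def yield_map_3d(beam: BeamSpec, phantom: PhantomSpec,
                 nuclides: Mapping[str, NuclideSpec],
                 cross_sections: Mapping[str, CrossSection],
                 model: StoppingModel, **profile_kwargs) -> dict[str, YieldMap]:
    """Per-nuclide 3D yield maps: 1D production profile spread over a
    uniform disc of the beam's footprint.

    Summing a map over x and y reproduces the 1D profile bin for bin.
    """
    dx, dy, dz = phantom.voxel_mm
    xc = phantom.axis_centers(0) - beam.entry_xy_mm[0]
    yc = phantom.axis_centers(1) - beam.entry_xy_mm[1]
    r = beam.diameter_mm / 2.0
    ex, ey = beam.entry_xy_mm
    if (abs(ex) + r > phantom.size_mm[0] / 2) or (abs(ey) + r > phantom.size_mm[1] / 2):
        raise ValueError("beam footprint falls outside the phantom entrance face")
    disc = (xc[:, None] ** 2 + yc[None, :] ** 2) <= r**2
    n_disc = int(disc.sum())
    if n_disc == 0:
        raise ValueError("beam footprint covers no voxel centers; refine the grid")
    out: dict[str, YieldMap] = {}
    for name, nuc in nuclides.items():
        prof = production_profile(beam.energy_MeV, nuc, cross_sections[name],
                                  model, phantom.material,
                                  z_max_mm=phantom.size_mm[2], dz_mm=dz,
                                  **profile_kwargs)
        vol = np.zeros(phantom.shape)
        vol[disc, :] = prof.values / n_disc
        out[name] = YieldMap(vol, phantom.voxel_mm, name, beam.energy_MeV)
    return out
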