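"""Peak localization and Bragg-to-13N offset computation.

The calibration quantity of the pipeline is the offset

    offset = (Bragg-peak depth) - (13N-peak depth),

computed per beam energy from the depth-dose profile and the 13N
production profile on a shared 0.5 mm grid, and swept over the therapeutic
band 45-250 MeV in 5 MeV steps.  Also houses the ROI geometry used by the
spectral ROI analysis and the published-table arithmetic utilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .activation import NUCLIDES, CrossSection, load_cross_section, production_profile
from .phantom import (
    DepthProfile,
    MaterialComposition,
    PhantomSpec,
    StoppingModel,
    WATER_GEL,
    depth_dose_profile,
)

__all__ = [
    "PeakEstimate",
    "find_peak",
    "depth_profile",
    "OffsetRecord",
    "OffsetTable",
    "PipelineConfig",
    "compute_offset",
    "sweep_energies",
    "benchmark_deviation",
    "load_range_benchmark",
    "load_published_offsets",
    "RoiBox",
    "default_rois",
]


@dataclass(frozen=True)
class PeakEstimate:
    depth_mm: float
    bin_index: int
    mode: str  # bin_center | parabolic


def find_peak(profile: DepthProfile, refine: str = "bin_center") -> PeakEstimate:
    """Global maximum of a depth profile; ties break toward smaller depth.

    ``parabolic`` fits a parabola through the three bins around the argmax
    (falls back to the bin center at the grid edges).
    """
    v = profile.values
    if v.size == 0 or not np.any(v > 0):
        raise ValueError("cannot locate a peak in an all-zero profile")
    k = int(np.argmax(v))  # first occurrence = shallowest on ties
    depth = float(profile.depth_mm[k])
    if refine == "parabolic" and 0 < k < v.size - 1:
        y0, y1, y2 = v[k - 1], v[k], v[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            depth += 0.5 * (y0 - y2) / denom * profile.step_mm
    elif refine not in ("bin_center", "parabolic"):
        raise ValueError(f"unknown refinement {refine!r}")
    return PeakEstimate(depth, k, refine)


def depth_profile(volume: np.ndarray, voxel_mm, roi_mask: np.ndarray | None = None) -> DepthProfile:
    """Reduce a 3D volume to depth by summing over a lateral ROI."""
    volume = np.asarray(volume, float)
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, bool)
        if roi_mask.shape != volume.shape[:2]:
            raise ValueError("lateral ROI shape must match (nx, ny)")
        if not roi_mask.any():
            raise ValueError("lateral ROI is empty")
        vals = volume[roi_mask, :].sum(axis=0)
    else:
        vals = volume.sum(axis=(0, 1))
    dz = voxel_mm[2]
    return DepthProfile((np.arange(vals.size) + 0.5) * dz, vals)


@dataclass(frozen=True)
class OffsetRecord:
    energy_MeV: float
    bragg_mm: float
    n13_mm: float

    @property
    def offset_mm(self) -> float:
        return self.bragg_mm - self.n13_mm


class OffsetTable:
    """Energy -> (Bragg depth, 13N depth, offset) with CSV round-tripping."""

    COLUMNS = ("energy_MeV", "bragg_mm", "n13_mm", "offset_mm")

    def __init__(self, df: pd.DataFrame) -> None:
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"offset table missing columns {sorted(missing)}")
        e = df["energy_MeV"].to_numpy(float)
        if np.any(np.diff(e) <= 0):
            raise ValueError("table energies must be strictly ascending")
        resid = df["offset_mm"] - (df["bragg_mm"] - df["n13_mm"])
        if np.max(np.abs(resid.to_numpy())) > 1e-9:
            raise ValueError("offset column must equal bragg - n13")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: list[OffsetRecord]) -> "OffsetTable":
        return cls(pd.DataFrame(
            [(r.energy_MeV, r.bragg_mm, r.n13_mm, r.offset_mm) for r in records],
            columns=list(cls.COLUMNS)))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def energies(self) -> np.ndarray:
        return self.df["energy_MeV"].to_numpy(float)

    @property
    def offsets(self) -> np.ndarray:
        return self.df["offset_mm"].to_numpy(float)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OffsetTable":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class PipelineConfig:
    """Shared knobs of the dose/activation comparison."""

    model: StoppingModel
    material: MaterialComposition = WATER_GEL
    dz_mm: float = 0.5
    straggle: bool = True
    fluence_lambda_mm: float | None = 1000.0
    substeps: int = 10
    refine: str = "bin_center"

    @classmethod
    def default(cls) -> "PipelineConfig":
        return cls(model=StoppingModel.bragg_kleeman())


def compute_offset(energy_MeV: float, config: PipelineConfig | None = None,
                   xs_n13: CrossSection | None = None) -> OffsetRecord:
    """Bragg-peak and 13N-peak depths on one grid, and their difference."""
    config = config or PipelineConfig.default()
    xs = xs_n13 or load_cross_section("N13")
    kw = dict(dz_mm=config.dz_mm, straggle=config.straggle,
              fluence_lambda_mm=config.fluence_lambda_mm,
              substeps=config.substeps)
    dose = depth_dose_profile(energy_MeV, config.model, config.material, **kw)
    n13 = production_profile(energy_MeV, NUCLIDES["N13"], xs, config.model,
                             config.material, **kw)
    zb = find_peak(dose, config.refine).depth_mm
    zn = find_peak(n13, config.refine).depth_mm
    return OffsetRecord(energy_MeV, zb, zn)


def sweep_energies(start_MeV: float = 45.0, stop_MeV: float = 250.0,
                   step_MeV: float = 5.0, config: PipelineConfig | None = None,
                   xs_n13: CrossSection | None = None) -> OffsetTable:
    """One OffsetRecord per energy; the default sweep yields 42 rows."""
    if step_MeV <= 0 or start_MeV >= stop_MeV:
        raise ValueError("need start < stop and a positive step")
    config = config or PipelineConfig.default()
    xs = xs_n13 or load_cross_section("N13")
    energies = np.arange(start_MeV, stop_MeV + step_MeV / 2, step_MeV)
    return OffsetTable.from_records(
        [compute_offset(float(e), config, xs) for e in energies])


def benchmark_deviation(range_a_mm: float, range_b_mm: float) -> tuple[float, float, float]:
    """(mean range, absolute deviation, percent of mean to 2 decimals)."""
    if range_a_mm <= 0 or range_b_mm <= 0:
        raise ValueError("ranges must be positive")
    mean = (range_a_mm + range_b_mm) / 2.0
    dev = abs(range_a_mm - range_b_mm)
    return mean, dev, round(100.0 * dev / mean, 2)


def _read_fixture(name: str) -> pd.DataFrame:
    with resources.files("protonrange.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_range_benchmark() -> pd.DataFrame:
    """Published PHITS-vs-SRIM range comparison (80/160/240 MeV)."""
    return _read_fixture("range_benchmark_phits_srim.csv")


def load_published_offsets() -> OffsetTable:
    """The published 42-row offset table (45-250 MeV, 5 MeV steps)."""
    return OffsetTable(_read_fixture("offset_table_45_250.csv"))


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned box in phantom coordinates (mm), z from the entry face."""

    name: str
    x_mm: tuple[float, float]
    y_mm: tuple[float, float]
    z_mm: tuple[float, float]

    def mask(self, phantom: PhantomSpec) -> np.ndarray:
        xc = phantom.axis_centers(0)
        yc = phantom.axis_centers(1)
        zc = phantom.axis_centers(2)
        mx = (xc >= self.x_mm[0]) & (xc <= self.x_mm[1])
        my = (yc >= self.y_mm[0]) & (yc <= self.y_mm[1])
        mz = (zc >= self.z_mm[0]) & (zc <= self.z_mm[1])
        return mx[:, None, None] & my[None, :, None] & mz[None, None, :]


def default_rois(phantom: PhantomSpec, bragg_depth_mm: float,
                 beam_halfwidth_mm: float = 5.0) -> dict[str, RoiBox]:
    """The four analysis boxes: whole phantom, entrance edge (first 10 mm),
    plateau (20-80% of the Bragg depth), and Bragg peak (+- 5 mm)."""
    hx = phantom.size_mm[0] / 2
    hy = phantom.size_mm[1] / 2
    w = beam_halfwidth_mm
    rb = bragg_depth_mm
    return {
        "whole": RoiBox("whole", (-hx, hx), (-hy, hy), (0, phantom.size_mm[2])),
        "edge": RoiBox("edge", (-w, w), (-w, w), (0, 10.0)),
        "plateau": RoiBox("plateau", (-w, w), (-w, w), (0.2 * rb, 0.8 * rb)),
        "peak": RoiBox("peak", (-w, w), (-w, w), (rb - 5.0, rb + 5.0)),
    }
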