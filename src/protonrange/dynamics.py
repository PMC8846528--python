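"""Dynamic PET frame synthesis from yield maps.

Irradiation is treated as an impulse at t = 0: every produced nucleus is in
place when the clock starts, and activity decays as A(t) = lambda N0
exp(-lambda t).  Frames store expected decay counts (frame integrals of the
activity), not decay-corrected values; optional Poisson noise models
counting statistics.

On-disk form: a 4D NIfTI volume + a frame-schedule CSV + a JSON metadata
sidecar.  The reader accepts the same trio for externally produced data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .activation import NUCLIDES, NuclideSpec, YieldMap

__all__ = [
    "FrameSchedule",
    "DynamicSeries",
    "activity_at",
    "decays_between",
    "build_frames",
    "add_poisson_noise",
    "save_series",
    "load_series",
]


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping acquisition frames in seconds."""

    start_s: np.ndarray
    end_s: np.ndarray

    def __post_init__(self) -> None:
        t1 = np.asarray(self.start_s, float)
        t2 = np.asarray(self.end_s, float)
        if t1.ndim != 1 or t1.size == 0 or t1.shape != t2.shape:
            raise ValueError("schedule needs matching 1D start/end arrays")
        if np.any(t2 <= t1):
            raise ValueError("frame ends must exceed frame starts")
        if np.any(t1[1:] < t2[:-1] - 1e-9):
            raise ValueError("frames must not overlap")
        if np.any(np.diff(t1) <= 0):
            raise ValueError("frame starts must increase")
        object.__setattr__(self, "start_s", t1)
        object.__setattr__(self, "end_s", t2)

    @classmethod
    def uniform(cls, n_frames: int = 75, frame_s: float = 60.0,
                t0_s: float = 0.0) -> "FrameSchedule":
        """Default: 75 one-minute frames starting at the end of irradiation."""
        t1 = t0_s + np.arange(n_frames) * frame_s
        return cls(t1, t1 + frame_s)

    def __len__(self) -> int:
        return int(self.start_s.size)

    @property
    def durations_s(self) -> np.ndarray:
        return self.end_s - self.start_s

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"frame_start_s": self.start_s,
                      "frame_end_s": self.end_s}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FrameSchedule":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["frame_start_s"].to_numpy(), df["frame_end_s"].to_numpy())


@dataclass
class DynamicSeries:
    """Time-ordered count volumes: data shape (nx, ny, nz, n_frames)."""

    data: np.ndarray
    schedule: FrameSchedule
    voxel_mm: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, float)
        if d.ndim != 4:
            raise ValueError("series data must be 4D (x, y, z, frame)")
        if d.shape[3] != len(self.schedule):
            raise ValueError("frame count must match the schedule length")
        if np.any(d < 0):
            raise ValueError("counts must be non-negative")
        self.data = d

    def voxel_tac(self, i: int, j: int, k: int) -> np.ndarray:
        return self.data[i, j, k, :]


def activity_at(n0: float, decay_constant_s: float, t_s) -> np.ndarray | float:
    """A(t) = lambda N0 exp(-lambda t) for an impulse-produced population."""
    if decay_constant_s <= 0:
        raise ValueError("decay constant must be positive")
    if np.any(np.asarray(n0) < 0):
        raise ValueError("N0 must be non-negative")
    return decay_constant_s * n0 * np.exp(-decay_constant_s * np.asarray(t_s, float))


def decays_between(n0, decay_constant_s: float, t1_s, t2_s):
    """Closed-form decays in [t1, t2]: N0 (e^{-lambda t1} - e^{-lambda t2})."""
    if decay_constant_s <= 0:
        raise ValueError("decay constant must be positive")
    lam = decay_constant_s
    return np.asarray(n0) * (np.exp(-lam * np.asarray(t1_s))
                             - np.exp(-lam * np.asarray(t2_s)))


def build_frames(yield_maps: Mapping[str, YieldMap], schedule: FrameSchedule,
                 registry: Mapping[str, NuclideSpec] = NUCLIDES, *,
                 scale: float = 1.0, meta: dict | None = None) -> DynamicSeries:
    """Noiseless dynamic series: per-voxel counts are the summed closed-form
    frame integrals of each nuclide's decay."""
    maps = list(yield_maps.items())
    if not maps:
        raise ValueError("need at least one yield map")
    shape = maps[0][1].values.shape
    voxel = maps[0][1].voxel_mm
    for name, m in maps:
        if m.values.shape != shape or m.voxel_mm != voxel:
            raise ValueError(f"yield map {name!r} is on a different voxel grid")
    data = np.zeros(shape + (len(schedule),))
    for name, m in maps:
        lam = registry[name].decay_constant_s
        weights = (np.exp(-lam * schedule.start_s)
                   - np.exp(-lam * schedule.end_s))  # (n_frames,)
        data += scale * m.values[..., None] * weights
    info = {"beam_energy_MeV": maps[0][1].beam_energy_MeV,
            "nuclides": [n for n, _ in maps], "noise": None}
    info.update(meta or {})
    return DynamicSeries(data, schedule, voxel, info)


def add_poisson_noise(series: DynamicSeries, scale: float = 1.0,
                      seed: int | None = None) -> DynamicSeries:
    """Replace each voxel-frame count by a Poisson draw with mean
    scale * count.  Same seed, same series -> bit-identical output."""
    if scale <= 0:
        raise ValueError("noise scale must be positive")
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(scale * series.data).astype(float)
    meta = dict(series.meta)
    meta["noise"] = {"kind": "poisson", "scale": scale, "seed": seed}
    return DynamicSeries(noisy, series.schedule, series.voxel_mm, meta)


def save_series(series: DynamicSeries, prefix) -> None:
    """Write the NIfTI + schedule CSV + JSON metadata trio at ``prefix``."""
    import nibabel as nib

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(series.voxel_mm) + [1.0])
    nib.save(nib.Nifti1Image(series.data, affine), str(prefix) + ".nii")
    series.schedule.to_csv(str(prefix) + "_frames.csv")
    with open(str(prefix) + ".json", "w") as fh:
        json.dump({"voxel_mm": list(series.voxel_mm), **series.meta}, fh, indent=1)


def load_series(prefix) -> DynamicSeries:
    import nibabel as nib

    prefix = str(prefix)
    img = nib.load(prefix + ".nii")
    with open(prefix + ".json") as fh:
        meta = json.load(fh)
    voxel = tuple(meta.pop("voxel_mm"))
    schedule = FrameSchedule.from_csv(prefix + "_frames.csv")
    return DynamicSeries(np.asarray(img.dataobj, float), schedule, voxel, meta)
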