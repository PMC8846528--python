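"""Spectral analysis: recover half-lives and separate the 13N component.

First fits a noiseless three-component time-activity curve on the default
log-spaced beta grid (1e-4 to 0.1 s^-1, M = 1000) and reports the
amplitude-weighted half-life in each nuclide band.  Then runs the voxel-wise
analysis on a synthetic 80 MeV acquisition (15-75 min window) and prints the
ROI band totals.
"""

import numpy as np

import protonrange as pr

LN2 = np.log(2.0)

# --- half-life recovery from a single TAC ---
schedule = pr.FrameSchedule.uniform(75, 60.0)
grid = pr.make_beta_grid()
basis = pr.build_irf_basis(schedule, grid)
tac = np.zeros(len(schedule))
for spec in pr.NUCLIDES.values():
    lam = spec.decay_constant_s
    tac += (np.exp(-lam * schedule.start_s) - np.exp(-lam * schedule.end_s)) / lam

fit = pr.fit_voxel(tac, basis)
bands = pr.default_bands(grid)
print("nuclide   true T1/2    recovered T1/2")
for name, spec in pr.NUCLIDES.items():
    t12 = LN2 / fit.weighted_beta(*bands[name]) / 60.0
    print(f"{name:7s}  {spec.half_life_min:7.3f} min  {t12:10.4f} min")
print("NNLS splits each exponential over adjacent grid points; the")
print("amplitude-weighted beta lands within one grid step of the truth.\n")

# --- voxel-wise SA of an 80 MeV run, ROI spectra ---
phantom = pr.PhantomSpec(size_mm=(24, 24, 70), voxel_mm=(2, 2, 0.5))
model = pr.StoppingModel.bragg_kleeman()
xs = {n: pr.load_cross_section(n) for n in pr.NUCLIDES}
maps = pr.yield_map_3d(pr.BeamSpec(80.0), phantom, pr.NUCLIDES, xs, model)
series = pr.build_frames(maps, pr.FrameSchedule.uniform(60, 60.0, t0_s=900.0))
image = pr.fit_series(series, mask="axis")

bragg = pr.find_peak(pr.depth_dose_profile(80.0, model, z_max_mm=70.0)).depth_mm
rois = pr.default_rois(phantom, bragg)
print("ROI band totals (summed alpha; amplitudes at the 15 min window start):")
for name in ("peak", "plateau", "edge"):
    tot = image.roi_band_totals(rois[name].mask(phantom), pr.default_bands(grid))
    winner = max(tot, key=tot.get)
    pretty = ", ".join(f"{k} {v:.4f}" for k, v in tot.items())
    print(f"  {name:8s} {pretty}   -> dominated by {winner}")
print("13N dominates the Bragg-peak ROI; the long-lived 11C dominates the")
print("plateau once the short-lived 15O has decayed away.")
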