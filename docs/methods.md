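# Methods

This note records the models behind `protonrange`, the defaults and why
they were chosen, and what the synthetic pipeline does and does not
emulate.

## Beam and phantom model

The phantom is a homogeneous water-gel block (default 100 × 100 × 400 mm),
density 1.010 g/cm³, composition by weight H 11.00%, C 4.65%, O 84.35% —
an agar/water mix with no nitrogen, so every ¹³N nucleus comes from the
beam's interaction with ¹⁶O rather than from pre-existing ¹⁴N. The beam is
a monoenergetic pencil beam along +z with a uniform 10 mm circular
footprint; depth is measured from the entrance face. Air upstream of the
phantom is ignored (its energy loss is negligible at these energies).

**Range–energy relation.** Two interchangeable modes:

- *Bragg–Kleeman* (default): R[cm] = α E^p with α = 0.0022, p = 1.77 for
  water, divided by the material density. It is analytically invertible,
  which makes the residual-energy map E(z) = ((R − z)/α)^{1/p} exact and
  fast.
- *Table*: numerical integration R(E) = ∫ dE′/S(E′) of the packaged
  stopping-power table, with monotone (PCHIP) interpolation and two Newton
  refinements for the inverse. This mode is the independent oracle for the
  closed form; the two agree within 3% over 45–250 MeV.

The packaged table (`stopping_power_water_synthetic.csv`) is computed from
the uncorrected Bethe formula with I = 75 eV and Z/A = 0.55509; it is a
synthetic stand-in for an evaluated stopping-power compilation, accurate to
about a percent above a few MeV (e.g. 7.29 MeV cm²/g at 100 MeV, CSDA
range 5.18 g/cm² at 80 MeV), which is ample for peak-position questions.
Both modes carry ranges in areal density internally, so the 1/ρ density
scaling of range is exact by construction.

**Depth dose.** Dose per bin is the residual-energy difference across the
bin edges (exact binning of dE/dz) weighted by a surviving-fluence factor
Φ(z) = exp(−z/Λ) with Λ = 1000 mm representing first-order nuclear removal
— it tilts the plateau but does not move peak positions materially.
Profiles are computed on a fine sub-grid (10 sub-steps per bin), convolved
with a Gaussian of width σ_R = 0.012 R^0.935 (cm) to model range
straggling, then re-binned to the default 0.5 mm grid. With straggling and
fluence attenuation off, the integrated profile equals the beam energy
exactly (energy conservation), which the tests exploit.

## Activation model

Production of each emitter follows the thin-target form
Y(z) = n_target · σ(E(z)) · Φ(z), gated strictly below the reaction
threshold. The nuclide registry is:

| nuclide | T½ (min) | reaction | threshold (MeV) |
|---|---|---|---|
| ¹¹C | 20.39 | ¹²C(p,pn)¹¹C | 20.61 |
| ¹⁵O | 2.037 | ¹⁶O(p,pn)¹⁵O | 16.79 |
| ¹³N | 9.965 | ¹⁶O(p,2p2n)¹³N (incl. (p,α)) | 5.660 |

Outputs are relative (per primary proton): the target number density folds
mass fraction and atomic mass into a normalization constant that cancels in
every peak-position and ratio question. ¹¹C production from ¹⁶O is not
modelled; only the three channels above are.

**Cross-section fixtures.** The packaged excitation functions are synthetic
CSV curves (linear between knots, constant above the last knot, zero below
threshold) encoding the published qualitative shapes. The ¹³N curve rises
from its 5.660 MeV threshold to a ~29 mb bump at 13 MeV, decays with a
9 MeV scale, and settles on a flat 4 mb plateau over 37.5–250 MeV. The
bump parameters are the one deliberately calibrated element of the
generator: the near-threshold shape controls where the ¹³N peak forms
relative to the end of range, and it was fixed once so that the swept
offsets reproduce the published 1.0–2.0 mm band, then frozen. The absolute
scales (¹¹C peaking near 90 mb at 45 MeV, ¹⁵O near 68 mb at 28 MeV) follow
the published curves closely enough that the ROI spectra reproduce the
qualitative nuclide ordering (see below); peak positions are insensitive
to them.

**Straggling of production.** The same Gaussian σ_R convolution applied to
the dose is applied to the production profiles: physically the stopping
depth of each proton straggles, so the production cutoff does too. Without
it the high-energy offsets would be systematically wrong (the smeared dose
peak moves proximal while an unsmeared ¹³N peak would not). The strict
"zero below threshold" guarantee therefore holds exactly in straggle-off
mode, and to within the 5σ Gaussian tail otherwise.

**3D maps.** The lateral profile is a uniform disc: every voxel whose
center lies in the footprint gets an equal share of the 1D profile, so the
x,y-sum reproduces the 1D profile bin for bin (an exactness the tests
assert at 1e-9).

## Dynamics

Irradiation is an impulse at t = 0: all nuclei are in place when the clock
starts (a finite-duration build-up mode is out of scope). Frames store
expected decay counts, i.e. closed-form integrals
N₀(e^{−λt₁} − e^{−λt₂}) summed over nuclides — not decay-corrected values
and not point samples; the spectral stage operates on raw frame counts.
The default schedule is 75 one-minute frames. Poisson noise is applied
per voxel-frame with a seeded `numpy` generator; the seed is recorded in
the series metadata so any noisy realization is reproducible bit for bit.

## Spectral analysis

Each voxel's TAC is modelled as C_v = Σ_j α_j IRF_j with α_j ≥ 0, where
the basis columns are frame-averaged impulse responses
(e^{−β t₁} − e^{−β t₂})/(βΔt) on a log-uniform grid of M = 1000 decay
constants between 10⁻⁴ and 0.1 s⁻¹ (endpoints exact). Frame averaging —
rather than point sampling — is used because frames are integrals of
counts. The fit is `scipy.optimize.nnls`; it is deterministic and needs no
initialization.

Because the grid is discrete, a single exponential is typically split over
a few adjacent grid points. Components are therefore grouped into bands
with edges at the geometric midpoints of the registry decay constants
(≈ 8.1·10⁻⁴ and 2.56·10⁻³ s⁻¹) — symmetric in log-β, the grid's own
metric — and each band is summarized by its amplitude-weighted mean β.
On noiseless data this recovers the generating half-life within one grid
step (a factor of ~1.007).

**Reference time.** The impulse is referenced to the start of the supplied
schedule, so fitting a late window yields amplitudes equal to each
component's activity at the window start. The default ROI analysis uses
the 15–75 min window (the 60-minute dataset): by then ¹⁵O (T½ ≈ 2 min)
has decayed ~5 half-lives of its dominance away, and the spectra show the
clinically meaningful ordering — ¹³N dominates the Bragg-peak ROI, ¹¹C the
plateau and entrance regions. With a window starting at t = 0 the ¹⁵O
amplitude (λN₀ with the largest λ) trivially dominates every
oxygen-containing ROI.

**S_v and thresholding.** S_v = Σ_j α_j β_j up-weights fast decay,
enhancing ¹⁵O/¹³N against the ¹¹C background; voxels are kept iff
S_v strictly exceeds the threshold (default 1.5, in the arbitrary count
units of the run — scale it with your normalization). Voxel iteration
defaults to the beam-axis column for tractability; a full-volume
(`nonzero`) mode is available.

## Peak finding and offsets

Peaks are reported at bin centers by default (ties break toward the
shallower bin), matching the 0.5 mm quantization of the published offset
table; an opt-in parabolic refinement fits the three bins around the
argmax and localizes a smooth peak to a few percent of a bin. The offset
at one energy is computed from the dose and ¹³N profiles on one shared
grid; the default sweep covers 45–250 MeV in 5 MeV steps (42 rows).
Reported offsets are therefore multiples of 0.5 mm.

The published 42-row offset table and the PHITS/SRIM range benchmark are
packaged verbatim as fixtures. The benchmark's "range" values (59/58 mm at
80 MeV) exceed CSDA water ranges and are used only by the arithmetic
utility (mean, absolute deviation, percent to 2 decimals); the physics
model is deliberately not tuned to them.

ROI geometry (the published figure gives no numbers): whole = full
phantom; edge = first 10 mm; plateau = [0.2 R_B, 0.8 R_B];
peak = R_B ± 5 mm, where R_B is the located Bragg depth. All overridable.

## Calibration (PeakCalib)

Bragg depth, ¹³N depth and offset are interpolated independently against
energy — piecewise linear or natural cubic spline (clamped boundaries
optional); "natural" is the standard reading of a non-linear cubic-spline
lookup. Both interpolants pass through every knot exactly, and the dense
export grid uses 0.1 MeV steps (2051 rows for the default table). The
identity offset = bragg − n13 is exact on the linear grid and verified,
not enforced, for the cubic. Extrapolation beyond the knot range raises:
offsets outside the simulated band are unvalidated.

## Problem sizes and numerical choices

- Depth profiles: 0.5 mm bins, 10× sub-stepping, Gaussian convolution on
  the fine grid. The full 42-energy sweep runs in a few seconds.
- Spectral fits: 75×1000 (or 60×1000) NNLS per voxel, ~10 ms each; the
  synthetic ROI analyses use a 24 × 24 × 70 mm phantom at (2, 2, 0.5) mm
  voxels with the beam-axis mask, which keeps a full run under two
  seconds while exercising every stage.
- Ties, degenerate inputs: all-zero TACs short-circuit to a zero fit;
  all-zero profiles refuse peak finding; grids that do not cover
  range + 5σ_R raise with the required extent in the message.

## What the generator does not emulate

No nuclear-interaction transport (secondary particles, lateral Molière
scattering), no scanner model (sensitivity, attenuation, randoms,
reconstruction), no SOBP beams, no heterogeneous geometries, and no
denoising. Passing tests therefore demonstrate the internal consistency
of the analysis chain and its behaviour under the stated activation
kinetics — not performance on measured PET data, where noise, resolution
and washout effects enter before the spectral stage.
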