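# protonrange

Proton-therapy range verification from positron-emitter activation imaging.

A proton beam stopping in tissue activates short-lived β⁺ emitters — ¹¹C,
¹⁵O and ¹³N — whose annihilation photons can be imaged with PET. Because
the ¹⁶O(p,2p2n)¹³N channel has a much lower production threshold
(5.660 MeV) than the ¹⁵O (16.79 MeV) and ¹¹C (20.61 MeV) channels, ¹³N is
produced closest to the end of the proton range: its activity peak sits a
stable 1–2 mm proximal to the Bragg peak across the whole therapeutic
energy band. Measure the ¹³N peak, add the calibrated offset, and you have
the Bragg-peak position.

`protonrange` implements that idea end to end, for medical physicists and
methods researchers who want a tested, scriptable sandbox rather than a
full Monte Carlo chain:

- **Analytic phantom physics** — Bragg–Kleeman range–energy relation
  R = αE^p (or numerical integration of a packaged stopping-power table),
  residual energy vs depth, depth-dose curves with Gaussian range
  straggling σ_R = 0.012 R^0.935.
- **Activation** — threshold-gated production profiles
  Y(z) ∝ n_target · σ(E(z)) · Φ(z) and 3D yield maps for a pencil beam in
  a homogeneous water-gel phantom (ρ = 1.010 g/cm³, H/C/O only).
- **Dynamics** — impulse-irradiation decay to 1-minute PET frames
  (default 75 min), optional seeded Poisson counting noise, NIfTI I/O.
- **Spectral analysis** — per-voxel non-negative least squares
  decomposition of the time-activity curve C_v(t) = Σ_j α_j IRF_j onto a
  log-uniform grid of decay constants β ∈ [10⁻⁴, 0.1] s⁻¹ (M = 1000),
  the S_v = Σ_j α_j β_j background-suppression statistic, per-nuclide band
  images and ROI spectra.
- **Range finding & calibration** — peak localization, the 45–250 MeV
  offset sweep, and a PeakCalib-style linear / natural-cubic-spline lookup
  of the offset at 0.1 MeV resolution.

## Worked example

```python
import protonrange as pr

rec = pr.compute_offset(80.0)          # analytic 80 MeV pipeline, 0.5 mm bins
print(rec.bragg_mm, rec.n13_mm, rec.offset_mm)
# 50.25 48.75 1.5

table = pr.sweep_energies(45.0, 250.0, 5.0)   # 42 energies
print(table.offsets.min(), table.offsets.max())
# 1.0 2.0

curve = pr.fit_interpolant(pr.load_published_offsets(), "linear")
print(curve.estimate_bragg(48.0, 80.0))       # measured 13N depth -> Bragg
# 50.0
```

The Bragg peak of the 80 MeV beam is found at 50.25 mm and the ¹³N
production peak at 48.75 mm, an offset of 1.5 mm; over the full sweep every
offset lies in the 1–2 mm band, which is what makes the ¹³N peak a usable
range proxy. The last line applies the calibration: a ¹³N peak measured at
48.0 mm with a known 80 MeV beam implies a Bragg peak at 50.0 mm.

Spectral analysis of a noiseless three-component time-activity curve
(75 one-minute frames) recovers the half-lives from the frame data alone:

```
nuclide   true T1/2    recovered T1/2
C11       20.390 min     20.3898 min
O15        2.037 min      2.0370 min
N13        9.965 min      9.9651 min
```

The `examples/` directory holds one short narrative script per capability
(depth dose, activation profiles, dynamic frames, spectral analysis, the
offset sweep, calibration); each prints the numbers it computes and a line
on what they mean.

A thin CLI covers the shell-facing pieces:

```sh
protonrange sweep --out offsets.csv
protonrange peakcalib --energy 127.3 --n13-depth 150.0 --export-grid grid.csv
protonrange sa --series run80 --out-prefix run80_sa
```

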