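# Methods

This note documents the simulation model, the reconstruction, the metrics,
and the numerical and design choices behind `simtempo`. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Simulation model

**Sample.** A square grid of side `N` with exactly `round(density · N²)`
pixels set to `max_signal` photons (positions drawn without replacement
from a seeded generator). The exact-count construction — rather than
per-pixel Bernoulli sampling — makes the emitter count deterministic and
testable. Emitters may be adjacent; no minimum-separation constraint is
imposed. A sparse point field has spectral support at essentially every
spatial frequency, which is what lets a single sample probe the whole
Fourier plane at once. Defaults: `density = 0.01`, `max_signal = 1` photon
for noise-free runs (any positive value gives identical metrics, since
z-scoring removes the intensity scale; `max_signal` only matters for the
Poisson-noise experiments).

**Temporal modulation.** The sample's brightness follows
`GTm(t) = 0.75 + sin(2πt/Tm)/4`, bounded in [0.5, 1] so that no frame is
completely dark. `t` is the 0-based frame index; output surfaces (CSV
headers, logs) report 1-based frame numbers. `Tm` is the modulation period
in frames. Default series length is 512 frames at full scale; a single
emitter layout is reused for every `Tm` in a sweep (fixed per run seed).

**Microscope.** Incoherent imaging with the circular-pupil OTF — the 2D
autocorrelation of a circular aperture — implemented in closed form:
`T(ρ) = (2/π)(arccos ρ − ρ√(1−ρ²))`, `ρ = |f|/f_c`, zero beyond the cutoff
`f_c`. The closed form is exact and grid-independent; the numeric
disk-autocorrelation is retained in the tests as an independent oracle
(agreement within 1e-3, the discretization bound). Imaging is circular
convolution (plain transform-multiply, periodic boundaries, no padding);
the PSF is the non-negative Airy intensity pattern, so blurred images stay
non-negative up to float rounding. Default `f_c = N/4` (128 on the 512
grid), i.e. a real-domain cutoff period of 4 px.

**Illumination.** Nine patterns `1 + m·cos(2π(k̂·r)/p + φ)` in angle-major
order; angles default to 0°, 60°, 120° and phases to 0, 2π/3, 4π/3 —
equally spaced values are the standard SIM choice and keep the
phase-mixing system well conditioned. Modulation depth `m = 1` by default;
the mean-1 intensity convention makes the total dose equal to widefield
(the three phase patterns at one angle sum exactly to the constant 3).
The fringe period defaults to 4.75 px, slightly above the cutoff period so
the fringes remain transmissible. Only the emission path is blurred; the
excitation patterns are not filtered by the detection OTF. The fringe
frequency `N/p` is generally non-integer and is never snapped to the grid;
consequently each pattern's spatial mean deviates from 1 by spectral
leakage of order `1/N` (~2·10⁻³ at `N = 512`).

**Noise.** Optional Poisson shot noise, applied after blurring: each pixel
an independent draw with mean equal to the blurred intensity, one seeded
generator per acquisition. Blur can leave float-rounding negatives of
order 1e-16 of the peak; values above a 1e-9 relative tolerance raise an
error (never a silent clip), values inside it are floored at zero. Camera
read noise and gain are deliberately out of scope (a best-case noise
model).

**Order of operations** is fixed: temporal modulation → pattern
multiplication → OTF blur → Poisson noise.

## Reconstruction

Per 9-frame window, a Gustafsson-style inversion with parameters taken as
known from the simulator (no pattern estimation — the experiment controls
the illumination exactly):

1. **Separation.** For each angle, the three phase-shifted frame spectra
   are unmixed per Fourier pixel by inverting the 3×3 system with
   coefficients `{1, (m/2)e^{iφ}, (m/2)e^{−iφ}}`, giving the centre
   component `O(k)S(k)` and aliased components `O(k)S(k∓p)`. Degenerate
   phase sets (condition number > 1e8) raise an ill-conditioned error.
2. **Shifting.** Aliased components are translated by the exact fringe
   wave vector — generally sub-pixel — by modulating the real-domain
   signal with the conjugate carrier (Fourier shift theorem).
3. **Wiener combination.** All nine components are merged as
   `Σ m_c O_c* X_c / (Σ m_c² O_c² + w²)` with `O_c` the analytically
   evaluated shifted OTFs, `m_c` the modulation coefficients (1 for centre,
   m/2 for sides), and `w` the Wiener constant (default 0.05, a
   conventional small regularizer; the metrics used for acceptance are
   insensitive to its exact value). A triangle apodization falling
   linearly to zero at the extended pass-band radius `round(f_c + N/p)`
   suppresses ringing; `apodization="none"` is available for diagnostics.

The output grid equals the input grid: the extended support radius (236 at
full scale) is below the Nyquist radius 256, so no upsampling is needed.
No per-window brightness renormalization is applied by default — this
preserves linearity (scaling the raw stack scales every reconstruction).
An optional per-window mean-equalization flag reproduces the mechanism by
which normalization gives interleaved rolling reconstructions inconsistent
brightness scalings.

**Window schemes.** `conventional` strides by 9 (disjoint windows),
`rolling3` by 3 (every window contains three complete same-angle phase
triples), `rolling1` by 1 (two thirds of windows contain one phase triple
split between the window's last and first frames). Frames within a window
are grouped purely by pattern index `t mod 9`, exactly as the raw schedule
dictates, with no reordering or interpolation; every 9th rolling-1 window
is therefore bit-identical to the corresponding conventional window.

**Exactness and periodic boundaries.** The separation/shift/combination
algebra is exact: with grid-commensurate fringes (integer wave-vector
components) a constant sample reconstructs flat to machine precision.
With the default non-integer fringe frequency, the periodic-boundary
carrier is spectrally leaky and deterministic wrap residuals remain; these
are static across windows and are largely removed by the z-scoring in the
metrics.

## Metrics

For each Fourier pixel of the reconstructed series, the magnitude trace
`|I(fx, fy, t)|` is z-scored (population convention) and compared with the
z-scored ground truth:

- **RMSE** `= sqrt(mean((Ĩ − G̃)²))`, algebraically `sqrt(2(1−ρ))` with
  `ρ` the Pearson correlation — bounded in [0, 2]. An uncorrelated trace
  scores √2 in expectation (the suite verifies √2 ± 0.02 over 10 000
  white-noise traces); a trace reproducing the modulation in anti-phase
  scores 2. Some descriptions put the pure-noise level at "one"; the
  mathematics of z-scored operands gives √2, and this implementation
  follows the mathematics.
- **Dot metric** — the inner product of the two temporal power spectra,
  insensitive to phase lag; reported normalized to [0, 1] by the product
  of power-spectrum norms. The dot-metric period sweep is restricted to
  even integer divisors of the series length so the ground truth's power
  concentrates in single temporal-frequency bins; a single-bin extraction
  (normalized magnitude at the modulation frequency) is available as an
  option. The RMSE sweep uses all integer periods.

**Registration.** The reconstruction from window `[i, i+8]` is compared
against `GTm(i + 4)` — the window midpoint, whose content the 9-frame
window actually represents. Registration to the window start is available
as an option; it adds a uniform half-window lag to every spatial
frequency, which at short periods saturates all bins at the √2 floor and
masks the differential (frequency-dependent) lag of interest. The
differential degradation of high spatial frequencies survives centering,
and is what the trend tests measure.

**Degeneracy.** A pixel trace with exactly zero temporal variance is
invalid (NaN) and excluded from radial averages. The threshold is exact
rather than a relative floor on purpose: when the modulation is perfectly
periodic within the 9-frame pattern cycle (e.g. `Tm = 9`, every-frame
reconstruction, noise-free), traces are constant up to float rounding, and
z-scoring that rounding yields a deterministic sequence uncorrelated with
the ground truth — scoring at the √2 noise floor, which is exactly how an
unresolvable temporal frequency should read. The analytic ground-truth
trace itself uses a small absolute epsilon (1e-9 against its 0.25
amplitude): if the registered sampling hits a constant phase (e.g. period
2 sampled at integer frames, or a period dividing the window stride), the
whole comparison is undefined and that period is recorded as missing.

**Radial averaging.** Bin `r` averages all valid pixels whose floored
distance from DC equals `r`, up to the Nyquist radius `N/2`; empty bins
are missing (NaN), never zero. Widefield bins are `r < f_c`;
super-resolved bins `f_c ≤ r <` the SIM limit.

## Experiment scales

The full-scale configuration (512-pixel grid, cutoff 128, fringe 4.75 px,
512 frames, 512 periods) is available but slow. The reduced "desk" scale
preserves the dimensionless ratios that drive the physics — cutoff period
`N/f_c = 4` px, fringe period 4.75 px (1.1875× the cutoff period), and 16
conventional windows (144 frames) — on a 128-pixel grid with cutoff 32,
giving a SIM limit of 59 frequency pixels. The trend experiments run at
this scale with fixed seeds: modulation periods 9 (= window length),
16 (≈ 1.8× window), and 72 (8× window), period 12 for the scheme
comparison, and peak signal 10 photons for the Poisson arm. Desk-scale
results reproduce the qualitative structure of the full-scale maps
(temporal low-pass behaviour at the window length, worse fidelity of
super-resolved frequencies, noise-driven degradation, no rolling-scheme
benefit for super-resolved content); absolute RMSE values at the two
scales differ because bin populations and window counts differ.

What the synthetic data does *not* emulate: structured (non-point)
specimens, sample motion or photobleaching, camera read noise and gain,
pattern imperfections (phase jitter, angle error, depth drift), and
out-of-focus background. Passing trend tests therefore demonstrate
properties of the reconstruction schemes under ideal illumination control,
not performance bounds for any particular instrument.

## Known limitations

- Periodic (circular) convolution throughout: fine for synthetic periodic
  samples; real data would need edge windowing.
- The non-integer fringe frequency leaves deterministic spectral-leakage
  residuals (see above); they are shared by any periodic-domain simulation
  with incommensurate fringes.
- Pattern parameters are known, never estimated; applying the metrics to
  experimentally acquired stacks is supported only through the
  TIFF-ingestion path of `assess`, with externally supplied timing.
- The spatial-resolution gain is reported as the pass-band ratio
  (236/128 ≈ 1.84 at full scale); no attempt is made to measure effective
  resolution from reconstructed images beyond the two-point phantom test.
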