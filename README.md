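# simtempo

**Spatiotemporal resolution assessment of structured illumination
microscopy (SIM).**

Super-resolution SIM needs nine raw frames (3 fringe orientations × 3
phases) per reconstructed image, so its temporal resolution is not a single
number: spatial frequencies inside the widefield pass band are present in
every raw frame, while super-resolved frequencies are only sampled when the
right illumination pattern aliases them into the microscope's pass band.
`simtempo` measures this *per spatial frequency*: it simulates a sample
whose overall brightness follows a known sinusoidal modulation, images it
through a model microscope under a structured-illumination sequence,
reconstructs super-resolved time series under conventional and "rolling"
window schemes, and scores how faithfully every spatial frequency of the
reconstruction reproduces the known modulation.

It is aimed at microscopists and methods developers who want to know, for a
given reconstruction scheme and imaging rate, which combinations of spatial
and temporal frequency are trustworthy — in particular whether rolling
(overlapping-window) reconstruction actually buys temporal resolution for
the super-resolved content.

## Model

- **Sample** — a field of point emitters (1% of pixels at a common peak
  intensity), modulated in time by `GTm(t) = 0.75 + sin(2πt/Tm)/4`, which
  oscillates between 0.5 and 1 so no frame is ever dark.
- **Microscope** — incoherent imaging with the classic circular-pupil OTF
  (autocorrelation of a circular aperture), hard cutoff at radius `f_c`
  frequency pixels; default `f_c = N/4` so the real-domain cutoff period is
  4 px.
- **Acquisition** — each raw frame is
  `Poisson?(OTF ⊗ (sample · GTm(t) · pattern(t mod 9)))` with sinusoidal
  patterns `1 + m·cos(2π k̂·r/p + φ)` of period `p = 4.75` px, slightly
  above the cutoff period so the fringes remain transmissible.
- **Reconstruction** — per angle, the three phase-shifted frames are
  unmixed pixel-wise in the Fourier domain into centre and ±aliased
  components; aliased components are shifted to their true positions by
  exact sub-pixel shifts and all nine components merged by a generalized
  Wiener filter with triangle apodization. The extended pass band reaches
  `round(f_c + N/p)` — 236 frequency pixels on a 512 grid (vs the 256
  Nyquist radius). Window schemes: `conventional` (stride 9), `rolling3`
  (stride 3, phase triples intact), `rolling1` (stride 1, one split triple
  in two thirds of windows).
- **Metrics** — each Fourier pixel's magnitude trace `|I(fx, fy, t)|` is
  z-scored and compared with the z-scored `GTm`:
  `RMSE = sqrt(mean((Ĩ − G̃)²)) = sqrt(2(1−ρ))` ∈ [0, 2]
  (0 = perfect tracking, √2 = uncorrelated noise floor, 2 = anti-phase),
  plus a phase-insensitive power-spectrum dot product. Maps are radially
  averaged into profiles over spatial-frequency radius and stacked over
  modulation periods into spatiotemporal heatmaps.

## Worked example

Score an interleaved (every-frame) rolling reconstruction at a modulation
period of 72 frames, on a 128-pixel grid (cutoff 32, so the same
cutoff-period and fringe ratios as the full 512-pixel setup):

```python
import simtempo as st

samp = st.generate_point_sample(128, 0.01, 1.0, seed=7)
patterns = st.make_pattern_set(128, fringe_period=4.75)
otf = st.make_otf(128, cutoff=32.0)
limit = st.sim_passband_limit(32.0, 4.75, 128)
print(f"widefield cutoff: 32 px   SIM pass-band limit: {limit} px")

gt = st.build_ground_truth_stack(samp, n_frames=144, tm=72.0)
raw = st.acquire_raw_frames(gt, patterns, otf)
hr = st.reconstruct_series(raw, patterns, otf,
                           st.ReconstructionConfig(scheme="rolling1"))
print(f"reconstructed {hr.n_frames} super-resolved frames "
      f"from {gt.n_frames} raw frames")

rmse = st.rmse_map(st.spectrum_series(hr), gt.trace)
prof = st.radial_average(rmse)
for r in (2, 16, 40, 56):
    print(f"radius {r:3d}: mean RMSE = {prof.bins[r]:.3f}  "
          f"({prof.counts[r]} pixels)")
```

prints

```
widefield cutoff: 32 px   SIM pass-band limit: 59 px
reconstructed 136 super-resolved frames from 144 raw frames
radius   2: mean RMSE = 0.058  (16 pixels)
radius  16: mean RMSE = 0.075  (96 pixels)
radius  40: mean RMSE = 0.275  (236 pixels)
radius  56: mean RMSE = 0.599  (344 pixels)
```

Radii 2 and 16 lie inside the widefield pass band and track the modulation
closely (RMSE ≪ 1); radii 40 and 56 are super-resolved frequencies, which
reproduce the same temporal modulation markedly worse even though the
modulation period (72 frames) is eight times the reconstruction window —
the central observation this package quantifies.

## Command line

```sh
simtempo simulate  --size 128 --cutoff 32 --frames 144 --tm 72 --out sim/
simtempo reconstruct sim/raw.tif --cutoff 32 --scheme rolling1 --out rec/
simtempo assess rec/hr.tif --tm 72 --out maps/
simtempo suite --scale desk --out figures/
```

`suite` reproduces the four canonical experiment layouts (single-pixel
traces, the RMSE and dot-product period sweeps, the Poisson-noise
sensitivity panel, and the rolling-minus-conventional difference maps) at a
reduced scale in a couple of minutes; `--scale full` runs the complete
512-pixel, 512-period configuration (hours).

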