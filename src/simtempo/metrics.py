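"""Spatiotemporal resolution metrics: spectral tracking of the modulation.

Every spatial frequency of the reconstructed series is tracked over time
through the magnitude of its 2D Fourier coefficient, z-scored, and compared
with the (equally z-scored) known temporal ground truth:

* ``rmse_trace`` — root-mean-square error between two z-scored traces.  For
  population-z-scored operands it equals sqrt(2 (1 - rho)) with rho the
  Pearson correlation, hence is bounded in [0, 2]: 0 for perfect tracking,
  2 for tracking in perfect anti-phase, and sqrt(2) in expectation for an
  uncorrelated (pure noise) trace.
* ``dot_metric`` — inner product of the two temporal power spectra,
  insensitive to any phase lag between the traces; reported normalized to
  [0, 1] by the product of power-spectrum norms.

Per-pixel maps over the Fourier plane are radially averaged into profiles
over spatial-frequency magnitude, and profiles for many modulation periods
are stacked into a spatiotemporal map (radius x period).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .acquisition import PatternSet, acquire_raw_frames
from .optics import OTFModel
from .reconstruction import HRStack, ReconstructionConfig, reconstruct_series
from .sample import (
    ModulationTrace,
    SampleImage,
    build_ground_truth_stack,
    modulation_value,
)

__all__ = [
    "SpectrumSeries",
    "NormalizedTrace",
    "RMSEMap",
    "RadialProfile",
    "SpatioTemporalMap",
    "DegenerateTraceError",
    "spectrum_series",
    "normalize_trace",
    "rmse_trace",
    "rmse_map",
    "dot_map",
    "radial_average",
    "dot_metric",
    "even_divisor_periods",
    "sweep_modulation_periods",
    "difference_map",
]

logger = logging.getLogger(__name__)

# Degeneracy is exact: only a trace with literally zero temporal variance is
# invalid.  A trace whose variation is mere float rounding (e.g. a modulation
# that is perfectly periodic within the pattern cycle) z-scores to an
# arbitrary deterministic sequence uncorrelated with the ground truth and
# lands at the RMSE noise floor sqrt(2) — which is precisely how an
# unresolvable temporal frequency should score.
_STD_FLOOR = 0.0


class DegenerateTraceError(ValueError):
    """A trace has zero temporal variance and cannot be z-scored."""


@dataclass
class SpectrumSeries:
    """|I(fx, fy, t)| per reconstructed frame, centred frequency layout."""

    magnitudes: np.ndarray  # (time, fy, fx)
    times: np.ndarray  # raw-frame time assigned to each entry

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[0]

    @property
    def size(self) -> int:
        return self.magnitudes.shape[1]


@dataclass
class NormalizedTrace:
    """A z-scored time series with its source mean and standard deviation."""

    values: np.ndarray
    mean: float
    std: float


@dataclass
class RMSEMap:
    """Per-Fourier-pixel RMSE (or dot metric); invalid pixels are NaN."""

    values: np.ndarray  # (fy, fx)
    nt: int
    tm: float

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass
class RadialProfile:
    """Radially averaged metric: bin r covers radii [r, r+1) from DC."""

    bins: np.ndarray  # metric value per radius bin; NaN where empty
    counts: np.ndarray  # valid pixels per bin


@dataclass
class SpatioTemporalMap:
    """Radial profiles stacked over the modulation-period axis.

    ``matrix[r, j]`` is the radially averaged metric at spatial-frequency
    radius r for modulation period ``periods[j]``; ``kind`` is "rmse" or
    "dot".
    """

    matrix: np.ndarray  # (n_bins, n_periods)
    periods: np.ndarray
    kind: str

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            self.matrix,
            index=np.arange(self.matrix.shape[0]),
            columns=self.periods,
        )
        df.index.name = "radius"
        df.columns.name = "Tm"
        df.to_csv(Path(path))

    def to_npz(self, path) -> None:
        np.savez(
            Path(path),
            matrix=self.matrix,
            periods=self.periods,
            kind=np.array(self.kind),
        )

    @classmethod
    def from_npz(cls, path) -> "SpatioTemporalMap":
        data = np.load(Path(path))
        return cls(
            matrix=data["matrix"],
            periods=data["periods"],
            kind=str(data["kind"]),
        )

    def plot(self, path, cutoff: float | None = None,
             limit: float | None = None, title: str | None = None) -> None:
        """Render the map as a heatmap with pass-band limits overlaid."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 5))
        im = ax.imshow(
            self.matrix,
            origin="lower",
            aspect="auto",
            extent=(
                float(self.periods[0]),
                float(self.periods[-1]),
                0,
                self.matrix.shape[0],
            ),
            cmap="viridis",
        )
        if cutoff is not None:
            ax.axhline(cutoff, color="white", ls="--", lw=1,
                       label="widefield limit")
        if limit is not None:
            ax.axhline(limit, color="black", ls="--", lw=1, label="SIM limit")
        ax.set_xlabel("modulation period Tm (frames)")
        ax.set_ylabel("spatial frequency radius (pixels)")
        ax.set_title(title or f"{self.kind} map")
        ax.legend(loc="upper right", fontsize=8)
        fig.colorbar(im, ax=ax, label=self.kind)
        fig.savefig(Path(path), dpi=120)
        plt.close(fig)


def spectrum_series(hr, times=None) -> SpectrumSeries:
    """2D transform magnitude of each frame, centred on DC.

    ``hr`` may be an `HRStack` (window-start times are carried over) or a
    plain (time, y, x) array (times default to 0..T-1).
    """
    if isinstance(hr, HRStack):
        frames = hr.frames
        times = hr.window_start if times is None else np.asarray(times)
    else:
        frames = np.asarray(hr)
        times = np.arange(frames.shape[0]) if times is None else np.asarray(times)
    if frames.shape[0] == 0:
        raise ValueError("empty stack")
    mags = np.empty(frames.shape, dtype=np.float64)
    for t in range(frames.shape[0]):
        mags[t] = np.abs(np.fft.fftshift(np.fft.fft2(frames[t])))
    return SpectrumSeries(magnitudes=mags, times=times)


def normalize_trace(trace) -> NormalizedTrace:
    """z-score a time series (population convention).

    A zero-variance trace cannot carry temporal information and raises
    `DegenerateTraceError`; map-level code marks such pixels invalid and
    excludes them from radial averages instead.
    """
    values = np.asarray(trace, dtype=np.float64)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("trace must be 1D with at least 2 samples")
    mean = values.mean()
    std = values.std()
    if std == 0.0:
        raise DegenerateTraceError("trace has zero temporal variance")
    return NormalizedTrace(values=(values - mean) / std, mean=mean, std=std)


def _trace_values(x) -> np.ndarray:
    return x.values if isinstance(x, NormalizedTrace) else np.asarray(x)


def rmse_trace(x, g) -> float:
    """RMSE between two z-scored traces: sqrt(mean((x - g)^2)).

    For population-z-scored operands this equals sqrt(2 (1 - rho)) with rho
    their Pearson correlation, so it lies in [0, 2].
    """
    xv, gv = _trace_values(x), _trace_values(g)
    if xv.shape != gv.shape:
        raise ValueError(f"trace lengths differ: {xv.shape} vs {gv.shape}")
    return float(np.sqrt(np.mean((xv - gv) ** 2)))


def dot_metric(x, g, normalized: bool = True) -> float:
    """Inner product of two temporal power spectra (phase-insensitive).

    ``sum_f |FFT(x)|^2 * |FFT(g)|^2`` over temporal frequency bins; with
    ``normalized`` (default) the value is divided by the product of the
    power-spectrum Euclidean norms, giving 1 for identical modulation
    content (regardless of phase lag) and 0 for disjoint content.
    """
    xv, gv = _trace_values(x), _trace_values(g)
    if xv.shape != gv.shape:
        raise ValueError(f"trace lengths differ: {xv.shape} vs {gv.shape}")
    px = np.abs(np.fft.fft(xv)) ** 2
    pg = np.abs(np.fft.fft(gv)) ** 2
    raw = float(np.dot(px, pg))
    if not normalized:
        return raw
    denom = float(np.linalg.norm(px) * np.linalg.norm(pg))
    return raw / denom if denom > 0 else np.nan


def _registration_times(spectra: SpectrumSeries, registration: str) -> np.ndarray:
    if registration == "start":
        return np.asarray(spectra.times, dtype=np.float64)
    if registration == "center":
        return np.asarray(spectra.times, dtype=np.float64) + 4.0
    raise ValueError(f"registration must be 'start' or 'center', got {registration!r}")


def _zscore_stack(mags: np.ndarray):
    """z-score each pixel's trace along time; return (z, valid mask)."""
    mean = mags.mean(axis=0)
    std = mags.std(axis=0)
    valid = std > _STD_FLOOR
    safe = np.where(valid, std, 1.0)
    z = (mags - mean[None]) / safe[None]
    return z, valid


def rmse_map(
    spectra: SpectrumSeries,
    gt: ModulationTrace,
    registration: str = "center",
) -> RMSEMap:
    """Per-Fourier-pixel RMSE between magnitude traces and the ground truth.

    The ground truth GTm is evaluated at the time assigned to each
    reconstructed frame — by default the window midpoint
    (``registration="center"``, the raw time whose content the 9-frame
    window actually represents); ``"start"`` assigns the window's first raw
    frame instead, which adds a uniform half-window lag to every spatial
    frequency and saturates the RMSE at short periods.  Both
    operands are z-scored before differencing, which is what bounds the
    result in [0, 2].  Degenerate (zero-variance) pixels are NaN.
    """
    times = _registration_times(spectra, registration)
    g = modulation_value(times, gt.tm)
    gstd = g.std()
    # the ground truth is analytic with amplitude 0.25: anything at float
    # rounding level means the registered sampling hit a constant phase
    if gstd <= 1e-9:
        raise DegenerateTraceError(
            "ground-truth trace is constant at the registered frame times"
        )
    zg = (g - g.mean()) / gstd
    z, valid = _zscore_stack(spectra.magnitudes)
    values = np.sqrt(np.mean((z - zg[:, None, None]) ** 2, axis=0))
    values[~valid] = np.nan
    return RMSEMap(values=values, nt=spectra.n_frames, tm=gt.tm)


def dot_map(
    spectra: SpectrumSeries,
    gt: ModulationTrace,
    registration: str = "center",
    single_bin: bool = False,
) -> RMSEMap:
    """Per-Fourier-pixel phase-insensitive similarity with the ground truth.

    Default: normalized power-spectrum dot product per pixel.  With
    ``single_bin`` the map instead holds the pixel's normalized temporal-
    frequency magnitude at the ground truth's oscillation frequency (the
    dominant bin of the z-scored GTm power spectrum).
    """
    times = _registration_times(spectra, registration)
    g = modulation_value(times, gt.tm)
    gstd = g.std()
    # the ground truth is analytic with amplitude 0.25: anything at float
    # rounding level means the registered sampling hit a constant phase
    if gstd <= 1e-9:
        raise DegenerateTraceError(
            "ground-truth trace is constant at the registered frame times"
        )
    zg = (g - g.mean()) / gstd
    pg = np.abs(np.fft.fft(zg)) ** 2

    z, valid = _zscore_stack(spectra.magnitudes)
    pz = np.abs(np.fft.fft(z, axis=0)) ** 2
    if single_bin:
        b = int(np.argmax(pg))
        total = np.sqrt(np.sum(pz**2, axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            values = pz[b] / total
    else:
        num = np.einsum("t,tyx->yx", pg, pz)
        denom = np.linalg.norm(pg) * np.sqrt(np.sum(pz**2, axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            values = num / denom
    values[~valid] = np.nan
    return RMSEMap(values=values, nt=spectra.n_frames, tm=gt.tm)


def radial_average(map_) -> RadialProfile:
    """Average a Fourier-plane map over annuli [r, r+1) centred on DC.

    Bin r collects pixels whose floored distance from DC equals r, up to
    the Nyquist radius N/2.  Invalid (NaN) pixels are excluded from both
    the mean and the count; a bin with no valid pixel is NaN with count 0.
    """
    values = map_.values if isinstance(map_, RMSEMap) else np.asarray(map_)
    n = values.shape[0]
    c = n // 2
    idx = np.arange(n, dtype=np.float64) - c
    radius = np.hypot(idx[None, :], idx[:, None])
    rbin = np.floor(radius).astype(int)
    n_bins = n // 2
    in_range = rbin < n_bins
    finite = np.isfinite(values) & in_range
    counts = np.bincount(rbin[finite], minlength=n_bins)[:n_bins]
    sums = np.bincount(
        rbin[finite], weights=values[finite], minlength=n_bins
    )[:n_bins]
    with np.errstate(invalid="ignore", divide="ignore"):
        bins = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return RadialProfile(bins=bins, counts=counts)


def even_divisor_periods(n_frames: int) -> np.ndarray:
    """Even integer divisors of ``n_frames``, ascending.

    The dot-product sweep restricts modulation periods to this set so that
    the ground truth's temporal power concentrates in single transform bins.
    """
    divs = [d for d in range(2, n_frames + 1, 2) if n_frames % d == 0]
    return np.array(divs)


def sweep_modulation_periods(
    sample: SampleImage,
    patterns: PatternSet,
    otf: OTFModel,
    config: ReconstructionConfig,
    periods,
    n_frames: int,
    *,
    kind: str = "rmse",
    noise: bool = False,
    seed: int = 0,
    registration: str = "center",
) -> SpatioTemporalMap:
    """Full pipeline sweep: per period, simulate -> acquire -> reconstruct
    -> metric map -> radial average; profiles are stacked into a
    spatiotemporal map.

    One sample is reused for every period (the emitter layout is fixed per
    run seed).  For ``kind="dot"`` the period list is restricted to even
    integer divisors of ``n_frames``; other requested periods are dropped
    with a warning.  A stage failure for one period logs the error and
    leaves that column NaN.
    """
    periods = np.asarray(list(periods), dtype=np.float64)
    if len(periods) == 0:
        raise ValueError("period list must be non-empty")
    if kind not in ("rmse", "dot"):
        raise ValueError(f"kind must be 'rmse' or 'dot', got {kind!r}")
    if kind == "dot":
        allowed = set(even_divisor_periods(n_frames).tolist())
        keep = np.array([p in allowed for p in periods])
        if not keep.all():
            logger.warning(
                "dot-metric sweep: dropping %d periods that are not even "
                "integer divisors of %d",
                int((~keep).sum()),
                n_frames,
            )
        periods = periods[keep]
        if len(periods) == 0:
            raise ValueError(
                "no requested period is an even integer divisor of "
                f"{n_frames}"
            )

    n_bins = sample.size // 2
    matrix = np.full((n_bins, len(periods)), np.nan)
    for j, tm in enumerate(periods):
        try:
            gt = build_ground_truth_stack(sample, n_frames, tm)
            raw = acquire_raw_frames(
                gt, patterns, otf, noise_on=noise, seed=seed + j
            )
            hr = reconstruct_series(raw, patterns, otf, config)
            spectra = spectrum_series(hr)
            if kind == "rmse":
                m = rmse_map(spectra, gt.trace, registration)
            else:
                m = dot_map(spectra, gt.trace, registration)
            matrix[:, j] = radial_average(m).bins
            logger.info("period Tm=%g done (%d/%d)", tm, j + 1, len(periods))
        except Exception:
            logger.exception("period Tm=%g failed; column left missing", tm)
    return SpatioTemporalMap(matrix=matrix, periods=periods, kind=kind)


def difference_map(
    a: SpatioTemporalMap, b: SpatioTemporalMap
) -> SpatioTemporalMap:
    """Elementwise a - b; missing cells propagate as NaN."""
    if a.matrix.shape != b.matrix.shape or not np.array_equal(
        a.periods, b.periods
    ):
        raise ValueError("maps have mismatching axes")
    return SpatioTemporalMap(
        matrix=a.matrix - b.matrix, periods=a.periods.copy(), kind=a.kind
    )
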