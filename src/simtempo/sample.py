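"""Sparse point-emitter phantoms and sinusoidal temporal intensity modulation.

The simulated specimen is a field of isolated point emitters: a blank image
in which a small fraction of pixels (1% by default) is set to a common peak
intensity.  Such a sample has spectral support at essentially every spatial
frequency, which makes it suitable for probing how temporal information is
transferred at each spatial frequency independently.

The specimen's overall brightness is modulated over time by an offset sine

    GTm(t) = 0.75 + sin(2 pi t / Tm) / 4

which oscillates between 0.5 and 1, so that no frame is ever completely dark
and the modulation never drives the signal to zero intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SampleImage",
    "ModulationTrace",
    "GroundTruthStack",
    "generate_point_sample",
    "two_point_phantom",
    "modulation_value",
    "build_ground_truth_stack",
    "write_stack_tiff",
    "write_trace_csv",
]

#: Minimum number of raw frames needed for one reconstruction window
#: (3 pattern angles x 3 phases).
MIN_FRAMES = 9


@dataclass
class SampleImage:
    """A static 2D specimen: non-negative intensities on a square grid.

    Nonzero pixels all carry the same peak intensity ``max_signal``
    (photons); everything else is zero.
    """

    pixels: np.ndarray
    max_signal: float

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_emitters(self) -> int:
        return int(np.count_nonzero(self.pixels))


@dataclass
class ModulationTrace:
    """The known temporal ground truth GTm(t) for one modulation period.

    ``values[t] = 0.75 + sin(2 pi t / tm) / 4`` for t = 0 .. n_frames-1
    (0-based frame index), bounded in [0.5, 1].
    """

    tm: float
    values: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @classmethod
    def make(cls, tm: float, n_frames: int) -> "ModulationTrace":
        return cls(tm=tm, values=modulation_value(np.arange(n_frames), tm))


@dataclass
class GroundTruthStack:
    """Noiseless time series: frame t = sample.pixels * trace.values[t]."""

    frames: np.ndarray  # (time, y, x)
    trace: ModulationTrace

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def size(self) -> int:
        return self.frames.shape[1]


def generate_point_sample(
    size: int, density: float, max_signal: float = 1.0, seed: int = 0
) -> SampleImage:
    """Scatter point emitters over a blank image.

    Exactly ``round(density * size**2)`` distinct pixels are set to
    ``max_signal``; positions are drawn without replacement from a seeded
    generator, so the emitter count is deterministic and the image is
    bit-reproducible for a given seed.

    Parameters
    ----------
    size
        Grid side in pixels (>= 16).
    density
        Fraction of pixels that are emitters, in [0, 1].
    max_signal
        Peak emitter intensity in photons (> 0).
    seed
        Seed for the position draw.
    """
    if size < 16:
        raise ValueError(f"size must be >= 16, got {size}")
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must be in [0, 1], got {density}")
    if max_signal <= 0:
        raise ValueError(f"max_signal must be positive, got {max_signal}")

    n_emitters = int(round(density * size * size))
    rng = np.random.default_rng(seed)
    flat = rng.choice(size * size, size=n_emitters, replace=False)
    pixels = np.zeros(size * size, dtype=np.float64)
    pixels[flat] = max_signal
    return SampleImage(pixels=pixels.reshape(size, size), max_signal=max_signal)


def two_point_phantom(
    size: int, separation: int, max_signal: float = 1.0
) -> SampleImage:
    """Two point emitters ``separation`` pixels apart along x, centred.

    Used by resolution tests: two points closer than the widefield cutoff
    period but farther than the extended SIM period should be resolved only
    in the reconstruction.
    """
    if size < 16:
        raise ValueError(f"size must be >= 16, got {size}")
    if max_signal <= 0:
        raise ValueError(f"max_signal must be positive, got {max_signal}")
    pixels = np.zeros((size, size), dtype=np.float64)
    c = size // 2
    half = separation // 2
    pixels[c, c - half] = max_signal
    pixels[c, c - half + separation] = max_signal
    return SampleImage(pixels=pixels, max_signal=max_signal)


def modulation_value(t, tm: float):
    """Evaluate the ground-truth modulation GTm = 0.75 + sin(2 pi t/Tm)/4.

    Accepts scalar or array ``t`` (frames, 0-based); ``tm`` is the
    modulation period in frames and must be positive.
    """
    if tm <= 0:
        raise ValueError(f"modulation period must be positive, got {tm}")
    t = np.asarray(t, dtype=np.float64)
    out = 0.75 + np.sin(2.0 * np.pi * t / tm) / 4.0
    return float(out) if out.ndim == 0 else out


def build_ground_truth_stack(
    sample: SampleImage, n_frames: int, tm: float
) -> GroundTruthStack:
    """Modulate a static sample over time.

    Frame t equals ``sample.pixels * GTm(t)`` exactly (noise free); the
    modulation trace is recorded alongside the stack.  At least 9 frames are
    required, one full pattern cycle.
    """
    if n_frames < MIN_FRAMES:
        raise ValueError(
            f"n_frames must be >= {MIN_FRAMES} (one reconstruction window), "
            f"got {n_frames}"
        )
    trace = ModulationTrace.make(tm, n_frames)
    frames = sample.pixels[None, :, :] * trace.values[:, None, None]
    return GroundTruthStack(frames=frames, trace=trace)


def write_stack_tiff(path, frames: np.ndarray) -> None:
    """Write a (time, y, x) stack as multi-page 32-bit float TIFF."""
    import tifffile

    tifffile.imwrite(str(path), np.asarray(frames, dtype=np.float32))


def write_trace_csv(path, trace: ModulationTrace) -> None:
    """Write a modulation trace as a 2-column CSV (1-based frame, GTm)."""
    import pandas as pd

    pd.DataFrame(
        {"frame": np.arange(1, trace.n_frames + 1), "GTm": trace.values}
    ).to_csv(Path(path), index=False)
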