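"""Structured-illumination acquisition: fringe patterns, raw frames, noise.

A SIM acquisition cycles through 9 sinusoidal illumination patterns — 3
fringe orientations x 3 phases, angle-major order — multiplying the sample,
after which the emission is low-pass filtered by the detection OTF.  Optional
shot noise draws each pixel from a Poisson distribution whose mean is the
blurred intensity.

The order of operations is fixed: temporal modulation, then pattern
multiplication, then OTF blurring, then Poisson noise.  Only the emission
path is blurred; the excitation fringes themselves are not filtered (their
period, 4.75 px by default, is chosen just above the OTF cutoff period so
they remain transmissible).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .optics import OTFModel, apply_otf
from .sample import GroundTruthStack

__all__ = [
    "PatternSet",
    "RawFrameStack",
    "make_pattern_set",
    "acquire_raw_frames",
    "add_poisson",
    "write_raw_stack",
    "read_raw_stack",
]

DEFAULT_ANGLES_DEG = (0.0, 60.0, 120.0)
DEFAULT_PHASES = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)

# Blurring a non-negative image with the non-negative Airy PSF can leave
# float-rounding negatives of order 1e-16 * peak; anything worse signals a
# genuine invariant violation and is raised, never clipped.
_NEG_TOL = 1e-9


@dataclass
class PatternSet:
    """The 9 illumination masks with their angles, phases and fringe period.

    Ordering is angle-major: patterns 0-2 share ``angles_deg[0]`` with
    phases 0, 2pi/3, 4pi/3; patterns 3-5 the second angle; 6-8 the third.
    Each mask is ``1 + m cos(2 pi k.r / p + phi)`` — spatial mean 1 (up to
    spectral-leakage of order 1/N for the non-integer fringe frequency), and
    the three phase masks at one angle sum exactly to the constant 3.
    """

    patterns: np.ndarray  # (9, N, N)
    angles_deg: tuple
    phases: tuple
    fringe_period: float
    modulation_depth: float

    @property
    def size(self) -> int:
        return self.patterns.shape[1]

    def shift_vector(self, angle_index: int) -> np.ndarray:
        """Fringe wave vector (kx, ky) in frequency pixels for one angle."""
        theta = np.deg2rad(self.angles_deg[angle_index])
        return (self.size / self.fringe_period) * np.array(
            [np.cos(theta), np.sin(theta)]
        )


@dataclass
class RawFrameStack:
    """Raw SIM frames; frame t used pattern ``t mod 9``."""

    frames: np.ndarray  # (time, y, x), photons
    noise_applied: bool
    seed: int | None

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def pattern_index(self) -> np.ndarray:
        return np.arange(self.n_frames) % 9


def make_pattern_set(
    size: int,
    fringe_period: float = 4.75,
    angles_deg: tuple = DEFAULT_ANGLES_DEG,
    modulation_depth: float = 1.0,
    phases: tuple = DEFAULT_PHASES,
) -> PatternSet:
    """Build the 9-pattern sinusoidal illumination sequence.

    ``pattern(r) = 1 + m * cos(2 pi (k_hat . r) / fringe_period + phi)``
    evaluated per pixel from the analytic cosine — the fringe frequency
    ``size / fringe_period`` need not be an integer and is never snapped to
    the grid.
    """
    if fringe_period <= 2:
        raise ValueError(
            "fringe_period must exceed 2 pixels (fringe frequency below "
            f"Nyquist), got {fringe_period}"
        )
    # m = 0 (uniform widefield illumination) is allowed for diagnostics;
    # component separation rejects it later as a singular mixing system.
    if not 0 <= modulation_depth <= 1:
        raise ValueError(
            f"modulation_depth must be in [0, 1], got {modulation_depth}"
        )
    if len(angles_deg) != 3 or len(phases) != 3:
        raise ValueError("exactly 3 angles and 3 phases are required")

    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    patterns = np.empty((9, size, size), dtype=np.float64)
    for a, theta_deg in enumerate(angles_deg):
        theta = np.deg2rad(theta_deg)
        proj = x * np.cos(theta) + y * np.sin(theta)
        for j, phi in enumerate(phases):
            patterns[3 * a + j] = 1.0 + modulation_depth * np.cos(
                2.0 * np.pi * proj / fringe_period + phi
            )
    return PatternSet(
        patterns=patterns,
        angles_deg=tuple(angles_deg),
        phases=tuple(phases),
        fringe_period=float(fringe_period),
        modulation_depth=float(modulation_depth),
    )


def add_poisson(image: np.ndarray, seed: int) -> np.ndarray:
    """Poisson shot noise: each pixel an independent draw with mean = pixel.

    Output is integer-valued (as float64).  Negative input is rejected.
    """
    image = np.asarray(image, dtype=np.float64)
    if np.any(image < 0):
        raise ValueError("Poisson means must be non-negative")
    rng = np.random.default_rng(seed)
    return rng.poisson(image).astype(np.float64)


def acquire_raw_frames(
    gt: GroundTruthStack,
    patterns: PatternSet,
    otf: OTFModel,
    noise_on: bool = False,
    seed: int = 0,
) -> RawFrameStack:
    """Form the raw SIM stack from a modulated ground-truth stack.

    Frame t is ``Poisson?(apply_otf(gt.frames[t] * patterns[t mod 9]))``
    with the Poisson step applied only when ``noise_on``, after blurring.
    A single generator seeded once drives all frames, so the stack is
    reproducible from (inputs, seed).
    """
    if gt.size != patterns.size or gt.size != otf.size:
        raise ValueError("ground truth, patterns and OTF grids must match")
    if gt.n_frames < 9:
        raise ValueError("at least 9 frames are required")

    rng = np.random.default_rng(seed) if noise_on else None
    frames = np.empty_like(gt.frames)
    for t in range(gt.n_frames):
        blurred = apply_otf(gt.frames[t] * patterns.patterns[t % 9], otf)
        if noise_on:
            lo = blurred.min()
            if lo < 0:
                peak = blurred.max()
                if lo < -_NEG_TOL * max(peak, 1.0):
                    raise RuntimeError(
                        "negative intensity entering the Poisson step "
                        f"({lo:g}); acquisition invariant violated"
                    )
                blurred = np.maximum(blurred, 0.0)  # float rounding floor
            blurred = rng.poisson(blurred).astype(np.float64)
        frames[t] = blurred
    return RawFrameStack(
        frames=frames, noise_applied=noise_on, seed=seed if noise_on else None
    )


def write_raw_stack(path, raw: RawFrameStack, patterns: PatternSet,
                    tm: float | None = None) -> None:
    """Write a raw stack as multi-page float32 TIFF plus a YAML sidecar.

    The sidecar (``<path>.yaml``) records angles, phases, fringe period,
    modulation depth, seed and, when known, the modulation period.
    """
    import tifffile
    import yaml

    path = Path(path)
    tifffile.imwrite(str(path), raw.frames.astype(np.float32))
    meta = {
        "angles_deg": [float(a) for a in patterns.angles_deg],
        "phases": [float(p) for p in patterns.phases],
        "fringe_period": patterns.fringe_period,
        "modulation_depth": patterns.modulation_depth,
        "noise_applied": bool(raw.noise_applied),
        "seed": raw.seed,
        "tm": tm,
    }
    with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_raw_stack(path) -> tuple[RawFrameStack, PatternSet, float | None]:
    """Read a raw stack and its sidecar back; inverse of `write_raw_stack`."""
    import tifffile
    import yaml

    path = Path(path)
    frames = tifffile.imread(str(path)).astype(np.float64)
    with open(path.with_suffix(path.suffix + ".yaml")) as fh:
        meta = yaml.safe_load(fh)
    patterns = make_pattern_set(
        size=frames.shape[1],
        fringe_period=meta["fringe_period"],
        angles_deg=tuple(meta["angles_deg"]),
        modulation_depth=meta["modulation_depth"],
        phases=tuple(meta["phases"]),
    )
    raw = RawFrameStack(
        frames=frames,
        noise_applied=meta["noise_applied"],
        seed=meta["seed"],
    )
    return raw, patterns, meta.get("tm")
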