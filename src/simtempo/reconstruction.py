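"""Gustafsson-style SIM reconstruction with conventional and rolling windows.

Each super-resolved image is reconstructed from 9 raw frames (3 angles x 3
phases).  Per angle, the three phase-shifted frames are unmixed pixel-wise in
the Fourier domain into a centre component and two components aliased by the
fringe wave vector; the aliased components are translated back to their true
frequency positions (by exact sub-pixel shifts via the Fourier shift
theorem), and all nine components are merged by a generalized Wiener filter
weighted with the correspondingly shifted OTFs, followed by a triangle
apodization that tapers to zero at the extended SIM pass-band radius.

Window scheduling over a long raw stack:

* ``conventional`` — disjoint windows, stride 9 (frames 1-9, 10-18, ...);
* ``rolling3``     — stride 3, so every window still contains three complete
  same-angle phase triples (frames 1-9, 4-12, 7-15, ...);
* ``rolling1``     — stride 1; in two thirds of windows one phase triple is
  split between the window's last and first frames.

Frames inside a window are grouped purely by pattern index (t mod 9),
exactly as the raw schedule dictates — no reordering or interpolation — so
every 9th rolling-1 window is bit-identical to a conventional one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import PatternSet, RawFrameStack
from .optics import OTFModel, sim_passband_limit

__all__ = [
    "ReconstructionConfig",
    "HRStack",
    "IllConditionedError",
    "window_starts",
    "separate_components",
    "shift_component",
    "assemble_hr",
    "reconstruct_series",
    "Reconstructor",
]

SCHEME_STRIDES = {"conventional": 9, "rolling3": 3, "rolling1": 1}


class IllConditionedError(ValueError):
    """The phase-mixing system is (numerically) singular."""


@dataclass
class ReconstructionConfig:
    """Reconstruction settings.

    wiener
        Regularization constant in the generalized Wiener denominator
        (dimensionless, added as wiener**2).  Default 0.05, a conventional
        small regularizer.
    apodization
        ``"triangle"`` — window falling linearly to zero at the SIM limit
        radius (default) — or ``"none"`` for diagnostics.
    equalize_window_means
        Optional per-window mean-brightness normalization.  Off by default
        to preserve linearity; switching it on reproduces the artefact
        mechanism by which interleaved rolling reconstructions acquire
        inconsistent brightness scalings.
    """

    scheme: str = "conventional"
    wiener: float = 0.05
    apodization: str = "triangle"
    equalize_window_means: bool = False

    def __post_init__(self) -> None:
        if self.scheme not in SCHEME_STRIDES:
            raise ValueError(
                f"scheme must be one of {sorted(SCHEME_STRIDES)}, "
                f"got {self.scheme!r}"
            )
        if self.wiener <= 0:
            raise ValueError(f"wiener must be positive, got {self.wiener}")
        if self.apodization not in ("triangle", "none"):
            raise ValueError(
                f"apodization must be 'triangle' or 'none', "
                f"got {self.apodization!r}"
            )

    @property
    def stride(self) -> int:
        return SCHEME_STRIDES[self.scheme]


@dataclass
class HRStack:
    """Super-resolved time series H(x, y, t) for one window scheme."""

    frames: np.ndarray  # (window, y, x)
    window_start: np.ndarray  # first raw-frame index (0-based) per window
    scheme: str

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def size(self) -> int:
        return self.frames.shape[1]


def window_starts(n_raw: int, scheme: str) -> np.ndarray:
    """0-based first-frame indices of every reconstruction window.

    Counts: floor(n/9) for conventional, floor((n-9)/3)+1 for rolling-3,
    n-8 for rolling-1.
    """
    if scheme not in SCHEME_STRIDES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if n_raw < 9:
        raise ValueError(
            f"need at least 9 raw frames for one window, got {n_raw}"
        )
    return np.arange(0, n_raw - 8, SCHEME_STRIDES[scheme])


def _mixing_inverse(phases, m: float) -> np.ndarray:
    """Inverse of the 3x3 phase-mixing matrix.

    Row j mixes {centre, +shift, -shift} components into frame j with
    coefficients {1, (m/2) e^{i phi_j}, (m/2) e^{-i phi_j}}.
    """
    phases = np.asarray(phases, dtype=np.float64)
    M = np.stack(
        [
            np.ones(3, dtype=complex),
            0.5 * m * np.exp(1j * phases),
            0.5 * m * np.exp(-1j * phases),
        ],
        axis=1,
    )
    if np.linalg.cond(M) > 1e8:
        raise IllConditionedError(
            f"degenerate phase set {tuple(phases)}: mixing matrix singular"
        )
    return np.linalg.inv(M)


def separate_components(
    frames: np.ndarray, phases, m: float
) -> np.ndarray:
    """Unmix 3 phase-shifted frames at one angle into spectral components.

    Returns an array of 3 complex spectra in unshifted FFT layout:
    index 0 the centre component OTF(k)*S(k), index 1 the '+' component
    OTF(k)*S(k - p), index 2 the '-' component OTF(k)*S(k + p), where p is
    the fringe wave vector.  The per-pixel 3x3 system is identical at every
    Fourier pixel, so one matrix inverse applied to the three frame spectra
    suffices.
    """
    frames = np.asarray(frames)
    if frames.shape[0] != 3:
        raise ValueError("exactly 3 frames are required")
    Minv = _mixing_inverse(phases, m)
    D = np.fft.fft2(frames, axes=(-2, -1))
    return np.einsum("cj,jyx->cyx", Minv, D)


def shift_component(spectrum: np.ndarray, shift) -> np.ndarray:
    """Translate a spectrum by an exact (possibly sub-pixel) shift.

    Returns ``out(k) = spectrum(k + shift)`` with ``shift = (kx, ky)`` in
    frequency pixels, implemented by modulating the real-domain signal with
    a complex exponential (Fourier shift theorem); for integer shifts this
    coincides with an array roll.
    """
    spectrum = np.asarray(spectrum)
    n = spectrum.shape[-1]
    shift = np.asarray(shift, dtype=np.float64)
    if np.hypot(*shift) >= n / 2:
        raise ValueError(f"|shift| must be below the Nyquist radius {n / 2}")
    x = np.arange(n, dtype=np.float64)
    ramp = np.exp(
        -2j * np.pi * (shift[0] * x[None, :] + shift[1] * x[:, None]) / n
    )
    return np.fft.fft2(np.fft.ifft2(spectrum) * ramp)


class Reconstructor:
    """Precomputed reconstruction kernels for one (patterns, OTF, config).

    Holds the mixing inverse, the analytically evaluated shifted OTFs, the
    shared Wiener denominator and the apodization window, so that windows of
    a long series are reconstructed with a handful of FFTs each.
    """

    def __init__(
        self,
        patterns: PatternSet,
        otf: OTFModel,
        config: ReconstructionConfig,
    ) -> None:
        if patterns.size != otf.size:
            raise ValueError("pattern and OTF grids must match")
        self.patterns = patterns
        self.otf = otf
        self.config = config
        n = patterns.size
        self.size = n
        self.limit = sim_passband_limit(
            otf.cutoff, patterns.fringe_period, n
        )
        self._minv = _mixing_inverse(
            patterns.phases, patterns.modulation_depth
        )

        k = np.fft.fftfreq(n) * n  # unshifted frequency coords
        kx, ky = k[None, :], k[:, None]
        x = np.arange(n, dtype=np.float64)
        self._otf0 = otf.value_at(kx, ky)
        self._otf_plus, self._otf_minus = [], []
        self._ramp_plus, self._ramp_minus = [], []
        for a in range(3):
            px, py = patterns.shift_vector(a)
            self._otf_plus.append(otf.value_at(kx + px, ky + py))
            self._otf_minus.append(otf.value_at(kx - px, ky - py))
            ramp = np.exp(
                -2j * np.pi * (px * x[None, :] + py * x[:, None]) / n
            )
            self._ramp_plus.append(ramp)
            self._ramp_minus.append(np.conj(ramp))

        w_side = (patterns.modulation_depth / 2.0) ** 2
        denom = 3.0 * self._otf0**2 + w_side * sum(
            op**2 + om**2
            for op, om in zip(self._otf_plus, self._otf_minus)
        )
        self._denom = denom + config.wiener**2
        self._w_side = w_side

        radius = np.hypot(kx, ky)
        if config.apodization == "triangle":
            self._apod = np.clip(1.0 - radius / self.limit, 0.0, 1.0)
        else:
            self._apod = np.ones((n, n))

    def reconstruct_window(
        self, frames: np.ndarray, pattern_indices: np.ndarray
    ) -> np.ndarray:
        """Reconstruct one super-resolved image from 9 raw frames.

        ``pattern_indices`` gives each frame's pattern index (t mod 9); all
        nine indices must be present exactly once.  Frames are grouped by
        pattern index regardless of temporal order within the window.
        """
        frames = np.asarray(frames, dtype=np.float64)
        pattern_indices = np.asarray(pattern_indices)
        if frames.shape[0] != 9:
            raise ValueError("a window holds exactly 9 frames")
        if sorted(pattern_indices.tolist()) != list(range(9)):
            raise ValueError("window must contain each pattern index once")

        ordered = frames[np.argsort(pattern_indices)]
        num = np.zeros((self.size, self.size), dtype=complex)
        for a in range(3):
            D = np.fft.fft2(ordered[3 * a : 3 * a + 3], axes=(-2, -1))
            C = np.einsum("cj,jyx->cyx", self._minv, D)
            num += self._otf0 * C[0]
            num += (
                self._w_side
                * self._otf_plus[a]
                * np.fft.fft2(np.fft.ifft2(C[1]) * self._ramp_plus[a])
            )
            num += (
                self._w_side
                * self._otf_minus[a]
                * np.fft.fft2(np.fft.ifft2(C[2]) * self._ramp_minus[a])
            )
        hr = np.fft.ifft2(num / self._denom * self._apod).real
        if self.config.equalize_window_means:
            mean = hr.mean()
            if mean > 0:
                hr = hr / mean
        return hr


def assemble_hr(
    angle_components,
    patterns: PatternSet,
    otf: OTFModel,
    config: ReconstructionConfig,
) -> np.ndarray:
    """Merge separated spectral components into one super-resolved image.

    ``angle_components`` is a sequence of 3 per-angle arrays, each holding
    the 3 separated (not yet shifted) spectra from `separate_components`.
    The aliased components are shifted to their true frequency positions and
    merged by the generalized Wiener filter with triangle apodization.
    """
    recon = Reconstructor(patterns, otf, config)
    num = np.zeros((recon.size, recon.size), dtype=complex)
    for a, C in enumerate(angle_components):
        C = np.asarray(C)
        num += recon._otf0 * C[0]
        num += (
            recon._w_side
            * recon._otf_plus[a]
            * np.fft.fft2(np.fft.ifft2(C[1]) * recon._ramp_plus[a])
        )
        num += (
            recon._w_side
            * recon._otf_minus[a]
            * np.fft.fft2(np.fft.ifft2(C[2]) * recon._ramp_minus[a])
        )
    hr = np.fft.ifft2(num / recon._denom * recon._apod).real
    if config.equalize_window_means:
        mean = hr.mean()
        if mean > 0:
            hr = hr / mean
    return hr


def reconstruct_series(
    raw: RawFrameStack,
    patterns: PatternSet,
    otf: OTFModel,
    config: ReconstructionConfig,
) -> HRStack:
    """Reconstruct every window of a raw series under the configured scheme.

    Windows are enumerated by the scheme stride (9 / 3 / 1); each window's
    9 frames are grouped into angle triples by pattern index (wrapping
    across the window for rolling-1 offsets not divisible by 3) and
    reconstructed independently.
    """
    starts = window_starts(raw.n_frames, config.scheme)
    recon = Reconstructor(patterns, otf, config)
    pattern_index = raw.pattern_index
    frames = np.empty((len(starts), raw.frames.shape[1], raw.frames.shape[2]))
    for w, s in enumerate(starts):
        sl = slice(s, s + 9)
        frames[w] = recon.reconstruct_window(
            raw.frames[sl], pattern_index[sl]
        )
    return HRStack(frames=frames, window_start=starts, scheme=config.scheme)
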