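"""Microscope model: optical transfer function and low-pass imaging.

The detection OTF is the 2D autocorrelation of a circular aperture — the
incoherent transfer function of an ideal circular-pupil microscope.  It has
the closed form

    T(rho) = (2/pi) * (arccos(rho) - rho * sqrt(1 - rho^2)),   rho = |f| / f_c

for rho <= 1 and zero beyond, where f_c is the cutoff radius in frequency
pixels.  T is 1 at DC, radially symmetric, monotonically decreasing, and
vanishes at the cutoff; its inverse transform (the PSF) is the non-negative
Airy intensity pattern, so blurring a non-negative image stays non-negative
up to float rounding.

Structured illumination extends the observable region: aliasing by a fringe
of real-domain period ``p`` shifts information by ``N/p`` frequency pixels,
so the extended pass-band radius is ``round(f_c + N/p)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OTFModel",
    "make_otf",
    "apply_otf",
    "sim_passband_limit",
    "write_otf_tiff",
]


def _chord_overlap(rho: np.ndarray) -> np.ndarray:
    """Normalized overlap area of two unit disks at centre distance 2*rho."""
    rho = np.asarray(rho, dtype=np.float64)
    inside = rho < 1.0
    r = np.clip(rho, 0.0, 1.0)
    val = (2.0 / np.pi) * (np.arccos(r) - r * np.sqrt(1.0 - r * r))
    return np.where(inside, val, 0.0)


@dataclass
class OTFModel:
    """Radially symmetric detection OTF with a hard cutoff.

    ``transfer`` is stored in centred layout (DC at pixel (N//2, N//2));
    ``value_at`` evaluates the same closed form at arbitrary, possibly
    sub-pixel, frequency coordinates — used when weighting spectral
    components shifted by the non-integer fringe frequency.
    """

    transfer: np.ndarray  # (N, N), centred frequency layout
    cutoff: float  # frequency pixels

    @property
    def size(self) -> int:
        return self.transfer.shape[0]

    def value_at(self, kx, ky) -> np.ndarray:
        """Analytic OTF gain at frequency coordinates (kx, ky) from DC."""
        return _chord_overlap(np.hypot(kx, ky) / self.cutoff)


def make_otf(size: int, cutoff: float) -> OTFModel:
    """Build the disk-autocorrelation OTF on an ``size`` x ``size`` grid.

    ``cutoff`` is the pass-band radius in frequency pixels and must not
    exceed the Nyquist radius ``size/2``.
    """
    if not 0 < cutoff <= size / 2:
        raise ValueError(
            f"cutoff must be in (0, {size / 2}] (Nyquist radius), got {cutoff}"
        )
    k = np.arange(size, dtype=np.float64) - size // 2
    transfer = _chord_overlap(np.hypot(k[None, :], k[:, None]) / cutoff)
    return OTFModel(transfer=transfer, cutoff=float(cutoff))


def apply_otf(image: np.ndarray, otf: OTFModel) -> np.ndarray:
    """Image an intensity distribution through the microscope.

    Multiplies the image spectrum by the OTF (circular convolution with the
    PSF; periodic boundaries) and returns the real part — the imaginary
    residue is float noise since the transfer is real and symmetric.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape != otf.transfer.shape:
        raise ValueError(
            f"image shape {image.shape} does not match OTF grid "
            f"{otf.transfer.shape}"
        )
    spec = np.fft.fft2(image) * np.fft.ifftshift(otf.transfer)
    return np.fft.ifft2(spec).real


def sim_passband_limit(cutoff: float, fringe_period: float, size: int) -> int:
    """Radius of the extended SIM pass band, in frequency pixels.

    The illumination fringe of real-domain period ``fringe_period`` aliases
    information from ``size / fringe_period`` frequency pixels beyond the
    widefield cutoff, so the extended limit is
    ``round(cutoff + size / fringe_period)``.  An infinite period (uniform
    illumination) degenerates to the widefield cutoff.
    """
    if fringe_period <= 2:
        raise ValueError(
            "fringe_period must exceed 2 pixels (fringe frequency below "
            f"Nyquist), got {fringe_period}"
        )
    shift = 0.0 if np.isinf(fringe_period) else size / fringe_period
    return int(round(cutoff + shift))


def write_otf_tiff(path, otf: OTFModel) -> None:
    """Export the centred transfer grid as a single-page float32 TIFF."""
    import tifffile

    tifffile.imwrite(str(path), otf.transfer.astype(np.float32))
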