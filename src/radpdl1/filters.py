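"""The 15-image filter bank: 7 Laplacian-of-Gaussian scales + 8 wavelet subbands.

First-order and texture features are computed from each response image, so
every filter is size-preserving: LoG responses come from ``scipy``'s
Gaussian-Laplace operator with sigma expressed in millimetres on the
isotropically resampled grid, and the wavelet stage is a single-level
undecimated separable 3D decomposition (high- or low-pass along each axis)
so the subbands stay aligned with the lesion mask.

Subband labels concatenate the per-axis filter choices in (x, y, z) order:
``HHL`` means high-pass along x and y, low-pass along z.  Boundary handling
is edge replication for both filter families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pywt
from scipy import ndimage

from .types import FilteredImage, LesionVolume

DEFAULT_LOG_SIGMAS_MM = (0.1, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0)
DEFAULT_WAVELET = "coif1"

#: the 8 subband labels in deterministic (lexicographic) order
SUBBAND_LABELS = tuple("".join(c) for c in product("HL", repeat=3))


@dataclass(frozen=True)
class FilterBankConfig:
    log_sigmas_mm: tuple[float, ...] = DEFAULT_LOG_SIGMAS_MM
    wavelet_name: str = DEFAULT_WAVELET

    def __post_init__(self) -> None:
        sig = tuple(float(s) for s in self.log_sigmas_mm)
        if any(s <= 0 for s in sig):
            raise ValueError("LoG sigmas must be strictly positive")
        if len(set(sig)) != len(sig):
            raise ValueError("LoG sigmas must be unique")
        object.__setattr__(self, "log_sigmas_mm", sig)

    @property
    def n_images(self) -> int:
        return len(self.log_sigmas_mm) + len(SUBBAND_LABELS)


def _sigma_label(sigma: float) -> str:
    s = f"{sigma:g}"
    return f"log-sigma-{s}"


def _log_kernels(sigma_vox: float) -> tuple[np.ndarray, np.ndarray]:
    """Discrete 1D Gaussian (sum 1) and its second derivative (sum 0).

    The raw truncated second-derivative kernel has a small nonzero DC
    component; projecting it out along the Gaussian restores the exact
    zero response to constant (and, by symmetry, linear) inputs.
    """
    radius = max(int(4.0 * sigma_vox + 0.5), 1)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-x ** 2 / (2.0 * sigma_vox ** 2))
    g /= g.sum()
    g2 = g * (x ** 2 - sigma_vox ** 2) / sigma_vox ** 4
    g2 -= g * g2.sum()
    return g, g2


def log_filter(vol: LesionVolume, sigma_mm: float) -> FilteredImage:
    """Laplacian-of-Gaussian response at scale ``sigma_mm``.

    Requires an isotropic grid so a physical sigma maps to a single
    voxel-unit sigma.  Separable implementation: the Laplacian is the sum
    over axes of the second-derivative-of-Gaussian along that axis and
    Gaussian smoothing along the others.  The response to an isolated
    bright impulse is negative at its centre (the operator is not negated).
    """
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    if not vol.is_isotropic:
        raise ValueError("LoG filtering requires isotropic spacing; resample first")
    sigma_vox = sigma_mm / vol.spacing_mm[0]
    g, g2 = _log_kernels(sigma_vox)
    resp = np.zeros_like(vol.intensities)
    for deriv_axis in range(3):
        part = vol.intensities
        for axis in range(3):
            taps = g2 if axis == deriv_axis else g
            part = ndimage.correlate1d(part, taps, axis=axis, mode="nearest")
        resp += part
    return FilteredImage(_sigma_label(sigma_mm), resp)


def _separable_filter(img: np.ndarray, taps: dict[str, np.ndarray],
                      label: str) -> np.ndarray:
    out = img
    for axis, choice in enumerate(label):
        out = ndimage.convolve1d(out, taps[choice], axis=axis, mode="nearest")
    return out


def wavelet_decompose(vol: LesionVolume,
                      wavelet_name: str = DEFAULT_WAVELET) -> list[FilteredImage]:
    """Single-level undecimated 3D wavelet decomposition -> 8 subbands.

    Per axis the decomposition low-pass (L) or high-pass (H) filter of the
    chosen basis is applied without downsampling, preserving the grid.
    Subbands are returned in lexicographic label order (HHH ... LLL).
    """
    w = pywt.Wavelet(wavelet_name)
    taps = {"L": np.asarray(w.dec_lo, dtype=np.float64),
            "H": np.asarray(w.dec_hi, dtype=np.float64)}
    flen = len(taps["L"])
    if min(vol.intensities.shape) < flen:
        raise ValueError(
            f"volume shape {vol.intensities.shape} smaller than the "
            f"{wavelet_name} filter length {flen} along some axis"
        )
    out = []
    for label in SUBBAND_LABELS:
        resp = _separable_filter(vol.intensities, taps, label)
        out.append(FilteredImage(f"wavelet-{label}", resp))
    return out


def filter_bank(vol: LesionVolume,
                config: FilterBankConfig = FilterBankConfig()) -> list[FilteredImage]:
    """All response images: LoG by ascending sigma, then wavelet subbands."""
    images = [log_filter(vol, s) for s in sorted(config.log_sigmas_mm)]
    images.extend(wavelet_decompose(vol, config.wavelet_name))
    labels = [im.source_filter for im in images]
    assert len(set(labels)) == len(labels)
    return images
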