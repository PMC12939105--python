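"""Volume standardisation ahead of feature extraction.

CT volumes arrive with scanner-dependent voxel sizes; texture statistics
are only comparable across patients on a common grid, so every volume is
resampled to isotropic voxels (1 mm default) and the intensities are
truncated to the lung display window (level −600 HU, width 1500 HU) before
anything downstream sees them.  Order of operations: resample, then window,
then crop to the lesion bounding box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import LesionVolume

DEFAULT_TARGET_SPACING = (1.0, 1.0, 1.0)


@dataclass(frozen=True)
class WindowParams:
    """Intensity truncation window; defaults are the standard lung window."""

    level: float = -600.0
    width: float = 1500.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be positive")

    @property
    def lo(self) -> float:
        return self.level - self.width / 2.0

    @property
    def hi(self) -> float:
        return self.level + self.width / 2.0


def resample_isotropic(
    vol: LesionVolume,
    target_mm: tuple[float, float, float] = DEFAULT_TARGET_SPACING,
) -> LesionVolume:
    """Resample intensities (trilinear) and mask (nearest) to ``target_mm``.

    The physical extent of the grid is preserved to within one voxel; if the
    input is already on the target grid the volume is returned unchanged
    (identity path, no interpolation noise).

    Raises
    ------
    ValueError
        If the mask is empty after resampling.
    """
    target = tuple(float(t) for t in target_mm)
    if any(t <= 0 for t in target):
        raise ValueError("target spacing must be positive")
    if all(abs(s - t) < 1e-9 for s, t in zip(vol.spacing_mm, target)):
        return vol.copy()

    zoom = [s / t for s, t in zip(vol.spacing_mm, target)]
    intens = ndimage.zoom(vol.intensities, zoom, order=1, mode="nearest")
    mask = ndimage.zoom(vol.mask.astype(np.uint8), zoom, order=0,
                        mode="nearest", grid_mode=False).astype(bool)
    if mask.shape != intens.shape:  # pragma: no cover - zoom is consistent
        mask = np.zeros(intens.shape, dtype=bool)
    if not mask.any():
        raise ValueError(
            f"mask vanished during resampling (patient {vol.patient_id!r}); "
            "lesion smaller than the target voxel size"
        )
    return LesionVolume(intens, target, mask, vol.patient_id)


def window_hu(vol: LesionVolume, w: WindowParams = WindowParams()) -> LesionVolume:
    """Clamp intensities to [level - width/2, level + width/2]."""
    clipped = np.clip(vol.intensities, w.lo, w.hi)
    return LesionVolume(clipped, vol.spacing_mm, vol.mask.copy(), vol.patient_id)


def crop_to_mask(vol: LesionVolume, margin_voxels: int = 2) -> LesionVolume:
    """Crop to the tight bounding box of the mask plus a voxel margin.

    The margin is clipped to the grid, so a margin larger than the volume
    returns the full grid; re-cropping a cropped volume is a no-op.
    """
    if margin_voxels < 0:
        raise ValueError("margin_voxels must be >= 0")
    idx = np.nonzero(vol.mask)
    slices = []
    for ax in range(3):
        lo = max(int(idx[ax].min()) - margin_voxels, 0)
        hi = min(int(idx[ax].max()) + margin_voxels + 1, vol.mask.shape[ax])
        slices.append(slice(lo, hi))
    sl = tuple(slices)
    return LesionVolume(
        vol.intensities[sl].copy(), vol.spacing_mm, vol.mask[sl].copy(),
        vol.patient_id,
    )


def preprocess(
    vol: LesionVolume,
    target_mm: tuple[float, float, float] = DEFAULT_TARGET_SPACING,
    window: WindowParams = WindowParams(),
    margin_voxels: int = 2,
) -> LesionVolume:
    """Full standardisation chain: resample -> window -> crop."""
    return crop_to_mask(window_hu(resample_isotropic(vol, target_mm), window),
                        margin_voxels)
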