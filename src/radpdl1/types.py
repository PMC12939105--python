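"""Core domain containers shared across the pipeline.

The unit of imaging input is a :class:`LesionVolume`: a 3D block of CT
intensities in Hounsfield units, its per-axis voxel spacing in millimetres,
and a binary lesion mask aligned voxel-for-voxel with the intensities.
Axis order is (x, y, z) everywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LesionVolume:
    """A 3D CT sub-volume with an aligned binary lesion mask.

    Parameters
    ----------
    intensities
        3D array of CT numbers in Hounsfield units.
    spacing_mm
        Voxel size along (x, y, z) in millimetres.
    mask
        Boolean array, same shape as ``intensities``; True marks lesion.
    patient_id
        Identifier used for split bookkeeping and error messages.
    """

    intensities: np.ndarray
    spacing_mm: tuple[float, float, float]
    mask: np.ndarray
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if self.mask.shape != self.intensities.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != intensity shape "
                f"{self.intensities.shape} (patient {self.patient_id!r})"
            )
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be three positive values")
        if not self.mask.any():
            raise ValueError(
                f"mask has no foreground voxel (patient {self.patient_id!r})"
            )

    @property
    def is_isotropic(self) -> bool:
        s = self.spacing_mm
        return abs(s[0] - s[1]) < 1e-9 and abs(s[1] - s[2]) < 1e-9

    def masked_intensities(self) -> np.ndarray:
        """Flat array of intensities inside the mask."""
        return self.intensities[self.mask]

    def copy(self) -> "LesionVolume":
        return LesionVolume(
            self.intensities.copy(), self.spacing_mm, self.mask.copy(),
            self.patient_id,
        )


@dataclass
class FilteredImage:
    """One response image of the filter bank, same grid as its source."""

    source_filter: str
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)


@dataclass
class FeatureVector:
    """Named radiomics representation of one lesion.

    Names follow ``<filter>_<family>_<feature>``, e.g.
    ``wavelet-HHL_glszm_SizeZoneNonUniformityNormalized``; shape features
    carry the filter tag ``original``.
    """

    values: dict[str, float] = field(default_factory=dict)
    patient_id: str = ""

    def __len__(self) -> int:
        return len(self.values)

    def names(self) -> list[str]:
        return list(self.values)

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=np.float64)
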