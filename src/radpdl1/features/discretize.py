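"""Fixed-bin-width gray-level discretization of a masked ROI.

Texture matrices are defined over a small set of integer gray levels, so
masked intensities are binned with a fixed width anchored at the ROI
minimum: ``level = floor((x - min) / width) + 1``.  Anchoring at the
minimum makes every texture feature invariant to a constant intensity
offset, which is the behaviour wanted for HU data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_BIN_WIDTH_HU = 25.0


@dataclass
class DiscretizedROI:
    """Integer gray levels of the masked voxels on the original 3D grid.

    ``levels`` is 0 outside the mask and in [1, n_levels] inside.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_width: float

    def masked_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def discretize(intensities: np.ndarray, mask: np.ndarray,
               bin_width: float = DEFAULT_BIN_WIDTH_HU) -> DiscretizedROI:
    """Bin masked intensities into gray levels of fixed ``bin_width``."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot discretize an empty ROI")
    x = np.asarray(intensities, dtype=np.float64)
    lo = x[mask].min()
    levels = np.zeros(x.shape, dtype=np.int64)
    levels[mask] = np.floor((x[mask] - lo) / bin_width).astype(np.int64) + 1
    return DiscretizedROI(levels, mask, int(levels.max()), float(bin_width))
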