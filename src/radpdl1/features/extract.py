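"""Per-lesion assembly of the full 1409-dimensional feature vector.

Composition under the default configuration:

- 14 shape features from the original mask (filter tag ``original``);
- per filtered image of the 15-image bank (7 LoG scales + 8 wavelet
  subbands): 18 first-order + 75 texture features, i.e. 93 per image;
- totals: 7 * 93 = 651 LoG-derived, 8 * 93 = 744 wavelet-derived,
  651 + 744 + 14 = 1409.

Feature names follow ``<filter>_<family>_<feature>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..filters import FilterBankConfig, filter_bank
from ..types import FeatureVector, LesionVolume
from .discretize import DEFAULT_BIN_WIDTH_HU, discretize
from .firstorder import firstorder_features
from .shape import shape_features
from .texture import texture_features

EXPECTED_TOTAL = 1409


@dataclass(frozen=True)
class ExtractionConfig:
    filters: FilterBankConfig = field(default_factory=FilterBankConfig)
    bin_width_hu: float = DEFAULT_BIN_WIDTH_HU
    gldm_alpha: int = 0

    def __post_init__(self) -> None:
        if self.bin_width_hu <= 0:
            raise ValueError("bin_width_hu must be positive")


def extract_all(vol: LesionVolume,
                config: ExtractionConfig = ExtractionConfig()) -> FeatureVector:
    """Compute the named feature vector of one preprocessed lesion."""
    if not vol.is_isotropic:
        raise ValueError(
            f"extraction requires isotropic spacing, got {vol.spacing_mm} "
            f"(patient {vol.patient_id!r}); run preprocessing first"
        )
    values: dict[str, float] = {}
    for name, val in shape_features(vol.mask, vol.spacing_mm).items():
        values[f"original_shape_{name}"] = val

    voxel_vol = float(np.prod(vol.spacing_mm))
    for img in filter_bank(vol, config.filters):
        roi = img.intensities[vol.mask]
        for name, val in firstorder_features(
                roi, voxel_vol, config.bin_width_hu).items():
            values[f"{img.source_filter}_firstorder_{name}"] = val
        droi = discretize(img.intensities, vol.mask, config.bin_width_hu)
        for name, val in texture_features(droi).items():
            values[f"{img.source_filter}_{name}"] = val

    return FeatureVector(values, vol.patient_id)


def extract_cohort(volumes: list[LesionVolume],
                   config: ExtractionConfig = ExtractionConfig()) -> pd.DataFrame:
    """Feature table: one row per lesion, patient_id as the index."""
    rows = []
    for vol in volumes:
        fv = extract_all(vol, config)
        rows.append(pd.Series(fv.values, name=vol.patient_id))
    return pd.DataFrame(rows).rename_axis("patient_id")


def count_by_branch(fv: FeatureVector) -> dict[str, int]:
    """Decompose the feature count by filter branch and family."""
    names = fv.names()
    return {
        "total": len(names),
        "shape": sum(n.startswith("original_shape_") for n in names),
        "firstorder": sum("_firstorder_" in n for n in names),
        "texture": sum(any(f"_{fam}_" in n for fam in
                           ("glcm", "glrlm", "glszm", "gldm", "ngtdm"))
                       for n in names),
        "log": sum(n.startswith("log-sigma-") for n in names),
        "wavelet": sum(n.startswith("wavelet-") for n in names),
    }
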