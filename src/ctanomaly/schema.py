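"""Shared label schema for the multi-organ anomaly-detection pipeline.

One place defines the mask label integers, the organ list and the
per-organ disease-category taxonomy; every other module imports from
here so a phantom volume, a parsed report and a trained classifier all
agree on what "kidney_L" or "liver/mass" means.
"""

from __future__ import annotations

# Integer labels used in the multi-organ segmentation masks. The first six
# are the organs the anomaly detector is trained on; kidneys are kept as
# separate left/right structures throughout the pipeline. The remaining
# structures are part of the segmentation schema but carry no disease
# categories here.
MASK_LABELS: dict[str, int] = {
    "liver": 1,
    "gallbladder": 2,
    "pancreas": 3,
    "spleen": 4,
    "kidney_L": 5,
    "kidney_R": 6,
    "esophagus": 7,
    "stomach": 8,
    "duodenum": 9,
    "aorta": 10,
    "adrenal_L": 11,
    "adrenal_R": 12,
    "bladder": 13,
    "prostate_uterus": 14,
}

#: Organs with disease categories, in canonical report order.
TARGET_ORGANS: tuple[str, ...] = (
    "liver",
    "gallbladder",
    "pancreas",
    "spleen",
    "kidney_L",
    "kidney_R",
)

#: Catch-all category for abnormal finding words that no table entry maps;
#: present in every organ's vector so "abnormal == any category" always holds.
OTHER_CATEGORY = "other"

# Disease categories per organ (both kidneys share the kidney taxonomy).
_KIDNEY_CATEGORIES = ("mass", "cyst", "stone", "hydronephrosis")
ORGAN_CATEGORIES: dict[str, tuple[str, ...]] = {
    "liver": ("mass", "cyst", "fatty_change"),
    "gallbladder": ("stone", "polyp", "wall_thickening"),
    "pancreas": ("mass", "cyst", "duct_dilation"),
    "spleen": ("mass", "splenomegaly"),
    "kidney_L": _KIDNEY_CATEGORIES,
    "kidney_R": _KIDNEY_CATEGORIES,
}


def categories_for(organ: str, include_other: bool = True) -> tuple[str, ...]:
    """Category vector layout for one organ (optionally with ``other``)."""
    base = ORGAN_CATEGORIES[organ]
    return base + (OTHER_CATEGORY,) if include_other else base


def organ_of_mask_label(label: int) -> str:
    for name, value in MASK_LABELS.items():
        if value == label:
            return name
    raise KeyError(f"unknown mask label {label}")
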