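"""Tissue class codes shared across the pipeline.

Every per-pixel label map in the package uses these integer codes. The four
classes are the ones a Levai-Laczko-stained section resolves: background /
soft tissue, pre-existing (old) bone, newly formed bone, and bone-substitute
material (particle agglomerates).
"""

from __future__ import annotations

from enum import IntEnum


class Tissue(IntEnum):
    """Integer codes for the four tissue classes of a segmented section."""

    SOFT = 0
    OLD_BONE = 1
    NEW_BONE = 2
    SUBSTITUTE = 3


#: Canonical order of class names, indexable by code.
CLASS_NAMES = ("soft_tissue", "old_bone", "new_bone", "substitute")

#: Default stain-appearance model: mean RGB (0-255) per class. Old bone is a
#: light pink, new bone darker and purple (larger red-green difference),
#: soft tissue near-white, substitute grey-brown. The red-green difference is
#: the axis the segmentation cascade discriminates bone from soft tissue on.
DEFAULT_CLASS_COLORS: dict[str, tuple[float, float, float]] = {
    "soft_tissue": (243.0, 241.0, 237.0),
    "old_bone": (236.0, 176.0, 190.0),
    "new_bone": (165.0, 90.0, 155.0),
    "substitute": (130.0, 120.0, 110.0),
}
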