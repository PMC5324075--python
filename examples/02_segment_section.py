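"""Run the rule-based segmentation cascade on a phantom section.

Segments a noisy rendered section (quadtree split, coarse classification,
isolated-bone declassification, adaptive red-green threshold, surface-
tension smoothing, geometric old/new bone split, manual substitute overlay)
and scores it against the phantom's ground-truth labels.
"""

import numpy as np

from histobridge import PhantomConfig, Tissue, generate_section, segment_section

truth = generate_section(
    PhantomConfig(seed=7, pixel_pitch_um=10.0, canal_spec=[0.5], agglomerate_count=20)
)
seg = segment_section(
    truth.image, truth.geometry, substitute_mask=truth.substitute_mask
)

print("cascade stages:", " -> ".join(seg.provenance))
print(f"adaptive red-green threshold: {seg.adaptive_threshold:.1f}")


def dice(a, b):
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


bone_s = (seg.labels == Tissue.OLD_BONE) | (seg.labels == Tissue.NEW_BONE)
bone_t = (truth.labels == Tissue.OLD_BONE) | (truth.labels == Tissue.NEW_BONE)
print(f"Dice bone        : {dice(bone_s, bone_t):.4f}")
print(f"Dice soft tissue : {dice(seg.labels == 0, truth.labels == 0):.4f}")
print(f"mismatched pixels: {(seg.labels != truth.labels).sum()} of {seg.labels.size}")

# At the default noise (sd 10/255) both Dice values sit above 0.999; with
# noise_sd=0 the recovered map equals the ground truth exactly.
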