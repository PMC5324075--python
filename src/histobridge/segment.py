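"""Rule-based split-and-classify segmentation of stained histology sections.

The cascade mirrors classic object-based histology segmentation:

1. quadtree split — square objects are quartered until each meets a
   per-channel colour-variance homogeneity criterion;
2. coarse classification — background (soft tissue) is seeded with a very
   conservative colour-distance threshold and grown into surrounding leaves
   with a less restrictive one; bone is then classified among the remaining
   leaves by the red-green colour-layer difference;
3. isolated bone objects (fewer than two edge-neighbouring bone objects) are
   declassified;
4. an adaptive threshold is computed from the mean red-green difference of
   the coarsely classified bone and applied at the pixel level inside bone
   and unclassified objects;
5. the bone/soft boundary is smoothed by alternating growing and shrinking
   constrained by surface tension (majority-vote curvature flow), small
   enclosed islands are absorbed, and a single boundary-refinement pass may
   shift the border where that increases the red-green separation of the two
   classes;
6. bone is split into old vs new bone by the drill-hole geometry (new bone
   regenerates inside the drill hole), optionally colour-refined in a
   boundary band;
7. substitute material, which cannot be told apart from its surroundings
   reliably by colour rules, is overlaid from a manually supplied mask.

Coordinates are 0-based; rectangles are half-open. Pixel connectivity is
8-connected for masks/components and 4-connected (shared edges) for
leaf-neighbour relations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
from scipy import ndimage

from .roi import DefectGeometry
from .tissue import DEFAULT_CLASS_COLORS, Tissue

__all__ = [
    "QuadtreeNode",
    "SegmentationMap",
    "SegmentationParams",
    "NoBoneDetectedError",
    "quadtree_split",
    "coarse_classify",
    "declassify_isolated_bone",
    "adaptive_threshold",
    "pixel_threshold_and_smooth",
    "split_new_vs_old_bone",
    "apply_substitute_mask",
    "segment_section",
]

_BACKGROUND = "background"
_BONE = "bone"
_UNCLASSIFIED = "unclassified"

_NEIGH8 = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


class NoBoneDetectedError(RuntimeError):
    """Raised when the adaptive threshold is requested without any bone."""


@dataclass
class QuadtreeNode:
    """A node of the quadtree decomposition.

    ``bounds`` is a half-open rectangle ``(r0, r1, c0, c1)``; children tile
    the parent exactly. Leaves satisfy the homogeneity criterion (max
    per-channel colour variance <= tolerance) or are single pixels.
    """

    bounds: tuple[int, int, int, int]
    children: list["QuadtreeNode"] = field(default_factory=list)
    variance: float = 0.0
    mean_rgb: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mean_rg_diff: float = 0.0
    coarse_class: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def area(self) -> int:
        r0, r1, c0, c1 = self.bounds
        return (r1 - r0) * (c1 - c0)

    def leaves(self) -> Iterator["QuadtreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                yield node
            else:
                stack.extend(node.children)


@dataclass
class SegmentationMap:
    """Per-pixel class map with the provenance of how it was produced."""

    labels: np.ndarray
    pixel_pitch_um: float
    adaptive_threshold: Optional[float] = None
    provenance: list[str] = field(default_factory=list)

    def copy(self) -> "SegmentationMap":
        return SegmentationMap(
            labels=self.labels.copy(),
            pixel_pitch_um=self.pixel_pitch_um,
            adaptive_threshold=self.adaptive_threshold,
            provenance=list(self.provenance),
        )


@dataclass
class SegmentationParams:
    """Tunable knobs of the cascade.

    The homogeneity tolerance is a per-channel colour variance (squared
    0-255 units) and must exceed the image noise variance for uniform
    regions to stop splitting; the default suits the phantom's default noise
    (sd 10 -> variance 100). Colour-distance thresholds are Euclidean RGB
    distances to the background reference colour. ``rg_threshold_scale`` is
    the factor applied to the mean bone red-green difference; with a
    near-white background it acts as a midpoint rule.
    """

    homogeneity_tol: float = 120.0
    conservative_bg_tol: float = 25.0
    growth_tol: float = 50.0
    bone_rg_min: float = 25.0
    rg_threshold_scale: float = 0.5
    smooth_iters: int = 2
    flip_majority: int = 6
    min_island_px: int = 16
    refine_window: int = 7
    refine: bool = True
    new_old_band_um: float = 0.0
    background_reference: Optional[tuple[float, float, float]] = None


# ---------------------------------------------------------------------------
# quadtree split
# ---------------------------------------------------------------------------


class _Integral:
    """Summed-area tables for O(1) per-rectangle channel sums and variances."""

    def __init__(self, image: np.ndarray):
        img = np.asarray(image, dtype=np.float64)
        self.s1 = np.zeros((img.shape[0] + 1, img.shape[1] + 1, 3))
        self.s2 = np.zeros_like(self.s1)
        np.cumsum(np.cumsum(img, axis=0), axis=1, out=self.s1[1:, 1:])
        np.cumsum(np.cumsum(img * img, axis=0), axis=1, out=self.s2[1:, 1:])

    def stats(self, r0: int, r1: int, c0: int, c1: int):
        n = (r1 - r0) * (c1 - c0)
        s = (
            self.s1[r1, c1]
            - self.s1[r0, c1]
            - self.s1[r1, c0]
            + self.s1[r0, c0]
        )
        q = (
            self.s2[r1, c1]
            - self.s2[r0, c1]
            - self.s2[r1, c0]
            + self.s2[r0, c0]
        )
        mean = s / n
        var = q / n - mean * mean
        return mean, np.maximum(var, 0.0)


def quadtree_split(image: np.ndarray, homogeneity_tol: float) -> QuadtreeNode:
    """Quadtree decomposition of an RGB raster.

    Square objects are quartered until the maximum per-channel colour
    variance does not exceed ``homogeneity_tol`` or the object is a single
    pixel. Non-square images are handled by splitting on a conceptual
    enclosing power-of-two square whose children are clipped to the image,
    so the leaf set always tiles the image exactly.
    """
    image = _as_rgb(image)
    height, width = image.shape[:2]
    if height == 0 or width == 0:
        raise ValueError("image must be non-empty")
    integral = _Integral(image)
    side = 1
    while side < max(height, width):
        side *= 2

    def make_node(r0, r1, c0, c1):
        mean, var = integral.stats(r0, r1, c0, c1)
        node = QuadtreeNode(
            bounds=(r0, r1, c0, c1),
            variance=float(var.max()),
            mean_rgb=tuple(mean),
            mean_rg_diff=float(mean[0] - mean[1]),
        )
        return node

    root = make_node(0, height, 0, width)
    # stack carries (node, conceptual square bounds)
    stack = [(root, (0, side, 0, side))]
    while stack:
        node, (sr0, sr1, sc0, sc1) = stack.pop()
        if node.variance <= homogeneity_tol:
            continue
        if sr1 - sr0 <= 1 and sc1 - sc0 <= 1:
            continue  # single conceptual pixel: forced leaf
        rm = (sr0 + sr1) // 2
        cm = (sc0 + sc1) // 2
        for qr0, qr1, qc0, qc1 in (
            (sr0, rm, sc0, cm),
            (sr0, rm, cm, sc1),
            (rm, sr1, sc0, cm),
            (rm, sr1, cm, sc1),
        ):
            r0, r1 = max(qr0, 0), min(qr1, height)
            c0, c1 = max(qc0, 0), min(qc1, width)
            if r1 <= r0 or c1 <= c0:
                continue  # quadrant lies entirely in the conceptual padding
            child = make_node(r0, r1, c0, c1)
            node.children.append(child)
            stack.append((child, (qr0, qr1, qc0, qc1)))
    return root


def leaf_id_map(tree: QuadtreeNode, shape: tuple[int, int]):
    """Paint leaf indices into an array; returns (id_map, list of leaves)."""
    leaves = list(tree.leaves())
    ids = np.full(shape, -1, dtype=np.int64)
    for i, leaf in enumerate(leaves):
        r0, r1, c0, c1 = leaf.bounds
        ids[r0:r1, c0:c1] = i
    return ids, leaves


def _leaf_adjacency(ids: np.ndarray, n: int) -> list[set[int]]:
    """Edge-sharing (von Neumann) adjacency between leaf rectangles."""
    pairs = []
    h = np.stack([ids[:, :-1].ravel(), ids[:, 1:].ravel()], axis=1)
    v = np.stack([ids[:-1, :].ravel(), ids[1:, :].ravel()], axis=1)
    for arr in (h, v):
        arr = arr[arr[:, 0] != arr[:, 1]]
        pairs.append(np.unique(arr, axis=0))
    adj: list[set[int]] = [set() for _ in range(n)]
    for arr in pairs:
        for a, b in arr:
            adj[a].add(int(b))
            adj[b].add(int(a))
    return adj


# ---------------------------------------------------------------------------
# coarse leaf classification
# ---------------------------------------------------------------------------


def estimate_background_reference(tree: QuadtreeNode) -> tuple[float, float, float]:
    """Estimate the background (soft tissue) reference colour of a slide.

    The colour balance of an individual image is taken from its brightest
    leaves: the area-weighted mean colour of leaves whose mean brightness is
    at or above the 95th percentile (background is the lightest material on
    a stained section).
    """
    leaves = list(tree.leaves())
    bright = np.array([sum(l.mean_rgb) for l in leaves])
    areas = np.array([l.area for l in leaves], dtype=np.float64)
    order = np.argsort(bright)[::-1]
    cum = np.cumsum(areas[order])
    keep = order[: max(1, int(np.searchsorted(cum, 0.05 * cum[-1]) + 1))]
    w = areas[keep]
    cols = np.array([leaves[i].mean_rgb for i in keep])
    ref = (cols * w[:, None]).sum(axis=0) / w.sum()
    return tuple(ref)


def coarse_classify(
    tree: QuadtreeNode,
    image: np.ndarray,
    conservative_bg_tol: float,
    growth_tol: float,
    bone_rg_min: float = 25.0,
    background_reference: Optional[tuple[float, float, float]] = None,
) -> QuadtreeNode:
    """Label quadtree leaves background / bone / unclassified.

    Background seeds are leaves within ``conservative_bg_tol`` RGB distance
    of the background reference colour; the background region is grown from
    the seeds into edge-adjacent leaves within ``growth_tol``. Among the
    remaining leaves, bone is identified by a mean red-green difference of at
    least ``bone_rg_min``; everything else stays unclassified.
    """
    image = _as_rgb(image)
    ids, leaves = leaf_id_map(tree, image.shape[:2])
    if background_reference is None:
        background_reference = estimate_background_reference(tree)
    ref = np.asarray(background_reference, dtype=np.float64)
    dist = np.array(
        [np.linalg.norm(np.asarray(l.mean_rgb) - ref) for l in leaves]
    )
    is_bg = dist <= conservative_bg_tol
    adj = _leaf_adjacency(ids, len(leaves))
    frontier = list(np.flatnonzero(is_bg))
    while frontier:
        i = frontier.pop()
        for j in adj[i]:
            if not is_bg[j] and dist[j] <= growth_tol:
                is_bg[j] = True
                frontier.append(j)
    for i, leaf in enumerate(leaves):
        if is_bg[i]:
            leaf.coarse_class = _BACKGROUND
        elif leaf.mean_rg_diff >= bone_rg_min:
            leaf.coarse_class = _BONE
        else:
            leaf.coarse_class = _UNCLASSIFIED
    return tree


def declassify_isolated_bone(
    tree: QuadtreeNode, shape: Optional[tuple[int, int]] = None
) -> QuadtreeNode:
    """Declassify bone leaves not bordered by bone on at least two sides.

    A neighbour is any leaf sharing an edge segment (4-connectivity on leaf
    rectangles) and counts once. The pass is simultaneous: counts are taken
    on the incoming classification, then all flips are applied together.
    A bone leaf without any non-bone neighbour (e.g. the single leaf of a
    solid-bone image) is kept: there is no surrounding evidence against it.
    """
    if shape is None:
        r0, r1, c0, c1 = tree.bounds
        shape = (r1, c1)
    ids, leaves = leaf_id_map(tree, shape)
    adj = _leaf_adjacency(ids, len(leaves))
    bone = np.array([l.coarse_class == _BONE for l in leaves])
    to_drop = [
        i
        for i in np.flatnonzero(bone)
        if sum(1 for j in adj[i] if bone[j]) < 2
        and any(not bone[j] for j in adj[i])
    ]
    for i in to_drop:
        leaves[i].coarse_class = _UNCLASSIFIED
    return tree


def coarse_label_image(tree: QuadtreeNode, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise the coarse leaf classes: 0 background, 1 bone, 2 unclassified."""
    out = np.full(shape, 2, dtype=np.uint8)
    for leaf in tree.leaves():
        r0, r1, c0, c1 = leaf.bounds
        if leaf.coarse_class == _BACKGROUND:
            out[r0:r1, c0:c1] = 0
        elif leaf.coarse_class == _BONE:
            out[r0:r1, c0:c1] = 1
    return out


# ---------------------------------------------------------------------------
# adaptive threshold and pixel-level refinement
# ---------------------------------------------------------------------------


def adaptive_threshold(
    tree: QuadtreeNode, image: np.ndarray, scale: float = 0.5
) -> float:
    """Slide-adaptive red-green threshold.

    The mean difference between the red and green layers over all pixels of
    coarsely bone-classified leaves, times ``scale``. With a near-white
    background (red-green difference ~ 0) the default 0.5 places the
    threshold midway between background and bone.
    """
    image = _as_rgb(image)
    diff = image[..., 0].astype(np.float64) - image[..., 1].astype(np.float64)
    total = 0.0
    npx = 0
    for leaf in tree.leaves():
        if leaf.coarse_class == _BONE:
            r0, r1, c0, c1 = leaf.bounds
            total += diff[r0:r1, c0:c1].sum()
            npx += leaf.area
    if npx == 0:
        raise NoBoneDetectedError("no bone-classified objects to derive a threshold")
    return scale * total / npx


def _neighbour_counts(mask: np.ndarray) -> np.ndarray:
    """8-neighbour same-class counts, replicating edge pixels outward."""
    return ndimage.correlate(mask.astype(np.uint8), _NEIGH8, mode="nearest")


def _absorb_islands(bone: np.ndarray, min_island_px: int) -> np.ndarray:
    """Absorb connected components smaller than ``min_island_px`` that are
    completely enclosed by the other class (i.e. do not touch the frame)."""
    s8 = np.ones((3, 3), dtype=bool)
    for target, value in ((bone, False), (~bone, True)):
        lab, n = ndimage.label(target, structure=s8)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())
        border = np.zeros(n + 1, dtype=bool)
        for edge in (lab[0], lab[-1], lab[:, 0], lab[:, -1]):
            border[np.unique(edge)] = True
        small = (sizes < min_island_px) & ~border
        small[0] = False
        if small.any():
            bone = bone.copy()
            bone[small[lab]] = value
    return bone


def _refine_boundary(
    bone: np.ndarray, diff: np.ndarray, window: int
) -> np.ndarray:
    """One simultaneous boundary pass: flip a boundary pixel iff that
    increases the absolute difference of local mean red-green between the
    two classes within the window centred on it."""
    k = np.ones((window, window))
    b = bone.astype(np.float64)
    n_b = ndimage.correlate(b, k, mode="constant", cval=0.0)
    s_b = ndimage.correlate(diff * b, k, mode="constant", cval=0.0)
    # constant-0 padding keeps out-of-frame cells out of both class counts
    n_s = ndimage.correlate(1.0 - b, k, mode="constant", cval=0.0)
    s_s = ndimage.correlate(diff * (1.0 - b), k, mode="constant", cval=0.0)

    counts = _neighbour_counts(bone)
    boundary = (bone & (counts < 8)) | (~bone & (counts > 0))

    with np.errstate(divide="ignore", invalid="ignore"):
        cur = np.abs(s_b / n_b - s_s / n_s)
        # flipping a bone pixel to soft
        new_b2s = np.abs((s_b - diff) / (n_b - 1) - (s_s + diff) / (n_s + 1))
        # flipping a soft pixel to bone
        new_s2b = np.abs((s_b + diff) / (n_b + 1) - (s_s - diff) / (n_s - 1))
    ok = np.isfinite(cur)
    flip_b2s = bone & boundary & ok & np.isfinite(new_b2s) & (new_b2s > cur + 1e-9)
    flip_s2b = ~bone & boundary & ok & np.isfinite(new_s2b) & (new_s2b > cur + 1e-9)
    out = bone.copy()
    out[flip_b2s] = False
    out[flip_s2b] = True
    return out


def pixel_threshold_and_smooth(
    image: np.ndarray,
    coarse: np.ndarray,
    t: float,
    pixel_pitch_um: float,
    smooth_iters: int = 2,
    flip_majority: int = 6,
    min_island_px: int = 16,
    refine_window: int = 7,
    refine: bool = True,
) -> SegmentationMap:
    """Pixel-level thresholding of bone vs soft tissue plus boundary cleanup.

    Pixels inside bone or unclassified coarse objects with a red-green
    difference of at least ``t`` become bone; everything else is soft
    tissue. ``smooth_iters`` rounds of alternating growing and shrinking
    follow, constrained by surface tension: a pixel flips only when at least
    ``flip_majority`` of its 8 neighbours already hold the target class.
    Small enclosed islands are absorbed and, optionally, one
    boundary-refinement pass shifts the border where that increases the
    red-green separation of the classes.
    """
    if not np.isfinite(t):
        raise ValueError("threshold must be finite")
    if smooth_iters < 0:
        raise ValueError("smooth_iters must be >= 0")
    image = _as_rgb(image)
    diff = image[..., 0].astype(np.float64) - image[..., 1].astype(np.float64)
    bone = (coarse != 0) & (diff >= t)
    provenance = ["pixel_threshold"]

    for i in range(smooth_iters):
        counts = _neighbour_counts(bone)
        if i % 2 == 0:  # growing
            bone = bone | (~bone & (counts >= flip_majority))
        else:  # shrinking
            bone = bone & ~((8 - counts) >= flip_majority)
    if smooth_iters:
        provenance.append(f"surface_tension_smooth[{smooth_iters}]")

    bone = _absorb_islands(bone, min_island_px)
    provenance.append(f"absorb_islands[<{min_island_px}px]")

    if refine:
        bone = _refine_boundary(bone, diff, refine_window)
        provenance.append(f"boundary_refine[{refine_window}x{refine_window}]")

    labels = np.where(bone, np.uint8(Tissue.OLD_BONE), np.uint8(Tissue.SOFT))
    return SegmentationMap(
        labels=labels,
        pixel_pitch_um=pixel_pitch_um,
        adaptive_threshold=t,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# old/new bone split and substitute overlay
# ---------------------------------------------------------------------------


def split_new_vs_old_bone(
    segmap: SegmentationMap,
    image: Optional[np.ndarray],
    geometry: DefectGeometry,
    band_um: float = 0.0,
    old_color: Optional[tuple[float, float, float]] = None,
    new_color: Optional[tuple[float, float, float]] = None,
) -> SegmentationMap:
    """Split bone into new (inside the drill hole) vs old (outside).

    Pre-existing bone stains a lighter pink than the darker, purple new bone,
    but the decisive rule is geometric: regenerated bone lies within the
    drill-hole breadth. An optional colour-based override is applied within a
    band of ``band_um`` around each drill boundary, reassigning bone pixels
    to the nearer of the two reference colours.
    """
    out = segmap.copy()
    bone = (out.labels == Tissue.OLD_BONE) | (out.labels == Tissue.NEW_BONE)
    cols = np.arange(out.labels.shape[1])
    inside = (cols >= geometry.drill_left) & (cols < geometry.drill_right)
    out.labels[bone & inside[None, :]] = Tissue.NEW_BONE
    out.labels[bone & ~inside[None, :]] = Tissue.OLD_BONE

    if band_um > 0 and image is not None:
        band_px = max(1, geometry.mm_to_px(band_um / 1000.0))
        in_band = (np.abs(cols - geometry.drill_left) < band_px) | (
            np.abs(cols - geometry.drill_right) < band_px
        )
        sel = bone & in_band[None, :]
        if sel.any():
            img = _as_rgb(image).astype(np.float64)
            oc = np.asarray(old_color or DEFAULT_CLASS_COLORS["old_bone"])
            nc = np.asarray(new_color or DEFAULT_CLASS_COLORS["new_bone"])
            d_old = ((img - oc) ** 2).sum(axis=-1)
            d_new = ((img - nc) ** 2).sum(axis=-1)
            out.labels[sel & (d_new < d_old)] = Tissue.NEW_BONE
            out.labels[sel & (d_new >= d_old)] = Tissue.OLD_BONE
        out.provenance.append(f"new_old_colour_band[{band_um}um]")
    out.provenance.append("new_old_geometric_split")
    return out


def apply_substitute_mask(
    segmap: SegmentationMap, mask: np.ndarray
) -> SegmentationMap:
    """Overlay the manually classified substitute-material mask.

    Substitute materials cannot be distinguished reliably by the automatic
    colour rules, so any non-zero mask pixel overrides the automatic class.
    """
    if mask.shape != segmap.labels.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match labels {segmap.labels.shape}"
        )
    out = segmap.copy()
    out.labels[mask.astype(bool)] = Tissue.SUBSTITUTE
    out.provenance.append("substitute_mask_overlay")
    return out


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------


def segment_section(
    image: np.ndarray,
    geometry: DefectGeometry,
    substitute_mask: Optional[np.ndarray] = None,
    params: Optional[SegmentationParams] = None,
) -> SegmentationMap:
    """Run the full cascade on one section image."""
    p = params or SegmentationParams()
    image = _as_rgb(image)
    tree = quadtree_split(image, p.homogeneity_tol)
    coarse_classify(
        tree,
        image,
        conservative_bg_tol=p.conservative_bg_tol,
        growth_tol=p.growth_tol,
        bone_rg_min=p.bone_rg_min,
        background_reference=p.background_reference,
    )
    declassify_isolated_bone(tree, image.shape[:2])
    t = adaptive_threshold(tree, image, scale=p.rg_threshold_scale)
    coarse = coarse_label_image(tree, image.shape[:2])
    segmap = pixel_threshold_and_smooth(
        image,
        coarse,
        t,
        pixel_pitch_um=geometry.pixel_pitch_um,
        smooth_iters=p.smooth_iters,
        flip_majority=p.flip_majority,
        min_island_px=p.min_island_px,
        refine_window=p.refine_window,
        refine=p.refine,
    )
    segmap.provenance = [
        "quadtree_split",
        "coarse_classify",
        "declassify_isolated_bone",
        "adaptive_threshold",
    ] + segmap.provenance
    segmap = split_new_vs_old_bone(
        segmap, image, geometry, band_um=p.new_old_band_um
    )
    if substitute_mask is not None:
        segmap = apply_substitute_mask(segmap, substitute_mask)
    return segmap


def _as_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("expected an RGB raster of shape (H, W, 3)")
    return image[..., :3]
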