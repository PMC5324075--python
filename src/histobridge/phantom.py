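"""Synthetic stained-section and micro-CT phantoms with exact ground truth.

The phantom emulates a two-compartment drill-hole defect in a flat bone: a
cortical plate (periosteal margin above, endosteal margin below) over a
medullary (marrow) space, with an 8 mm defect through the plate. Pre-existing
bone flanks the defect; new bone regenerates inside it from the endosteal
side up to a configurable fill fraction; soft-tissue canals may breach the
cortex from the periosteal side; substitute-material particle agglomerates
of configurable count and size populate a target region. Rendering draws
each tissue class from a mean RGB colour with Gaussian per-channel noise —
old bone a light pink, new bone darker purple, soft tissue near-white,
substitute grey-brown — so the red-green difference is the axis that
discriminates bone from soft tissue, as the segmentation cascade expects.

3D phantoms are a cortical plate slab over a cavity, optionally breached by
straight or tortuous canals or indented by blind pockets; ground-truth
bridging follows directly from the canal specification.

Everything is deterministic: the same config (including its seed) yields
bit-identical outputs. Ground-truth reports are computed from the label map
by direct pixel counting (the metrics module), so recovery tests compare a
measured pipeline output against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import metrics as _metrics
from .bridging import CTVolume
from .roi import DefectGeometry, DefectROIs, build_rois
from .segment import SegmentationMap
from .tissue import DEFAULT_CLASS_COLORS, Tissue

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "InfeasibleConfigError",
    "generate_section",
    "generate_volume",
    "generate_cohort",
    "DEFAULT_GROUP_REGIMES",
]


class InfeasibleConfigError(ValueError):
    """Requested phantom content cannot fit the defect geometry."""


@dataclass
class PhantomConfig:
    """Parameters of one synthetic defect phantom.

    Section geometry defaults emulate the study setting: an 8 mm drill-hole
    through a 2 mm cortical plate, imaged at 1.283 um/px (full resolution) —
    tests and examples typically use a coarser pitch such as 10 um/px, which
    scales every structure consistently. ``agglomerate_area_mm2`` is a
    log-normal spec ``(median, sigma)``; sigma 0 gives fixed-size
    agglomerates. ``canal_spec`` lists widths (mm) of soft-tissue canals
    breaching the cortex; an empty list means the plate is intact.
    """

    seed: int = 0
    # ---- section raster ----
    pixel_pitch_um: float = 1.283
    section_width_mm: float = 10.0
    section_height_mm: float = 6.0
    defect_diameter_mm: float = 8.0
    cortical_thickness_mm: float = 2.0
    periosteal_depth_mm: float = 1.5
    class_colors: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COLORS)
    )
    noise_sd: float = 10.0
    new_bone_fill_fraction: float = 0.7
    trabecular_fill_fraction: float = 0.3
    trabecular_radius_mm: float = 0.075
    agglomerate_count: int = 0
    agglomerate_area_mm2: tuple[float, float] = (0.008, 0.0)
    agglomerate_region: str = "medullary"
    canal_spec: Sequence[float] = field(default_factory=list)
    # ---- volume raster ----
    volume_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_pitch_um: float = 17.2
    volume_canal_tortuous: bool = False
    pocket_spec: Sequence[tuple[float, float]] = field(default_factory=list)
    volume_noise_sd: float = 1500.0

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0 or self.voxel_pitch_um <= 0:
            raise ValueError("pixel pitches must be positive")
        if self.defect_diameter_mm <= 0:
            raise ValueError("defect_diameter_mm must be positive")
        if self.cortical_thickness_mm <= 0:
            raise ValueError("cortical_thickness_mm must be positive")
        if not 0.0 <= self.new_bone_fill_fraction <= 1.0:
            raise ValueError("new_bone_fill_fraction must lie in [0, 1]")
        if self.agglomerate_count < 0:
            raise ValueError("agglomerate_count must be non-negative")
        if self.defect_diameter_mm >= self.section_width_mm:
            raise ValueError("defect must be narrower than the section")
        if np.isscalar(self.agglomerate_area_mm2):
            self.agglomerate_area_mm2 = (float(self.agglomerate_area_mm2), 0.0)
        if self.agglomerate_region not in ("medullary", "cortical"):
            raise ValueError("agglomerate_region must be 'medullary' or 'cortical'")

    def mm_to_px(self, mm: float) -> int:
        return int(round(mm * 1000.0 / self.pixel_pitch_um))


@dataclass
class PhantomTruth:
    """Phantom output bundle: rendered data plus exact ground truth."""

    config: PhantomConfig
    image: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    geometry: Optional[DefectGeometry] = None
    rois: Optional[DefectROIs] = None
    true_report: Optional[_metrics.HistoReport] = None
    volume: Optional[CTVolume] = None
    slab: Optional[tuple[int, int]] = None
    true_bridged: Optional[bool] = None

    @property
    def substitute_mask(self) -> np.ndarray:
        """The manual-classification stand-in: ground-truth substitute pixels."""
        return self.labels == Tissue.SUBSTITUTE


# ---------------------------------------------------------------------------
# section phantom
# ---------------------------------------------------------------------------


def generate_section(config: PhantomConfig) -> PhantomTruth:
    """Render one synthetic histology section with exact labels.

    Layout (top to bottom): periosteal soft tissue, cortical plate (old bone
    flanking the drill hole, new-bone fill inside it, canals through it),
    marrow space with trabecular new bone inside the medullary ROI band, and
    substitute agglomerates in the configured region.
    """
    rng = np.random.default_rng(config.seed)
    width = config.mm_to_px(config.section_width_mm)
    height = config.mm_to_px(config.section_height_mm)
    peri = config.mm_to_px(config.periosteal_depth_mm)
    endo = peri + config.mm_to_px(config.cortical_thickness_mm)
    if endo >= height:
        raise InfeasibleConfigError("cortical plate does not fit the section height")
    defect_px = config.mm_to_px(config.defect_diameter_mm)
    drill_left = (width - defect_px) // 2
    drill_right = drill_left + defect_px

    geometry = DefectGeometry(
        drill_left=drill_left,
        drill_right=drill_right,
        periosteal_margin=np.full(width, peri),
        endosteal_margin=np.full(width, endo),
        pixel_pitch_um=config.pixel_pitch_um,
    )
    rois = build_rois(geometry, (height, width))

    labels = np.full((height, width), np.uint8(Tissue.SOFT))
    labels[peri:endo, :drill_left] = Tissue.OLD_BONE
    labels[peri:endo, drill_right:] = Tissue.OLD_BONE

    # new-bone fill grows from the endosteal side of the defect
    thickness = endo - peri
    fill_rows = int(round(config.new_bone_fill_fraction * thickness))
    if fill_rows > 0:
        labels[endo - fill_rows : endo, drill_left:drill_right] = Tissue.NEW_BONE

    canal_mask = _carve_canals(labels, config, geometry)
    _place_agglomerates(labels, rois, config, rng, forbidden=canal_mask)
    _place_trabecular_bone(labels, rois, config, rng)

    image = _render(labels, config, rng)
    true_report = _metrics.compute_report(
        SegmentationMap(labels=labels, pixel_pitch_um=config.pixel_pitch_um),
        rois,
    )
    return PhantomTruth(
        config=config,
        image=image,
        labels=labels,
        geometry=geometry,
        rois=rois,
        true_report=true_report,
    )


def _carve_canals(
    labels: np.ndarray, config: PhantomConfig, geom: DefectGeometry
) -> np.ndarray:
    """Soft-tissue canals from the periosteal margin through the cortex."""
    canal = np.zeros_like(labels, dtype=bool)
    widths = list(config.canal_spec)
    if not widths:
        return canal
    peri = int(geom.periosteal_margin[0])
    endo = int(geom.endosteal_margin[0])
    breadth = geom.drill_breadth_px
    centers = [
        geom.drill_left + int(round((i + 1) / (len(widths) + 1) * breadth))
        for i in range(len(widths))
    ]
    for center, w_mm in zip(centers, widths):
        w_px = max(1, config.mm_to_px(w_mm))
        if w_mm >= config.defect_diameter_mm:
            raise InfeasibleConfigError(
                f"canal of {w_mm} mm is as wide as the {config.defect_diameter_mm} mm defect"
            )
        c0 = max(geom.drill_left, center - w_px // 2)
        c1 = min(geom.drill_right, c0 + w_px)
        labels[peri:endo, c0:c1] = Tissue.SOFT
        canal[peri:endo, c0:c1] = True
    return canal


def _place_trabecular_bone(
    labels: np.ndarray, rois: DefectROIs, config: PhantomConfig, rng: np.random.Generator
) -> None:
    """Trabecular new bone in the medullary ROI (regenerated cancellous bone
    inside the drill breadth), covering ~ the target area fraction.

    Elements are osteon-scale axis-aligned square blocks snapped to a
    power-of-two pixel grid. Rectilinear, grid-aligned shapes keep every
    phantom boundary resolvable by the quadtree homogeneity criterion at any
    noise level, which is what makes noiseless recovery exact."""
    target = config.trabecular_fill_fraction
    if target <= 0:
        return
    mask = rois.medullary_mask
    rr, cc = np.nonzero(mask)
    r0, r1, c0, c1 = rr.min(), rr.max() + 1, cc.min(), cc.max() + 1
    side_px = max(2, config.mm_to_px(2 * config.trabecular_radius_mm))
    side = 2 ** int(round(np.log2(side_px)))
    row_slots = np.arange(-(-r0 // side) * side, r1 - side + 1, side)
    col_slots = np.arange(-(-c0 // side) * side, c1 - side + 1, side)
    if row_slots.size == 0 or col_slots.size == 0:
        return
    # keep 1 px clear of substitute so agglomerates stay 8-disconnected
    near_sub = ndimage.binary_dilation(
        labels == Tissue.SUBSTITUTE, np.ones((3, 3), bool)
    )
    slots = [
        (r, c)
        for r in row_slots
        for c in col_slots
        if not near_sub[r : r + side, c : c + side].any()
    ]
    rng.shuffle(slots)
    n_blocks = int(round(target * mask.sum() / (side * side)))
    for r, c in slots[:n_blocks]:
        labels[r : r + side, c : c + side] = Tissue.NEW_BONE


def _lognormal_areas(
    spec: tuple[float, float], n: int, rng: np.random.Generator
) -> np.ndarray:
    median, sigma = spec
    if median <= 0:
        raise ValueError("agglomerate area median must be positive")
    if sigma == 0:
        return np.full(n, median)
    return median * np.exp(sigma * rng.standard_normal(n))


def _ellipse_pixels(
    center: tuple[int, int],
    area_px: int,
    max_half_height: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of an ellipse of exactly ``area_px`` pixels.

    The semi-minor axis (rows) is capped at ``max_half_height`` so large
    agglomerates elongate to fit a band-shaped region; the pixel set is the
    ``area_px`` pixels of smallest normalised elliptical radius, so the
    realised area is exact by construction.
    """
    b = min(np.sqrt(area_px / np.pi), float(max_half_height))
    b = max(b, 1.0)
    a = max(area_px / (np.pi * b), 1.0)
    hr = int(np.ceil(b)) + 1
    hc = int(np.ceil(a)) + 1
    dr = np.arange(-hr, hr + 1)
    dc = np.arange(-hc, hc + 1)
    rho = (dr[:, None] / b) ** 2 + (dc[None, :] / a) ** 2
    order = np.argsort(rho, axis=None, kind="stable")[:area_px]
    rr, cc = np.unravel_index(order, rho.shape)
    return rr - hr + center[0], cc - hc + center[1]


def _place_agglomerates(
    labels: np.ndarray,
    rois: DefectROIs,
    config: PhantomConfig,
    rng: np.random.Generator,
    forbidden: Optional[np.ndarray] = None,
) -> None:
    """Place non-touching substitute agglomerates of exact pixel areas."""
    n = config.agglomerate_count
    if n == 0:
        return
    region = rois.mask(config.agglomerate_region)
    # agglomerates embed in soft tissue, 1 px clear of bone, so the rendered
    # bone boundaries stay exactly the rasterised ground-truth shapes
    allowed = (
        region
        & ~ndimage.binary_dilation(
            labels != Tissue.SOFT, np.ones((3, 3), bool)
        )
    )
    if forbidden is not None:
        allowed &= ~forbidden
    if not allowed.any():
        raise InfeasibleConfigError("no soft-tissue space for agglomerates")
    rr, cc = np.nonzero(allowed)
    r0, r1, c0, c1 = rr.min(), rr.max() + 1, cc.min(), cc.max() + 1
    px2mm2 = (config.pixel_pitch_um / 1000.0) ** 2
    areas_mm2 = _lognormal_areas(config.agglomerate_area_mm2, n, rng)
    areas_px = np.maximum(1, np.round(areas_mm2 / px2mm2).astype(int))
    if areas_px.sum() > 0.8 * allowed.sum():
        raise InfeasibleConfigError(
            "requested total agglomerate area exceeds the available region"
        )
    blocked = np.zeros_like(region)
    half_h = max(1, (r1 - r0) // 2 - 1)
    for area_px in np.sort(areas_px)[::-1]:  # large first: easier packing
        b = min(np.sqrt(area_px / np.pi), float(half_h))
        a = max(area_px / (np.pi * max(b, 1.0)), 1.0)
        hr, hc = int(np.ceil(b)) + 1, int(np.ceil(a)) + 1
        placed = False
        for _ in range(500):
            cr = int(rng.integers(r0 + hr, max(r0 + hr + 1, r1 - hr)))
            ccen = int(rng.integers(c0 + hc, max(c0 + hc + 1, c1 - hc)))
            prr, pcc = _ellipse_pixels((cr, ccen), int(area_px), half_h)
            if (
                prr.min() < 0
                or pcc.min() < 0
                or prr.max() >= labels.shape[0]
                or pcc.max() >= labels.shape[1]
            ):
                continue
            if not allowed[prr, pcc].all():
                continue
            # keep a 1-px moat so agglomerates stay 8-disconnected
            window = blocked[
                max(prr.min() - 1, 0) : prr.max() + 2,
                max(pcc.min() - 1, 0) : pcc.max() + 2,
            ]
            cand = np.zeros_like(window)
            cand[prr - max(prr.min() - 1, 0), pcc - max(pcc.min() - 1, 0)] = True
            if (ndimage.binary_dilation(cand, np.ones((3, 3), bool)) & window).any():
                continue
            labels[prr, pcc] = Tissue.SUBSTITUTE
            blocked[prr, pcc] = True
            placed = True
            break
        if not placed:
            raise InfeasibleConfigError(
                "could not place all agglomerates without overlap; "
                "reduce count or area"
            )


def _render(
    labels: np.ndarray, config: PhantomConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-class mean colours with Gaussian per-channel noise."""
    from .tissue import CLASS_NAMES

    means = np.zeros((4, 3))
    for code, name in enumerate(CLASS_NAMES):
        means[code] = config.class_colors[name]
    img = means[labels]
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# volume phantom
# ---------------------------------------------------------------------------


def generate_volume(config: PhantomConfig) -> PhantomTruth:
    """Render one synthetic micro-CT defect volume with known bridging state.

    Axis 0 points periosteal -> medullary. A cortical plate slab spans the
    full transverse extent; canals from ``canal_spec`` breach it (straight
    cylinders, or tortuous random-walk channels when
    ``volume_canal_tortuous``); ``pocket_spec`` adds blind pockets that
    indent but do not breach the plate. ``true_bridged`` is exactly
    "no canal requested".
    """
    rng = np.random.default_rng(config.seed)
    nz, ny, nx = config.volume_shape
    pitch = config.voxel_pitch_um
    thick_vox = max(3, int(round(config.cortical_thickness_mm * 1000.0 / pitch)))
    z0 = max(2, nz // 4)
    z1 = min(nz - 2, z0 + thick_vox)
    if z1 - z0 < 3:
        raise InfeasibleConfigError("volume too shallow for a cortical slab")

    bone = np.zeros((nz, ny, nx), dtype=bool)
    bone[z0:z1] = True

    def carve_cylinder(cy, cx, radius, zlo, zhi, wander=False):
        yy, xx = np.ogrid[:ny, :nx]
        y, x = cy, cx
        for z in range(zlo, zhi):
            bone[z][(yy - y) ** 2 + (xx - x) ** 2 <= radius * radius] = False
            if wander:
                y = int(np.clip(y + rng.integers(-1, 2), radius + 1, ny - radius - 2))
                x = int(np.clip(x + rng.integers(-1, 2), radius + 1, nx - radius - 2))

    for w_mm in config.canal_spec:
        w_vox = max(1, int(round(w_mm * 1000.0 / pitch)))
        if w_vox >= min(ny, nx) - 4:
            raise InfeasibleConfigError(
                f"canal of {w_mm} mm does not fit the transverse extent"
            )
        radius = max(0.5, w_vox / 2.0)
        margin = int(np.ceil(radius)) + 2
        cy = int(rng.integers(margin, ny - margin))
        cx = int(rng.integers(margin, nx - margin))
        carve_cylinder(cy, cx, radius, z0, z1, wander=config.volume_canal_tortuous)

    for w_mm, depth_frac in config.pocket_spec:
        if not 0.0 < depth_frac < 1.0:
            raise ValueError("pocket depth fraction must lie in (0, 1)")
        w_vox = max(1, int(round(w_mm * 1000.0 / pitch)))
        radius = max(0.5, w_vox / 2.0)
        margin = int(np.ceil(radius)) + 2
        cy = int(rng.integers(margin, ny - margin))
        cx = int(rng.integers(margin, nx - margin))
        depth = max(1, int(round(depth_frac * (z1 - z0))))
        carve_cylinder(cy, cx, radius, z0, min(z0 + depth, z1 - 1))

    intensity = np.where(bone, 30000.0, 10000.0)
    if config.volume_noise_sd > 0:
        intensity = intensity + rng.normal(
            0.0, config.volume_noise_sd, size=intensity.shape
        )
    data = np.clip(np.round(intensity), 0, 65535).astype(np.uint16)
    return PhantomTruth(
        config=config,
        volume=CTVolume(data=data, voxel_pitch_um=pitch, axis=0),
        slab=(z0, z1),
        true_bridged=len(list(config.canal_spec)) == 0,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: Per-treatment phantom regimes emulating the study's material behaviour:
#: fill fraction of the cortical defect by new bone, and agglomerate
#: count/size in the medullary region (log-normal median mm^2, sigma).
DEFAULT_GROUP_REGIMES: dict[str, dict] = {
    "empty": {"new_bone_fill_fraction": 0.35, "agglomerate_count": 0, "canal_spec": [0.5]},
    "autologous": {"new_bone_fill_fraction": 0.40, "agglomerate_count": 0, "canal_spec": [0.5]},
    "Ostim": {
        "new_bone_fill_fraction": 0.50,
        "agglomerate_count": 40,
        "agglomerate_area_mm2": (0.008, 0.25),
        "canal_spec": [0.4],
    },
    "nHA-LC": {
        "new_bone_fill_fraction": 0.70,
        "agglomerate_count": 25,
        "agglomerate_area_mm2": (0.051, 0.25),
        "canal_spec": [],
    },
    "nHA-HC": {
        "new_bone_fill_fraction": 0.30,
        "agglomerate_count": 2,
        "agglomerate_area_mm2": (0.9, 0.25),
        "canal_spec": [],
    },
}


def generate_cohort(
    n_animals: int,
    groups: Sequence[str],
    seed: int,
    base_config: Optional[PhantomConfig] = None,
    group_effects: Optional[dict[str, float]] = None,
    group_configs: Optional[dict[str, dict]] = None,
    animal_sd: float = 0.0,
    defect_sd: float = 0.0,
    timepoints: Sequence[int] = (6, 12),
) -> tuple[pd.DataFrame, list[PhantomTruth]]:
    """Generate one section phantom per animal x treatment group.

    Each animal carries every group (the within-animal randomised-defect
    design) and one timepoint (animals alternate over ``timepoints``). Group
    identity acts on the new-bone fill fraction: ``group_effects`` gives the
    per-group offset in nBV/TV percentage points; an animal-level random
    intercept with sd ``animal_sd`` (percentage points) is shared by all
    defects of one animal, which is what the mixed model's random factor
    estimates, and ``defect_sd`` adds independent per-defect residual
    variation on the same scale. ``group_configs`` may override any other PhantomConfig field
    per group (e.g. the agglomerate regime); defaults come from
    ``DEFAULT_GROUP_REGIMES`` when the group name is known, else the base
    config.

    Returns the manifest (one row per defect: animal_id, treatment,
    timepoint, seed) and the list of PhantomTruth in manifest order.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    if not groups:
        raise ValueError("groups must be non-empty")
    base = base_config or PhantomConfig()
    effects = group_effects or {}
    overrides = group_configs or {}
    rng = np.random.default_rng(seed)
    rows = []
    truths = []
    for i in range(n_animals):
        animal_id = f"sheep{i + 1:02d}"
        timepoint = timepoints[i % len(timepoints)]
        animal_shift = rng.normal(0.0, animal_sd) / 100.0 if animal_sd > 0 else 0.0
        for group in groups:
            cfg_kwargs = dict(overrides.get(group, DEFAULT_GROUP_REGIMES.get(group, {})))
            fill = cfg_kwargs.pop(
                "new_bone_fill_fraction", base.new_bone_fill_fraction
            )
            defect_shift = (
                rng.normal(0.0, defect_sd) / 100.0 if defect_sd > 0 else 0.0
            )
            fill = float(
                np.clip(
                    fill + effects.get(group, 0.0) / 100.0 + animal_shift + defect_shift,
                    0.0,
                    1.0,
                )
            )
            phantom_seed = int(rng.integers(2**31))
            cfg = replace(
                base,
                seed=phantom_seed,
                new_bone_fill_fraction=fill,
                **cfg_kwargs,
            )
            truths.append(generate_section(cfg))
            rows.append(
                {
                    "animal_id": animal_id,
                    "treatment": group,
                    "timepoint": timepoint,
                    "seed": phantom_seed,
                }
            )
    return pd.DataFrame(rows), truths
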