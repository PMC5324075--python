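"""Regions of interest for drill-hole defect histomorphometry.

The cortical ROI is the area between the drill-hole boundaries and the
periosteal (outer) / endosteal (inner) cortical margins. The medullary ROI is
a band of 1 mm height located 1 mm beneath the endosteal margin, oriented
parallel to it and spanning the whole breadth of the drill hole.

Coordinates are 0-based with half-open pixel rectangles. Margins are supplied
per column (polylines), typically from phantom ground truth or a manual
annotation file; millimetre-to-pixel conversion uses floor so a nominal 1 mm
band never exceeds 1 mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


class ROIError(ValueError):
    """Raised when a requested ROI is empty or falls outside the image."""


@dataclass
class DefectGeometry:
    """Drill-hole and cortical-margin geometry for one section.

    Parameters
    ----------
    drill_left, drill_right
        Column range of the drill hole, half-open ``[drill_left, drill_right)``.
    periosteal_margin, endosteal_margin
        Per-column row coordinate of the outer / inner cortical boundary.
        Scalars are broadcast to every column.
    pixel_pitch_um
        Physical pixel size in micrometres.
    """

    drill_left: int
    drill_right: int
    periosteal_margin: np.ndarray
    endosteal_margin: np.ndarray
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        self.periosteal_margin = np.atleast_1d(
            np.asarray(self.periosteal_margin, dtype=np.int64)
        )
        self.endosteal_margin = np.atleast_1d(
            np.asarray(self.endosteal_margin, dtype=np.int64)
        )
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.drill_right - self.drill_left <= 0:
            raise ValueError("drill_right must exceed drill_left")
        if self.periosteal_margin.shape != self.endosteal_margin.shape:
            raise ValueError("margins must have equal length")
        if np.any(self.periosteal_margin >= self.endosteal_margin):
            raise ValueError("periosteal margin must lie above the endosteal margin")

    @property
    def drill_breadth_px(self) -> int:
        return self.drill_right - self.drill_left

    @property
    def drill_breadth_mm(self) -> float:
        return self.drill_breadth_px * self.pixel_pitch_um / 1000.0

    def mm_to_px(self, mm: float) -> int:
        """Convert a length in mm to whole pixels (floor)."""
        return int(np.floor(mm * 1000.0 / self.pixel_pitch_um))

    def margins_for_width(self, width: int) -> tuple[np.ndarray, np.ndarray]:
        """Broadcast the margins to an image width."""
        peri, endo = self.periosteal_margin, self.endosteal_margin
        if peri.size == 1:
            peri = np.full(width, int(peri[0]), dtype=np.int64)
            endo = np.full(width, int(self.endosteal_margin[0]), dtype=np.int64)
        elif peri.size != width:
            raise ValueError(f"margins of length {peri.size} do not match width {width}")
        return peri, endo

    def to_json(self) -> str:
        return json.dumps(
            {
                "drill_left": int(self.drill_left),
                "drill_right": int(self.drill_right),
                "periosteal_margin": self.periosteal_margin.tolist(),
                "endosteal_margin": self.endosteal_margin.tolist(),
                "pixel_pitch_um": float(self.pixel_pitch_um),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DefectGeometry":
        d = json.loads(text)
        return cls(
            drill_left=d["drill_left"],
            drill_right=d["drill_right"],
            periosteal_margin=np.asarray(d["periosteal_margin"]),
            endosteal_margin=np.asarray(d["endosteal_margin"]),
            pixel_pitch_um=d["pixel_pitch_um"],
        )


@dataclass
class DefectROIs:
    """Cortical and medullary ROI masks plus the geometry they came from."""

    cortical_mask: np.ndarray
    medullary_mask: np.ndarray
    geometry: DefectGeometry = field(repr=False)

    def __post_init__(self) -> None:
        if self.cortical_mask.shape != self.medullary_mask.shape:
            raise ValueError("ROI masks must share a frame")
        if np.any(self.cortical_mask & self.medullary_mask):
            raise ValueError("cortical and medullary ROIs must be disjoint")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cortical_mask.shape

    def mask(self, roi: str) -> np.ndarray:
        if roi == "cortical":
            return self.cortical_mask
        if roi == "medullary":
            return self.medullary_mask
        raise KeyError(roi)


def build_cortical_roi(geom: DefectGeometry, shape: tuple[int, int]) -> np.ndarray:
    """Mask of the cortical ROI: drill columns between the two margins."""
    height, width = shape
    peri, endo = geom.margins_for_width(width)
    cols = np.arange(width)
    in_cols = (cols >= geom.drill_left) & (cols < geom.drill_right)
    rows = np.arange(height)[:, None]
    mask = in_cols[None, :] & (rows >= peri[None, :]) & (rows < endo[None, :])
    if not mask.any():
        raise ROIError("cortical ROI is empty for this geometry/frame")
    return mask


def build_medullary_roi(
    geom: DefectGeometry,
    shape: tuple[int, int],
    offset_mm: float = 1.0,
    height_mm: float = 1.0,
) -> np.ndarray:
    """Mask of the medullary ROI band.

    The band starts ``offset_mm`` below the endosteal margin, follows its
    contour (oriented parallel), has ``height_mm`` thickness and the drill
    hole's column span.
    """
    height, width = shape
    _, endo = geom.margins_for_width(width)
    off = geom.mm_to_px(offset_mm)
    h = geom.mm_to_px(height_mm)
    top = endo + off
    bottom = top + h
    if np.any(bottom[geom.drill_left : geom.drill_right] > height):
        raise ROIError("medullary band exceeds the image bounds")
    cols = np.arange(width)
    in_cols = (cols >= geom.drill_left) & (cols < geom.drill_right)
    rows = np.arange(height)[:, None]
    mask = in_cols[None, :] & (rows >= top[None, :]) & (rows < bottom[None, :])
    if not mask.any():
        raise ROIError("medullary ROI is empty for this geometry/frame")
    return mask


def build_rois(geom: DefectGeometry, shape: tuple[int, int]) -> DefectROIs:
    """Construct both ROIs for one section frame."""
    return DefectROIs(
        cortical_mask=build_cortical_roi(geom, shape),
        medullary_mask=build_medullary_roi(geom, shape),
        geometry=geom,
    )


def periosteal_zone(geom: DefectGeometry, shape: tuple[int, int]) -> np.ndarray:
    """Mask of everything above the periosteal margin (the periosteal side)."""
    height, width = shape
    peri, _ = geom.margins_for_width(width)
    rows = np.arange(height)[:, None]
    return rows < peri[None, :]
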