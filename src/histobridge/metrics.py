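"""ROI-restricted histomorphometry of a segmented defect section.

Computes, per region of interest, the classic parameters of bone-substitute
histomorphometry: tissue area TV, newly formed bone nBV, substitute material
BS.V, soft-tissue/void Vd.V, the composite Co.V = nBV + BS.V, the periosteal
void Ps.Vd.V (soft tissue that penetrated from the periosteal side), the
TV-relative percentages of each, and particle-agglomerate statistics
(count BS.Pa.N, count density BS.Pa.N/TV, mean area BS.Pa.Ar).

The field's symbols are volumetric (BS.V, nBV) although a section measures
areas; values here are mm^2 and the symbol names are kept. All quantities
derive from integer pixel counts converted by the squared pixel pitch.
Agglomerates are 8-connected components of the substitute class; a component
straddling an ROI boundary contributes only its in-ROI area and is counted
once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .roi import DefectROIs, periosteal_zone
from .segment import SegmentationMap
from .tissue import Tissue

_S8 = np.ones((3, 3), dtype=bool)

ROI_NAMES = ("cortical", "medullary")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero upward (reproduces printed integers)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class Agglomerate:
    """One substitute particle agglomerate clipped to an ROI."""

    id: int
    area_mm2: float
    area_px: int
    centroid: tuple[float, float]


@dataclass
class ROIMetrics:
    """Histomorphometric parameters for one ROI of one section."""

    roi: str
    pixel_pitch_um: float
    # raw pixel counts
    tv_px: int
    nbv_px: int
    bsv_px: int
    vdv_px: int
    ov_px: int
    psvdv_px: int
    agglomerates: list[Agglomerate] = field(default_factory=list)

    @property
    def _px2mm2(self) -> float:
        return (self.pixel_pitch_um / 1000.0) ** 2

    @property
    def tv_mm2(self) -> float:
        return self.tv_px * self._px2mm2

    @property
    def nbv_mm2(self) -> float:
        return self.nbv_px * self._px2mm2

    @property
    def bsv_mm2(self) -> float:
        return self.bsv_px * self._px2mm2

    @property
    def vdv_mm2(self) -> float:
        return self.vdv_px * self._px2mm2

    @property
    def old_bone_mm2(self) -> float:
        return self.ov_px * self._px2mm2

    @property
    def cov_mm2(self) -> float:
        return self.nbv_mm2 + self.bsv_mm2

    @property
    def psvdv_mm2(self) -> float:
        return self.psvdv_px * self._px2mm2

    def _pct(self, px: int) -> float:
        return 100.0 * px / self.tv_px

    @property
    def nbv_tv_pct(self) -> float:
        return self._pct(self.nbv_px)

    @property
    def bsv_tv_pct(self) -> float:
        return self._pct(self.bsv_px)

    @property
    def cov_tv_pct(self) -> float:
        return self._pct(self.nbv_px + self.bsv_px)

    @property
    def vdv_tv_pct(self) -> float:
        return self._pct(self.vdv_px)

    @property
    def psvdv_tv_pct(self) -> float:
        return self._pct(self.psvdv_px)

    @property
    def bs_pa_n(self) -> int:
        return len(self.agglomerates)

    @property
    def bs_pa_n_per_mm2(self) -> float:
        return self.bs_pa_n / self.tv_mm2

    @property
    def bs_pa_ar_mm2(self) -> Optional[float]:
        """Mean agglomerate area; missing (None), not 0, when there are none."""
        if not self.agglomerates:
            return None
        return float(np.mean([a.area_mm2 for a in self.agglomerates]))

    def to_dict(self) -> dict:
        return {
            "roi": self.roi,
            "TV_mm2": self.tv_mm2,
            "nBV_mm2": self.nbv_mm2,
            "BSV_mm2": self.bsv_mm2,
            "VdV_mm2": self.vdv_mm2,
            "old_bone_mm2": self.old_bone_mm2,
            "CoV_mm2": self.cov_mm2,
            "PsVdV_mm2": self.psvdv_mm2,
            "nBV_TV_pct": self.nbv_tv_pct,
            "BSV_TV_pct": self.bsv_tv_pct,
            "CoV_TV_pct": self.cov_tv_pct,
            "PsVdV_TV_pct": self.psvdv_tv_pct,
            "BS_Pa_N": self.bs_pa_n,
            "BS_Pa_N_per_mm2": self.bs_pa_n_per_mm2,
            "BS_Pa_Ar_mm2": self.bs_pa_ar_mm2,
        }


@dataclass
class HistoReport:
    """Per-section histomorphometry: one ROIMetrics per ROI."""

    rois: dict[str, ROIMetrics]

    def __getitem__(self, roi: str) -> ROIMetrics:
        return self.rois[roi]

    def to_dict(self) -> dict:
        return {name: m.to_dict() for name, m in self.rois.items()}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_rows(self, **meta) -> list[dict]:
        """Flatten to one row per ROI, with optional manifest metadata."""
        rows = []
        for name, m in self.rois.items():
            row = dict(meta)
            row.update(m.to_dict())
            rows.append(row)
        return rows


def _labels_of(segmap) -> tuple[np.ndarray, float]:
    if isinstance(segmap, SegmentationMap):
        return segmap.labels, segmap.pixel_pitch_um
    raise TypeError("expected a SegmentationMap")


def compute_areas(
    segmap: SegmentationMap, rois: DefectROIs, roi: str
) -> dict[str, int]:
    """Per-class pixel counts within one ROI."""
    labels, _ = _labels_of(segmap)
    mask = rois.mask(roi)
    if not mask.any():
        raise ValueError(f"{roi} ROI is empty")
    vals = labels[mask]
    counts = np.bincount(vals, minlength=4)
    return {
        "tv_px": int(vals.size),
        "nbv_px": int(counts[Tissue.NEW_BONE]),
        "bsv_px": int(counts[Tissue.SUBSTITUTE]),
        "vdv_px": int(counts[Tissue.SOFT]),
        "ov_px": int(counts[Tissue.OLD_BONE]),
    }


def agglomerate_stats(
    segmap: SegmentationMap, rois: DefectROIs, roi: str
) -> list[Agglomerate]:
    """Substitute agglomerates intersecting one ROI.

    Components are labelled 8-connected on the full substitute mask; each
    component intersecting the ROI is counted once with its in-ROI (clipped)
    area.
    """
    labels, pitch = _labels_of(segmap)
    mask = rois.mask(roi)
    sub = labels == Tissue.SUBSTITUTE
    lab, n = ndimage.label(sub, structure=_S8)
    out: list[Agglomerate] = []
    if n == 0:
        return out
    in_roi = np.where(mask, lab, 0)
    counts = np.bincount(in_roi.ravel(), minlength=n + 1)
    px2mm2 = (pitch / 1000.0) ** 2
    for comp in np.flatnonzero(counts[1:] > 0) + 1:
        sel = in_roi == comp
        rr, cc = np.nonzero(sel)
        out.append(
            Agglomerate(
                id=int(comp),
                area_px=int(counts[comp]),
                area_mm2=float(counts[comp] * px2mm2),
                centroid=(float(rr.mean()), float(cc.mean())),
            )
        )
    return out


def periosteal_void(
    segmap: SegmentationMap, rois: DefectROIs, roi: str
) -> int:
    """Pixels of soft tissue in the ROI that penetrated from the periosteal side.

    A soft-tissue pixel counts iff its 8-connected soft-tissue component also
    contains pixels on the periosteal side of the cortical plate (above the
    periosteal margin). Enclosed marrow spaces and soft tissue touching only
    the endosteal side are excluded.
    """
    labels, _ = _labels_of(segmap)
    mask = rois.mask(roi)
    soft = labels == Tissue.SOFT
    lab, n = ndimage.label(soft, structure=_S8)
    if n == 0:
        return 0
    zone = periosteal_zone(rois.geometry, labels.shape)
    peri_comps = np.unique(lab[zone & soft])
    peri_comps = peri_comps[peri_comps > 0]
    if peri_comps.size == 0:
        return 0
    connected = np.isin(lab, peri_comps)
    return int(np.count_nonzero(connected & mask))


def compute_report(segmap: SegmentationMap, rois: DefectROIs) -> HistoReport:
    """Full histomorphometric report for one section (both ROIs)."""
    _, pitch = _labels_of(segmap)
    out: dict[str, ROIMetrics] = {}
    for roi in ROI_NAMES:
        areas = compute_areas(segmap, rois, roi)
        aggl = agglomerate_stats(segmap, rois, roi)
        psv = periosteal_void(segmap, rois, roi)
        out[roi] = ROIMetrics(
            roi=roi,
            pixel_pitch_um=pitch,
            psvdv_px=psv,
            agglomerates=aggl,
            **areas,
        )
    return HistoReport(rois=out)


def reports_to_table(
    reports: list[HistoReport], manifest: pd.DataFrame
) -> pd.DataFrame:
    """Tidy cohort table: one row per defect x ROI x parameter.

    ``manifest`` must have one row per report with at least ``animal_id``,
    ``treatment`` and ``timepoint`` columns.
    """
    if len(reports) != len(manifest):
        raise ValueError("one manifest row per report required")
    params = [
        "nBV_TV_pct",
        "BSV_TV_pct",
        "CoV_TV_pct",
        "PsVdV_TV_pct",
        "BS_Pa_N_per_mm2",
        "BS_Pa_Ar_mm2",
    ]
    rows = []
    for (_, meta), report in zip(manifest.iterrows(), reports):
        for roi, m in report.rois.items():
            d = m.to_dict()
            for p in params:
                rows.append(
                    {
                        **{k: meta[k] for k in ("animal_id", "treatment", "timepoint")},
                        "roi": roi,
                        "parameter": p,
                        "value": d[p],
                    }
                )
    return pd.DataFrame(rows)
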