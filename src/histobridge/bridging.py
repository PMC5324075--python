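"""Micro-CT defect-bridging classification and group-level bridging rates.

A drill-hole defect is "bridging" when the continuity of the cortical bone
plate has been completely restored and no opening remains; "non-bridging"
when a continuous opening in the cortical bone connects the medullary cavity
with the periosteal area. The classifier formalises that definition as a 3D
flood fill: seed the non-bone (sub-threshold) phase at the periosteal face of
the cortical slab and test whether it reaches the medullary face. When it
does, a witness voxel path through the opening is returned.

Group-level rates use round-half-up integer percentages; cross-timepoint
averages are taken on the unrounded timepoint percentages and then rounded,
which is the convention that reproduces printed study summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .metrics import round_half_up

__all__ = [
    "CTVolume",
    "BridgingResult",
    "classify_bridging",
    "bridging_rate",
    "records_from_counts",
    "STUDY_BRIDGING_COUNTS",
]


@dataclass
class CTVolume:
    """A 3D intensity volume with isotropic voxel pitch.

    ``axis`` is the array axis pointing from the periosteal side toward the
    medullary cavity (slice 0 = periosteal).
    """

    data: np.ndarray
    voxel_pitch_um: float
    axis: int = 0

    def __post_init__(self) -> None:
        if self.voxel_pitch_um <= 0:
            raise ValueError("voxel_pitch_um must be positive")
        if self.data.ndim != 3:
            raise ValueError("expected a 3D volume")
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be 0, 1 or 2")


@dataclass
class BridgingResult:
    """Binary bridging decision with an optional witness opening."""

    bridged: bool
    witness_path: Optional[list[tuple[int, int, int]]]
    bone_threshold_used: float

    def __post_init__(self) -> None:
        if self.bridged and self.witness_path is not None:
            raise ValueError("a bridged defect cannot have a witness path")
        if not self.bridged and self.witness_path is None:
            raise ValueError("a non-bridged defect must carry a witness path")


_CONN_ORDER = {6: 1, 18: 2, 26: 3}


def _structure(connectivity: int) -> np.ndarray:
    try:
        return ndimage.generate_binary_structure(3, _CONN_ORDER[connectivity])
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None


def classify_bridging(
    vol: CTVolume,
    bone_threshold: Optional[float] = None,
    connectivity: int = 26,
    slab: Optional[tuple[int, int]] = None,
) -> BridgingResult:
    """Classify one defect volume as bridging vs non-bridging.

    Parameters
    ----------
    vol
        The micro-CT volume.
    bone_threshold
        Intensity at or above which a voxel is bone. Default: Otsu on the
        slab histogram.
    connectivity
        Voxel connectivity of the void phase (6, 18 or 26; default the
        strictest test of "no opening remained").
    slab
        Half-open slice bounds of the cortical plate along ``vol.axis``.
        Default: the whole extent.
    """
    data = np.moveaxis(vol.data, vol.axis, 0)
    z0, z1 = slab if slab is not None else (0, data.shape[0])
    if not (0 <= z0 < z1 <= data.shape[0]):
        raise ValueError("slab bounds outside the volume")
    sub = data[z0:z1]
    if bone_threshold is None:
        # threshold on the whole volume: the slab alone may be single-phase
        bone_threshold = float(threshold_otsu(data.ravel()))
    lo, hi = float(data.min()), float(data.max())
    if not (lo <= bone_threshold <= hi):
        raise ValueError(
            f"bone threshold {bone_threshold} outside intensity range [{lo}, {hi}]"
        )
    void = sub < bone_threshold
    structure = _structure(connectivity)
    lab, n = ndimage.label(void, structure=structure)
    top = np.unique(lab[0])
    bottom = np.unique(lab[-1])
    through = np.intersect1d(top, bottom)
    through = through[through > 0]
    if through.size == 0:
        return BridgingResult(True, None, bone_threshold)
    path = _witness_path(void & np.isin(lab, through), structure)
    # back to global coordinates along the original axis order
    out = []
    for z, y, x in path:
        coord = [z + z0, y, x]
        coord.insert(vol.axis, coord.pop(0))
        out.append(tuple(int(v) for v in coord))
    return BridgingResult(False, out, bone_threshold)


def _witness_path(void: np.ndarray, structure: np.ndarray) -> list[tuple[int, int, int]]:
    """Shortest voxel path from the top to the bottom face through ``void``.

    Breadth-first wavefront implemented as masked dilations (distance map),
    then a greedy strictly-descending backtrack from a reached bottom voxel.
    """
    dist = np.full(void.shape, -1, dtype=np.int32)
    front = np.zeros_like(void)
    front[0] = void[0]
    dist[front] = 0
    reached = front.copy()
    d = 0
    while not reached[-1].any():
        nxt = ndimage.binary_dilation(reached, structure=structure) & void & ~reached
        if not nxt.any():
            raise RuntimeError("void faces are not connected")  # pragma: no cover
        d += 1
        dist[nxt] = d
        reached |= nxt
    # backtrack from the bottom voxel with the smallest distance
    yy, xx = np.nonzero(reached[-1])
    i = int(np.argmin(dist[-1, yy, xx]))
    cur = (void.shape[0] - 1, int(yy[i]), int(xx[i]))
    path = [cur]
    offsets = np.argwhere(structure) - 1
    while dist[cur] > 0:
        z, y, x = cur
        for dz, dy, dx in offsets:
            nz_, ny_, nx_ = z + dz, y + dy, x + dx
            if (
                0 <= nz_ < void.shape[0]
                and 0 <= ny_ < void.shape[1]
                and 0 <= nx_ < void.shape[2]
                and dist[nz_, ny_, nx_] == dist[cur] - 1
            ):
                cur = (int(nz_), int(ny_), int(nx_))
                path.append(cur)
                break
        else:  # pragma: no cover
            raise RuntimeError("backtrack failed")
    path.reverse()
    return path


# ---------------------------------------------------------------------------
# group-level rates
# ---------------------------------------------------------------------------

#: Observed bridging counts of the source study, (n_bridged, n_total) per
#: treatment and timepoint (months). These printed counts are inputs to
#: `bridging_rate`; the percentages are recomputed, not stored.
STUDY_BRIDGING_COUNTS: dict[str, dict[int, tuple[int, int]]] = {
    "empty": {6: (3, 11), 12: (4, 12)},
    "autologous": {6: (2, 12), 12: (3, 12)},
    "Ostim": {6: (6, 11), 12: (5, 12)},
    "nHA-LC": {6: (9, 11), 12: (9, 12)},
    "nHA-HC": {6: (11, 12), 12: (10, 12)},
}


def records_from_counts(
    counts: dict[str, dict[int, tuple[int, int]]]
) -> list[tuple[str, int, bool]]:
    """Expand per-group (bridged, total) counts to per-defect records."""
    records = []
    for group, by_tp in counts.items():
        for tp, (nb, nt) in by_tp.items():
            records.extend((group, tp, True) for _ in range(nb))
            records.extend((group, tp, False) for _ in range(nt - nb))
    return records


def bridging_rate(
    records: Iterable[tuple[str, int, bool]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-defect bridging decisions into rate tables.

    Parameters
    ----------
    records
        Iterable of ``(group, timepoint, bridged)`` tuples.

    Returns
    -------
    per_timepoint, per_group
        ``per_timepoint`` has one row per group x timepoint with ``n_bridged``,
        ``n_total`` and the round-half-up integer percentage ``pct``.
        ``per_group`` averages the unrounded timepoint percentages per group
        (``avg_pct``) and also reports the complementary non-bridging average
        (``avg_nonbridged_pct``); both round-half-up to integers.
    """
    df = pd.DataFrame(list(records), columns=["group", "timepoint", "bridged"])
    if df.empty:
        raise ValueError("no bridging records")
    rows = []
    for (group, tp), sub in df.groupby(["group", "timepoint"], sort=False):
        n_total = len(sub)
        if n_total == 0:  # pragma: no cover
            continue
        n_bridged = int(sub["bridged"].sum())
        exact = 100.0 * n_bridged / n_total
        rows.append(
            {
                "group": group,
                "timepoint": tp,
                "n_bridged": n_bridged,
                "n_total": n_total,
                "pct_exact": exact,
                "pct": int(round_half_up(exact)),
            }
        )
    per_tp = pd.DataFrame(rows)
    grp_rows = []
    for group, sub in per_tp.groupby("group", sort=False):
        avg = float(sub["pct_exact"].mean())
        grp_rows.append(
            {
                "group": group,
                "avg_pct": int(round_half_up(avg)),
                "avg_nonbridged_pct": int(round_half_up(100.0 - avg)),
            }
        )
    return per_tp, pd.DataFrame(grp_rows)
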