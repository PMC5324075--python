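"""File I/O for the pipeline's standard formats.

Section images travel as TIFF/PNG, label maps and ROI masks as indexed PNG,
geometry and reports as JSON, volumes as NIfTI or DICOM series, manifests
and cohort tables as CSV, configs as YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .bridging import BridgingResult, CTVolume
from .phantom import PhantomConfig, PhantomTruth
from .roi import DefectGeometry
from .segment import SegmentationMap

# fixed palette for indexed label PNGs (class code -> display colour)
_PALETTE = [
    (255, 255, 255),  # soft tissue
    (240, 170, 190),  # old bone
    (150, 60, 140),  # new bone
    (110, 100, 90),  # substitute
]

PathLike = Union[str, Path]


def write_image(path: PathLike, image: np.ndarray) -> None:
    """RGB section image as TIFF or PNG, by extension."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image)


def read_image(path: PathLike) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def write_labels(path: PathLike, labels: np.ndarray) -> None:
    """Class map as indexed (palette) PNG."""
    im = Image.fromarray(labels.astype(np.uint8), mode="P")
    flat = [c for rgb in _PALETTE for c in rgb]
    im.putpalette(flat + [0] * (768 - len(flat)))
    im.save(Path(path))


def read_labels(path: PathLike) -> np.ndarray:
    return np.asarray(Image.open(Path(path)), dtype=np.uint8)


def write_segmentation(segmap: SegmentationMap, png_path: PathLike) -> None:
    """Indexed PNG plus a JSON sidecar (threshold, stage provenance)."""
    write_labels(png_path, segmap.labels)
    sidecar = Path(png_path).with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "pixel_pitch_um": segmap.pixel_pitch_um,
                "adaptive_threshold": segmap.adaptive_threshold,
                "provenance": segmap.provenance,
            },
            indent=2,
        )
    )


def read_segmentation(png_path: PathLike) -> SegmentationMap:
    labels = read_labels(png_path)
    meta = json.loads(Path(png_path).with_suffix(".json").read_text())
    return SegmentationMap(
        labels=labels,
        pixel_pitch_um=meta["pixel_pitch_um"],
        adaptive_threshold=meta["adaptive_threshold"],
        provenance=meta["provenance"],
    )


def write_geometry(path: PathLike, geom: DefectGeometry) -> None:
    Path(path).write_text(geom.to_json())


def read_geometry(path: PathLike) -> DefectGeometry:
    return DefectGeometry.from_json(Path(path).read_text())


def write_config(path: PathLike, config: PhantomConfig) -> None:
    d = asdict(config)
    d["agglomerate_area_mm2"] = list(d["agglomerate_area_mm2"])
    d["volume_shape"] = list(d["volume_shape"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_config(path: PathLike) -> PhantomConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["agglomerate_area_mm2"] = tuple(d["agglomerate_area_mm2"])
    d["volume_shape"] = tuple(d["volume_shape"])
    d["class_colors"] = {k: tuple(v) for k, v in d["class_colors"].items()}
    d["canal_spec"] = list(d.get("canal_spec") or [])
    d["pocket_spec"] = [tuple(p) for p in (d.get("pocket_spec") or [])]
    return PhantomConfig(**d)


def write_volume(path: PathLike, vol: CTVolume) -> None:
    """Volume as NIfTI; the voxel pitch goes into the affine (mm units)."""
    pitch_mm = vol.voxel_pitch_um / 1000.0
    affine = np.diag([pitch_mm, pitch_mm, pitch_mm, 1.0])
    nib.save(nib.Nifti1Image(vol.data.astype(np.int32), affine), str(path))


def read_volume(path: PathLike, axis: int = 0) -> CTVolume:
    """Read a NIfTI volume or a directory of DICOM slices."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path, axis=axis)
    img = nib.load(str(path))
    pitch_mm = float(img.header.get_zooms()[0])
    data = np.asarray(img.dataobj)
    return CTVolume(data=data, voxel_pitch_um=pitch_mm * 1000.0, axis=axis)


def _read_dicom_series(directory: Path, axis: int = 0) -> CTVolume:
    import pydicom

    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM slices in {directory}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices.sort(key=lambda s: int(getattr(s, "InstanceNumber", 0)))
    data = np.stack([s.pixel_array for s in slices], axis=0)
    spacing = getattr(slices[0], "PixelSpacing", None)
    pitch_um = float(spacing[0]) * 1000.0 if spacing is not None else 1000.0
    return CTVolume(data=data, voxel_pitch_um=pitch_um, axis=axis)


def write_bridging_result(path: PathLike, result: BridgingResult) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "bridged": result.bridged,
                "bone_threshold_used": result.bone_threshold_used,
                "witness_path": result.witness_path,
            }
        )
    )


def write_manifest(path: PathLike, manifest: pd.DataFrame) -> None:
    manifest.to_csv(Path(path), index=False)


def read_manifest(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_report_csv(path: PathLike, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def save_section_phantom(truth: PhantomTruth, directory: PathLike) -> None:
    """Persist one section phantom: image, labels, geometry, truth report."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_image(directory / "section.png", truth.image)
    write_labels(directory / "labels.png", truth.labels)
    write_geometry(directory / "geometry.json", truth.geometry)
    write_config(directory / "config.yaml", truth.config)
    (directory / "true_report.json").write_text(truth.true_report.to_json(indent=2))
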