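"""Readers and writers for the pipeline's on-disk artifacts.

Formats: OCT volumes as multi-page TIFF (pages along depth) or NIfTI;
optical-property, OD and COPA maps as 32-bit float TIFF with a JSON metadata
sidecar; stain images as 8-bit RGB TIFF; ROI sets and ROI tables as CSV;
fit reports as JSON.  Write-then-read round-trips preserve integer data
bit-exactly and maps to float32 precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .glm import ROI
from .histology import COPAMap, ODMap, StainImage
from .oct import OCTVolume, OpticalPropertyMap

ROI_CSV_COLUMNS = ["roi_id", "center_x_um", "center_y_um", "radius_um",
                   "layer", "tissue_class", "region"]


class SchemaError(ValueError):
    """A file does not conform to its documented schema."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _read_json(path: Path) -> dict:
    if not path.exists():
        raise SchemaError(f"missing metadata sidecar {path}")
    return json.loads(path.read_text())


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def write_volume(path: str | Path, volume: OCTVolume) -> None:
    """Write a volume as multi-page TIFF (.tif) or NIfTI (.nii/.nii.gz)."""
    path = Path(path)
    if path.suffix in {".tif", ".tiff"}:
        # pages along z; float32
        tifffile.imwrite(path, volume.intensities.astype(np.float32)
                         .transpose(2, 0, 1))
        _write_json(_sidecar(path), {"z_spacing_um": volume.z_spacing,
                                     "lateral_spacing_um": volume.lateral_spacing})
    elif path.name.endswith((".nii", ".nii.gz")):
        affine = np.diag([volume.lateral_spacing, volume.lateral_spacing,
                          volume.z_spacing, 1.0])
        nib.save(nib.Nifti1Image(volume.intensities.astype(np.float32), affine),
                 str(path))
    else:
        raise SchemaError(f"unsupported volume format {path.suffix!r}")


def read_volume(path: str | Path) -> OCTVolume:
    path = Path(path)
    if path.suffix in {".tif", ".tiff"}:
        data = tifffile.imread(path).transpose(1, 2, 0)
        meta = _read_json(_sidecar(path))
        try:
            return OCTVolume(np.asarray(data, dtype=float),
                             meta["z_spacing_um"], meta["lateral_spacing_um"])
        except KeyError as exc:
            raise SchemaError(f"volume sidecar missing field {exc}") from exc
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        return OCTVolume(np.asarray(img.get_fdata(), dtype=float),
                         float(zooms[2]), float(zooms[0]))
    raise SchemaError(f"unsupported volume format {path.suffix!r}")


# ---------------------------------------------------------------------------
# 2D maps
# ---------------------------------------------------------------------------

def write_map(path: str | Path, values: np.ndarray, pixel_pitch: float,
              quantity: str, extra: dict | None = None) -> None:
    """Float32 TIFF plus JSON sidecar (quantity, pitch, extras)."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))
    meta = {"quantity": quantity, "pixel_pitch_um": pixel_pitch}
    meta.update(extra or {})
    _write_json(_sidecar(path), meta)


def read_map(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=float)
    meta = _read_json(_sidecar(path))
    for field in ("quantity", "pixel_pitch_um"):
        if field not in meta:
            raise SchemaError(f"map sidecar {path} missing field {field!r}")
    return values, meta


def write_property_map(path: str | Path, pmap: OpticalPropertyMap,
                       extra: dict | None = None) -> None:
    vals = pmap.values.copy()
    vals[~pmap.mask] = np.nan  # masked pixels stored as NaN
    write_map(path, vals, pmap.pixel_pitch, pmap.quantity, extra)


def read_property_map(path: str | Path) -> OpticalPropertyMap:
    values, meta = read_map(path)
    return OpticalPropertyMap(values, meta["quantity"], meta["pixel_pitch_um"],
                              np.isfinite(values))


def read_od_map(path: str | Path) -> ODMap:
    values, meta = read_map(path)
    return ODMap(values, meta["pixel_pitch_um"])


def read_copa_map(path: str | Path) -> COPAMap:
    values, meta = read_map(path)
    try:
        return COPAMap(values, meta["box_size_um"], meta["pixel_pitch_um"])
    except KeyError as exc:
        raise SchemaError(f"COPA sidecar missing field {exc}") from exc


# ---------------------------------------------------------------------------
# Stain images
# ---------------------------------------------------------------------------

def write_stain_image(path: str | Path, image: StainImage) -> None:
    path = Path(path)
    tifffile.imwrite(path, image.rgb, photometric="rgb")
    _write_json(_sidecar(path), {"pixel_pitch_um": image.pixel_pitch,
                                 "stain": image.stain})


def read_stain_image(path: str | Path) -> StainImage:
    path = Path(path)
    rgb = tifffile.imread(path)
    meta = _read_json(_sidecar(path))
    try:
        return StainImage(rgb, meta["pixel_pitch_um"], meta["stain"])
    except KeyError as exc:
        raise SchemaError(f"stain sidecar missing field {exc}") from exc


# ---------------------------------------------------------------------------
# ROI sets and tables
# ---------------------------------------------------------------------------

def write_rois(path: str | Path, rois: Sequence[ROI]) -> None:
    pd.DataFrame([{
        "roi_id": r.roi_id, "center_x_um": r.center_x, "center_y_um": r.center_y,
        "radius_um": r.radius, "layer": r.layer, "tissue_class": r.tissue_class,
        "region": r.region,
    } for r in rois]).to_csv(path, index=False)


def read_rois(path: str | Path) -> list[ROI]:
    frame = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in ROI_CSV_COLUMNS[:6] if c not in frame.columns]
    if missing:
        raise SchemaError(f"ROI CSV {path} missing columns {missing}")
    rois = []
    for i, row in frame.iterrows():
        if row["tissue_class"] not in {"grey", "white"}:
            raise SchemaError(f"ROI CSV {path} line {i + 2}: invalid "
                              f"tissue_class {row['tissue_class']!r}")
        rois.append(ROI(str(row["roi_id"]), float(row["center_x_um"]),
                        float(row["center_y_um"]), float(row["radius_um"]),
                        layer=str(row["layer"]),
                        tissue_class=str(row["tissue_class"]),
                        region=str(row.get("region", ""))))
    return rois


def write_roi_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_roi_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, keep_default_na=False,
                        na_values=[""], dtype={"roi_id": str})
    for col in ("roi_id", "mean_mu_s", "mean_od", "mean_copa", "tissue_class"):
        if col not in table.columns:
            raise SchemaError(f"ROI table {path} missing column {col!r}")
    return table


# ---------------------------------------------------------------------------
# Fit reports and calibration
# ---------------------------------------------------------------------------

def write_fit_report(path: str | Path, report: dict) -> None:
    _write_json(Path(path), report)


def read_fit_report(path: str | Path) -> dict:
    return _read_json(Path(path))


def write_calibration(path: str | Path, zf: float, zrs: float,
                      known_mu_s: float) -> None:
    _write_json(Path(path), {"zf_um": zf, "zrs_um": zrs,
                             "phantom_mu_s_mm": known_mu_s})


def read_calibration(path: str | Path) -> tuple[float, float]:
    meta = _read_json(Path(path))
    try:
        return float(meta["zf_um"]), float(meta["zrs_um"])
    except KeyError as exc:
        raise SchemaError(f"calibration file missing field {exc}") from exc
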