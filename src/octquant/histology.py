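"""Quantitative maps from stained-slide RGB images.

Two standard stains are quantified:

* **Gallyas silver** (myelin): each RGB channel is optionally normalised and
  converted to decadic optical density, OD = -(1/3) * sum_i log10(I_i / 255),
  so that darker (more myelinated) tissue has higher OD.
* **Nissl** (cell bodies): cell bodies are segmented by thresholding, small
  objects (glia) are removed by an area filter, and the cellular occupation
  per area (COPA) — the fraction of a sliding 200 x 200 um neighbourhood
  covered by cell bodies — is computed.  Under Mie scattering with a
  constant phase function, mu_s of the cellular compartment is proportional
  to number density times cross-sectional area, which COPA measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

logger = logging.getLogger(__name__)

#: OD assigned to zero-intensity (8-bit floor) pixels to avoid infinities.
DEFAULT_CLIP_OD = 3.0


@dataclass
class StainImage:
    """8-bit RGB histology image with pixel pitch in um."""

    rgb: np.ndarray           # (h, w, 3) uint8
    pixel_pitch: float = 1.9  # um, nominal digitisation pitch
    stain: str = "gallyas"    # {"gallyas", "nissl"}

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("stain image must be (h, w, 3)")
        if self.rgb.dtype != np.uint8:
            if self.rgb.min() < 0 or self.rgb.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            # digitised slides are 8-bit; float arrays (e.g. analytic test
            # patterns) are kept as-is
            if not np.issubdtype(self.rgb.dtype, np.floating):
                self.rgb = self.rgb.astype(np.uint8)
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.stain not in {"gallyas", "nissl"}:
            raise ValueError(f"unknown stain {self.stain!r}")


@dataclass
class ODMap:
    values: np.ndarray
    pixel_pitch: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("OD values must be finite and nonnegative")


@dataclass
class CellMask:
    values: np.ndarray  # bool, True inside cell bodies
    pixel_pitch: float
    min_area_applied: float = 0.0  # um^2

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)


@dataclass
class COPAMap:
    values: np.ndarray  # fractions in [0, 1]
    box_size: float     # um
    stride: float       # um == output pixel pitch

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("COPA values must lie in [0, 1]")

    @property
    def pixel_pitch(self) -> float:
        return self.stride


# ---------------------------------------------------------------------------
# Gallyas optical density
# ---------------------------------------------------------------------------

def normalize_channels(image: StainImage, low_pct: float = 1.0,
                       high_pct: float = 99.0) -> StainImage:
    """Linearly rescale each channel so its percentiles map to [0, 255].

    Percentile (rather than min/max) anchoring is robust to stain debris and
    dust outliers.  A constant channel cannot be rescaled and is passed
    through with a warning.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("require 0 <= low_pct < high_pct <= 100")
    out = np.empty_like(image.rgb)
    for c in range(3):
        ch = image.rgb[:, :, c].astype(float)
        lo, hi = np.percentile(ch, [low_pct, high_pct])
        if hi <= lo:
            logger.warning("channel %d is constant; normalization skipped", c)
            out[:, :, c] = image.rgb[:, :, c]
            continue
        scaled = np.clip((ch - lo) / (hi - lo) * 255.0, 0, 255)
        out[:, :, c] = np.round(scaled).astype(np.uint8)
    return StainImage(out, image.pixel_pitch, image.stain)


def compute_od_map(image: StainImage, clip_od: float = DEFAULT_CLIP_OD) -> ODMap:
    """Mean decadic optical density per pixel.

    OD = -(1/3) * sum over R,G,B of log10(I / 255); channels at intensity 0
    are clipped to ``clip_od`` per channel.  Antitone in intensity: darkening
    any channel never decreases the OD.
    """
    rgb = image.rgb.astype(float)
    with np.errstate(divide="ignore"):
        od_ch = -np.log10(rgb / 255.0)
    od_ch = np.minimum(od_ch, clip_od)
    return ODMap(od_ch.mean(axis=2), image.pixel_pitch)


# ---------------------------------------------------------------------------
# Nissl segmentation and COPA
# ---------------------------------------------------------------------------

def segment_cell_bodies(image: StainImage, threshold_mode: str | float = "otsu",
                        min_area_um2: float = 50.0) -> CellMask:
    """Threshold-based cell-body segmentation with a glia-excluding area filter.

    The grayscale OD image is thresholded (Otsu by default, or a fixed OD
    value) and connected components smaller than ``min_area_um2`` are
    removed.  The default 50 um^2 keeps neuron somata (radius >= ~4 um)
    while discarding the smaller glia.  A blank image yields an empty mask.
    """
    if image.stain != "nissl":
        raise ValueError("cell segmentation expects a Nissl image")
    od = compute_od_map(image).values
    if threshold_mode == "otsu":
        if np.ptp(od) == 0:
            return CellMask(np.zeros(od.shape, dtype=bool), image.pixel_pitch,
                            min_area_um2)
        thr = threshold_otsu(od)
    else:
        thr = float(threshold_mode)
    mask = od > thr
    min_px = int(np.ceil(min_area_um2 / image.pixel_pitch ** 2))
    if min_px > 1:
        # drop components with fewer than min_px pixels (glia exclusion)
        mask = remove_small_objects(mask, max_size=min_px - 1)
    return CellMask(mask, image.pixel_pitch, min_area_um2)


def compute_copa_map(mask: CellMask, box_size: float = 200.0,
                     stride: float = 30.0) -> COPAMap:
    """Sliding-box cell occupancy: fraction of 1-pixels in a box around each
    output position.

    Output pixel (i, j) is centred at ((j + 0.5) * stride, (i + 0.5) * stride)
    um; the box extends box_size/2 to each side and is truncated at image
    borders, where only in-bounds pixels enter the fraction.  The default
    stride of 30 um aligns the COPA grid with the block-averaged mu_s maps.
    """
    if box_size < mask.pixel_pitch:
        raise ValueError("box smaller than one pixel")
    if stride <= 0:
        raise ValueError("stride must be positive")
    m = mask.values.astype(np.int64)
    h, w = m.shape
    pitch = mask.pixel_pitch
    # integral image with a leading zero row/column
    integ = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(m, axis=0), axis=1, out=integ[1:, 1:])

    out_h = int(h * pitch // stride)
    out_w = int(w * pitch // stride)
    if out_h == 0 or out_w == 0:
        raise ValueError("mask smaller than one stride")
    ii, jj = np.meshgrid(np.arange(out_h), np.arange(out_w), indexing="ij")
    cy = (ii + 0.5) * stride
    cx = (jj + 0.5) * stride
    half = box_size / 2.0
    # pixel k covers [k*pitch, (k+1)*pitch): include pixels overlapping the box
    r0 = np.clip(np.floor((cy - half) / pitch).astype(int), 0, h)
    r1 = np.clip(np.ceil((cy + half) / pitch).astype(int), 0, h)
    c0 = np.clip(np.floor((cx - half) / pitch).astype(int), 0, w)
    c1 = np.clip(np.ceil((cx + half) / pitch).astype(int), 0, w)
    count = (integ[r1, c1] - integ[r0, c1] - integ[r1, c0] + integ[r0, c0])
    total = (r1 - r0) * (c1 - c0)
    vals = np.where(total > 0, count / np.maximum(total, 1), 0.0)
    return COPAMap(vals, box_size, stride)


def resample_map(values: np.ndarray, source_pitch: float,
                 target_pitch: float) -> np.ndarray:
    """Block-mean downsampling of a 2D map to a coarser pitch.

    Only integer downsampling factors are applied (factor = floor of the
    pitch ratio); trailing partial blocks are dropped, so the overall mean
    is conserved exactly on edge-complete inputs.  Upsampling is refused.
    """
    if target_pitch < source_pitch:
        raise ValueError("resample_map only downsamples (target >= source pitch)")
    f = int(target_pitch // source_pitch)
    values = np.asarray(values, dtype=float)
    h, w = values.shape
    bh, bw = h // f, w // f
    if bh == 0 or bw == 0:
        raise ValueError("map smaller than one target pixel")
    v = values[: bh * f, : bw * f]
    return v.reshape(bh, f, bw, f).mean(axis=(1, 3))
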