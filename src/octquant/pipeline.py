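"""End-to-end orchestration: simulate -> calibrate -> fit -> histology -> GLM.

A :class:`PipelineConfig` (loadable from YAML, unknown keys rejected) fixes
the phantom, the imaging system, the noise model and the analysis settings.
:func:`run_pipeline` executes the five stages, writes every intermediate
artifact into a run directory and produces a machine-readable
``summary.json`` holding the recovered GLM coefficients, their confidence
intervals, the model comparison, the four back-scattering screens and the
region summary.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import glm as glm_mod
from . import histology as histo
from . import io as io_mod
from . import oct as oct_mod
from . import synthetic as synth

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _from_mapping(cls, data: dict, context: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown keys in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class HistoSettings:
    """Histology-quantification settings.

    Channel normalisation is off by default: the synthetic slides are
    rendered with a calibrated intensity-to-OD relation, whereas percentile
    normalisation exists to standardise real slides with unknown
    illumination.
    """

    normalize: bool = False
    low_pct: float = 1.0
    high_pct: float = 99.0
    threshold: str | float = "otsu"
    box_um: float = 200.0
    stride_um: float = 30.0
    min_area_um2: float = 50.0


@dataclass
class GLMSettings:
    model: str = "multivariate"
    correction: str = "bonferroni"   # {"bonferroni", "none"}
    ratio_floor: float = 0.1         # mm^-1, mask for the mu_b'/mu_s ratio


@dataclass
class SimulationSettings:
    """Phantom dimensions and calibration-phantom geometry."""

    lateral_extent_um: float = 870.0
    depth_um: float = 600.0
    stain_pitch_um: float = 1.9
    rois_per_layer: int = 20
    block_lateral_um: float = 30.0
    calib_mu_s: float = 5.0          # Intralipid-like phantom, mm^-1
    calib_lateral_px: int = 150      # pooled A-lines per side for calibration


@dataclass
class PipelineConfig:
    system: oct_mod.SystemConfig = field(default_factory=oct_mod.SystemConfig)
    noise: synth.NoiseConfig = field(default_factory=synth.NoiseConfig)
    layers: Sequence[synth.LayerSpec] = field(default_factory=synth.default_layers)
    glm_params: tuple = synth.DEFAULT_GLM_PARAMS
    histo: HistoSettings = field(default_factory=HistoSettings)
    glm: GLMSettings = field(default_factory=GLMSettings)
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    seed: int = 0
    region: str = "phantom"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        parsed = {}
        if "system" in data:
            parsed["system"] = _from_mapping(oct_mod.SystemConfig,
                                             data.pop("system"), "system")
        if "noise" in data:
            parsed["noise"] = _from_mapping(synth.NoiseConfig,
                                            data.pop("noise"), "noise")
        if "layers" in data:
            parsed["layers"] = [_from_mapping(synth.LayerSpec, d, "layers")
                                for d in data.pop("layers")]
        if "glm_params" in data:
            parsed["glm_params"] = tuple(data.pop("glm_params"))
        for key, sub in [("histo", HistoSettings), ("glm", GLMSettings),
                         ("simulation", SimulationSettings)]:
            if key in data:
                parsed[key] = _from_mapping(sub, data.pop(key), key)
        for key in ("seed", "region"):
            if key in data:
                parsed[key] = data.pop(key)
        if data:
            raise ValueError(f"unknown config keys: {sorted(data)}")
        return cls(**parsed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [encode(v) for v in obj]
            return obj
        return {
            "system": encode(self.system), "noise": encode(self.noise),
            "layers": [encode(l) for l in self.layers],
            "glm_params": list(self.glm_params), "histo": encode(self.histo),
            "glm": encode(self.glm), "simulation": encode(self.simulation),
            "seed": self.seed, "region": self.region,
        }

    def validate(self) -> None:
        if len(self.layers) < 2 or not any(l.tissue_class == "white"
                                           for l in self.layers):
            raise ValueError("config must define >= 2 layers including "
                             ">= 1 white-matter layer")


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.2f s", name,
                        time.perf_counter() - t0)
            return out
        return inner
    return wrap


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

@_stage("simulate")
def stage_simulate(config: PipelineConfig) -> synth.LinkedDataset:
    sim = config.simulation
    return synth.generate_linked_dataset(
        glm_params=config.glm_params, layers=config.layers,
        system=config.system, noise=config.noise, seed=config.seed,
        lateral_extent=sim.lateral_extent_um, depth_um=sim.depth_um,
        stain_pitch=sim.stain_pitch_um, rois_per_layer=sim.rois_per_layer,
        copa_box_um=config.histo.box_um)


@_stage("calibrate")
def stage_calibrate(config: PipelineConfig) -> tuple[float, float]:
    """Recover (zf, zrs) from a homogeneous speckled phantom of known mu_s."""
    sim = config.simulation
    npx = sim.calib_lateral_px
    extent = npx * config.system.lateral_spacing
    layer = synth.LayerSpec("intralipid", "grey", extent, 0.0)
    bundle = synth.generate_layer_phantom(
        [layer], extent, config.system.lateral_spacing,
        glm_params=(sim.calib_mu_s, 0.0, 0.0),
        noise=dataclasses.replace(config.noise, mu_s_noise_sd=0.0,
                                  seed=config.seed + 7))
    phantom = synth.generate_oct_volume(
        bundle, config.system,
        dataclasses.replace(config.noise, seed=config.seed + 7),
        depth_um=sim.depth_um)
    return oct_mod.calibrate_confocal(phantom, sim.calib_mu_s, config.system)


@_stage("fit-oct")
def stage_fit_oct(config: PipelineConfig, volume: oct_mod.OCTVolume,
                  zf: float, zrs: float):
    cal = oct_mod.calibrated_config(config.system, zf, zrs)
    mu_s_map, mu_b_map = oct_mod.fit_volume(volume, cal,
                                            config.simulation.block_lateral_um)
    ratio = oct_mod.compute_ratio_map(mu_b_map, mu_s_map,
                                      floor=config.glm.ratio_floor)
    aip = oct_mod.compute_aip(volume)
    return mu_s_map, mu_b_map, ratio, aip


@_stage("histo")
def stage_histo(config: PipelineConfig, gallyas: histo.StainImage,
                nissl: histo.StainImage):
    h = config.histo
    gal = histo.normalize_channels(gallyas, h.low_pct, h.high_pct) \
        if h.normalize else gallyas
    od_map = histo.compute_od_map(gal)
    mask = histo.segment_cell_bodies(nissl, h.threshold, h.min_area_um2)
    copa_map = histo.compute_copa_map(mask, h.box_um, h.stride_um)
    return od_map, copa_map, mask


@_stage("glm")
def stage_glm(config: PipelineConfig, rois, mu_s_map, mu_b_map, ratio_map,
              od_map, copa_map):
    mu_s_means = glm_mod.extract_roi_means(mu_s_map.values, mu_s_map.pixel_pitch,
                                           rois, mu_s_map.mask)
    mu_b_means = glm_mod.extract_roi_means(mu_b_map.values, mu_b_map.pixel_pitch,
                                           rois, mu_b_map.mask)
    ratio_means = glm_mod.extract_roi_means(ratio_map.values,
                                            ratio_map.pixel_pitch, rois,
                                            ratio_map.mask)
    od_means = glm_mod.extract_roi_means(od_map.values, od_map.pixel_pitch, rois)
    copa_means = glm_mod.extract_roi_means(copa_map.values, copa_map.pixel_pitch,
                                           rois)
    table = glm_mod.build_roi_table(rois, mu_s_means, od_means, copa_means,
                                    extra={"mean_mu_b": mu_b_means,
                                           "mean_ratio": ratio_means})
    table["region"] = config.region
    comparison = glm_mod.compare_models(table)
    screens = glm_mod.univariate_screens(table)
    summary_frame = glm_mod.region_summaries({config.region: table})
    return table, comparison, screens, summary_frame


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 write_volume: bool = False) -> dict:
    """Run all stages, write artifacts into ``out_dir``, return the summary.

    The (large) simulated volume is only written when ``write_volume`` is
    set; all maps, images, tables and reports are always written.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run config: %s", json.dumps(config.to_dict(), sort_keys=True))

    dataset = stage_simulate(config)
    zf, zrs = stage_calibrate(config)
    mu_s_map, mu_b_map, ratio_map, aip = stage_fit_oct(config, dataset.volume,
                                                       zf, zrs)
    od_map, copa_map, mask = stage_histo(config, dataset.gallyas, dataset.nissl)
    table, comparison, screens, regions = stage_glm(
        config, dataset.rois, mu_s_map, mu_b_map, ratio_map, od_map, copa_map)

    # ---- artifacts -------------------------------------------------------
    if write_volume:
        io_mod.write_volume(out / "volume.tif", dataset.volume)
    io_mod.write_stain_image(out / "gallyas.tif", dataset.gallyas)
    io_mod.write_stain_image(out / "nissl.tif", dataset.nissl)
    io_mod.write_calibration(out / "calibration.json", zf, zrs,
                             config.simulation.calib_mu_s)
    io_mod.write_property_map(out / "mu_s.tif", mu_s_map)
    io_mod.write_property_map(out / "mu_b.tif", mu_b_map)
    io_mod.write_property_map(out / "ratio.tif", ratio_map)
    io_mod.write_property_map(out / "aip.tif", aip)
    io_mod.write_map(out / "od.tif", od_map.values, od_map.pixel_pitch, "od")
    io_mod.write_map(out / "copa.tif", copa_map.values, copa_map.pixel_pitch,
                     "copa", {"box_size_um": copa_map.box_size})
    io_mod.write_rois(out / "rois.csv", dataset.rois)
    io_mod.write_roi_table(out / "roi_table.csv", table)

    multi = comparison["fits"]["multivariate"]
    uni = comparison["fits"]["univariate"]
    ci = multi.conf_int()
    summary = {
        "seed": config.seed,
        "true_glm_params": list(config.glm_params),
        "calibration": {"zf_um": zf, "zrs_um": zrs,
                        "true_zf_um": config.system.zf,
                        "true_zrs_um": config.system.zrs},
        "n_rois": int(len(table)),
        "multivariate": multi.to_dict(),
        "univariate": uni.to_dict(),
        "multivariate_ci95": {name: [float(lo), float(hi)] for name, (lo, hi)
                              in zip(multi.term_names, ci)},
        "k1_rel_difference": comparison["k1_rel_difference"],
        "screens": {name: fit.to_dict() for name, fit in screens.items()},
        "regions": regions.to_dict(orient="records"),
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    frames = [glm_mod.fits_to_frame({"univariate": uni, "multivariate": multi},
                                    config.region),
              glm_mod.fits_to_frame(screens, config.region)]
    io_mod.write_roi_table(out / "glm_report.csv",
                           pd.concat(frames, ignore_index=True))
    return summary
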