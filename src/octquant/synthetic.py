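"""Co-registered ground-truth phantoms for the whole pipeline.

Real inputs to this pipeline are serial block-face OCT volumes of human
brain and nearby Gallyas/Nissl stained slices; none are publicly deposited,
so every stage is validated on layered synthetic tissue with known ground
truth instead.  A phantom is a stack of flat horizontal bands (supragranular
cortex, granular/infragranular layers, white matter) with per-layer myelin
density (on the Gallyas OD scale), neuron density and size.  From these the
generator produces, all in one lateral coordinate frame:

* ground-truth maps of OD, COPA, mu_s and mu_b', tied together by the
  scattering model mu_s = b + k1 * OD + k2 * COPA (+ residual noise),
  with COPA identically zero on white matter;
* a speckled OCT volume following R(z) = mu_b' exp(-2 mu_s z) h(z) H(z),
  with fully developed speckle modelled as i.i.d. unit-mean exponential
  multiplicative intensity noise per voxel;
* a Gallyas-like RGB image with intensity 255 * 10^(-OD * gain) per channel
  and optional log-normal staining jitter;
* a Nissl-like RGB image of dark elliptical neuron somata plus smaller glia
  disks, together with the exact neuron-body raster mask used in rendering;
* programmatically placed, non-overlapping circular ROIs (about 20 per
  layer, 200-500 histology pixels in area) labelled with layer and tissue
  class.

Every generator is a pure function of its arguments and seed: identical
inputs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .glm import ROI
from .histology import CellMask, StainImage, compute_copa_map
from .oct import OCTVolume, SystemConfig, confocal_weight, sensitivity_rolloff, UM_PER_MM

# Render colours (R, G, B) for the Nissl-like image.
_NISSL_BACKGROUND = (235, 228, 238)
_NISSL_NEURON = (70, 45, 110)
_NISSL_GLIA = (150, 125, 170)

#: ROI radii (um) giving areas of roughly 400-500 pixels at the 1.9 um
#: histology pitch while guaranteeing that at least one pixel centre of a
#: 30 um property-map grid falls inside the circle.
ROI_RADIUS_RANGE = (21.5, 23.9)


@dataclass
class LayerSpec:
    """One horizontal tissue band of the phantom."""

    name: str
    tissue_class: str            # {"grey", "white"}
    thickness: float             # um
    myelin_density: float        # Gallyas OD scale, unitless >= 0
    cell_density: float = 0.0    # neuron somata per mm^2
    cell_radius_mean: float = 7.0   # um
    cell_radius_sd: float = 1.0     # um
    glia_density: float = 0.0    # glia per mm^2
    glia_radius: float = 2.5     # um

    def __post_init__(self) -> None:
        if self.tissue_class not in {"grey", "white"}:
            raise ValueError(f"unknown tissue_class {self.tissue_class!r}")
        if self.thickness <= 0:
            raise ValueError("layer thickness must be positive")
        if min(self.myelin_density, self.cell_density, self.glia_density) < 0:
            raise ValueError("densities must be nonnegative")
        if self.cell_density > 0 and self.cell_radius_mean <= self.glia_radius:
            raise ValueError("cell_radius_mean must exceed glia_radius "
                             "(size filtering must be well-posed)")

    @property
    def analytic_copa(self) -> float:
        """Expected occupancy: density times mean cross-sectional area.

        For radius ~ N(mean, sd), E[pi r^2] = pi (mean^2 + sd^2).
        """
        if self.tissue_class == "white" or self.cell_density == 0:
            return 0.0
        mean_area_mm2 = np.pi * (self.cell_radius_mean ** 2
                                 + self.cell_radius_sd ** 2) * 1e-6
        return float(self.cell_density * mean_area_mm2)


@dataclass
class NoiseConfig:
    """Noise model for the simulated measurements.

    ``speckle`` multiplies each OCT voxel by a unit-mean exponential draw
    (fully developed speckle) when set to ``"exponential_intensity"``.
    ``od_jitter_sd`` is log-normal staining jitter on the Gallyas image, in
    decadic OD units.  ``mu_s_noise_sd`` (mm^-1) is residual scattering
    heterogeneity not explained by myelin and cell bodies, drawn on a
    coarse grid of ``mu_s_noise_grid_um`` cells so that it survives block
    averaging the way real tissue heterogeneity does.
    """

    speckle: str = "exponential_intensity"   # {"none", "exponential_intensity"}
    additive_floor: float = 0.0
    od_jitter_sd: float = 0.005
    copa_jitter_sd: float = 0.0
    mu_s_noise_sd: float = 0.3
    mu_s_noise_grid_um: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speckle not in {"none", "exponential_intensity"}:
            raise ValueError(f"unknown speckle mode {self.speckle!r}")
        if self.additive_floor < 0:
            raise ValueError("additive_floor must be nonnegative")
        if min(self.od_jitter_sd, self.copa_jitter_sd, self.mu_s_noise_sd) < 0:
            raise ValueError("noise standard deviations must be nonnegative")


NOISELESS = NoiseConfig(speckle="none", additive_floor=0.0, od_jitter_sd=0.0,
                        copa_jitter_sd=0.0, mu_s_noise_sd=0.0)


@dataclass
class GroundTruthBundle:
    """Ground-truth maps sharing one lateral frame (rows = y, cols = x).

    Pixel (i, j) is centred at y = (i + 0.5) * pixel_pitch,
    x = (j + 0.5) * pixel_pitch, in micrometres.
    """

    true_mu_s_map: np.ndarray    # mm^-1
    true_mu_b_map: np.ndarray    # relative units
    true_od_map: np.ndarray      # unitless
    true_copa_map: np.ndarray    # fraction in [0, 1]
    cell_centers: list           # (x_um, y_um, radius_um)
    glm_params: tuple            # (b, k1, k2)
    rng_seed: int
    pixel_pitch: float           # um
    layers: Sequence[LayerSpec] = field(default_factory=list)
    layer_rows: list = field(default_factory=list)  # (name, class, row0, row1)

    @property
    def white_row_mask(self) -> np.ndarray:
        mask = np.zeros(self.true_od_map.shape[0], dtype=bool)
        for _, cls, r0, r1 in self.layer_rows:
            if cls == "white":
                mask[r0:r1] = True
        return mask

    def layer_band_um(self, name: str) -> tuple[float, float]:
        for lname, _, r0, r1 in self.layer_rows:
            if lname == name:
                return r0 * self.pixel_pitch, r1 * self.pixel_pitch
        raise KeyError(name)


def default_layers() -> list[LayerSpec]:
    """A four-band cortical column: three grey laminae over white matter.

    Myelin densities increase with depth as in cortex; neuron densities give
    COPA values of roughly 0.16, 0.22 and 0.10 via the density x mean-area
    identity, with COPA zero in white matter.
    """
    return [
        LayerSpec("supragranular", "grey", 406.0, 0.25, cell_density=1000.0,
                  glia_density=150.0),
        LayerSpec("granular", "grey", 406.0, 0.45, cell_density=1400.0,
                  glia_density=150.0),
        LayerSpec("infragranular", "grey", 406.0, 0.65, cell_density=640.0,
                  glia_density=150.0),
        LayerSpec("white_matter", "white", 406.0, 1.0, cell_density=0.0,
                  glia_density=300.0),
    ]


DEFAULT_GLM_PARAMS = (1.0, 7.2, 5.0)


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

def _layer_rows(layers: Sequence[LayerSpec], pixel_pitch: float):
    rows = []
    r = 0
    for layer in layers:
        n = int(round(layer.thickness / pixel_pitch))
        if n < 1:
            raise ValueError(f"layer {layer.name!r} thinner than one pixel")
        rows.append((layer.name, layer.tissue_class, r, r + n))
        r += n
    return rows, r


def _place_cells(layers, layer_rows, pixel_pitch, extent_x, rng):
    """Scatter neuron somata per grey layer without overlap.

    Somata do not overlap on real Nissl slides at these densities, and the
    occupancy analysis relies on that, so candidate centres are rejection
    sampled against the somata already placed.  The count is the expected
    one (density times band area) and centres are uniform over the full
    band, so the realised occupancy matches the analytic density-times-area
    value up to radius sampling and rasterisation.
    """
    centers = []
    for layer, (_, _, r0, r1) in zip(layers, layer_rows):
        if layer.tissue_class == "white" or layer.cell_density == 0:
            continue
        y0, y1 = r0 * pixel_pitch, r1 * pixel_pitch
        area_mm2 = (y1 - y0) * extent_x * 1e-6
        n = int(round(layer.cell_density * area_mm2))
        radii = np.clip(rng.normal(layer.cell_radius_mean, layer.cell_radius_sd, n),
                        layer.glia_radius + 0.5, None)
        px = np.empty(n)
        py = np.empty(n)
        pr = np.empty(n)
        k = 0
        for r in radii:
            for _ in range(200):
                x = rng.uniform(0.0, extent_x)
                y = rng.uniform(y0, y1)
                if k == 0 or np.all((x - px[:k]) ** 2 + (y - py[:k]) ** 2
                                    > (r + pr[:k]) ** 2):
                    px[k], py[k], pr[k] = x, y, r
                    k += 1
                    break
        centers.extend((float(px[i]), float(py[i]), float(pr[i]))
                       for i in range(k))
    return centers


def generate_layer_phantom(layers: Sequence[LayerSpec], lateral_extent: float,
                           pixel_pitch: float,
                           glm_params: tuple = DEFAULT_GLM_PARAMS,
                           noise: Optional[NoiseConfig] = None,
                           od_gradient_frac: float = 0.0,
                           mu_b_floor: float = 0.1,
                           mu_b_per_mu_s: float = 0.2) -> GroundTruthBundle:
    """Stack layers into ground-truth maps tied to known GLM coefficients.

    The lateral frame is ``lateral_extent`` wide (x) and the summed layer
    thickness tall (y).  The OD map carries each layer's myelin density
    (optionally with a linear across-x gradient of ``od_gradient_frac`` to
    create within-layer spread); the COPA map is the analytic
    density-times-area occupancy for grey layers and exactly zero for white
    matter; mu_s follows b + k1*OD + k2*COPA plus coarse-grained residual
    noise, and mu_b' is an affine function of mu_s (back-scattering tracks
    scattering in brain tissue).
    """
    if not layers:
        raise ValueError("need at least one layer")
    if lateral_extent <= 0 or pixel_pitch <= 0:
        raise ValueError("lateral extent and pixel pitch must be positive")
    nx = lateral_extent / pixel_pitch
    if abs(nx - round(nx)) > 1e-9:
        raise ValueError("pixel_pitch must divide lateral_extent")
    nx = int(round(nx))
    noise = noise if noise is not None else NoiseConfig()
    rng = np.random.default_rng(np.random.SeedSequence([noise.seed, 101]))

    layer_rows, ny = _layer_rows(layers, pixel_pitch)
    od = np.zeros((ny, nx))
    copa = np.zeros((ny, nx))
    grad = 1.0 + od_gradient_frac * np.linspace(-1.0, 1.0, nx)
    for layer, (_, _, r0, r1) in zip(layers, layer_rows):
        od[r0:r1, :] = layer.myelin_density * grad
        copa[r0:r1, :] = layer.analytic_copa
    if noise.copa_jitter_sd > 0:
        copa = copa + rng.normal(0.0, noise.copa_jitter_sd, copa.shape)
    white = np.zeros((ny, nx), dtype=bool)
    for _, cls, r0, r1 in layer_rows:
        if cls == "white":
            white[r0:r1, :] = True
    copa[white] = 0.0
    copa = np.clip(copa, 0.0, 1.0)

    b, k1, k2 = glm_params
    mu_s = b + k1 * od + k2 * copa
    if noise.mu_s_noise_sd > 0:
        cells = max(1, int(round(noise.mu_s_noise_grid_um / pixel_pitch)))
        coarse = rng.normal(0.0, noise.mu_s_noise_sd,
                            (ny // cells + 1, nx // cells + 1))
        mu_s = mu_s + np.repeat(np.repeat(coarse, cells, 0), cells, 1)[:ny, :nx]
    mu_s = np.clip(mu_s, 0.0, None)
    mu_b = mu_b_floor + mu_b_per_mu_s * mu_s

    centers = _place_cells(layers, layer_rows, pixel_pitch, lateral_extent, rng)
    return GroundTruthBundle(mu_s, mu_b, od, copa, centers, tuple(glm_params),
                             noise.seed, pixel_pitch, list(layers), layer_rows)


# ---------------------------------------------------------------------------
# OCT volume
# ---------------------------------------------------------------------------

def generate_oct_volume(bundle: GroundTruthBundle, system: SystemConfig,
                        noise: Optional[NoiseConfig] = None,
                        depth_um: float = 600.0) -> OCTVolume:
    """Forward-model a speckled OCT volume from a ground-truth bundle.

    Each A-line is R(z) = mu_b' exp(-2 mu_s z) h(z) H(z) for its lateral
    pixel, multiplied per voxel by i.i.d. unit-mean exponential speckle when
    enabled, plus the additive noise floor.  Deterministic given the noise
    seed.
    """
    noise = noise if noise is not None else NoiseConfig()
    if abs(system.lateral_spacing - bundle.pixel_pitch) > 1e-9:
        raise ValueError("system lateral spacing must match the bundle pitch")
    nz = int(round(depth_um / system.z_spacing))
    if nz < 2:
        raise ValueError("depth too small for the axial sampling")
    z = np.arange(nz) * system.z_spacing
    axial = (confocal_weight(z, system.zf, system.zrs)
             * sensitivity_rolloff(z, system))
    mu_s = bundle.true_mu_s_map
    mu_b = bundle.true_mu_b_map
    if noise.speckle == "none":
        # exact double-precision evaluation, identical to model_profile
        r = mu_b[:, :, None] * np.exp(-2.0 * mu_s[:, :, None] * z / UM_PER_MM)
        r *= confocal_weight(z, system.zf, system.zrs)[None, None, :]
        r *= sensitivity_rolloff(z, system)[None, None, :]
    else:
        # speckled volumes are large; build the Beer-Lambert decay as a
        # single-precision cumulative product along depth (relative rounding
        # ~1e-6, far below the speckle) to keep memory traffic down
        ny, nx = mu_s.shape
        step = np.exp(-2.0 * mu_s * system.z_spacing / UM_PER_MM
                      ).astype(np.float32)
        r = np.empty((ny, nx, nz), dtype=np.float32)
        r[:, :, 0] = 1.0
        r[:, :, 1:] = step[:, :, None]
        np.cumprod(r, axis=2, out=r)
        r *= mu_b[:, :, None].astype(np.float32)
        r *= axial[None, None, :].astype(np.float32)
        rng = np.random.default_rng(np.random.SeedSequence([noise.seed, 202]))
        # unit-mean exponential speckle by inverse CDF on float32 uniforms:
        # u in [0, 1) so -log1p(-u) is finite and ~ Exp(1)
        u = rng.random(size=r.shape, dtype=np.float32)
        np.negative(u, out=u)
        np.log1p(u, out=u)
        np.negative(u, out=u)
        r *= u
    if noise.additive_floor:
        r += np.float32(noise.additive_floor) if r.dtype == np.float32 \
            else noise.additive_floor
    return OCTVolume(r, system.z_spacing, system.lateral_spacing)


# ---------------------------------------------------------------------------
# Stained-slide rendering
# ---------------------------------------------------------------------------

def _sample_bundle(values: np.ndarray, bundle_pitch: float, out_shape,
                   out_pitch: float) -> np.ndarray:
    """Nearest-neighbour sampling of a bundle map onto a finer stain grid."""
    h, w = out_shape
    ri = np.clip(((np.arange(h) + 0.5) * out_pitch / bundle_pitch).astype(int),
                 0, values.shape[0] - 1)
    ci = np.clip(((np.arange(w) + 0.5) * out_pitch / bundle_pitch).astype(int),
                 0, values.shape[1] - 1)
    return values[np.ix_(ri, ci)]


def _stain_shape(bundle: GroundTruthBundle, pixel_pitch: float):
    ny, nx = bundle.true_od_map.shape
    return (int(round(ny * bundle.pixel_pitch / pixel_pitch)),
            int(round(nx * bundle.pixel_pitch / pixel_pitch)))


def generate_gallyas_image(bundle: GroundTruthBundle, stain_gain: float = 1.0,
                           seed: Optional[int] = None, pixel_pitch: float = 1.9,
                           od_jitter_sd: float = 0.0) -> StainImage:
    """Render a Gallyas-like RGB slide from the true OD map.

    Per-channel intensity is 255 * 10^(-OD * stain_gain), optionally with
    multiplicative log-normal staining jitter of ``od_jitter_sd`` decadic OD
    units, quantised to 8 bits.  Running OD conversion on the output (with
    normalisation disabled and gain 1) recovers the true OD up to jitter and
    quantisation.
    """
    if stain_gain <= 0:
        raise ValueError("stain_gain must be positive")
    shape = _stain_shape(bundle, pixel_pitch)
    od = _sample_bundle(bundle.true_od_map, bundle.pixel_pitch, shape, pixel_pitch)
    intensity = 255.0 * np.power(10.0, -od * stain_gain)
    if od_jitter_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed or 0, 303]))
        intensity = intensity * np.power(10.0, rng.normal(0.0, od_jitter_sd, shape))
    rgb = np.clip(np.round(intensity), 0, 255).astype(np.uint8)
    return StainImage(np.repeat(rgb[:, :, None], 3, axis=2), pixel_pitch, "gallyas")


def generate_nissl_image(bundle: GroundTruthBundle, seed: Optional[int] = None,
                         pixel_pitch: float = 1.9
                         ) -> tuple[StainImage, CellMask]:
    """Render a Nissl-like RGB slide and its neuron-body ground-truth mask.

    Neuron somata from ``bundle.cell_centers`` are drawn as dark ellipses
    (random aspect 0.75-1 and orientation, preserving the stored
    cross-sectional area); overlapping somata are unioned in the mask.
    Smaller glia disks are rendered in the image but excluded from the
    returned mask, which is the segmentation ground truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed or 0, 404]))
    shape = _stain_shape(bundle, pixel_pitch)
    mask = np.zeros(shape, dtype=bool)
    for x, y, r in bundle.cell_centers:
        aspect = rng.uniform(0.75, 1.0)
        theta = rng.uniform(0.0, np.pi)
        # semi-axes r/sqrt(aspect), r*sqrt(aspect) keep the area pi r^2
        a = r / np.sqrt(aspect) / pixel_pitch
        bb = r * np.sqrt(aspect) / pixel_pitch
        rr, cc = draw_ellipse(y / pixel_pitch - 0.5, x / pixel_pitch - 0.5,
                              a, bb, shape=shape, rotation=theta)
        mask[rr, cc] = True

    glia = np.zeros(shape, dtype=bool)
    extent_x = shape[1] * pixel_pitch
    for layer, (_, _, r0, r1) in zip(bundle.layers, bundle.layer_rows):
        if layer.glia_density == 0:
            continue
        y0 = r0 * bundle.pixel_pitch
        y1 = r1 * bundle.pixel_pitch
        n = rng.poisson(layer.glia_density * (y1 - y0) * extent_x * 1e-6)
        for _ in range(n):
            gx = rng.uniform(0, extent_x)
            gy = rng.uniform(y0, y1)
            rr, cc = draw_ellipse(gy / pixel_pitch - 0.5, gx / pixel_pitch - 0.5,
                                  layer.glia_radius / pixel_pitch,
                                  layer.glia_radius / pixel_pitch, shape=shape)
            glia[rr, cc] = True

    rgb = np.empty(shape + (3,), dtype=np.uint8)
    for c in range(3):
        ch = np.full(shape, _NISSL_BACKGROUND[c], dtype=np.uint8)
        ch[glia] = _NISSL_GLIA[c]
        ch[mask] = _NISSL_NEURON[c]
        rgb[:, :, c] = ch
    return (StainImage(rgb, pixel_pitch, "nissl"),
            CellMask(mask, pixel_pitch))


# ---------------------------------------------------------------------------
# ROI placement and the linked dataset
# ---------------------------------------------------------------------------

def place_rois(bundle: GroundTruthBundle, rois_per_layer: int = 20,
               seed: Optional[int] = None, copa_box_um: float = 200.0,
               edge_margin_um: float = 55.0,
               max_attempts: int = 4000) -> list[ROI]:
    """Rejection-sample non-overlapping circular ROIs within each layer band.

    Each ROI has a radius drawn from :data:`ROI_RADIUS_RANGE` (about 400-500
    histology pixels in area).  Centres keep a margin from layer boundaries
    — half the COPA box in grey matter, so that occupancy neighbourhoods do
    not straddle layers — and from the lateral edges, so every ROI lies
    strictly inside its band and inside the fitted-map footprint.
    """
    extent_x = bundle.true_od_map.shape[1] * bundle.pixel_pitch
    rng = np.random.default_rng(np.random.SeedSequence([seed or 0, 505]))
    rois: list[ROI] = []
    for layer in bundle.layers:
        y0, y1 = bundle.layer_band_um(layer.name)
        placed = []
        attempts = 0
        while len(placed) < rois_per_layer and attempts < max_attempts:
            attempts += 1
            r = rng.uniform(*ROI_RADIUS_RANGE)
            band_margin = r + (copa_box_um / 2.0
                               if layer.tissue_class == "grey" else 0.0)
            if y1 - y0 <= 2 * band_margin:
                raise ValueError(
                    f"layer {layer.name!r} ({y1 - y0:.0f} um) is too thin for "
                    f"ROIs needing a {band_margin:.0f} um margin")
            x = rng.uniform(r + edge_margin_um, extent_x - r - edge_margin_um)
            y = rng.uniform(y0 + band_margin, y1 - band_margin)
            if all((x - q.center_x) ** 2 + (y - q.center_y) ** 2
                   > (r + q.radius) ** 2 for q in placed):
                placed.append(ROI(f"{layer.name}_{len(placed):02d}", x, y, r,
                                  layer=layer.name,
                                  tissue_class=layer.tissue_class))
        rois.extend(placed)
    return rois


@dataclass
class LinkedDataset:
    """One coherent phantom: volume, slides, ground truth and ROIs."""

    volume: OCTVolume
    gallyas: StainImage
    nissl: StainImage
    true_cell_mask: CellMask
    bundle: GroundTruthBundle
    rois: list


def generate_linked_dataset(glm_params: tuple = DEFAULT_GLM_PARAMS,
                            layers: Optional[Sequence[LayerSpec]] = None,
                            system: Optional[SystemConfig] = None,
                            noise: Optional[NoiseConfig] = None,
                            seed: int = 0,
                            lateral_extent: float = 870.0,
                            depth_um: float = 600.0,
                            stain_pitch: float = 1.9,
                            rois_per_layer: int = 20,
                            copa_box_um: float = 200.0) -> LinkedDataset:
    """Generate a fully linked phantom with self-consistent ground truth.

    The Nissl slide is rendered first and the *realised* occupancy of its
    neuron mask (200 um sliding box) replaces the analytic COPA in the
    ground truth before mu_s is formed, so that the scattering a pixel
    exhibits reflects the cells actually present there rather than their
    expectation.  White-matter COPA remains exactly zero.
    """
    layers = list(layers) if layers is not None else default_layers()
    if len(layers) < 2 or not any(l.tissue_class == "white" for l in layers):
        raise ValueError("need >= 2 layers including >= 1 white-matter layer")
    system = system if system is not None else SystemConfig()
    noise = (replace(noise, seed=seed) if noise is not None
             else NoiseConfig(seed=seed))

    bundle = generate_layer_phantom(layers, lateral_extent,
                                    system.lateral_spacing, glm_params, noise)
    nissl, true_mask = generate_nissl_image(bundle, seed=seed,
                                            pixel_pitch=stain_pitch)

    # realised COPA on the bundle grid, white matter forced to zero
    copa = compute_copa_map(true_mask, box_size=copa_box_um,
                            stride=bundle.pixel_pitch).values
    ny, nx = bundle.true_od_map.shape
    realized = np.zeros((ny, nx))
    realized[: copa.shape[0], : copa.shape[1]] = copa[:ny, :nx]
    realized[bundle.white_row_mask, :] = 0.0

    b, k1, k2 = glm_params
    rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    mu_s = b + k1 * bundle.true_od_map + k2 * realized
    if noise.mu_s_noise_sd > 0:
        cells = max(1, int(round(noise.mu_s_noise_grid_um / bundle.pixel_pitch)))
        coarse = rng.normal(0.0, noise.mu_s_noise_sd,
                            (ny // cells + 1, nx // cells + 1))
        mu_s = mu_s + np.repeat(np.repeat(coarse, cells, 0), cells, 1)[:ny, :nx]
    mu_s = np.clip(mu_s, 0.0, None)
    mu_b = 0.1 + 0.2 * mu_s
    bundle = replace(bundle, true_copa_map=realized, true_mu_s_map=mu_s,
                     true_mu_b_map=mu_b)

    volume = generate_oct_volume(bundle, system, noise, depth_um=depth_um)
    gallyas = generate_gallyas_image(bundle, stain_gain=1.0, seed=seed,
                                     pixel_pitch=stain_pitch,
                                     od_jitter_sd=noise.od_jitter_sd)
    rois = place_rois(bundle, rois_per_layer=rois_per_layer, seed=seed,
                      copa_box_um=copa_box_um)
    return LinkedDataset(volume, gallyas, nissl, true_mask, bundle, rois)
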