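"""Synthetic MWPA study generator.

Implements the multiplicative forward model

    v(r, lambda) = E(r) * Gamma * mu_abs(r, lambda) * F(lambda)
                   * exp(-mu_eff(lambda) * depth(r)) + N

on a simple scene: a tissue block under a water layer, with 0-3 ellipsoidal
ablation lesions at fixed lateral offsets, optional low-amplitude "side-lobe"
streaks flanking each lesion, depth-dependent fluence decay, a smooth
system-sensitivity field, per-pixel spectral jitter and additive Gaussian
noise.  Ground-truth masks mark lesion interiors as ablated, background
tissue as non-ablated, and a boundary band (wider axially than laterally)
plus the water region as unlabeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from pals.core_io import (
    ABLATED,
    NON_ABLATED,
    UNLABELED,
    STATE_RAW,
    FluenceSpectrum,
    Frame,
    LabelMask,
    MWPACube,
    USImage,
    ValidationError,
    WavelengthGrid,
    make_grid,
)

WATER = 0
TISSUE = 1
LESION_BASE = 2  # lesion k occupies code LESION_BASE + k

_RATIO_WINDOW_NM = (720.0, 790.0)


def nonablated_spectrum(grid: WavelengthGrid) -> np.ndarray:
    """Deoxyhemoglobin-like background absorption (1/cm): a 760-nm feature
    on a declining near-infrared baseline."""
    wl = grid.to_array()
    return (
        0.45
        + 3.1 * np.exp(-(wl - 690.0) / 75.0)
        + 1.1 * np.exp(-(((wl - 758.0) / 20.0) ** 2))
    )


def ablated_spectrum(grid: WavelengthGrid) -> np.ndarray:
    """Lesion absorption (1/cm), elevated relative to background with the
    largest ablated:non-ablated ratio near 780 nm."""
    wl = grid.to_array()
    ratio = 1.0 + 0.8 * np.exp(-(((wl - 780.0) / 45.0) ** 2))
    return ratio * nonablated_spectrum(grid)


def default_fluence(grid: WavelengthGrid) -> FluenceSpectrum:
    """Smooth pulse-energy spectrum peaking at 14.74 mJ near 715 nm and
    approaching 7.93 mJ at 950 nm."""
    wl = grid.to_array()
    energy = 7.93 + (14.74 - 7.93) * np.exp(-(((wl - 715.0) / 150.0) ** 2))
    return FluenceSpectrum(grid=grid, energy_mJ=energy)


@dataclass
class PhantomConfig:
    """All forward-model fields and scene-geometry parameters."""

    grid: WavelengthGrid
    height_px: int
    width_px: int
    pixel_pitch_um: float
    mu_abs_nonablated: np.ndarray
    mu_abs_ablated: np.ndarray
    fluence: FluenceSpectrum
    mu_eff: np.ndarray  # per-wavelength effective attenuation, 1/cm
    grueneisen: float = 1.0
    sensitivity_amplitude: float = 0.15
    sensitivity_correlation_px: float = 8.0
    noise_sigma: float = 0.0
    spectrum_jitter_cv: float = 0.0
    surface_depth_mm: float = 4.0
    lesion_depth_mm: float = 8.0
    lesion_axes_mm: tuple[float, float] = (3.2, 1.8)  # (axial, lateral) semi-axes
    lesion_offsets_mm: tuple[float, ...] = (-5.0, 0.0, 5.0)
    boundary_band_px: int = 12
    side_lobes: bool = False
    sidelobe_blend: float = 0.75
    mu_water: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.mu_abs_nonablated = np.asarray(self.mu_abs_nonablated, dtype=float)
        self.mu_abs_ablated = np.asarray(self.mu_abs_ablated, dtype=float)
        self.mu_eff = np.asarray(self.mu_eff, dtype=float)
        n = len(self.grid)
        for name in ("mu_abs_nonablated", "mu_abs_ablated", "mu_eff"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have length {n}")
        if np.any(self.mu_abs_nonablated <= 0) or np.any(self.mu_abs_ablated <= 0):
            raise ValidationError("absorption spectra must be strictly positive")
        if self.noise_sigma < 0 or self.grueneisen <= 0 or self.boundary_band_px < 0:
            raise ValidationError("invalid noise/grueneisen/boundary parameters")
        ratio = self.mu_abs_ablated / self.mu_abs_nonablated
        peak_nm = self.grid.to_array()[int(np.argmax(ratio))]
        lo, hi = _RATIO_WINDOW_NM
        if not lo <= peak_nm <= hi:
            raise ValidationError(
                f"ablated:non-ablated ratio peaks at {peak_nm} nm, outside "
                f"[{lo}, {hi}] nm"
            )

    @property
    def pitch_cm(self) -> float:
        return self.pixel_pitch_um * 1e-4

    @property
    def pitch_mm(self) -> float:
        return self.pixel_pitch_um * 1e-3


def default_config(seed: int = 0, **overrides) -> PhantomConfig:
    """Full-scale configuration: 339 x 512 frames at 73.92-um pitch,
    53 wavelengths 690-950 nm."""
    grid = overrides.pop("grid", make_grid(690, 950, 5))
    cfg = dict(
        grid=grid,
        height_px=339,
        width_px=512,
        pixel_pitch_um=73.92,
        mu_abs_nonablated=nonablated_spectrum(grid),
        mu_abs_ablated=ablated_spectrum(grid),
        fluence=default_fluence(grid),
        mu_eff=np.full(len(grid), 0.8),
        noise_sigma=0.25,
        spectrum_jitter_cv=0.06,
        seed=seed,
    )
    cfg.update(overrides)
    return PhantomConfig(**cfg)


def reduced_config(seed: int = 0, **overrides) -> PhantomConfig:
    """Desk-scale configuration (96 x 128 frames at 4x coarser pitch)
    covering the same physical view; intended for tests and CI.  Lesions are
    slightly enlarged so they remain resolvable after the segmenter's 8x
    downsampling."""
    overrides.setdefault("height_px", 96)
    overrides.setdefault("width_px", 128)
    overrides.setdefault("pixel_pitch_um", 295.68)
    overrides.setdefault("lesion_axes_mm", (3.2, 1.8))
    overrides.setdefault("boundary_band_px", 8)
    return default_config(seed=seed, **overrides)


@dataclass
class Scene:
    """A rendered-ready description of one frame's tissue content."""

    tissue_map: np.ndarray  # H x W int codes (WATER/TISSUE/LESION_BASE+k)
    depth_map: np.ndarray  # H x W depth below tissue surface (cm); 0 in water
    mu_abs_field: np.ndarray  # H x W x Lambda absorption (1/cm)
    sidelobe_map: np.ndarray  # H x W bool
    surface_row: int
    lesions: list[tuple[int, int, float, float]]  # (row, col, ax_px, lat_px)


def _lesion_geometry(config: PhantomConfig, n_lesions: int):
    """Pixel-space lesion centers and semi-axes; order: left, center, right."""
    surface_row = int(round(config.surface_depth_mm / config.pitch_mm))
    row_c = surface_row + int(round(config.lesion_depth_mm / config.pitch_mm))
    a_ax = config.lesion_axes_mm[0] / config.pitch_mm
    a_lat = config.lesion_axes_mm[1] / config.pitch_mm
    lesions = []
    for k in range(n_lesions):
        offset_mm = config.lesion_offsets_mm[k]
        col_c = config.width_px / 2.0 + offset_mm / config.pitch_mm
        lesions.append((row_c, int(round(col_c)), a_ax, a_lat))
    return surface_row, lesions


def build_scene(
    config: PhantomConfig, n_lesions: int, rng: np.random.Generator | None = None
) -> Scene:
    """Lay out water, tissue block and ``n_lesions`` elliptical lesions.

    Lesions are placed at the configured lateral offsets from the frame
    centerline (first left, then center, then right) at a fixed focal depth.
    """
    if not 0 <= n_lesions <= len(config.lesion_offsets_mm):
        raise ValidationError(f"n_lesions must be in 0..{len(config.lesion_offsets_mm)}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    H, W, L = config.height_px, config.width_px, len(config.grid)
    surface_row, lesions = _lesion_geometry(config, n_lesions)

    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]
    tissue_map = np.where(rows >= surface_row, TISSUE, WATER).astype(np.int16)
    tissue_map = np.broadcast_to(tissue_map, (H, W)).copy()

    band_ax, band_lat = _band_widths(config)
    for k, (rc, cc, a_ax, a_lat) in enumerate(lesions):
        if (
            rc - a_ax - band_ax < 0
            or rc + a_ax + band_ax >= H
            or cc - a_lat - band_lat < 0
            or cc + a_lat + band_lat >= W
        ):
            raise ValidationError(f"lesion {k} (incl. boundary band) exceeds frame")
        rho = ((rows - rc) / a_ax) ** 2 + ((cols - cc) / a_lat) ** 2
        tissue_map[rho <= 1.0] = LESION_BASE + k

    sidelobe_map = np.zeros((H, W), dtype=bool)
    if config.side_lobes:
        for rc, cc, a_ax, a_lat in lesions:
            gap = int(np.ceil(a_lat + band_lat)) + 1
            half_len = max(2, int(round(a_lat)))
            for sign in (-1, 1):
                c0 = cc + sign * (gap + half_len)
                c_lo, c_hi = c0 - half_len, c0 + half_len
                # one-pixel-tall lateral streak: lesion-like spectrum,
                # texture unlike a real lesion
                sl = (slice(max(rc, 0), min(rc + 1, H)),
                      slice(max(c_lo, 0), min(c_hi + 1, W)))
                sidelobe_map[sl] = True
        sidelobe_map &= tissue_map == TISSUE

    depth_map = np.maximum(rows - surface_row, 0) * config.pitch_cm
    depth_map = np.broadcast_to(depth_map, (H, W)).astype(float).copy()
    depth_map[tissue_map == WATER] = 0.0

    mu = np.empty((H, W, L), dtype=np.float32)
    mu[:] = config.mu_water
    base = config.mu_abs_nonablated.astype(np.float32)
    lesion_spec = config.mu_abs_ablated.astype(np.float32)
    mu[tissue_map == TISSUE] = base
    mu[tissue_map >= LESION_BASE] = lesion_spec
    blend = config.sidelobe_blend
    mu[sidelobe_map] = blend * lesion_spec + (1.0 - blend) * base
    if config.spectrum_jitter_cv > 0:
        jitter = 1.0 + config.spectrum_jitter_cv * rng.standard_normal((H, W, L))
        in_tissue = tissue_map != WATER
        mu[in_tissue] *= np.clip(jitter, 0.1, None)[in_tissue].astype(np.float32)

    return Scene(
        tissue_map=tissue_map,
        depth_map=depth_map,
        mu_abs_field=mu,
        sidelobe_map=sidelobe_map,
        surface_row=surface_row,
        lesions=lesions,
    )


def _band_widths(config: PhantomConfig) -> tuple[int, int]:
    """Unlabeled-band half-widths (axial, lateral); the axial band is wider
    because lesion depth is less certain than lateral position."""
    band_ax = int(config.boundary_band_px)
    band_lat = int(round(band_ax * 0.5))
    return band_ax, band_lat


def _sensitivity_field(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative system-sensitivity field E(r) with mean 1."""
    H, W = config.height_px, config.width_px
    if config.sensitivity_amplitude == 0:
        return np.ones((H, W))
    noise = rng.standard_normal((H, W))
    smooth = ndimage.gaussian_filter(noise, sigma=config.sensitivity_correlation_px)
    span = np.abs(smooth).max()
    if span > 0:
        smooth = smooth / span * config.sensitivity_amplitude
    return 1.0 + smooth


def render_mwpa(
    config: PhantomConfig,
    scene: Scene,
    rng: np.random.Generator | None = None,
    sensitivity: np.ndarray | None = None,
) -> MWPACube:
    """Evaluate the forward model over the scene; returns a raw-state cube.

    ``sensitivity`` can be supplied to share one system-sensitivity field
    across several renders (all frames of one tissue block).
    """
    if scene.mu_abs_field.shape != (
        config.height_px,
        config.width_px,
        len(config.grid),
    ):
        raise ValidationError("scene and config dimensions disagree")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    E = sensitivity if sensitivity is not None else _sensitivity_field(config, rng)
    F = config.fluence.energy_mJ
    gamma = np.exp(-config.mu_eff[None, None, :] * scene.depth_map[:, :, None])
    v = (
        E[:, :, None]
        * config.grueneisen
        * scene.mu_abs_field
        * F[None, None, :]
        * gamma
    )
    if config.noise_sigma > 0:
        v = v + config.noise_sigma * rng.standard_normal(v.shape)
    v = np.clip(v, 0.0, None).astype(np.float32)
    return MWPACube(
        intensities=v,
        grid=config.grid,
        pixel_pitch_um=config.pixel_pitch_um,
        state=STATE_RAW,
    )


def render_us(
    config: PhantomConfig, scene: Scene, rng: np.random.Generator | None = None
) -> USImage:
    """Speckle-textured backdrop image with tissue/water contrast."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    H, W = scene.tissue_map.shape
    base = np.where(scene.tissue_map == WATER, 0.15, 0.6)
    speckle = rng.rayleigh(scale=1.0, size=(H, W))
    img = ndimage.gaussian_filter(base * speckle, sigma=0.8)
    return USImage(
        intensities=np.clip(img, 0, None).astype(np.float32),
        pixel_pitch_um=config.pixel_pitch_um,
    )


def make_mask(config: PhantomConfig, scene: Scene) -> LabelMask:
    """Ternary ground truth with an unlabeled boundary band around lesions.

    The band half-width is larger in the axial (row) direction than the
    lateral (column) direction, mirroring the labeling uncertainty of the
    emulated acquisition.
    """
    H, W = scene.tissue_map.shape
    codes = np.full((H, W), UNLABELED, dtype=np.uint8)
    codes[scene.tissue_map != WATER] = NON_ABLATED
    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]
    band_ax, band_lat = _band_widths(config)
    for rc, cc, a_ax, a_lat in scene.lesions:
        if band_ax > 0 or band_lat > 0:
            rho_band = ((rows - rc) / (a_ax + band_ax)) ** 2 + (
                (cols - cc) / (a_lat + band_lat)
            ) ** 2
            codes[(rho_band <= 1.0) & (codes == NON_ABLATED)] = UNLABELED
    for rc, cc, a_ax, a_lat in scene.lesions:
        rho = ((rows - rc) / a_ax) ** 2 + ((cols - cc) / a_lat) ** 2
        codes[rho <= 1.0] = ABLATED
    return LabelMask(codes=codes)


def make_frame(
    config: PhantomConfig,
    n_lesions: int,
    block_id: str = "block00",
    scene_rng: np.random.Generator | None = None,
    render_rng: np.random.Generator | None = None,
) -> Frame:
    """Convenience wrapper: scene + cube + US + mask for one frame."""
    scene = build_scene(config, n_lesions, rng=scene_rng)
    cube = render_mwpa(config, scene, rng=render_rng)
    us = render_us(config, scene, rng=np.random.default_rng(config.seed + 7))
    mask = make_mask(config, scene)
    return Frame(cube=cube, us=us, mask=mask, block_id=block_id, n_lesions=n_lesions)


def make_study(
    config: PhantomConfig, n_blocks: int, frames_per_block: int
) -> list[Frame]:
    """Emulate the acquisition schedule: each block is imaged after
    0, 1, ..., frames_per_block-1 ablations.

    Block-level variation (spectral tilt, sensitivity field, pixel jitter)
    is shared across a block's frames; per-frame noise differs.
    """
    if frames_per_block < 1:
        raise ValidationError("frames_per_block must be >= 1")
    frames: list[Frame] = []
    root = np.random.SeedSequence(config.seed)
    block_seeds = root.spawn(n_blocks)
    wl = config.grid.to_array()
    for b in range(n_blocks):
        block_rng = np.random.default_rng(block_seeds[b])
        tilt = block_rng.normal(0.0, 0.15)
        tilt_factor = (wl / wl.mean()) ** tilt
        block_cfg = replace(
            config,
            mu_abs_nonablated=config.mu_abs_nonablated * tilt_factor,
            mu_abs_ablated=config.mu_abs_ablated * tilt_factor,
        )
        # Shared per-block fields: jitter realization and sensitivity field.
        scene_rng_state = np.random.default_rng(block_seeds[b].spawn(1)[0])
        jitter_seed = scene_rng_state.integers(2**31)
        sens_seed = scene_rng_state.integers(2**31)
        block_id = f"block{b:02d}"
        sensitivity = _sensitivity_field(block_cfg, np.random.default_rng(sens_seed))
        for f in range(frames_per_block):
            n_lesions = min(f, len(config.lesion_offsets_mm))
            scene = build_scene(
                block_cfg, n_lesions, rng=np.random.default_rng(jitter_seed)
            )
            render_rng = np.random.default_rng([sens_seed, f])
            cube = render_mwpa(block_cfg, scene, rng=render_rng, sensitivity=sensitivity)
            us = render_us(
                block_cfg, scene, rng=np.random.default_rng([sens_seed, f, 1])
            )
            mask = make_mask(block_cfg, scene)
            frames.append(
                Frame(cube=cube, us=us, mask=mask, block_id=block_id, n_lesions=n_lesions)
            )
    return frames
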