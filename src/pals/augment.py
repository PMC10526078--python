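"""Training-set augmentation: x24 per input frame.

Six photometric variants (original, two Gaussian-noise draws, three box-blur
sizes) crossed with four geometric orientations (identity, vertical flip,
horizontal flip, 180-degree rotation).  Photometric operations act on the
image cube only; geometric operations are applied consistently to the cube,
the ultrasound image and the label mask.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from pals.core_io import Frame, LabelMask, MWPACube, ValidationError

BLUR_SIZES = (3, 5, 7)


def blur(cube: MWPACube, k: int) -> MWPACube:
    """Smooth each wavelength channel with a k x k mean filter
    (edge-replicated borders)."""
    if k % 2 == 0:
        raise ValidationError(f"blur window must be odd, got {k}")
    out = ndimage.uniform_filter(
        cube.intensities, size=(k, k, 1), mode="nearest"
    ).astype(np.float32)
    return dataclasses.replace(cube, intensities=out)


def corrupt_noise(cube: MWPACube, sigma: float, seed: int) -> MWPACube:
    """Add i.i.d. zero-mean Gaussian noise per element, clipped to >= 0."""
    if sigma <= 0:
        raise ValidationError(f"sigma must be positive, got {sigma}")
    rng = np.random.default_rng(seed)
    out = cube.intensities + sigma * rng.standard_normal(cube.intensities.shape)
    out = np.clip(out, 0.0, None).astype(np.float32)
    return dataclasses.replace(cube, intensities=out)


def _apply_geometric(frame: Frame, op) -> Frame:
    cube = dataclasses.replace(
        frame.cube, intensities=np.ascontiguousarray(op(frame.cube.intensities))
    )
    us = dataclasses.replace(
        frame.us, intensities=np.ascontiguousarray(op(frame.us.intensities))
    )
    mask = LabelMask(codes=np.ascontiguousarray(op(frame.mask.codes)))
    return dataclasses.replace(frame, cube=cube, us=us, mask=mask)


def geometric_variants(frame: Frame) -> list[Frame]:
    """{identity, flip up-down, flip left-right, rotate 180} applied
    consistently to cube, US and mask."""
    ops = [
        lambda a: a,
        lambda a: np.flip(a, axis=0),
        lambda a: np.flip(a, axis=1),
        lambda a: np.flip(np.flip(a, axis=0), axis=1),
    ]
    return [_apply_geometric(frame, op) for op in ops]


def photometric_variants(frame: Frame, sigma: float, seed: int) -> list[Frame]:
    """Original, two noise draws, three blur sizes — six cubes, masks untouched."""
    variants = [frame]
    for j in range(2):
        variants.append(
            dataclasses.replace(frame, cube=corrupt_noise(frame.cube, sigma, seed + j))
        )
    for k in BLUR_SIZES:
        variants.append(dataclasses.replace(frame, cube=blur(frame.cube, k)))
    return variants


def augment_set(
    frames: list[Frame], sigma: float = 0.05, seed: int = 0
) -> list[Frame]:
    """Expand each frame into 24 variants (6 photometric x 4 geometric)."""
    if not frames:
        raise ValidationError("augment_set requires a nonempty frame list")
    out: list[Frame] = []
    for i, frame in enumerate(frames):
        for variant in photometric_variants(frame, sigma, seed + 1000 * i):
            out.extend(geometric_variants(variant))
    return out
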