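"""Two-step spectral normalization of raw MWPA cubes.

Step 1 divides each channel by the measured laser pulse energy at that
wavelength; step 2 divides each pixel spectrum by its own maximum.  The
result is a per-pixel normalized absorption spectrum in [0, 1], invariant
to any positive per-pixel rescaling of the raw data (system sensitivity,
Grueneisen coefficient, global fluence scale).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from pals.core_io import (
    STATE_FLUENCE_NORMALIZED,
    STATE_MAX_NORMALIZED,
    STATE_RAW,
    FluenceSpectrum,
    Frame,
    MWPACube,
    ValidationError,
)


def normalize_fluence(cube: MWPACube, fluence: FluenceSpectrum) -> MWPACube:
    """Divide each wavelength channel by the laser pulse energy F(lambda)."""
    if cube.state != STATE_RAW:
        raise ValidationError(f"expected a raw cube, got state {cube.state!r}")
    if tuple(fluence.grid.values) != tuple(cube.grid.values):
        raise ValidationError("fluence grid does not match cube grid")
    if np.any(fluence.energy_mJ <= 0):
        raise ValidationError("pulse energy must be strictly positive")
    out = cube.intensities / fluence.energy_mJ.astype(np.float32)[None, None, :]
    return MWPACube(
        intensities=out,
        grid=cube.grid,
        pixel_pitch_um=cube.pixel_pitch_um,
        state=STATE_FLUENCE_NORMALIZED,
    )


def normalize_max(cube: MWPACube) -> MWPACube:
    """Divide each pixel spectrum by its own maximum element.

    All-zero pixel spectra are left as zero vectors.  Negative amplitudes
    (possible in beamformed real data) are clipped to zero first.
    Idempotent: applying twice equals applying once.
    """
    if cube.state not in (STATE_FLUENCE_NORMALIZED, STATE_MAX_NORMALIZED):
        raise ValidationError(
            f"expected a fluence- or max-normalized cube, got {cube.state!r}"
        )
    v = np.clip(cube.intensities, 0.0, None)
    peak = v.max(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(peak > 0, v / peak, 0.0).astype(np.float32)
    return MWPACube(
        intensities=out,
        grid=cube.grid,
        pixel_pitch_um=cube.pixel_pitch_um,
        state=STATE_MAX_NORMALIZED,
    )


def preprocess_cube(cube: MWPACube, fluence: FluenceSpectrum) -> MWPACube:
    """Fluence normalization followed by per-pixel max normalization."""
    return normalize_max(normalize_fluence(cube, fluence))


def preprocess_frame(frame: Frame, fluence: FluenceSpectrum) -> Frame:
    """Return a frame whose cube has been normalized; US and mask untouched."""
    return dataclasses.replace(frame, cube=preprocess_cube(frame.cube, fluence))
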