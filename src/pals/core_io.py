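"""Domain types and file I/O shared by all pipeline stages.

Image cubes are stored either as multi-page TIFF (one page per wavelength,
pages in ascending-wavelength order) or as an HDF5 container with datasets
``intensities``, ``wavelengths_nm``, ``pixel_pitch_um`` and ``state``.
Label masks are single-page 8-bit images with the code mapping
0 = unlabeled, 1 = non-ablated, 2 = ablated.  Laser pulse-energy spectra
are CSV files with header ``wavelength_nm,energy_mJ``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from PIL import Image

# Label codes (8-bit mask values).
UNLABELED = 0
NON_ABLATED = 1
ABLATED = 2

# Cube provenance states.
STATE_RAW = "raw"
STATE_FLUENCE_NORMALIZED = "fluence_normalized"
STATE_MAX_NORMALIZED = "max_normalized"
_STATES = (STATE_RAW, STATE_FLUENCE_NORMALIZED, STATE_MAX_NORMALIZED)


class FormatError(ValueError):
    """Raised when a file does not match the expected on-disk layout."""


class ValidationError(ValueError):
    """Raised when in-memory data violates a domain invariant."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered set of imaging wavelengths in nanometres.

    A regular grid is described by ``start_nm``/``stop_nm``/``step_nm``;
    irregular grids (produced by wavelength subsetting) carry explicit
    ``values`` and have ``step_nm`` set to ``None``.
    """

    start_nm: float
    stop_nm: float
    step_nm: float | None
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise ValidationError("wavelength grid must contain at least one value")
        if np.any(np.diff(v) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if self.step_nm is not None:
            expected = self.start_nm + self.step_nm * np.arange(v.size)
            if not np.allclose(v, expected):
                raise ValidationError("values inconsistent with start/step")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "WavelengthGrid":
        vals = tuple(float(v) for v in values)
        return cls(start_nm=vals[0], stop_nm=vals[-1], step_nm=None, values=vals)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of a wavelength in the grid; raises if absent."""
        arr = np.asarray(self.values)
        hits = np.nonzero(np.isclose(arr, wavelength_nm))[0]
        if hits.size == 0:
            raise ValidationError(f"wavelength {wavelength_nm} nm not in grid")
        return int(hits[0])

    def to_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def make_grid(start_nm: float, stop_nm: float, step_nm: float) -> WavelengthGrid:
    """Build a regular wavelength grid from ``start_nm`` to ``stop_nm`` inclusive.

    ``(stop_nm - start_nm)`` must be an integer multiple of ``step_nm``;
    e.g. ``make_grid(690, 950, 5)`` yields 53 wavelengths.
    """
    if step_nm <= 0:
        raise ValidationError(f"step_nm must be positive, got {step_nm}")
    if stop_nm < start_nm:
        raise ValidationError("stop_nm must be >= start_nm")
    span = stop_nm - start_nm
    n_steps = span / step_nm
    remainder = span - round(n_steps) * step_nm
    if abs(remainder) > 1e-9 * max(1.0, abs(span)):
        raise ValidationError(
            f"range ({start_nm}, {stop_nm}) not divisible by step {step_nm}: "
            f"remainder {remainder}"
        )
    count = int(round(n_steps)) + 1
    values = tuple(float(start_nm + k * step_nm) for k in range(count))
    return WavelengthGrid(float(start_nm), float(stop_nm), float(step_nm), values)


@dataclass
class MWPACube:
    """H x W x Lambda intensity cube with provenance state."""

    intensities: np.ndarray
    grid: WavelengthGrid
    pixel_pitch_um: float
    state: str = STATE_RAW

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.ndim != 3:
            raise ValidationError("intensities must be H x W x Lambda")
        if self.intensities.shape[2] != len(self.grid):
            raise ValidationError(
                f"channel count {self.intensities.shape[2]} != grid length "
                f"{len(self.grid)}"
            )
        if self.state not in _STATES:
            raise ValidationError(f"unknown state {self.state!r}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities must be finite")
        if self.state in (STATE_RAW, STATE_FLUENCE_NORMALIZED):
            if np.any(self.intensities < 0):
                raise ValidationError(f"negative values in a {self.state} cube")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def height(self) -> int:
        return self.intensities.shape[0]

    @property
    def width(self) -> int:
        return self.intensities.shape[1]


@dataclass
class USImage:
    """Co-registered single-channel ultrasound image."""

    intensities: np.ndarray
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.ndim != 2:
            raise ValidationError("US image must be 2-D")
        if np.any(self.intensities < 0):
            raise ValidationError("US intensities must be non-negative")


@dataclass
class LabelMask:
    """Ternary per-pixel ground truth: ablated / non-ablated / unlabeled."""

    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2:
            raise ValidationError("mask must be 2-D")
        bad = ~np.isin(self.codes, (UNLABELED, NON_ABLATED, ABLATED))
        if np.any(bad):
            raise ValidationError(
                f"mask contains invalid codes {sorted(np.unique(self.codes[bad]))}"
            )

    def count(self, code: int) -> int:
        return int(np.count_nonzero(self.codes == code))


@dataclass
class FluenceSpectrum:
    """Per-wavelength laser pulse energy (mJ) measured at the fiber output."""

    grid: WavelengthGrid
    energy_mJ: np.ndarray

    def __post_init__(self) -> None:
        self.energy_mJ = np.asarray(self.energy_mJ, dtype=float)
        if self.energy_mJ.ndim != 1 or self.energy_mJ.size != len(self.grid):
            raise ValidationError("energy length must equal grid length")
        if np.any(self.energy_mJ <= 0):
            raise ValidationError("pulse energy must be strictly positive")


@dataclass
class Frame:
    """One co-registered acquisition: MWPA cube + US image + label mask."""

    cube: MWPACube
    us: USImage
    mask: LabelMask
    block_id: str
    n_lesions: int

    def __post_init__(self) -> None:
        hw = self.cube.intensities.shape[:2]
        if self.us.intensities.shape != hw or self.mask.codes.shape != hw:
            raise ValidationError("cube, US and mask must share H x W")
        if not 0 <= self.n_lesions <= 3:
            raise ValidationError("n_lesions must be in 0..3")


@dataclass
class SegmentationResult:
    """Per-pixel class scores plus the binary decision map.

    ``scores`` is H x W x 2 (channel 0: non-ablated, channel 1: ablated);
    ``decision`` is the H x W argmax over channels with ties resolved to
    non-ablated (0).
    """

    scores: np.ndarray
    decision: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float32)
        self.decision = np.asarray(self.decision, dtype=np.uint8)
        if self.scores.ndim != 3 or self.scores.shape[2] != 2:
            raise ValidationError("scores must be H x W x 2")
        if self.decision.shape != self.scores.shape[:2]:
            raise ValidationError("decision must share H x W with scores")

    @classmethod
    def from_scores(cls, scores: np.ndarray) -> "SegmentationResult":
        scores = np.asarray(scores, dtype=np.float32)
        decision = (scores[:, :, 1] > scores[:, :, 0]).astype(np.uint8)
        return cls(scores=scores, decision=decision)


# ---------------------------------------------------------------------------
# Acquisition arithmetic
# ---------------------------------------------------------------------------

def acquisition_frame_rate(
    repetition_hz: float,
    firings_per_wavelength: int,
    wavelengths_per_frame: int,
) -> float:
    """Maximum MWPA frame rate of a pulsed-laser acquisition system.

    frames/s = laser repetition rate / firings per wavelength / wavelengths
    per frame, assuming no signal averaging.
    """
    if repetition_hz <= 0 or firings_per_wavelength < 1 or wavelengths_per_frame < 1:
        raise ValidationError("rates and counts must be positive")
    return repetition_hz / firings_per_wavelength / wavelengths_per_frame


def view_extent_cm(n_pixels: int, pixel_pitch_um: float) -> float:
    """Physical extent of ``n_pixels`` at ``pixel_pitch_um`` spacing, in cm."""
    return n_pixels * pixel_pitch_um * 1e-4


# ---------------------------------------------------------------------------
# Cube I/O
# ---------------------------------------------------------------------------

def write_cube(cube: MWPACube, path: str | Path) -> None:
    """Write a cube as multi-page TIFF (.tif/.tiff) or HDF5 (.h5/.hdf5)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        meta = {
            "wavelengths_nm": list(cube.grid.values),
            "pixel_pitch_um": cube.pixel_pitch_um,
            "state": cube.state,
        }
        pages = np.ascontiguousarray(np.moveaxis(cube.intensities, 2, 0))
        tifffile.imwrite(
            path,
            pages,
            photometric="minisblack",  # one page per wavelength, never RGB
            description=json.dumps(meta),
        )
    elif path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("intensities", data=cube.intensities)
            f.create_dataset("wavelengths_nm", data=cube.grid.to_array())
            f.create_dataset("pixel_pitch_um", data=cube.pixel_pitch_um)
            f.create_dataset("state", data=cube.state)
    else:
        raise FormatError(f"unsupported cube extension {path.suffix!r}")


def read_cube(path: str | Path) -> MWPACube:
    """Read a cube written by :func:`write_cube` (round-trips bit-exactly)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            desc = tf.pages[0].description
            try:
                meta = json.loads(desc)
                wavelengths = meta["wavelengths_nm"]
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise FormatError(f"missing cube metadata in {path}") from exc
            pages = tf.asarray()
        if pages.ndim == 2:
            pages = pages[None]
        if pages.shape[0] != len(wavelengths):
            raise FormatError(
                f"{path}: {pages.shape[0]} pages but {len(wavelengths)} wavelengths"
            )
        grid = _grid_from_values(wavelengths)
        return MWPACube(
            intensities=np.moveaxis(pages, 0, 2),
            grid=grid,
            pixel_pitch_um=float(meta["pixel_pitch_um"]),
            state=str(meta["state"]),
        )
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            for key in ("intensities", "wavelengths_nm", "pixel_pitch_um", "state"):
                if key not in f:
                    raise FormatError(f"{path}: missing dataset {key!r}")
            intensities = f["intensities"][()]
            wavelengths = f["wavelengths_nm"][()]
            pitch = float(f["pixel_pitch_um"][()])
            state = f["state"][()]
        if isinstance(state, bytes):
            state = state.decode()
        if intensities.shape[2] != len(wavelengths):
            raise FormatError(
                f"{path}: channel count {intensities.shape[2]} != "
                f"{len(wavelengths)} wavelengths"
            )
        return MWPACube(
            intensities=intensities,
            grid=_grid_from_values(wavelengths),
            pixel_pitch_um=pitch,
            state=str(state),
        )
    raise FormatError(f"unsupported cube extension {path.suffix!r}")


def _grid_from_values(values: Sequence[float]) -> WavelengthGrid:
    """Rebuild a grid from stored values, recovering regular step if present."""
    vals = np.asarray(values, dtype=float)
    if vals.size > 1:
        steps = np.diff(vals)
        if np.allclose(steps, steps[0]):
            return make_grid(vals[0], vals[-1], steps[0])
    elif vals.size == 1:
        return make_grid(vals[0], vals[0], 1.0)
    return WavelengthGrid.from_values(vals)


# ---------------------------------------------------------------------------
# Mask I/O
# ---------------------------------------------------------------------------

def write_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a mask as a single-page 8-bit PNG or TIFF."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        Image.fromarray(mask.codes, mode="L").save(path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, mask.codes)
    else:
        raise FormatError(f"unsupported mask extension {path.suffix!r}")


def read_mask(path: str | Path) -> LabelMask:
    path = Path(path)
    if path.suffix.lower() == ".png":
        codes = np.asarray(Image.open(path), dtype=np.uint8)
    elif path.suffix.lower() in (".tif", ".tiff"):
        codes = tifffile.imread(path)
    else:
        raise FormatError(f"unsupported mask extension {path.suffix!r}")
    return LabelMask(codes=codes)  # constructor validates code set


# ---------------------------------------------------------------------------
# Fluence spectrum I/O
# ---------------------------------------------------------------------------

def write_fluence(spectrum: FluenceSpectrum, path: str | Path) -> None:
    lines = ["wavelength_nm,energy_mJ"]
    for wl, e in zip(spectrum.grid.values, spectrum.energy_mJ):
        lines.append(f"{wl:g},{float(e)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fluence(path: str | Path) -> FluenceSpectrum:
    import csv

    wavelengths: list[float] = []
    energies: list[float] = []
    with open(path, newline="") as f:
        reader = csv.DictReader(f)
        if reader.fieldnames is None or not {"wavelength_nm", "energy_mJ"} <= set(
            reader.fieldnames
        ):
            raise FormatError(f"{path}: expected header wavelength_nm,energy_mJ")
        for row in reader:
            wavelengths.append(float(row["wavelength_nm"]))
            energies.append(float(row["energy_mJ"]))
    return FluenceSpectrum(
        grid=_grid_from_values(wavelengths), energy_mJ=np.asarray(energies)
    )
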