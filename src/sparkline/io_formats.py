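"""Reading and writing of line-scan images, label masks, parameter files and
event/summary tables.

Conventions used throughout the package:

* axis 0 = time (scan lines), axis 1 = space (pixels along the scanned line);
* times are milliseconds from the start of the recording, positions are
  micrometres from the start of the scan line;
* intervals (bounding boxes, windows) are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.measure import label as cc_label


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted."""


@dataclass
class LineScanImage:
    """A calibrated confocal line-scan record (kymograph).

    Parameters
    ----------
    pixels
        2D array of non-negative fluorescence counts, axis 0 = time (lines),
        axis 1 = space.
    time_step
        Milliseconds per scan line.
    pixel_size
        Micrometres per spatial pixel.
    bit_depth
        Bit depth of the acquisition (values must fit in it).
    source_path
        Origin of the data, for bookkeeping only.
    """

    pixels: np.ndarray
    time_step: float
    pixel_size: float
    bit_depth: int = 12
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("line-scan image must be 2D (time x space)")
        if self.pixels.shape[0] < 16 or self.pixels.shape[1] < 16:
            raise ValueError(
                "line-scan image must have at least 16 lines and 16 spatial pixels"
            )
        if not (self.time_step > 0 and self.pixel_size > 0):
            raise ValueError("time_step and pixel_size must be positive")
        if self.pixels.size and float(self.pixels.min()) < 0:
            raise ValueError("pixel values must be non-negative")
        if self.pixels.size and float(self.pixels.max()) > 2**self.bit_depth - 1:
            raise ValueError(
                f"pixel values exceed the {self.bit_depth}-bit range"
            )

    @property
    def n_lines(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def duration_ms(self) -> float:
        return self.n_lines * self.time_step

    @property
    def scan_length_um(self) -> float:
        return self.n_pixels * self.pixel_size


@dataclass
class LabelMask:
    """Integer event-segmentation mask; 0 = background, k > 0 = event k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label mask must be integer-valued")
        if self.labels.size and int(self.labels.min()) < 0:
            raise ValueError("label mask must be non-negative")

    @property
    def n_events(self) -> int:
        return int(self.labels.max(initial=0))

    def pixel_set(self, label: int) -> np.ndarray:
        """Boolean mask of one event's pixels."""
        return self.labels == label

    def relabel_sequential(self) -> "LabelMask":
        """Map labels onto a gapless {0..K} set, preserving order."""
        values = np.unique(self.labels)
        values = values[values > 0]
        lut = np.zeros(int(self.labels.max(initial=0)) + 1, dtype=self.labels.dtype)
        lut[values] = np.arange(1, len(values) + 1, dtype=self.labels.dtype)
        return LabelMask(lut[self.labels])


@dataclass
class DetectionParams:
    """Tunable parameters of the event-detection pipeline.

    All physical parameters are in micrometres / milliseconds; thresholds on
    the combined detection score live on a [0, 1] scale.  The default
    ``detect_threshold`` of 0.45 is the sensitive setting; 0.6 is the
    conventional less-sensitive alternative.
    """

    detect_threshold: float = 0.45
    candidate_z: float = 2.0
    denoise_sigma_space: float = 0.2  # µm
    denoise_sigma_time: float = 4.0  # ms
    long_spark_min_duration: float = 150.0  # ms
    wave_min_width: float = 25.0  # µm
    miniwave_min_width: float = 8.0  # µm
    split_min_distance: float = 1.2  # µm
    split_min_distance_time: float = 12.0  # ms
    split_min_prominence: float = 0.3  # ΔF/F0
    min_event_area: float = 1.0  # µm·ms
    baseline_exclusion_z: float = 2.0
    connectivity: int = 8
    score_z_half: float = 8.0
    score_area_half: float = 30.0  # µm·ms

    def __post_init__(self) -> None:
        if not 0.0 <= self.detect_threshold <= 1.0:
            raise ValueError("detect_threshold must lie in [0, 1]")
        if not self.miniwave_min_width < self.wave_min_width:
            raise ValueError("miniwave_min_width must be below wave_min_width")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        for name in (
            "denoise_sigma_space",
            "denoise_sigma_time",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in (
            "long_spark_min_duration",
            "wave_min_width",
            "miniwave_min_width",
            "split_min_distance",
            "split_min_distance_time",
            "split_min_prominence",
            "min_event_area",
            "baseline_exclusion_z",
            "score_z_half",
            "score_area_half",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "DetectionParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown detection parameters: {sorted(unknown)}")
        return cls(**data)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "DetectionParams":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def replace(self, **kwargs) -> "DetectionParams":
        return dataclasses.replace(self, **kwargs)


def _read_gray_array(path) -> np.ndarray:
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalise reader errors
        raise FormatError(f"cannot read image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise FormatError(f"{path}: RGB(A) images are not supported")
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-page 2D grayscale image")
    return arr


def _orient(arr: np.ndarray, orientation: str) -> tuple[np.ndarray, bool]:
    if orientation == "time_rows":
        return arr, False
    if orientation == "time_cols":
        return arr.T, True
    if orientation == "auto":
        # line-scan records are time-dominant: the longer axis is time
        if arr.shape[0] >= arr.shape[1]:
            return arr, False
        return arr.T, True
    raise ValueError("orientation must be one of auto, time_rows, time_cols")


def read_linescan(
    path,
    orientation: str = "auto",
    time_step: float | None = None,
    pixel_size: float | None = None,
) -> LineScanImage:
    """Read a grayscale TIFF/PNG line scan.

    ``orientation`` controls which file axis is time: ``"time_rows"`` keeps the
    file layout, ``"time_cols"`` transposes, and ``"auto"`` makes the longer
    axis time.  Calibration is taken from the flags; for TIFFs written by this
    package it falls back to embedded metadata.
    """
    arr = _read_gray_array(path)
    meta = read_calibration(path)
    if time_step is None:
        time_step = meta.get("time_step")
    if pixel_size is None:
        pixel_size = meta.get("pixel_size")
    if time_step is None or pixel_size is None:
        raise ValueError(
            "time_step and pixel_size must be given (no calibration metadata found)"
        )
    if time_step <= 0 or pixel_size <= 0:
        raise ValueError("calibration values must be positive")
    arr, transposed = _orient(arr, orientation)
    bit_depth = meta.get("bit_depth")
    if bit_depth is None:
        bit_depth = _infer_bit_depth(arr)
    img = LineScanImage(
        pixels=arr,
        time_step=float(time_step),
        pixel_size=float(pixel_size),
        bit_depth=int(bit_depth),
        source_path=str(path),
    )
    img.transposed_on_read = transposed
    return img


def _infer_bit_depth(arr: np.ndarray) -> int:
    vmax = float(arr.max(initial=0))
    for bits in (8, 12, 16):
        if vmax <= 2**bits - 1:
            return bits
    return 32


def read_calibration(path) -> dict:
    """Calibration metadata embedded in a TIFF description, if any."""
    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        return {}
    try:
        with tifffile.TiffFile(path) as tf:
            desc = tf.pages[0].description
        data = json.loads(desc)
        return data if isinstance(data, dict) else {}
    except Exception:  # noqa: BLE001 - absent/foreign metadata is not an error
        return {}


def write_linescan(image: LineScanImage, path) -> None:
    """Write a line scan as single-page grayscale TIFF with calibration
    metadata in the page description (JSON)."""
    meta = {
        "time_step": image.time_step,
        "pixel_size": image.pixel_size,
        "bit_depth": image.bit_depth,
        "axes": "time,space",
    }
    arr = image.pixels
    if not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float32)
    tifffile.imwrite(path, arr, description=json.dumps(meta))


def read_mask(path, relabel: bool = False, orientation: str = "auto") -> LabelMask:
    """Read an integer label mask (TIFF/PNG).

    With ``relabel=True`` a binary mask is split into 8-connected components.
    """
    arr = _read_gray_array(path)
    if not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr != np.round(arr)):
            raise FormatError(f"{path}: mask must be integer-valued")
        arr = arr.astype(np.int64)
    arr, _ = _orient(arr, orientation)
    if relabel:
        arr = cc_label(arr > 0, connectivity=2)
    return LabelMask(arr.astype(np.int32))


def write_mask(mask: LabelMask, path) -> None:
    seq = mask.relabel_sequential()
    tifffile.imwrite(path, seq.labels.astype(np.int32))


# ---------------------------------------------------------------------------
# Event and summary tables

#: Column order of the per-event CSV (documented, stable).
EVENT_COLUMNS = [
    "id",
    "class",
    "t_start_ms",
    "t_end_ms",
    "x_start_um",
    "x_end_um",
    "peak_time_ms",
    "peak_position_um",
    "amplitude",
    "peak_f_f0",
    "full_width_um",
    "fwhm_um",
    "full_duration_ms",
    "fdhm_ms",
    "time_to_peak_ms",
    "tau_decay_ms",
    "score",
]

#: Numeric feature columns summarised with median and IQR.
FEATURE_COLUMNS = [
    "amplitude",
    "peak_f_f0",
    "full_width_um",
    "fwhm_um",
    "full_duration_ms",
    "fdhm_ms",
    "time_to_peak_ms",
    "tau_decay_ms",
]


def events_to_frame(events) -> pd.DataFrame:
    """Per-event table in the documented column order.

    ``events`` is a sequence of objects exposing a ``row()`` dict (see
    ``sparkline.features.MeasuredEvent``).
    """
    rows = [ev.row() for ev in events]
    frame = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return frame


def write_event_tables(events, summary, event_path, summary_path) -> None:
    """Write the per-event CSV and the one-row recording summary CSV.

    Quartiles in the summary use linear interpolation between order
    statistics.  Missing values are written as empty fields.
    """
    frame = events_to_frame(events)
    frame.to_csv(event_path, index=False)
    summary.to_frame().to_csv(summary_path, index=False)
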