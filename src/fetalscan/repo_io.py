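"""Repository walking, DICOM header/pixel access and CSV manifests.

A retrospective study starts from a directory tree of DICOM objects — 2D
B-mode stills, multi-frame cine loops, Doppler overlays, dual displays —
accumulated over years from several scanner vendors.  This module exposes
exactly the header fields the triage cascade needs (frame count, dimensions,
photometric interpretation, pixel spacing) without decoding pixel data until
a stage actually asks for it, and provides the CSV manifest type every
pipeline stage reads and writes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pydicom
import pandas as pd

logger = logging.getLogger(__name__)


class Photometric(Enum):
    GRAY = "GRAY"
    RGB = "RGB"


@dataclass(frozen=True)
class UltrasoundFile:
    """One DICOM object with the header fields the triage cascade needs.

    ``number_of_frames`` mirrors DICOM tag (0028,0008); its mere presence
    with a value > 1 marks a cine loop, so triage never decodes frames.
    """

    source_id: str
    rows: int
    cols: int
    photometric: Photometric
    number_of_frames: Optional[int] = None
    pixel_spacing_mm: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if self.number_of_frames is not None and self.number_of_frames < 1:
            raise ValueError("number_of_frames must be >= 1 when present")
        if self.pixel_spacing_mm is not None:
            if any(s <= 0 for s in self.pixel_spacing_mm):
                raise ValueError("pixel spacing components must be > 0")


@dataclass
class ImageRecord:
    """Decoded pixels of one frame, rescaled to the 8-bit range.

    ``pixels`` is (rows, cols) float for grayscale or (rows, cols, 3) for
    color, values in [0, 255].
    """

    source_id: str
    pixels: np.ndarray
    pixel_spacing_mm: Optional[Tuple[float, float]] = None

    @property
    def is_color(self) -> bool:
        return self.pixels.ndim == 3


@dataclass
class Manifest:
    """Per-stage audit table: one row per DICOM object per pipeline stage.

    Stored as CSV (UTF-8, header row) so a hospital-scale run remains
    auditable with ordinary tools.  All values are kept as strings so a
    write/read round trip is lossless field-for-field.  CSV cannot represent
    "key absent" distinctly from "empty value", so rows should carry a
    homogeneous set of auxiliary keys per stage; an absent value reads back
    as the empty string.
    """

    rows: list = field(default_factory=list)

    COLUMNS = ("source_id", "stage", "label")

    def append(self, source_id: str, stage: str, label: str, **aux: str) -> None:
        row = {"source_id": str(source_id), "stage": str(stage), "label": str(label)}
        row.update({str(k): str(v) for k, v in aux.items()})
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, dtype=str)

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Manifest):
            return NotImplemented
        return self.rows == other.rows


def _parse_header(path: Path) -> Optional[UltrasoundFile]:
    try:
        ds = pydicom.dcmread(path, stop_before_pixels=True)
    except Exception:  # noqa: BLE001 - any parse failure means "not a DICOM", skip
        return None
    try:
        rows = int(ds.Rows)
        cols = int(ds.Columns)
    except AttributeError:
        return None
    nof = getattr(ds, "NumberOfFrames", None)
    nof = int(nof) if nof is not None else None
    samples = int(getattr(ds, "SamplesPerPixel", 1))
    photometric = Photometric.RGB if samples == 3 else Photometric.GRAY
    spacing = getattr(ds, "PixelSpacing", None)
    spacing_mm: Optional[Tuple[float, float]] = None
    if spacing is not None and len(spacing) == 2:
        r, c = float(spacing[0]), float(spacing[1])
        if r > 0 and c > 0:
            spacing_mm = (r, c)
    return UltrasoundFile(
        source_id=str(path),
        rows=rows,
        cols=cols,
        photometric=photometric,
        number_of_frames=nof,
        pixel_spacing_mm=spacing_mm,
    )


def scan_repository(root) -> list:
    """Walk ``root`` and return one :class:`UltrasoundFile` per parseable DICOM.

    Files are visited in deterministic lexicographic order; unparseable files
    are logged and skipped (never fatal).  Only headers are read.

    Raises
    ------
    FileNotFoundError
        If ``root`` does not exist.
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(f"repository root does not exist: {root}")
    records = []
    skipped = 0
    for path in sorted(p for p in root.rglob("*") if p.is_file()):
        rec = _parse_header(path)
        if rec is None:
            skipped += 1
            logger.warning("skipping unparseable file: %s", path)
            continue
        records.append(rec)
    logger.info("scanned %s: %d DICOM objects, %d skipped", root, len(records), skipped)
    return records


def _rescale_to_8bit(arr: np.ndarray) -> np.ndarray:
    """Linear rescale by the array maximum so peak intensity maps to 255.

    Cascade thresholds are stated for 8-bit-scale intensities, so deeper
    bit depths are normalised up front.
    """
    arr = arr.astype(np.float64)
    mx = arr.max() if arr.size else 0.0
    if mx > 255.0:
        arr = arr * (255.0 / mx)
    return np.clip(arr, 0.0, 255.0)


def load_pixels(file: UltrasoundFile, frame_index: int = 0) -> ImageRecord:
    """Decode one frame of ``file``, rescaled to [0, 255].

    Color (RGB) content is preserved as a 3-channel array; palette/YBR
    variants are normalised to RGB by pydicom's pixel handlers.
    """
    ds = pydicom.dcmread(file.source_id)
    arr = ds.pixel_array
    n_frames = file.number_of_frames or 1
    if frame_index < 0 or frame_index >= n_frames:
        raise IndexError(
            f"frame_index {frame_index} out of range for {file.source_id} "
            f"({n_frames} frame(s))"
        )
    if n_frames > 1:
        arr = arr[frame_index]
    arr = _rescale_to_8bit(arr)
    if arr.ndim == 3 and arr.shape[-1] != 3:
        raise ValueError(f"unsupported channel layout in {file.source_id}")
    return ImageRecord(
        source_id=file.source_id,
        pixels=arr,
        pixel_spacing_mm=file.pixel_spacing_mm,
    )


def write_manifest(manifest: Manifest, path) -> None:
    """Write ``manifest`` as a UTF-8 CSV with a fixed leading header."""
    df = manifest.to_frame()
    if df.empty:
        df = pd.DataFrame(columns=list(Manifest.COLUMNS))
    else:
        fixed = [c for c in Manifest.COLUMNS if c in df.columns]
        rest = [c for c in df.columns if c not in Manifest.COLUMNS]
        df = df[fixed + rest]
    df.to_csv(path, index=False, encoding="utf-8")


def read_manifest(path) -> Manifest:
    """Read a CSV manifest written by :func:`write_manifest`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    m = Manifest()
    for _, row in df.iterrows():
        m.rows.append({k: v for k, v in row.items()})
    return m
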