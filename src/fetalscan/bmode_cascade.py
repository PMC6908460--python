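"""Four-filter cascade routing DICOM objects to the B-mode stream.

A hospital ultrasound repository mixes 2D B-mode stills with cine loops,
dual displays, color Doppler overlays, and M-mode/pulsed-Doppler traces.
The cascade applies four cheap sequential filters — the first positive
filter assigns its label and stops; whatever survives all four is B-mode:

1. *Video*: the DICOM NumberOfFrames header (0028,0008) is present and > 1.
   No pixel data is decoded.  4D rendered-surface snapshots are stored as
   multi-frame clips, so this filter removes them too.
2. *Dual display*: the column intensity profile has a deep trough (a
   near-black gutter between the two panels) near the middle of the frame.
3. *Color Doppler*: after RGB->HSV conversion, enough pixels carry real
   chroma (saturation and value both above t = 0.1).
4. *M-mode / pulsed Doppler*: the row-sum profile has a dominant peak in
   the top half (the B-mode reference strip) with topological prominence
   above 50000 and first-half/second-half peak ratio above 2.5 — the
   spectral trace below the strip keeps the bottom half dark.

The prominence and ratio bounds are empirical values for 8-bit intensities
summed across a ~800-pixel-wide frame; they are exposed in
:class:`CascadeConfig` together with an optional width-normalised mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.signal import find_peaks, peak_prominences
from skimage.color import rgb2hsv

from .repo_io import ImageRecord, Photometric, UltrasoundFile, load_pixels

logger = logging.getLogger(__name__)

# ITU-R 601 luma weights: deterministic standard grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


class ModalityLabel(Enum):
    VIDEO = "VIDEO"
    DUAL_DISPLAY = "DUAL_DISPLAY"
    COLOR_DOPPLER = "COLOR_DOPPLER"
    MMODE_OR_PULSED = "MMODE_OR_PULSED"
    BMODE = "BMODE"


class ProfileAxis(Enum):
    COLUMN_SUMS = "COLUMN_SUMS"
    ROW_SUMS = "ROW_SUMS"


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds and plumbing parameters of the four filters.

    ``color_threshold`` (t = 0.1), ``prominence_min`` (50000) and
    ``half_ratio_min`` (2.5) are the cascade's decision constants; the
    remaining fields quantify "trough near the middle" for the dual-display
    filter and guard the Doppler filter against chroma noise.

    ``normalize_profile`` divides row sums by the column count before the
    prominence test, making ``prominence_min`` width-independent (set a
    per-pixel bound when enabling it).
    """

    color_threshold: float = 0.1
    prominence_min: float = 50000.0
    half_ratio_min: float = 2.5
    gutter_window_frac: float = 0.2
    gutter_depth_frac: float = 0.2
    min_colored_frac: float = 0.001
    smooth_window: int = 11
    normalize_profile: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.color_threshold < 1.0:
            raise ValueError("color_threshold must be in (0,1)")
        if not 0.0 < self.gutter_window_frac < 1.0:
            raise ValueError("gutter_window_frac must be in (0,1)")
        if not 0.0 < self.gutter_depth_frac < 1.0:
            raise ValueError("gutter_depth_frac must be in (0,1)")
        if not 0.0 <= self.min_colored_frac < 1.0:
            raise ValueError("min_colored_frac must be in [0,1)")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and positive")


@dataclass
class IntensityProfile:
    axis: ProfileAxis
    values: np.ndarray


@dataclass
class ModalityDecision:
    """Cascade outcome for one file: the label plus per-filter evidence.

    Evidence keys are present iff the deciding (or inspected) filter ran,
    so a decision is auditable filter by filter.
    """

    label: Optional[ModalityLabel]
    evidence: Dict[str, object] = field(default_factory=dict)


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma of an RGB array; grayscale passes through."""
    if pixels.ndim == 2:
        return pixels.astype(np.float64)
    return pixels.astype(np.float64) @ _LUMA


def is_video(file: UltrasoundFile) -> bool:
    """True iff the NumberOfFrames header is present and exceeds 1.

    A missing header means the file is not a multi-frame object; a value of
    exactly 1 is a still.
    """
    return file.number_of_frames is not None and file.number_of_frames > 1


def column_profile(image: ImageRecord) -> IntensityProfile:
    """Sum of grayscale intensities in each image column."""
    gray = to_grayscale(image.pixels)
    if gray.size == 0:
        raise ValueError("empty image")
    return IntensityProfile(ProfileAxis.COLUMN_SUMS, gray.sum(axis=0))


def row_profile(image: ImageRecord) -> IntensityProfile:
    """Sum of grayscale intensities in each image row."""
    gray = to_grayscale(image.pixels)
    if gray.size == 0:
        raise ValueError("empty image")
    return IntensityProfile(ProfileAxis.ROW_SUMS, gray.sum(axis=1))


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.astype(np.float64)
    kernel = np.ones(window) / window
    # reflect-pad so the smoothed profile keeps its length and edges are unbiased
    half = window // 2
    padded = np.pad(values.astype(np.float64), half, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def detect_dual_display(
    image: ImageRecord, cfg: CascadeConfig = CascadeConfig()
) -> Tuple[bool, Optional[int]]:
    """Look for the near-black gutter between side-by-side panels.

    The smoothed column profile is searched inside a central window of width
    ``gutter_window_frac * cols``; the frame is a dual display iff the
    minimum there falls below ``gutter_depth_frac`` times the median of the
    full profile.  Returns ``(flag, split_x)`` with ``split_x`` the gutter
    column when flagged.
    """
    profile = column_profile(image)
    cols = profile.values.size
    if cols < 32:
        return False, None
    smoothed = _moving_average(profile.values, cfg.smooth_window)
    half_w = int(round(cfg.gutter_window_frac * cols / 2))
    center = cols // 2
    lo, hi = max(0, center - half_w), min(cols, center + half_w + 1)
    window = smoothed[lo:hi]
    m = float(window.min())
    big_m = float(np.median(smoothed))
    if m < cfg.gutter_depth_frac * big_m:
        # a wide gutter smooths to a flat minimum: report the plateau center
        plateau = np.nonzero(window <= m + 1e-9)[0]
        split_x = lo + int(round(float(plateau.mean())))
        return True, split_x
    return False, None


def detect_color_doppler(
    image: ImageRecord, cfg: CascadeConfig = CascadeConfig()
) -> Tuple[bool, np.ndarray]:
    """Flag frames with a genuine chroma overlay.

    RGB is converted to HSV (channels in [0,1]); a pixel counts as colored
    when saturation and value are both >= ``color_threshold``.  Saturation is
    what separates a color-coded velocity map from grayscale tissue stored
    as RGB (where S == 0 identically); the joint value test discards black
    pixels whose hue is meaningless.  The frame is Doppler iff the colored
    count exceeds ``min_colored_frac`` of the pixel count.
    """
    if not image.is_color:
        return False, np.zeros(image.pixels.shape[:2], dtype=bool)
    hsv = rgb2hsv(image.pixels / 255.0)
    mask = (hsv[..., 1] >= cfg.color_threshold) & (hsv[..., 2] >= cfg.color_threshold)
    n_pix = mask.size
    flagged = int(mask.sum()) > cfg.min_colored_frac * n_pix
    return flagged, mask


def _half_peaks(values: np.ndarray) -> Tuple[Optional[int], float]:
    """Highest local maximum of a profile segment: (index, height).

    Plateaus count once, at their leftmost sample.  Returns (None, 0) when
    the segment is monotone (no interior local maximum).
    """
    if values.size < 3:
        return None, 0.0
    peaks, props = find_peaks(values, plateau_size=(1, None))
    if peaks.size == 0:
        return None, 0.0
    idx = np.argmax(values[props["left_edges"]])
    left = int(props["left_edges"][idx])
    return left, float(values[left])


def detect_mmode_pulsed(
    image: ImageRecord, cfg: CascadeConfig = CascadeConfig()
) -> Tuple[bool, Dict[str, float]]:
    """Detect the bright-strip-over-dark-trace layout of M-mode/pulsed files.

    The row-sum profile is split at mid-height.  Let P1/P2 be the heights of
    the highest peaks in the first (top) and second halves.  The frame is
    flagged iff prominence(P1) > ``prominence_min`` and P1/P2 >
    ``half_ratio_min`` (a missing or zero second-half peak makes the ratio
    +inf).  Evidence carries both peaks and the prominence.
    """
    profile = row_profile(image)
    values = profile.values.astype(np.float64)
    rows = values.size
    if rows < 32:
        return False, {}
    if cfg.normalize_profile:
        values = values / to_grayscale(image.pixels).shape[1]
    half = rows // 2
    i1, p1 = _half_peaks(values[:half])
    i2, p2 = _half_peaks(values[half:])
    evidence: Dict[str, float] = {"first_half_peak": p1, "second_half_peak": p2}
    if i1 is None:
        evidence["prominence"] = 0.0
        return False, evidence
    # topological prominence measured on the full profile
    prom = float(peak_prominences(values, [i1])[0][0])
    evidence["prominence"] = prom
    ratio = np.inf if p2 == 0.0 else p1 / p2
    evidence["half_ratio"] = float(ratio)
    flagged = prom > cfg.prominence_min and ratio > cfg.half_ratio_min
    return bool(flagged), evidence


def classify_modality(
    file: UltrasoundFile,
    cfg: CascadeConfig = CascadeConfig(),
    image: Optional[ImageRecord] = None,
) -> ModalityDecision:
    """Run the four filters in order; the first positive one labels the file.

    ``image`` may be supplied to skip re-decoding pixels; otherwise pixels
    are loaded only if the file passes the header-only video filter.  Decode
    failures yield a decision with ``label=None`` and an ``error`` evidence
    key.
    """
    evidence: Dict[str, object] = {}

    evidence["number_of_frames"] = file.number_of_frames
    if is_video(file):
        return ModalityDecision(ModalityLabel.VIDEO, evidence)

    if image is None:
        try:
            image = load_pixels(file)
        except Exception as exc:  # noqa: BLE001 - per-file isolation
            logger.error("pixel decode failed for %s: %s", file.source_id, exc)
            evidence["error"] = str(exc)
            return ModalityDecision(None, evidence)

    dual, split_x = detect_dual_display(image, cfg)
    evidence["split_x"] = split_x
    if dual:
        return ModalityDecision(ModalityLabel.DUAL_DISPLAY, evidence)

    doppler, mask = detect_color_doppler(image, cfg)
    evidence["colored_pixel_count"] = int(mask.sum())
    if doppler:
        return ModalityDecision(ModalityLabel.COLOR_DOPPLER, evidence)

    mmode, mm_evidence = detect_mmode_pulsed(image, cfg)
    evidence.update(mm_evidence)
    if mmode:
        return ModalityDecision(ModalityLabel.MMODE_OR_PULSED, evidence)

    return ModalityDecision(ModalityLabel.BMODE, evidence)


def split_dual(image: ImageRecord, split_x: int) -> Tuple[ImageRecord, ImageRecord]:
    """Emit the two halves of a dual display as derived records."""
    left = ImageRecord(
        source_id=f"{image.source_id}#left",
        pixels=image.pixels[:, :split_x].copy(),
        pixel_spacing_mm=image.pixel_spacing_mm,
    )
    right = ImageRecord(
        source_id=f"{image.source_id}#right",
        pixels=image.pixels[:, split_x:].copy(),
        pixel_spacing_mm=image.pixel_spacing_mm,
    )
    return left, right
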