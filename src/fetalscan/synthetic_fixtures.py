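"""Seeded ultrasound phantom generators with per-stage ground truth.

The hospital repository the pipeline targets is not redistributable, so
every stage is exercised on schematic phantoms that reproduce the pixel
statistics each filter keys on: multiplicative gamma speckle, sector
geometry, dual-display gutters, chroma overlays, M-mode/pulsed-Doppler
layouts, multi-frame cine objects, 14 organ-plane motifs, and full
transcerebellar (TC) anatomy — skull ring, midline falx, butterfly
thalamus, dark "guitar" negative space, cerebellum — with a known true
diameter.

Every generator is deterministic: (phantom type, seed, parameters) fixes
the output byte-for-byte.  Modality phantoms satisfy or violate each
cascade criterion by a wide margin (>= 25%), so routing correctness is a
soundness check rather than a threshold-tuning exercise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon
from skimage.transform import rotate as sk_rotate

from .repo_io import Manifest
from .thalamus_biometry import GUITAR_L, WAIST_INDICES, EllipseParams, GuitarShape

logger = logging.getLogger(__name__)

MODALITY_KINDS = ("bmode", "dual", "doppler", "pulsed", "mmode", "video", "fourd")

#: cascade label each phantom kind must receive
EXPECTED_LABELS = {
    "bmode": "BMODE",
    "dual": "DUAL_DISPLAY",
    "doppler": "COLOR_DOPPLER",
    "pulsed": "MMODE_OR_PULSED",
    "mmode": "MMODE_OR_PULSED",
    "video": "VIDEO",
    "fourd": "VIDEO",
}

PLANE_CLASSES = (
    "Abdomen",
    "Arm",
    "BloodVessels",
    "CordInsertion",
    "Face",
    "FemurHumerus",
    "Foot",
    "Genitals",
    "Head",
    "Heart",
    "Kidney",
    "Leg",
    "Spine",
    "Hand",
)

#: guitar deformation-field standard deviations (px at the reference scale)
GUITAR_FIELD_SIGMAS = (6.0, 3.0, 1.5)
#: reference guitar size (max centroid-to-landmark radius, px) of the
#: training population; phantom guitars scale the fields proportionally
GUITAR_REF_RADIUS = 40.0


@dataclass
class PhantomTruth:
    """Ground truth recorded by a generator for one phantom."""

    source_id: str
    seed: int
    modality: Optional[str] = None
    plane: Optional[str] = None
    head_subplane: Optional[str] = None
    skull: Optional[EllipseParams] = None
    guitar: Optional[GuitarShape] = None
    diameter_px: Optional[float] = None
    gutter_x: Optional[int] = None
    color_mask: Optional[np.ndarray] = None
    orientation: Optional[str] = None
    truncated: bool = False
    mirrored: bool = False
    extras: Dict[str, object] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# low-level drawing helpers


def _speckle(rng: np.random.Generator, shape: Tuple[int, int], smooth: float = 0.0) -> np.ndarray:
    """Unit-mean multiplicative gamma speckle (shape 4), optionally smoothed."""
    g = rng.gamma(4.0, 1.0 / 4.0, size=shape)
    if smooth > 0:
        g = gaussian_filter(g, smooth)
        g = g / g.mean()
    return g


def _sector_mask(shape: Tuple[int, int], half_angle: float = 0.7) -> np.ndarray:
    """Fan-shaped imaging sector with apex at the top center."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    apex = (-0.05 * rows, cols / 2)
    dy = yy - apex[0]
    dx = xx - apex[1]
    ang = np.arctan2(dx, dy)  # 0 points straight down
    r = np.hypot(dx, dy)
    return (np.abs(ang) < half_angle) & (r < 1.12 * rows) & (r > 0.08 * rows)


def _bmode_canvas(rng: np.random.Generator, shape: Tuple[int, int] = (600, 800)) -> np.ndarray:
    """Sector x smooth tissue background x speckle: a plain B-mode still."""
    rows, cols = shape
    base = np.full(shape, 90.0)
    for _ in range(6):  # smooth low-frequency tissue blobs
        cy, cx = rng.uniform(0.2, 0.9) * rows, rng.uniform(0.2, 0.8) * cols
        amp = rng.uniform(-25, 35)
        sig = rng.uniform(40, 120)
        yy, xx = np.mgrid[0:rows, 0:cols]
        base += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2))
    img = np.clip(base, 30, 200) * _speckle(rng, shape)
    img[~_sector_mask(shape)] = 0.0
    return np.clip(img, 0, 255)


def render_polygon_mask(landmarks: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    """Filled-polygon mask of a landmark outline on a canvas of ``shape``."""
    rr, cc = draw_polygon(landmarks[:, 1], landmarks[:, 0], shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


# ---------------------------------------------------------------------------
# guitar geometry


def _base_guitar_radii(n: int = GUITAR_L) -> Tuple[np.ndarray, np.ndarray]:
    """Sampling directions and unit-max radii of the canonical guitar.

    Directions start superior (straight up in image coordinates) and
    advance clockwise in image view; the outline has a large anterior bulb,
    a smaller posterior bulb and a pinched waist at indices
    :data:`WAIST_INDICES`.
    """
    psi = -np.pi / 2 + 2 * np.pi * np.arange(n) / n
    f = (0.35 + 0.65 * np.abs(np.cos(psi)) ** 1.5) * (1 + 0.18 * np.cos(psi))
    return psi, f / f.max()


def _deformation_fields(psi: np.ndarray) -> np.ndarray:
    """Three fixed smooth radial deformation fields (rows: field index).

    Harmonic radial perturbations: bulb asymmetry (cos), elongation
    (cos 2x) and a tri-lobe wiggle (sin 3x); mutually orthogonal over the
    uniform landmark grid.
    """
    return np.stack([np.cos(psi), np.cos(2 * psi), np.sin(3 * psi)])


def guitar_landmarks(
    center: Tuple[float, float],
    max_radius: float,
    coeffs: Sequence[float] = (0.0, 0.0, 0.0),
    rotation: float = 0.0,
) -> np.ndarray:
    """Image-coordinate landmarks of a (possibly deformed) guitar.

    ``coeffs`` weight the three deformation fields in px at the reference
    scale (:data:`GUITAR_REF_RADIUS`) and are scaled with ``max_radius``.
    """
    psi, base = _base_guitar_radii()
    fields = _deformation_fields(psi)
    dr = np.asarray(coeffs, dtype=np.float64) @ fields
    r = max_radius * base + dr * (max_radius / GUITAR_REF_RADIUS)
    r = np.maximum(r, 0.05 * max_radius)
    ang = psi + rotation
    x = center[0] + r * np.cos(ang)
    y = center[1] + r * np.sin(ang)
    return np.column_stack([x, y])


def make_guitar_population(n: int = 100, seed: int = 0) -> Tuple[List[GuitarShape], np.ndarray]:
    """Training population of guitar shapes with recorded coefficients.

    Each shape is the canonical outline deformed along the three fixed
    fields with zero-mean normal coefficients (sigmas
    :data:`GUITAR_FIELD_SIGMAS`) plus similarity jitter.  The drawn
    coefficient sample is whitened so the population realises the nominal
    field variances exactly and without cross-correlation — the generated
    deformations are then a sharp oracle for the shape model's principal
    modes.  Returns the shapes and the (n, 3) coefficient matrix.
    """
    if n < 3:
        raise ValueError("population needs n >= 3")
    rng = np.random.default_rng(seed)
    sig = np.asarray(GUITAR_FIELD_SIGMAS)
    coeffs = rng.normal(0.0, sig, size=(n, 3))
    if n > 4 and np.all(sig > 0):  # exact sample decorrelation at nominal sigmas
        centered = coeffs - coeffs.mean(axis=0)
        chol = np.linalg.cholesky(np.cov(centered.T))
        coeffs = (centered @ np.linalg.inv(chol).T) * sig
    shapes: List[GuitarShape] = []
    for i in range(n):
        scale = GUITAR_REF_RADIUS * rng.uniform(0.9, 1.1)
        rot = rng.uniform(-0.1, 0.1)
        center = rng.uniform(-20, 20, size=2) + 100.0
        lm = guitar_landmarks((center[0], center[1]), scale, coeffs[i], rotation=rot)
        shapes.append(GuitarShape(lm))
    return shapes, coeffs


# ---------------------------------------------------------------------------
# DICOM writing


def _write_dicom(
    path: Path,
    pixels: np.ndarray,
    uid_suffix: str,
    number_of_frames: Optional[int] = None,
    pixel_spacing: Optional[Tuple[float, float]] = None,
) -> None:
    """Minimal deterministic Secondary Capture DICOM (8-bit gray or RGB)."""
    arr = np.asarray(pixels)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = f"1.2.826.0.1.3680043.8.498.{uid_suffix}"
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "US"
    ds.PatientName = "PHANTOM"
    ds.PatientID = "PHANTOM"

    frames = number_of_frames or 1
    color = arr.ndim == 3 and arr.shape[-1] == 3 and frames == 1
    if frames > 1:
        ds.NumberOfFrames = frames
        ds.Rows, ds.Columns = arr.shape[1], arr.shape[2]
    else:
        ds.Rows, ds.Columns = arr.shape[0], arr.shape[1]
    ds.SamplesPerPixel = 3 if color else 1
    ds.PhotometricInterpretation = "RGB" if color else "MONOCHROME2"
    if color:
        ds.PlanarConfiguration = 0
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    if pixel_spacing is not None:
        ds.PixelSpacing = [str(pixel_spacing[0]), str(pixel_spacing[1])]
    ds.PixelData = arr.tobytes()
    pydicom.dcmwrite(path, ds, enforce_file_format=True)


# ---------------------------------------------------------------------------
# modality phantoms


def _dual_phantom(rng: np.random.Generator) -> Tuple[np.ndarray, int]:
    panel = (600, 380)
    left = _bmode_canvas(rng, panel)
    right = _bmode_canvas(rng, panel)
    gutter = np.full((600, 40), 3.0)
    img = np.hstack([left, gutter, right])
    return img, 380 + 20


def _doppler_phantom(rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    gray = _bmode_canvas(rng)
    rgb = np.repeat(gray[..., None], 3, axis=2)
    rows, cols = gray.shape
    h = w = 90  # 8100 px on a 600x800 frame: ~1.7% of the frame
    r0 = int(0.45 * rows)
    c0 = int(0.45 * cols)
    mask = np.zeros((rows, cols), dtype=bool)
    mask[r0 : r0 + h, c0 : c0 + w] = True
    toward = rng.random() < 0.5
    color = np.array([210.0, 30.0, 30.0]) if toward else np.array([30.0, 60.0, 210.0])
    rgb[mask] = color
    return rgb, mask


def _trace_strip_phantom(rng: np.random.Generator, kind: str) -> np.ndarray:
    """Shared layout of M-mode and pulsed-Doppler displays.

    A bright B-mode reference band in the top half over a near-black lower
    half carrying only a thin trace: the row-sum profile then has a
    dominant, high-prominence first-half peak.
    """
    rows, cols = 600, 800
    img = np.full((rows, cols), 15.0)
    band = _bmode_canvas(rng, (160, cols))
    band = np.clip(band + 80.0, 0, 255)  # reference strip is bright
    img[80:240] = band
    xs = np.arange(cols)
    if kind == "pulsed":
        trace_y = 450 + 80 * np.sin(2 * np.pi * xs / 120.0) * rng.uniform(0.8, 1.0)
        for x, y in zip(xs, trace_y):
            img[int(np.clip(y, 310, rows - 2)) : int(np.clip(y, 310, rows - 2)) + 2, x] = 190.0
    else:  # mmode: several faint wavy horizontal bands
        for y0 in (380, 440, 500):
            trace_y = y0 + 12 * np.sin(2 * np.pi * xs / 90.0 + y0)
            for x, y in zip(xs, trace_y):
                img[int(np.clip(y, 310, rows - 2)), x] = 70.0
    return img


def _video_frames(rng: np.random.Generator, fourd: bool) -> Tuple[np.ndarray, int]:
    nf = int(rng.integers(10, 61))
    frames = np.empty((nf, 64, 64))
    yy, xx = np.mgrid[0:64, 0:64]
    for i in range(nf):
        if fourd:  # rendered-surface look: smooth shaded blob
            cy, cx = 32 + 6 * np.sin(i / 4), 32 + 6 * np.cos(i / 4)
            r = np.hypot(yy - cy, xx - cx)
            frames[i] = np.clip(220 - 4.5 * r, 20, 255)
        else:
            frames[i] = np.clip(
                100 * _speckle(rng, (64, 64)) * ((np.hypot(yy - 32, xx - 32) < 22)), 0, 255
            )
    return frames, nf


def make_modality_suite(
    out_dir, n_per_class: int = 40, seed: int = 0
) -> Tuple[List[Path], List[PhantomTruth], Manifest]:
    """Write one DICOM per phantom for all 7 modality kinds.

    Returns the written paths, the per-file truths and a truth manifest
    (stage ``modality_truth``).  ``n_per_class >= 1``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: List[Path] = []
    truths: List[PhantomTruth] = []
    manifest = Manifest()
    for kind_i, kind in enumerate(MODALITY_KINDS):
        for j in range(n_per_class):
            child_seed = seed * 10007 + kind_i * 1009 + j
            rng = np.random.default_rng(child_seed)
            name = f"{kind}_{j:03d}.dcm"
            path = out_dir / name
            truth = PhantomTruth(
                source_id=str(path), seed=child_seed, modality=EXPECTED_LABELS[kind]
            )
            uid = f"{seed % 1000}.{kind_i}.{j}"
            if kind == "bmode":
                _write_dicom(path, _bmode_canvas(rng), uid)
            elif kind == "dual":
                img, gutter_x = _dual_phantom(rng)
                truth.gutter_x = gutter_x
                _write_dicom(path, img, uid)
            elif kind == "doppler":
                rgb, mask = _doppler_phantom(rng)
                truth.color_mask = mask
                _write_dicom(path, rgb, uid)
            elif kind in ("pulsed", "mmode"):
                _write_dicom(path, _trace_strip_phantom(rng, kind), uid)
            else:  # video / fourd
                frames, nf = _video_frames(rng, fourd=(kind == "fourd"))
                truth.extras["number_of_frames"] = nf
                _write_dicom(path, frames, uid, number_of_frames=nf)
            paths.append(path)
            truths.append(truth)
            manifest.append(str(path), "modality_truth", truth.modality, kind=kind)
    return paths, truths, manifest


# ---------------------------------------------------------------------------
# plane phantoms


def _draw_blob(img: np.ndarray, cy: float, cx: float, r: float, val: float) -> None:
    rr, cc = draw_disk((cy, cx), r, shape=img.shape)
    img[rr, cc] = val


def _draw_bar(img, cy, cx, length, width, angle, val) -> None:
    dy, dx = np.sin(angle), np.cos(angle)
    half = length / 2
    corners = np.array(
        [
            [cx - half * dx - width / 2 * dy, cy - half * dy + width / 2 * dx],
            [cx + half * dx - width / 2 * dy, cy + half * dy + width / 2 * dx],
            [cx + half * dx + width / 2 * dy, cy + half * dy - width / 2 * dx],
            [cx - half * dx + width / 2 * dy, cy - half * dy - width / 2 * dx],
        ]
    )
    rr, cc = draw_polygon(corners[:, 1], corners[:, 0], shape=img.shape)
    img[rr, cc] = val


def _draw_ring(img, cy, cx, a, b, val, thickness=4) -> None:
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    r = np.sqrt(((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2)
    band = thickness / (2 * min(a, b))
    img[np.abs(r - 1.0) < band] = val


def _plane_motif(organ: str, tc_like: bool, rng: np.random.Generator) -> np.ndarray:
    """Canonical 256x256 motif of one organ class, before jitter/speckle."""
    img = np.full((256, 256), 35.0)
    c = 128.0
    if organ == "Abdomen":
        _draw_blob(img, c, c, 75, 115)
        _draw_blob(img, c + 15, c - 20, 18, 35)  # stomach bubble
    elif organ == "Arm":
        _draw_bar(img, c, c, 120, 14, 0.5, 180)
    elif organ == "BloodVessels":
        xs = np.arange(30, 226)
        for off, val in ((-16, 160), (16, 160)):
            ys = c + off + 10 * np.sin(xs / 30.0)
            for x, y in zip(xs, ys):
                img[int(y) : int(y) + 4, x] = val
    elif organ == "CordInsertion":
        _draw_blob(img, c, c, 55, 100)
        _draw_bar(img, c - 50, c - 50, 130, 8, 0.8, 190)
    elif organ == "Face":
        _draw_ring(img, c, c - 20, 60, 85, 170, thickness=8)
        img[:, :100] = 35.0  # open crescent (profile)
        _draw_blob(img, c - 20, c + 30, 10, 150)  # nose knob
    elif organ == "FemurHumerus":
        _draw_bar(img, c, c, 170, 18, 0.0, 210)
    elif organ == "Foot":
        _draw_blob(img, c + 25, c, 40, 110)
        for i in range(5):
            _draw_blob(img, c - 30, 80 + i * 24, 8, 190)
    elif organ == "Genitals":
        pts = np.array([[c - 35, c + 30], [c + 35, c + 30], [c, c - 40]])
        rr, cc = draw_polygon(pts[:, 1], pts[:, 0], shape=img.shape)
        img[rr, cc] = 140
    elif organ == "Head":
        # heads are rendered at full TC-phantom geometry so the classifier
        # trains on the same anatomy the biometry stage receives
        img = make_head_plane_image(int(rng.integers(2**31)), tc_like)
    elif organ == "Heart":
        _draw_blob(img, c, c, 60, 90)
        for dy in (-20, 20):
            for dx in (-20, 20):
                _draw_blob(img, c + dy, c + dx, 13, 25)  # four dark chambers
    elif organ == "Kidney":
        _draw_blob(img, c, c, 55, 130)
        _draw_blob(img, c, c + 30, 28, 35)  # renal pelvis notch
    elif organ == "Leg":
        _draw_bar(img, c - 25, c - 20, 110, 14, 0.2, 190)
        _draw_bar(img, c + 35, c + 15, 110, 14, 1.1, 190)
    elif organ == "Spine":
        for i in range(9):
            _draw_bar(img, 40 + i * 22, c + 10 * np.sin(i / 2.0), 30, 7, 0.0, 200)
    elif organ == "Hand":
        for i in range(5):
            _draw_bar(img, c, c, 100, 6, -0.5 + i * 0.25, 180)
    else:
        raise ValueError(f"unknown organ {organ}")
    del rng
    return img


def make_head_plane_image(seed: int, tc_like: bool, size: Optional[int] = None) -> np.ndarray:
    """Axial head image at full phantom geometry for the plane suite.

    TC-like heads are genuine TC phantoms; non-TC (TT/TV-like) heads share
    the skull/falx rendering but show a small central mass instead of the
    butterfly/guitar complex, and no cerebellum.  The image stays at native
    phantom resolution unless ``size`` asks for a central-cropped downscale,
    so classifier training sees exactly what the deployed pipeline sees.
    """
    if tc_like:
        img, _ = make_tc_phantom(seed)
    else:
        rng = np.random.default_rng(seed)
        rows, cols = 600, 800
        a = rng.uniform(160, 200)
        b = a * rng.uniform(0.72, 0.85)
        cx = 400 + rng.uniform(-10, 10)
        cy = 300 + rng.uniform(-10, 10)
        theta = rng.uniform(-0.04, 0.04)
        img = np.full((rows, cols), 35.0)
        yy, xx = np.mgrid[0:rows, 0:cols]
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        r_norm = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        img[r_norm <= 1.0] = 60.0
        for t in np.arange(-0.92 * a, 0.92 * a, 0.5):  # continuous falx
            px, py = cx + t * ct, cy + t * st
            img[int(py) - 1 : int(py) + 2, int(px)] = 180.0
        _draw_blob(img, cy, cx, 0.12 * b, 120.0)  # central mass, no butterfly
        img[np.abs(r_norm - 1.0) * min(a, b) < 3.0] = 200.0
        img = np.clip(img * _speckle(rng, (rows, cols), smooth=1.5), 0, 255)
    if size is None:
        return img
    side = img.shape[0]
    c0 = (img.shape[1] - side) // 2
    square = img[:, c0 : c0 + side]
    from skimage.transform import resize as _resize

    return _resize(square, (size, size), preserve_range=True, anti_aliasing=True)


def make_plane_suite(
    n_per_class: int = 40, seed: int = 0
) -> Tuple[List[np.ndarray], List[PhantomTruth]]:
    """In-memory suite of organ-plane phantom images with labels.

    Each organ has a distinct parametric motif, randomized by similarity
    jitter (rotation +-15 deg, scale +-10%) and speckle.  The Head class is
    split half/half into TC-like and non-TC (TT/TV-like) variants for the
    intra-plane task.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    images: List[np.ndarray] = []
    truths: List[PhantomTruth] = []
    for org_i, organ in enumerate(PLANE_CLASSES):
        for j in range(n_per_class):
            child_seed = seed * 20011 + org_i * 1013 + j
            rng = np.random.default_rng(child_seed)
            tc_like = organ == "Head" and j < n_per_class // 2
            if organ == "Head":
                # native-resolution head phantoms: the same rendering (and
                # therefore descriptor statistics) the deployed pipeline
                # receives; rotation jitter only, speckle is already baked in
                img = make_head_plane_image(int(rng.integers(2**31)), tc_like)
                angle = rng.uniform(-15, 15)
                img = sk_rotate(img, angle, resize=False, mode="edge", preserve_range=True)
            else:
                img = _plane_motif(organ, tc_like, rng)
                angle = rng.uniform(-15, 15)
                scale = rng.uniform(0.9, 1.1)
                # edge fill keeps jittered borders at tissue intensity,
                # matching the unjittered images the pipeline sees
                img = sk_rotate(img, angle, resize=False, mode="edge", preserve_range=True)
                if scale != 1.0:
                    from skimage.transform import rescale

                    img = rescale(img, scale, preserve_range=True, anti_aliasing=True)
                    if scale > 1.0:
                        off = (img.shape[0] - 256) // 2
                        img = img[off : off + 256, off : off + 256]
                    else:
                        pad = 256 - img.shape[0]
                        img = np.pad(img, ((pad // 2, pad - pad // 2),) * 2, mode="edge")
                img = np.clip(img * _speckle(rng, img.shape, smooth=1.0), 0, 255)
            images.append(img)
            truths.append(
                PhantomTruth(
                    source_id=f"plane_{organ}_{j:03d}",
                    seed=child_seed,
                    plane=organ,
                    head_subplane=("TC" if tc_like else "NON_TC") if organ == "Head" else None,
                )
            )
    return images, truths


def make_ellipse_ring_phantom(
    seed: int,
    cx: float = 400.0,
    cy: float = 300.0,
    a: float = 180.0,
    b: float = 140.0,
    theta: float = 0.3,
    missing_arc_frac: float = 0.0,
    thickness: float = 3.0,
    shape: Tuple[int, int] = (600, 800),
) -> Tuple[np.ndarray, PhantomTruth]:
    """Bright elliptical ring over speckled background, known parameters.

    ``missing_arc_frac`` removes a contiguous fraction of the ring arc to
    emulate an incompletely imaged skull.
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    img = np.full(shape, 50.0)
    ring = np.abs(r - 1.0) * min(a, b) < thickness / 2 + 1
    if missing_arc_frac > 0:
        ang = np.arctan2(v / b, u / a)
        start = rng.uniform(-np.pi, np.pi)
        rel = np.mod(ang - start, 2 * np.pi)
        ring = ring & ~(rel < missing_arc_frac * 2 * np.pi)
    img[ring] = 220.0
    img = np.clip(img * _speckle(rng, shape, smooth=1.0), 0, 255)
    truth = PhantomTruth(
        source_id=f"ring_{seed}",
        seed=seed,
        skull=EllipseParams(cx=cx, cy=cy, a=a, b=b, theta=theta),
        extras={"missing_arc_frac": missing_arc_frac},
    )
    return img, truth


# ---------------------------------------------------------------------------
# TC-plane phantoms


def make_tc_phantom(
    seed: int,
    diameter_px: Optional[float] = None,
    truncate_skull: bool = False,
    mirror: bool = False,
    deform: Optional[Sequence[float]] = None,
) -> Tuple[np.ndarray, PhantomTruth]:
    """Full transcerebellar-plane phantom with known thalamus diameter.

    Anatomy (image coordinates, anterior to the left): bright elliptical
    skull ring, midline falx along the major axis (interrupted centrally),
    a vertical butterfly thalamus whose outer lobe edges are exactly
    ``diameter_px`` apart, the dark guitar negative space drawn over the
    butterfly center, and a cerebellum blob marking the occiput (right
    side, or left when ``mirror``).  ``deform`` gives the three guitar
    deformation-field coefficients (px at reference scale; default: drawn
    from the training distribution truncated at +-2 sigma).

    Returns the image and a truth record carrying the skull ellipse, the
    guitar landmarks, the true diameter and the orientation.
    """
    rng = np.random.default_rng(seed)
    rows, cols = 600, 800
    a = rng.uniform(160, 200)
    b = a * rng.uniform(0.72, 0.85)
    cx = 400 + rng.uniform(-10, 10)
    cy = 300 + rng.uniform(-10, 10)
    theta = rng.uniform(-0.04, 0.04)
    if deform is None:
        sig = np.asarray(GUITAR_FIELD_SIGMAS)
        deform = np.clip(rng.normal(0.0, sig), -2 * sig, 2 * sig)
    deform = np.asarray(deform, dtype=np.float64)
    # waist half-height of this particular guitar, so the butterfly always
    # reaches well past the waist landmarks
    g_rad_tmp = 0.35 * b
    lm_tmp = guitar_landmarks((0.0, 0.0), g_rad_tmp, deform, rotation=np.pi)
    waist_r = float(max(np.linalg.norm(lm_tmp[WAIST_INDICES[0]]),
                        np.linalg.norm(lm_tmp[WAIST_INDICES[1]])))
    if diameter_px is None:
        lo = max(60.0, 2.0 * (waist_r + 12.0))
        diameter_px = float(rng.uniform(lo, 200))
    if not 60 <= diameter_px <= 200:
        raise ValueError("diameter_px must lie in [60, 200]")

    img = np.full((rows, cols), 35.0)
    yy, xx = np.mgrid[0:rows, 0:cols]
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    r_norm = np.sqrt((u / a) ** 2 + (v / b) ** 2)

    img[r_norm <= 1.0] = 60.0  # intracranial background

    # butterfly thalamus: two tangent lobes spanning exactly diameter_px
    lobe_sy = diameter_px / 4.0
    lobe_sx = max(9.0, 0.18 * diameter_px)
    for sgn in (-1.0, 1.0):
        ly = cy + sgn * diameter_px / 4.0
        lobe = ((xx - cx) / lobe_sx) ** 2 + ((yy - ly) / lobe_sy) ** 2 <= 1.0
        img[lobe] = 190.0
    butterfly = img == 190.0

    # guitar negative space over the butterfly center; the larger anterior
    # bulb points away from the cerebellum (occiput right => anterior left)
    g_rad = 0.35 * b
    guitar_lm = guitar_landmarks((cx, cy), g_rad, deform, rotation=theta + np.pi)
    g_mask = render_polygon_mask(guitar_lm, (rows, cols))
    img[g_mask] = 30.0

    # midline falx along the major axis, interrupted around the guitar
    gap = 1.15 * g_rad
    for t in np.arange(-0.92 * a, 0.92 * a, 0.5):
        if abs(t) < gap:
            continue
        px = cx + t * ct
        py = cy + t * st
        img[int(py) - 1 : int(py) + 2, int(px)] = 180.0

    # cerebellum blob marks the occiput (posterior), clear of the waist line
    occ_sign = 1.0
    cb_x = cx + occ_sign * 0.84 * a * ct
    cb_y = cy + occ_sign * 0.84 * a * st
    _draw_blob(img, cb_y, cb_x, 0.09 * a, 150.0)

    # skull: bright ring of ~6 px
    ring = np.abs(r_norm - 1.0) * min(a, b) < 3.0
    if truncate_skull:
        # remove 35% of the arc so inlier coverage drops below the flag bound
        ang = np.arctan2(v / b, u / a)
        start = rng.uniform(-np.pi, np.pi)
        width = 0.35 * 2 * np.pi
        rel = np.mod(ang - start, 2 * np.pi)
        ring = ring & ~(rel < width)
    img[ring] = 200.0

    img = np.clip(img * _speckle(rng, (rows, cols), smooth=1.5), 0, 255)

    orientation = "RIGHT_OCCIPUT"
    if mirror:
        img = img[:, ::-1].copy()
        guitar_lm = _mirror_landmarks(guitar_lm, cols)
        cx = (cols - 1) - cx
        theta = float(np.mod(np.pi - theta, np.pi))
        orientation = "LEFT_OCCIPUT"
        butterfly = butterfly[:, ::-1]

    truth = PhantomTruth(
        source_id=f"tc_{seed}",
        seed=seed,
        modality="BMODE",
        plane="Head",
        head_subplane="TC",
        skull=EllipseParams(cx=cx, cy=cy, a=a, b=b, theta=theta),
        guitar=GuitarShape(guitar_lm),
        diameter_px=float(diameter_px),
        orientation=orientation,
        truncated=truncate_skull,
        mirrored=mirror,
        extras={"deform": deform.tolist(), "butterfly_mask": butterfly},
    )
    return img, truth


def _mirror_landmarks(lm: np.ndarray, cols: int) -> np.ndarray:
    """Reflect landmarks about the vertical image axis, keeping the
    clockwise-from-superior ordering convention."""
    reflected = lm.copy()
    reflected[:, 0] = (cols - 1) - reflected[:, 0]
    n = reflected.shape[0]
    order = (-np.arange(n)) % n
    return reflected[order]


def make_tc_suite(
    n: int = 25, seed: int = 0, **kwargs
) -> Tuple[List[np.ndarray], List[PhantomTruth]]:
    """A batch of TC phantoms with independent child seeds."""
    images, truths = [], []
    for i in range(n):
        img, truth = make_tc_phantom(seed * 30013 + i, **kwargs)
        images.append(img)
        truths.append(truth)
    return images, truths


def write_tc_suite_dicom(
    out_dir, n: int = 25, seed: int = 0, pixel_spacing: Tuple[float, float] = (0.1, 0.1)
) -> Tuple[List[Path], List[PhantomTruth]]:
    """Write a TC suite as DICOM files with pixel spacing headers."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, truths = make_tc_suite(n, seed)
    paths = []
    for i, (img, truth) in enumerate(zip(images, truths)):
        path = out_dir / f"tc_{i:03d}.dcm"
        _write_dicom(path, img, f"{seed % 1000}.9.{i}", pixel_spacing=pixel_spacing)
        truth.source_id = str(path)
        paths.append(path)
    return paths, truths
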