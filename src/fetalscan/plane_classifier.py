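"""Hierarchical fetal standard-plane recognition.

B-mode images are mapped to one of 14 fetal organ classes (inter-plane
stage) and, for head images only, to transcerebellar (TC) versus non-TC
axial sub-planes (intra-plane stage).  Both stages are linear-kernel
support-vector machines over image features; the feature extractor is a
pluggable contract so the same SVM hierarchy runs on a fine-tuned CNN's
penultimate-layer activations or, by default, on a deterministic
hand-crafted descriptor that needs no pretrained weights.

Training images are augmented six-fold (a central crop plus its four
corner crops and center crop) and resized to 227x227 with the aspect ratio
preserved by symmetric zero padding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import List, Optional, Sequence, Tuple

import joblib
import numpy as np
from skimage.transform import resize as _sk_resize
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)

ORGAN_CLASSES = (
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


class HeadSubplane(Enum):
    TC = "TC"
    NON_TC = "NON_TC"


@dataclass(frozen=True)
class PlaneLabel:
    """Organ class plus, for head images only, the TC/non-TC sub-plane."""

    organ: str
    head_subplane: Optional[HeadSubplane] = None

    def __post_init__(self) -> None:
        if self.organ not in ORGAN_CLASSES:
            raise ValueError(f"unknown organ class: {self.organ}")
        if self.head_subplane is not None and self.organ != "Head":
            raise ValueError("head_subplane is only defined for Head images")


@dataclass(frozen=True)
class TrainConfig:
    """Training-time knobs shared by the extractor and SVM stages.

    ``lr_last``/``lr_rest`` are the layer-specific learning rates of the
    CNN fine-tune (new final layer learns 10x faster than the pretrained
    body); they are inert for the default hand-crafted extractor.  The loss
    is cross-entropy and the optimizer stochastic gradient descent by
    contract.  ``train_frac`` is the training share of the 90/10
    train/validation split, stratified by class with ``seed``.
    """

    input_size: Tuple[int, int] = (227, 227)
    feature_dim: int = 4096
    lr_last: float = 1e-3
    lr_rest: float = 1e-4
    train_frac: float = 0.9
    seed: int = 0
    svm_c: float = 1.0
    loss: str = "cross-entropy"
    optimizer: str = "sgd"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must be in (0,1)")
        if self.lr_last <= 0 or self.lr_rest <= 0:
            raise ValueError("learning rates must be positive")


@dataclass
class AugmentationSet:
    """Exactly six same-sized variants of one source image."""

    variants: List[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.variants) != 6:
            raise ValueError("an augmentation set holds exactly 6 variants")
        shapes = {v.shape for v in self.variants}
        if len(shapes) != 1:
            raise ValueError("all variants must share one shape")


def resize_preserving_aspect(
    image: np.ndarray, size: Tuple[int, int] = (227, 227)
) -> np.ndarray:
    """Scale so the longer side fits ``size``, zero-pad the shorter side.

    Padding is split symmetrically (extra pixel to the trailing side), so
    no anisotropic scaling ever occurs.
    """
    if image.size == 0:
        raise ValueError("empty image")
    rows, cols = image.shape[:2]
    out_r, out_c = size
    scale = min(out_r / rows, out_c / cols)
    new_r = max(1, int(round(rows * scale)))
    new_c = max(1, int(round(cols * scale)))
    new_r, new_c = min(new_r, out_r), min(new_c, out_c)
    scaled = _sk_resize(
        image.astype(np.float64),
        (new_r, new_c),
        order=1,
        anti_aliasing=(scale < 1.0),
        preserve_range=True,
    )
    pad_r, pad_c = out_r - new_r, out_c - new_c
    pads = [(pad_r // 2, pad_r - pad_r // 2), (pad_c // 2, pad_c - pad_c // 2)]
    if image.ndim == 3:
        pads.append((0, 0))
    return np.pad(scaled, pads, mode="constant")


def augment_six_crops(
    image: np.ndarray,
    crop_frac: float = 0.9,
    size: Tuple[int, int] = (227, 227),
) -> AugmentationSet:
    """Six-fold crop augmentation of one image.

    Variant 1 is the central square crop ``c`` with side
    ``crop_frac * min(rows, cols)``; variants 2-6 are the four corner crops
    and the center crop of ``c`` (side ``crop_frac * side(c)``).  Every
    variant is resized (aspect preserved) to ``size``.  Deterministic.
    """
    if not 0.0 < crop_frac <= 1.0:
        raise ValueError("crop_frac must be in (0,1]")
    rows, cols = image.shape[:2]
    if rows < 2 or cols < 2:
        raise ValueError("image too small to augment")

    def central(img: np.ndarray, side: int) -> Tuple[int, int]:
        r0 = (img.shape[0] - side) // 2
        c0 = (img.shape[1] - side) // 2
        return r0, c0

    side_c = max(2, int(round(crop_frac * min(rows, cols))))
    r0, c0 = central(image, side_c)
    c = image[r0 : r0 + side_c, c0 : c0 + side_c]

    side_s = max(1, int(round(crop_frac * side_c)))
    off = side_c - side_s
    corners = [(0, 0), (0, off), (off, 0), (off, off)]
    rc, cc = central(c, side_s)
    windows = [c] + [c[r : r + side_s, col : col + side_s] for r, col in corners]
    windows.append(c[rc : rc + side_s, cc : cc + side_s])
    variants = [resize_preserving_aspect(w, size) for w in windows]
    return AugmentationSet(variants)


# ---------------------------------------------------------------------------
# feature extractors


class FeatureExtractor:
    """Behavioral contract: image (resized) -> fixed-length finite vector."""

    name: str = "base"
    feature_dim: int = 0
    deterministic: bool = True

    def extract(self, image: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class LiteFeatureExtractor(FeatureExtractor):
    """Deterministic multiscale gradient-orientation + intensity descriptor.

    For each of three dyadic scales the image is divided into a 4x4 grid of
    cells; each cell contributes an 8-bin magnitude-weighted gradient
    orientation histogram plus its mean and standard deviation of intensity
    (on the [0,1] scale).  A black image therefore maps to the all-zero
    vector.  feature_dim = 3 scales x 16 cells x (8 + 2) = 480.
    """

    name = "lite"
    deterministic = True

    _SCALES = (1, 2, 4)
    _GRID = 4
    _BINS = 8

    def __init__(self) -> None:
        self.feature_dim = len(self._SCALES) * self._GRID**2 * (self._BINS + 2)

    def extract(self, image: np.ndarray) -> np.ndarray:
        if image.ndim == 3:
            image = image @ np.array([0.299, 0.587, 0.114])
        img = image.astype(np.float64) / 255.0
        chunks: List[np.ndarray] = []
        for s in self._SCALES:
            sub = img[::s, ::s]
            gy, gx = np.gradient(sub)
            mag = np.hypot(gx, gy)
            ang = np.mod(np.arctan2(gy, gx), np.pi)  # orientation, not direction
            bin_idx = np.minimum((ang / np.pi * self._BINS).astype(int), self._BINS - 1)
            r_edges = np.linspace(0, sub.shape[0], self._GRID + 1).astype(int)
            c_edges = np.linspace(0, sub.shape[1], self._GRID + 1).astype(int)
            for i in range(self._GRID):
                for j in range(self._GRID):
                    cell = (slice(r_edges[i], r_edges[i + 1]), slice(c_edges[j], c_edges[j + 1]))
                    hist = np.bincount(
                        bin_idx[cell].ravel(),
                        weights=mag[cell].ravel(),
                        minlength=self._BINS,
                    )
                    cell_px = sub[cell]
                    stats = np.array([cell_px.mean(), cell_px.std()])
                    chunks.append(np.concatenate([hist, stats]))
        vec = np.concatenate(chunks)
        assert vec.size == self.feature_dim
        return vec


class AlexNetFeatureExtractor(FeatureExtractor):
    """AlexNet-topology fine-tuned CNN feature extractor (4096-dim contract).

    The final 1000-way layer is replaced by a 14-way fetal-organ layer and
    the network fine-tuned with layer-specific learning rates
    (``TrainConfig.lr_last`` for the new layer, ``lr_rest`` elsewhere);
    features are the penultimate fully connected activations.  Requires a
    deep-learning backend with pretrained weights and is therefore
    constructed lazily.
    """

    name = "alexnet-ft"
    feature_dim = 4096
    deterministic = False

    def __init__(self) -> None:
        try:
            import torch  # noqa: F401
        except ImportError as exc:
            raise RuntimeError(
                "feature extractor 'alexnet-ft' needs the torch backend and "
                "pretrained AlexNet weights; use the default 'lite' extractor"
            ) from exc

    def extract(self, image: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError("fine-tuned weights must be loaded first")


_EXTRACTORS = {"lite": LiteFeatureExtractor, "alexnet-ft": AlexNetFeatureExtractor}


def get_extractor(name: str = "lite") -> FeatureExtractor:
    try:
        cls = _EXTRACTORS[name]
    except KeyError:
        raise KeyError(f"unknown feature extractor: {name!r}") from None
    return cls()


def extract_features(image: np.ndarray, extractor: FeatureExtractor) -> np.ndarray:
    """Feature vector of one (already resized) image."""
    vec = np.asarray(extractor.extract(image), dtype=np.float64)
    if vec.shape != (extractor.feature_dim,):
        raise ValueError(
            f"extractor {extractor.name} returned shape {vec.shape}, "
            f"expected ({extractor.feature_dim},)"
        )
    if not np.all(np.isfinite(vec)):
        raise ValueError(f"extractor {extractor.name} returned non-finite entries")
    return vec


def image_features(
    image: np.ndarray,
    extractor: FeatureExtractor,
    cfg: TrainConfig = TrainConfig(),
) -> np.ndarray:
    """Features of the central augmentation variant (the SVM-time default)."""
    aug = augment_six_crops(image, size=cfg.input_size)
    return extract_features(aug.variants[0], extractor)


# ---------------------------------------------------------------------------
# SVM stages


class Stage(Enum):
    INTER = "INTER"
    INTRA_TC = "INTRA_TC"


@dataclass
class PlaneModel:
    """A trained linear-SVM stage (with feature standardisation) bound to
    its feature extractor."""

    stage: Stage
    classes: Tuple[str, ...]
    svm: Pipeline
    extractor_name: str
    validation_accuracy: float

    def predict(self, features: np.ndarray) -> str:
        features = np.atleast_2d(features)
        # ties in decision values broken toward the lowest class index
        scores = self.svm.decision_function(features)
        classes = self.svm[-1].classes_
        if scores.ndim == 1:  # binary: signed distance to the hyperplane
            idx = int(scores[0] > 0)
        else:
            idx = int(np.argmax(scores[0]))
        return str(classes[idx])

    def save(self, path) -> None:
        joblib.dump(
            {
                "format_version": 1,
                "stage": self.stage.value,
                "classes": self.classes,
                "svm": self.svm,
                "extractor_name": self.extractor_name,
                "validation_accuracy": self.validation_accuracy,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "PlaneModel":
        blob = joblib.load(path)
        return cls(
            stage=Stage(blob["stage"]),
            classes=tuple(blob["classes"]),
            svm=blob["svm"],
            extractor_name=blob["extractor_name"],
            validation_accuracy=float(blob["validation_accuracy"]),
        )


def _fit_linear_svm(
    features: np.ndarray,
    labels: Sequence[str],
    cfg: TrainConfig,
    stage: Stage,
    classes: Tuple[str, ...],
    extractor_name: str,
) -> PlaneModel:
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    x_tr, x_va, y_tr, y_va = train_test_split(
        features,
        labels,
        train_size=cfg.train_frac,
        random_state=cfg.seed,
        stratify=labels,
    )
    svm = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svc", LinearSVC(C=cfg.svm_c, random_state=cfg.seed, max_iter=10000)),
        ]
    )
    svm.fit(x_tr, y_tr)
    val_acc = float((svm.predict(x_va) == y_va).mean())
    logger.info("%s stage validation accuracy: %.4f", stage.value, val_acc)
    return PlaneModel(
        stage=stage,
        classes=classes,
        svm=svm,
        extractor_name=extractor_name,
        validation_accuracy=val_acc,
    )


def train_inter_plane(
    features: np.ndarray,
    labels: Sequence[str],
    cfg: TrainConfig = TrainConfig(),
    extractor_name: str = "lite",
) -> PlaneModel:
    """Train the 14-class one-vs-rest linear SVM over organ classes."""
    labels = np.asarray(labels)
    missing = [c for c in ORGAN_CLASSES if c not in set(labels)]
    if missing:
        raise ValueError(f"missing organ classes in training labels: {missing}")
    unknown = sorted(set(labels) - set(ORGAN_CLASSES))
    if unknown:
        raise ValueError(f"labels outside the 14-class set: {unknown}")
    counts = {c: int((labels == c).sum()) for c in ORGAN_CLASSES}
    if min(counts.values()) < 2:
        raise ValueError("need >= 2 examples per organ class")
    return _fit_linear_svm(features, labels, cfg, Stage.INTER, ORGAN_CLASSES, extractor_name)


def train_intra_plane_tc(
    features_tc: np.ndarray,
    features_non_tc: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
    extractor_name: str = "lite",
) -> PlaneModel:
    """Train the binary TC vs non-TC linear SVM for head images.

    The reference design is near-balanced (129 TC vs 131 non-TC); no class
    reweighting is applied by default.
    """
    features_tc = np.asarray(features_tc, dtype=np.float64)
    features_non_tc = np.asarray(features_non_tc, dtype=np.float64)
    if len(features_tc) == 0 or len(features_non_tc) == 0:
        raise ValueError("both TC and non-TC classes must be nonempty")
    logger.info(
        "intra-plane class balance: %d TC / %d non-TC",
        len(features_tc),
        len(features_non_tc),
    )
    features = np.vstack([features_tc, features_non_tc])
    labels = np.array(
        [HeadSubplane.TC.value] * len(features_tc)
        + [HeadSubplane.NON_TC.value] * len(features_non_tc)
    )
    return _fit_linear_svm(
        features, labels, cfg, Stage.INTRA_TC,
        (HeadSubplane.TC.value, HeadSubplane.NON_TC.value), extractor_name,
    )


def classify_hierarchical(
    image: np.ndarray,
    inter: PlaneModel,
    intra: PlaneModel,
    extractor: FeatureExtractor,
    cfg: TrainConfig = TrainConfig(),
) -> PlaneLabel:
    """Organ prediction, then TC/non-TC only for head images.

    Non-head images never touch the intra-plane model, so the sub-plane
    stage cannot contaminate the other 13 organ routes.
    """
    if inter.extractor_name != intra.extractor_name:
        raise ValueError(
            "inter and intra models were trained with different extractors: "
            f"{inter.extractor_name!r} vs {intra.extractor_name!r}"
        )
    if extractor.name != inter.extractor_name:
        raise ValueError(
            f"extractor {extractor.name!r} does not match the models "
            f"({inter.extractor_name!r})"
        )
    feats = image_features(image, extractor, cfg)
    organ = inter.predict(feats)
    if organ != "Head":
        return PlaneLabel(organ=organ)
    sub = intra.predict(feats)
    return PlaneLabel(organ="Head", head_subplane=HeadSubplane(sub))
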