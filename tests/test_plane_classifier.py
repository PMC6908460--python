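"""Six-crop augmentation, aspect-preserving resize, the deterministic
feature extractor and the two SVM stages."""

import numpy as np
import pytest

from fetalscan import plane_classifier as pc


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(0)


# --- augmentation and resize ----------------------------------------------


def test_six_crops_cardinality(rng):
    img = rng.uniform(0, 255, (120, 160))
    aug = pc.augment_six_crops(img)
    assert len(aug.variants) == 6
    assert all(v.shape == (227, 227) for v in aug.variants)


def test_six_crops_scale_to_batches(rng):
    """n inputs always produce exactly 6n augmented images."""
    images = [rng.uniform(0, 255, (40, 40)) for _ in range(7)]
    total = sum(len(pc.augment_six_crops(im, size=(32, 32)).variants) for im in images)
    assert total == 42


def test_identity_crop_fraction(rng):
    img = rng.uniform(0, 255, (64, 64))
    aug = pc.augment_six_crops(img, crop_frac=1.0, size=(64, 64))
    assert np.allclose(aug.variants[0], pc.resize_preserving_aspect(img, (64, 64)))


def test_degenerate_image_rejected():
    with pytest.raises(ValueError):
        pc.augment_six_crops(np.zeros((1, 1)))


def test_resize_identity():
    img = np.arange(227 * 227, dtype=float).reshape(227, 227)
    out = pc.resize_preserving_aspect(img)
    assert out.shape == (227, 227)
    assert np.allclose(out, img)


def test_resize_pads_shorter_side_symmetrically():
    img = np.ones((454, 227))
    out = pc.resize_preserving_aspect(img, (227, 227))
    assert out.shape == (227, 227)
    cols_used = (out.sum(axis=0) > 0).sum()
    assert cols_used == 114  # 227 / 2 rounded, zero padding split left/right
    left_pad = np.argmax(out.sum(axis=0) > 0)
    assert abs(left_pad - (227 - 114) // 2) <= 1


def test_resize_never_distorts_aspect(rng):
    for shape in [(100, 30), (31, 97), (10, 300)]:
        img = rng.uniform(0, 255, shape)
        out = pc.resize_preserving_aspect(img, (64, 64))
        used_r = (out.sum(axis=1) > 0).sum()
        used_c = (out.sum(axis=0) > 0).sum()
        in_ratio = shape[0] / shape[1]
        out_ratio = used_r / used_c
        assert out_ratio == pytest.approx(in_ratio, rel=0.1)


# --- feature extractor -----------------------------------------------------


def test_lite_extractor_deterministic(rng):
    ext = pc.get_extractor("lite")
    img = rng.uniform(0, 255, (227, 227))
    v1 = pc.extract_features(img, ext)
    v2 = pc.extract_features(img, ext)
    assert np.array_equal(v1, v2)
    assert v1.shape == (ext.feature_dim,)


def test_black_image_maps_to_null_descriptor():
    ext = pc.get_extractor("lite")
    vec = pc.extract_features(np.zeros((227, 227)), ext)
    assert np.allclose(vec, 0.0)


def test_unknown_extractor_name():
    with pytest.raises(KeyError, match="nope"):
        pc.get_extractor("nope")


def test_class_similarity_structure(plane_suite):
    """Same-class phantom descriptors are closer (cosine) than cross-class."""
    images, truths, feats, ext, cfg = plane_suite
    by_class: dict = {}
    for f, t in zip(feats, truths):
        by_class.setdefault(t.plane, []).append(f)

    def cos(a, b):
        return a @ b / (np.linalg.norm(a) * np.linalg.norm(b) + 1e-12)

    same = np.mean([cos(v[0], v[1]) for v in by_class.values()])
    keys = sorted(by_class)
    cross = np.mean(
        [cos(by_class[keys[i]][0], by_class[keys[i + 1]][0]) for i in range(len(keys) - 1)]
    )
    assert same > cross


# --- SVM stages ------------------------------------------------------------


def _gaussian_clusters(rng, n_classes, n_per, dim=20, sigma=0.05):
    feats, labels = [], []
    for i, cls in enumerate(pc.ORGAN_CLASSES[:n_classes]):
        center = rng.normal(0, 1, dim)
        feats.append(center + sigma * rng.normal(0, 1, (n_per, dim)))
        labels += [cls] * n_per
    return np.vstack(feats), np.array(labels)


def test_separable_clusters_reach_perfect_validation(rng):
    feats, labels = _gaussian_clusters(rng, 14, 20)
    model = pc.train_inter_plane(feats, labels, pc.TrainConfig(seed=0))
    assert model.validation_accuracy == 1.0


def test_missing_class_is_an_error(rng):
    feats, labels = _gaussian_clusters(rng, 13, 10)
    with pytest.raises(ValueError, match="Hand"):
        pc.train_inter_plane(feats, labels, pc.TrainConfig(seed=0))


def test_duplicate_features_relabelled_give_chance_accuracy(rng):
    """Identical feature clouds under two labels are undecidable."""
    feats, labels = _gaussian_clusters(rng, 14, 20)
    mask_a = labels == "Abdomen"
    feats[labels == "Arm"] = feats[mask_a]  # Arm becomes a copy of Abdomen
    model = pc.train_inter_plane(feats, labels, pc.TrainConfig(seed=0))
    # accuracy over the confusable pair is far below the separable ceiling
    both = np.isin(labels, ["Abdomen", "Arm"])
    acc = np.mean([model.predict(f) == y for f, y in zip(feats[both], labels[both])])
    assert acc <= 0.75


def test_intra_label_swap_symmetry(rng):
    a = rng.normal(0, 1, (30, 10)) + 3
    b = rng.normal(0, 1, (30, 10)) - 3
    m1 = pc.train_intra_plane_tc(a, b, pc.TrainConfig(seed=0))
    m2 = pc.train_intra_plane_tc(b, a, pc.TrainConfig(seed=0))
    x = rng.normal(0, 1, 10) + 3
    assert m1.predict(x) == "TC" and m2.predict(x) == "NON_TC"


def test_empty_intra_class_rejected(rng):
    with pytest.raises(ValueError):
        pc.train_intra_plane_tc(np.zeros((0, 5)), rng.normal(0, 1, (5, 5)))


def test_training_is_seed_reproducible(rng):
    feats, labels = _gaussian_clusters(rng, 14, 10)
    m1 = pc.train_inter_plane(feats, labels, pc.TrainConfig(seed=3))
    m2 = pc.train_inter_plane(feats, labels, pc.TrainConfig(seed=3))
    probe = feats[::7]
    assert [m1.predict(f) for f in probe] == [m2.predict(f) for f in probe]


# --- hierarchy -------------------------------------------------------------


def test_non_head_images_never_touch_intra_model(plane_models):
    from fetalscan import synthetic_fixtures as sf

    pm = plane_models
    rng = np.random.default_rng(5)
    femur = sf._plane_motif("FemurHumerus", False, rng)
    label = pc.classify_hierarchical(femur, pm["inter"], pm["intra"], pm["extractor"], pm["cfg"])
    assert label.organ != "Head" or label.head_subplane is not None
    if label.organ != "Head":
        assert label.head_subplane is None


def test_tc_and_non_tc_heads_route_end_to_end(plane_models):
    """Fresh full-resolution head phantoms (never seen in training) are
    recognised as Head and routed to the correct sub-plane in the large
    majority of cases."""
    from fetalscan import synthetic_fixtures as sf

    pm = plane_models
    correct = 0
    n = 10
    for i in range(n):
        tc_img, _ = sf.make_tc_phantom(987000 + i)
        lbl = pc.classify_hierarchical(
            tc_img, pm["inter"], pm["intra"], pm["extractor"], pm["cfg"]
        )
        correct += lbl.organ == "Head" and lbl.head_subplane is pc.HeadSubplane.TC
        tt_img = sf.make_head_plane_image(988000 + i, tc_like=False)
        lbl = pc.classify_hierarchical(
            tt_img, pm["inter"], pm["intra"], pm["extractor"], pm["cfg"]
        )
        correct += lbl.organ == "Head" and lbl.head_subplane is pc.HeadSubplane.NON_TC
    assert correct >= 0.8 * 2 * n


def test_extractor_mismatch_is_an_error(plane_models, rng):
    pm = plane_models
    bad = pc.LiteFeatureExtractor()
    bad.name = "other"
    with pytest.raises(ValueError, match="extractor"):
        pc.classify_hierarchical(
            np.zeros((64, 64)), pm["inter"], pm["intra"], bad, pm["cfg"]
        )


def test_plane_label_invariant():
    with pytest.raises(ValueError):
        pc.PlaneLabel(organ="Femur")  # not a class name
    with pytest.raises(ValueError):
        pc.PlaneLabel(organ="Spine", head_subplane=pc.HeadSubplane.TC)


def test_model_save_load_roundtrip(tmp_path, rng):
    feats, labels = _gaussian_clusters(rng, 14, 10)
    model = pc.train_inter_plane(feats, labels, pc.TrainConfig(seed=0))
    path = tmp_path / "inter.joblib"
    model.save(path)
    loaded = pc.PlaneModel.load(path)
    probe = feats[::5]
    assert [model.predict(f) for f in probe] == [loaded.predict(f) for f in probe]
    assert loaded.stage is pc.Stage.INTER
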