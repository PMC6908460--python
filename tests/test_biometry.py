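"""Diffusion denoising, skull localization, shape model, segmentation and
diameter measurement."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from fetalscan import synthetic_fixtures as sf
from fetalscan import thalamus_biometry as tb
from fetalscan.repo_io import ImageRecord


# --- diffusion -------------------------------------------------------------


def test_constant_image_unchanged():
    img = np.full((40, 50), 77.0)
    assert np.allclose(tb.denoise_diffusion(img), img)


def test_extremum_principle_and_smoothing():
    rng = np.random.default_rng(0)
    step = np.zeros((60, 100))
    step[:, 50:] = 100.0
    noisy = step + rng.normal(0, 10, step.shape)
    out = tb.denoise_diffusion(noisy)
    assert out.min() >= noisy.min() - 1e-9
    assert out.max() <= noisy.max() + 1e-9
    # flat-region variance shrinks, edge stays put
    assert out[:, 10:40].var() < noisy[:, 10:40].var()
    edge = int(np.abs(np.diff(out.mean(axis=0))).argmax())
    assert abs(edge - 49) <= 1


def test_infinite_conductance_approaches_heat_diffusion():
    yy, xx = np.mgrid[0:80, 0:90]
    img = 100 + 60 * np.exp(-((yy - 40) ** 2 + (xx - 30) ** 2) / 300) + 40 * np.sin(xx / 15)
    cfg = tb.DiffusionConfig(iterations=5, time_step=0.2, conductance=1e6)
    out = tb.denoise_diffusion(img, cfg)
    ref = gaussian_filter(img, sigma=np.sqrt(2 * 0.2 * 5), mode="nearest")
    assert np.abs(out - ref)[4:-4, 4:-4].max() < 2.0


def test_unstable_time_step_rejected():
    with pytest.raises(ValueError):
        tb.DiffusionConfig(time_step=0.3)


# --- skull detection -------------------------------------------------------


def test_skull_recovery_on_ring_phantom():
    img, truth = sf.make_ellipse_ring_phantom(0)
    est = tb.detect_skull_ellipse(tb.denoise_diffusion(img), seed=0)
    ts = truth.skull
    assert np.hypot(est.cx - ts.cx, est.cy - ts.cy) <= 2.0
    assert abs(est.a - ts.a) / ts.a <= 0.03
    assert abs(est.b - ts.b) / ts.b <= 0.03
    assert abs(est.theta - ts.theta) <= 0.05


def test_circle_is_flagged_degenerate_theta():
    img, _ = sf.make_ellipse_ring_phantom(1, a=150.0, b=150.0, theta=0.0)
    est = tb.detect_skull_ellipse(tb.denoise_diffusion(img), seed=0)
    assert est.degenerate_theta
    assert est.a == pytest.approx(est.b, rel=0.02)


def test_occluded_ring_still_recovered():
    img, truth = sf.make_ellipse_ring_phantom(3, missing_arc_frac=0.25)
    est = tb.detect_skull_ellipse(tb.denoise_diffusion(img), seed=0)
    assert abs(est.a - truth.skull.a) / truth.skull.a <= 0.05
    assert abs(est.b - truth.skull.b) / truth.skull.b <= 0.05


def test_too_few_edge_points_raise():
    with pytest.raises(tb.SkullNotFoundError):
        tb.detect_skull_ellipse(np.zeros((50, 50)), seed=0)


def test_rht_bit_reproducible():
    img, _ = sf.make_ellipse_ring_phantom(2)
    den = tb.denoise_diffusion(img)
    e1 = tb.detect_skull_ellipse(den, seed=7)
    e2 = tb.detect_skull_ellipse(den, seed=7)
    assert (e1.cx, e1.cy, e1.a, e1.b, e1.theta) == (e2.cx, e2.cy, e2.a, e2.b, e2.theta)


# --- intracranial mask and orientation -------------------------------------


def test_mask_area_matches_eroded_ellipse():
    skull = tb.EllipseParams(cx=100, cy=80, a=70, b=50, theta=0.2)
    img = np.ones((160, 200))
    out = tb.mask_intracranial(img, skull, erosion_px=8)
    area = out.sum()
    expect = np.pi * (70 - 8) * (50 - 8)
    perimeter = np.pi * (3 * (62 + 42) - np.sqrt((3 * 62 + 42) * (62 + 3 * 42)))
    assert abs(area - expect) <= perimeter


def test_point_outside_ellipse_always_zero():
    skull = tb.EllipseParams(cx=50, cy=50, a=20, b=15, theta=0.0)
    out = tb.mask_intracranial(np.ones((100, 100)), skull)
    assert out[5, 5] == 0.0
    assert out[50, 50] == 1.0


def test_whole_frame_ellipse_leaves_interior_unchanged():
    skull = tb.EllipseParams(cx=50, cy=50, a=500, b=500, theta=0.0)
    img = np.arange(100 * 100, dtype=float).reshape(100, 100)
    out = tb.mask_intracranial(img, skull)
    assert np.array_equal(out, img)


def test_orientation_mirror_equivariance():
    img, truth = sf.make_tc_phantom(11, diameter_px=120)
    den = tb.denoise_diffusion(img)
    sk = tb.detect_skull_ellipse(den, seed=0)
    masked = tb.mask_intracranial(den, sk)
    res = tb.classify_orientation(masked, sk)
    assert res.label.value == truth.orientation

    mirrored = masked[:, ::-1].copy()
    sk_m = tb.EllipseParams(
        cx=(masked.shape[1] - 1) - sk.cx, cy=sk.cy, a=sk.a, b=sk.b,
        theta=float(np.mod(np.pi - sk.theta, np.pi)),
    )
    res_m = tb.classify_orientation(mirrored, sk_m)
    assert res_m.label != res.label


def test_symmetric_image_ties_to_left_low_confidence():
    skull = tb.EllipseParams(cx=100, cy=80, a=70, b=50, theta=0.0)
    img = tb.mask_intracranial(np.full((160, 200), 90.0), skull)
    res = tb.classify_orientation(img, skull)
    assert res.label is tb.OrientationLabel.LEFT_OCCIPUT
    assert res.low_confidence


# --- statistical shape model ----------------------------------------------


def test_identical_shapes_give_zero_modes():
    rng = np.random.default_rng(0)
    base = rng.uniform(-10, 10, (tb.GUITAR_L, 2))
    shapes = []
    for i in range(6):
        ang = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        shapes.append(tb.GuitarShape(3.0 * (base @ rot.T) + rng.uniform(-5, 5, 2)))
    model = tb.build_ssm(shapes)
    assert model.k == 0
    assert model.total_variance < 1e-12


def test_full_mode_reconstruction(guitar_population):
    """Keeping every mode reproduces each aligned training shape exactly."""
    shapes, _ = guitar_population
    model = tb.build_ssm(shapes, variance_retained=1.0)
    mean_flat = model.mean_shape.landmarks.ravel()
    for s in shapes[::10]:
        aligned = tb.procrustes_align(s.landmarks, model.mean_shape.landmarks).ravel()
        b = model.modes @ (aligned - mean_flat)
        recon = mean_flat + b @ model.modes
        rms = np.sqrt(np.mean((recon - aligned) ** 2))
        assert rms < 1e-8


def test_alignment_invariance_of_scores(guitar_ssm, guitar_population):
    shapes, _ = guitar_population
    s = shapes[0].landmarks
    ang = 0.7
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    transformed = tb.GuitarShape(2.5 * (s @ rot.T) + [40.0, -17.0])
    b0 = tb.ssm_scores(guitar_ssm, shapes[0])
    b1 = tb.ssm_scores(guitar_ssm, transformed)
    assert np.allclose(b0, b1, atol=1e-8)


def test_eigenvalue_sum_equals_total_variance(guitar_population):
    shapes, _ = guitar_population
    model = tb.build_ssm(shapes, variance_retained=1.0)
    aligned = np.stack(
        [tb.procrustes_align(s.landmarks, model.mean_shape.landmarks).ravel() for s in shapes]
    )
    total = ((aligned - aligned.mean(axis=0)) ** 2).sum() / (len(shapes) - 1)
    assert model.eigenvalues.sum() == pytest.approx(total, rel=1e-10)


def test_ssm_save_load_roundtrip(tmp_path, guitar_ssm):
    path = tmp_path / "ssm.npz"
    guitar_ssm.save(path)
    loaded = tb.ShapeModel.load(path)
    assert np.allclose(loaded.mean_shape.landmarks, guitar_ssm.mean_shape.landmarks)
    assert np.allclose(loaded.modes, guitar_ssm.modes)
    assert loaded.k == guitar_ssm.k


# --- segmentation ----------------------------------------------------------


def test_mean_shape_phantom_segments_near_perfectly(guitar_ssm):
    """A binary phantom drawn from the model's own mean shape is recovered
    with Dice >= 0.98."""
    skull = tb.EllipseParams(cx=400, cy=300, a=180, b=140, theta=0.0)
    mean = guitar_ssm.mean_shape.landmarks
    centered = mean - mean.mean(axis=0)
    scale = 0.35 * skull.b / np.max(np.linalg.norm(centered, axis=1))
    lm = centered * scale + [skull.cx, skull.cy]
    truth_mask = sf.render_polygon_mask(lm, (600, 800))
    img = np.full((600, 800), 160.0)
    img[truth_mask] = 20.0
    img = tb.mask_intracranial(img, skull, erosion_px=0)
    mask, fitted, info = tb.segment_guitar(img, guitar_ssm, skull)
    dice = 2 * (mask & truth_mask).sum() / (mask.sum() + truth_mask.sum())
    assert dice >= 0.98


def test_energy_sequence_non_increasing(tc_pipeline_results):
    _, _, _, _, energy_seqs = tc_pipeline_results
    for seq in energy_seqs:
        diffs = np.diff(np.asarray(seq))
        assert np.all(diffs <= 1e-6)


def test_large_beta_collapses_to_subspace(guitar_ssm):
    """With beta very large the fitted coefficients stay inside the clamp,
    so the SSM-projection residual of the result is zero."""
    img, truth = sf.make_tc_phantom(21, diameter_px=140)
    den = tb.denoise_diffusion(img)
    sk = tb.detect_skull_ellipse(den, seed=0)
    masked = tb.mask_intracranial(den, sk)
    cfg = tb.LevelSetConfig(beta=1e6)
    _, fitted, info = tb.segment_guitar(masked, guitar_ssm, sk, cfg)
    b = np.asarray(info["params"][4:])
    clamp = cfg.b_limit * np.sqrt(guitar_ssm.eigenvalues)
    assert np.all(np.abs(b) <= clamp + 1e-9)


# --- measurement -----------------------------------------------------------


def test_diameter_equals_endpoint_distance_and_mm_conversion(tc_pipeline_results):
    _, truths, results, _, _ = tc_pipeline_results
    for res in results:
        (x1, y1), (x2, y2) = res.endpoints
        assert res.diameter_px == pytest.approx(np.hypot(x2 - x1, y2 - y1))
        assert res.diameter_mm == pytest.approx(res.diameter_px * 0.1)


def test_known_diameter_recovered_within_five_percent(guitar_ssm):
    img, truth = sf.make_tc_phantom(0, diameter_px=120)
    rec = ImageRecord("t", img, pixel_spacing_mm=(0.1, 0.1))
    res = tb.measure_pipeline(rec, guitar_ssm)
    assert res.diameter_px == pytest.approx(120.0, rel=0.05)
    assert res.diameter_mm == pytest.approx(res.diameter_px * 0.1)


def test_missing_spacing_flags_and_omits_mm(guitar_ssm):
    img, _ = sf.make_tc_phantom(1, diameter_px=100)
    res = tb.measure_pipeline(ImageRecord("t", img, pixel_spacing_mm=None), guitar_ssm)
    assert res.diameter_mm is None
    assert "no_spacing" in res.flags


def test_truncated_skull_sets_incomplete_flag(guitar_ssm):
    img, _ = sf.make_tc_phantom(3, truncate_skull=True)
    res = tb.measure_pipeline(ImageRecord("t", img, pixel_spacing_mm=(0.1, 0.1)), guitar_ssm)
    assert "skull_incomplete" in res.flags
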