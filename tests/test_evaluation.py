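"""Metrics, inter-reader agreement, the review gallery and the pipeline
driver's conservation property."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fetalscan import evaluation as ev
from fetalscan import thalamus_biometry as tb


# --- accuracy / precision / recall -----------------------------------------


def test_apr_exact_formulas():
    r = ev.compute_apr(ev.ConfusionCounts(tp=80, tn=15, fp=2, fn=3))
    assert r.accuracy == pytest.approx(0.95)
    assert r.precision == pytest.approx(80 / 82)
    assert r.recall == pytest.approx(80 / 83)


def test_perfect_classifier_all_ones():
    r = ev.compute_apr(ev.ConfusionCounts(tp=10, tn=5, fp=0, fn=0))
    assert (r.accuracy, r.precision, r.recall) == (1.0, 1.0, 1.0)


def test_zero_tp_with_errors():
    r = ev.compute_apr(ev.ConfusionCounts(tp=0, tn=5, fp=3, fn=2))
    assert r.precision == 0.0 and r.recall == 0.0


def test_undefined_metrics_are_none_not_zero():
    r = ev.compute_apr(ev.ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
    assert r.precision is None and r.recall is None
    assert r.as_percent()["precision"] is None


def test_all_zero_counts_error():
    with pytest.raises(ValueError):
        ev.compute_apr(ev.ConfusionCounts(0, 0, 0, 0))


def test_confusion_from_label_sequences():
    pred = ["B", "B", "O", "B", "O"]
    true = ["B", "O", "O", "B", "B"]
    c = ev.confusion_for_label(pred, true, positive="B")
    assert (c.tp, c.tn, c.fp, c.fn) == (2, 1, 1, 1)


# --- agreement -------------------------------------------------------------


def test_identical_raters():
    r = ev.compute_agreement(["a", "b", "a"], ["a", "b", "a"])
    assert r.percent_agreement == 100.0 and r.kappa == 1.0


def test_hand_computed_two_by_two_table():
    """(a,b,c,d) = (20,5,5,70): p_o = 0.90, p_e = 0.625, kappa = 0.7333..."""
    a = ["x"] * 20 + ["y"] * 5 + ["x"] * 5 + ["y"] * 70
    b = ["x"] * 20 + ["x"] * 5 + ["y"] * 5 + ["y"] * 70
    r = ev.compute_agreement(a, b)
    assert r.percent_agreement == pytest.approx(90.0)
    assert r.kappa == pytest.approx(0.73333, abs=1e-4)


def test_kappa_matches_reference_implementation():
    from sklearn.metrics import cohen_kappa_score

    rng = np.random.default_rng(3)
    a = rng.choice(["p", "q", "r"], 500, p=[0.5, 0.3, 0.2])
    b = np.where(rng.random(500) < 0.7, a, rng.choice(["p", "q", "r"], 500))
    ours = ev.compute_agreement(a, b).kappa
    assert ours == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)


def test_independent_raters_have_near_zero_kappa():
    rng = np.random.default_rng(0)
    a = rng.integers(0, 2, 10000)
    b = rng.integers(0, 2, 10000)
    assert abs(ev.compute_agreement(a, b).kappa) <= 0.05


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        ev.compute_agreement([1, 2], [1])


@settings(max_examples=50, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)), min_size=2, max_size=60))
def test_kappa_never_exceeds_observed_agreement(pairs):
    """Chance correction: kappa <= p_o whenever p_e > 0."""
    a = [p[0] for p in pairs]
    b = [p[1] for p in pairs]
    r = ev.compute_agreement(a, b)
    assert r.kappa <= r.percent_agreement / 100.0 + 1e-12


# --- gallery ---------------------------------------------------------------


def _fake_result(i, with_mm=True):
    return tb.BiometryResult(
        diameter_px=100.0 + i,
        diameter_mm=(10.0 + i / 10) if with_mm else None,
        endpoints=((50.0, 40.0), (50.0, 140.0 + i)),
        orientation=tb.OrientationLabel.LEFT_OCCIPUT,
        skull=tb.EllipseParams(100, 100, 80, 60, 0.0),
        flags=set() if with_mm else {"no_spacing"},
        source_id=f"img_{i}",
    )


def test_gallery_ten_tiles_and_template(tmp_path):
    rng = np.random.default_rng(0)
    results = [_fake_result(i) for i in range(10)]
    images = {r.source_id: rng.uniform(0, 255, (120, 160)) for r in results}
    out = ev.build_review_gallery(images, results, tmp_path / "g")
    quality = (out / "quality.html").read_text()
    measures = (out / "measurements.html").read_text()
    assert quality.count('class="tile"') == 10
    assert measures.count('class="tile"') == 10
    import pandas as pd

    template = pd.read_csv(out / "assessment_template.csv")
    assert len(template) == 10
    assert list(template["source_id"]) == [r.source_id for r in results]


def test_gallery_empty_results_is_valid(tmp_path):
    out = ev.build_review_gallery({}, [], tmp_path / "g")
    assert (out / "quality.html").exists()
    assert (out / "measurements.html").exists()


def test_gallery_missing_image_gets_placeholder(tmp_path):
    results = [_fake_result(0)]
    out = ev.build_review_gallery({}, results, tmp_path / "g")
    assert "image unavailable" in (out / "measurements.html").read_text()


# --- pipeline conservation --------------------------------------------------


def test_every_file_has_exactly_one_disposition(tmp_path, plane_models, guitar_ssm):
    from fetalscan import synthetic_fixtures as sf

    repo = tmp_path / "repo"
    paths, truths, _ = sf.make_modality_suite(repo, n_per_class=1, seed=2)
    tc_paths, _ = sf.write_tc_suite_dicom(repo, n=1, seed=3)
    pm = plane_models
    out = ev.run_pipeline(
        repo, pm["inter"], pm["intra"], guitar_ssm,
        out_dir=tmp_path / "out", seed=0, build_gallery=False,
    )
    n_files = len(paths) + len(tc_paths)
    assert out.counts["files"] == n_files
    assert len(out.modality_manifest) == n_files
    labelled = {r["source_id"] for r in out.modality_manifest.rows}
    assert len(labelled) == n_files  # exactly one terminal row per file


def test_pipeline_rerun_is_deterministic(tmp_path, plane_models, guitar_ssm):
    from fetalscan import repo_io, synthetic_fixtures as sf

    repo = tmp_path / "repo"
    sf.make_modality_suite(repo, n_per_class=1, seed=6)
    pm = plane_models
    for sub in ("o1", "o2"):
        ev.run_pipeline(repo, pm["inter"], pm["intra"], guitar_ssm,
                        out_dir=tmp_path / sub, seed=0, build_gallery=False)
    for name in ("modality.csv", "plane.csv", "biometry.csv"):
        assert (tmp_path / "o1" / name).read_bytes() == (tmp_path / "o2" / name).read_bytes()
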