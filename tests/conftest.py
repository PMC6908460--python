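"""Shared fixtures: the expensive phantom suites and trained models are
built once per session and reused by unit and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from fetalscan import plane_classifier as pc
from fetalscan import synthetic_fixtures as sf
from fetalscan import thalamus_biometry as tb
from fetalscan.repo_io import ImageRecord


@pytest.fixture(scope="session")
def guitar_population():
    shapes, coeffs = sf.make_guitar_population(100, seed=0)
    return shapes, coeffs


@pytest.fixture(scope="session")
def guitar_ssm(guitar_population):
    shapes, _ = guitar_population
    return tb.build_ssm(shapes)


@pytest.fixture(scope="session")
def modality_suite_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("modality")
    paths, truths, manifest = sf.make_modality_suite(out, n_per_class=40, seed=0)
    return out, truths


@pytest.fixture(scope="session")
def plane_suite():
    images, truths = sf.make_plane_suite(n_per_class=40, seed=0)
    ext = pc.get_extractor("lite")
    cfg = pc.TrainConfig(seed=0)
    feats = np.array([pc.image_features(im, ext, cfg) for im in images])
    return images, truths, feats, ext, cfg


@pytest.fixture(scope="session")
def plane_models(plane_suite):
    """Inter/intra models trained on a stratified 90/10 split, plus the
    held-out indices for holdout evaluation."""
    from sklearn.model_selection import train_test_split

    images, truths, feats, ext, cfg = plane_suite
    labels = np.array([t.plane for t in truths])
    idx = np.arange(len(labels))
    itr, ite = train_test_split(idx, train_size=0.9, random_state=0, stratify=labels)
    inter = pc.train_inter_plane(feats[itr], labels[itr], cfg)

    heads = [i for i, t in enumerate(truths) if t.plane == "Head"]
    tc = [i for i in heads if truths[i].head_subplane == "TC"]
    non = [i for i in heads if truths[i].head_subplane == "NON_TC"]
    tc_tr, tc_te = tc[:15], tc[15:]
    non_tr, non_te = non[:15], non[15:]
    intra = pc.train_intra_plane_tc(feats[tc_tr], feats[non_tr], cfg)
    return {
        "inter": inter,
        "intra": intra,
        "extractor": ext,
        "cfg": cfg,
        "feats": feats,
        "labels": labels,
        "inter_test_idx": ite,
        "intra_test": (tc_te, non_te),
        "truths": truths,
    }


@pytest.fixture(scope="session")
def tc_pipeline_results(guitar_ssm):
    """Full biometry pipeline over the 25-phantom suite: results, Dice
    scores against truth masks and the recorded energy sequences."""
    images, truths = sf.make_tc_suite(25, seed=0)
    results, dices, energy_seqs = [], [], []
    for img, tr in zip(images, truths):
        rec = ImageRecord(source_id=tr.source_id, pixels=img, pixel_spacing_mm=(0.1, 0.1))
        outs: dict = {}
        res = tb.measure_pipeline(rec, guitar_ssm, stage_outputs=outs)
        tmask = sf.render_polygon_mask(tr.guitar.landmarks, img.shape)
        m = outs["guitar_mask"]
        dices.append(2 * (m & tmask).sum() / (m.sum() + tmask.sum()))
        energy_seqs.append(outs["segmentation_info"]["energies"])
        results.append(res)
    return images, truths, results, np.array(dices), energy_seqs
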