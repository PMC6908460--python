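"""Clinician-auditable evaluation: APR metrics, inter-reader agreement,
the static review gallery and the end-to-end pipeline driver.

The review gallery mirrors the two-step sonographer workflow: one page to
assess the quality of the retrieved images (thalamus and cisterna magna
visibility) and one to confirm the automated measurement, with the
measurement line drawn over each image.  It is plain offline HTML + PNG +
CSV — no server, so it can sit next to the results of a repository run.
"""

from __future__ import annotations

import base64
import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from . import bmode_cascade as bc
from . import plane_classifier as pc
from . import repo_io
from . import thalamus_biometry as tbio

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy, precision and recall in [0, 1]; ``None`` marks a metric
    whose denominator is zero (reported as undefined, never as 0)."""

    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]

    def as_percent(self) -> Dict[str, Optional[float]]:
        return {
            k: (None if v is None else 100.0 * v)
            for k, v in (
                ("accuracy", self.accuracy),
                ("precision", self.precision),
                ("recall", self.recall),
            )
        }


@dataclass(frozen=True)
class AgreementReport:
    percent_agreement: float
    kappa: float
    table: pd.DataFrame


def compute_apr(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy (TP+TN)/(TP+TN+FP+FN), precision TP/(TP+FP), recall TP/(TP+FN).

    A zero denominator yields ``None`` for that metric rather than a silent
    0; all-zero counts are an error.
    """
    if counts.total == 0:
        raise ValueError("all-zero confusion counts")
    accuracy = (counts.tp + counts.tn) / counts.total
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall)


def confusion_for_label(
    predicted: Sequence[str], truth: Sequence[str], positive: str
) -> ConfusionCounts:
    """One-vs-rest confusion counts for ``positive`` over paired labels."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    p = np.asarray(predicted) == positive
    t = np.asarray(truth) == positive
    return ConfusionCounts(
        tp=int((p & t).sum()),
        tn=int((~p & ~t).sum()),
        fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


def compute_agreement(labels_a: Sequence, labels_b: Sequence) -> AgreementReport:
    """Percentage agreement and Cohen's kappa between two raters.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with ``p_e`` the chance agreement
    from the raters' marginal label frequencies; when both raters are
    constant and identical (``p_e = 1``) kappa is defined as 1.  Works for
    any number of categories.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label sequences must be 1D and of equal length")
    if a.size == 0:
        raise ValueError("empty label sequences")
    cats = np.union1d(a, b)
    p_o = float((a == b).mean())
    pa = np.array([(a == c).mean() for c in cats])
    pb = np.array([(b == c).mean() for c in cats])
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-15:
        kappa = 1.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    table = pd.DataFrame(
        [[int(((a == ca) & (b == cb)).sum()) for cb in cats] for ca in cats],
        index=cats,
        columns=cats,
    )
    return AgreementReport(percent_agreement=100.0 * p_o, kappa=float(kappa), table=table)


# ---------------------------------------------------------------------------
# review gallery


_PAGE_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
body {{ font-family: sans-serif; background: #111; color: #eee; }}
.tile {{ display: inline-block; margin: 8px; padding: 8px; background: #222;
         border-radius: 6px; vertical-align: top; width: 340px; }}
.tile img {{ width: 320px; }}
.tile .missing {{ width: 320px; height: 240px; background: #333; color: #c66;
                  display: flex; align-items: center; justify-content: center; }}
label {{ margin-right: 10px; }}
button {{ margin: 12px; padding: 6px 14px; }}
</style></head>
<body>
<h1>{title}</h1>
<p>{subtitle}</p>
<button onclick="exportCSV()">Export assessments to CSV</button>
<div id="tiles">
{tiles}
</div>
<script>
function exportCSV() {{
  const rows = [{csv_header}];
  document.querySelectorAll('.tile').forEach(t => {{
    const vals = [t.dataset.sourceId];
    t.querySelectorAll('select').forEach(s => vals.push(s.value));
    rows.push(vals.map(v => '"' + String(v).replace(/"/g, '""') + '"').join(','));
  }});
  const blob = new Blob([rows.join('\\n')], {{type: 'text/csv'}});
  const a = document.createElement('a');
  a.href = URL.createObjectURL(blob);
  a.download = '{csv_name}';
  a.click();
}}
</script>
</body></html>
"""


def _img_to_data_uri(arr: np.ndarray, overlay: Optional[Tuple] = None) -> str:
    """PNG data URI of a grayscale/color array, optionally with the
    measurement line and endpoints drawn on top."""
    a = np.clip(arr, 0, 255).astype(np.uint8)
    if a.ndim == 2:
        a = np.stack([a] * 3, axis=-1)
    im = Image.fromarray(a)
    if overlay is not None:
        (x1, y1), (x2, y2) = overlay
        draw = ImageDraw.Draw(im)
        draw.line([(x1, y1), (x2, y2)], fill=(255, 220, 0), width=2)
        for x, y in ((x1, y1), (x2, y2)):
            draw.ellipse([x - 4, y - 4, x + 4, y + 4], outline=(255, 60, 60), width=2)
    buf = io.BytesIO()
    im.save(buf, format="PNG")
    return "data:image/png;base64," + base64.b64encode(buf.getvalue()).decode()


_QUALITY_FIELDS = ("thalamus_visible", "cisterna_magna_visible")


def build_review_gallery(
    images: Dict[str, np.ndarray],
    results: Sequence[tbio.BiometryResult],
    out_dir,
) -> Path:
    """Write the two-page static review gallery and the assessment template.

    Page one grades image quality (thalamus / cisterna magna visibility);
    page two confirms the automated measurement, whose line and endpoints
    are overlaid exactly at the result's pixel coordinates.  Missing images
    become placeholder tiles.  Returns the gallery directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def tile(res: tbio.BiometryResult, with_overlay: bool, controls: List[str]) -> str:
        img = images.get(res.source_id)
        if img is None:
            body = '<div class="missing">image unavailable</div>'
        else:
            overlay = res.endpoints if with_overlay else None
            body = f'<img src="{_img_to_data_uri(img, overlay)}">'
        ctrl = "".join(
            f'<label>{c}: <select><option>unrated</option>'
            f"<option>yes</option><option>no</option></select></label>"
            for c in controls
        )
        mm = "" if res.diameter_mm is None else f" / {res.diameter_mm:.2f} mm"
        flags = ", ".join(sorted(res.flags)) or "none"
        return (
            f'<div class="tile" data-source-id="{res.source_id}">{body}'
            f"<p>{res.source_id}<br>diameter: {res.diameter_px:.1f} px{mm}<br>"
            f"flags: {flags}</p>{ctrl}</div>"
        )

    quality_tiles = "\n".join(tile(r, False, list(_QUALITY_FIELDS)) for r in results)
    measure_tiles = "\n".join(tile(r, True, ["measurement_acceptable"]) for r in results)

    (out_dir / "quality.html").write_text(
        _PAGE_TEMPLATE.format(
            title="Image quality assessment",
            subtitle="Grade the visibility of the thalamus and the cisterna magna.",
            tiles=quality_tiles,
            csv_header='"source_id","thalamus_visible","cisterna_magna_visible"',
            csv_name="quality_assessment.csv",
        ),
        encoding="utf-8",
    )
    (out_dir / "measurements.html").write_text(
        _PAGE_TEMPLATE.format(
            title="Measurement confirmation",
            subtitle="Confirm the automated thalamus diameter (line overlaid).",
            tiles=measure_tiles,
            csv_header='"source_id","measurement_acceptable"',
            csv_name="measurement_assessment.csv",
        ),
        encoding="utf-8",
    )
    template = pd.DataFrame(
        {
            "source_id": [r.source_id for r in results],
            **{f: [""] * len(results) for f in _QUALITY_FIELDS},
            "measurement_acceptable": [""] * len(results),
        }
    )
    template.to_csv(out_dir / "assessment_template.csv", index=False)
    return out_dir


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineOutputs:
    modality_manifest: repo_io.Manifest
    plane_manifest: repo_io.Manifest
    results: List[tbio.BiometryResult]
    counts: Dict[str, int]
    gallery_dir: Optional[Path] = None


def run_pipeline(
    input_dir,
    inter: pc.PlaneModel,
    intra: pc.PlaneModel,
    ssm: tbio.ShapeModel,
    out_dir=None,
    extractor: Optional[pc.FeatureExtractor] = None,
    cascade_cfg: bc.CascadeConfig = bc.CascadeConfig(),
    seed: int = 0,
    build_gallery: bool = True,
) -> PipelineOutputs:
    """Triage -> plane classification (B-mode only) -> TC-only biometry.

    Every input file ends in exactly one terminal disposition: a modality
    label, a decode error, or a skipped unparseable file; per-stage counts
    are logged in the repository-run reporting style (files in, B-mode out,
    structure-of-interest out).
    """
    extractor = extractor or pc.get_extractor(inter.extractor_name)
    files = repo_io.scan_repository(input_dir)
    modality_manifest = repo_io.Manifest()
    plane_manifest = repo_io.Manifest()
    results: List[tbio.BiometryResult] = []
    images: Dict[str, np.ndarray] = {}
    counts = {"files": len(files), "bmode": 0, "tc": 0, "errors": 0}

    for f in files:
        decision = bc.classify_modality(f, cascade_cfg)
        label = decision.label.value if decision.label else "ERROR"
        modality_manifest.append(f.source_id, "modality", label)
        if decision.label is None:
            counts["errors"] += 1
            continue
        if decision.label is not bc.ModalityLabel.BMODE:
            continue
        counts["bmode"] += 1
        try:
            record = repo_io.load_pixels(f)
            pixels = record.pixels
            if pixels.ndim == 3:
                pixels = bc.to_grayscale(pixels)
            plane = pc.classify_hierarchical(pixels, inter, intra, extractor)
        except Exception as exc:  # noqa: BLE001 - per-file isolation
            logger.error("plane classification failed for %s: %s", f.source_id, exc)
            plane_manifest.append(f.source_id, "plane", "ERROR")
            counts["errors"] += 1
            continue
        sub = plane.head_subplane.value if plane.head_subplane else ""
        plane_manifest.append(f.source_id, "plane", plane.organ, head_subplane=sub)
        if plane.organ != "Head" or plane.head_subplane is not pc.HeadSubplane.TC:
            continue
        counts["tc"] += 1
        try:
            result = tbio.measure_pipeline(record, ssm, seed=seed)
        except Exception as exc:  # noqa: BLE001
            logger.error("biometry failed for %s: %s", f.source_id, exc)
            counts["errors"] += 1
            continue
        results.append(result)
        images[f.source_id] = pixels

    logger.info(
        "pipeline: %(files)d files in, %(bmode)d B-mode, %(tc)d TC, %(errors)d errors",
        counts,
    )
    gallery_dir = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        repo_io.write_manifest(modality_manifest, out_dir / "modality.csv")
        repo_io.write_manifest(plane_manifest, out_dir / "plane.csv")
        results_df = pd.DataFrame(
            {
                "source_id": [r.source_id for r in results],
                "diameter_px": [r.diameter_px for r in results],
                "diameter_mm": [r.diameter_mm for r in results],
                "x1": [r.endpoints[0][0] for r in results],
                "y1": [r.endpoints[0][1] for r in results],
                "x2": [r.endpoints[1][0] for r in results],
                "y2": [r.endpoints[1][1] for r in results],
                "orientation": [r.orientation.value for r in results],
                "flags": [";".join(sorted(r.flags)) for r in results],
            }
        )
        results_df.to_csv(out_dir / "biometry.csv", index=False)
        if build_gallery:
            gallery_dir = build_review_gallery(images, results, out_dir / "gallery")
    return PipelineOutputs(
        modality_manifest=modality_manifest,
        plane_manifest=plane_manifest,
        results=results,
        counts=counts,
        gallery_dir=gallery_dir,
    )
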