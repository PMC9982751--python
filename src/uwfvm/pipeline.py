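"""End-to-end pipeline: simulate -> segment -> measure -> stats.

A single :class:`PipelineConfig` (YAML-serializable) drives all stages;
one global seed fans out to per-stage seeds through named seed sequences,
so stages are independently reproducible.  Every run writes a manifest
with the config hash, per-file checksums, and the seeds used, sufficient
to reproduce any output byte-for-byte on the deterministic (baseline
segmenter) path."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as uio
from . import morpho, segment, stats, synth

logger = logging.getLogger("uwfvm")

_STAGE_IDS = {"simulate": 1, "segment": 2, "measure": 3, "stats": 4}


@dataclass
class PipelineConfig:
    out_dir: str = "uwfvm_out"
    input_dir: Optional[str] = None  # ingest instead of simulate when set
    n_per_grade: int = 5
    include_hc: bool = False
    full_scale: bool = False
    image_dialect: str = "png8"
    segmenter: str = "baseline"  # "baseline" or a model checkpoint path
    tile_size: int = segment.DEFAULT_TILE_SIZE
    binarization_threshold: float = 0.5
    mask_source: str = "predicted"  # morphometry input: "predicted" | "truth"
    window_radius: int = 5
    min_branch_len: int = 5
    region_method: str = "hull"
    posthoc: str = "welch"
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        return int((self.seed * 48271 + 1009 * _STAGE_IDS[stage]) % (2**31 - 1))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class PipelineReport:
    manifest: dict
    morphometry: pd.DataFrame
    cohort: pd.DataFrame
    stats_report: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run all stages; any stage failure aborts with a stage-tagged error."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config),
                      "config_hash": config.config_hash(),
                      "stage_seeds": {s: config.stage_seed(s) for s in _STAGE_IDS},
                      "files": {}}
    mcfg = morpho.MorphoConfig(window_radius=config.window_radius,
                               min_branch_len=config.min_branch_len,
                               region_method=config.region_method)
    model = None
    if config.segmenter not in ("baseline", "truth"):
        from ._mlp import TinyMLP

        model = segment.SegmenterModel(
            mlp=TinyMLP.load(config.segmenter),
            config=segment.TrainConfig(tile_size=config.tile_size,
                                       binarization_threshold=config.binarization_threshold),
        )

    rows_cohort, rows_morpho, seg_rows = [], [], []
    try:
        eyes = _iter_eyes(config)
    except Exception as exc:  # noqa: BLE001 - stage tagging
        raise RuntimeError(f"[simulate] {exc}") from exc

    for row, image, truth_mask, tree in eyes:
        rows_cohort.append(row)
        eye_id = row["eye_id"]
        try:
            if config.segmenter == "baseline":
                pred = segment.predict_mask("baseline", image)
            elif config.segmenter == "truth":
                pred = truth_mask
            else:
                pred = segment.predict_mask(model, image,
                                            threshold=config.binarization_threshold)
            if truth_mask is not None:
                m = segment.evaluate_segmentation(pred, truth_mask, image.fov_mask())
                seg_rows.append({"eye_id": eye_id, **m.as_dict()})
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"[segment] {eye_id}: {exc}") from exc
        try:
            meas_mask = truth_mask if (config.mask_source == "truth"
                                       and truth_mask is not None) else pred
            rec = morpho.compute_morphometry(meas_mask, image.landmarks,
                                             mcfg, eye_id=eye_id)
            rows_morpho.append(rec.as_dict())
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"[measure] {eye_id}: {exc}") from exc
        logger.info("processed %s", eye_id)

    cohort = pd.DataFrame(rows_cohort)
    morpho_df = pd.DataFrame(rows_morpho)
    full = cohort.merge(morpho_df, on="eye_id")
    full_path = out / "cohort_morphometry.csv"
    full.to_csv(full_path, index=False)
    if seg_rows:
        pd.DataFrame(seg_rows).to_csv(out / "segmentation_metrics.csv", index=False)

    try:
        report = _stats_stage(full, config, out)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"[stats] {exc}") from exc

    for f in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        if f.name != "manifest.json":
            manifest["files"][f.name] = _checksum(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return PipelineReport(manifest=manifest, morphometry=morpho_df,
                          cohort=full, stats_report=report)


def _iter_eyes(config: PipelineConfig):
    if config.input_dir is not None:
        for png in sorted(Path(config.input_dir).glob("*.png")):
            if png.stem.endswith("_mask"):
                continue
            image = uio.read_image(png, dialect=None)
            mask_path = png.with_name(png.stem + "_mask.png")
            truth = uio.read_mask(mask_path) if mask_path.exists() else None
            row = {"eye_id": png.stem, "grade": image.grade,
                   **{k: image.meta.get(k, np.nan)
                      for k in ("sex", "age", "AL_mm", "BCVA_logMAR")}}
            yield row, image, truth, None
        return
    overrides = {}
    if config.full_scale:
        overrides = dict(image_width=synth.FULL_SCALE[1],
                         image_height=synth.FULL_SCALE[0])
    yield from synth.iter_cohort_eyes(config.n_per_grade,
                                      base_seed=config.stage_seed("simulate"),
                                      include_hc=config.include_hc,
                                      **overrides)


def _stats_stage(full: pd.DataFrame, config: PipelineConfig, out: Path) -> dict:
    report: dict = {}
    graded = full[full["grade"] != "HC"]
    present = [g for g in synth.MYOPIA_GRADES
               if (graded["grade"] == g).sum() >= 2]
    for metric in stats.METRIC_COLUMNS:
        if metric not in graded.columns:
            continue
        summary = stats.summarize_by_grade(graded, metric, grades=present)
        summary.to_csv(out / f"summary_{metric}.csv")
        groups = [graded.loc[graded["grade"] == g, metric].to_numpy()
                  for g in present]
        f, p = stats.anova_oneway(groups)
        report[metric] = {"anova_F": f, "anova_p": p,
                          "grade_means": summary["mean"].to_dict()}
        if len(present) == len(synth.MYOPIA_GRADES):
            pw = stats.pairwise_grade_comparisons(graded, metric,
                                                  method=config.posthoc)
            pw.to_csv(out / f"pairwise_{metric}.csv")
    if graded["age"].notna().all() and len(graded) >= 3:
        corr = stats.correlation_table(graded)
        corr.to_csv(out / "correlations.csv")
        report["correlations"] = corr.filter(like="r_").to_dict()
    (out / "stats_report.json").write_text(json.dumps(report, indent=1))
    return report
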