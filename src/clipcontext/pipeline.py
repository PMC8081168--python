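"""End-to-end pipeline: generate -> extract -> fuse -> describe -> model -> infer.

Every stage reads and writes plain CSV so any stage can later be fed real
data with the same schemas.  One root seed derives all stage seeds; the run
manifest echoes the configuration so every number in the report is traceable
to a stage and a seed.  Clips are rendered and measured one at a time
(streaming), so memory stays flat regardless of study size.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from clipcontext import descriptives, fusion, inference, media, mixedlm, synthetic
from clipcontext.config import GeneratorConfig, RunConfig
from clipcontext.fusion import ATTENDANCE_CODES

log = logging.getLogger("clipcontext")


def extract_algo_ratings(
    situations: list[synthetic.Situation],
    config: GeneratorConfig,
    calibration_db: float = media.DEFAULT_CALIBRATION_DB,
    k: float = 3.0,
    min_area: int = 9,
) -> tuple[pd.DataFrame, list[synthetic.AnnotatorPanel]]:
    """Render each clip, run the extraction algorithms, discard the media."""
    ratings = []
    panels = []
    for clip, panel in synthetic.iter_clips(situations, config):
        r = media.rate_clip(clip, calibration_db=calibration_db, k=k, min_area=min_area)
        ratings.append(asdict(r))
        panels.append(panel)
    cols = [
        "situation_id",
        "raw_luminance",
        "perceived_lightness",
        "brightness_bin",
        "raw_db",
        "loudness_bin",
        "person_count",
    ]
    return pd.DataFrame(ratings, columns=cols), panels


def fuse_annotations(panels: list[synthetic.AnnotatorPanel]) -> pd.DataFrame:
    """Fuse raw five-rater panels into per-situation annotator measures."""
    cols = ["situation_id", "a_brightness", "a_loudness", "a_attendance"]
    return pd.DataFrame([fusion.fuse_panel(p) for p in panels], columns=cols)


def run_all(config: RunConfig) -> Path:
    """Run the full pipeline and write the report directory.

    Stage failures are logged with the stage name; downstream stages that
    depend on a failed stage are skipped, independent ones still run.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    gen = config.generator.replace(seed=config.seed)
    status: dict[str, str] = {}

    def stage(name, fn, *deps):
        if any(status.get(d) != "ok" for d in deps):
            status[name] = "skipped"
            log.info("stage=%s skipped (failed dependency)", name)
            return None
        t0 = time.time()
        try:
            result = fn()
            status[name] = "ok"
            log.info("stage=%s ok (%.1fs)", name, time.time() - t0)
            return result
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            status[name] = f"failed: {exc}"
            log.error("stage=%s failed: %s", name, exc)
            return None

    situations = stage("generate", lambda: synthetic.generate_situations(gen))
    if situations is not None:
        sit_df = synthetic.situations_to_frame(situations)
        sit_df.to_csv(out / "situations.csv", index=False)
        log.info("stage=generate rows=%d", len(sit_df))
    else:
        sit_df = None

    extracted = stage(
        "extract",
        lambda: extract_algo_ratings(
            situations, gen, config.calibration_db, config.detector_k, config.detector_min_area
        ),
        "generate",
    )
    if extracted is not None:
        algo_df, panels = extracted
        algo_df.to_csv(out / "algo_ratings.csv", index=False)
        synthetic.panels_to_frame(panels).to_csv(out / "annotations.csv", index=False)
    else:
        algo_df, panels = None, None

    fused = stage("fuse", lambda: fuse_annotations(panels), "extract")
    if fused is not None:
        fused.to_csv(out / "fused.csv", index=False)

    source_table = stage(
        "assemble",
        lambda: descriptives.assemble_source_table(sit_df, fused, algo_df),
        "generate",
        "extract",
        "fuse",
    )
    if source_table is not None:
        source_table.to_csv(out / "source_table.csv", index=False)

    # With no clips at all, the annotator and algorithm sources do not exist:
    # downstream stages run on the participant source alone, from the full
    # situation table.
    participants_only = source_table is None or len(source_table) == 0
    if participants_only and sit_df is not None:
        status["assemble"] = "ok"
        model_table = sit_df
        sources = ("participants",)
        log.info("no clips: describe/model/infer restricted to the participant source")
    else:
        model_table = source_table
        sources = None  # all three

    def _describe():
        if not participants_only:
            t1 = descriptives.table1_report(source_table)
            t1["means"].to_csv(out / "table1_means.csv", index=False)
            t1["correlations"].to_csv(out / "table1_correlations.csv", index=False)
            for (dim, s1, s2), m in t1["correspondence"].items():
                m.to_csv(out / f"correspondence_{dim}_{s1}_{s2}.csv")
            if config.write_figures:
                _correspondence_figures(t1["correspondence"], out)
        t2 = descriptives.table2_report(
            source_table if not participants_only else sit_df.iloc[0:0], sit_df
        )
        t2.to_csv(out / "table2.csv", index=False)
        return t2

    stage("describe", _describe, "assemble")

    def _model():
        kwargs = {} if sources is None else {"sources": sources}
        t3 = mixedlm.table3_report(
            model_table, g=config.hl_groups, n_nodes=config.quadrature_nodes, **kwargs
        )
        t3.to_csv(out / "table3.csv", index=False)
        return t3

    stage("model", _model, "assemble")

    def _infer():
        kwargs = {} if sources is None else {"sources": sources}
        reports = inference.inference_report(
            model_table,
            n_trees=config.n_trees,
            mode=config.inference_mode,
            seed=config.seed,
            iterations=config.inference_iterations,
            **kwargs,
        )
        df = inference.reports_to_frame(reports)
        df.to_csv(out / "inference.csv", index=False)
        return df

    stage("infer", _infer, "assemble")

    manifest = {
        "seed": config.seed,
        "stages": status,
        "config": asdict(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _correspondence_figures(matrices: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for (dim, s1, s2), m in matrices.items():
        fig, ax = plt.subplots(figsize=(4, 3.5))
        ax.imshow(m.to_numpy(), cmap="Blues")
        ax.set_xlabel(s2)
        ax.set_ylabel(s1)
        ax.set_title(dim)
        fig.tight_layout()
        fig.savefig(out / f"correspondence_{dim}_{s1}_{s2}.png", dpi=100)
        plt.close(fig)


def validate_study(study_dir: str | Path) -> list[dict]:
    """Schema/range/cross-reference checks on a written study directory.

    Returns a machine-readable issue list (empty when the study is clean);
    data problems are reported as issues, never raised.
    """
    d = Path(study_dir)
    issues: list[dict] = []
    sit_path = d / "situations.csv"
    ann_path = d / "annotations.csv"
    if not sit_path.exists():
        return [{"kind": "missing_file", "path": str(sit_path)}]
    situations = pd.read_csv(sit_path)
    for col in synthetic.SITUATION_COLUMNS:
        if col not in situations.columns:
            issues.append({"kind": "missing_column", "table": "situations", "column": col})
    for col in ("p_brightness", "p_loudness"):
        if col in situations.columns:
            bad = situations[~situations[col].between(0, 4)]
            for sid in bad["situation_id"]:
                issues.append(
                    {"kind": "range_violation", "table": "situations", "column": col, "situation_id": int(sid)}
                )
    if "p_attendance" in situations.columns:
        bad = situations[situations["p_attendance"] < 0]
        for sid in bad["situation_id"]:
            issues.append(
                {"kind": "range_violation", "table": "situations", "column": "p_attendance", "situation_id": int(sid)}
            )
    if not ann_path.exists():
        issues.append({"kind": "missing_file", "path": str(ann_path)})
        return issues
    annotations = pd.read_csv(ann_path)
    for col in synthetic.ANNOTATION_COLUMNS:
        if col not in annotations.columns:
            issues.append({"kind": "missing_column", "table": "annotations", "column": col})
    for col in ("brightness", "music", "chatter"):
        if col in annotations.columns:
            bad = annotations[~annotations[col].between(0, 4)]
            for _, r in bad.iterrows():
                issues.append(
                    {
                        "kind": "range_violation",
                        "table": "annotations",
                        "column": col,
                        "situation_id": int(r["situation_id"]),
                        "rater_id": int(r["rater_id"]),
                    }
                )
    if "attendance_cat" in annotations.columns:
        bad = annotations[~annotations["attendance_cat"].isin(ATTENDANCE_CODES)]
        for _, r in bad.iterrows():
            issues.append(
                {"kind": "invalid_category", "table": "annotations", "situation_id": int(r["situation_id"])}
            )
    arity = annotations.groupby("situation_id").size()
    for sid, k in arity.items():
        if k != 5:
            issues.append({"kind": "rater_arity", "situation_id": int(sid), "n_raters": int(k)})
    if "has_clip" in situations.columns:
        for sid in situations.loc[situations["has_clip"] == 1, "situation_id"]:
            if not (d / "clips" / str(int(sid))).is_dir():
                issues.append({"kind": "missing_clip", "situation_id": int(sid)})
    annotated = set(annotations["situation_id"].unique())
    known = set(situations["situation_id"])
    for sid in sorted(annotated - known):
        issues.append({"kind": "orphan_annotation", "situation_id": int(sid)})
    return issues
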