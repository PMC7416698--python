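"""End-to-end pipeline: simulate -> process scans -> fit/evaluate models ->
predict BCM cohorts -> treatment-potential reports."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import curvefit, io, models, oct, potential, synth
from .config import RunConfig

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.8g"

METHODS = ("I", "II", "CF")
TARGETS = ("FS", "VA")


@dataclass
class PipelineResult:
    config: RunConfig
    training_records: list[models.SubjectRecord]
    bcm_records: list[models.SubjectRecord]
    evaluations: dict[str, models.ModelEvaluation]
    curve_fits: dict[str, curvefit.CurveFitResult]
    potentials: pd.DataFrame
    group_comparisons: dict[str, dict]
    outdir: Path


def _scan_seed(seed: int, subject_id: str, scan_idx: int) -> int:
    import hashlib

    h = hashlib.sha256(f"{seed}:{subject_id}:{scan_idx}".encode()).digest()
    return int.from_bytes(h[:4], "big")


def process_subject(
    row: synth.CohortRow, config: RunConfig, save_dir: Path | None = None
) -> models.SubjectRecord:
    """Render, align, segment and featurize one subject's three scans."""
    all_samples: list[oct.StructuralSample] = []
    for k in range(3):
        scan_id = f"{row.subject_id}_scan{k + 1}"
        scan = synth.render_bscan(
            row.retina,
            lateral_extent=config.lateral_extent_deg,
            n_ascans=config.render_n_ascans,
            axial_step=config.axial_step_um,
            noise_sd=config.render_noise_sd,
            seed=_scan_seed(config.seed, row.subject_id, k),
        )
        scan = oct.downsample_lrps(scan, config.downsample_target_per_15deg)
        scan = oct.align_to_brm(scan)
        foveola = oct.locate_foveola(scan)
        seg = oct.segment_layers(scan)
        samples = oct.extract_samples(scan, seg, foveola, scan_id=scan_id)
        all_samples.extend(samples)
        if save_dir is not None:
            io.write_bscan(scan, save_dir / f"{scan_id}.tsv")
    return models.SubjectRecord(
        subject_id=row.subject_id,
        group=row.group,
        fs_measured=row.fs_db,
        va_measured=row.va_decimal,
        samples=all_samples,
    )


def build_records(
    cohort: synth.CohortTable, config: RunConfig, save_dir: Path | None = None
) -> list[models.SubjectRecord]:
    return [process_subject(row, config, save_dir) for row in cohort]


def _samples_frame(records: list[models.SubjectRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for s in rec.samples:
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "scan_id": s.scan_id,
                    "eccentricity_deg": s.eccentricity,
                    "onl_um": s.onl,
                    "is_um": s.is_len,
                    "cos_um": s.cos_len,
                    "rpe_um": s.rpe,
                    "n_extrema": s.n_extrema,
                }
            )
    return pd.DataFrame(rows)


def _mean_foveal_onl(rec: models.SubjectRecord) -> float:
    return float(np.nanmean(rec.foveal_onl_per_scan()))


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage and persist config, logs and all tables under
    ``config.outdir``.  Deterministic: same config + seed gives byte-identical
    report tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    logger.info("stage simulate: generating cohorts (seed=%d)", config.seed)
    training = synth.generate_training_cohort(
        config.n_ird, config.n_normal, config.noise_fs_sd, config.noise_va_sd,
        config.onl_cos_corr, seed=config.seed,
    )
    bcm_del = synth.generate_bcm_cohort("deletion", config.n_bcm_deletion, seed=config.seed + 1)
    bcm_c203r = synth.generate_bcm_cohort("C203R", config.n_bcm_c203r, seed=config.seed + 2)
    io.write_cohort(training, outdir / "cohort_training.csv")
    io.write_cohort(bcm_del, outdir / "cohort_bcm_deletion.csv")
    io.write_cohort(bcm_c203r, outdir / "cohort_bcm_c203r.csv")

    logger.info("stage process: rendering + segmenting scans")
    try:
        training_records = build_records(training, config)
        bcm_records = build_records(bcm_del, config) + build_records(bcm_c203r, config)
    except Exception as e:
        raise RuntimeError(f"stage process failed: {e}") from e
    _samples_frame(training_records + bcm_records).to_csv(
        outdir / "features.csv", index=False, float_format=_FLOAT_FMT
    )

    logger.info("stage evaluate: LOSO over %d subjects", len(training_records))
    evaluations: dict[str, models.ModelEvaluation] = {}
    trained: dict[str, models.TrainedModel] = {}
    for spec in models.default_model_specs(
        n_trees=config.n_trees, min_leaf=config.min_leaf,
        seed=config.seed, include_ecc=config.include_ecc_in_model_ii,
    ):
        ev = models.loso_evaluate(training_records, spec)
        evaluations[spec.name] = ev
        logger.info("model %s: %d folds, rmse=%.3f", spec.name, ev.n_folds, ev.rmse)
        ev.records.to_csv(
            outdir / f"loso_{spec.name}.csv", index=False, float_format=_FLOAT_FMT
        )
        trained[spec.name] = models.train_final(training_records, spec, evaluation=ev)

    logger.info("stage fit: curve fits")
    curve_fits: dict[str, curvefit.CurveFitResult] = {}
    onl = [_mean_foveal_onl(r) for r in training_records]
    for target in TARGETS:
        pairs = [
            (o, r.target_value(target))
            for o, r in zip(onl, training_records)
            if r.target_value(target) is not None and np.isfinite(o) and o > 0
        ]
        curve_fits[target] = curvefit.fit_log_model(
            [p[0] for p in pairs], [p[1] for p in pairs], target
        )
    with (outdir / "curve_fits.json").open("w") as fh:
        json.dump({k: dataclasses.asdict(v) for k, v in curve_fits.items()}, fh, indent=2)

    logger.info("stage potential: predicting BCM cohorts")
    pot_rows = []
    for rec in bcm_records:
        genotype = rec.group
        onls = np.asarray(rec.foveal_onl_per_scan(), dtype=float)
        if not np.any(np.isfinite(onls)):
            raise RuntimeError(
                f"stage potential: subject {rec.subject_id} has no usable foveal ONL"
            )
        onls = np.where(np.isfinite(onls), onls, np.nanmean(onls))
        foveal_onls = list(np.maximum(onls, 1.0))
        for target in TARGETS:
            measured = rec.fs_measured if target == "FS" else rec.va_measured
            for method in METHODS:
                if method == "CF":
                    pred = curvefit.predict_cf(curve_fits[target], foveal_onls)
                else:
                    pred = models.predict_subject(trained[f"{method}-{target}"], rec.samples)
                tp = potential.treatment_potential(
                    measured, pred, target, method=method,
                    subject_id=rec.subject_id, nd_floor_db=config.nd_floor_db,
                )
                pot_rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "group": genotype,
                        "target": target,
                        "method": method,
                        "measured": "" if tp.measured is None else tp.measured,
                        "measured_floored": tp.measured_floored,
                        "predicted": tp.predicted_value,
                        "half_width": tp.half_width,
                        "delta": tp.delta,
                        "delta_logmar": "" if tp.delta_logmar is None else tp.delta_logmar,
                        "lines_gained": "" if tp.lines_gained is None else tp.lines_gained,
                        "snellen_predicted": "" if tp.snellen_predicted is None else tp.snellen_predicted,
                    }
                )
    potentials = pd.DataFrame(pot_rows)
    potentials.to_csv(outdir / "potentials.csv", index=False, float_format=_FLOAT_FMT)
    for target in TARGETS:  # one report table per (target, method): 6 tables
        for method in METHODS:
            sub = potentials[(potentials["target"] == target) & (potentials["method"] == method)]
            sub.to_csv(
                outdir / f"potential_{target}_{method}.csv", index=False, float_format=_FLOAT_FMT
            )

    group_comparisons = {}
    summaries = []
    for target in TARGETS:
        sub = potentials[potentials["target"] == target]
        cmp = potential.compare_groups(sub, seed=config.seed)
        group_comparisons[target] = cmp
        s = cmp["summary"].copy()
        s.insert(0, "target", target)
        summaries.append(s)
    pd.concat(summaries, ignore_index=True).to_csv(
        outdir / "group_summary.csv", index=False, float_format=_FLOAT_FMT
    )
    with (outdir / "group_tests.json").open("w") as fh:
        json.dump(
            {t: c["tests"] for t, c in group_comparisons.items()}, fh, indent=2, default=str
        )

    eval_summary = pd.DataFrame(
        [
            {"model": name, "n_folds": ev.n_folds, "rmse": ev.rmse,
             "half_width_1p96_rmse": 1.96 * ev.rmse}
            for name, ev in evaluations.items()
        ]
        + [
            {"model": f"CF-{t}", "n_folds": "", "rmse": cf.rmse,
             "half_width_1p96_rmse": 1.96 * cf.rmse}
            for t, cf in curve_fits.items()
        ]
    )
    eval_summary.to_csv(outdir / "model_evaluation.csv", index=False, float_format=_FLOAT_FMT)

    return PipelineResult(
        config=config,
        training_records=training_records,
        bcm_records=bcm_records,
        evaluations=evaluations,
        curve_fits=curve_fits,
        potentials=potentials,
        group_comparisons=group_comparisons,
        outdir=outdir,
    )
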