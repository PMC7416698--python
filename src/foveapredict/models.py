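"""Supervised structure-function models.

Two random-forest families: Model I on segmentation-derived features
(thicknesses, extrema count, eccentricity and interaction terms) and Model II
on raw reflectivity vectors; both predict either foveal sensitivity (FS, dB)
or decimal visual acuity (VA).  Evaluation is leave-one-subject-out
cross-validation with the subject-level prediction defined as the unweighted
mean of its 21 row-level predictions (3 scans x 7 eccentricities).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .oct import StructuralSample
from .prediction import Prediction

logger = logging.getLogger(__name__)

Family = Literal["I", "II"]
Target = Literal["FS", "VA"]

SAMPLES_PER_SUBJECT = 21  # 3 scans x 7 eccentricities

MODEL_I_COLUMNS = (
    "onl", "is_len", "cos_len", "rpe", "n_extrema", "abs_ecc",
    "onl_x_cos", "onl_x_ecc", "cos_x_ecc",
    "onl_missing", "is_missing", "cos_missing", "rpe_missing",
)


@dataclass
class SubjectRecord:
    """One subject's labels and its 21 structural samples."""

    subject_id: str
    group: str
    fs_measured: float | None  # None = non-detectable
    va_measured: float
    samples: list[StructuralSample]

    def __post_init__(self) -> None:
        if len(self.samples) != SAMPLES_PER_SUBJECT:
            raise ValueError(
                f"subject {self.subject_id}: expected {SAMPLES_PER_SUBJECT} samples, "
                f"got {len(self.samples)}"
            )
        scan_ids = {s.scan_id for s in self.samples}
        if len(scan_ids) != 3:
            raise ValueError(f"subject {self.subject_id}: expected 3 scans, got {len(scan_ids)}")

    def target_value(self, target: Target) -> float | None:
        return self.fs_measured if target == "FS" else self.va_measured

    def foveal_onl_per_scan(self) -> list[float]:
        """Foveal (0-eccentricity) ONL of each of the three scans, in um."""
        out = []
        for sid in sorted({s.scan_id for s in self.samples}):
            vals = [s.onl for s in self.samples if s.scan_id == sid and s.eccentricity == 0.0]
            if len(vals) != 1:
                raise ValueError(f"scan {sid}: expected one foveal sample, got {len(vals)}")
            out.append(vals[0])
        return out


@dataclass(frozen=True)
class ModelSpec:
    """One of the paper-style four models with forest hyperparameters."""

    family: Family
    target: Target
    n_trees: int = 500
    min_leaf: int = 2
    features_per_split: int | None = None  # None -> floor(p / 3)
    seed: int = 0
    include_ecc: bool = True  # Model II position tag

    def __post_init__(self) -> None:
        if self.family not in ("I", "II") or self.target not in ("FS", "VA"):
            raise ValueError(f"unknown model family/target {self.family!r}-{self.target!r}")

    @property
    def name(self) -> str:
        return f"{self.family}-{self.target}"


@dataclass
class ModelEvaluation:
    """Leave-one-subject-out results: per-subject measured/predicted + RMSE."""

    records: pd.DataFrame  # columns subject_id, measured, predicted
    rmse: float

    @property
    def n_folds(self) -> int:
        return len(self.records)


@dataclass
class TrainedModel:
    forest: RandomForestRegressor
    spec: ModelSpec
    rmse: float | None  # from loso_evaluate; needed for prediction half-widths
    y_min: float
    y_max: float


def rmse(measured: Sequence[float], predicted: Sequence[float]) -> float:
    """Root of the mean squared per-subject (measured - predicted)."""
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.ndim != 1 or m.size < 1:
        raise ValueError("measured and predicted must be equal-length 1-d, n >= 1")
    return float(np.sqrt(np.mean((m - p) ** 2)))


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def design_matrix_I(samples: Sequence[StructuralSample]) -> pd.DataFrame:
    """Model I feature rows: thicknesses, extrema count, |eccentricity| and
    the ONL*COS / thickness*eccentricity interaction terms.

    Flagged (NaN) thicknesses are imputed as 0 with a per-thickness indicator
    column: absence of a band is signal, not missingness at random.
    """
    rows = []
    for s in samples:
        vals = {}
        miss = {}
        for name in ("onl", "is_len", "cos_len", "rpe"):
            v = getattr(s, name)
            miss[name] = 0.0 if np.isfinite(v) else 1.0
            vals[name] = v if np.isfinite(v) else 0.0
        aecc = abs(s.eccentricity)
        rows.append(
            {
                "onl": vals["onl"],
                "is_len": vals["is_len"],
                "cos_len": vals["cos_len"],
                "rpe": vals["rpe"],
                "n_extrema": float(s.n_extrema),
                "abs_ecc": aecc,
                "onl_x_cos": vals["onl"] * vals["cos_len"],
                "onl_x_ecc": vals["onl"] * aecc,
                "cos_x_ecc": vals["cos_len"] * aecc,
                "onl_missing": miss["onl"],
                "is_missing": miss["is_len"],
                "cos_missing": miss["cos_len"],
                "rpe_missing": miss["rpe"],
            }
        )
    return pd.DataFrame(rows, columns=list(MODEL_I_COLUMNS))


def design_matrix_II(
    samples: Sequence[StructuralSample], include_ecc: bool = True
) -> pd.DataFrame:
    """Model II feature rows: the raw reflectivity vector (plus |ecc| as a
    position tag unless disabled).  Ragged vectors are rejected."""
    lengths = {s.reflectivity_vec.size for s in samples}
    if len(lengths) != 1:
        raise ValueError(f"ragged reflectivity vectors: lengths {sorted(lengths)}")
    (p,) = lengths
    X = np.vstack([s.reflectivity_vec for s in samples])
    cols = [f"refl_{i}" for i in range(p)]
    df = pd.DataFrame(X, columns=cols)
    if include_ecc:
        df["abs_ecc"] = [abs(s.eccentricity) for s in samples]
    return df


def _design_matrix(samples: Sequence[StructuralSample], spec: ModelSpec) -> pd.DataFrame:
    if spec.family == "I":
        return design_matrix_I(samples)
    return design_matrix_II(samples, include_ecc=spec.include_ecc)


# ---------------------------------------------------------------------------
# fitting / evaluation
# ---------------------------------------------------------------------------

def _fold_seed(seed: int, subject_id: str) -> int:
    h = hashlib.sha256(f"{seed}:{subject_id}".encode()).digest()
    return int.from_bytes(h[:4], "big")


def _make_forest(spec: ModelSpec, p: int, seed: int) -> RandomForestRegressor:
    mf = spec.features_per_split if spec.features_per_split is not None else max(1, p // 3)
    return RandomForestRegressor(
        n_estimators=spec.n_trees,
        min_samples_leaf=spec.min_leaf,
        max_features=min(mf, p),
        random_state=seed,
        n_jobs=1,
    )


def _usable_subjects(cohort: Sequence[SubjectRecord], spec: ModelSpec) -> list[SubjectRecord]:
    usable = []
    for rec in cohort:
        if rec.target_value(spec.target) is None:
            logger.warning(
                "subject %s has no measurable %s; excluded from folds",
                rec.subject_id, spec.target,
            )
            continue
        usable.append(rec)
    # canonical order: results independent of caller's cohort ordering
    return sorted(usable, key=lambda r: r.subject_id)


def loso_evaluate(
    cohort: Sequence[SubjectRecord], spec: ModelSpec, seed: int | None = None
) -> ModelEvaluation:
    """Leave-one-subject-out cross-validation.

    One fold per subject with a measurable target; each fold fits a fresh
    forest on every row of the remaining subjects and predicts the held-out
    subject as the mean of its 21 row predictions.  The per-fold forest seed
    is derived from ``(seed, subject_id)`` so results are reproducible and
    independent of fold order.
    """
    if seed is None:
        seed = spec.seed
    usable = _usable_subjects(cohort, spec)
    if len(usable) < 3:
        raise ValueError(f"need >= 3 subjects with measurable {spec.target}")

    X_all = {rec.subject_id: _design_matrix(rec.samples, spec).to_numpy() for rec in usable}
    y_all = {rec.subject_id: float(rec.target_value(spec.target)) for rec in usable}
    p = next(iter(X_all.values())).shape[1]

    out = []
    for rec in usable:
        train_ids = [r.subject_id for r in usable if r.subject_id != rec.subject_id]
        assert rec.subject_id not in train_ids  # no leakage, by construction
        X_tr = np.vstack([X_all[i] for i in train_ids])
        y_tr = np.concatenate([np.full(X_all[i].shape[0], y_all[i]) for i in train_ids])
        forest = _make_forest(spec, p, _fold_seed(seed, rec.subject_id))
        forest.fit(X_tr, y_tr)
        pred = float(np.mean(forest.predict(X_all[rec.subject_id])))
        out.append({"subject_id": rec.subject_id, "measured": y_all[rec.subject_id], "predicted": pred})

    records = pd.DataFrame(out)
    return ModelEvaluation(
        records=records,
        rmse=rmse(records["measured"], records["predicted"]),
    )


def train_final(
    cohort: Sequence[SubjectRecord],
    spec: ModelSpec,
    seed: int | None = None,
    evaluation: ModelEvaluation | None = None,
) -> TrainedModel:
    """Fit the final forest on all rows of all usable subjects.

    ``evaluation`` (from :func:`loso_evaluate`) supplies the RMSE used for
    prediction half-widths.
    """
    if seed is None:
        seed = spec.seed
    usable = _usable_subjects(cohort, spec)
    if len(usable) < 2:
        raise ValueError("need at least 2 subjects to train")
    X = np.vstack([_design_matrix(rec.samples, spec).to_numpy() for rec in usable])
    y = np.concatenate(
        [np.full(SAMPLES_PER_SUBJECT, float(rec.target_value(spec.target))) for rec in usable]
    )
    forest = _make_forest(spec, X.shape[1], _fold_seed(seed, "__final__"))
    forest.fit(X, y)
    return TrainedModel(
        forest=forest,
        spec=spec,
        rmse=None if evaluation is None else evaluation.rmse,
        y_min=float(y.min()),
        y_max=float(y.max()),
    )


def predict_subject(model: TrainedModel, samples: Sequence[StructuralSample]) -> Prediction:
    """Subject-level prediction: mean of the 21 row predictions, with
    half-width ``1.96 * RMSE`` of the evaluated model."""
    if len(samples) != SAMPLES_PER_SUBJECT:
        raise ValueError(f"expected {SAMPLES_PER_SUBJECT} samples, got {len(samples)}")
    if model.rmse is None:
        raise ValueError("model has no evaluation RMSE; run loso_evaluate first")
    X = _design_matrix(samples, model.spec).to_numpy()
    value = float(np.mean(model.forest.predict(X)))
    return Prediction(value=value, half_width=1.96 * model.rmse)


def default_model_specs(
    n_trees: int = 500, min_leaf: int = 2, seed: int = 0, include_ecc: bool = True
) -> list[ModelSpec]:
    """The four paper-style models: I-FS, I-VA, II-FS, II-VA."""
    return [
        ModelSpec(family=f, target=t, n_trees=n_trees, min_leaf=min_leaf,
                  seed=seed, include_ecc=include_ecc)
        for f in ("I", "II")
        for t in ("FS", "VA")
    ]
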