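"""Response preparation, classifier mapping, and validation schemes.

The response is prepared by piecewise-linear interpolation of the sparse
clinical assessments to weekly values, then rounding to the nearest
integer so the task becomes multi-class classification (ties at .5 round
half away from zero).  A random forest maps the selected dysphonia
measures to the integer UPDRS class; the predicted score is the
predicted class label.  Performance is summarized by the mean absolute
error MAE = (1/N) sum_i |yhat_i - y_i|.

Two validation schemes are provided, mirroring the two deployment
scenarios:

* ``cross_validate`` -- 10-fold cross-validation repeated (by default)
  100 times with a fresh random permutation each repeat, phonation-level
  splits within one sex stratum; reports mean, sd and the empirical 95%
  confidence interval of the per-repeat MAEs.
* ``tracking_validate`` -- leave-one-subject-out tracking: the model is
  trained on all other subjects plus the left-out subject's first weeks
  (default 4), with that subject's early UPDRS mean attached as an extra
  calibration feature, and evaluated on the subject's remaining weeks
  (within-week predictions averaged before the error).

Subject identifiers, age and timing columns are never presented to the
learner; this is asserted before every fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .clinical import MOTOR_RANGE, TOTAL_RANGE, UPDRSAssessment, UPDRSTrajectory

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationReport", "interpolate_weekly", "discretize", "mae",
    "fit_predict", "cross_validate", "tracking_validate", "spearman_report",
    "FORBIDDEN_COLUMNS", "CALIBRATION_COLUMN",
]

FORBIDDEN_COLUMNS = frozenset({
    "subject_id", "age", "week", "slot", "sex", "loudness",
    "motor_updrs", "total_updrs",
})
CALIBRATION_COLUMN = "calibration_updrs_mean"
_RF_DEFAULTS = dict(n_estimators=500, max_features="sqrt")


@dataclass
class ValidationReport:
    """Per-repeat MAEs and their summary for one validation run."""

    scheme: str                      # "cv10x100" | "tracking"
    stratum: str                     # "male" | "female" | "all"
    response: str                    # "motor" | "total"
    per_repeat_mae: np.ndarray
    mae_mean: float
    mae_sd: float
    ci95: tuple[float, float]
    n_train: int
    n_test: int
    selected_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.per_repeat_mae = np.asarray(self.per_repeat_mae, dtype=float)
        if np.any(self.per_repeat_mae < 0):
            raise ValueError("MAE cannot be negative")
        tol = 1e-9 * max(1.0, abs(self.mae_mean))
        if not (self.ci95[0] - tol <= self.mae_mean <= self.ci95[1] + tol):
            raise ValueError("CI does not bracket the mean")

    def summary(self) -> str:
        return (
            f"{self.scheme} [{self.stratum}/{self.response}] "
            f"MAE {self.mae_mean:.2f} +/- {self.mae_sd:.2f} "
            f"(95% CI [{self.ci95[0]:.2f}, {self.ci95[1]:.2f}]; "
            f"n_train={self.n_train}, n_test={self.n_test}, "
            f"repeats={self.per_repeat_mae.size})"
        )


# ----------------------------------------------------- response preparation
def interpolate_weekly(assessments: Sequence[UPDRSAssessment]) -> UPDRSTrajectory:
    """Weekly UPDRS by piecewise-linear interpolation through the visits."""
    if len(assessments) < 2:
        raise ValueError("need at least two assessments to interpolate")
    weeks = [a.week for a in assessments]
    if len(set(weeks)) != len(weeks):
        raise ValueError("duplicate assessment weeks")
    assessments = sorted(assessments, key=lambda a: a.week)
    src = np.array([a.week for a in assessments], dtype=float)
    grid = np.arange(assessments[0].week, assessments[-1].week + 1)
    motor = np.interp(grid, src, [a.motor for a in assessments])
    total = np.interp(grid, src, [a.total for a in assessments])
    return UPDRSTrajectory(
        subject_id="",
        weeks=grid,
        motor_weekly=motor,
        total_weekly=total,
        source_weeks=tuple(int(a.week) for a in assessments),
    )


def discretize(y: float | np.ndarray, scale: str = "motor") -> np.ndarray | int:
    """Round a UPDRS score to the nearest integer class.

    Ties (.5) round half away from zero.  Out-of-range scores are
    rejected against the motor [0, 108] or total [0, 176] scale.
    """
    lo, hi = MOTOR_RANGE if scale == "motor" else TOTAL_RANGE
    arr = np.asarray(y, dtype=float)
    if np.any(arr < lo) or np.any(arr > hi):
        raise ValueError(f"score outside the {scale}-UPDRS range [{lo}, {hi}]")
    rounded = np.floor(arr + 0.5).astype(int)   # half away from zero (scores >= 0)
    return int(rounded) if np.isscalar(y) else rounded


def mae(predicted, actual) -> float:
    """Mean absolute error between predicted and actual scores."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValueError("length mismatch between predictions and actuals")
    if p.size == 0:
        raise ValueError("empty prediction set")
    return float(np.mean(np.abs(p - a)))


# ------------------------------------------------------------ learner layer
def _check_columns(columns) -> None:
    bad = FORBIDDEN_COLUMNS.intersection(columns)
    if bad:
        raise ValueError(f"identifier/timing columns must not reach the learner: {sorted(bad)}")


def _impute_medians(train: pd.DataFrame, test: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    med = train.median(numeric_only=True)
    med = med.fillna(0.0)
    return train.fillna(med), test.fillna(med)


def fit_predict(
    train_X: pd.DataFrame,
    train_y,
    test_X: pd.DataFrame,
    feature_subset: Optional[Sequence[str]] = None,
    params: Optional[dict] = None,
    seed: int = 0,
    learner: str = "rf",
) -> np.ndarray:
    """Fit the classifier on discretized scores and predict integer scores.

    ``learner="dummy"`` predicts the rounded training mean -- the
    baseline any informative model must beat.
    """
    if feature_subset is not None:
        missing = [f for f in feature_subset if f not in train_X.columns]
        if missing:
            raise ValueError(f"feature subset not in the registry/table: {missing}")
        train_X = train_X[list(feature_subset)]
        test_X = test_X[list(feature_subset)]
    _check_columns(train_X.columns)
    y = np.asarray(train_y)
    if not np.issubdtype(y.dtype, np.integer):
        raise ValueError("training response must be discretized to integer classes")
    if learner == "dummy":
        return np.full(len(test_X), int(np.floor(y.mean() + 0.5)))
    train_X, test_X = _impute_medians(train_X, test_X)
    rf_params = dict(_RF_DEFAULTS)
    rf_params.update(params or {})
    model = RandomForestClassifier(random_state=int(seed) & 0x7FFFFFFF, n_jobs=1, **rf_params)
    model.fit(train_X.to_numpy(), y)
    return model.predict(test_X.to_numpy()).astype(int)


# -------------------------------------------------------------- validation
def _split_features_response(data: pd.DataFrame, response: str) -> tuple[pd.DataFrame, np.ndarray, str]:
    col = {"motor": "motor_updrs", "total": "total_updrs"}.get(response, response)
    if col not in data.columns:
        raise ValueError(f"response column {col!r} not in table")
    scale = "motor" if "motor" in col else "total"
    y = discretize(data[col].to_numpy(), scale=scale)
    drop = [c for c in data.columns if c in FORBIDDEN_COLUMNS or c == col]
    X = data.drop(columns=drop)
    return X, y, scale


def _summarize(per_repeat: np.ndarray, scheme: str, stratum: str, response: str,
               n_train: int, n_test: int, features: list[str]) -> ValidationReport:
    per_repeat = np.asarray(per_repeat, dtype=float)
    ci = (float(np.percentile(per_repeat, 2.5)), float(np.percentile(per_repeat, 97.5)))
    return ValidationReport(
        scheme=scheme,
        stratum=stratum,
        response=response,
        per_repeat_mae=per_repeat,
        mae_mean=float(np.mean(per_repeat)),
        mae_sd=float(np.std(per_repeat, ddof=1)) if per_repeat.size > 1 else 0.0,
        ci95=ci,
        n_train=n_train,
        n_test=n_test,
        selected_features=features,
    )


def cross_validate(
    data: pd.DataFrame,
    response: str = "motor",
    n_folds: int = 10,
    n_repeats: int = 100,
    seed: int = 0,
    feature_subset: Optional[Sequence[str]] = None,
    params: Optional[dict] = None,
    learner: str = "rf",
    stratum: str = "all",
) -> ValidationReport:
    """Repeated k-fold cross-validation at phonation level.

    Each repeat randomly permutes the rows, splits them into ``n_folds``
    contiguous blocks, and averages the fold test MAEs; the report
    carries the distribution of per-repeat MAEs.  Nominal split sizes
    follow the 90/10 convention: n_test = floor(N / n_folds),
    n_train = N - n_test.
    """
    n = len(data)
    if n_folds < 2 or n_folds > n:
        raise ValueError("n_folds must be in [2, n_samples]")
    X, y, _ = _split_features_response(data, response)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xCF]))
    per_repeat = np.empty(n_repeats)
    for rep in range(n_repeats):
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_folds)
        fold_maes = np.empty(n_folds)
        for i, test_idx in enumerate(folds):
            train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
            pred = fit_predict(
                X.iloc[train_idx], y[train_idx], X.iloc[test_idx],
                feature_subset=feature_subset, params=params,
                seed=int(rng.integers(0, 2**31 - 1)), learner=learner,
            )
            fold_maes[i] = mae(pred, y[test_idx])
        per_repeat[rep] = fold_maes.mean()
    return _summarize(
        per_repeat, f"cv{n_folds}x{n_repeats}", stratum, response,
        n_train=n - n // n_folds, n_test=n // n_folds,
        features=list(feature_subset) if feature_subset else [],
    )


def tracking_validate(
    data: pd.DataFrame,
    response: str = "total",
    calibration_weeks: int = 4,
    seed: int = 0,
    feature_subset: Optional[Sequence[str]] = None,
    params: Optional[dict] = None,
    stratum: str = "all",
) -> ValidationReport:
    """Leave-one-subject-out tracking validation with early-week calibration.

    For each left-out subject, training data are all rows of the other
    subjects plus the subject's own first ``calibration_weeks`` weeks;
    the mean of those weeks' UPDRS is attached to every row as a
    calibration column (each training subject carries its own early-week
    mean).  Predictions on the remaining weeks are averaged within week
    before the absolute error; the report aggregates per-subject MAEs.
    """
    if "subject_id" not in data.columns or "week" not in data.columns:
        raise ValueError("tracking requires subject_id and week columns")
    subjects = data["subject_id"].unique()
    if subjects.size < 2:
        raise ValueError("tracking requires at least two subjects")
    col = {"motor": "motor_updrs", "total": "total_updrs"}[response]
    scale = "motor" if response == "motor" else "total"

    # per-subject early-week calibration value (mean of first weeks' UPDRS)
    calib: dict[str, float] = {}
    usable: list[str] = []
    for sid, grp in data.groupby("subject_id"):
        weeks = np.sort(grp["week"].unique())
        if weeks.size < calibration_weeks + 1:
            logger.info("subject %s skipped: only %d weeks", sid, weeks.size)
            continue
        early = weeks[:calibration_weeks]
        calib[sid] = float(grp.loc[grp["week"].isin(early), col].mean())
        usable.append(sid)
    if len(usable) < 2:
        raise ValueError("fewer than two subjects have enough weeks for tracking")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x7C]))
    per_subject = []
    n_train_last = n_test_last = 0
    for sid in usable:
        own = data[data["subject_id"] == sid]
        weeks = np.sort(own["week"].unique())
        early_weeks = set(weeks[:calibration_weeks])
        own_calib = own[own["week"].isin(early_weeks)]
        own_test = own[~own["week"].isin(early_weeks)]
        others = data[(data["subject_id"] != sid) & (data["subject_id"].isin(usable))]
        train = pd.concat([others, own_calib], axis=0)

        X_tr, y_tr, _ = _split_features_response(train, response)
        X_te, y_te, _ = _split_features_response(own_test, response)
        X_tr = X_tr.copy()
        X_te = X_te.copy()
        X_tr[CALIBRATION_COLUMN] = train["subject_id"].map(calib).to_numpy()
        X_te[CALIBRATION_COLUMN] = calib[sid]

        subset = list(feature_subset) + [CALIBRATION_COLUMN] if feature_subset else None
        pred = fit_predict(X_tr, y_tr, X_te, feature_subset=subset, params=params,
                           seed=int(rng.integers(0, 2**31 - 1)))

        # average within-week predictions, then error per week
        frame = pd.DataFrame({
            "week": own_test["week"].to_numpy(),
            "pred": pred.astype(float),
            "actual": y_te.astype(float),
        })
        weekly = frame.groupby("week").agg(pred=("pred", "mean"), actual=("actual", "first"))
        per_subject.append(mae(weekly["pred"].to_numpy(), weekly["actual"].to_numpy()))
        n_train_last, n_test_last = len(train), len(own_test)
    return _summarize(
        np.asarray(per_subject), "tracking", stratum, response,
        n_train=n_train_last, n_test=n_test_last,
        features=list(feature_subset) if feature_subset else [],
    )


def spearman_report(X: pd.DataFrame, y) -> pd.DataFrame:
    """Spearman rho and two-sided p per feature column against the response."""
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("response is constant; correlations undefined")
    rows = []
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        ok = np.isfinite(x)
        if x[ok].size < 3 or np.unique(x[ok]).size < 2:
            rows.append({"feature": col, "rho": np.nan, "p": np.nan, "flag": "constant_or_missing"})
            continue
        rho, p = stats.spearmanr(x[ok], y[ok])
        rows.append({"feature": col, "rho": float(rho), "p": float(p), "flag": ""})
    return pd.DataFrame(rows).set_index("feature")
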