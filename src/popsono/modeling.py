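"""Per-pathology gradient-boosted classification.

One XGBoost binary classifier is trained per prolapse target on the
(organ, window) records.  Class imbalance is handled by weighting positive
records with ``|Neg| / |Pos|``; hyperparameters are chosen by randomized
search scored by record-level average precision under grouped 5-fold
cross-validation (all records of a patient stay in one fold, preventing
leakage across the many records each patient contributes).  Patient-level
diagnoses are obtained by majority vote over a patient's record-level
calls, with ties resolved toward the positive (recall-favouring) side.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint, uniform
from sklearn.metrics import average_precision_score
from sklearn.model_selection import ParameterSampler
from xgboost import XGBClassifier

from popsono.features import FEATURE_COLUMNS
from popsono.organs import ORGANS

TARGETS: tuple[str, ...] = (
    "cystocele",
    "cystourethrocele",
    "uterine_prolapse",
    "cervical_elongation",
    "rectocele",
    "enterocele",
    "any_prolapse",
)

RECORD_THRESHOLD = 0.5  # record-level probability cut before voting


@dataclass(frozen=True)
class SplitPlan:
    """Patient-level train/test split."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"patients in both train and test: {sorted(overlap)}")


def split_patients(
    patient_ids: Sequence[str],
    train_frac: float = 0.68,
    seed: int = 0,
    train_count: int | None = None,
) -> SplitPlan:
    """Randomly split patients (not records) into train and test sets.

    By default the train size is ``round(train_frac * n)``; pass
    ``train_count`` to pin exact set sizes instead of relying on the
    fraction's rounding.
    """
    ids = list(dict.fromkeys(patient_ids))
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 patients to split")
    if train_count is None:
        train_count = int(round(train_frac * n))
    if not 1 <= train_count <= n - 1:
        raise ValueError(f"train_count {train_count} leaves an empty split for n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train = tuple(ids[i] for i in sorted(order[:train_count]))
    test = tuple(ids[i] for i in sorted(order[train_count:]))
    return SplitPlan(train_ids=train, test_ids=test, seed=seed)


def compute_pos_weight(labels: Sequence[int] | np.ndarray, target: str = "") -> float:
    """Positive-class weight |Neg| / |Pos|.

    After weighting, the total weighted mass of positive records equals the
    mass of negative records exactly.
    """
    y = np.asarray(labels).astype(int)
    pos = int((y == 1).sum())
    neg = int((y == 0).sum())
    if pos == 0:
        name = f" for target {target!r}" if target else ""
        raise ValueError(f"no positive records{name}: pos_weight undefined")
    return neg / pos


def grouped_kfold(
    groups: Sequence, k: int = 5, seed: int = 0
) -> np.ndarray:
    """Assign each record to one of k folds, keeping groups intact.

    Groups (patients) are shuffled and split into k contiguous blocks, so
    fold group-counts differ by at most one and no group straddles folds.
    Returns an integer fold id per record.
    """
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(uniq) < k:
        raise ValueError(f"{len(uniq)} groups cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    fold_of_group: dict = {}
    for fold, block in enumerate(np.array_split(uniq[order], k)):
        for g in block:
            fold_of_group[g] = fold
    return np.array([fold_of_group[g] for g in groups], dtype=int)


def average_precision(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Average precision: sum over thresholds of (R_n - R_{n-1}) * P_n."""
    y = np.asarray(labels).astype(int)
    if y.sum() == 0:
        raise ValueError("average precision undefined without positive labels")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def default_search_space() -> dict:
    """Shipped randomized-search space over standard GBM ranges."""
    return {
        "max_depth": randint(2, 9),
        "learning_rate": loguniform(0.01, 0.3),
        "n_estimators": randint(50, 501),
        "subsample": uniform(0.5, 0.5),
        "colsample_bytree": uniform(0.5, 0.5),
        "reg_lambda": uniform(0.0, 10.0),
    }


@dataclass
class SearchConfig:
    n_iter: int = 25
    k: int = 5
    seed: int = 0
    space: dict | None = None

    def __post_init__(self) -> None:
        if self.k != 5:
            raise ValueError("grouped cross-validation uses k = 5 folds")
        if self.n_iter < 1:
            raise ValueError("n_iter must be at least 1")
        if self.space is not None and not self.space:
            raise ValueError("search space must be non-empty")

    def resolved_space(self) -> dict:
        return self.space if self.space is not None else default_search_space()


@dataclass
class FittedModel:
    target: str
    params: dict
    booster: object  # anything exposing predict_proba (XGBClassifier or adapter)
    pos_weight: float
    cv_ap: list[float] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)
    seed: int = 0


@dataclass(frozen=True)
class PatientPrediction:
    patient_id: str
    target: str
    record_calls: tuple[int, ...]
    final: int


def design_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Model inputs: the 68 aggregate features plus the integer-coded organ."""
    X = table[list(FEATURE_COLUMNS)].astype(float).copy()
    X["organ_code"] = table["organ"].map({o: i for i, o in enumerate(ORGANS)})
    if X["organ_code"].isna().any():
        bad = sorted(set(table.loc[X["organ_code"].isna(), "organ"]))
        raise ValueError(f"unknown organ values: {bad}")
    return X


def _make_booster(params: dict, pos_weight: float, seed: int) -> XGBClassifier:
    return XGBClassifier(
        **params,
        objective="binary:logistic",
        tree_method="hist",
        scale_pos_weight=pos_weight,
        random_state=seed,
        n_jobs=1,
        eval_metric="logloss",
    )


def tune_and_train(
    table: pd.DataFrame, target: str, search: SearchConfig
) -> FittedModel:
    """Randomized hyperparameter search with grouped 5-fold CV, then refit.

    Candidates are scored by mean record-level average precision over the
    grouped folds (folds whose validation part has no positive record are
    skipped, their AP being undefined).  The best candidate is refit on the
    full training table with the training-set pos_weight applied.
    """
    if target not in table.columns:
        raise ValueError(f"target column {target!r} missing from table")
    y = table[target].to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError(f"target {target!r} is single-class in the training table")
    X = design_matrix(table)
    constant = [c for c in X.columns if X[c].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(f"all-constant features: {constant}", stacklevel=2)
    groups = table["patient_id"].to_numpy()
    folds = grouped_kfold(groups, k=search.k, seed=search.seed)
    _assert_group_integrity(groups, folds)

    candidates = list(
        ParameterSampler(search.resolved_space(), n_iter=search.n_iter, random_state=search.seed)
    )
    best_score = -np.inf
    best_params: dict | None = None
    best_fold_ap: list[float] = []
    Xv = X.to_numpy()
    for params in candidates:
        fold_ap: list[float] = []
        for fold in range(search.k):
            tr = folds != fold
            va = ~tr
            y_tr, y_va = y[tr], y[va]
            if y_tr.sum() == 0 or y_va.sum() == 0:
                continue
            w = compute_pos_weight(y_tr, target)
            booster = _make_booster(params, w, search.seed)
            booster.fit(Xv[tr], y_tr)
            scores = booster.predict_proba(Xv[va])[:, 1]
            fold_ap.append(average_precision(scores, y_va))
        if not fold_ap:
            continue
        score = float(np.mean(fold_ap))
        if score > best_score:
            best_score, best_params, best_fold_ap = score, params, fold_ap
    if best_params is None:
        raise ValueError(
            f"no usable CV fold for target {target!r}: positives too sparse"
        )

    full_weight = compute_pos_weight(y, target)
    final = _make_booster(best_params, full_weight, search.seed)
    final.fit(Xv, y)
    return FittedModel(
        target=target,
        params=dict(best_params),
        booster=final,
        pos_weight=full_weight,
        cv_ap=best_fold_ap,
        feature_names=list(X.columns),
        seed=search.seed,
    )


def _assert_group_integrity(groups: np.ndarray, folds: np.ndarray) -> None:
    frame = pd.DataFrame({"g": groups, "f": folds})
    per_group = frame.groupby("g")["f"].nunique()
    if (per_group > 1).any():
        raise AssertionError("group integrity violated: a patient straddles folds")


def predict_records(model: FittedModel, table: pd.DataFrame) -> np.ndarray:
    """Record-level positive-class probabilities."""
    X = design_matrix(table)[model.feature_names]
    return model.booster.predict_proba(X.to_numpy())[:, 1]


def vote(calls: Sequence[int]) -> int:
    """Majority vote over record-level calls; an exact tie is positive."""
    calls = np.asarray(calls).astype(int)
    if calls.size == 0:
        raise ValueError("cannot vote over zero records")
    n_pos = int(calls.sum())
    return int(n_pos >= calls.size - n_pos)


def predict_patient(model: FittedModel, records: pd.DataFrame) -> PatientPrediction:
    """Vote a patient's record-level calls into one diagnosis.

    Each record is scored and thresholded at 0.5; the most frequent call
    wins and an exact tie is resolved as positive.
    """
    if len(records) == 0:
        raise ValueError("need at least one record to predict a patient")
    pids = records["patient_id"].unique()
    if len(pids) != 1:
        raise ValueError("predict_patient expects records of a single patient")
    calls = (predict_records(model, records) >= RECORD_THRESHOLD).astype(int)
    final = vote(calls)
    return PatientPrediction(
        patient_id=str(pids[0]),
        target=model.target,
        record_calls=tuple(int(c) for c in calls),
        final=final,
    )


def predict_patients(model: FittedModel, table: pd.DataFrame) -> pd.DataFrame:
    """Patient-level predictions for every patient in a feature table."""
    rows = [
        {
            "patient_id": pid,
            "target": model.target,
            "prediction": predict_patient(model, group).final,
        }
        for pid, group in table.groupby("patient_id", sort=True)
    ]
    return pd.DataFrame(rows, columns=["patient_id", "target", "prediction"])


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


class _BoosterProba:
    """Minimal predict_proba adapter around a raw xgboost Booster."""

    def __init__(self, booster) -> None:
        self._booster = booster

    def predict_proba(self, X) -> np.ndarray:
        import xgboost as xgb

        p = self._booster.predict(xgb.DMatrix(np.asarray(X), missing=np.nan))
        return np.column_stack([1.0 - p, p])


def save_model(model: FittedModel, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    booster = (
        model.booster.get_booster()
        if hasattr(model.booster, "get_booster")
        else model.booster._booster
    )
    booster.save_model(out_dir / "booster.json")
    meta = {
        "target": model.target,
        "params": model.params,
        "pos_weight": model.pos_weight,
        "cv_ap": model.cv_ap,
        "feature_names": model.feature_names,
        "seed": model.seed,
    }
    (out_dir / "meta.json").write_text(json.dumps(meta, indent=2))
    return out_dir


def load_model(model_dir: str | Path) -> FittedModel:
    import xgboost as xgb

    model_dir = Path(model_dir)
    meta = json.loads((model_dir / "meta.json").read_text())
    raw = xgb.Booster()
    raw.load_model(model_dir / "booster.json")
    booster = _BoosterProba(raw)
    return FittedModel(
        target=meta["target"],
        params=meta["params"],
        booster=booster,
        pos_weight=meta["pos_weight"],
        cv_ap=meta["cv_ap"],
        feature_names=meta["feature_names"],
        seed=meta["seed"],
    )
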