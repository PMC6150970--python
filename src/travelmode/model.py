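"""Five-class gradient-boosted tree model: training, prediction,
participant-level cross-validation and the moving-window-size sweep.

The classifier is an XGBoost multiclass ensemble with a deliberately
conservative configuration: learning rate 0.1 (half-strength updates to
avoid over-fitting), 200 boosting rounds, row subsample 0.2, maximum tree
depth 10 and minimum split loss (gamma) 10. Prediction takes the argmax of
the per-class probabilities, breaking exact ties by the canonical mode order
(walk, cycle, vehicle, train, stationary). Missing feature values (epochs
without a GPS match) are passed through as NaN and routed by the trees'
native default directions.

Cross-validation is at the participant level: people, not epochs, are
randomly assigned to folds, so no individual contributes to both the
training and the test side of any fold. Training is single-threaded by
default, which makes fixed-seed runs reproducible at the label level;
parallelism is opt-in and excluded from that contract.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .evaluation import ConfusionMatrix, confusion_matrix, f1, mode_metrics
from .io_formats import MODES
from .window_features import assemble_feature_matrix, build_feature_rows

log = logging.getLogger(__name__)

#: Questionnaire travel-mode categories collapsed to the five model classes.
REPORTED_MODE_MAP = {
    "walk": "walk",
    "bicycle": "cycle",
    "car/van driver": "vehicle",
    "car/van passenger": "vehicle",
    "taxi": "vehicle",
    "motorcycle/moped/scooter": "vehicle",
    "bus/minibus/coach": "vehicle",
    "train (overground)": "train",
    "underground": "train",
}


def map_reported_mode(reported: str) -> str:
    """Collapse a reported questionnaire category into one of the five
    model classes (motorised road transport pools into "vehicle", overground
    and underground rail into "train")."""
    key = str(reported).strip().lower()
    try:
        return REPORTED_MODE_MAP[key]
    except KeyError:
        valid = ", ".join(sorted(REPORTED_MODE_MAP))
        raise ValueError(
            f"unknown reported mode {reported!r}; valid inputs: {valid}"
        ) from None


@dataclass
class GbtConfig:
    """Gradient-boosted tree hyperparameters (defaults as published)."""

    learning_rate: float = 0.1
    n_rounds: int = 200
    subsample: float = 0.2
    max_depth: int = 10
    gamma: float = 10.0
    seed: int = 0
    n_threads: int = 1
    tree_method: str = "hist"

    def __post_init__(self):
        if min(self.learning_rate, self.n_rounds, self.subsample,
               self.max_depth) <= 0 or self.gamma < 0:
            raise ValueError("GbtConfig values must be positive")

    def xgb_params(self, num_class: int) -> dict:
        return {
            "objective": "multi:softprob",
            "num_class": num_class,
            "eta": self.learning_rate,
            "subsample": self.subsample,
            "max_depth": self.max_depth,
            "gamma": self.gamma,
            "seed": self.seed,
            "nthread": self.n_threads,
            "tree_method": self.tree_method,
        }


def assign_participant_folds(participants, k: int = 5, seed: int = 0) -> dict:
    """Randomly assign participants to ``k`` folds (seeded shuffle then
    round-robin); fold sizes differ by at most one. Returns
    participant_id -> fold index in 1..k."""
    ids = list(dict.fromkeys(participants))  # unique, order-preserving
    if len(ids) < k:
        raise ValueError(f"need >= {k} participants, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return {ids[j]: (i % k) + 1 for i, j in enumerate(order)}


@dataclass
class TrainedModel:
    """Fitted ensemble plus the schema needed to apply it safely."""

    booster: xgb.Booster
    column_names: list
    classes: list = field(default_factory=lambda: list(MODES))
    present_classes: list = field(default_factory=list)  # trained subset
    config: GbtConfig = field(default_factory=GbtConfig)

    def save(self, path) -> None:
        """Persist to a single JSON file (booster + schema + config)."""
        raw = self.booster.save_raw(raw_format="json").decode()
        obj = {"format": "travelmode-gbt-1", "columns": self.column_names,
               "classes": self.classes, "present_classes": self.present_classes,
               "config": asdict(self.config), "booster": json.loads(raw)}
        with open(path, "w") as fh:
            json.dump(obj, fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            obj = json.load(fh)
        if obj.get("format") != "travelmode-gbt-1" or obj.get("classes") != list(MODES):
            raise ValueError("schema error: not a travelmode model file")
        booster = xgb.Booster()
        booster.load_model(bytearray(json.dumps(obj["booster"]).encode()))
        return cls(booster, obj["columns"], obj["classes"],
                   obj["present_classes"], GbtConfig(**obj["config"]))


def train_classifier(matrix: pd.DataFrame, labels, config: GbtConfig,
                     column_names=None) -> TrainedModel:
    """Fit the multiclass ensemble.

    ``labels`` must contain at least two of the five modes; classes absent
    from the training data are carried with probability 0 at prediction.
    """
    cols = list(column_names or matrix.columns)
    y = pd.Series(list(labels))
    present = [m for m in MODES if (y == m).any()]
    if len(present) < 2:
        raise ValueError("training labels contain fewer than 2 classes")
    if len(present) < len(MODES):
        warnings.warn(f"classes absent from training data: "
                      f"{sorted(set(MODES) - set(present))}")
    code = {m: i for i, m in enumerate(present)}
    dtrain = xgb.DMatrix(np.asarray(matrix, dtype=float),
                         label=y.map(code).to_numpy(), missing=np.nan,
                         feature_names=cols, nthread=config.n_threads)
    booster = xgb.train(config.xgb_params(len(present)), dtrain,
                        num_boost_round=config.n_rounds)
    return TrainedModel(booster, cols, list(MODES), present, config)


def predict_modes(model: TrainedModel, matrix: pd.DataFrame):
    """Predict labels and per-class probabilities.

    Returns ``(labels, probs)`` where ``probs`` is a DataFrame over the five
    canonical modes (columns summing to 1 per row); the label is the argmax,
    ties resolved to the earlier mode in canonical order. Raises on a column
    mismatch."""
    if list(matrix.columns) != model.column_names:
        raise ValueError("schema error: feature columns do not match model")
    dmat = xgb.DMatrix(np.asarray(matrix, dtype=float), missing=np.nan,
                       feature_names=model.column_names,
                       nthread=model.config.n_threads)
    raw = model.booster.predict(dmat)
    probs = pd.DataFrame(0.0, index=range(len(matrix)), columns=list(MODES))
    probs.loc[:, model.present_classes] = raw
    labels = probs.to_numpy().argmax(axis=1)  # first max = canonical tie-break
    return [MODES[i] for i in labels], probs


def cross_validate(rows: pd.DataFrame, config: GbtConfig, k: int = 5,
                   seed: int = 0, require_gps: bool = False):
    """Participant-level k-fold cross-validation over labelled feature rows.

    Returns ``(per_fold, pooled, predictions)``: one confusion matrix per
    fold, their elementwise sum (whose total equals the number of evaluated
    rows), and the out-of-fold predicted label per evaluated row.
    """
    matrix, labels, cols = assemble_feature_matrix(rows, require_gps=require_gps)
    if labels is None or labels.isna().any():
        raise ValueError("cross_validate requires fully labelled rows")
    pids = rows.loc[~rows["nonwear"].astype(bool)]
    if require_gps:
        pids = pids.loc[pids["has_gps"].astype(bool)]
    pids = pids["participant_id"].reset_index(drop=True)
    folds = assign_participant_folds(pids, k=k, seed=seed)
    fold_of_row = pids.map(folds)
    per_fold, pred_all = [], pd.Series(index=matrix.index, dtype=object)
    for fold in range(1, k + 1):
        test_mask = (fold_of_row == fold).to_numpy()
        train_pids = set(pids[~test_mask])
        assert not (set(pids[test_mask]) & train_pids), \
            "participant leaked across the fold split"
        if not test_mask.any():
            continue
        mdl = train_classifier(matrix[~test_mask], labels[~test_mask],
                               config, cols)
        pred, _ = predict_modes(mdl, matrix[test_mask])
        per_fold.append(confusion_matrix(labels[test_mask], pred))
        pred_all[test_mask] = pred
        log.info("fold %d: %d train / %d test rows", fold,
                 int((~test_mask).sum()), int(test_mask.sum()))
    pooled = per_fold[0]
    for cm in per_fold[1:]:
        pooled = pooled + cm
    assert pooled.total == len(matrix)
    return per_fold, pooled, pred_all


def active_travel_score(cm: ConfusionMatrix) -> float:
    """Mean of walk and cycle F1 (%): the window-sweep selection score."""
    mm = mode_metrics(cm)
    return float(np.mean([mm.loc["walk", "f1"], mm.loc["cycle", "f1"]]))


def window_size_sweep(train_data: dict, holdout_data: dict,
                      config: GbtConfig,
                      candidate_minutes=(1, 2, 3, 4, 5)):
    """Choose the moving-window length on held-out participants.

    ``train_data`` and ``holdout_data`` map participant_id ->
    ``(epochs, fixes)`` (epoch feature tables with labels, and GPS fixes);
    the two participant sets must be disjoint. For each candidate window the
    feature rows are rebuilt, a model trained, and the mean of walk and
    cycle F1 measured on the holdout. Returns ``(scores, best_minutes)``
    where ``scores`` is a DataFrame indexed by window length.
    """
    if not candidate_minutes:
        raise ValueError("no candidate window sizes")
    overlap = set(train_data) & set(holdout_data)
    if overlap:
        raise ValueError(f"holdout participants overlap training: {sorted(overlap)}")
    records = []
    for w in candidate_minutes:
        train_rows = pd.concat(
            [build_feature_rows(ep, fx, w) for ep, fx in train_data.values()],
            ignore_index=True)
        hold_rows = pd.concat(
            [build_feature_rows(ep, fx, w) for ep, fx in holdout_data.values()],
            ignore_index=True)
        Xtr, ytr, cols = assemble_feature_matrix(train_rows)
        Xho, yho, _ = assemble_feature_matrix(hold_rows)
        mdl = train_classifier(Xtr, ytr, config, cols)
        pred, _ = predict_modes(mdl, Xho)
        cm = confusion_matrix(yho, pred)
        records.append({"window_minutes": w,
                        "active_travel_f1": active_travel_score(cm)})
        log.info("window sweep: %s min -> active-travel F1 %.2f",
                 w, records[-1]["active_travel_f1"])
    scores = pd.DataFrame(records).set_index("window_minutes")
    best = scores["active_travel_f1"].idxmax()
    return scores, best
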