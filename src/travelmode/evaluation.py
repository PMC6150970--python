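"""Test-performance measures and time-in-mode summaries.

The confusion matrix is laid out with predicted mode on rows and observed
mode on columns, in the canonical order (walk, cycle, vehicle, train,
stationary). Per-mode measures, as percentages:

* PPV (precision)      = 100 * TP / row sum (all epochs predicted that mode)
* sensitivity (recall) = 100 * TP / column sum (all epochs truly that mode)
* F1                   = harmonic mean of PPV and sensitivity

plus overall accuracy (trace / total), the unweighted mean sensitivity over
the five modes and the active-travel sensitivity (mean of walk and cycle).
A mode never predicted has undefined PPV, a mode never observed undefined
sensitivity; these are reported as missing (NaN), never as 0, and any mean
over a missing value is itself missing — silently zero-filling would inflate
summary means. Percentages are kept at full precision internally and rounded
half-up to one decimal only at the reporting layer.

Time-in-mode tables convert 10-s epoch counts to minutes per mode, averaged
over participants.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .epoch_features import EPOCH_SECONDS
from .io_formats import MODES


def round1(x: float) -> float:
    """Round half-up to one decimal (reporting convention)."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return float("nan")
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"),
                                                  rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """5x5 epoch counts; ``counts[p, o]`` = predicted mode p, observed o."""

    counts: np.ndarray
    labels: tuple = MODES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.labels)
        if self.counts.shape != (n, n):
            raise ValueError(f"confusion matrix must be {n}x{n}")
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("label order mismatch")
        return ConfusionMatrix(self.counts + other.counts, self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=pd.Index(self.labels, name="predicted"),
                            columns=pd.Index(self.labels, name="observed"))


def confusion_matrix(observed, predicted, labels=MODES) -> ConfusionMatrix:
    """Count (predicted, observed) epoch pairs into the canonical layout."""
    observed, predicted = list(observed), list(predicted)
    if len(observed) != len(predicted):
        raise ValueError("observed and predicted differ in length")
    idx = {m: i for i, m in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for o, p in zip(observed, predicted):
        counts[idx[p], idx[o]] += 1
    return ConfusionMatrix(counts, tuple(labels))


def _mode_index(cm: ConfusionMatrix, mode: str) -> int:
    try:
        return cm.labels.index(mode)
    except ValueError:
        raise KeyError(f"unknown mode {mode!r}; valid: {cm.labels}") from None


def ppv(cm: ConfusionMatrix, mode: str) -> float:
    """Positive predictive value (%) for one mode; NaN when never predicted."""
    i = _mode_index(cm, mode)
    row = cm.counts[i].sum()
    return float("nan") if row == 0 else 100.0 * cm.counts[i, i] / row


def sensitivity(cm: ConfusionMatrix, mode: str) -> float:
    """Sensitivity/recall (%) for one mode; NaN when never observed."""
    i = _mode_index(cm, mode)
    col = cm.counts[:, i].sum()
    return float("nan") if col == 0 else 100.0 * cm.counts[i, i] / col


def f1(ppv_pct: float, sensitivity_pct: float) -> float:
    """Harmonic mean of PPV and sensitivity (both %); 0 when both are 0."""
    if np.isnan(ppv_pct) or np.isnan(sensitivity_pct):
        return float("nan")
    if ppv_pct + sensitivity_pct == 0:
        return 0.0
    return 2.0 * ppv_pct * sensitivity_pct / (ppv_pct + sensitivity_pct)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Percentage of epochs predicted correctly overall."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def mean_sensitivity(sensitivities) -> float:
    """Unweighted mean of the five per-mode sensitivities; missing if any is."""
    v = np.asarray(list(sensitivities), dtype=float)
    if len(v) != len(MODES):
        raise ValueError(f"need {len(MODES)} sensitivities")
    return float("nan") if np.isnan(v).any() else float(v.mean())


def active_travel_sensitivity(walk_sens: float, cycle_sens: float) -> float:
    """Unweighted mean of walk and cycle sensitivity (%)."""
    if np.isnan(walk_sens) or np.isnan(cycle_sens):
        return float("nan")
    return (walk_sens + cycle_sens) / 2.0


def mode_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-mode PPV/sensitivity/F1 plus the summary rows, full precision."""
    rows = {}
    for m in cm.labels:
        p, s = ppv(cm, m), sensitivity(cm, m)
        rows[m] = {"ppv": p, "sensitivity": s, "f1": f1(p, s)}
    df = pd.DataFrame(rows).T
    df.index.name = "mode"
    return df


def summary_metrics(cm: ConfusionMatrix) -> dict:
    per_mode = mode_metrics(cm)
    sens = per_mode["sensitivity"]
    return {
        "overall_accuracy": overall_accuracy(cm),
        "mean_sensitivity": mean_sensitivity(sens.loc[list(MODES)]),
        "active_travel_sensitivity": active_travel_sensitivity(
            sens.loc["walk"], sens.loc["cycle"]),
    }


def epochs_to_hours(n_epochs: int) -> float:
    """Hours covered by ``n`` 10-s epochs, to one decimal."""
    if n_epochs < 0:
        raise ValueError("epoch count must be non-negative")
    return round1(n_epochs * EPOCH_SECONDS / 3600.0)


def epochs_to_minutes(n_epochs: int) -> float:
    if n_epochs < 0:
        raise ValueError("epoch count must be non-negative")
    return round1(n_epochs * EPOCH_SECONDS / 60.0)


def time_in_mode(labelled: pd.DataFrame, label_col: str = "label") -> pd.Series:
    """Mean minutes per participant spent in each mode.

    ``labelled`` needs ``participant_id`` and a mode column; each epoch
    counts 10 s / 60 per participant, averaged over participants (absent
    modes count 0 for that participant)."""
    if labelled.empty or labelled["participant_id"].nunique() == 0:
        raise ValueError("no participants")
    counts = (labelled.groupby(["participant_id", label_col], observed=False)
              .size().unstack(fill_value=0)
              .reindex(columns=list(MODES), fill_value=0))
    minutes = counts * EPOCH_SECONDS / 60.0
    return minutes.mean(axis=0)


def proportion_in_mode(minutes_per_mode: pd.Series, mode: str) -> float:
    """Share (%) of the summed per-mode minutes spent in one mode."""
    total = float(minutes_per_mode.sum())
    if total <= 0:
        raise ValueError("total time is zero")
    return 100.0 * float(minutes_per_mode[mode]) / total


def format_report(cm: ConfusionMatrix) -> str:
    """Human-readable confusion matrix + per-mode metrics + summary lines."""
    per_mode = mode_metrics(cm)
    lines = ["Confusion matrix (rows = predicted, columns = observed):",
             cm.to_frame().to_string(), "",
             "Per-mode accuracy scores (%):"]
    disp = per_mode.apply(lambda col: col.map(round1))
    lines.append(disp.to_string())
    s = summary_metrics(cm)
    lines += ["",
              f"Overall accuracy: {round1(s['overall_accuracy'])}%",
              f"Mean sensitivity: {round1(s['mean_sensitivity'])}%",
              f"Active-travel sensitivity: {round1(s['active_travel_sensitivity'])}%"]
    return "\n".join(lines)
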