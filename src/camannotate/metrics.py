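"""Per-participant agreement metrics.

Model-vs-annotator agreement is evaluated per participant: a confusion
matrix over the fixed class order (SB, LIPA, MVPA), Cohen's kappa, per-class
precision/recall/F1 and accuracy, with the spread across participants
reported as five-number summaries (min, Q1, median, Q3, max — the quartile
plot representation).  Kappa is chance-corrected: 0 at the agreement level
of a random classifier with the observed marginals, 1 at perfect agreement.

Undefined-metric policy: a participant whose matrix makes kappa (chance
agreement 1) or a class F1 (no truth and no predictions of the class)
undefined is excluded from that metric's summary; exclusion counts are
carried on the summary so the denominators stay visible.  Zero-filling was
rejected because it biases the medians of rare classes downwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import INTENSITY_CLASSES


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are truth, columns are prediction."""
    classes: tuple
    counts: np.ndarray
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float | None:
        n = self.n
        return float(np.trace(self.counts) / n) if n else None


def confusion_matrix(truth, pred, classes=INTENSITY_CLASSES) -> ConfusionMatrix:
    """Tally a confusion matrix; pairs with either side outside ``classes``
    (e.g. unknown-intensity images) are dropped and counted."""
    truth = np.asarray(list(truth), dtype=object)
    pred = np.asarray(list(pred), dtype=object)
    if truth.shape != pred.shape:
        raise ValueError("truth and pred must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k), dtype=np.int64)
    dropped = 0
    for t, p in zip(truth, pred):
        if t in index and p in index:
            counts[index[t], index[p]] += 1
        else:
            dropped += 1
    return ConfusionMatrix(tuple(classes), counts, dropped)


def cohens_kappa(cm: ConfusionMatrix) -> float | None:
    """Cohen's kappa, or None when undefined (empty matrix or chance
    agreement p_e = 1, i.e. both raters constant on one class)."""
    n = cm.n
    if n == 0:
        return None
    p_o = np.trace(cm.counts) / n
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    p_e = float(row @ col) / (n * n)
    if p_e >= 1.0 - 1e-12:
        return None
    return float((p_o - p_e) / (1.0 - p_e))


def per_class_prf(cm: ConfusionMatrix) -> dict:
    """Per-class precision, recall and F1 from a confusion matrix.

    recall_k = cm[k,k] / row_k, precision_k = cm[k,k] / col_k, F1 the
    harmonic mean of the two.  Any 0/0 is returned as None (undefined)
    rather than zero-filled.
    """
    out = {}
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    for i, c in enumerate(cm.classes):
        tp = float(cm.counts[i, i])
        recall = tp / row[i] if row[i] > 0 else None
        precision = tp / col[i] if col[i] > 0 else None
        if precision is None or recall is None or precision + recall == 0:
            f1 = None
        else:
            f1 = 2 * precision * recall / (precision + recall)
        out[c] = {"precision": precision, "recall": recall, "f1": f1}
    return out


@dataclass
class ParticipantMetrics:
    participant_id: object
    cm: ConfusionMatrix
    kappa: float | None
    precision: dict
    recall: dict
    f1: dict
    accuracy: float | None
    class_counts: dict
    n: int
    n_dropped: int


def _metrics_from_cm(pid, cm: ConfusionMatrix) -> ParticipantMetrics:
    prf = per_class_prf(cm)
    return ParticipantMetrics(
        participant_id=pid,
        cm=cm,
        kappa=cohens_kappa(cm),
        precision={c: prf[c]["precision"] for c in cm.classes},
        recall={c: prf[c]["recall"] for c in cm.classes},
        f1={c: prf[c]["f1"] for c in cm.classes},
        accuracy=cm.accuracy,
        class_counts={c: int(cm.counts[i].sum())
                      for i, c in enumerate(cm.classes)},
        n=cm.n,
        n_dropped=cm.n_dropped,
    )


def per_participant_metrics(df: pd.DataFrame, truth_col: str = "truth",
                            pred_col: str = "pred",
                            participant_col: str = "participant_id",
                            classes=INTENSITY_CLASSES,
                            ) -> list[ParticipantMetrics]:
    """One :class:`ParticipantMetrics` per participant, ordered by id.

    Rows with unknown intensity on either side are dropped per participant
    (counts retained on the record); participants left with no usable rows
    are omitted.
    """
    for col in (truth_col, pred_col, participant_col):
        if col not in df.columns:
            raise ValueError(f"evaluation table missing column {col!r}")
    out = []
    for pid, grp in df.groupby(participant_col, sort=True):
        cm = confusion_matrix(grp[truth_col], grp[pred_col], classes)
        if cm.n == 0:
            continue
        out.append(_metrics_from_cm(pid, cm))
    return out


def pooled_metrics(df: pd.DataFrame, truth_col: str = "truth",
                   pred_col: str = "pred",
                   classes=INTENSITY_CLASSES) -> ParticipantMetrics:
    """Metrics over all rows pooled into one matrix (id 'pooled')."""
    cm = confusion_matrix(df[truth_col], df[pred_col], classes)
    return _metrics_from_cm("pooled", cm)


@dataclass
class FiveNumberSummary:
    min: float
    q1: float
    median: float
    q3: float
    max: float
    n: int
    n_excluded: int = 0

    def as_tuple(self):
        return (self.min, self.q1, self.median, self.q3, self.max)


def five_number_summary(values) -> FiveNumberSummary | None:
    """Min/Q1/median/Q3/max with linear-interpolation quantiles.

    None/NaN entries (undefined per-participant metrics) are excluded and
    counted; returns None when no defined values remain.
    """
    values = list(values)
    vals = [v for v in values if v is not None and not np.isnan(v)]
    excluded = len(values) - len(vals)
    if not vals:
        return None
    q = np.percentile(vals, [0, 25, 50, 75, 100])
    return FiveNumberSummary(*map(float, q), n=len(vals), n_excluded=excluded)


def summarize_metric(metrics: list[ParticipantMetrics], name: str,
                     cls: str | None = None) -> FiveNumberSummary | None:
    """Five-number summary of one metric across participants.

    ``name`` is 'kappa', 'accuracy', or one of 'f1'/'precision'/'recall'
    with ``cls`` naming the class.
    """
    if cls is None:
        vals = [getattr(m, name) for m in metrics]
    else:
        vals = [getattr(m, name)[cls] for m in metrics]
    return five_number_summary(vals)


def stratified_metrics(df: pd.DataFrame, stratum_col: str,
                       truth_col: str = "truth", pred_col: str = "pred",
                       participant_col: str = "participant_id",
                       min_support: int = 10) -> dict:
    """Per-participant metrics within each stratum (e.g. dark vs bright
    images).  Participants with fewer than ``min_support`` usable rows in a
    stratum are flagged low-support; empty strata are omitted."""
    out = {}
    for stratum, grp in df.groupby(stratum_col, sort=True):
        metrics = per_participant_metrics(grp, truth_col, pred_col,
                                          participant_col)
        if not metrics:
            continue
        out[stratum] = {
            "metrics": metrics,
            "low_support": [m.participant_id for m in metrics
                            if m.n < min_support],
        }
    return out


def metrics_table(metrics: list[ParticipantMetrics]) -> pd.DataFrame:
    """Flatten participant metrics to a DataFrame for serialisation."""
    rows = []
    for m in metrics:
        row = {"participant_id": m.participant_id, "n": m.n,
               "n_dropped": m.n_dropped, "kappa": m.kappa,
               "accuracy": m.accuracy}
        for c in m.cm.classes:
            row[f"f1_{c}"] = m.f1[c]
            row[f"precision_{c}"] = m.precision[c]
            row[f"recall_{c}"] = m.recall[c]
            row[f"count_{c}"] = m.class_counts[c]
        rows.append(row)
    return pd.DataFrame(rows)


def quartile_plot(summaries: dict, path=None, title: str = ""):
    """Quartile plot of five-number summaries (one vertical line + box per
    key).  Returns the matplotlib figure; saves to ``path`` if given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keys = [k for k, s in summaries.items() if s is not None]
    fig, ax = plt.subplots(figsize=(1.2 * max(len(keys), 3) + 1, 4))
    for x, k in enumerate(keys):
        s = summaries[k]
        ax.vlines(x, s.min, s.max, color="0.6", lw=1)
        ax.vlines(x, s.q1, s.q3, color="C0", lw=6, alpha=0.6)
        ax.plot(x, s.median, "s", color="C0")
    ax.set_xticks(range(len(keys)))
    ax.set_xticklabels(keys)
    ax.set_ylim(-0.05, 1.05)
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
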