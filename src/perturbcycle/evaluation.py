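"""Prediction quality metrics: r2, explained variance, DEG-restricted scores.

The single-cell protocol averages predicted and actual profiles per
(perturbation, context) condition before scoring; the paired (bulk)
protocol scores each sample directly and summarizes per condition.
Differentially expressed genes are always selected from actual data only
(control vs treated means), never from predictions.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "r2_score",
    "explained_variance",
    "select_top_degs",
    "evaluate_single_cell",
    "evaluate_paired",
    "ConditionMetrics",
    "EvaluationReport",
    "UNDEFINED_METRIC",
]

logger = logging.getLogger(__name__)

#: sentinel for metrics on a constant actual vector (excluded from summaries)
UNDEFINED_METRIC = float("nan")

FC_PSEUDOCOUNT = 1e-2


def r2_score(pred: np.ndarray, actual: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (can be negative)."""
    pred = np.asarray(pred, dtype=np.float64).ravel()
    actual = np.asarray(actual, dtype=np.float64).ravel()
    if pred.shape != actual.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {actual.shape}")
    if actual.size < 2:
        raise ValueError("need at least 2 values")
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    if ss_tot == 0.0:
        logger.warning("r2_score: constant actual vector; metric undefined")
        return UNDEFINED_METRIC
    ss_res = float(np.sum((actual - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def explained_variance(pred: np.ndarray, actual: np.ndarray) -> float:
    """1 - Var(actual - pred)/Var(actual); insensitive to constant bias."""
    pred = np.asarray(pred, dtype=np.float64).ravel()
    actual = np.asarray(actual, dtype=np.float64).ravel()
    if pred.shape != actual.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {actual.shape}")
    if actual.size < 2:
        raise ValueError("need at least 2 values")
    var_actual = float(np.var(actual))
    if var_actual == 0.0:
        logger.warning("explained_variance: constant actual vector; metric undefined")
        return UNDEFINED_METRIC
    return 1.0 - float(np.var(actual - pred)) / var_actual


def select_top_degs(
    control_mean: np.ndarray,
    treated_mean: np.ndarray,
    n: int = 50,
    threshold: float = 1.0,
    log_space: bool = False,
) -> np.ndarray:
    """Indices of up to ``n`` genes with |log2 fold change| >= threshold.

    Ranked by |log2 fc| descending, ties broken by gene index ascending.
    With ``log_space=True`` the inputs are already log2-scaled and the fold
    change is their difference; otherwise a pseudocount ratio is used.
    """
    c = np.asarray(control_mean, dtype=np.float64).ravel()
    t = np.asarray(treated_mean, dtype=np.float64).ravel()
    if c.shape != t.shape:
        raise ValueError(f"length mismatch: {c.shape} vs {t.shape}")
    if log_space:
        lfc = t - c
    else:
        if (c < 0).any() or (t < 0).any():
            raise ValueError(
                "negative means under the ratio fold-change convention; "
                "pass log_space=True for log-scaled data"
            )
        lfc = np.log2((t + FC_PSEUDOCOUNT) / (c + FC_PSEUDOCOUNT))
    abs_lfc = np.abs(lfc)
    eligible = np.flatnonzero(abs_lfc >= threshold)
    # stable sort on (-|lfc|, index): mergesort preserves index order on ties
    order = eligible[np.argsort(-abs_lfc[eligible], kind="mergesort")]
    return order[:n]


@dataclasses.dataclass
class ConditionMetrics:
    perturbation_id: str
    context_id: str
    r2_all: float
    ev_all: float
    r2_deg: float
    ev_deg: float
    n_cells: int
    n_degs: int


@dataclasses.dataclass
class EvaluationReport:
    per_condition: list[ConditionMetrics]
    summary: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(c) for c in self.per_condition])


def _summarize(per_condition: list[ConditionMetrics]) -> dict[str, float]:
    summary: dict[str, float] = {}
    for metric in ("r2_all", "ev_all", "r2_deg", "ev_deg"):
        vals = np.array(
            [getattr(c, metric) for c in per_condition], dtype=np.float64
        )
        vals = vals[np.isfinite(vals)]
        summary[f"mean_{metric}"] = float(vals.mean()) if vals.size else UNDEFINED_METRIC
        summary[f"median_{metric}"] = float(np.median(vals)) if vals.size else UNDEFINED_METRIC
    return summary


def _condition_metrics(
    pert: str,
    ctx: str,
    pred_mean: np.ndarray,
    actual_mean: np.ndarray,
    control_mean: np.ndarray,
    n_cells: int,
    n_degs: int,
    deg_threshold: float,
    log_space: bool,
) -> ConditionMetrics:
    degs = select_top_degs(
        control_mean, actual_mean, n=n_degs, threshold=deg_threshold, log_space=log_space
    )
    if degs.size >= 2:
        r2_deg = r2_score(pred_mean[degs], actual_mean[degs])
        ev_deg = explained_variance(pred_mean[degs], actual_mean[degs])
    else:
        r2_deg = ev_deg = UNDEFINED_METRIC
    return ConditionMetrics(
        perturbation_id=pert,
        context_id=ctx,
        r2_all=r2_score(pred_mean, actual_mean),
        ev_all=explained_variance(pred_mean, actual_mean),
        r2_deg=r2_deg,
        ev_deg=ev_deg,
        n_cells=n_cells,
        n_degs=int(degs.size),
    )


def evaluate_single_cell(
    pred_cells: np.ndarray,
    actual_cells: np.ndarray,
    pred_groups: Sequence[tuple[str, str]],
    actual_groups: Sequence[tuple[str, str]],
    control_mean: np.ndarray,
    n_degs: int = 50,
    deg_threshold: float = 1.0,
    log_space: bool = False,
    control_means_by_context: Optional[dict[str, np.ndarray]] = None,
) -> EvaluationReport:
    """Score mean predicted vs mean actual profiles per (perturbation, context).

    ``pred_groups`` / ``actual_groups`` label each row of the corresponding
    matrix with its condition. Conditions present on only one side are
    skipped with a warning.
    """
    pred_cells = np.atleast_2d(np.asarray(pred_cells, dtype=np.float64))
    actual_cells = np.atleast_2d(np.asarray(actual_cells, dtype=np.float64))
    pred_idx: dict[tuple[str, str], list[int]] = {}
    for i, key in enumerate(pred_groups):
        pred_idx.setdefault(tuple(key), []).append(i)
    actual_idx: dict[tuple[str, str], list[int]] = {}
    for i, key in enumerate(actual_groups):
        actual_idx.setdefault(tuple(key), []).append(i)

    per_condition = []
    for key in pred_idx:
        if key not in actual_idx:
            logger.warning("condition %s missing from actual side; skipped", key)
            continue
        pert, ctx = key
        rows_p, rows_a = pred_idx[key], actual_idx[key]
        cmean = (
            control_means_by_context[ctx]
            if control_means_by_context is not None
            else control_mean
        )
        per_condition.append(
            _condition_metrics(
                pert,
                ctx,
                pred_cells[rows_p].mean(axis=0),
                actual_cells[rows_a].mean(axis=0),
                np.asarray(cmean, dtype=np.float64).ravel(),
                n_cells=len(rows_a),
                n_degs=n_degs,
                deg_threshold=deg_threshold,
                log_space=log_space,
            )
        )
    for key in actual_idx:
        if key not in pred_idx:
            logger.warning("condition %s missing from predicted side; skipped", key)
    return EvaluationReport(per_condition, _summarize(per_condition))


def evaluate_paired(
    pred: np.ndarray,
    actual: np.ndarray,
    groups: Sequence[tuple[str, str]],
    control_mean: np.ndarray,
    n_degs: int = 50,
    deg_threshold: float = 1.0,
    log_space: bool = False,
) -> EvaluationReport:
    """Per-sample scoring (no cell averaging), summarized per condition.

    Each row of ``pred``/``actual`` is one sample; r2/EV are computed per
    sample and averaged within each (perturbation, context) condition. The
    DEG subset per condition comes from actual means only.
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=np.float64))
    actual = np.atleast_2d(np.asarray(actual, dtype=np.float64))
    if pred.shape != actual.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {actual.shape}")
    idx: dict[tuple[str, str], list[int]] = {}
    for i, key in enumerate(groups):
        idx.setdefault(tuple(key), []).append(i)

    per_condition = []
    cmean = np.asarray(control_mean, dtype=np.float64).ravel()
    for (pert, ctx), rows in idx.items():
        actual_mean = actual[rows].mean(axis=0)
        degs = select_top_degs(
            cmean, actual_mean, n=n_degs, threshold=deg_threshold, log_space=log_space
        )
        r2s, evs, r2d, evd = [], [], [], []
        for i in rows:
            r2s.append(r2_score(pred[i], actual[i]))
            evs.append(explained_variance(pred[i], actual[i]))
            if degs.size >= 2:
                r2d.append(r2_score(pred[i][degs], actual[i][degs]))
                evd.append(explained_variance(pred[i][degs], actual[i][degs]))

        def _nanmean(vals):
            arr = np.array(vals, dtype=np.float64)
            arr = arr[np.isfinite(arr)]
            return float(arr.mean()) if arr.size else UNDEFINED_METRIC

        per_condition.append(
            ConditionMetrics(
                perturbation_id=pert,
                context_id=ctx,
                r2_all=_nanmean(r2s),
                ev_all=_nanmean(evs),
                r2_deg=_nanmean(r2d),
                ev_deg=_nanmean(evd),
                n_cells=len(rows),
                n_degs=int(degs.size),
            )
        )
    return EvaluationReport(per_condition, _summarize(per_condition))
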