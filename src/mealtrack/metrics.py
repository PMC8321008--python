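"""Absolute-error metrics and the evaluation harness.

The pipeline is scored against ground truth with the absolute error
AE = |x_hat - x|, its mean (MAE) and the percent mean relative error
MRE% = (100/n) * sum(|x_hat - x| / x).  The relative error is taken with
absolute value per term so that MRE is non-negative and matches the
reference summary rows; a zero truth value is an error rather than being
skipped, since a 1-based frame index is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GroundTruth, SessionTable

__all__ = [
    "MetricsResult",
    "absolute_error",
    "mean_absolute_error",
    "mean_relative_error_percent",
    "evaluate_tables",
]


@dataclass
class MetricsResult:
    """Per-item absolute errors plus their MAE / MRE% summaries."""

    ae: np.ndarray
    mae: float
    mre_percent: float
    n: int


def absolute_error(estimate: float, truth: float) -> float:
    """AE = |estimate - truth|."""
    return abs(estimate - truth)


def _as_aligned(estimates, truths) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(estimates, dtype=float)
    t = np.asarray(truths, dtype=float)
    if x.shape != t.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {t.shape}")
    if x.size == 0:
        raise ValueError("empty series")
    return x, t


def mean_absolute_error(estimates, truths) -> float:
    """MAE = (1/n) * sum |estimate_t - truth_t|."""
    x, t = _as_aligned(estimates, truths)
    return float(np.mean(np.abs(x - t)))


def mean_relative_error_percent(estimates, truths) -> float:
    """MRE% = (100/n) * sum |estimate_t - truth_t| / truth_t."""
    x, t = _as_aligned(estimates, truths)
    if np.any(t == 0):
        raise ZeroDivisionError("relative error undefined for truth value 0")
    return float(np.mean(np.abs(x - t) / t) * 100.0)


def compute_metrics(estimates, truths) -> MetricsResult:
    x, t = _as_aligned(estimates, truths)
    ae = np.abs(x - t)
    return MetricsResult(
        ae=ae,
        mae=float(ae.mean()),
        mre_percent=mean_relative_error_percent(x, t),
        n=int(x.size),
    )


def _table_bounds(table: SessionTable) -> dict[int, tuple[int, int]]:
    """Per-test overall meal bounds: first SF and last EF across segments."""
    bounds: dict[int, tuple[int, int]] = {}
    for seg in table:
        sf, ef = bounds.get(seg.test_number, (seg.sf, seg.ef))
        bounds[seg.test_number] = (min(sf, seg.sf), max(ef, seg.ef))
    return bounds


def evaluate_tables(
    setparam_auto: SessionTable,
    ground_truth: list[GroundTruth],
    setparam_manual: SessionTable | None = None,
    actions: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Score automatic (and optionally manual) SF/EF and action counts.

    Returns a frame with one row per available comparison (SFA, EFA, SFM,
    EFM, Actions) and columns ``mae``, ``mre_percent`` and ``n``.  All
    tables are aligned on test_number; unmatched test numbers are an
    error naming the offenders.
    """
    gt = {g.test_number: g for g in ground_truth}

    def aligned(table: SessionTable, label: str) -> tuple[np.ndarray, ...]:
        bounds = _table_bounds(table)
        missing = sorted(set(bounds) ^ set(gt))
        if missing:
            raise ValueError(f"{label}: unmatched test numbers {missing}")
        tests = sorted(bounds)
        sf = np.array([bounds[t][0] for t in tests], dtype=float)
        ef = np.array([bounds[t][1] for t in tests], dtype=float)
        sf_t = np.array([gt[t].sf_gt for t in tests], dtype=float)
        ef_t = np.array([gt[t].ef_gt for t in tests], dtype=float)
        return sf, ef, sf_t, ef_t

    rows: list[dict] = []

    def add(label: str, est: np.ndarray, tru: np.ndarray) -> None:
        res = compute_metrics(est, tru)
        rows.append(
            {"quantity": label, "mae": res.mae, "mre_percent": res.mre_percent, "n": res.n}
        )

    sf_a, ef_a, sf_t, ef_t = aligned(setparam_auto, "automatic")
    add("SFA", sf_a, sf_t)
    add("EFA", ef_a, ef_t)
    if setparam_manual is not None:
        sf_m, ef_m, sf_t2, ef_t2 = aligned(setparam_manual, "manual")
        add("SFM", sf_m, sf_t2)
        add("EFM", ef_m, ef_t2)
    if actions is not None:
        missing = sorted(set(actions) ^ set(gt))
        if missing:
            raise ValueError(f"actions: unmatched test numbers {missing}")
        tests = sorted(actions)
        est = np.array([actions[t] for t in tests], dtype=float)
        tru = np.array([gt[t].actions_gt for t in tests], dtype=float)
        add("Actions", est, tru)
    return pd.DataFrame(rows).set_index("quantity")
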