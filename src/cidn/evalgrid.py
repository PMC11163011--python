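"""Objective-evaluation experiment grid and paired nonparametric statistics.

Evaluates enhancement systems over a masker x SNR x processing grid, one row
per item x processing x metric, then runs paired Wilcoxon signed-rank tests
between processing conditions with Benjamini-Hochberg false-discovery-rate
control over the full family of planned comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as scs
from statsmodels.stats.multitest import multipletests

from . import metrics as metrics_mod
from .types import InvalidArgumentError, Waveform, require

__all__ = [
    "ConditionGrid",
    "EvalItem",
    "evaluate_grid",
    "paired_wilcoxon",
    "fdr_adjust",
    "count_planned_comparisons",
    "wilcoxon_fdr_summary",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConditionGrid:
    """The default objective-evaluation factors: 2 maskers x 3 SNRs x 3
    processings x 3 metrics (54 planned pairwise comparisons)."""

    maskers: tuple = ("ccitt", "ttb")
    snrs_db: tuple = (1.0, 5.0, 10.0)
    processings: tuple = ("unprocessed", "rnn", "sepformer")
    metrics: tuple = ("si_sdr", "pesq", "stoi")

    def __post_init__(self) -> None:
        for name in ("maskers", "snrs_db", "processings", "metrics"):
            require(len(getattr(self, name)) > 0, f"{name} must be non-empty")


@dataclass(frozen=True)
class EvalItem:
    """One test mixture: clean reference plus noisy mixture and its labels."""

    id: str
    masker: str
    snr_db: float
    clean: Waveform
    noisy: Waveform


def _metric_value(metric: str, clean: Waveform, estimate: Waveform):
    if metric == "si_sdr":
        return metrics_mod.si_sdr_db(clean, estimate)
    if metric == "stoi":
        return metrics_mod.stoi(clean, estimate)
    if metric == "pesq":
        return metrics_mod.pesq_adapter(clean, estimate)
    raise InvalidArgumentError(f"unknown metric {metric!r}")


def evaluate_grid(
    systems: Mapping[str, Callable[[Waveform], Waveform]],
    items: Sequence[EvalItem],
    grid: ConditionGrid | None = None,
) -> pd.DataFrame:
    """Long-format metric table: one row per item x processing x metric.

    ``systems`` maps processing names to noisy->estimate callables; the
    ``unprocessed`` processing always scores the noisy mixture itself.
    Items whose evaluation fails are skipped with a log entry.
    """
    grid = grid or ConditionGrid()
    rows = []
    for item in items:
        estimates: dict[str, Waveform] = {}
        for proc in grid.processings:
            if proc == "unprocessed":
                estimates[proc] = item.noisy
            else:
                if proc not in systems:
                    raise InvalidArgumentError(f"no system registered for {proc!r}")
                estimates[proc] = systems[proc](item.noisy)
        for proc, est in estimates.items():
            for metric in grid.metrics:
                try:
                    value = _metric_value(metric, item.clean, est)
                except InvalidArgumentError as exc:
                    log.warning("skipping %s/%s/%s: %s", item.id, proc, metric, exc)
                    continue
                rows.append(
                    {
                        "item": item.id,
                        "masker": item.masker,
                        "snr_db": item.snr_db,
                        "processing": proc,
                        "metric": metric,
                        "value": np.nan if value is None else value,
                    }
                )
    return pd.DataFrame(rows)


def paired_wilcoxon(
    table: pd.DataFrame, condition_a: str, condition_b: str,
    value_col: str = "value", condition_col: str = "processing",
    pair_col: str = "item",
) -> dict:
    """Two-sided Wilcoxon signed-rank test between two paired conditions.

    Zero differences are excluded; the exact null distribution is used for
    n <= 25 without ties, a normal approximation with continuity correction
    otherwise.  Requires >= 5 informative pairs.
    """
    a = table[table[condition_col] == condition_a].set_index(pair_col)[value_col]
    b = table[table[condition_col] == condition_b].set_index(pair_col)[value_col]
    common = a.index.intersection(b.index)
    if len(common) < len(a) or len(common) < len(b):
        raise InvalidArgumentError("conditions are not fully paired")
    d = (a.loc[common] - b.loc[common]).to_numpy(dtype=float)
    d = d[d != 0.0]
    n = len(d)
    if n < 5:
        raise InvalidArgumentError(
            f"insufficient informative pairs after zero exclusion (n={n})"
        )
    ranks = scs.rankdata(np.abs(d))
    has_ties = len(np.unique(ranks)) < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = scs.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"),
                       alternative="two-sided", method=method)
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue), "n": n}


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def count_planned_comparisons(
    grid: ConditionGrid | None = None,
    pairings: Sequence[tuple] | None = None,
) -> int:
    """|metrics| x |maskers| x |snrs| x |processing pairs|."""
    grid = grid or ConditionGrid()
    if pairings is None:
        procs = grid.processings
        pairings = [
            (procs[i], procs[j])
            for i in range(len(procs))
            for j in range(i + 1, len(procs))
        ]
    return len(grid.metrics) * len(grid.maskers) * len(grid.snrs_db) * len(pairings)


def wilcoxon_fdr_summary(
    table: pd.DataFrame, grid: ConditionGrid | None = None
) -> pd.DataFrame:
    """All planned pairwise comparisons with raw and BH-adjusted p-values.

    One comparison per metric x masker x SNR x processing pair; metrics with
    no recorded values (e.g. an absent PESQ backend) are dropped.
    """
    grid = grid or ConditionGrid()
    procs = grid.processings
    pairs = [
        (procs[i], procs[j])
        for i in range(len(procs))
        for j in range(i + 1, len(procs))
    ]
    rows = []
    for metric in grid.metrics:
        sub_m = table[(table["metric"] == metric) & table["value"].notna()]
        if sub_m.empty:
            continue
        for masker in grid.maskers:
            for snr in grid.snrs_db:
                sub = sub_m[(sub_m["masker"] == masker) & (sub_m["snr_db"] == snr)]
                for a, b in pairs:
                    res = paired_wilcoxon(sub, a, b)
                    rows.append(
                        {
                            "metric": metric,
                            "masker": masker,
                            "snr_db": snr,
                            "condition_a": a,
                            "condition_b": b,
                            "statistic": res["statistic"],
                            "p_raw": res["p_value"],
                            "n": res["n"],
                        }
                    )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_fdr"] = fdr_adjust(out["p_raw"])
    return out
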