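"""Distance-error metrics and bond-change-stratified error analysis.

Molecular MAE / MAPE average first over the N(N-1)/2 strict pairs of each
reaction and then over reactions, so every reaction contributes equally
regardless of its size. MAE is reported in pm, MAPE in percent.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .structures import BondChange


def _check_matched(pred: Sequence[np.ndarray], true: Sequence[np.ndarray]):
    if len(pred) != len(true):
        raise ValueError("pred and true must cover the same reactions")
    for p, t in zip(pred, true):
        if np.shape(p) != np.shape(t):
            raise ValueError("per-reaction pair counts differ between pred and true")


def molecular_mae(pred: Sequence[np.ndarray], true: Sequence[np.ndarray]) -> float:
    """Mean over reactions of the per-reaction mean absolute distance error.

    Inputs are per-reaction arrays of strict-pair distances in pm (any
    consistent unit; the result carries that unit).
    """
    _check_matched(pred, true)
    per_reaction = [
        float(np.mean(np.abs(np.asarray(t) - np.asarray(p))))
        for p, t in zip(pred, true)
    ]
    return float(np.mean(per_reaction))


def molecular_mape(pred: Sequence[np.ndarray], true: Sequence[np.ndarray]) -> float:
    """Mean over reactions of the per-reaction mean absolute percentage error."""
    _check_matched(pred, true)
    per_reaction = []
    for p, t in zip(pred, true):
        t = np.asarray(t, dtype=np.float64)
        if np.any(t <= 0):
            raise ValueError("true distances must be positive for MAPE")
        per_reaction.append(float(np.mean(np.abs(t - np.asarray(p)) / t)) * 100.0)
    return float(np.mean(per_reaction))


@dataclasses.dataclass
class MetricReport:
    molecular_mae_pm: float
    molecular_mape_pct: float
    per_category_ape_pct: dict[BondChange, float]
    category_counts: dict[BondChange, int]
    n_reactions: int

    def to_rows(self) -> list[dict]:
        rows = [
            {"metric": "molecular_mae_pm", "category": "all",
             "value": self.molecular_mae_pm, "n": self.n_reactions},
            {"metric": "molecular_mape_pct", "category": "all",
             "value": self.molecular_mape_pct, "n": self.n_reactions},
        ]
        for cat, v in self.per_category_ape_pct.items():
            rows.append({
                "metric": "mean_ape_pct", "category": cat.value, "value": v,
                "n": self.category_counts[cat],
            })
        return rows


def stratified_errors(
    pred: Sequence[np.ndarray],
    true: Sequence[np.ndarray],
    categories: Sequence[Sequence[BondChange]],
) -> MetricReport:
    """Molecular metrics plus per-bond-change-category mean APE.

    Category errors are pooled over all pairs of all reactions (not averaged
    per molecule first), matching how per-pair error distributions are
    normally stratified.
    """
    _check_matched(pred, true)
    ape_by_cat: dict[BondChange, list] = {c: [] for c in BondChange}
    for p, t, cats in zip(pred, true, categories):
        p, t = np.asarray(p, dtype=np.float64), np.asarray(t, dtype=np.float64)
        ape = np.abs(t - p) / t * 100.0
        for e, c in zip(ape, cats):
            ape_by_cat[c].append(float(e))
    present = {c: v for c, v in ape_by_cat.items() if v}
    return MetricReport(
        molecular_mae_pm=molecular_mae(pred, true),
        molecular_mape_pct=molecular_mape(pred, true),
        per_category_ape_pct={c: float(np.mean(v)) for c, v in present.items()},
        category_counts={c: len(v) for c, v in present.items()},
        n_reactions=len(pred),
    )
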