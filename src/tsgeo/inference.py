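"""Inference: single-checkpoint prediction, test-time augmentation by
reaction reversal, and multi-checkpoint ensembling.

Test-time augmentation (TTA) evaluates the model on both the forward and the
reversed reaction and averages the predicted distances, which removes the
direction dependence of the prediction exactly. Ensembles keep every
member's distance set — the joint reconstruction consumes all of them — and
also expose the per-pair mean for metric evaluation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .model import Checkpoint, PSIModel
from .structures import PM_PER_ANGSTROM, Reaction


@dataclasses.dataclass
class DistancePrediction:
    """Predicted TS distances for one reaction.

    ``d_pred`` has one row per contributing model (pm); ``d_interp`` holds
    the interpolated-structure distances they normalize against (pm).
    """

    pair_index: np.ndarray       # (n_strict, 2)
    d_interp: np.ndarray         # (n_strict,), pm
    d_pred: np.ndarray           # (n_members, n_strict), pm
    checkpoint_ids: tuple[str, ...]
    tta: bool

    def __post_init__(self):
        self.d_pred = np.atleast_2d(np.asarray(self.d_pred, dtype=np.float64))
        if np.any(self.d_pred <= 0):
            raise ValueError("predicted distances must be positive")

    @property
    def n_members(self) -> int:
        return self.d_pred.shape[0]

    @property
    def mean(self) -> np.ndarray:
        """Per-pair ensemble-mean predicted distance, pm."""
        return self.d_pred.mean(axis=0)

    def to_frame(self, reaction_id: str = "") -> pd.DataFrame:
        rows = []
        mean = self.mean
        for k, (i, j) in enumerate(self.pair_index):
            row = {
                "reaction_id": reaction_id, "i": int(i), "j": int(j),
                "d_interp_pm": self.d_interp[k], "d_pred_mean_pm": mean[k],
            }
            for m, cid in enumerate(self.checkpoint_ids):
                row[f"d_pred_pm[{cid}]"] = self.d_pred[m, k]
            rows.append(row)
        return pd.DataFrame(rows)


@dataclasses.dataclass
class EnsembleSpec:
    """Which checkpoints form the ensemble and whether TTA is applied."""

    checkpoints: Sequence[Checkpoint]
    use_tta: bool = True

    def __post_init__(self):
        if not self.checkpoints:
            raise ValueError("an ensemble needs at least one checkpoint")
        elems = set()
        for c in self.checkpoints:
            fcfg = c.fcfg if isinstance(c, PSIModel) else c.featurizer_config
            elems.add(tuple(fcfg.elements))
        if len(elems) != 1:
            raise ValueError("ensemble members must share an element set")


def _as_model(ckpt: Checkpoint | PSIModel) -> tuple[PSIModel, str]:
    if isinstance(ckpt, PSIModel):
        return ckpt, "model"
    return ckpt.build_model(), (ckpt.checkpoint_id or "ckpt")


def predict_single(reaction: Reaction, ckpt: Checkpoint | PSIModel) -> DistancePrediction:
    """Deterministic forward-direction prediction from one checkpoint."""
    model, cid = _as_model(ckpt)
    pair_index, d_interp, d_pred = model.predict_distances(reaction)
    return DistancePrediction(
        pair_index=pair_index,
        d_interp=d_interp * PM_PER_ANGSTROM,
        d_pred=d_pred[np.newaxis, :] * PM_PER_ANGSTROM,
        checkpoint_ids=(cid,),
        tta=False,
    )


def predict_tta(reaction: Reaction, ckpt: Checkpoint | PSIModel) -> DistancePrediction:
    """Average of forward and reversed-reaction predictions.

    The two contributions are combined with a symmetric accumulation
    (0.5*a + 0.5*b), so predict_tta(r) and predict_tta(reverse(r)) agree to
    the last bit.
    """
    model, cid = _as_model(ckpt)
    fwd = predict_single(reaction, model)
    bwd = predict_single(reaction.reverse(), model)
    d_pred = 0.5 * fwd.d_pred + 0.5 * bwd.d_pred
    d_interp = 0.5 * fwd.d_interp + 0.5 * bwd.d_interp
    return DistancePrediction(
        pair_index=fwd.pair_index, d_interp=d_interp, d_pred=d_pred,
        checkpoint_ids=(cid,), tta=True,
    )


def predict_ensemble(reaction: Reaction, spec: EnsembleSpec) -> DistancePrediction:
    """Evaluate every member (optionally with TTA) and stack their distances.

    Members are independent; the result does not depend on evaluation order
    beyond the row order, and the per-pair mean not at all.
    """
    member_preds = []
    ids = []
    for ckpt in spec.checkpoints:
        pred = (predict_tta if spec.use_tta else predict_single)(reaction, ckpt)
        member_preds.append(pred)
        ids.append(pred.checkpoint_ids[0])
    first = member_preds[0]
    return DistancePrediction(
        pair_index=first.pair_index,
        d_interp=first.d_interp,
        d_pred=np.vstack([p.d_pred for p in member_preds]),
        checkpoint_ids=tuple(ids),
        tta=spec.use_tta,
    )


class EnsembleTSPredictor:
    """Estimator-style facade over an ensemble of trained checkpoints."""

    def __init__(self, checkpoints: Sequence[Checkpoint | PSIModel],
                 use_tta: bool = True):
        self.checkpoints = list(checkpoints)
        self.use_tta = use_tta

    def predict(self, X: list[Reaction]) -> list[DistancePrediction]:
        spec = EnsembleSpec(self.checkpoints, use_tta=self.use_tta)
        return [predict_ensemble(r, spec) for r in X]

    def get_params(self, deep=True):
        return {"checkpoints": self.checkpoints, "use_tta": self.use_tta}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self
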