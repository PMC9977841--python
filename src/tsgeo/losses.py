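"""Training losses: distance error, auxiliary properties, and the EDM penalty.

The total loss is L = c*L1 + c'*(L2 + L3):

* L1 — molecular MAE of the predicted TS distances (averaged per reaction
  first, then over the batch), differentiable through d_pred = ratio * d_I.
* L2 — sum of MAEs of molecular energy and vibrational/rotational entropy
  for reactant and product, from summed per-atom contributions; targets
  without labels are skipped.
* L3 — Euclidean-distance-matrix penalty. A matrix of squared distances
  realizable by 3-D points has at most five nonzero eigenvalues and zero
  trace; with eigenvalues e_1..e_N in descending order of magnitude and
  m = min(5, N), L3 = sum_{i<=m} e_i + sum_{i>m} |e_i| penalizes both a
  nonzero leading-eigenvalue sum and any residual spectrum. For N <= 5 the
  penalty degenerates to the (always zero) trace, so it only constrains
  systems with more than five atoms.

Losses are computed in Angstrom (L1) and the label units (L2); metrics
reported to users are converted to pm / percent by the metrics module.
"""

from __future__ import annotations

import numpy as np

from . import autodiff
from .autodiff import Tensor
from .model import ModelOutput, PROPERTY_TARGETS
from .structures import Reaction


def loss_l1(outputs: list[ModelOutput], reactions: list[Reaction]) -> Tensor:
    """Batch molecular MAE (A) of predicted vs reference TS distances."""
    if len(outputs) != len(reactions):
        raise ValueError("outputs and reactions must align")
    terms = []
    for out, rxn in zip(outputs, reactions):
        if rxn.ts_ref is None:
            raise ValueError(f"reaction {rxn.reaction_id!r} has no reference TS")
        d_true = rxn.ts_ref.strict_pair_distances(out.pair_index)
        terms.append((out.d_pred - d_true).abs().mean())
    return sum(terms[1:], terms[0]) * (1.0 / len(terms))


def loss_l2(outputs: list[ModelOutput], reactions: list[Reaction]) -> Tensor:
    """Property MAE summed over roles (reactant, product) and labeled targets."""
    per_target: dict[tuple, list] = {}
    for out, rxn in zip(outputs, reactions):
        mol = out.molecular_properties()
        if mol is None:
            raise ValueError("model has no property head")
        labels = rxn.properties or {}
        for role in ("reactant", "product"):
            have = labels.get(role, {})
            for k, key in enumerate(PROPERTY_TARGETS):
                if key not in have:
                    continue  # unlabeled target: skipped
                err = (mol[role][k] - have[key]).abs()
                per_target.setdefault((role, key), []).append(err)
    if not per_target:
        return Tensor(0.0)
    total = None
    for errs in per_target.values():
        mae = sum(errs[1:], errs[0]) * (1.0 / len(errs))
        total = mae if total is None else total + mae
    return total


def edm_penalty(d_pred: Tensor, pair_index: np.ndarray, n_atoms: int) -> Tensor:
    """L3 for one reaction from its predicted strict-pair distances (A)."""
    if n_atoms <= 1:
        return Tensor(0.0)
    sq = d_pred * d_pred
    mat = autodiff.sym_matrix_from_pairs(sq, pair_index, n_atoms)
    eig = autodiff.eigvalsh(mat)  # ascending
    order = np.argsort(-np.abs(eig.data), kind="stable")  # descending magnitude
    sorted_eig = eig[order]
    m = min(5, n_atoms)
    leading = sorted_eig[:m].sum()
    if m < n_atoms:
        residual = sorted_eig[m:].abs().sum()
        return leading + residual
    return leading


def loss_l3(outputs: list[ModelOutput], reactions: list[Reaction]) -> Tensor:
    """Batch-mean EDM penalty of the predicted TS distance sets."""
    terms = [
        edm_penalty(out.d_pred, out.pair_index, rxn.n_atoms)
        for out, rxn in zip(outputs, reactions)
    ]
    return sum(terms[1:], terms[0]) * (1.0 / len(terms))


def edm_penalty_value(distances: np.ndarray, pair_index: np.ndarray,
                      n_atoms: int) -> float:
    """Non-differentiable L3 of a concrete distance set (A)."""
    return float(edm_penalty(Tensor(np.asarray(distances, dtype=np.float64)),
                             pair_index, n_atoms).data)


def total_loss(outputs, reactions, c: float = 2000.0, c_prime: float = 0.0,
               property_head: bool = False) -> tuple[Tensor, dict]:
    """L = c*L1 + c'*(L2 + L3); returns the scalar and a float breakdown."""
    l1 = loss_l1(outputs, reactions)
    parts = {"L1": float(l1.data)}
    total = c * l1
    if c_prime > 0.0:
        l3 = loss_l3(outputs, reactions)
        parts["L3"] = float(l3.data)
        aux = l3
        if property_head:
            l2 = loss_l2(outputs, reactions)
            parts["L2"] = float(l2.data)
            aux = l2 + l3
        total = total + c_prime * aux
    parts["L"] = float(total.data)
    return total, parts
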