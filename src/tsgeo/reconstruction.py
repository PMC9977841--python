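"""3-D coordinate reconstruction from predicted interatomic distances.

The optimizer finds atomic positions X* minimizing

    sum_k sum_{i<j} w_ij * | d_ij^k - ||X_i - X_j|| |

over the members k of the (possibly single-model) prediction, with Gaussian
weights w_ij = exp(-alpha * d_ij^2) computed from the ensemble-mean
predicted distance so that short — chemically bonded — distances dominate.
The absolute value is smoothed as sqrt(x^2 + eps^2) and minimized with
L-BFGS-B from the interpolated geometry (or any supplied start); a second
polishing pass with a much smaller eps sharpens convergence near the
non-smooth optimum. Distances are handled in Angstrom internally.

Interatomic distances do not distinguish enantiomers, so the reconstructed
geometry's chirality is not controlled.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import minimize

from .inference import DistancePrediction
from .structures import PM_PER_ANGSTROM, Structure


@dataclasses.dataclass
class ReconstructionConfig:
    alpha: float = 0.2          # 1/A^2, Gaussian weight exponent
    tol: float = 1e-15          # ftol; effectively "run to stationarity"
    max_iter: int = 5000
    smooth_eps: float = 1e-6    # A, |x| ~ sqrt(x^2 + eps^2)
    polish: bool = True         # second pass with eps -> eps * 1e-3

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclasses.dataclass
class ReconstructionResult:
    structure: Structure
    objective: float        # exact (non-smoothed) weighted L1 objective
    n_iterations: int
    converged: bool


def pair_weights(d_angstrom: np.ndarray, alpha: float) -> np.ndarray:
    """Gaussian distance weights w = exp(-alpha d^2); w(0) = 1."""
    d = np.asarray(d_angstrom, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    return np.exp(-alpha * d * d)


def _objective_terms(x, pairs, d_targets, w, eps):
    """(smoothed objective, gradient) for flattened coordinates x."""
    coords = x.reshape(-1, 3)
    i, j = pairs[:, 0], pairs[:, 1]
    diff = coords[i] - coords[j]                     # (n_pairs, 3)
    r = np.linalg.norm(diff, axis=1)
    r_safe = np.maximum(r, 1e-12)
    resid = d_targets - r[np.newaxis, :]             # (n_members, n_pairs)
    smooth = np.sqrt(resid**2 + eps**2)
    f = float(np.sum(w[np.newaxis, :] * smooth))
    # d smooth/d r = -resid / smooth ; chain through r
    dfdr = np.sum(w[np.newaxis, :] * (-resid / smooth), axis=0)  # (n_pairs,)
    g_pair = (dfdr / r_safe)[:, np.newaxis] * diff
    grad = np.zeros_like(coords)
    np.add.at(grad, i, g_pair)
    np.add.at(grad, j, -g_pair)
    return f, grad.ravel()


def exact_objective(coords: np.ndarray, pairs: np.ndarray,
                    d_targets: np.ndarray, w: np.ndarray) -> float:
    i, j = pairs[:, 0], pairs[:, 1]
    r = np.linalg.norm(coords[i] - coords[j], axis=1)
    return float(np.sum(w[np.newaxis, :] * np.abs(d_targets - r[np.newaxis, :])))


def reconstruct(pred: DistancePrediction, init: Structure,
                cfg: ReconstructionConfig | None = None) -> ReconstructionResult:
    """Rebuild a TS geometry from a distance prediction.

    ``init`` is the starting geometry (normally the interpolated structure).
    Non-convergence within ``max_iter`` returns the best-found geometry with
    ``converged=False`` rather than raising.
    """
    cfg = cfg or ReconstructionConfig()
    pairs = pred.pair_index
    n_atoms = init.n_atoms
    if pairs.max() >= n_atoms:
        raise ValueError("initial structure has fewer atoms than the prediction")
    d_targets = pred.d_pred / PM_PER_ANGSTROM        # (n_members, n_pairs), A
    w = pair_weights(pred.mean / PM_PER_ANGSTROM, cfg.alpha)

    x0 = init.coordinates.ravel().copy()
    total_iter = 0
    # graduated smoothing: a generous first epsilon keeps the surface benign
    # far from the optimum, the later stages sharpen |x| near convergence
    stages = [cfg.smooth_eps * 100.0, cfg.smooth_eps]
    if cfg.polish:
        stages.append(cfg.smooth_eps * 1e-3)
    res = None
    for eps in stages:
        res = minimize(
            _objective_terms, x0, args=(pairs, d_targets, w, eps),
            method="L-BFGS-B", jac=True,
            options={"maxiter": cfg.max_iter, "ftol": cfg.tol, "gtol": 1e-14,
                     "maxcor": 20},
        )
        x0 = res.x
        total_iter += int(res.nit)
    coords = x0.reshape(-1, 3)
    return ReconstructionResult(
        structure=Structure(init.atomic_numbers.copy(), coords, label="ts"),
        objective=exact_objective(coords, pairs, d_targets, w),
        n_iterations=total_iter,
        converged=bool(res.success) or res.status == 0,
    )


class TSReconstructor:
    """Estimator-style facade: transform distance predictions to geometries."""

    def __init__(self, alpha: float = 0.2, tol: float = 1e-15,
                 max_iter: int = 5000):
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter

    def _cfg(self) -> ReconstructionConfig:
        return ReconstructionConfig(alpha=self.alpha, tol=self.tol,
                                    max_iter=self.max_iter)

    def transform(self, predictions: list[DistancePrediction],
                  inits: list[Structure]) -> list[ReconstructionResult]:
        return [reconstruct(p, s, self._cfg()) for p, s in zip(predictions, inits)]

    def get_params(self, deep=True):
        return {"alpha": self.alpha, "tol": self.tol, "max_iter": self.max_iter}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self
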