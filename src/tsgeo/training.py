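"""Training: splitting, the optimization loop, checkpoint selection, and the
scikit-learn-style estimator wrapping them.

Training minimizes L = c*L1 + c'*(L2 + L3) with Adam under a cosine
learning-rate decay, and keeps the model parameters of the epochs with the
five best validation molecular MAPE values; those checkpoints are the raw
material of ensembles. All randomness (splits, initialization, batch order)
derives from one integer seed.
"""

from __future__ import annotations

import copy
import dataclasses

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .featurize import DEFAULT_ELEMENTS, FeaturizerConfig
from .losses import total_loss
from .metrics import molecular_mape
from .model import Checkpoint, ModelConfig, PSIModel
from .nn import Adam
from .structures import PM_PER_ANGSTROM, Reaction, strict_pairs


@dataclasses.dataclass
class LossWeights:
    c: float = 2000.0
    c_prime: float = 0.0

    def __post_init__(self):
        if self.c < 0 or self.c_prime < 0:
            raise ValueError("loss weights must be non-negative")


@dataclasses.dataclass
class TrainSettings:
    lr: float = 1e-4
    n_epochs: int = 300
    batch_size: int = 16
    n_keep: int = 5
    cosine_decay: bool = True
    seed: int = 0


def split_reactions(reactions: list[Reaction], fractions=(0.8, 0.1, 0.1),
                    seed: int = 0) -> tuple[list, list, list]:
    """Random by-reaction train/validation/test split (default 80-10-10)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reactions))
    n_train = int(round(fractions[0] * len(reactions)))
    n_val = int(round(fractions[1] * len(reactions)))
    idx_train = order[:n_train]
    idx_val = order[n_train:n_train + n_val]
    idx_test = order[n_train + n_val:]
    pick = lambda idx: [reactions[i] for i in idx]
    return pick(idx_train), pick(idx_val), pick(idx_test)


def evaluate_mape(model: PSIModel, reactions: list[Reaction]) -> float:
    """Validation molecular MAPE (%) of the model's TS distances."""
    pred, true = [], []
    for rxn in reactions:
        pair_index, _, d_pred = model.predict_distances(rxn)
        pred.append(d_pred * PM_PER_ANGSTROM)
        true.append(rxn.ts_ref.strict_pair_distances(pair_index) * PM_PER_ANGSTROM)
    return molecular_mape(pred, true)


def interpolation_baseline_mape(model: PSIModel, reactions: list[Reaction]) -> float:
    """Molecular MAPE of the ratio==1 baseline (the interpolated geometry)."""
    pred, true = [], []
    for rxn in reactions:
        interp = model.make_interpolated(rxn)
        out_pairs = strict_pairs(rxn.n_atoms)
        pred.append(interp.strict_pair_distances(out_pairs) * PM_PER_ANGSTROM)
        true.append(rxn.ts_ref.strict_pair_distances(out_pairs) * PM_PER_ANGSTROM)
    return molecular_mape(pred, true)


def train(
    train_set: list[Reaction],
    val_set: list[Reaction],
    mcfg: ModelConfig | None = None,
    fcfg: FeaturizerConfig | None = None,
    weights: LossWeights | None = None,
    settings: TrainSettings | None = None,
    log_fn=None,
) -> tuple[list[Checkpoint], list[dict]]:
    """Train one model; return (top-n_keep checkpoints by val MAPE, history).

    Raises on empty splits and aborts with diagnostics if the loss becomes
    non-finite.
    """
    if not train_set or not val_set:
        raise ValueError("training and validation sets must be non-empty")
    mcfg = mcfg or ModelConfig()
    fcfg = fcfg or FeaturizerConfig()
    weights = weights or LossWeights()
    settings = settings or TrainSettings()

    model = PSIModel(mcfg, fcfg)
    opt = Adam(model.parameters(), lr=settings.lr)
    rng = np.random.default_rng(settings.seed)
    history: list[dict] = []
    kept: list[Checkpoint] = []

    for epoch in range(settings.n_epochs):
        if settings.cosine_decay:
            opt.lr = settings.lr * 0.5 * (
                1.0 + np.cos(np.pi * epoch / max(1, settings.n_epochs))
            )
        order = rng.permutation(len(train_set))
        epoch_parts: dict[str, float] = {}
        n_batches = 0
        for start in range(0, len(order), settings.batch_size):
            batch = [train_set[i] for i in order[start:start + settings.batch_size]]
            outputs = model.forward_batch(batch)
            loss, parts = total_loss(
                outputs, batch, c=weights.c, c_prime=weights.c_prime,
                property_head=mcfg.property_head,
            )
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {parts}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            for k, v in parts.items():
                epoch_parts[k] = epoch_parts.get(k, 0.0) + v
            n_batches += 1
        record = {k: v / n_batches for k, v in epoch_parts.items()}
        record["epoch"] = epoch
        record["val_mape"] = evaluate_mape(model, val_set)
        history.append(record)
        if log_fn is not None:
            log_fn(record)

        ckpt = Checkpoint(
            state=copy.deepcopy(model.state_dict()),
            model_config=mcfg,
            featurizer_config=fcfg,
            val_mape=record["val_mape"],
            epoch=epoch,
            seed=settings.seed,
            checkpoint_id=f"seed{settings.seed}-epoch{epoch}",
        )
        kept.append(ckpt)
        kept.sort(key=lambda c: c.val_mape)
        del kept[settings.n_keep:]

    return kept, history


class TSDistanceRegressor(RegressorMixin, BaseEstimator):
    """Predicts transition-state interatomic distances of atom-mapped reactions.

    scikit-learn-style estimator: ``fit`` takes a list of reactions whose
    ``ts_ref`` provides the target distances, trains the PSI model, and keeps
    the five checkpoints with the best validation molecular MAPE;
    ``predict`` returns, per reaction, the predicted strict-pair TS distances
    in pm (from the best checkpoint).

    Parameters mirror the architecture, featurizer, and optimizer settings;
    see :class:`ModelConfig`, :class:`FeaturizerConfig`, and
    :class:`TrainSettings` for their meaning.
    """

    def __init__(self, n_psi_layers=2, encoder_heads=4, encoder_ffn_mult=2,
                 head_hidden=256, property_head=False, interp_fraction=0.5,
                 align_before_interp=False, n_embed=32, n_rbf=64,
                 grid_min=0.0, grid_max=8.0, gamma=None,
                 elements=DEFAULT_ELEMENTS, c=2000.0, c_prime=0.0,
                 lr=1e-4, n_epochs=300, batch_size=16, n_keep=5,
                 cosine_decay=True, val_fraction=0.1, seed=0):
        self.n_psi_layers = n_psi_layers
        self.encoder_heads = encoder_heads
        self.encoder_ffn_mult = encoder_ffn_mult
        self.head_hidden = head_hidden
        self.property_head = property_head
        self.interp_fraction = interp_fraction
        self.align_before_interp = align_before_interp
        self.n_embed = n_embed
        self.n_rbf = n_rbf
        self.grid_min = grid_min
        self.grid_max = grid_max
        self.gamma = gamma
        self.elements = elements
        self.c = c
        self.c_prime = c_prime
        self.lr = lr
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.n_keep = n_keep
        self.cosine_decay = cosine_decay
        self.val_fraction = val_fraction
        self.seed = seed

    # -- config assembly ------------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            n_psi_layers=self.n_psi_layers, encoder_heads=self.encoder_heads,
            encoder_ffn_mult=self.encoder_ffn_mult, head_hidden=self.head_hidden,
            property_head=self.property_head, interp_fraction=self.interp_fraction,
            align_before_interp=self.align_before_interp, seed=self.seed,
        )

    def _featurizer_config(self) -> FeaturizerConfig:
        return FeaturizerConfig(
            n_embed=self.n_embed, n_rbf=self.n_rbf, grid_min=self.grid_min,
            grid_max=self.grid_max, gamma=self.gamma,
            elements=tuple(self.elements),
        )

    # -- estimator API --------------------------------------------------------
    def fit(self, X: list[Reaction], y=None, validation_set=None):
        """Train on reactions with reference TS structures.

        If ``validation_set`` is not given, ``val_fraction`` of X is held
        out (seeded) for checkpoint selection.
        """
        X = list(X)
        if validation_set is None:
            frac = self.val_fraction
            train_set, val_set, _ = split_reactions(
                X, (1.0 - frac, frac, 0.0), seed=self.seed
            )
        else:
            train_set, val_set = X, list(validation_set)
        checkpoints, history = train(
            train_set, val_set,
            mcfg=self._model_config(),
            fcfg=self._featurizer_config(),
            weights=LossWeights(self.c, self.c_prime),
            settings=TrainSettings(
                lr=self.lr, n_epochs=self.n_epochs, batch_size=self.batch_size,
                n_keep=self.n_keep, cosine_decay=self.cosine_decay,
                seed=self.seed,
            ),
        )
        self.checkpoints_ = checkpoints
        self.history_ = history
        self.model_ = checkpoints[0].build_model()
        self.val_mape_ = checkpoints[0].val_mape
        self.baseline_mape_ = interpolation_baseline_mape(self.model_, val_set)
        return self

    def predict(self, X: list[Reaction]) -> list[np.ndarray]:
        """Predicted strict-pair TS distances (pm), one array per reaction."""
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted")
        return [
            self.model_.predict_distances(r)[2] * PM_PER_ANGSTROM for r in X
        ]

    def score(self, X: list[Reaction], y=None) -> float:
        """Negative molecular MAPE against the reactions' reference TS."""
        pred = self.predict(X)
        true = [
            r.ts_ref.strict_pair_distances(strict_pairs(r.n_atoms)) * PM_PER_ANGSTROM
            for r in X
        ]
        return -molecular_mape(pred, true)
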