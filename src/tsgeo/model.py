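"""The pair-sequence-interaction (PSI) model.

Each PSI layer first lets all pairs of one structure interact through a
transformer encoder (permutation-equivariant over pairs, size-extensive),
then runs a bidirectional GRU across the length-3 structure sequence
(reactant, interpolated, product) for each pair independently. The BiGRU
concatenates forward and backward states, so every layer doubles the feature
width: 128 -> 256 -> 512 with the default two stacked layers.

Two readouts follow: the ratio head maps the interpolated-structure features
of each strict pair (i > j) to log(d_TS / d_I) — exponentiated so predicted
ratios are structurally positive — and the optional property head maps
atom-aggregated reactant/product features to per-atom contributions to the
electronic energy and vibrational/rotational entropies.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from . import autodiff
from .autodiff import Tensor, concatenate
from .featurize import FeaturizerConfig, pair_distance_features
from .nn import BiGRU, MLPHead, Module, TransformerEncoderBlock
from .structures import Reaction, Structure, interpolate

PROPERTY_TARGETS = ("E", "S_vib", "S_rot")


@dataclasses.dataclass
class ModelConfig:
    """Architecture hyperparameters."""

    n_psi_layers: int = 2
    encoder_heads: int = 4
    encoder_ffn_mult: int = 2
    head_hidden: int = 256
    property_head: bool = False
    interp_fraction: float = 0.5
    align_before_interp: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclasses.dataclass
class ModelOutput:
    """Per-reaction forward-pass result."""

    ratios: Tensor                 # (n_strict,) predicted d_TS / d_I, > 0
    pair_index: np.ndarray         # (n_strict, 2) rows (i, j), i > j
    d_interp: np.ndarray           # (n_strict,) interpolated distances, A
    atomic_props: Optional[dict]   # role -> Tensor (N_atom, 3) or None

    @property
    def d_pred(self) -> Tensor:
        """Predicted TS distances (A), differentiable."""
        return self.ratios * self.d_interp

    def molecular_properties(self) -> Optional[dict]:
        """role -> Tensor (3,): summed atomic contributions (E, S_vib, S_rot)."""
        if self.atomic_props is None:
            return None
        return {role: t.sum(axis=0) for role, t in self.atomic_props.items()}


class PSILayer(Module):
    def __init__(self, width: int, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.encoder = self.add_child(
            "encoder",
            TransformerEncoderBlock(width, cfg.encoder_heads, cfg.encoder_ffn_mult, rng),
        )
        self.gru = self.add_child("gru", BiGRU(width, rng))

    def __call__(self, x: Tensor, blocks=None) -> Tensor:
        # step 1: intra-structure pair interaction (batched over slices,
        # attention confined to each slice and, in a batch, each reaction);
        # step 2: cross-structure sequence update per pair
        return self.gru(self.encoder(x, blocks))


def atom_pair_incidence(pair_index: np.ndarray, n_atoms: int) -> np.ndarray:
    """Matrix A (N_atom, N_pairs): f_atom = A @ f_pair with symmetric recovery.

    Each off-diagonal stored pair (i, j), i > j, contributes to both atoms i
    and j (f_ij = f_ji); a diagonal pair contributes once to its atom.
    """
    a = np.zeros((n_atoms, pair_index.shape[0]))
    for col, (i, j) in enumerate(pair_index):
        a[i, col] += 1.0
        if i != j:
            a[j, col] += 1.0
    return a


def aggregate_atomic(pair_features: Tensor, pair_index: np.ndarray,
                     n_atoms: int) -> Tensor:
    """Sum pair features into per-atom features, f_i = sum_j f_ij."""
    return Tensor(atom_pair_incidence(pair_index, n_atoms)) @ pair_features


class PSIModel(Module):
    """Stacked PSI layers plus ratio / property readouts."""

    def __init__(self, mcfg: ModelConfig | None = None,
                 fcfg: FeaturizerConfig | None = None):
        super().__init__()
        self.mcfg = mcfg or ModelConfig()
        self.fcfg = fcfg or FeaturizerConfig()
        rng = np.random.default_rng(self.mcfg.seed)
        self.embed = self.add_param(
            "embed",
            rng.normal(0.0, 1.0, size=(len(self.fcfg.elements), self.fcfg.n_embed)),
        )
        width = self.fcfg.n_features
        self.psi_layers: list[PSILayer] = []
        for k in range(self.mcfg.n_psi_layers):
            layer = self.add_child(f"psi{k}", PSILayer(width, self.mcfg, rng))
            self.psi_layers.append(layer)
            width *= 2  # bidirectional concatenation doubles the width
        self.final_width = width
        self.ratio_head = self.add_child(
            "ratio_head", MLPHead(width, self.mcfg.head_hidden, 1, rng, zero_out=True)
        )
        if self.mcfg.property_head:
            self.prop_head = self.add_child(
                "prop_head",
                MLPHead(width, self.mcfg.head_hidden, len(PROPERTY_TARGETS), rng,
                        zero_out=True),
            )
        else:
            self.prop_head = None

    # -- forward --------------------------------------------------------------
    def make_interpolated(self, reaction: Reaction) -> Structure:
        return interpolate(
            reaction, self.mcfg.interp_fraction, align=self.mcfg.align_before_interp
        )

    def forward_batch(self, reactions: list[Reaction],
                      interps: list[Structure] | None = None) -> list[ModelOutput]:
        """One differentiable pass over a batch of reactions.

        Reactions are concatenated along the pair axis so the projection and
        recurrent matmuls are shared; attention and the readouts respect
        per-reaction block boundaries (no cross-reaction mixing), so each
        output equals the reaction processed alone.
        """
        if interps is None:
            interps = [self.make_interpolated(r) for r in reactions]
        feats = [
            pair_distance_features(r, it, self.fcfg)
            for r, it in zip(reactions, interps)
        ]
        blocks, start = [], 0
        for f in feats:
            blocks.append((start, start + f.n_pairs))
            start += f.n_pairs
        pair_elems = np.concatenate([f.pair_elements for f in feats], axis=0)
        rbf = np.concatenate(
            [f.values[:, :, 2 * self.fcfg.n_embed:] for f in feats], axis=0
        )
        ei = self.embed[pair_elems[:, 0]]
        ej = self.embed[pair_elems[:, 1]]
        x = autodiff.stack(
            [concatenate([ei, ej, Tensor(rbf[:, s, :])], axis=1) for s in range(3)],
            axis=0,
        )  # (3, total_pairs, N_f)
        for layer in self.psi_layers:
            x = layer(x, blocks)

        strict_all = np.concatenate(
            [f.pair_index[:, 0] > f.pair_index[:, 1] for f in feats]
        )
        raw = self.ratio_head(x[1][strict_all]).reshape(-1)
        ratios_all = raw.exp()

        outputs = []
        offset = 0
        for f, (b0, _) in zip(feats, blocks):
            strict = f.pair_index[:, 0] > f.pair_index[:, 1]
            n_strict = int(strict.sum())
            ratios = ratios_all[offset:offset + n_strict]
            offset += n_strict
            atomic_props = None
            if self.prop_head is not None:
                atomic_props = {}
                n_atoms = int(f.pair_index.max()) + 1
                for role, s in (("reactant", 0), ("product", 2)):
                    xs = x[(s, slice(b0, b0 + f.n_pairs))]
                    atom_feats = aggregate_atomic(xs, f.pair_index, n_atoms)
                    atomic_props[role] = self.prop_head(atom_feats)
            outputs.append(ModelOutput(
                ratios=ratios,
                pair_index=f.pair_index[strict],
                d_interp=f.distances[strict, 1],
                atomic_props=atomic_props,
            ))
        return outputs

    def forward(self, reaction: Reaction,
                interp: Structure | None = None) -> ModelOutput:
        return self.forward_batch(
            [reaction], None if interp is None else [interp]
        )[0]

    __call__ = forward

    def predict_distances(self, reaction: Reaction) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Non-differentiable convenience: (pair_index, d_interp, d_pred), A."""
        out = self.forward(reaction)
        return out.pair_index, out.d_interp, out.ratios.data * out.d_interp


@dataclasses.dataclass
class Checkpoint:
    """Trained weights plus the metadata needed to rebuild the model."""

    state: dict[str, np.ndarray]
    model_config: ModelConfig
    featurizer_config: FeaturizerConfig
    val_mape: float = float("nan")
    epoch: int = -1
    seed: int = 0
    checkpoint_id: str = ""

    def build_model(self) -> PSIModel:
        model = PSIModel(self.model_config, self.featurizer_config)
        model.load_state_dict(self.state)
        return model

    def save(self, path: str) -> None:
        import json
        import os

        meta = {
            "model_config": self.model_config.to_dict(),
            "featurizer_config": self.featurizer_config.to_dict(),
            "val_mape": self.val_mape,
            "epoch": self.epoch,
            "seed": self.seed,
            "checkpoint_id": self.checkpoint_id,
        }
        root, _ = os.path.splitext(path)
        np.savez(root + ".npz", **self.state)
        with open(root + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "Checkpoint":
        import json
        import os

        root, _ = os.path.splitext(path)
        with np.load(root + ".npz") as npz:
            state = {k: npz[k] for k in npz.files}
        with open(root + ".json") as fh:
            meta = json.load(fh)
        return cls(
            state=state,
            model_config=ModelConfig.from_dict(meta["model_config"]),
            featurizer_config=FeaturizerConfig.from_dict(meta["featurizer_config"]),
            val_mape=meta.get("val_mape", float("nan")),
            epoch=meta.get("epoch", -1),
            seed=meta.get("seed", 0),
            checkpoint_id=meta.get("checkpoint_id", os.path.basename(root)),
        )
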