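"""Pair featurization: distances on a Gaussian grid plus atom embeddings.

Each reaction becomes a tensor of shape (N_pairs, 3, N_f): one row per
unordered atom pair (i >= j, diagonal included), one slice per structure in
the fixed order (reactant, interpolated, product), and N_f = 2*n_embed +
n_rbf features per entry — the learned embeddings of the two atomic numbers
concatenated with the Gaussian-expanded interatomic distance. Only atomic
numbers and distances enter, so the tensor is exactly invariant under rigid
motions of the structures.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .structures import Reaction, Structure, all_pairs

DEFAULT_ELEMENTS = (1, 6, 7, 8)

STRUCTURE_ORDER = ("reactant", "interpolated", "product")


@dataclasses.dataclass
class FeaturizerConfig:
    """Geometry of the pair features.

    The Gaussian grid spans [grid_min, grid_max] A with ``n_rbf`` equidistant
    centers; ``gamma`` (1/A^2) is the kernel width, by default matched to the
    grid spacing as gamma = 1/(2*spacing^2). Total feature width is
    N_f = 2*n_embed + n_rbf (128 with the defaults).
    """

    n_embed: int = 32
    n_rbf: int = 64
    grid_min: float = 0.0
    grid_max: float = 8.0
    gamma: float | None = None
    elements: tuple[int, ...] = DEFAULT_ELEMENTS

    def __post_init__(self):
        self.elements = tuple(int(z) for z in self.elements)
        if self.n_rbf < 2:
            raise ValueError("n_rbf must be >= 2")
        if self.grid_max <= self.grid_min:
            raise ValueError("grid_max must exceed grid_min")
        if self.gamma is None:
            spacing = (self.grid_max - self.grid_min) / (self.n_rbf - 1)
            self.gamma = 1.0 / (2.0 * spacing**2)

    @property
    def n_features(self) -> int:
        return 2 * self.n_embed + self.n_rbf

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.grid_min, self.grid_max, self.n_rbf)

    def element_index(self) -> dict[int, int]:
        return {z: k for k, z in enumerate(self.elements)}

    def to_dict(self) -> dict:
        return {
            "n_embed": self.n_embed, "n_rbf": self.n_rbf,
            "grid_min": self.grid_min, "grid_max": self.grid_max,
            "gamma": self.gamma, "elements": list(self.elements),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeaturizerConfig":
        d = dict(d)
        d["elements"] = tuple(d.get("elements", DEFAULT_ELEMENTS))
        return cls(**d)


@dataclasses.dataclass
class PairFeatureTensor:
    """(N_pairs, 3, N_f) feature array with its pair bookkeeping."""

    values: np.ndarray           # (N_pairs, 3, N_f)
    pair_index: np.ndarray       # (N_pairs, 2), rows (i, j) with i >= j
    distances: np.ndarray        # (N_pairs, 3) raw distances, A
    pair_elements: np.ndarray    # (N_pairs, 2) element-table indices of (i, j)

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]


def expand_distance(d, cfg: FeaturizerConfig) -> np.ndarray:
    """Gaussian-grid expansion exp(-gamma (d - mu_k)^2), values in (0, 1]."""
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    return np.exp(-cfg.gamma * (d[..., np.newaxis] - cfg.grid) ** 2)


def pair_distance_features(
    reaction: Reaction, interp: Structure, cfg: FeaturizerConfig
) -> PairFeatureTensor:
    """Distance-derived part of the feature tensor (embedding slots zeroed).

    The model fills the embedding blocks from its learned table; this
    function is also the public featurizer when given a concrete table via
    :func:`featurize_reaction`.
    """
    n = reaction.n_atoms
    pairs = all_pairs(n)
    elem_index = cfg.element_index()
    try:
        pair_elems = np.array(
            [[elem_index[int(reaction.reactant.atomic_numbers[i])],
              elem_index[int(reaction.reactant.atomic_numbers[j])]]
             for i, j in pairs],
            dtype=np.int64,
        )
    except KeyError as exc:
        raise ValueError(
            f"element Z={exc.args[0]} not covered by the featurizer "
            f"(supported: {cfg.elements})"
        ) from None
    # canonicalize the within-pair slot order by element, not by atom index:
    # atom indices are not chemically meaningful, so ordering the two
    # embedding blocks by Z keeps the row content invariant under any
    # consistent atom reordering (ties: same element, order irrelevant)
    pair_elems = np.sort(pair_elems, axis=1)[:, ::-1]
    structures = (reaction.reactant, interp, reaction.product)
    distances = np.stack(
        [s.strict_pair_distances(pairs) for s in structures], axis=1
    )  # (N_pairs, 3)
    values = np.zeros((pairs.shape[0], 3, cfg.n_features))
    values[:, :, 2 * cfg.n_embed:] = expand_distance(distances, cfg)
    return PairFeatureTensor(values, pairs, distances, pair_elems)


def featurize_reaction(
    reaction: Reaction,
    interp: Structure,
    cfg: FeaturizerConfig,
    embeddings: np.ndarray,
) -> PairFeatureTensor:
    """Full (N_pairs, 3, N_f) tensor given an embedding table.

    ``embeddings`` has one row of width n_embed per element in
    ``cfg.elements``. Row (i, j) concatenates embed(Z_i), embed(Z_j) and the
    Gaussian-expanded distance, identically for the three structure slices
    except for the distance block.
    """
    embeddings = np.asarray(embeddings, dtype=np.float64)
    if embeddings.shape != (len(cfg.elements), cfg.n_embed):
        raise ValueError(
            f"embedding table must be {(len(cfg.elements), cfg.n_embed)}, "
            f"got {embeddings.shape}"
        )
    t = pair_distance_features(reaction, interp, cfg)
    ei = embeddings[t.pair_elements[:, 0]]  # (N_pairs, n_embed)
    ej = embeddings[t.pair_elements[:, 1]]
    t.values[:, :, : cfg.n_embed] = ei[:, np.newaxis, :]
    t.values[:, :, cfg.n_embed: 2 * cfg.n_embed] = ej[:, np.newaxis, :]
    return t
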