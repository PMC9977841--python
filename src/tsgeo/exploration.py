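"""Multi-path TS exploration: normal-mode sampling, alignment, ensemble
prediction, and clustering to representative structures.

Normal-mode sampling (NMS) displaces an equilibrium structure along each
real harmonic mode by a random amplitude q = s * sqrt(2 c kT / k_mode) with
c ~ U[0, 1] and random sign s, so the expected harmonic potential energy is
kT/2 per mode. Sampled reactant/product pairs are rigidly aligned, fed to
the ensemble predictor, reconstructed, and finally clustered on their
interatomic-distance vectors with affinity propagation; the exemplars are
returned as the representative TS candidates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from typing import Optional

import numpy as np
from sklearn.cluster import AffinityPropagation

from .inference import EnsembleSpec, predict_ensemble
from .reconstruction import ReconstructionConfig, reconstruct
from .structures import (ATOMIC_MASSES, Reaction, Structure, kabsch_align,
                         strict_pairs)
from .synthetic import KB_KCAL_MOL, NormalModes, frequency_to_force_constant

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ExplorationConfig:
    n_samples: int = 2000
    temperature: float = 300.0     # K
    damping: float = 0.9           # affinity-propagation damping
    preference: Optional[float] = None  # None -> median similarity
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")


def nms_sample(nm: NormalModes, cfg: ExplorationConfig,
               rng: Optional[np.random.Generator] = None) -> list[Structure]:
    """Draw ``n_samples`` thermally displaced structures along the real modes.

    At T = 0 every sample is the equilibrium structure. Imaginary-frequency
    modes are excluded.
    """
    real = nm.frequencies > 0
    if nm.n_modes and not np.any(real):
        raise ValueError("no real-frequency modes to sample")
    freqs = nm.frequencies[real]
    modes = nm.modes[real]
    k_mode = frequency_to_force_constant(freqs)  # kcal/mol/(amu A^2)
    masses = np.array([ATOMIC_MASSES[int(z)]
                       for z in nm.equilibrium.atomic_numbers])
    inv_sqrt_m = 1.0 / np.sqrt(masses)[:, np.newaxis]
    rng = rng or np.random.default_rng(cfg.seed)
    kt = KB_KCAL_MOL * cfg.temperature
    samples = []
    for _ in range(cfg.n_samples):
        c = rng.uniform(0.0, 1.0, size=freqs.size)
        sign = rng.choice([-1.0, 1.0], size=freqs.size)
        q = sign * np.sqrt(2.0 * c * kt / k_mode)   # mass-weighted amplitude
        disp = np.tensordot(q, modes, axes=(0, 0)) * inv_sqrt_m
        samples.append(Structure(
            nm.equilibrium.atomic_numbers.copy(),
            nm.equilibrium.coordinates + disp,
        ))
    return samples


def harmonic_energy(nm: NormalModes, s: Structure) -> float:
    """Harmonic potential energy (kcal/mol) of a displaced structure."""
    masses = np.array([ATOMIC_MASSES[int(z)]
                       for z in nm.equilibrium.atomic_numbers])
    disp_mw = (s.coordinates - nm.equilibrium.coordinates) * \
        np.sqrt(masses)[:, np.newaxis]
    real = nm.frequencies > 0
    k_mode = frequency_to_force_constant(nm.frequencies[real])
    q = np.tensordot(nm.modes[real], disp_mw, axes=([1, 2], [0, 1]))
    return float(0.5 * np.sum(k_mode * q * q))


def align(mobile: Structure, target: Structure) -> tuple[Structure, float]:
    """Rigid superposition (rotation + translation, no reflection) of
    ``mobile`` onto ``target``; returns the moved structure and the RMSD (A)."""
    if mobile.n_atoms != target.n_atoms or \
            not np.array_equal(mobile.atomic_numbers, target.atomic_numbers):
        raise ValueError("structures must share N_atom and element order")
    coords, rmsd = kabsch_align(mobile.coordinates, target.coordinates)
    return Structure(mobile.atomic_numbers.copy(), coords,
                     label=mobile.label), rmsd


def _distance_features(structures: list[Structure]) -> np.ndarray:
    pairs = strict_pairs(structures[0].n_atoms)
    return np.stack([s.strict_pair_distances(pairs) for s in structures])


def cluster_representative_indices(structures: list[Structure],
                                   cfg: ExplorationConfig) -> list[int]:
    """Indices of affinity-propagation exemplars on distance features.

    Exemplars are members of the input set; the cluster count is
    data-dependent. If message passing fails to converge, the medoid of the
    whole set is returned with a warning.
    """
    if not structures:
        raise ValueError("need at least one structure")
    if len(structures) == 1:
        return [0]
    feats = _distance_features(structures)
    if np.allclose(feats, feats[0]):
        return [0]  # all identical: a single exemplar
    ap = AffinityPropagation(
        damping=cfg.damping, preference=cfg.preference, random_state=cfg.seed,
        max_iter=500,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        try:
            ap.fit(feats)
        except UserWarning:
            logger.warning("affinity propagation did not converge; "
                           "falling back to the global medoid")
            d2 = ((feats[:, np.newaxis, :] - feats[np.newaxis, :, :]) ** 2).sum(-1)
            return [int(np.argmin(d2.sum(axis=1)))]
    return [int(k) for k in ap.cluster_centers_indices_]


def cluster_representatives(structures: list[Structure],
                            cfg: ExplorationConfig) -> list[Structure]:
    """Affinity-propagation exemplar structures (subset of the input)."""
    return [structures[k]
            for k in cluster_representative_indices(structures, cfg)]


def explore(reaction: Reaction, modes_r: NormalModes, modes_p: NormalModes,
            spec: EnsembleSpec, cfg: ExplorationConfig,
            recon_cfg: ReconstructionConfig | None = None,
            interp_fraction: float = 0.5) -> list[tuple[Structure, int]]:
    """Sample conformer pairs, predict + reconstruct a TS for each, cluster.

    Returns (representative TS, index of the sampled pair that produced it).
    Failures of individual samples are skipped with a log record.
    """
    from .structures import interpolate

    rng = np.random.default_rng(cfg.seed)
    samples_r = nms_sample(modes_r, cfg, rng)
    samples_p = nms_sample(modes_p, cfg, rng)
    recon_cfg = recon_cfg or ReconstructionConfig()
    ts_structures, provenance = [], []
    for k, (sr, sp) in enumerate(zip(samples_r, samples_p)):
        try:
            sp_aligned, _ = align(sp, sr)
            rxn = Reaction(
                reactant=sr.copy(label="reactant"),
                product=sp_aligned.copy(label="product"),
                reaction_id=f"{reaction.reaction_id}-nms{k}",
            )
            pred = predict_ensemble(rxn, spec)
            init = interpolate(rxn, interp_fraction)
            result = reconstruct(pred, init, recon_cfg)
            ts_structures.append(result.structure)
            provenance.append(k)
        except Exception as exc:  # partial failures are tolerated
            logger.warning("sample %d failed: %s", k, exc)
    if not ts_structures:
        raise RuntimeError("every sampled pair failed")
    rep_idx = cluster_representative_indices(ts_structures, cfg)
    return [(ts_structures[k], provenance[k]) for k in rep_idx]


# -- modes file I/O ------------------------------------------------------------

def write_modes(nm: NormalModes, path: str) -> None:
    payload = {
        "frequencies_cm": nm.frequencies.tolist(),
        "modes": nm.modes.tolist(),
        "atomic_numbers": nm.equilibrium.atomic_numbers.tolist(),
        "coordinates": nm.equilibrium.coordinates.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_modes(path: str) -> NormalModes:
    with open(path) as fh:
        payload = json.load(fh)
    return NormalModes(
        frequencies=np.asarray(payload["frequencies_cm"], dtype=np.float64),
        modes=np.asarray(payload["modes"], dtype=np.float64),
        equilibrium=Structure(
            np.asarray(payload["atomic_numbers"], dtype=np.int64),
            np.asarray(payload["coordinates"], dtype=np.float64),
        ),
    )
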