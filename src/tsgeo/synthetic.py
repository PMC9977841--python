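"""Synthetic atom-mapped reactions with exactly realizable reference TSs.

The generator stands in for curated reaction databases: each toy reaction
is a reactant built by random chain growth, a product obtained by moving one
atom between neighbors (bond breakage + formation) or by smooth radial
stretches, and a reference TS constructed as the coordinate midpoint plus a
bend orthogonal to the reactant->product displacement. Because the TS is
built in coordinate space, its distance set is realizable in 3-D by
construction (the EDM penalty of the targets is identically zero), and the
ratio targets d_TS/d_I deviate from 1 in proportion to ``bend_scale``.

A smooth Morse-like pairwise toy energy provides property labels (E, and
entropy-like functionals S_vib, S_rot), analytic gradients for relaxation,
and an analytic Hessian for normal modes — enough to exercise training,
multi-label plumbing, and normal-mode sampling without quantum chemistry.
The energies are not chemically meaningful.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import minimize

from .structures import ATOMIC_MASSES, Reaction, Structure, strict_pairs

# toy per-element parameters: covalent-like radius (A) and well depth
_RADIUS = {1: 0.35, 6: 0.75, 7: 0.71, 8: 0.66}
_DEPTH = {1: 100.0, 6: 150.0, 7: 140.0, 8: 160.0}
_MORSE_A = 1.8  # 1/A

# unit conversions for frequencies
_KCALMOL_PER_J = 1.0 / (4184.0 / 6.02214076e23)
_LAMBDA_TO_OMEGA2 = 4184.0 / 6.02214076e23 / (1.66053907e-27 * 1e-20)  # 1/s^2
_C_CM = 2.99792458e10  # cm/s
KB_KCAL_MOL = 0.0019872043  # kcal/mol/K


@dataclasses.dataclass
class SyntheticConfig:
    n_reactions: int = 100
    n_atoms_range: tuple[int, int] = (4, 8)
    elements: tuple[int, ...] = (1, 6, 7, 8)
    bend_scale: float = 0.3
    noise: float = 0.03           # A, label-free jitter on product atoms
    p_bond_change: float = 0.6    # fraction of reactions with an atom transfer
    stretch_range: tuple[float, float] = (0.95, 1.12)  # radial deformation
    min_separation: float = 0.8   # A, hard lower bound on pair distances
    seed: int = 0

    def __post_init__(self):
        if self.n_atoms_range[0] < 2:
            raise ValueError("need at least 2 atoms")
        if self.bend_scale < 0:
            raise ValueError("bend_scale must be >= 0")


# -- toy energy ----------------------------------------------------------------

def _pair_params(zi: int, zj: int) -> tuple[float, float]:
    r0 = _RADIUS[int(zi)] + _RADIUS[int(zj)]
    d = float(np.sqrt(_DEPTH[int(zi)] * _DEPTH[int(zj)]))
    return r0, d


def toy_energy(s: Structure) -> float:
    """Morse-like pairwise energy, kcal/mol (toy scale)."""
    pairs = strict_pairs(s.n_atoms)
    e = 0.0
    for i, j in pairs:
        r0, d = _pair_params(s.atomic_numbers[i], s.atomic_numbers[j])
        r = float(np.linalg.norm(s.coordinates[i] - s.coordinates[j]))
        e += d * ((1.0 - np.exp(-_MORSE_A * (r - r0))) ** 2 - 1.0)
    return e


def toy_gradient(s: Structure) -> np.ndarray:
    pairs = strict_pairs(s.n_atoms)
    grad = np.zeros_like(s.coordinates)
    for i, j in pairs:
        r0, d = _pair_params(s.atomic_numbers[i], s.atomic_numbers[j])
        diff = s.coordinates[i] - s.coordinates[j]
        r = float(np.linalg.norm(diff))
        u = np.exp(-_MORSE_A * (r - r0))
        dphi = 2.0 * _MORSE_A * d * (1.0 - u) * u
        g = dphi * diff / r
        grad[i] += g
        grad[j] -= g
    return grad


def toy_hessian_cartesian(s: Structure) -> np.ndarray:
    """Analytic 3N x 3N second-derivative matrix of the toy energy."""
    n = s.n_atoms
    h = np.zeros((3 * n, 3 * n))
    eye = np.eye(3)
    for i, j in strict_pairs(n):
        r0, d = _pair_params(s.atomic_numbers[i], s.atomic_numbers[j])
        diff = s.coordinates[i] - s.coordinates[j]
        r = float(np.linalg.norm(diff))
        uvec = diff / r
        x = np.exp(-_MORSE_A * (r - r0))
        dphi = 2.0 * _MORSE_A * d * (1.0 - x) * x
        d2phi = 2.0 * _MORSE_A**2 * d * (2.0 * x * x - x)
        block = d2phi * np.outer(uvec, uvec) + (dphi / r) * (eye - np.outer(uvec, uvec))
        for a, b, sign in ((i, i, 1.0), (j, j, 1.0), (i, j, -1.0), (j, i, -1.0)):
            h[3 * a:3 * a + 3, 3 * b:3 * b + 3] += sign * block
    return h


def relax_structure(s: Structure, max_iter: int = 500) -> Structure:
    """Minimize the toy energy from the given geometry (local relaxation)."""
    numbers = s.atomic_numbers

    def fg(x):
        st = Structure(numbers, x.reshape(-1, 3))
        return toy_energy(st), toy_gradient(st).ravel()

    res = minimize(fg, s.coordinates.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10})
    return Structure(numbers.copy(), res.x.reshape(-1, 3), label=s.label)


@dataclasses.dataclass(eq=False)
class NormalModes:
    """Harmonic modes: frequencies (cm^-1) + mass-weighted orthonormal modes."""

    frequencies: np.ndarray       # (n_modes,), cm^-1 (negative = imaginary)
    modes: np.ndarray             # (n_modes, N_atom, 3), mass-weighted
    equilibrium: Structure

    @property
    def n_modes(self) -> int:
        return self.frequencies.size


def toy_hessian(s: Structure, zero_cutoff_cm: float = 1.0) -> NormalModes:
    """Mass-weighted normal modes of the toy energy at (a minimum near) ``s``.

    Modes with |frequency| below ``zero_cutoff_cm`` (translations, and
    rotations at stationary points) are removed.
    """
    n = s.n_atoms
    h = toy_hessian_cartesian(s)
    if not np.all(np.isfinite(h)):
        raise ValueError("non-finite Hessian")
    masses = np.array([ATOMIC_MASSES[int(z)] for z in s.atomic_numbers])
    inv_sqrt_m = np.repeat(1.0 / np.sqrt(masses), 3)
    h_mw = h * np.outer(inv_sqrt_m, inv_sqrt_m)
    lam, vec = np.linalg.eigh(h_mw)  # lam in kcal/mol/(amu A^2)
    omega2 = lam * _LAMBDA_TO_OMEGA2
    freq_cm = np.sign(omega2) * np.sqrt(np.abs(omega2)) / (2.0 * np.pi * _C_CM)
    keep = np.abs(freq_cm) >= zero_cutoff_cm
    modes = vec.T[keep].reshape(-1, n, 3)
    return NormalModes(frequencies=freq_cm[keep], modes=modes,
                       equilibrium=s.copy())


def frequency_to_force_constant(freq_cm: np.ndarray) -> np.ndarray:
    """cm^-1 -> mass-weighted force constant, kcal/mol/(amu A^2)."""
    omega2 = (2.0 * np.pi * _C_CM * np.asarray(freq_cm, dtype=np.float64)) ** 2
    return omega2 / _LAMBDA_TO_OMEGA2


# -- property labels -----------------------------------------------------------

def toy_properties(s: Structure) -> dict:
    """Smooth deterministic property labels for one structure."""
    pairs = strict_pairs(s.n_atoms)
    r = s.strict_pair_distances(pairs)
    return {
        "E": toy_energy(s),
        "S_vib": float(10.0 * np.sum(np.log1p(r))),
        "S_rot": float(5.0 * np.log1p(np.sum(r * r))),
    }


# -- geometry construction -----------------------------------------------------

def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _min_separation(coords: np.ndarray) -> float:
    n = coords.shape[0]
    if n < 2:
        return np.inf
    d = coords[:, np.newaxis, :] - coords[np.newaxis, :, :]
    r = np.linalg.norm(d, axis=-1)
    return float(r[np.triu_indices(n, 1)].min())


def _grow_reactant(numbers: np.ndarray, rng: np.random.Generator,
                   min_sep: float) -> np.ndarray | None:
    n = numbers.size
    coords = np.zeros((n, 3))
    for k in range(1, n):
        placed = False
        for _ in range(60):
            parent = int(rng.integers(0, k))
            r0, _ = _pair_params(numbers[parent], numbers[k])
            length = r0 * rng.uniform(0.95, 1.15)
            candidate = coords[parent] + length * _random_unit(rng)
            dist = np.linalg.norm(coords[:k] - candidate, axis=1)
            if dist.min() >= min_sep:
                coords[k] = candidate
                placed = True
                break
        if not placed:
            return None
    return coords


def _make_product(numbers: np.ndarray, reactant: np.ndarray,
                  rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray | None:
    n = numbers.size
    coords = reactant.copy()
    if n >= 3 and rng.uniform() < cfg.p_bond_change:
        # atom transfer: move atom a from its nearest neighbor b to atom c
        a = int(rng.integers(1, n))
        dist = np.linalg.norm(reactant - reactant[a], axis=1)
        dist[a] = np.inf
        b = int(np.argmin(dist))
        others = [k for k in range(n) if k not in (a, b)]
        c = int(rng.choice(others))
        r0, _ = _pair_params(numbers[a], numbers[c])
        for _ in range(60):
            candidate = reactant[c] + r0 * rng.uniform(1.0, 1.1) * _random_unit(rng)
            rest = np.delete(np.arange(n), a)
            if np.linalg.norm(coords[rest] - candidate, axis=1).min() >= cfg.min_separation:
                coords[a] = candidate
                break
        else:
            return None
    else:
        # bond-preserving deformation: radial stretch about the centroid
        centroid = coords.mean(axis=0)
        scale = rng.uniform(*cfg.stretch_range)
        coords = centroid + scale * (coords - centroid)
    coords = coords + rng.normal(scale=cfg.noise, size=coords.shape)
    if _min_separation(coords) < cfg.min_separation:
        return None
    return coords


def _make_ts(reactant: np.ndarray, product: np.ndarray,
             bend_scale: float) -> np.ndarray:
    """Midpoint plus a bend orthogonal to each atom's R->P displacement.

    The bend direction is the component of the atom's radial vector (from
    the reactant centroid) orthogonal to its displacement — a deterministic,
    rotation- AND reflection-equivariant function of the endpoint geometry.
    The reference TS is therefore fully determined by the reactant/product
    distance matrices, so the distance-ratio targets are a learnable
    function of what the model sees, as for real single-step reactions.
    """
    delta = product - reactant
    mid = 0.5 * (reactant + product)
    if bend_scale == 0.0:
        return mid
    centroid = reactant.mean(axis=0)
    bend = np.zeros_like(mid)
    norms = np.linalg.norm(delta, axis=1)
    for a in range(mid.shape[0]):
        if norms[a] < 1e-8:
            continue
        d_hat = delta[a] / norms[a]
        radial = reactant[a] - centroid
        v = radial - np.dot(radial, d_hat) * d_hat
        if np.linalg.norm(v) < 1e-8:
            continue  # displacement parallel to the radial vector: no bend
        bend[a] = bend_scale * norms[a] * (v / np.linalg.norm(v))
    return mid + bend


def generate(cfg: SyntheticConfig) -> list[Reaction]:
    """Generate a deterministic list of toy reactions with reference TSs.

    Every reaction carries a reference TS whose distances are exactly
    realizable in 3-D, property labels for all three roles, and ground-truth
    distance ratios d_TS/d_I within [0.5, 2].
    """
    rng = np.random.default_rng(cfg.seed)
    reactions: list[Reaction] = []
    failures = 0
    while len(reactions) < cfg.n_reactions:
        if failures > 200 * cfg.n_reactions:
            raise RuntimeError(
                "separation constraints unsatisfiable under this configuration"
            )
        n = int(rng.integers(cfg.n_atoms_range[0], cfg.n_atoms_range[1] + 1))
        numbers = rng.choice(cfg.elements, size=n)
        numbers.sort()  # cosmetic: stable element ordering within a reaction
        reactant = _grow_reactant(numbers, rng, cfg.min_separation)
        if reactant is None:
            failures += 1
            continue
        product = _make_product(numbers, reactant, rng, cfg)
        if product is None:
            failures += 1
            continue
        ts = _make_ts(reactant, product, cfg.bend_scale)
        interp = 0.5 * (reactant + product)
        pairs = strict_pairs(n)
        d_ts = np.linalg.norm(ts[pairs[:, 0]] - ts[pairs[:, 1]], axis=1)
        d_i = np.linalg.norm(interp[pairs[:, 0]] - interp[pairs[:, 1]], axis=1)
        if (_min_separation(ts) < 0.7 * cfg.min_separation
                or d_i.min() < 1e-3
                or np.any(d_ts / d_i < 0.5) or np.any(d_ts / d_i > 2.0)):
            failures += 1
            continue
        r_s = Structure(numbers.copy(), reactant, label="reactant")
        p_s = Structure(numbers.copy(), product, label="product")
        t_s = Structure(numbers.copy(), ts, label="ts")
        reactions.append(Reaction(
            reactant=r_s, product=p_s, ts_ref=t_s,
            properties={
                "reactant": toy_properties(r_s),
                "product": toy_properties(p_s),
                "ts": toy_properties(t_s),
            },
            reaction_id=f"synth-{cfg.seed}-{len(reactions):05d}",
        ))
    return reactions


def write_dataset(reactions: list[Reaction], out_dir: str) -> str:
    """Write reactions as multi-frame XYZ plus a JSON-lines manifest.

    Returns the manifest path; the layout round-trips through
    :func:`tsgeo.io.load_dataset`.
    """
    import os

    from .io import write_manifest, write_reaction_xyz

    os.makedirs(out_dir, exist_ok=True)
    entries = []
    for r in reactions:
        fname = f"{r.reaction_id}.xyz"
        write_reaction_xyz(r, os.path.join(out_dir, fname))
        entries.append({
            "id": r.reaction_id, "path": fname,
            "frames": "RTP" if r.ts_ref is not None else "RP",
        })
    manifest = os.path.join(out_dir, "manifest.jsonl")
    write_manifest(entries, manifest)
    return manifest
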