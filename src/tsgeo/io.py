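"""Multi-frame XYZ and JSON-lines manifest I/O.

A reaction file is a standard multi-frame XYZ with 2 frames (reactant,
product) or 3 frames (reactant, TS, product). Comment lines may carry
``key=value`` fields; ``E=...``, ``S_vib=...`` and ``S_rot=...`` are read as
property labels of that frame.

The manifest is JSON-lines, one record per reaction:
``{"id": ..., "path": ..., "frames": "RP" | "RTP"}``.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, Optional

import numpy as np

from .structures import Reaction, Structure, number_for, symbol_for

_PROPERTY_KEYS = ("E", "S_vib", "S_rot")


class XYZParseError(ValueError):
    pass


def _parse_comment_properties(comment: str) -> dict:
    props = {}
    for token in comment.split():
        if "=" not in token:
            continue
        key, _, val = token.partition("=")
        if key in _PROPERTY_KEYS:
            try:
                props[key] = float(val)
            except ValueError:
                pass
    return props


def read_xyz_frames(path: str) -> list[tuple[Structure, dict]]:
    """Parse a multi-frame XYZ file into (Structure, properties) tuples."""
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
        except (ValueError, IndexError):
            raise XYZParseError(
                f"{path}:{pos + 1}: expected an atom count, got {lines[pos]!r}"
            )
        if pos + 1 + n >= len(lines) + 1 and n > 0:
            pass
        if pos + 2 + n > len(lines) + 1:
            raise XYZParseError(f"{path}:{pos + 1}: truncated frame of {n} atoms")
        comment = lines[pos + 1].rstrip("\n") if pos + 1 < len(lines) else ""
        numbers, coords = [], []
        for k in range(n):
            ln = pos + 2 + k
            if ln >= len(lines):
                raise XYZParseError(f"{path}:{ln + 1}: truncated frame")
            parts = lines[ln].split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"{path}:{ln + 1}: expected 'symbol x y z', got {lines[ln]!r}"
                )
            sym = parts[0]
            try:
                z = int(sym)
            except ValueError:
                z = number_for(sym)
            try:
                xyz = [float(v) for v in parts[1:4]]
            except ValueError:
                raise XYZParseError(f"{path}:{ln + 1}: malformed coordinate")
            numbers.append(z)
            coords.append(xyz)
        frames.append(
            (Structure(np.array(numbers), np.array(coords)),
             _parse_comment_properties(comment))
        )
        pos += 2 + n
    if not frames:
        raise XYZParseError(f"{path}: no frames found")
    return frames


def read_reaction_xyz(path: str, manifest_entry: Optional[dict] = None) -> Reaction:
    """Read a 2- or 3-frame XYZ reaction file.

    ``manifest_entry`` may declare ``frames`` ("RP" or "RTP") and ``id``; the
    declared frame count must match the file.
    """
    entry = manifest_entry or {}
    frames = read_xyz_frames(path)
    declared = entry.get("frames")
    if declared is not None:
        expected = {"RP": 2, "RTP": 3}.get(declared)
        if expected is None:
            raise ValueError(f"manifest frames must be 'RP' or 'RTP', got {declared!r}")
        if len(frames) != expected:
            raise XYZParseError(
                f"{path}: manifest declares {declared} ({expected} frames) but "
                f"file has {len(frames)}"
            )
    if len(frames) == 2:
        (reactant, p_r), (product, p_p) = frames
        ts = None
        p_t = {}
    elif len(frames) == 3:
        (reactant, p_r), (ts, p_t), (product, p_p) = frames
    else:
        raise XYZParseError(
            f"{path}: a reaction file must have 2 or 3 frames, found {len(frames)}"
        )
    reactant.label = "reactant"
    product.label = "product"
    if ts is not None:
        ts.label = "ts"
    properties = {}
    for role, p in (("reactant", p_r), ("product", p_p), ("ts", p_t)):
        if p:
            properties[role] = p
    return Reaction(
        reactant=reactant,
        product=product,
        ts_ref=ts,
        properties=properties or None,
        reaction_id=str(entry.get("id", os.path.splitext(os.path.basename(path))[0])),
    )


def format_structure_xyz(s: Structure, comment: str = "") -> str:
    lines = [str(s.n_atoms), comment.replace("\n", " ")]
    for z, (x, y, zc) in zip(s.atomic_numbers, s.coordinates):
        lines.append(f"{symbol_for(z):<2s} {x:18.10f} {y:18.10f} {zc:18.10f}")
    return "\n".join(lines) + "\n"


def write_structure_xyz(s: Structure, path: str, comment: str = "") -> None:
    """Write a single structure as standard XYZ (round-trips to <= 1e-6 A)."""
    with open(path, "w") as fh:
        fh.write(format_structure_xyz(s, comment))


def write_reaction_xyz(r: Reaction, path: str) -> None:
    """Write a reaction as multi-frame XYZ (R[,TS],P), with property fields."""

    def comment_for(role: str) -> str:
        parts = [f"{r.reaction_id} {role}"]
        if r.properties and role in r.properties:
            parts += [f"{k}={v:.10g}" for k, v in r.properties[role].items()]
        return " ".join(parts)

    frames = [(r.reactant, "reactant")]
    if r.ts_ref is not None:
        frames.append((r.ts_ref, "ts"))
    frames.append((r.product, "product"))
    with open(path, "w") as fh:
        for s, role in frames:
            fh.write(format_structure_xyz(s, comment_for(role)))


def write_manifest(entries: Iterable[dict], path: str) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(json.dumps(e) + "\n")


def read_manifest(path: str) -> list[dict]:
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                entries.append(json.loads(line))
    return entries


def load_dataset(manifest_path: str) -> list[Reaction]:
    """Load every reaction referenced by a JSON-lines manifest."""
    base = os.path.dirname(os.path.abspath(manifest_path))
    reactions = []
    for entry in read_manifest(manifest_path):
        path = entry["path"]
        if not os.path.isabs(path):
            path = os.path.join(base, path)
        reactions.append(read_reaction_xyz(path, entry))
    return reactions
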