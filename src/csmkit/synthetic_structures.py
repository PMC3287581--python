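"""Idealized protein-like coordinate generators for end-to-end testing.

Real benchmark sets (SCOP domains, EC-labelled chains) need bulk downloads;
these generators produce chains whose contact-distance signatures carry the
same qualitative structure at desk scale.  Four geometry families are
modelled on canonical Cα backbone geometry:

* ``ideal_helix`` — α-helix: rise 1.5 Å/residue, 100° turn, radius 2.3 Å,
  giving a consecutive-Cα distance of ≈3.83 Å and one-turn (i, i+4)
  contacts near 6.2 Å, inside the 5–7 Å window that distinguishes helical
  proteins in contact-density profiles.
* ``extended_strand`` — β-strand-like zig-zag with 3.8 Å virtual bonds and
  (i, i+2) distances of 6.7 Å.
* ``polyproline_like`` — left-handed 3-residue-per-turn helix with 3.1 Å
  rise (collagen/PPII-like, maximally extended).
* ``random_coil`` — a freely-jointed 3.8 Å-step walk with a minimum
  separation of 3.8 Å between non-adjacent residues.

Gaussian coordinate noise (``noise_sd``) blurs the signatures and acts as a
difficulty dial for classification experiments.  All randomness flows from
``numpy.random.SeedSequence`` so identical specs give identical chains on
every platform; fixture files are emitted through the standard PDB writer
so downstream parsing is exercised, not bypassed.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .datasets import LabelTable
from .structure_io import CentroidScheme, ChainCoordinates, write_pdb

KINDS = ("ideal_helix", "extended_strand", "polyproline_like", "random_coil")

# canonical α-helix Cα geometry
_HELIX_RISE = 1.5  # Å per residue
_HELIX_TURN = math.radians(100.0)
_HELIX_RADIUS = 2.3  # Å

_BOND = 3.8  # consecutive-Cα virtual bond length, Å

# strand zig-zag chosen so the (i, i+2) distance is 6.7 Å
_STRAND_DX = 3.35
_STRAND_H = math.sqrt(_BOND**2 - _STRAND_DX**2) / 2.0

# polyproline-II-like: 3 residues/turn, 3.1 Å rise; radius fixed by the bond
_PP2_RISE = 3.1
_PP2_TURN = math.radians(-120.0)
_PP2_RADIUS = math.sqrt(_BOND**2 - _PP2_RISE**2) / (2.0 * math.sin(math.radians(60.0)))


@dataclass(frozen=True)
class GeometryFamily:
    """One synthetic chain recipe: geometry kind, length, noise and seed."""

    kind: str
    length: int
    noise_sd: float = 0.0
    seed: int = 0
    length_jitter: int = 0  # instance lengths vary uniformly in ±jitter

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.length < 2:
            raise ValueError("length must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _helix_points(n: int, rise: float, turn: float, radius: float) -> np.ndarray:
    i = np.arange(n)
    return np.column_stack(
        [radius * np.cos(i * turn), radius * np.sin(i * turn), rise * i]
    )


def _strand_points(n: int) -> np.ndarray:
    i = np.arange(n)
    return np.column_stack(
        [_STRAND_DX * i, _STRAND_H * np.where(i % 2 == 0, 1.0, -1.0), np.zeros(n)]
    )


def _coil_points(n: int, rng: np.random.Generator) -> np.ndarray:
    """Freely-jointed 3.8 Å walk; non-adjacent points kept ≥ 3.8 Å apart."""
    pts = [np.zeros(3)]
    for _ in range(n - 1):
        best, best_min = None, -np.inf
        for _attempt in range(200):
            v = rng.normal(size=3)
            v *= _BOND / np.linalg.norm(v)
            cand = pts[-1] + v
            others = np.array(pts[:-1]) if len(pts) > 1 else None
            dmin = (
                float(np.min(np.linalg.norm(others - cand, axis=1)))
                if others is not None
                else np.inf
            )
            if dmin >= _BOND:
                best = cand
                break
            if dmin > best_min:
                best, best_min = cand, dmin
        pts.append(best)
    return np.array(pts)


def make_chain(
    family: GeometryFamily,
    structure_id: str | None = None,
    chain_id: str = "A",
) -> ChainCoordinates:
    """Generate one chain from a geometry family (deterministic in the seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(family.seed))
    n = family.length
    if family.length_jitter:
        n = max(2, n + int(rng.integers(-family.length_jitter, family.length_jitter + 1)))
    if family.kind == "ideal_helix":
        pts = _helix_points(n, _HELIX_RISE, _HELIX_TURN, _HELIX_RADIUS)
    elif family.kind == "extended_strand":
        pts = _strand_points(n)
    elif family.kind == "polyproline_like":
        pts = _helix_points(n, _PP2_RISE, _PP2_TURN, _PP2_RADIUS)
    else:
        pts = _coil_points(n, rng)
    if family.noise_sd > 0:
        pts = pts + rng.normal(scale=family.noise_sd, size=pts.shape)
    sid = structure_id or f"{family.kind}_{family.seed}"
    rids = [(chain_id, i + 1, "") for i in range(len(pts))]
    return ChainCoordinates(sid, chain_id, CentroidScheme.CA, pts, rids)


def make_labeled_dataset(
    families: Sequence[tuple[GeometryFamily, str, int]],
    seed: int = 0,
) -> tuple[list[ChainCoordinates], LabelTable]:
    """Generate a labelled multi-class chain collection.

    ``families`` lists (template, class label, instance count) triples; at
    least two classes are required.  Each instance gets its own seed derived
    from the master ``seed`` through ``SeedSequence(seed).spawn`` so the
    dataset is reproducible end to end.  Labels land in the free-text
    ``family`` column of the returned LabelTable.
    """
    families = list(families)
    labels = [lab for _, lab, _ in families]
    if len(set(labels)) < 2:
        raise ValueError("need at least two distinct class labels")
    if any(count < 1 for _, _, count in families):
        raise ValueError("instance counts must be >= 1")
    geoms = {}
    for tmpl, lab, _ in families:
        key = (tmpl.kind, tmpl.length, tmpl.noise_sd)
        if key in geoms and geoms[key] != lab and tmpl.noise_sd == 0:
            warnings.warn(
                "identical zero-noise geometry used for two class labels; "
                "the classes are indistinguishable by construction",
                stacklevel=2,
            )
        geoms.setdefault(key, lab)

    total = sum(count for _, _, count in families)
    children = np.random.SeedSequence(seed).spawn(total)
    chains, rows = [], []
    idx = 0
    for tmpl, label, count in families:
        for j in range(count):
            child_seed = int(children[idx].generate_state(1)[0] % (2**31))
            idx += 1
            fam = GeometryFamily(
                tmpl.kind, tmpl.length, tmpl.noise_sd, child_seed, tmpl.length_jitter
            )
            sid = f"{label}_{j:03d}"
            chains.append(make_chain(fam, structure_id=sid))
            rows.append({"structure_id": sid, "family": label})
    table = LabelTable(pd.DataFrame(rows).set_index("structure_id"))
    return chains, table


PRESETS = {
    "two-class": (("helix", "ideal_helix"), ("strand", "extended_strand")),
    "four-class": (
        ("helix", "ideal_helix"),
        ("strand", "extended_strand"),
        ("pp2", "polyproline_like"),
        ("coil", "random_coil"),
    ),
}


def make_preset_dataset(
    preset: str,
    n_per_class: int = 30,
    noise_sd: float = 0.3,
    length: int = 50,
    seed: int = 0,
) -> tuple[list[ChainCoordinates], LabelTable]:
    """Convenience two-class (helix/strand) or four-class geometry dataset."""
    if preset not in PRESETS:
        raise ValueError(f"preset must be one of {sorted(PRESETS)}")
    families = [
        (GeometryFamily(kind, length, noise_sd), label, n_per_class)
        for label, kind in PRESETS[preset]
    ]
    return make_labeled_dataset(families, seed=seed)


def write_dataset(
    chains: Sequence[ChainCoordinates],
    table: LabelTable,
    out_dir: Union[str, os.PathLike],
) -> None:
    """Write chains as PDB fixture files plus a labels.tsv table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for chain in chains:
        write_pdb(chain, out / f"{chain.structure_id}.pdb")
    table.data.to_csv(out / "labels.tsv", sep="\t")
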