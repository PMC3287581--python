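"""Cutoff Scanning Matrix construction.

A protein chain, reduced to residue centroids, defines a contact graph at
every distance cutoff: vertices are residues, edges join pairs whose
centroids lie within the cutoff.  Scanning the cutoff over a grid (default
0.0–30.0 Å in 0.2 Å steps, 151 thresholds) and recording the edge count at
each threshold gives a cumulative contact vector — the chain's distance-
pattern signature.  Stacking one vector per structure yields the Cutoff
Scanning Matrix (CSM) used as the feature matrix for classification.

The threshold comparison is closed (distance ≤ cutoff) with an absolute
tolerance of 1e-9 Å so that exact-boundary distances are counted stably.
Features are raw integer cumulative counts; density and normalized forms
are explicit transforms used for inspection and plotting.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .errors import IdentifierCollisionError
from .structure_io import ChainCoordinates

#: Absolute tolerance (Å) for the closed threshold comparison.
DISTANCE_TOL = 1e-9


@dataclass(frozen=True)
class CutoffGrid:
    """Scanned distance thresholds d_min, d_min+step, ..., d_max (inclusive)."""

    d_min: float = 0.0
    d_max: float = 30.0
    step: float = 0.2

    def __post_init__(self) -> None:
        if self.d_min < 0 or self.step <= 0 or self.d_max <= self.d_min:
            raise ValueError("require d_min >= 0, step > 0, d_max > d_min")

    @property
    def n_thresholds(self) -> int:
        # guard against float drift in (d_max - d_min) / step producing an
        # off-by-one column count (e.g. 150 or 152 instead of 151)
        ratio = (self.d_max - self.d_min) / self.step
        return int(math.floor(ratio * (1.0 + 1e-12) + 1e-9)) + 1

    @property
    def thresholds(self) -> np.ndarray:
        return self.d_min + self.step * np.arange(self.n_thresholds)


@dataclass
class CSMVector:
    """Cumulative contact counts of one structure over a cutoff grid."""

    structure_id: str
    grid: CutoffGrid
    counts: np.ndarray  # non-negative, monotone non-decreasing ints
    n_residues: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != self.grid.n_thresholds:
            raise ValueError("counts length must match grid thresholds")

    @property
    def total_pairs(self) -> int:
        n = self.n_residues
        return n * (n - 1) // 2


@dataclass
class CSMatrix:
    """Structures × cutoffs feature matrix (rows are proteins)."""

    grid: CutoffGrid
    row_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.row_ids), self.grid.n_thresholds):
            raise ValueError("shape must be (len(row_ids), grid thresholds)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def take(self, indices: Sequence[int]) -> "CSMatrix":
        idx = list(indices)
        return CSMatrix(self.grid, [self.row_ids[i] for i in idx], self.values[idx])


def pairwise_distances(chain: ChainCoordinates) -> np.ndarray:
    """Euclidean distances over all unordered residue pairs (n(n-1)/2 values)."""
    if len(chain) < 2:
        return np.empty(0)
    return pdist(chain.points)


def cumulative_contact_vector(chain: ChainCoordinates, grid: CutoffGrid) -> CSMVector:
    """Count residue pairs within each threshold of the grid (closed comparison).

    Entry t is the edge count of the contact graph at cutoff ``thresholds[t]``.
    Implemented by sorting the pairwise distance multiset and binary-searching
    each threshold; equivalent by contract to the naive double-loop count.
    """
    dists = np.sort(pairwise_distances(chain))
    counts = np.searchsorted(dists, grid.thresholds + DISTANCE_TOL, side="right")
    return CSMVector(chain.structure_id, grid, counts, len(chain))


def build_csm_matrix(
    chains: Iterable[ChainCoordinates], grid: CutoffGrid | None = None
) -> CSMatrix:
    """Stack one cumulative contact vector per chain into a CSMatrix."""
    grid = grid or CutoffGrid()
    chains = list(chains)
    if not chains:
        raise ValueError("need at least one chain")
    ids = [c.structure_id for c in chains]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise IdentifierCollisionError(f"duplicate structure ids: {dupes}")
    rows = [cumulative_contact_vector(c, grid).counts for c in chains]
    return CSMatrix(grid, ids, np.vstack(rows))


def to_density(vector: CSMVector, normalize: bool = False) -> np.ndarray:
    """Per-threshold increments of a cumulative vector (first difference).

    With ``normalize`` the increments are divided by the total pair count
    n(n-1)/2, giving the fraction of pairs entering at each threshold.
    """
    dens = np.diff(vector.counts, prepend=0).astype(float)
    if normalize:
        total = vector.total_pairs
        if total > 0:
            dens = dens / total
    return dens


def write_csm_tsv(matrix: CSMatrix, path: Union[str, os.PathLike]) -> None:
    """Write a CSMatrix as TSV: first column structure_id, headers = cutoffs."""
    df = pd.DataFrame(
        matrix.values,
        index=pd.Index(matrix.row_ids, name="structure_id"),
        columns=[f"{t:.1f}" for t in matrix.grid.thresholds],
    )
    df.to_csv(path, sep="\t")


def read_csm_tsv(path: Union[str, os.PathLike], grid: CutoffGrid | None = None) -> CSMatrix:
    """Read a CSMatrix written by :func:`write_csm_tsv`.

    The grid is reconstructed from the header cutoffs unless given explicitly.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if grid is None:
        cuts = np.array([float(c) for c in df.columns])
        step = float(cuts[1] - cuts[0]) if len(cuts) > 1 else 1.0
        grid = CutoffGrid(float(cuts[0]), float(cuts[-1]), round(step, 9))
    return CSMatrix(grid, [str(i) for i in df.index], df.to_numpy())


def save_csm_npz(matrix: CSMatrix, path: Union[str, os.PathLike]) -> None:
    """Binary cache of a CSMatrix (numpy .npz: values, row_ids, grid params)."""
    np.savez_compressed(
        Path(path),
        values=matrix.values,
        row_ids=np.array(matrix.row_ids),
        grid=np.array([matrix.grid.d_min, matrix.grid.d_max, matrix.grid.step]),
    )


def load_csm_npz(path: Union[str, os.PathLike]) -> CSMatrix:
    data = np.load(Path(path), allow_pickle=False)
    g = data["grid"]
    return CSMatrix(
        CutoffGrid(float(g[0]), float(g[1]), float(g[2])),
        [str(r) for r in data["row_ids"]],
        data["values"],
    )
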