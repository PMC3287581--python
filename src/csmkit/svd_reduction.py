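"""SVD-based noise and dimensionality reduction of a CSM.

The feature matrix A (m structures × n cutoffs) is factored A = T·S·Dᵀ with
orthonormal T and D and non-increasing singular values on the diagonal of S.
Truncating to the top k singular values gives the best rank-k approximation
in Frobenius norm (Eckart–Young), with error equal to the root-sum-square of
the discarded singular values.  Structures are then represented by their row
projections Tₖ·Sₖ: for k = p these preserve pairwise row distances exactly
(the right factor is an isometry on row space), so nearest-neighbour results
are unchanged at full rank, while small k discards directions dominated by
noise.

The reduced rank is either fixed by the caller or chosen automatically at
the elbow of the singular-value spectrum: the largest consecutive drop on a
log scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .csm_features import CSMatrix
from .errors import NoElbowError, RankError

#: Singular values below this fraction of the largest are treated as zero.
_ZERO_FRAC = 1e-12


@dataclass
class SVDModel:
    """Thin SVD of a feature matrix, with optional stored column mean."""

    singular_values: np.ndarray  # descending, >= 0, length p
    left_factor: np.ndarray  # m × p, orthonormal columns (T)
    right_factor: np.ndarray  # n × p, orthonormal columns (D)
    row_ids: list[str]
    column_mean: np.ndarray | None = None  # set when decomposition was centered

    @property
    def p(self) -> int:
        return len(self.singular_values)

    def _check_rank(self, k: int) -> None:
        if not 1 <= k <= self.p:
            raise RankError(f"rank k={k} outside [1, {self.p}]")


def decompose(matrix: Union[CSMatrix, np.ndarray], center: bool = False,
              row_ids: Sequence[str] | None = None) -> SVDModel:
    """Thin SVD of a CSMatrix (or plain array), optionally column-centered.

    Centering subtracts the column mean before decomposing (PCA-style) and
    stores it for reconstruction; the default is the plain SVD of the raw
    count matrix.
    """
    if isinstance(matrix, CSMatrix):
        values = matrix.values
        ids = list(matrix.row_ids)
    else:
        values = np.asarray(matrix)
        ids = list(row_ids) if row_ids is not None else [str(i) for i in range(len(values))]
    A = np.asarray(values, dtype=float)
    if A.ndim != 2 or A.shape[0] < 1 or A.shape[1] < 1:
        raise ValueError("matrix must be 2-D and non-empty")
    if not np.all(np.isfinite(A)):
        raise ValueError("matrix entries must be finite")
    mean = None
    if center:
        mean = A.mean(axis=0)
        A = A - mean
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    return SVDModel(s, U, Vt.T, ids, mean)


def select_rank_elbow(
    singular_values: Sequence[float], policy: Union[str, int] = "auto"
) -> int:
    """Pick the reduced rank at the elbow of the singular-value spectrum.

    Auto policy: return the k maximizing log(σ_k / σ_{k+1}), i.e. the largest
    consecutive drop on a log scale, considering only drops that start at a
    non-negligible singular value (σ ≥ 1e-12·σ₁).  An integer policy is
    returned unchanged after range checking.

    Raises :class:`NoElbowError` when the retained spectrum is flat, in which
    case an explicit k must be given.
    """
    s = np.asarray(singular_values, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 singular values")
    if policy != "auto":
        k = int(policy)
        if not 1 <= k <= len(s):
            raise RankError(f"fixed rank {k} outside [1, {len(s)}]")
        return k
    floor = _ZERO_FRAC * max(s[0], 1.0)
    s_clip = np.maximum(s, floor)
    ratios = s_clip[:-1] / s_clip[1:]
    # only drops starting from a non-negligible value are candidate elbows
    valid = s[:-1] >= floor
    if not valid.any() or np.max(ratios[valid]) <= 1.0 + 1e-9:
        raise NoElbowError(
            "singular-value spectrum is flat; pass an explicit rank k"
        )
    ratios = np.where(valid, ratios, 0.0)
    return int(np.argmax(ratios)) + 1


@dataclass
class ReducedMatrix:
    """Rank-k row representation of the structures (rows of Tₖ·Sₖ)."""

    row_ids: list[str]
    k: int
    values: np.ndarray  # m × k

    def take(self, indices: Sequence[int]) -> "ReducedMatrix":
        idx = list(indices)
        return ReducedMatrix([self.row_ids[i] for i in idx], self.k, self.values[idx])


def project(model: SVDModel, k: int) -> ReducedMatrix:
    """Project structures to k dimensions: row i = (left factor row i)·diag(σ₁..σ_k).

    Pairwise Euclidean distances between projected rows equal those between
    rows of the rank-k reconstruction Aₖ.
    """
    model._check_rank(k)
    coords = model.left_factor[:, :k] * model.singular_values[:k]
    return ReducedMatrix(list(model.row_ids), k, coords)


def reconstruct(model: SVDModel, k: int) -> np.ndarray:
    """Rank-k approximation Tₖ·Sₖ·Dₖᵀ (plus the stored mean when centered)."""
    model._check_rank(k)
    A_k = (model.left_factor[:, :k] * model.singular_values[:k]) @ model.right_factor[:, :k].T
    if model.column_mean is not None:
        A_k = A_k + model.column_mean
    return A_k


def write_spectrum_tsv(model: SVDModel, path) -> None:
    """Singular-value spectrum as TSV (index, value)."""
    with open(path, "w") as fh:
        fh.write("index\tsingular_value\n")
        for i, v in enumerate(model.singular_values, start=1):
            fh.write(f"{i}\t{v:.10g}\n")


def write_reduced_tsv(reduced: ReducedMatrix, path) -> None:
    """ReducedMatrix as TSV (structure_id + k component columns)."""
    with open(path, "w") as fh:
        header = "\t".join(["structure_id"] + [f"c{i+1}" for i in range(reduced.k)])
        fh.write(header + "\n")
        for rid, row in zip(reduced.row_ids, reduced.values):
            fh.write(rid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
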