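"""End-to-end convenience: chains → CSM → (optional SVD) → cross-validated KNN.

Mirrors the standard workflow: build the cutoff-scanning feature matrix,
optionally reduce it with SVD at a fixed or elbow-selected rank, attach
labels, filter under-represented classes, and run stratified cross-
validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

from .classification_eval import ClassifierSpec, MetricsReport, cross_validate
from .csm_features import CSMatrix, CutoffGrid, build_csm_matrix
from .datasets import LabeledDataset, LabelTable, filter_min_representatives, select_level
from .structure_io import ChainCoordinates
from .svd_reduction import decompose, project, select_rank_elbow


@dataclass
class PipelineResult:
    """What an end-to-end run produced, for inspection and reporting."""

    csm: CSMatrix
    dataset: LabeledDataset
    report: MetricsReport
    svd_rank: int | None  # None when classification ran on raw counts


def run_pipeline(
    chains: Sequence[ChainCoordinates],
    table: LabelTable,
    level: str = "family",
    grid: CutoffGrid | None = None,
    svd_k: Union[int, str, None] = "auto",
    center: bool = False,
    spec: ClassifierSpec | None = None,
    folds: int = 10,
    min_representatives: int | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run CSM → SVD → classification and return the evaluation report.

    ``svd_k`` may be an integer rank, "auto" for elbow selection, or None to
    classify on the raw cumulative-count features.  ``min_representatives``
    defaults to ``folds`` so stratified cross-validation is always feasible.
    """
    csm = build_csm_matrix(chains, grid)
    dataset = select_level(table, csm, level)
    min_rep = folds if min_representatives is None else min_representatives
    dataset = filter_min_representatives(dataset, min_rep)

    rank: int | None = None
    if svd_k is not None:
        model = decompose(dataset.features, center=center)
        rank = select_rank_elbow(model.singular_values, policy=svd_k)
        dataset = dataset.with_features(project(model, rank))

    spec = spec or ClassifierSpec("knn", {"k_nn": 5}, seed=seed)
    report = cross_validate(dataset, spec, folds=folds, seed=seed)
    return PipelineResult(csm=csm, dataset=dataset, report=report, svd_rank=rank)
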