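"""Stitching per-block LASSO models into one polygenic score.

Each block model yields a per-sample linear score s_b = Σ_j beta_bj·X_bij.
Because blocks are fit independently, their relative normalization is
unknown; a multiple linear regression of the *raw* phenotype on the
block-score columns, fit on the validation set, supplies block weights
alpha_b (and an intercept). The deployable score is
Σ_b alpha_b·s_b + intercept; the unweighted variant (all alpha = 1) is
kept for before/after comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lassocore import BlockModel
from .simgen import GenotypeBlockSet

__all__ = [
    "BlockScoreMatrix",
    "StitchedPGS",
    "block_scores",
    "fit_block_weights",
    "assemble_and_score",
]


@dataclass
class BlockScoreMatrix:
    """samples × blocks matrix of per-block linear scores."""

    scores: np.ndarray
    sample_idx: np.ndarray
    block_ids: list[str]

    @property
    def null_blocks(self) -> np.ndarray:
        """Boolean mask of identically-zero (null-model) columns."""
        return np.all(self.scores == 0, axis=0)


def _resolve_columns(block, model: BlockModel) -> np.ndarray:
    """Map the model's SNV ids onto the genotype block's columns."""
    lookup = {sid: j for j, sid in enumerate(block.snvs["snv_id"])}
    cols = np.empty(len(model.features), int)
    for i, sid in enumerate(model.features["snv_id"]):
        if sid not in lookup:
            raise KeyError(f"SNV {sid!r} of model block {model.block_id!r} "
                           f"not present in genotype block {block.block_id!r}")
        cols[i] = lookup[sid]
    return cols


def block_scores(
    genotypes: GenotypeBlockSet,
    models: list[BlockModel],
    sample_idx: np.ndarray | None = None,
) -> BlockScoreMatrix:
    """Per-sample per-block scores on the original dosage scale.

    Missing dosages (NaN) are imputed with the model's training means
    before weighting. Null models contribute a zero column.
    """
    if sample_idx is None:
        sample_idx = np.arange(genotypes.n_samples)
    sample_idx = np.asarray(sample_idx)
    out = np.zeros((len(sample_idx), len(models)))
    for b, model in enumerate(models):
        if model.is_null or len(model.beta_std) == 0:
            continue
        block = genotypes.get_block(model.block_id)
        cols = _resolve_columns(block, model)
        X = block.dosages[np.ix_(sample_idx, cols)].astype(float)
        if np.isnan(X).any():
            nan_r, nan_c = np.where(np.isnan(X))
            X[nan_r, nan_c] = model.mean[nan_c]
        out[:, b] = X @ model.beta_raw
    return BlockScoreMatrix(
        scores=out, sample_idx=sample_idx, block_ids=[m.block_id for m in models]
    )


def fit_block_weights(
    scores_val: BlockScoreMatrix, pheno_val: np.ndarray
) -> tuple[np.ndarray, float]:
    """OLS of the raw phenotype on block-score columns → (alpha, intercept).

    Zero (null-model) columns are excluded from the regression and get
    alpha = 0. Requires more validation samples than non-null blocks.
    """
    y = np.asarray(pheno_val, float)
    S = scores_val.scores
    if len(y) != len(S):
        raise ValueError("phenotype and score matrix have different sample counts")
    active = ~scores_val.null_blocks
    n_active = int(active.sum())
    if len(y) < n_active + 1:
        raise ValueError(
            f"need more than {n_active} validation samples to fit {n_active} block weights"
        )
    alpha = np.zeros(S.shape[1])
    if n_active == 0:
        return alpha, float(y.mean())
    design = np.column_stack([np.ones(len(y)), S[:, active]])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    alpha[active] = coef[1:]
    return alpha, float(coef[0])


@dataclass
class StitchedPGS:
    """A deployable block-stitched polygenic score."""

    models: list[BlockModel]
    alpha: np.ndarray
    intercept: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.alpha) != len(self.models):
            raise ValueError("one alpha per block model is required")

    @property
    def block_ids(self) -> list[str]:
        return [m.block_id for m in self.models]


def assemble_and_score(
    pgs: StitchedPGS,
    genotypes: GenotypeBlockSet,
    sample_idx: np.ndarray | None = None,
    weighted: bool = True,
) -> np.ndarray:
    """Final per-sample PGS on a sample set.

    ``weighted=False`` gives the unweighted variant (all alpha = 1, no
    intercept), the pre-re-weighting baseline.
    """
    sm = block_scores(genotypes, pgs.models, sample_idx)
    if weighted:
        return sm.scores @ pgs.alpha + pgs.intercept
    return sm.scores.sum(axis=1)
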