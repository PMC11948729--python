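"""Performance metrics, composite uncertainties, CV orchestration.

A reported metric carries a standard deviation combining two effects in
quadrature: the spread over 5-fold cross-validation models
(sigma_cv-SD) and the finite size of the evaluation sample
(sigma_finite). For AUC the finite-size term is the empirical rule
1/(3·sqrt(N_cases)); for a Pearson correlation it is
sqrt((1-rho²)/(N-2)).

``crossval_run`` executes the whole pipeline per fold — single-marker
ranking, per-block (or global) LASSO with validation-set penalty
selection, block re-weighting — and applies each fold's model to one
common withheld test set, reporting the mean and fold SD of the test
metric. The test set never enters any training stage.

Agreement between a block-stitched and a global score is classified as
*full* when their ±1 sigma_total intervals overlap, *approximate* when
the relative signal loss is at most 20% (for AUC, measured above the
0.5 chance baseline), and *none* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .blockstitch import StitchedPGS, assemble_and_score, block_scores, fit_block_weights
from .featselect import rank_and_select, single_marker_scan
from .lassocore import BlockModel, fit_blocks, fit_lasso_path, make_lambda_grid, select_model
from .simgen import GenotypeBlockSet

__all__ = [
    "MetricResult",
    "FoldPlan",
    "CrossvalResult",
    "AgreementResult",
    "auc",
    "metric_uncertainty",
    "make_fold_plan",
    "crossval_run",
    "classify_agreement",
]


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann–Whitney) AUC; tied scores contribute 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    cases = labels == 1
    n1 = int(cases.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[cases].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class MetricResult:
    """A performance metric with its composite uncertainty."""

    metric: str                # "auc" | "correlation"
    value: float
    sigma_finite: float
    sigma_cv: float
    sigma_total: float
    n: int
    n_cases: int | None = None
    fold_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        expect = float(np.hypot(self.sigma_finite, self.sigma_cv))
        if abs(self.sigma_total - expect) > 1e-12:
            raise ValueError("sigma_total must combine the components in quadrature")


def metric_uncertainty(
    metric: str,
    value: float | None = None,
    n: int | None = None,
    n_cases: int | None = None,
    sigma_cv: float = 0.0,
) -> float:
    """Composite standard deviation of a metric (quadrature rule).

    AUC:         sqrt( (1 / (3·sqrt(N_cases)))² + sigma_cv² )
    correlation: sqrt( (1 - rho²)/(N - 2)      + sigma_cv² )
    """
    if metric == "auc":
        if n_cases is None or n_cases < 1:
            raise ValueError("AUC uncertainty requires N_cases >= 1")
        finite = 1.0 / (3.0 * np.sqrt(n_cases))
    elif metric == "correlation":
        if n is None or n <= 2:
            raise ValueError("correlation uncertainty requires N >= 3")
        if value is None:
            raise ValueError("correlation uncertainty requires the correlation value")
        finite = np.sqrt((1.0 - value**2) / (n - 2))
    else:
        raise ValueError("metric must be 'auc' or 'correlation'")
    return float(np.hypot(finite, sigma_cv))


def _metric_result(metric: str, fold_values: np.ndarray, n: int, n_cases: int | None) -> MetricResult:
    value = float(np.mean(fold_values))
    sigma_cv = float(np.std(fold_values, ddof=1)) if len(fold_values) > 1 else 0.0
    total = metric_uncertainty(metric, value=value, n=n, n_cases=n_cases, sigma_cv=sigma_cv)
    finite = float(np.sqrt(max(total**2 - sigma_cv**2, 0.0)))
    return MetricResult(
        metric=metric, value=value, sigma_finite=finite, sigma_cv=sigma_cv,
        sigma_total=total, n=n, n_cases=n_cases, fold_values=fold_values,
    )


@dataclass
class FoldPlan:
    """A fixed withheld test set plus K train/validation folds.

    The folds partition the non-test pool into K validation chunks; each
    fold trains on the pool minus its validation chunk. Test indices are
    disjoint from every fold's train and validation sets.
    """

    test_idx: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int

    def __post_init__(self) -> None:
        # degenerate plans (repeated folds) are allowed; overlap with the
        # withheld test set or within a fold is not
        test = set(self.test_idx.tolist())
        for train, val in self.folds:
            if test & set(train.tolist()) or test & set(val.tolist()):
                raise ValueError("test indices overlap a fold")
            if set(train.tolist()) & set(val.tolist()):
                raise ValueError("train and validation overlap within a fold")


def make_fold_plan(
    n_samples: int,
    n_folds: int = 5,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> FoldPlan:
    """Random test holdout + K-fold split of the remainder."""
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    n_test = int(round(test_fraction * n_samples))
    test_idx = np.sort(perm[:n_test])
    pool = perm[n_test:]
    chunks = np.array_split(pool, n_folds)
    folds = []
    for k in range(n_folds):
        val = np.sort(chunks[k])
        train = np.sort(np.concatenate([chunks[j] for j in range(n_folds) if j != k]))
        folds.append((train, val))
    return FoldPlan(test_idx=test_idx, folds=folds, seed=seed)


@dataclass
class CrossvalResult:
    """Per-fold models and pooled test metrics of a CV run."""

    mode: str                       # "block" | "global"
    fold_models: list
    weighted: MetricResult
    unweighted: MetricResult | None = None


def _rank_block_features(
    genotypes: GenotypeBlockSet,
    target: np.ndarray,
    train_idx: np.ndarray,
    k: int | None,
    maf_min: float,
) -> dict[str, np.ndarray]:
    """Top-k SNVs per block by single-marker p-value (training only)."""
    out: dict[str, np.ndarray] = {}
    for block in genotypes.blocks:
        scan = single_marker_scan(
            block.dosages, target, train_idx, block.snvs["pos_bp"].to_numpy()
        )
        kk = block.n_snvs if k is None else k
        out[block.block_id] = rank_and_select(scan, kk, maf_min).selected
    return out


def _rank_global_features(
    genotypes: GenotypeBlockSet,
    target: np.ndarray,
    train_idx: np.ndarray,
    k_total: int | None,
    maf_min: float,
) -> dict[str, np.ndarray]:
    """Top-k_total SNVs ranked across all blocks jointly."""
    recs = []
    for block in genotypes.blocks:
        scan = single_marker_scan(
            block.dosages, target, train_idx, block.snvs["pos_bp"].to_numpy()
        )
        ranked = rank_and_select(scan, block.n_snvs, maf_min)
        for j in ranked.order:
            recs.append((scan.p[j], scan.pos_bp[j], block.block_id, j))
    recs.sort(key=lambda r: (r[0], r[1]))
    if k_total is not None:
        recs = recs[:k_total]
    out: dict[str, list[int]] = {}
    for _, _, bid, j in recs:
        out.setdefault(bid, []).append(j)
    return {bid: np.sort(np.array(idx, int)) for bid, idx in out.items()}


def _global_fit_and_score(
    genotypes: GenotypeBlockSet,
    selected: dict[str, np.ndarray],
    target: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    test_idx: np.ndarray,
    metric: str,
    n_points: int,
    ratio: float,
) -> tuple[BlockModel, np.ndarray]:
    """One pooled LASSO over all selected features; returns test scores."""
    import pandas as pd

    mats, metas = [], []
    for block in genotypes.blocks:
        sel = selected.get(block.block_id, np.zeros(0, int))
        if len(sel):
            mats.append(block.dosages[:, sel])
            metas.append(block.snvs.iloc[sel][["snv_id", "chrom", "pos_bp", "a1"]])
    X = np.concatenate(mats, axis=1)
    meta = pd.concat(metas, ignore_index=True)
    grid = make_lambda_grid(X[train_idx], target[train_idx], n_points, ratio)
    path = fit_lasso_path(X[train_idx], target[train_idx], grid)
    model = select_model(path, X[val_idx], target[val_idx], metric, "global", meta)
    if model.is_null:
        return model, np.zeros(len(test_idx))
    cols = {sid: c for c, sid in enumerate(meta["snv_id"])}
    take = np.array([cols[s] for s in model.features["snv_id"]], int)
    return model, X[np.ix_(test_idx, take)] @ model.beta_raw


def _evaluate(metric: str, scores: np.ndarray, target: np.ndarray) -> float:
    if metric == "auc":
        return auc(scores, target)
    if np.std(scores) == 0 or np.std(target) == 0:
        return 0.0
    return float(np.corrcoef(scores, target)[0, 1])


def crossval_run(
    genotypes: GenotypeBlockSet,
    phenotype: np.ndarray,
    plan: FoldPlan,
    mode: str = "block",
    k: int | None = None,
    maf_min: float = 0.001,
    metric: str = "correlation",
    residual: np.ndarray | None = None,
    n_points: int = 100,
    ratio: float = 1e-3,
) -> CrossvalResult:
    """Run the full pipeline over every fold of a plan.

    ``residual`` is the training target (y*); when None the raw
    phenotype is used directly (the simulated traits have no
    covariates). Block weights are always regressed against the raw
    phenotype on the validation fold. Each fold's model is evaluated on
    the common withheld test set; the pooled value is the fold mean and
    sigma_cv-SD the fold standard deviation.
    """
    if mode not in ("block", "global"):
        raise ValueError("mode must be 'block' or 'global'")
    phenotype = np.asarray(phenotype, float)
    target = phenotype if residual is None else np.asarray(residual, float)
    test_idx = plan.test_idx
    n_cases = int((phenotype[test_idx] == 1).sum()) if metric == "auc" else None

    fold_models, w_vals, u_vals = [], [], []
    for train_idx, val_idx in plan.folds:
        if len(val_idx) == 0:
            raise ValueError("fold with empty validation set")
        if mode == "block":
            selected = _rank_block_features(genotypes, target, train_idx, k, maf_min)
            models = fit_blocks(genotypes, selected, target, train_idx, val_idx,
                                metric, n_points, ratio)
            sm_val = block_scores(genotypes, models, val_idx)
            alpha, intercept = fit_block_weights(sm_val, phenotype[val_idx])
            pgs = StitchedPGS(models=models, alpha=alpha, intercept=intercept,
                              provenance={"seed": plan.seed})
            fold_models.append(pgs)
            w = assemble_and_score(pgs, genotypes, test_idx, weighted=True)
            u = assemble_and_score(pgs, genotypes, test_idx, weighted=False)
            w_vals.append(_evaluate(metric, w, phenotype[test_idx]))
            u_vals.append(_evaluate(metric, u, phenotype[test_idx]))
        else:
            selected = _rank_global_features(genotypes, target, train_idx, k, maf_min)
            model, scores = _global_fit_and_score(
                genotypes, selected, target, train_idx, val_idx, test_idx,
                metric, n_points, ratio,
            )
            fold_models.append(model)
            w_vals.append(_evaluate(metric, scores, phenotype[test_idx]))

    weighted = _metric_result(metric, np.array(w_vals), len(test_idx), n_cases)
    unweighted = (
        _metric_result(metric, np.array(u_vals), len(test_idx), n_cases)
        if mode == "block" else None
    )
    return CrossvalResult(mode=mode, fold_models=fold_models,
                          weighted=weighted, unweighted=unweighted)


@dataclass
class AgreementResult:
    label: str            # "full" | "approximate" | "none"
    loss_fraction: float


def classify_agreement(global_mr: MetricResult, block_mr: MetricResult) -> AgreementResult:
    """Compare block vs global performance.

    *full*: the ±1 sigma_total intervals overlap. Otherwise the loss
    fraction is (g-b)/g for correlations or (g-b)/(g-0.5) for AUC;
    *approximate* if it is at most 0.2, else *none*.
    """
    if global_mr.metric != block_mr.metric:
        raise ValueError("metric types differ")
    g, b = global_mr.value, block_mr.value
    if global_mr.metric == "auc":
        if g <= 0.5:
            raise ValueError("loss fraction undefined: global AUC <= 0.5")
        loss = (g - b) / (g - 0.5)
    else:
        if g <= 0:
            raise ValueError("loss fraction undefined: global correlation <= 0")
        loss = (g - b) / g
    if abs(g - b) <= global_mr.sigma_total + block_mr.sigma_total:
        return AgreementResult("full", float(loss))
    if loss <= 0.2 + 1e-9:  # the 20% boundary itself still counts
        return AgreementResult("approximate", float(loss))
    return AgreementResult("none", float(loss))
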