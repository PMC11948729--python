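"""Single-marker scan and p-value ranking for per-block feature selection.

A genome-wide association scan here serves one purpose only: to rank
SNVs within a block (or across the autosome for the global baseline) so
the top-k can be fed to the LASSO. The per-SNV statistics are simple
linear regressions of the residual phenotype on dosage, computed only on
training samples; nothing beyond the rank order is retained downstream.

A frequency cut excludes SNVs whose training minor-allele frequency is
at or below ``maf_min`` (default 0.001) before ranking, to avoid
spurious associations from near-monomorphic markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MarkerScanResult",
    "RankedFeatures",
    "single_marker_scan",
    "rank_and_select",
]


@dataclass
class MarkerScanResult:
    """Per-SNV simple-regression statistics on the training samples.

    Arrays are aligned to the block's SNV order. ``zero_variance`` flags
    monomorphic-in-training SNVs: their p-value is set to 1 and they are
    never selected.
    """

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    freq: np.ndarray  # counted-allele frequency in training samples
    pos_bp: np.ndarray
    zero_variance: np.ndarray  # bool
    n_train: int


@dataclass
class RankedFeatures:
    """Ranking outcome for one block."""

    order: np.ndarray     # eligible SNV indices, ascending p (ties: position)
    selected: np.ndarray  # top-k subset of ``order``
    k_requested: int


def single_marker_scan(
    dosages: np.ndarray,
    residual: np.ndarray,
    train_idx: np.ndarray,
    pos_bp: np.ndarray | None = None,
) -> MarkerScanResult:
    """Regress the residual phenotype on each SNV dosage independently.

    Two-sided p-values come from the t distribution with n-2 degrees of
    freedom; equivalently t = r·sqrt((n-2)/(1-r²)) for Pearson r.
    """
    train_idx = np.asarray(train_idx)
    if train_idx.size == 0:
        raise ValueError("training index set is empty")
    if dosages.shape[1] == 0:
        raise ValueError("block has no SNVs")
    X = dosages[train_idx]
    y = np.asarray(residual)[train_idx]
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 training samples for a scan")

    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = xc.T @ yc
    syy = float(yc @ yc)

    zero_var = sxx == 0
    sxx_safe = np.where(zero_var, 1.0, sxx)

    beta = sxy / sxx_safe
    rss = np.maximum(syy - beta * sxy, 0.0)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[~np.isfinite(t)] = 0.0
    beta[zero_var] = 0.0
    se[zero_var] = np.nan
    t[zero_var] = 0.0
    p[zero_var] = 1.0

    freq = X.mean(axis=0) / 2.0
    if pos_bp is None:
        pos_bp = np.arange(dosages.shape[1])
    return MarkerScanResult(
        beta=beta, se=se, t=t, p=p, freq=freq,
        pos_bp=np.asarray(pos_bp), zero_variance=zero_var, n_train=n,
    )


def rank_and_select(
    scan: MarkerScanResult, k: int, maf_min: float = 0.001
) -> RankedFeatures:
    """Rank eligible SNVs by ascending p-value and take the top k.

    Eligibility requires min(f, 1-f) > maf_min on training samples and
    non-zero training variance. Ties in p are broken by ascending
    base-pair position (deterministic across platforms). k=0 is a valid
    request: the block contributes nothing.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    maf = np.minimum(scan.freq, 1.0 - scan.freq)
    eligible = (maf > maf_min) & ~scan.zero_variance
    idx = np.where(eligible)[0]
    order = idx[np.lexsort((scan.pos_bp[idx], scan.p[idx]))]
    return RankedFeatures(order=order, selected=order[:k], k_requested=k)
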