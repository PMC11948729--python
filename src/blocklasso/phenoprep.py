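"""Phenotype preparation: pre-filters, covariate regression, residuals.

The LASSO downstream is trained on a *residual* phenotype y*: the raw
trait with fitted covariate effects (age, sex, genetic principal
components) removed. Continuous traits are first z-scored within each
sex so that both sexes can be pooled; case-control labels are kept on
the 0/1 scale and residualized by ordinary (not logistic) least squares,
matching the single Gaussian-loss objective used for both trait types.

The covariate fit is estimated on training samples only and then applied
unchanged to validation/test samples, so no information leaks across
splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterRule",
    "Residualizer",
    "ResidualPhenotype",
    "apply_filters",
    "residualize",
]

_COMPARATORS = {
    "<": np.less,
    ">": np.greater,
    "<=": np.less_equal,
    ">=": np.greater_equal,
}


@dataclass(frozen=True)
class FilterRule:
    """Keep-rule on a phenotype/covariate field, e.g. BMI < 60 kg/m²."""

    field: str
    comparator: str  # one of < > <= >=
    threshold: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"comparator must be one of {sorted(_COMPARATORS)}")

    def passes(self, values: np.ndarray) -> np.ndarray:
        return _COMPARATORS[self.comparator](values, self.threshold)

    def __str__(self) -> str:
        return f"{self.field} {self.comparator} {self.threshold}"


def apply_filters(
    pheno: pd.DataFrame, rules: list[FilterRule]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop samples violating any rule; report removals per rule.

    Each rule's removal count is the number of samples failing that rule
    individually (a sample can count against several rules). Raises if
    every sample is filtered out or a rule names a missing column.
    """
    keep = np.ones(len(pheno), dtype=bool)
    report: dict[str, int] = {}
    for rule in rules:
        if rule.field not in pheno.columns:
            raise KeyError(f"filter rule references unknown field {rule.field!r}")
        ok = rule.passes(pheno[rule.field].to_numpy())
        report[str(rule)] = int((~ok).sum())
        keep &= ok
    out = pheno.loc[keep].copy()
    if len(out) == 0:
        raise ValueError("all samples removed by filters")
    return out, report


@dataclass
class ResidualPhenotype:
    """Covariate-adjusted phenotype y* plus the model that produced it."""

    sample_id: np.ndarray
    residual: np.ndarray
    mode: str  # "continuous" | "case_control"
    coefficients: dict[str, float]
    residualizer: "Residualizer"

    def __len__(self) -> int:
        return len(self.residual)


class Residualizer:
    """Fitted covariate transform, reusable on held-out samples.

    Continuous mode: z-score the trait within each sex (training means
    and SDs), then OLS on age + PCs; case_control mode: OLS of the 0/1
    label on age + sex + PCs. ``transform`` never refits.
    """

    def __init__(self, mode: str, pc_cols: list[str]):
        if mode not in ("continuous", "case_control"):
            raise ValueError("mode must be 'continuous' or 'case_control'")
        self.mode = mode
        self.pc_cols = pc_cols
        self.sex_stats: dict[int, tuple[float, float]] = {}
        self.coef: np.ndarray | None = None
        self.design_cols: list[str] = []

    # -- internal helpers -------------------------------------------------
    def _design(self, cov: pd.DataFrame) -> np.ndarray:
        cols = [cov[c].to_numpy(float) for c in self.design_cols]
        return np.column_stack([np.ones(len(cov))] + cols)

    def _zscore(self, values: np.ndarray, sex: np.ndarray) -> np.ndarray:
        z = np.empty_like(values, dtype=float)
        for s, (mu, sd) in self.sex_stats.items():
            mask = sex == s
            z[mask] = (values[mask] - mu) / sd
        return z

    def fit(self, pheno: pd.DataFrame, cov: pd.DataFrame) -> "Residualizer":
        values = pheno["value"].to_numpy(float)
        if self.mode == "continuous":
            sex = cov["sex"].to_numpy(int)
            for s in np.unique(sex):
                vals = values[sex == s]
                sd = float(vals.std())
                if sd == 0:
                    raise ValueError(f"phenotype constant within sex={s}; cannot z-score")
                self.sex_stats[int(s)] = (float(vals.mean()), sd)
            target = self._zscore(values, sex)
            self.design_cols = ["age"] + list(self.pc_cols)
        else:
            bad = set(np.unique(values)) - {0.0, 1.0}
            if bad:
                raise ValueError(f"case_control labels must be 0/1, found {sorted(bad)}")
            target = values
            self.design_cols = ["age", "sex"] + list(self.pc_cols)

        X = self._design(cov)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name offending columns via near-zero R diagonal of a QR factorization
            diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
            names = ["intercept"] + self.design_cols
            bad_cols = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
            raise np.linalg.LinAlgError(
                f"rank-deficient covariate matrix; collinear columns: {bad_cols}"
            )
        self.coef, *_ = np.linalg.lstsq(X, target, rcond=None)
        return self

    def transform(self, pheno: pd.DataFrame, cov: pd.DataFrame) -> ResidualPhenotype:
        if self.coef is None:
            raise RuntimeError("Residualizer not fitted")
        values = pheno["value"].to_numpy(float)
        if self.mode == "continuous":
            target = self._zscore(values, cov["sex"].to_numpy(int))
        else:
            target = values
        residual = target - self._design(cov) @ self.coef
        names = ["intercept"] + self.design_cols
        return ResidualPhenotype(
            sample_id=pheno["sample_id"].to_numpy(),
            residual=residual,
            mode=self.mode,
            coefficients=dict(zip(names, self.coef)),
            residualizer=self,
        )

    def fit_transform(self, pheno: pd.DataFrame, cov: pd.DataFrame) -> ResidualPhenotype:
        return self.fit(pheno, cov).transform(pheno, cov)


def residualize(
    pheno: pd.DataFrame,
    cov: pd.DataFrame,
    mode: str = "continuous",
    pc_cols: list[str] | None = None,
) -> ResidualPhenotype:
    """Fit the covariate model on (pheno, cov) and return residuals y*.

    Tables must be row-aligned by sample_id. ``pc_cols`` defaults to all
    columns named ``PC*`` in the covariate table.
    """
    if not np.array_equal(pheno["sample_id"].to_numpy(), cov["sample_id"].to_numpy()):
        raise ValueError("phenotype and covariate tables are not aligned by sample_id")
    if pheno["value"].isna().any():
        raise ValueError("phenotype contains missing values; filter first")
    if cov.drop(columns=["sample_id"]).isna().any().any():
        raise ValueError("covariates contain missing values; drop those samples first")
    if pc_cols is None:
        pc_cols = [c for c in cov.columns if c.upper().startswith("PC")]
    return Residualizer(mode, pc_cols).fit_transform(pheno, cov)
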