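"""File formats, run configuration, and the end-to-end pipeline.

Genotypes are read either from PLINK 1 binary filesets (.bed/.bim/.fam,
SNP-major; dosage = count of the .bim A1 allele) or from a
human-readable fixture TSV whose header is ``sample_id`` followed by one
column per SNV named ``chrom:pos:ref:alt``. Blocks are partitioned by
chromosome by default.

Model artifacts serialize to TSV: one table of per-SNV weights (on the
standardized scale together with training mean/SD, so either scale can
be reconstructed exactly) and one table of block weights alpha plus the
re-weighting intercept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .lassocore import BlockModel
from .blockstitch import StitchedPGS
from .simgen import GenotypeBlock, GenotypeBlockSet

__all__ = [
    "RunConfig",
    "read_genotypes",
    "write_fixture_tsv",
    "read_fixture_tsv",
    "write_plink",
    "read_plink",
    "save_pgs",
    "load_pgs",
    "run_pipeline",
]

BLOCK_SIZE_SWEEP = [10, 23, 50, 100, 227, 500, 1000, 2273, 5000, 10000, 22727]


# --------------------------------------------------------------------------
# fixture TSV
# --------------------------------------------------------------------------

def write_fixture_tsv(genotypes: GenotypeBlockSet, path: str | Path) -> None:
    """One TSV: sample_id column + one integer dosage column per SNV."""
    cols = {"sample_id": genotypes.sample_ids}
    for block in genotypes.blocks:
        for j, sid in enumerate(block.snvs["snv_id"]):
            cols[sid] = block.dosages[:, j].astype(int)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_fixture_tsv(path: str | Path) -> GenotypeBlockSet:
    """Read the fixture TSV, partitioning columns into per-chromosome blocks."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("fixture TSV must have a sample_id column")
    sample_ids = df["sample_id"].astype(str).tolist()
    snv_cols = [c for c in df.columns if c != "sample_id"]
    parsed = []
    for c in snv_cols:
        parts = c.split(":")
        if len(parts) != 4:
            raise ValueError(f"SNV column {c!r} is not chrom:pos:ref:alt")
        parsed.append((int(parts[0]), int(parts[1]), parts[2], parts[3], c))
    blocks = []
    for chrom in sorted({p[0] for p in parsed}):
        rows = sorted((p for p in parsed if p[0] == chrom), key=lambda p: p[1])
        dos = df[[p[4] for p in rows]].to_numpy(float)
        snvs = pd.DataFrame({
            "snv_id": [p[4] for p in rows],
            "chrom": chrom,
            "pos_bp": [p[1] for p in rows],
            "a1": [p[3] for p in rows],
            "a2": [p[2] for p in rows],
            "freq": np.nanmean(dos, axis=0) / 2.0,
        })
        blocks.append(GenotypeBlock(block_id=f"chr{chrom}", dosages=dos, snvs=snvs))
    return GenotypeBlockSet(blocks=blocks, sample_ids=sample_ids)


# --------------------------------------------------------------------------
# PLINK 1 binary
# --------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # magic + SNP-major flag
# 2-bit codes, per the PLINK 1 .bed spec, as (code -> A1-allele count):
# 00 -> 2 (hom A1), 01 -> missing, 10 -> 1 (het), 11 -> 0 (hom A2)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11}


def write_plink(genotypes: GenotypeBlockSet, prefix: str | Path) -> None:
    """Write .bed (SNP-major) / .bim (1-based positions) / .fam."""
    prefix = Path(prefix)
    n = genotypes.n_samples

    fam = pd.DataFrame({
        "fid": genotypes.sample_ids, "iid": genotypes.sample_ids,
        "father": 0, "mother": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", index=False, header=False)

    bim_rows, snp_columns = [], []
    for block in genotypes.blocks:
        for j in range(block.n_snvs):
            s = block.snvs.iloc[j]
            bim_rows.append((s["chrom"], s["snv_id"], 0, s["pos_bp"], s["a1"], s["a2"]))
            snp_columns.append(block.dosages[:, j])
    pd.DataFrame(bim_rows).to_csv(prefix.with_suffix(".bim"), sep="\t",
                                  index=False, header=False)

    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        for col in snp_columns:
            packed = np.zeros(n_bytes, dtype=np.uint8)
            for i, d in enumerate(col):
                code = 0b01 if np.isnan(d) else _DOSAGE_TO_CODE[int(d)]
                packed[i // 4] |= code << (2 * (i % 4))
            fh.write(packed.tobytes())


def read_plink(prefix: str | Path) -> GenotypeBlockSet:
    """Read a PLINK 1 fileset; dosage counts the .bim A1 allele."""
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snv_id", "cm", "pos_bp", "a1", "a2"])
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(".bed magic bytes wrong (expected SNP-major PLINK 1)")
    n_bytes = (n + 3) // 4
    if len(raw) != 3 + n_bytes * m:
        raise ValueError(f".bed size inconsistent with .bim ({m} SNVs) and .fam ({n} samples)")
    body = np.frombuffer(raw[3:], dtype=np.uint8).reshape(m, n_bytes)
    # unpack 2-bit codes: 4 genotypes per byte, lowest bits first
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    dosages = _CODE_TO_DOSAGE[codes.reshape(m, -1)[:, :n]].T  # (n_samples, m)

    blocks = []
    for chrom in sorted(bim["chrom"].unique()):
        idx = np.where((bim["chrom"] == chrom).to_numpy())[0]
        order = idx[np.argsort(bim["pos_bp"].to_numpy()[idx], kind="stable")]
        dos = dosages[:, order]
        snvs = bim.iloc[order][["snv_id", "chrom", "pos_bp", "a1", "a2"]].reset_index(drop=True)
        snvs["freq"] = np.nanmean(dos, axis=0) / 2.0
        blocks.append(GenotypeBlock(block_id=f"chr{chrom}", dosages=dos, snvs=snvs))
    return GenotypeBlockSet(blocks=blocks, sample_ids=fam[1].astype(str).tolist())


# --------------------------------------------------------------------------
# model serialization
# --------------------------------------------------------------------------

_INTERCEPT_ROW = "_intercept_"


def save_pgs(pgs: StitchedPGS, model_path: str | Path, weights_path: str | Path) -> None:
    """Serialize a stitched PGS to two TSVs (SNV weights, block weights)."""
    rows = []
    for m in pgs.models:
        for i in range(len(m.beta_std)):
            rows.append({
                "block_id": m.block_id,
                "snv_id": m.features["snv_id"].iloc[i],
                "chrom": m.features["chrom"].iloc[i],
                "pos_bp": int(m.features["pos_bp"].iloc[i]),
                "effect_allele": m.features["a1"].iloc[i],
                "beta_std_scale": m.beta_std[i],
                "feature_mean": m.mean[i],
                "feature_sd": m.sd[i],
                "selected_lambda": m.lambda_sel,
            })
    cols = ["block_id", "snv_id", "chrom", "pos_bp", "effect_allele",
            "beta_std_scale", "feature_mean", "feature_sd", "selected_lambda"]
    pd.DataFrame(rows, columns=cols).to_csv(model_path, sep="\t", index=False)

    wrows = [
        {"block_id": m.block_id, "alpha": a, "model_intercept": m.intercept}
        for m, a in zip(pgs.models, pgs.alpha)
    ]
    wrows.append({"block_id": _INTERCEPT_ROW, "alpha": pgs.intercept, "model_intercept": 0.0})
    pd.DataFrame(wrows).to_csv(weights_path, sep="\t", index=False)


def load_pgs(model_path: str | Path, weights_path: str | Path) -> StitchedPGS:
    mt = pd.read_csv(model_path, sep="\t")
    wt = pd.read_csv(weights_path, sep="\t")
    intercept = float(wt.loc[wt["block_id"] == _INTERCEPT_ROW, "alpha"].iloc[0])
    wt = wt[wt["block_id"] != _INTERCEPT_ROW]

    models, alpha = [], []
    for _, wrow in wt.iterrows():
        bid = wrow["block_id"]
        sub = mt[mt["block_id"] == bid]
        if len(sub) == 0:
            models.append(BlockModel.null(bid))
        else:
            models.append(BlockModel(
                block_id=bid,
                lambda_sel=float(sub["selected_lambda"].iloc[0]),
                beta_std=sub["beta_std_scale"].to_numpy(float),
                features=pd.DataFrame({
                    "snv_id": sub["snv_id"].to_numpy(),
                    "chrom": sub["chrom"].to_numpy(),
                    "pos_bp": sub["pos_bp"].to_numpy(),
                    "a1": sub["effect_allele"].to_numpy(),
                }),
                mean=sub["feature_mean"].to_numpy(float),
                sd=sub["feature_sd"].to_numpy(float),
                intercept=float(wrow["model_intercept"]),
            ))
        alpha.append(float(wrow["alpha"]))
    return StitchedPGS(models=models, alpha=np.array(alpha), intercept=intercept)


# --------------------------------------------------------------------------
# run configuration + pipeline
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Structured configuration of one end-to-end run."""

    genotypes: str | None = None          # path; None -> simulate
    genotype_format: str = "fixture-tsv"  # "fixture-tsv" | "plink1"
    phenotype: str | None = None          # TSV with sample_id, value
    covariates: str | None = None         # TSV with sample_id, age, sex, PC*
    out_dir: str = "blocklasso_out"
    mode: str = "continuous"              # phenotype mode
    metric: str = "correlation"
    k: int | None = None                  # SNVs per block (None -> all)
    sweep: list[int] | None = None        # block-size sweep grid
    maf_min: float = 0.001
    n_points: int = 100
    lambda_ratio: float = 1e-3
    n_folds: int = 5
    test_fraction: float = 0.2
    pc_count: int = 0
    seed: int = 0
    filters: list[dict] = field(default_factory=list)
    sim: dict = field(default_factory=dict)  # SimConfig overrides when simulating

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return RunConfig(**data)

    def sweep_grid(self) -> list[int]:
        return self.sweep if self.sweep is not None else list(BLOCK_SIZE_SWEEP)


def read_genotypes(path: str | Path, fmt: str = "fixture-tsv") -> GenotypeBlockSet:
    if fmt == "fixture-tsv":
        return read_fixture_tsv(path)
    if fmt == "plink1":
        return read_plink(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _metric_row(name: str, mr) -> dict:
    return {
        "model": name, "metric": mr.metric, "value": mr.value,
        "sigma_finite": mr.sigma_finite, "sigma_cv": mr.sigma_cv,
        "sigma_total": mr.sigma_total, "n": mr.n,
        "fold_values": ";".join(f"{v:.6f}" for v in mr.fold_values),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the six pipeline stages and write all artifacts.

    Stages: (1) split into train/validation folds plus a withheld test
    set; (2) residualize the phenotype on covariates (when provided);
    (3) rank SNVs per block by single-marker p-value; (4) per-block
    LASSO with validation-set penalty selection; (5) block re-weighting
    on the validation fold; (6) evaluation of every fold's model on the
    withheld test set. Writes a metrics report, serialized models, and
    the variance profile of the first fold's model.
    """
    from .evalstats import crossval_run, make_fold_plan
    from .phenoprep import FilterRule, apply_filters, residualize
    from .simgen import SimConfig, simulate_genotype_blocks, simulate_phenotype
    from .varprofile import bin_profile, pgs_covariance, per_chromosome_totals, variance_attribution

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.genotypes is None:
        sim_cfg = SimConfig(**{"seed": config.seed, **config.sim})
        genotypes = simulate_genotype_blocks(sim_cfg)
        phenotype, truth = simulate_phenotype(
            genotypes, sim_cfg.n_causal, sim_cfg.error_scale, seed=sim_cfg.seed + 1
        )
        pheno = pd.DataFrame({"sample_id": genotypes.sample_ids, "value": phenotype})
        residual_vec = None
    else:
        genotypes = read_genotypes(config.genotypes, config.genotype_format)
        pheno = pd.read_csv(config.phenotype, sep="\t")
        if config.filters:
            rules = [FilterRule(**r) for r in config.filters]
            pheno, report = apply_filters(pheno, rules)
            with open(out / "filter_report.json", "w") as fh:
                json.dump(report, fh, indent=2)
        keep = pheno["sample_id"].astype(str).tolist()
        sample_pos = {s: i for i, s in enumerate(genotypes.sample_ids)}
        order = [sample_pos[s] for s in keep]
        for b in genotypes.blocks:
            b.dosages = b.dosages[order]
        genotypes.sample_ids = keep
        if config.covariates is not None:
            cov = pd.read_csv(config.covariates, sep="\t")
            cov = cov.set_index("sample_id").loc[keep].reset_index()
            res = residualize(pheno, cov, mode=config.mode)
            residual_vec = res.residual
        else:
            residual_vec = None
        phenotype = pheno["value"].to_numpy(float)

    plan = make_fold_plan(
        genotypes.n_samples, config.n_folds, config.test_fraction, config.seed
    )
    result = crossval_run(
        genotypes, phenotype, plan, mode="block", k=config.k,
        maf_min=config.maf_min, metric=config.metric, residual=residual_vec,
        n_points=config.n_points, ratio=config.lambda_ratio,
    )

    rows = [_metric_row("block_weighted", result.weighted),
            _metric_row("block_unweighted", result.unweighted)]
    pd.DataFrame(rows).to_csv(out / "metrics.tsv", sep="\t", index=False)
    with open(out / "metrics.json", "w") as fh:
        json.dump(rows, fh, indent=2)

    for f, pgs in enumerate(result.fold_models):
        save_pgs(pgs, out / f"fold{f}_model.tsv", out / f"fold{f}_block_weights.tsv")

    pgs0 = result.fold_models[0]
    if not all(m.is_null for m in pgs0.models):
        K = pgs_covariance(genotypes, pgs0, plan.test_idx)
        prof = variance_attribution(K)
        bin_profile(prof).table.to_csv(out / "variance_profile.tsv", sep="\t", index=False)
        per_chromosome_totals(prof).to_csv(out / "variance_per_block.tsv", sep="\t", index=False)

    return {"metrics": rows, "out_dir": str(out), "n_folds": len(result.fold_models)}
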