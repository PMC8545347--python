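"""Phenotype/genotype readers, sample alignment, and the results writer.

Two genotype formats are supported:

* ``dosage_tsv`` — a variants-as-rows text matrix with columns
  ``SNPID CHR POS A1 A2`` followed by one dosage column per sample
  (A1 = non-effect allele, A2 = effect allele, ``NA`` = missing);
* ``vcf_dosage`` — standard VCF (plain or bgzip) using the per-sample
  ``DS`` dosage field, falling back to GT allele counts when DS is absent.
  Multi-allelic records are skipped with a warning.

Dosages always count the effect allele (ALT for VCF); no minor-allele
flipping is performed.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .glm import PhenotypeTable
from .scan import ScanConfig, VariantRecord, VariantResult, VariantStatus

logger = logging.getLogger("gescan")

__all__ = [
    "read_phenotype_table",
    "open_genotypes",
    "DosageTextSource",
    "VcfDosageSource",
    "align_samples",
    "write_dosage_tsv",
    "ResultWriter",
    "read_results",
]

DOSAGE_META_COLS = ["SNPID", "CHR", "POS", "A1", "A2"]


def read_phenotype_table(
    path: str | Path,
    id_col: str,
    outcome_col: str,
    covariate_cols: Sequence[str],
    exposure_cols: Sequence[str] = (),
    int_covariate_cols: Sequence[str] = (),
    family: str = "gaussian",
) -> PhenotypeTable:
    """Read a delimited phenotype/covariate file into a PhenotypeTable.

    Rows missing any required field are dropped (count logged). An
    intercept column is prepended. For ``family='binomial'`` the outcome
    must take exactly two values; codings other than {0,1} (e.g. {1,2})
    are remapped to 0/1 with the mapping logged.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    needed = [id_col, outcome_col, *covariate_cols]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ValueError(f"column(s) absent from {path}: {missing_cols}")
    for c in exposure_cols:
        if c not in covariate_cols:
            raise ValueError(f"exposure {c!r} is not among the covariates")
    for c in int_covariate_cols:
        if c not in covariate_cols:
            raise ValueError(f"interaction covariate {c!r} is not among the covariates")

    sub = df[needed].copy()
    n_before = len(sub)
    sub = sub.dropna()
    n_dropped = n_before - len(sub)
    if n_dropped:
        logger.info("dropped %d/%d rows with missing fields", n_dropped, n_before)
    if len(sub) == 0:
        raise ValueError("no complete rows in phenotype file")

    y = sub[outcome_col].to_numpy(dtype=float)
    if np.unique(y).size < 2:
        raise ValueError(f"outcome {outcome_col!r} is constant")
    if family.startswith("binom"):
        vals = np.unique(y)
        if vals.size != 2:
            raise ValueError(
                f"binary outcome must take exactly two values; saw {vals}"
            )
        if not np.array_equal(vals, [0.0, 1.0]):
            mapping = {vals[0]: 0.0, vals[1]: 1.0}
            logger.info("recoding outcome %s -> %s", vals.tolist(), [0, 1])
            y = np.where(y == vals[0], 0.0, 1.0)

    X = np.column_stack(
        [np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in covariate_cols]
    )
    return PhenotypeTable(
        sample_ids=sub[id_col].astype(str).to_numpy(),
        y=y,
        X=X,
        covariate_names=["intercept", *covariate_cols],
        exposure_names=list(exposure_cols),
        int_covariate_names=list(int_covariate_cols),
    )


class DosageTextSource:
    """Streaming reader of the dosage_tsv matrix format."""

    format = "dosage_tsv"

    def __init__(self, path: str | Path):
        self.path = Path(path)
        with open(self.path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        if header[: len(DOSAGE_META_COLS)] != DOSAGE_META_COLS:
            raise ValueError(
                f"{self.path}: expected header starting {DOSAGE_META_COLS}, "
                f"saw {header[:5]}"
            )
        self.sample_ids = np.array(header[len(DOSAGE_META_COLS):])
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"{self.path}: duplicate sample IDs in header")

    def __iter__(self) -> Iterator[VariantRecord]:
        n = len(self.sample_ids)
        with open(self.path) as fh:
            fh.readline()
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != len(DOSAGE_META_COLS) + n:
                    raise ValueError(
                        f"{self.path}:{lineno}: expected "
                        f"{len(DOSAGE_META_COLS) + n} fields, saw {len(fields)}"
                    )
                try:
                    pos = int(fields[2])
                    dos = np.array(
                        [np.nan if f == "NA" else float(f) for f in fields[5:]]
                    )
                except ValueError as exc:
                    raise ValueError(f"{self.path}:{lineno}: {exc}") from None
                yield VariantRecord(
                    variant_id=fields[0],
                    chrom=fields[1],
                    pos=pos,
                    non_effect_allele=fields[3],
                    effect_allele=fields[4],
                    dosages=dos,
                )


class VcfDosageSource:
    """VCF reader yielding effect-allele (ALT) dosages from DS, or GT counts."""

    format = "vcf_dosage"

    def __init__(self, path: str | Path):
        import pysam

        self.path = Path(path)
        with pysam.VariantFile(str(self.path)) as vf:
            self.sample_ids = np.array(list(vf.header.samples))
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"{self.path}: duplicate sample IDs")

    def __iter__(self) -> Iterator[VariantRecord]:
        import pysam

        with pysam.VariantFile(str(self.path)) as vf:
            for rec in vf:
                if rec.alts is None or len(rec.alts) != 1:
                    warnings.warn(
                        f"skipping non-biallelic record {rec.id or rec.pos} "
                        f"at {rec.chrom}:{rec.pos}",
                        stacklevel=2,
                    )
                    continue
                dos = np.full(len(self.sample_ids), np.nan)
                any_field = False
                for j, s in enumerate(self.sample_ids):
                    sample = rec.samples[s]
                    ds = sample.get("DS")
                    if ds is not None:
                        dos[j] = float(ds if not isinstance(ds, tuple) else ds[0])
                        any_field = True
                        continue
                    gt = sample.get("GT")
                    if gt is not None and not all(a is None for a in gt):
                        dos[j] = float(sum(a for a in gt if a is not None))
                        any_field = True
                if not any_field:
                    warnings.warn(
                        f"skipping record {rec.id or rec.pos}: no DS or GT fields",
                        stacklevel=2,
                    )
                    continue
                yield VariantRecord(
                    variant_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    chrom=str(rec.chrom),
                    pos=int(rec.pos),
                    non_effect_allele=rec.ref,
                    effect_allele=rec.alts[0],
                    dosages=dos,
                )


def open_genotypes(path: str | Path, format: str) -> DosageTextSource | VcfDosageSource:
    """Open a genotype source; format is 'dosage_tsv' or 'vcf'/'vcf_dosage'."""
    if format == "dosage_tsv":
        return DosageTextSource(path)
    if format in ("vcf", "vcf_dosage"):
        return VcfDosageSource(path)
    raise ValueError(f"unknown genotype format {format!r}")


def align_samples(
    source, pheno: PhenotypeTable
) -> tuple[np.ndarray, np.ndarray]:
    """Intersect genotype and phenotype samples, in phenotype order.

    Returns ``(pheno_rows, geno_cols)``: integer indices such that
    ``pheno.X[pheno_rows]`` and ``record.dosages[geno_cols]`` are aligned.
    """
    geno_ids = np.asarray(source.sample_ids).astype(str)
    pos = {s: j for j, s in enumerate(geno_ids)}
    pheno_rows, geno_cols = [], []
    for i, s in enumerate(np.asarray(pheno.sample_ids).astype(str)):
        j = pos.get(s)
        if j is not None:
            pheno_rows.append(i)
            geno_cols.append(j)
    if not pheno_rows:
        raise ValueError(
            "no overlapping samples between genotypes and phenotypes; first "
            f"genotype IDs: {geno_ids[:3].tolist()}, first phenotype IDs: "
            f"{np.asarray(pheno.sample_ids)[:3].tolist()}"
        )
    return np.array(pheno_rows, dtype=int), np.array(geno_cols, dtype=int)


def subset_phenotypes(pheno: PhenotypeTable, rows: np.ndarray) -> PhenotypeTable:
    """Restrict a phenotype table to the given row indices."""
    return PhenotypeTable(
        sample_ids=pheno.sample_ids[rows],
        y=pheno.y[rows],
        X=pheno.X[rows],
        covariate_names=list(pheno.covariate_names),
        exposure_names=list(pheno.exposure_names),
        int_covariate_names=list(pheno.int_covariate_names),
    )


def write_dosage_tsv(
    path: str | Path, variants: Sequence[VariantRecord], sample_ids: Sequence[str]
) -> None:
    """Write variants to the dosage_tsv format (NA marks missing)."""
    sample_ids = [str(s) for s in sample_ids]
    with open(path, "w") as fh:
        fh.write("\t".join(DOSAGE_META_COLS + sample_ids) + "\n")
        for v in variants:
            if len(v.dosages) != len(sample_ids):
                raise ValueError(f"{v.variant_id}: dosage length != sample count")
            vals = [
                "NA" if np.isnan(d) else format(float(d), "g") for d in v.dosages
            ]
            fh.write(
                "\t".join(
                    [v.variant_id, v.chrom, str(v.pos), v.non_effect_allele,
                     v.effect_allele] + vals
                )
                + "\n"
            )


class ResultWriter:
    """Tab-separated results writer with a fixed, config-derived header.

    Betas and SEs are printed with 6 significant digits, p-values in
    scientific notation with 6 significant digits; missing statistics are
    ``NA``. Robust runs add ``robust_``-prefixed SE columns.
    """

    def __init__(self, path: str | Path, cfg: ScanConfig):
        self.path = Path(path)
        self.cfg = cfg
        self._fh = open(self.path, "w")
        cols = [
            "SNPID", "CHR", "POS", "Non_Effect_Allele", "Effect_Allele",
            "N_Samples", "AF", "Beta_Marginal", "SE_Beta_Marginal",
            "Beta_G", "SE_Beta_G",
        ]
        for name in cfg.int_covariate_names:
            cols += [f"Beta_G-{name}", f"SE_Beta_G-{name}"]
        for name in cfg.exposure_names:
            cols += [f"Beta_G-{name}", f"SE_Beta_G-{name}"]
        if cfg.robust:
            cols.append("robust_SE_Beta_Marginal")
            cols.append("robust_SE_Beta_G")
            for name in cfg.int_covariate_names:
                cols.append(f"robust_SE_Beta_G-{name}")
            for name in cfg.exposure_names:
                cols.append(f"robust_SE_Beta_G-{name}")
        cols += ["P_Value_Marginal", "P_Value_Interaction", "P_Value_Joint", "STATUS"]
        self.columns = cols
        self._fh.write("\t".join(cols) + "\n")

    def write(self, res: VariantResult) -> None:
        cfg = self.cfg

        def num(x: float) -> str:
            return "NA" if x is None or not np.isfinite(x) else format(x, ".6g")

        def pval(p: float) -> str:
            return "NA" if not np.isfinite(p) else format(p, ".6e")

        row = [
            res.variant_id, res.chrom, str(res.pos),
            res.non_effect_allele, res.effect_allele,
            str(res.n_samples), num(res.af),
        ]
        if res.tested:
            se_model = np.sqrt(np.diag(res.cov_model))
            se_rob = np.sqrt(np.diag(res.cov_robust))
            betas = np.concatenate([[res.beta_g], res.beta_c, res.beta_s])
            row += [num(res.beta_marginal), num(res.se_marginal)]
            for b, s in zip(betas, se_model):
                row += [num(b), num(s)]
            if cfg.robust:
                row.append(num(res.robust_se_marginal))
                for s in se_rob:
                    row.append(num(s))
            row += [pval(res.p_marginal), pval(res.p_interaction),
                    pval(res.p_joint), res.status.value]
        else:
            n_blank = len(self.columns) - len(row) - 1
            row += ["NA"] * n_blank + [res.status.value]
        self._fh.write("\t".join(row) + "\n")

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "ResultWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def read_results(path: str | Path) -> pd.DataFrame:
    """Parse a results TSV back into a DataFrame (NA -> NaN)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
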