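"""Readers, writers and the summary-exchange wire format.

Site tables are delimited text (TSV or CSV) with a header: a sample
identifier, one additive genotype column (0/1/2), ``q`` binary phenotype
columns and optional categorical covariate columns.  Covariates may be
shared across phenotypes or phenotype-specific (e.g. a different
age-at-onset column per disease); they are cross-classified into opaque
stratum labels here so the test itself stays covariate-agnostic.

Round-1 and round-2 messages travel as JSON documents.  Python's ``json``
emits shortest-round-trip float literals, so serialization is lossless at
IEEE double precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import P_FLOOR, pooled_test
from .errors import SchemaError, ValidationError
from .types import (
    PooledCell,
    PooledReference,
    SiteDataset,
    Stage1Summary,
    Stage2Summary,
    StratumCell,
)

SCHEMA_VERSION = 1

__all__ = [
    "AnalysisConfig",
    "read_site_table",
    "write_site_table",
    "impute_phenotypes",
    "stage1_to_json",
    "stage1_from_json",
    "pooled_to_json",
    "pooled_from_json",
    "stage2_to_json",
    "stage2_from_json",
    "extract_variant_from_vcf",
    "bonferroni_threshold",
    "genomewide_scan",
]


@dataclass
class AnalysisConfig:
    """Column mapping and analysis options for one run.

    ``covariates`` may be a flat list (shared by all phenotypes) or a
    mapping phenotype-column -> list of covariate columns, supporting a
    different adjustment set per phenotype.
    """

    phenotypes: list[str]
    genotype: str = "genotype"
    sample_id: str = "sample_id"
    covariates: list[str] | Mapping[str, list[str]] | None = None
    alpha: float = 0.05
    pseudo_inverse: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.phenotypes:
            raise ValidationError("config must name at least one phenotype column")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must lie in (0, 1); got {self.alpha}")

    def covariates_for(self, phenotype: str) -> list[str]:
        if self.covariates is None:
            return []
        if isinstance(self.covariates, Mapping):
            return list(self.covariates.get(phenotype, []))
        return list(self.covariates)


def _cross_labels(df: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    if not cols:
        return None
    parts = [df[c].astype(str).to_numpy() for c in cols]
    return np.array(["|".join(vals) for vals in zip(*parts)], dtype=object)


def read_site_table(
    path, config: AnalysisConfig, site_id: str | None = None
) -> SiteDataset:
    """Load and validate one site's delimited table into a :class:`SiteDataset`.

    The delimiter is inferred from the extension (``.csv`` -> comma,
    otherwise tab).  Genotype must be coded 0/1/2 and phenotypes 0/1;
    violations are reported with the 1-based data row and column name.
    Rows with missing genotype or phenotype values are dropped
    (complete-case analysis).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    needed = [config.genotype] + list(config.phenotypes)
    cov_cols: list[str] = []
    for ph in config.phenotypes:
        for c in config.covariates_for(ph):
            if c not in cov_cols:
                cov_cols.append(c)
    needed += cov_cols
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing column(s) {missing}")

    complete = df[needed].notna().all(axis=1)
    df = df.loc[complete].reset_index(drop=True)
    if df.empty:
        raise ValidationError(f"{path.name}: no complete rows")

    geno = pd.to_numeric(df[config.genotype], errors="coerce").to_numpy()
    bad = np.flatnonzero(~np.isin(geno, (0.0, 1.0, 2.0)))
    if bad.size:
        raise ValidationError(
            f"{path.name}: column {config.genotype!r}, data row {bad[0] + 1}: "
            f"genotype must be 0/1/2, found {df[config.genotype].iloc[bad[0]]!r}"
        )
    pheno = np.empty((len(df), len(config.phenotypes)))
    for j, col in enumerate(config.phenotypes):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy()
        bad = np.flatnonzero(~np.isin(vals, (0.0, 1.0)))
        if bad.size:
            raise ValidationError(
                f"{path.name}: column {col!r}, data row {bad[0] + 1}: "
                f"phenotype must be 0/1, found {df[col].iloc[bad[0]]!r}"
            )
        pheno[:, j] = vals

    strata = None
    if any(config.covariates_for(ph) for ph in config.phenotypes):
        cols = []
        for ph in config.phenotypes:
            labels = _cross_labels(df, config.covariates_for(ph))
            if labels is None:
                labels = np.full(len(df), "__all__", dtype=object)
            cols.append(labels)
        strata = np.column_stack(cols)

    return SiteDataset(
        site_id=site_id or path.stem,
        genotype=geno,
        phenotypes=pheno,
        strata=strata,
    )


def write_site_table(data: SiteDataset, path, config: AnalysisConfig | None = None) -> None:
    """Write a :class:`SiteDataset` back to delimited text (inverse of reading)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    pheno_names = (
        list(config.phenotypes) if config else [f"y{j+1}" for j in range(data.q)]
    )
    out = {"sample_id": [f"{data.site_id}_{i+1}" for i in range(data.n)]}
    out["genotype"] = data.genotype.astype(int)
    for j, name in enumerate(pheno_names):
        col = data.phenotypes[:, j]
        out[name] = col.astype(int) if np.isin(col, (0.0, 1.0)).all() else col
    df = pd.DataFrame(out)
    if data.strata is not None:
        for j, name in enumerate(pheno_names):
            df[f"stratum_{name}"] = data.strata[:, j]
    df.to_csv(path, sep=sep, index=False)


def impute_phenotypes(
    phenotypes: np.ndarray,
    mode: str = "bernoulli",
    seed: int | None = None,
) -> np.ndarray:
    """Fill missing phenotype values from the observed disease prevalence.

    ``bernoulli`` draws each missing value as Bernoulli(prevalence) and
    requires a seed; ``expected`` substitutes the prevalence itself
    (deterministic, fractional — pair with
    ``allow_fractional_phenotypes=True`` on the dataset).
    """
    y = np.asarray(phenotypes, dtype=float).copy()
    if y.ndim == 1:
        y = y[:, None]
    if mode not in ("bernoulli", "expected"):
        raise ValidationError(f"unknown imputation mode {mode!r}")
    if mode == "bernoulli":
        if seed is None:
            raise ValidationError("bernoulli imputation requires a seed")
        rng = np.random.default_rng(seed)
    for j in range(y.shape[1]):
        col = y[:, j]
        miss = ~np.isfinite(col)
        if not miss.any():
            continue
        if not miss.all():
            prev = float(np.nanmean(col))
        else:
            raise ValidationError(f"phenotype column {j} is entirely missing")
        if mode == "bernoulli":
            col[miss] = (rng.random(miss.sum()) < prev).astype(float)
        else:
            col[miss] = prev
    return y


# ---------------------------------------------------------------------------
# JSON summary exchange
# ---------------------------------------------------------------------------

def stage1_to_json(summary: Stage1Summary) -> str:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "kind": "stage1",
        "site_id": summary.site_id,
        "n": summary.n,
        "q": summary.q,
        "cells": [
            {lab: {"n": c.n, "y_sum": c.y_sum, "x_sum": c.x_sum} for lab, c in cj.items()}
            for cj in summary.cells
        ],
    }
    return json.dumps(doc)


def _check_doc(doc: dict, kind: str) -> None:
    if not isinstance(doc, dict) or doc.get("kind") != kind:
        raise SchemaError(f"expected a {kind!r} document")
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema version {doc.get('schema_version')!r}"
        )


def stage1_from_json(text: str) -> Stage1Summary:
    doc = json.loads(text)
    _check_doc(doc, "stage1")
    cells = [
        {lab: StratumCell(int(c["n"]), float(c["y_sum"]), float(c["x_sum"])) for lab, c in cj.items()}
        for cj in doc["cells"]
    ]
    return Stage1Summary(site_id=doc["site_id"], n=int(doc["n"]), q=int(doc["q"]), cells=cells)


def pooled_to_json(ref: PooledReference) -> str:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "kind": "pooled",
        "n": ref.n,
        "q": ref.q,
        "cells": [
            {lab: {"n": c.n, "y_mean": c.y_mean, "x_mean": c.x_mean} for lab, c in cj.items()}
            for cj in ref.cells
        ],
    }
    return json.dumps(doc)


def pooled_from_json(text: str) -> PooledReference:
    doc = json.loads(text)
    _check_doc(doc, "pooled")
    cells = [
        {lab: PooledCell(int(c["n"]), float(c["y_mean"]), float(c["x_mean"])) for lab, c in cj.items()}
        for cj in doc["cells"]
    ]
    return PooledReference(n=int(doc["n"]), q=int(doc["q"]), cells=cells)


def stage2_to_json(summary: Stage2Summary) -> str:
    q = summary.S.shape[0]
    doc = {
        "schema_version": SCHEMA_VERSION,
        "kind": "stage2",
        "site_id": summary.site_id,
        "q": q,
        "S": summary.S.tolist(),
        "V": summary.V.ravel().tolist(),  # row-major
    }
    return json.dumps(doc)


def stage2_from_json(text: str) -> Stage2Summary:
    doc = json.loads(text)
    _check_doc(doc, "stage2")
    q = int(doc["q"])
    S = np.asarray(doc["S"], dtype=float)
    V = np.asarray(doc["V"], dtype=float).reshape(q, q)
    return Stage2Summary(site_id=doc["site_id"], S=S, V=V)


# ---------------------------------------------------------------------------
# VCF extraction
# ---------------------------------------------------------------------------

def extract_variant_from_vcf(path, variant: str) -> tuple[np.ndarray, list[str]]:
    """Extract one biallelic variant's additive genotypes from a VCF.

    ``variant`` is either an ID (e.g. ``rs123``) or ``chrom:pos`` (1-based,
    VCF convention).  Diploid GT fields are recoded to 0/1/2 ALT-allele
    counts; missing genotypes become NaN, to be handled by the
    complete-case policy downstream.  Returns ``(genotypes, sample_names)``.
    """
    from cyvcf2 import VCF

    chrom = pos = None
    if ":" in variant:
        chrom, pos_s = variant.split(":", 1)
        pos = int(pos_s)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        for rec in vcf:
            if chrom is not None:
                if rec.CHROM != chrom or rec.POS != pos:
                    continue
            elif rec.ID != variant:
                continue
            if len(rec.ALT) != 1:
                raise ValidationError(
                    f"variant {variant!r} is multiallelic (ALT={rec.ALT}); "
                    "split or normalize the VCF first"
                )
            gts = np.asarray(rec.genotypes, dtype=object)
            out = np.empty(len(samples))
            for i, g in enumerate(gts):
                alleles = [a for a in g[:-1]]  # last entry is phasing flag
                if any(a < 0 for a in alleles):
                    out[i] = np.nan
                else:
                    out[i] = float(sum(alleles))
            return out, samples
    finally:
        vcf.close()
    raise ValidationError(f"variant {variant!r} not found in {path}")


# ---------------------------------------------------------------------------
# genome-wide scan
# ---------------------------------------------------------------------------

def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / M."""
    if n_tests < 1:
        raise ValidationError("need at least one test")
    return alpha / n_tests


def genomewide_scan(
    genotypes: pd.DataFrame | np.ndarray,
    phenotypes: np.ndarray,
    strata: np.ndarray | None = None,
    snp_ids: Sequence[str] | None = None,
    alpha: float = 0.05,
    pseudo_inverse: bool = False,
) -> pd.DataFrame:
    """Joint pleiotropy test for every SNP column against all phenotypes.

    Runs one score test per SNP on the pooled table and flags SNPs whose
    p-value passes the Bonferroni threshold ``alpha / M``.  Degenerate SNPs
    (monomorphic, singular V) are reported with NaN statistics and an error
    note rather than aborting the scan.
    """
    if isinstance(genotypes, pd.DataFrame):
        snp_ids = list(genotypes.columns)
        G = genotypes.to_numpy(dtype=float)
    else:
        G = np.asarray(genotypes, dtype=float)
        if G.ndim == 1:
            G = G[:, None]
        if snp_ids is None:
            snp_ids = [f"snp{m+1}" for m in range(G.shape[1])]
    M = G.shape[1]
    threshold = bonferroni_threshold(M, alpha)
    rows = []
    for m in range(M):
        rec = {
            "snp_id": snp_ids[m], "T": np.nan, "df": np.nan, "p": np.nan,
            "p_floored": False, "significant": False, "note": "",
        }
        try:
            data = SiteDataset(
                site_id="scan", genotype=G[:, m], phenotypes=phenotypes, strata=strata
            )
            res = pooled_test(data, pseudo_inverse=pseudo_inverse)
            rec.update(
                T=res.statistic, df=res.df, p=res.p_value,
                p_floored=res.p_floored, significant=bool(res.p_raw < threshold),
            )
        except ValidationError as exc:
            rec["note"] = str(exc)
        except Exception as exc:  # degenerate SNP: flag, keep scanning
            rec["note"] = str(exc)
        rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = threshold
    out.attrs["n_tests"] = M
    return out
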