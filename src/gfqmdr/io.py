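"""Reading, writing and imputation of genotype/phenotype tables.

The on-disk format is plain TSV: a genotype matrix (first column sample id,
remaining columns one marker each, header row of marker ids) and a
two-column phenotype table (sample id, trait value).  Genotype entries are
0/1/2 minor-allele counts; anything unparseable — or a configurable missing
token — is treated as missing and later imputed (modal code per marker for
genotypes, mean for the trait).  A minimal VCF importer is included for
interoperability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenotypeMatrix

__all__ = ["Dataset", "read_dataset", "write_dataset", "impute_missing", "read_vcf"]

MISSING = -1


@dataclass
class Dataset:
    genotypes: GenotypeMatrix
    trait: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.genotypes.n_samples


def _parse_codes(df: pd.DataFrame, allele_map: dict | None) -> np.ndarray:
    """Map genotype strings to {0,1,2}; unparseable entries become MISSING."""
    codes = np.full(df.shape, MISSING, dtype=np.int64)
    for j, col in enumerate(df.columns):
        raw = df[col].astype(str).str.strip()
        if allele_map:
            mapped = raw.map({str(k): v for k, v in allele_map.items()})
        else:
            mapped = pd.to_numeric(raw, errors="coerce")
        vals = mapped.to_numpy(dtype=float, na_value=np.nan)
        ok = np.isfinite(vals)
        distinct = np.unique(vals[ok])
        if len(distinct) > 3:
            raise ValueError(f"marker {col!r} has {len(distinct)} codes; at most 3 allowed")
        if ok.any() and (vals[ok].min() < 0 or vals[ok].max() > 2):
            raise ValueError(f"marker {col!r} has codes outside 0..2")
        codes[ok, j] = vals[ok].astype(np.int64)
    return codes


def read_dataset(
    genotype_path: str | Path,
    phenotype_path: str | Path,
    allele_map: dict | None = None,
    missing_tokens: tuple[str, ...] = ("", "NA", "nan", ".", "-"),
) -> Dataset:
    """Load and sample-align a genotype TSV and a phenotype TSV by sample id.

    Raises on sample-id mismatch (listing offenders) and on markers with
    more than three distinct codes.
    """
    gdf = pd.read_csv(genotype_path, sep="\t", dtype=str, index_col=0)
    pdf = pd.read_csv(phenotype_path, sep="\t", dtype=str, index_col=0)
    if pdf.shape[1] != 1:
        raise ValueError("phenotype file must have exactly two columns (id, value)")
    gdf = gdf.replace(list(missing_tokens), np.nan)
    missing_in_pheno = sorted(set(gdf.index) - set(pdf.index))
    missing_in_geno = sorted(set(pdf.index) - set(gdf.index))
    if missing_in_pheno or missing_in_geno:
        raise ValueError(
            "sample ids do not match: "
            f"missing from phenotype file {missing_in_pheno}; "
            f"missing from genotype file {missing_in_geno}"
        )
    pdf = pdf.loc[gdf.index]
    codes = _parse_codes(gdf, allele_map)
    trait = pd.to_numeric(pdf.iloc[:, 0], errors="coerce").to_numpy(dtype=float)
    genotypes = GenotypeMatrix(
        codes=codes, marker_ids=list(gdf.columns), sample_ids=list(gdf.index)
    )
    prov = {"genotype_path": str(genotype_path), "phenotype_path": str(phenotype_path)}
    return Dataset(genotypes=genotypes, trait=trait, provenance=prov)


def write_dataset(dataset: Dataset, genotype_path: str | Path, phenotype_path: str | Path,
                  metadata_path: str | Path | None = None) -> None:
    """Write genotype and phenotype TSVs (and an optional JSON metadata sidecar)."""
    g = dataset.genotypes
    gdf = pd.DataFrame(g.codes, index=list(g.sample_ids), columns=list(g.marker_ids))
    gdf.index.name = "sample_id"
    gdf.to_csv(genotype_path, sep="\t")
    pdf = pd.DataFrame({"trait": dataset.trait}, index=list(g.sample_ids))
    pdf.index.name = "sample_id"
    pdf.to_csv(phenotype_path, sep="\t")
    if metadata_path is not None:
        Path(metadata_path).write_text(json.dumps(dataset.provenance, indent=2))


def impute_missing(dataset: Dataset) -> Dataset:
    """Fill missing genotypes with each marker's modal code and missing trait
    values with the trait mean.  Modal ties break to the lower code.  Raises
    if a marker has no observed genotype at all.  Idempotent."""
    codes = dataset.genotypes.codes.copy()
    n_geno_imputed = 0
    for j in range(codes.shape[1]):
        col = codes[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        observed = col[~miss]
        if observed.size == 0:
            raise ValueError(f"marker {dataset.genotypes.marker_ids[j]!r} is entirely missing")
        counts = np.bincount(observed, minlength=3)
        col[miss] = int(np.argmax(counts))  # argmax ties -> lower code
        n_geno_imputed += int(miss.sum())
    trait = np.asarray(dataset.trait, dtype=float).copy()
    miss = ~np.isfinite(trait)
    n_trait_imputed = int(miss.sum())
    if miss.any():
        if miss.all():
            raise ValueError("trait is entirely missing")
        trait[miss] = trait[~miss].mean()
    prov = dict(dataset.provenance)
    prov["imputed_genotypes"] = n_geno_imputed
    prov["imputed_trait_values"] = n_trait_imputed
    genotypes = GenotypeMatrix(
        codes=codes,
        marker_ids=dataset.genotypes.marker_ids,
        sample_ids=dataset.genotypes.sample_ids,
    )
    return Dataset(genotypes=genotypes, trait=trait, provenance=prov)


def read_vcf(vcf_path: str | Path, phenotype_path: str | Path) -> Dataset:
    """Import biallelic variants from a VCF: GT field -> 0/1/2 alternate-allele
    dosage; missing genotypes stay missing for :func:`impute_missing`."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    marker_ids, rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gts = np.array(var.gt_types)
        dosage = np.select([gts == 0, gts == 1, gts == 3], [0, 1, 2], default=MISSING)
        rows.append(dosage)
    codes = np.array(rows, dtype=np.int64).T
    pdf = pd.read_csv(phenotype_path, sep="\t", dtype=str, index_col=0)
    pdf = pdf.loc[samples]
    trait = pd.to_numeric(pdf.iloc[:, 0], errors="coerce").to_numpy(dtype=float)
    genotypes = GenotypeMatrix(codes=codes, marker_ids=marker_ids, sample_ids=samples)
    return Dataset(genotypes=genotypes, trait=trait,
                   provenance={"vcf_path": str(vcf_path), "phenotype_path": str(phenotype_path)})
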