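"""Plain-text interchange: minimal VCF, phenotype/stratum TSV, pool TSV.

Genotypes travel as a minimal VCF (biallelic SNVs, a GT FORMAT field only)
paired with a phenotype TSV (``sample_id, phenotype, stratum`` with
phenotype in {case, control}).  Pool pileups, stratum count tables,
association results and expression matrices are tidy TSVs.  VCF reading
goes through cyvcf2; writing is a direct text emitter since only the
GT-only subset is ever produced.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import MISSING, CohortData

__all__ = [
    "write_vcf",
    "write_phenotypes",
    "read_cohort",
    "write_pool_pileup",
    "read_pool_pileup",
    "write_expression",
    "read_expression",
    "read_stratum_tables",
    "write_association_results",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

POOL_COLUMNS = ["variant_id", "pool_id", "pool_role", "n_ref_reads", "n_alt_reads", "pool_size"]


def write_vcf(cohort: CohortData, path, variants: pd.DataFrame | None = None) -> None:
    """Write genotypes as a minimal GT-only VCF.

    ``variants`` may supply per-variant ``chrom, pos, ref, alt`` (indexed
    like ``cohort.variant_ids``); without it, placeholder coordinates on
    chromosome 1 and an A>G change are emitted — sufficient for count-based
    analyses, which never look at the alleles themselves.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in cohort.sample_ids)
            + "\n"
        )
        for i, vid in enumerate(cohort.variant_ids):
            if variants is not None:
                row = variants.loc[vid]
                chrom, pos, ref, alt = row["chrom"], int(row["pos"]), row["ref"], row["alt"]
            else:
                chrom, pos, ref, alt = "1", i + 1, "A", "G"
            gts = "\t".join(_GT[int(g)] for g in cohort.genotypes[i])
            fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def write_phenotypes(cohort: CohortData, path) -> None:
    """Write the sample sheet: sample_id, phenotype{case,control}, stratum."""
    pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "phenotype": np.where(cohort.is_case, "case", "control"),
            "stratum": cohort.stratum,
        }
    ).to_csv(path, sep="\t", index=False)


def read_cohort(vcf_path, phenotype_path) -> CohortData:
    """Load a cohort from a biallelic VCF plus a phenotype/stratum TSV.

    Sample order follows the VCF header; every VCF sample must appear in
    the phenotype sheet.  Multi-allelic records are rejected.
    """
    from cyvcf2 import VCF

    pheno = pd.read_csv(phenotype_path, sep="\t", dtype=str).set_index("sample_id")
    bad = set(pheno["phenotype"]) - {"case", "control"}
    if bad:
        raise ValueError(f"phenotype values must be case/control, got {sorted(bad)}")
    vcf = VCF(os.fspath(vcf_path), gts012=True)
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in pheno.index]
    if missing:
        raise ValueError(f"samples missing from phenotype sheet: {missing[:5]}")
    geno_rows, vids = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"multi-allelic record at {rec.CHROM}:{rec.POS}")
        g = np.asarray(rec.gt_types, dtype=np.int8)  # 0,1,2; 3 = unknown
        g[g == 3] = MISSING
        geno_rows.append(g)
        vids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
    pheno = pheno.loc[samples]
    return CohortData(
        genotypes=np.vstack(geno_rows) if geno_rows else np.empty((0, len(samples)), np.int8),
        is_case=(pheno["phenotype"] == "case").to_numpy(),
        stratum=pheno["stratum"].to_numpy(),
        sample_ids=np.asarray(samples),
        variant_ids=np.asarray(vids),
    )


def write_pool_pileup(pileup: pd.DataFrame, path) -> None:
    pileup.loc[:, POOL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pool_pileup(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(POOL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pool pileup missing columns: {sorted(missing)}")
    return df


def write_expression(matrix: pd.DataFrame, groups: pd.Series, matrix_path, groups_path) -> None:
    matrix.to_csv(matrix_path, sep="\t", index_label="gene")
    groups.rename_axis("sample_id").rename("group").to_frame().to_csv(groups_path, sep="\t")


def read_expression(matrix_path, groups_path) -> tuple[pd.DataFrame, pd.Series]:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col="gene")
    matrix.index.name = None  # header label is file-format plumbing only
    groups = pd.read_csv(groups_path, sep="\t", index_col="sample_id")["group"]
    groups.index.name = None
    return matrix, groups.loc[matrix.columns]


def read_stratum_tables(path) -> dict[str, list]:
    """Read pre-tabulated per-stratum allele counts.

    Expects columns ``variant_id, stratum, a, b, c, d``; returns
    {variant_id: [StratumTable, ...]} for summary-level odds-ratio work.
    """
    from .marv import StratumTable

    df = pd.read_csv(path, sep="\t")
    need = {"variant_id", "stratum", "a", "b", "c", "d"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"stratum table file missing columns: {sorted(missing)}")
    out: dict[str, list] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.variant_id), []).append(
            StratumTable(str(row.stratum), int(row.a), int(row.b), int(row.c), int(row.d))
        )
    return out


def write_association_results(results, path) -> None:
    """Write AssociationResults as a flat TSV, one row per variant."""
    rows = []
    for r in results:
        lo, hi = r.ci95 if r.ci95 is not None else (np.nan, np.nan)
        rows.append(
            {
                "variant_id": r.variant_id,
                "T": r.statistic,
                "p_perm": r.p_perm,
                "n_perm": r.n_perm,
                "or_mh": r.or_mh if r.or_mh is not None else np.nan,
                "ci_low": lo,
                "ci_high": hi,
                "n_alleles_case": r.n_alleles_case,
                "n_alleles_control": r.n_alleles_control,
                "correction_flag": int(r.zero_cell_corrected),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
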