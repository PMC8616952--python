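"""Readers and writers for the text formats the pipeline exchanges.

Covers GMT gene sets, BED-like annotations, PLINK BIM/FAM variant and
sample tables, GWAS summary-statistics TSV, score-matrix TSV and VCF
genotypes.  All genomic coordinates exposed by this module are 1-based
fully closed; BED input (0-based half-open) is converted on read.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_bed_annotation",
    "write_bed_annotation",
    "read_bim",
    "write_bim",
    "read_fam",
    "write_fam",
    "read_sumstats",
    "write_sumstats",
    "read_scores",
    "write_scores",
    "read_vcf_genotypes",
    "write_vcf_genotypes",
]


# ---------------------------------------------------------------- gene sets

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set name: [gene symbols]}``.

    Symbols are uppercased and deduplicated preserving file order; the
    description column is ignored.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line (need >= 2 fields): {line!r}")
            name = fields[0]
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                g = g.strip().upper()
                if g and g not in seen:
                    seen.add(g)
                    genes.append(g)
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# --------------------------------------------------------------- annotations

def read_bed_annotation(path: str | Path, zero_based: bool = True) -> pd.DataFrame:
    """Read a BED-like annotation (chrom, start, end, gene) into 1-based closed.

    With ``zero_based=True`` (standard BED) start is incremented by one on
    read; ``zero_based=False`` takes coordinates as already 1-based closed.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene"],
        dtype={"chrom": str, "gene": str},
    )
    if zero_based:
        df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df[["gene", "chrom", "start", "end"]]


def write_bed_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    """Write a 1-based closed annotation table as standard 0-based BED."""
    out = annot.copy()
    out["start"] = out["start"].astype(int) - 1
    out[["chrom", "start", "end", "gene"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ----------------------------------------------------------------- PLINK text

_BIM_COLS = ["chrom", "id", "cm", "bp", "a1", "a2"]


def read_bim(path: str | Path) -> pd.DataFrame:
    """Read a PLINK BIM file; returns columns id, chrom, bp, a1, a2."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=_BIM_COLS,
                     dtype={"chrom": str, "id": str, "a1": str, "a2": str})
    return df[["id", "chrom", "bp", "a1", "a2"]]


def write_bim(variants: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "chrom": variants["chrom"],
            "id": variants["id"],
            "cm": 0,
            "bp": variants["bp"],
            "a1": variants["a1"],
            "a2": variants["a2"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_fam(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    return df


def write_fam(individuals: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iid in individuals:
            fh.write(f"{iid}\t{iid}\t0\t0\t0\t-9\n")


# ------------------------------------------------------------ summary stats

def read_sumstats(path: str | Path):
    """Read GWAS summary statistics TSV into a :class:`~pathpgs.pgs.SumStats`.

    Expects a header with SNP, CHR, BP, A1, A2, BETA (or OR), SE, P
    (case-insensitive).  Odds ratios are converted to betas by natural log.
    """
    from .pgs import SumStats

    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    mapping = {"snp": "id", "chr": "chrom", "bp": "bp", "a1": "a1",
               "a2": "a2", "se": "se", "p": "p"}
    out = pd.DataFrame()
    for key, name in mapping.items():
        if key not in cols:
            raise ValueError(f"summary statistics lack column {key.upper()!r}")
        out[name] = df[cols[key]]
    if "beta" in cols:
        out["beta"] = df[cols["beta"]].astype(float)
    elif "or" in cols:
        out["beta"] = np.log(df[cols["or"]].astype(float))
    else:
        raise ValueError("summary statistics need a BETA or OR column")
    return SumStats(out[["id", "chrom", "bp", "a1", "a2", "beta", "se", "p"]])


def write_sumstats(ss, path: str | Path) -> None:
    out = ss.table.rename(
        columns={"id": "SNP", "chrom": "CHR", "bp": "BP", "a1": "A1",
                 "a2": "A2", "beta": "BETA", "se": "SE", "p": "P"}
    )
    out.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- scores

def write_scores(sm, path: str | Path) -> None:
    """Write a ScoreMatrix as TSV: individual id + one column per threshold."""
    df = pd.DataFrame(sm.scores, columns=[f"p_{t:.6g}" for t in sm.thresholds.thresholds])
    df.insert(0, "iid", sm.individuals)
    df.to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path):
    from .pgs import ScoreMatrix, ThresholdGrid

    df = pd.read_csv(path, sep="\t")
    iids = df["iid"].astype(str).tolist()
    tcols = [c for c in df.columns if c.startswith("p_")]
    thresholds = np.array([float(c[2:]) for c in tcols])
    scores = df[tcols].to_numpy(dtype=float)
    return ScoreMatrix(
        individuals=iids,
        thresholds=ThresholdGrid(thresholds),
        scores=scores,
        snp_counts=np.full(len(tcols), -1),
        standardized=False,
    )


# ------------------------------------------------------------------- VCF

def read_vcf_genotypes(path: str | Path):
    """Read diploid GT dosages from a VCF via cyvcf2.

    The counted (effect-reconcilable) allele is ALT; dosage is the ALT
    allele count, missing genotypes are NaN.
    """
    from cyvcf2 import VCF  # lazy: optional dependency

    from .pgs import GenotypeMatrix

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows, dosage_cols = [], []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        rows.append(
            {"id": var.ID or f"{var.CHROM}:{var.POS}", "chrom": str(var.CHROM),
             "bp": int(var.POS), "a1": alt, "a2": var.REF}
        )
        types = var.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        d = np.where(types == 0, 0.0,
                     np.where(types == 1, 1.0,
                              np.where(types == 3, 2.0, np.nan)))
        dosage_cols.append(d)
    snps = pd.DataFrame(rows)
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(individuals), 0))
    return GenotypeMatrix(individuals=individuals, snps=snps, dosages=dosages)


def write_vcf_genotypes(genos, path: str | Path) -> None:
    """Write a GenotypeMatrix as a minimal VCFv4.2 with GT fields.

    The counted allele (a1) is written as ALT, a2 as REF; dosage 2 becomes
    1/1, dosage 1 becomes 0/1, dosage 0 becomes 0/0, NaN becomes ./. .
    Dosages must be integral (raw simulated genotypes, not imputed).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genos.individuals) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in enumerate(genos.snps.itertuples(index=False)):
            col = genos.dosages[:, j]
            gts = [
                "./." if np.isnan(d) else gt_map[int(round(d))] for d in col
            ]
            fh.write(
                f"{row.chrom}\t{row.bp}\t{row.id}\t{row.a2}\t{row.a1}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )
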