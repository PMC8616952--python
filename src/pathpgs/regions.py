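"""Gene-set genomic regions and variant-to-pathway assignment.

A pathway is represented as a set of gene symbols.  Transcript intervals
(and, optionally, regulatory-element intervals annotated to the same
symbols) are unioned and merged per chromosome; variants falling inside
the merged regions are assigned to the pathway and become the SNP universe
for pathway-restricted polygenic scoring.

Coordinate convention: 1-based, fully closed intervals everywhere in this
package (ENSEMBL style).  BED files (0-based, half-open) are converted on
read by :func:`pathpgs.io.read_bed_annotation`.  Chromosome labels are
normalized by stripping a leading ``chr``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GenomicInterval",
    "RegionSet",
    "SnpSet",
    "load_gene_set",
    "build_regions",
    "assign_snps",
    "normalize_chrom",
]


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix and surrounding whitespace."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique, uppercased gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        upper = tuple(g.upper() for g in self.genes)
        seen: dict[str, None] = {}
        for g in upper:
            seen.setdefault(g, None)
        object.__setattr__(self, "genes", tuple(seen))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.genes


@dataclass(frozen=True)
class GenomicInterval:
    """1-based fully closed genomic interval attributed to gene symbol(s).

    ``gene`` may be a semicolon-joined list when intervals of several genes
    were coalesced during merging.  ``source`` records provenance
    (``transcript``, ``regulatory`` or ``merged``).
    """

    chrom: str
    start: int
    end: int
    gene: str
    source: str = "transcript"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chromosome label is empty")
        if self.start > self.end:
            raise ValueError(
                f"malformed interval {self.gene} {self.chrom}:{self.start}-{self.end} "
                "(start > end)"
            )

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.gene.split(";"))

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegionSet:
    """Merged intervals covering a gene set.

    ``genes_covered`` lists the subset of the gene set found in annotation;
    ``genes_missing`` the complement (logged on construction).
    """

    name: str
    intervals: list[GenomicInterval]
    genes_covered: tuple[str, ...] = ()
    genes_missing: tuple[str, ...] = field(default=())

    def total_span(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class SnpSet:
    """Variants assigned to a region set, in input order."""

    snp_ids: list[str]
    positions: list[tuple[str, int]]

    def __post_init__(self) -> None:
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate variant ids in SnpSet")
        if len(self.snp_ids) != len(self.positions):
            raise ValueError("snp_ids and positions have different lengths")

    def __len__(self) -> int:
        return len(self.snp_ids)


def load_gene_set(path: str, set_name: str) -> GeneSet:
    """Load one named gene set from a GMT file.

    GMT lines are tab-separated: name, description, then gene symbols.
    Symbols are uppercased and deduplicated preserving file order.
    """
    from .io import read_gmt

    sets = read_gmt(path)
    if set_name not in sets:
        raise KeyError(f"gene set not found: {set_name!r} (file has {sorted(sets)})")
    genes = sets[set_name]
    if not genes:
        raise ValueError(f"gene set {set_name!r} is empty")
    return GeneSet(name=set_name, genes=tuple(genes))


def _merge_sorted(rows: list[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    """Merge overlapping or book-ended (end+1 == next start) intervals.

    ``rows`` are (start, end, gene) sorted by start; gene labels of merged
    intervals are joined with ';' (sorted, unique).
    """
    merged: list[list] = []
    for start, end, gene in rows:
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
            merged[-1][2].update(gene.split(";"))
        else:
            merged.append([start, end, set(gene.split(";"))])
    return [(s, e, ";".join(sorted(g))) for s, e, g in merged]


def _annotation_rows(
    annot: pd.DataFrame, genes: tuple[str, ...], source: str
) -> list[GenomicInterval]:
    if annot is None or len(annot) == 0:
        return []
    required = {"gene", "chrom", "start", "end"}
    missing = required - set(annot.columns)
    if missing:
        raise ValueError(f"{source} annotation lacks columns {sorted(missing)}")
    sub = annot[annot["gene"].astype(str).str.upper().isin(genes)]
    out = []
    for row in sub.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if start > end:
            raise ValueError(
                f"malformed {source} interval for {row.gene}: "
                f"{row.chrom}:{start}-{end} (start > end)"
            )
        out.append(
            GenomicInterval(
                chrom=normalize_chrom(row.chrom),
                start=start,
                end=end,
                gene=str(row.gene).upper(),
                source=source,
            )
        )
    return out


def build_regions(
    gene_set: GeneSet,
    gene_annot: pd.DataFrame,
    reg_annot: pd.DataFrame | None = None,
) -> RegionSet:
    """Union transcript and regulatory intervals for a gene set and merge.

    Parameters
    ----------
    gene_set
        The pathway genes.
    gene_annot
        Table with columns ``gene, chrom, start, end`` (1-based closed)
        giving transcript coordinates.
    reg_annot
        Optional table of regulatory elements, same columns.

    Overlapping or book-ended intervals are coalesced per chromosome, across
    genes (SNP membership is unchanged by cross-gene coalescing).  Genes
    absent from both annotations are recorded in ``genes_missing``; if no
    gene is found at all an error is raised.
    """
    intervals = _annotation_rows(gene_annot, gene_set.genes, "transcript")
    intervals += _annotation_rows(reg_annot, gene_set.genes, "regulatory")
    covered = tuple(
        g for g in gene_set.genes if any(g in iv.genes for iv in intervals)
    )
    missing = tuple(g for g in gene_set.genes if g not in covered)
    if not covered:
        raise ValueError(
            f"no gene of set {gene_set.name!r} found in the provided annotation"
        )
    if missing:
        logger.warning(
            "gene set %s: %d/%d genes absent from annotation: %s",
            gene_set.name, len(missing), len(gene_set), ", ".join(missing),
        )

    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, iv.gene))

    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        rows = sorted(by_chrom[chrom])
        for start, end, gene in _merge_sorted(rows):
            merged.append(
                GenomicInterval(chrom=chrom, start=start, end=end, gene=gene,
                                source="merged" if ";" in gene else "transcript")
            )
    merged.sort(key=lambda iv: (iv.chrom, iv.start))
    return RegionSet(
        name=gene_set.name,
        intervals=merged,
        genes_covered=covered,
        genes_missing=missing,
    )


def assign_snps(regions: RegionSet, variants: pd.DataFrame) -> SnpSet:
    """Assign variants whose position falls inside a region interval.

    ``variants`` needs columns ``id, chrom, bp``; input order is preserved
    in the result.  Interval bounds are inclusive on both sides.  An empty
    variant table yields an empty SnpSet.
    """
    if len(variants) == 0:
        return SnpSet(snp_ids=[], positions=[])
    required = {"id", "chrom", "bp"}
    missing = required - set(variants.columns)
    if missing:
        raise ValueError(f"variant table lacks columns {sorted(missing)}")

    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for iv in regions.intervals:
        starts.setdefault(iv.chrom, [])
        starts[iv.chrom].append(iv.start)
        ends.setdefault(iv.chrom, [])
        ends[iv.chrom].append(iv.end)
    for chrom in starts:
        order = np.argsort(starts[chrom], kind="stable")
        starts[chrom] = np.asarray(starts[chrom])[order]
        ends[chrom] = np.asarray(ends[chrom])[order]

    chroms = variants["chrom"].map(normalize_chrom).to_numpy()
    bps = variants["bp"].to_numpy(dtype=np.int64)
    ids = variants["id"].astype(str).to_numpy()

    keep = np.zeros(len(variants), dtype=bool)
    for chrom in starts:
        mask = chroms == chrom
        if not mask.any():
            continue
        pos = bps[mask]
        # merged intervals are disjoint and sorted: the candidate interval is
        # the last one starting at or before the position
        idx = np.searchsorted(starts[chrom], pos, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos[ok] <= ends[chrom][idx[ok]]
        keep[mask] = ok

    return SnpSet(
        snp_ids=list(ids[keep]),
        positions=[(c, int(b)) for c, b in zip(chroms[keep], bps[keep])],
    )
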