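"""Synthetic genotype / summary-statistic / phenotype generator.

Emulates the statistical structure the pipeline assumes so that every
module can be exercised end to end without external data:

* LD-structured diploid genotypes — per gene, haplotype alleles are drawn
  by thresholding exchangeably correlated latent Gaussians at the gene's
  minor-allele frequency, giving Hardy-Weinberg dosages with tunable
  within-gene LD; genes occupy disjoint intervals spaced farther apart
  than the clumping window.
* GWAS summary statistics — marginal betas are the true per-SNP effects
  plus sampling noise with the standard marginal-regression standard
  error ``se = 1 / sqrt(2 * N * maf * (1 - maf))``; p-values are
  two-sided normal.
* Phenotypes — a latent adiposity factor carries the (standardized)
  pathway effect plus sex and age contributions; nine continuous
  metabolic variables load on three designed cluster factors (body fat,
  diet, strength/waist-hip ratio); four social questionnaire variables
  are drawn with configured prevalences and a logistic dependence on the
  latent factor, and are emitted as *raw* categorical answers so the
  coding operations are exercised; ten synthetic genetic PCs are
  standard normals.

Everything is deterministic under the config seed: one
``numpy.random.default_rng`` stream is consumed in the documented order
genotypes -> summary statistics -> phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .pgs import GenotypeMatrix, SumStats
from .regions import GeneSet

__all__ = [
    "SimConfig",
    "StudyData",
    "simulate_genotypes",
    "simulate_sumstats",
    "simulate_phenotypes",
    "simulate_study",
]

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    ``pathway_effect`` is the standardized effect of the true (noise-free)
    pathway score on the latent adiposity factor.  The causal architecture
    is sparse: ``causal_snps_per_gene`` evenly spaced SNPs per pathway gene
    carry true per-allele effect ``gwas_snp_effect`` in the pseudo-GWAS;
    the remaining SNPs are null.
    ``ld_block_rho`` is the latent-Gaussian exchangeable correlation within
    a gene; the realized genotype correlation is attenuated by the
    allele-frequency thresholding (about 0.85 at rho = 0.95).
    """

    n_individuals: int = 2000
    n_genes: int = 60
    genes_per_chrom: int = 10
    snps_per_gene: int = 20
    ld_block_rho: float = 0.95
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_pathway_genes: int = 10
    pathway_genes: tuple[str, ...] | None = None
    causal_snps_per_gene: int = 1
    pathway_effect: float = 0.1
    gwas_n: int = 300_000
    gwas_snp_effect: float = 0.02
    prevalences: dict = field(default_factory=lambda: {
        "loneliness": 0.18, "confide": 0.14,
        "social_contact": 0.05, "social_activity": 0.30,
    })
    social_latent_slope: float = 0.3
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.ld_block_rho < 1):
            raise ValueError("ld_block_rho must lie in [0, 1)")
        if self.pathway_genes is None and self.n_pathway_genes > self.n_genes:
            raise ValueError(
                f"n_pathway_genes={self.n_pathway_genes} exceeds n_genes={self.n_genes}"
            )
        for k, v in self.prevalences.items():
            if not (0 < v < 1):
                raise ValueError(f"prevalence {k} must lie in (0, 1)")

    def pathway(self) -> GeneSet:
        genes = self.pathway_genes or tuple(
            _gene_symbol(g) for g in range(self.n_pathway_genes)
        )
        return GeneSet(name="PATHWAY", genes=genes)

    def causal_snp_ids(self) -> list[str]:
        """Causal SNP ids: ``causal_snps_per_gene`` evenly spaced SNPs in
        each pathway gene (sparse causal architecture, deterministic)."""
        c = self.causal_snps_per_gene
        positions = [
            (k + 1) * self.snps_per_gene // (c + 1) for k in range(c)
        ]
        return [
            f"snp_{gene}_{j:02d}"
            for gene in self.pathway().genes
            for j in positions
        ]


@dataclass
class StudyData:
    """One simulated study: everything the pipeline consumes."""

    config: SimConfig
    genotypes: GenotypeMatrix
    gene_annot: pd.DataFrame
    sumstats: SumStats
    pathway: GeneSet
    phenotypes: pd.DataFrame


def _gene_symbol(g: int) -> str:
    return f"GENE{g:04d}"


def simulate_genotypes(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw LD-structured dosages plus the matching gene annotation.

    Returns the genotype matrix (snp table columns id, chrom, bp, a1, a2,
    gene) and a 1-based-closed gene annotation table (gene, chrom, start,
    end) covering each gene's SNPs.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n, rho = cfg.n_individuals, cfg.ld_block_rho
    snp_rows, annot_rows, blocks = [], [], []
    for g in range(cfg.n_genes):
        gene = _gene_symbol(g)
        chrom = str(1 + g // cfg.genes_per_chrom)
        k = g % cfg.genes_per_chrom
        start = 1_000_000 + k * 1_000_000
        m = cfg.snps_per_gene
        mafs = rng.uniform(*cfg.maf_range, size=m)
        thr = stats.norm.ppf(mafs)
        dose = np.zeros((n, m))
        for _hap in range(2):
            shared = rng.standard_normal(n)
            eps = rng.standard_normal((n, m))
            Z = np.sqrt(rho) * shared[:, None] + np.sqrt(1 - rho) * eps
            dose += (Z < thr[None, :]).astype(float)
        blocks.append(dose)
        pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
        for j in range(m):
            a1, a2 = _ALLELE_PAIRS[pair_idx[j]]
            snp_rows.append(
                {"id": f"snp_{gene}_{j:02d}", "chrom": chrom,
                 "bp": start + 100 * j, "a1": a1, "a2": a2, "gene": gene}
            )
        annot_rows.append(
            {"gene": gene, "chrom": chrom, "start": start,
             "end": start + 100 * (m - 1)}
        )
    snps = pd.DataFrame(snp_rows)
    genos = GenotypeMatrix(
        individuals=[f"ind{i:05d}" for i in range(n)],
        snps=snps,
        dosages=np.concatenate(blocks, axis=1),
    )
    return genos, pd.DataFrame(annot_rows)


def simulate_sumstats(
    genos: GenotypeMatrix,
    causal_snps,
    effect_size: float,
    gwas_n: int,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> SumStats:
    """Pseudo-GWAS marginal results: true effect plus sampling noise.

    ``causal_snps`` get true per-allele effect ``effect_size`` (counted on
    a1); all others are null.  Standard errors follow the marginal
    regression approximation from the empirical allele frequency.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    causal = set(map(str, causal_snps))
    unknown = causal - set(genos.snps["id"].astype(str))
    if unknown:
        raise KeyError(f"causal SNPs absent from variant table: {sorted(unknown)[:5]}")
    freq = np.nanmean(genos.dosages, axis=0) / 2.0
    freq = np.clip(freq, 0.01, 0.99)
    se = 1.0 / np.sqrt(2.0 * gwas_n * freq * (1.0 - freq))
    true = np.where(genos.snps["id"].astype(str).isin(causal), effect_size, 0.0)
    beta = true + rng.normal(0.0, se)
    z = beta / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    table = genos.snps[["id", "chrom", "bp", "a1", "a2"]].copy()
    table["beta"] = beta
    table["se"] = se
    table["p"] = p
    return SumStats(table)


def _raw_social_answers(
    coded: np.ndarray, missing: np.ndarray, variable: str, rng: np.random.Generator
) -> dict[str, list]:
    """Translate coded 0/1/missing values into raw questionnaire answers."""
    n = len(coded)
    if variable == "loneliness":
        raw = np.where(missing, "prefer not to answer",
                       np.where(coded == 1, "yes", "no"))
        return {"loneliness_raw": list(raw)}
    if variable == "confide":
        low = ["almost daily", "2-4 times a week", "about once a week",
               "about once a month"]
        high = ["once every few months", "never or almost never"]
        raw = [
            "do not know" if missing[i]
            else (rng.choice(high) if coded[i] == 1 else rng.choice(low))
            for i in range(n)
        ]
        return {"confide_raw": raw}
    if variable == "social_contact":
        household, visit = [], []
        weekly = ["almost daily", "2-4 times a week", "about once a week"]
        never = ["never or almost never", "no friends/family outside household"]
        for i in range(n):
            if missing[i]:
                household.append(1)
                visit.append("about once a month")  # covered by neither rule
            elif coded[i] == 1:
                household.append(1)
                visit.append(rng.choice(never))
            elif rng.random() < 0.8:
                household.append(int(rng.integers(2, 6)))
                visit.append(rng.choice(weekly + ["about once a month"]))
            else:
                household.append(1)
                visit.append(rng.choice(weekly))
        return {"household_n": household, "visit_freq_raw": visit}
    if variable == "social_activity":
        options = ["sports club or gym", "pub or social club", "religious group",
                   "adult education class", "other group activity"]
        raw = []
        for i in range(n):
            if missing[i]:
                raw.append("prefer not to answer")
            elif coded[i] == 1:
                raw.append("none of the above")
            else:
                k = int(rng.integers(1, 4))
                raw.append("|".join(rng.choice(options, size=k, replace=False)))
        return {"activities_raw": raw}
    raise ValueError(variable)


def simulate_phenotypes(
    genos: GenotypeMatrix,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate the phenotype table for a simulated cohort.

    The latent adiposity factor is ``pathway_effect`` times the
    standardized true pathway score (the causal-SNP dosage burden) plus
    sex and age contributions and noise.  The body-fat variables load on it directly; dietary and
    strength/waist-hip factors are weakly coupled (0.15) to it, so three
    well-separated correlation clusters emerge.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = genos.n_individuals
    causal = genos.snps["id"].isin(set(cfg.causal_snp_ids())).to_numpy()
    if not causal.any():
        raise ValueError("no causal SNP belongs to the configured pathway genes")
    raw_score = genos.dosages[:, causal] @ np.full(causal.sum(), cfg.gwas_snp_effect)
    sd = raw_score.std()
    # zero per-SNP effect: no pathway contribution to the latent factor
    z_path = (raw_score - raw_score.mean()) / sd if sd > 0 else np.zeros(n)

    sex = (rng.random(n) < 0.54).astype(float)  # 1 = female
    age = rng.integers(40, 70, size=n).astype(float)
    age_z = (age - age.mean()) / age.std()

    noise_sd = np.sqrt(max(1.0 - cfg.pathway_effect**2, 0.25))
    latent = (
        cfg.pathway_effect * z_path
        + 0.15 * (sex - sex.mean())
        + 0.10 * age_z
        + noise_sd * rng.standard_normal(n)
    )

    f_diet = 0.15 * latent + np.sqrt(1 - 0.15**2) * rng.standard_normal(n)
    f_strength = 0.15 * latent + np.sqrt(1 - 0.15**2) * rng.standard_normal(n)

    def load(factor: np.ndarray, lam: float) -> np.ndarray:
        return lam * factor + np.sqrt(1 - lam**2) * rng.standard_normal(n)

    cont = {
        "bmi": 27.4 + 4.8 * load(latent, 0.92),
        "bmi_impedance": 27.2 + 4.7 * load(latent, 0.92),
        "whole_body_fat_pct": np.clip(31.5 + 8.5 * load(latent, 0.92), 3, 75),
        "trunk_fat_pct": np.clip(31.0 + 9.0 * load(latent, 0.92), 3, 75),
        "energy_kj": np.clip(8800 + 2600 * load(f_diet, 0.75), 500, None),
        "sugar_g": np.clip(120 + 45 * load(f_diet, 0.75), 1, None),
        "food_weight_g": np.clip(2700 + 800 * load(f_diet, 0.75), 100, None),
        "grip_strength": np.clip(30.5 + 11.0 * load(f_strength, 0.63), 1, 90),
        "waist_hip_ratio": np.clip(0.87 + 0.09 * load(f_strength, 0.63), 0.5, 1.5),
    }

    table = pd.DataFrame({"iid": genos.individuals})
    table["sex"] = sex
    table["age"] = age
    for name, values in cont.items():
        vals = values.copy()
        miss = rng.random(n) < cfg.missing_rate
        vals[miss] = np.nan
        table[name] = vals

    for variable, prev in cfg.prevalences.items():
        prob = expit(logit(prev) + cfg.social_latent_slope * latent)
        coded = (rng.random(n) < prob).astype(float)
        missing = rng.random(n) < cfg.missing_rate
        for col, values in _raw_social_answers(coded, missing, variable, rng).items():
            table[col] = values

    for k in range(1, 11):
        table[f"gpc{k}"] = rng.standard_normal(n)
    return table


def simulate_study(cfg: SimConfig) -> StudyData:
    """Full simulated study: genotypes, GWAS, annotation and phenotypes."""
    rng = np.random.default_rng(cfg.seed)
    genos, annot = simulate_genotypes(cfg, rng=rng)
    pathway = cfg.pathway()
    causal = cfg.causal_snp_ids()
    ss = simulate_sumstats(genos, causal, cfg.gwas_snp_effect, cfg.gwas_n, rng=rng)
    pheno = simulate_phenotypes(genos, cfg, rng=rng)
    return StudyData(
        config=cfg, genotypes=genos, gene_annot=annot,
        sumstats=ss, pathway=pathway, phenotypes=pheno,
    )
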