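"""Clumping + thresholding polygenic scores over a p-value threshold grid.

The polygenic score of individual *i* at threshold *t* is

    PGS_i(t) = sum_{j : p_j <= t} beta_j * dosage_ij

with beta_j the GWAS marginal effect of the effect allele and dosage_ij the
(possibly imputed) effect-allele count.  SNPs are first restricted to a
pathway SNP set and LD-clumped (greedy, most significant index SNP first,
removing neighbours within a window whose squared genotype correlation
exceeds a cutoff).  Because the SNP subsets are nested across thresholds,
the whole threshold grid is scored with a single cumulative pass.

Threshold selection follows the empirical-p approach of C+T software: the
best threshold maximises the absolute Wald statistic of the score
coefficient in a covariate-adjusted model, and its significance is assessed
by permuting phenotype rows and comparing the observed max-|t| against the
permutation distribution of max-|t| over the grid (family-wise over the
thresholds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regions import SnpSet, normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "SumStats",
    "GenotypeMatrix",
    "ThresholdGrid",
    "ScoreMatrix",
    "ThresholdSelection",
    "make_grid",
    "clump",
    "score",
    "score_matrix",
    "select_threshold",
]

_VALID_ALLELES = {"A", "C", "G", "T"}
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class SumStats:
    """Per-SNP marginal GWAS results.

    ``table`` columns: id, chrom, bp, a1 (effect allele), a2 (other allele),
    beta (log-odds for binary traits), se, p.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "chrom", "bp", "a1", "a2", "beta", "se", "p"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"summary statistics lack columns {sorted(missing)}")
        t = self.table.copy()
        t["id"] = t["id"].astype(str)
        t["chrom"] = t["chrom"].map(normalize_chrom)
        t["a1"] = t["a1"].astype(str).str.upper()
        t["a2"] = t["a2"].astype(str).str.upper()
        if t["id"].duplicated().any():
            dups = t.loc[t["id"].duplicated(), "id"].head().tolist()
            raise ValueError(f"duplicate SNP ids in summary statistics: {dups}")
        p = t["p"].to_numpy(dtype=float)
        if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
            raise ValueError("p-values must lie in (0, 1]")
        bad = ~(t["a1"].isin(_VALID_ALLELES) & t["a2"].isin(_VALID_ALLELES))
        if bad.any():
            raise ValueError(
                f"non-ACGT alleles for SNPs {t.loc[bad, 'id'].head().tolist()}"
            )
        se = t["se"].to_numpy(dtype=float)
        if np.any(np.isfinite(se) & (se <= 0)):
            raise ValueError("standard errors must be positive where present")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, snp_ids) -> "SumStats":
        ids = set(map(str, snp_ids))
        return SumStats(self.table[self.table["id"].isin(ids)].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Diploid dosages, individuals x SNPs.

    ``snps`` columns: id, chrom, bp, a1 (counted allele), a2.  Dosages count
    copies of a1 in {0, 1, 2}; missing entries are NaN until imputation.
    """

    individuals: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.individuals), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.snps)} SNPs"
            )
        self.snps = self.snps.reset_index(drop=True)
        self._index = {s: j for j, s in enumerate(self.snps["id"].astype(str))}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def columns(self, snp_ids) -> np.ndarray:
        idx = [self._index[str(s)] for s in snp_ids]
        return self.dosages[:, idx]


@dataclass
class ThresholdGrid:
    """Ascending p-value cutoffs in (0, 1]."""

    thresholds: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if t.ndim != 1 or len(t) == 0:
            raise ValueError("threshold grid must be a non-empty 1-d array")
        if np.any(t <= 0) or np.any(t > 1):
            raise ValueError("thresholds must lie in (0, 1]")
        if np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        self.thresholds = t

    def __len__(self) -> int:
        return len(self.thresholds)


def make_grid(floor: float = 5e-8, upper: float = 1.0, step: float = 1e-3) -> ThresholdGrid:
    """Build the p-value threshold grid {floor} U {k*step} U {upper}.

    Multiples of ``step`` below the floor are dropped; the result is
    deduplicated and ascending.  Defaults give 1001 thresholds from the
    genome-wide floor 5e-8 up to 1 in increments of 0.001.
    """
    if not (0 < floor < upper <= 1):
        raise ValueError(f"need 0 < floor < upper <= 1, got floor={floor}, upper={upper}")
    if step <= 0:
        raise ValueError("step must be positive")
    ks = np.arange(1, int(np.floor(upper / step)) + 1)
    values = np.concatenate([[floor], ks * step, [upper]])
    values = values[(values >= floor) & (values <= upper)]
    return ThresholdGrid(np.unique(values))


@dataclass
class ScoreMatrix:
    """Individuals x thresholds polygenic scores.

    ``snp_counts[k]`` is the number of SNPs entering column k; the SNP
    subsets are nested across thresholds by construction.  ``degenerate``
    flags columns with zero SNPs or zero variance, which are left all-zero
    when standardizing.
    """

    individuals: list[str]
    thresholds: ThresholdGrid
    scores: np.ndarray
    snp_counts: np.ndarray
    standardized: bool
    degenerate: np.ndarray = field(default=None)
    snp_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.individuals), len(self.thresholds)):
            raise ValueError("score matrix shape mismatch")
        self.snp_counts = np.asarray(self.snp_counts)
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.thresholds), dtype=bool)

    def column(self, threshold: float) -> np.ndarray:
        k = int(np.argmin(np.abs(self.thresholds.thresholds - threshold)))
        if not np.isclose(self.thresholds.thresholds[k], threshold):
            raise KeyError(f"threshold {threshold} not in grid")
        return self.scores[:, k]


@dataclass
class ThresholdSelection:
    """Result of permutation-based optimal-threshold selection."""

    best_threshold: float
    best_fit_statistic: float
    empirical_p: float | None
    n_permutations: int
    seed: int | None
    statistics: np.ndarray = field(default=None, repr=False)


# ---------------------------------------------------------------- clumping

def clump(
    sumstats: SumStats,
    ld_ref: GenotypeMatrix,
    snp_subset: SnpSet | list[str],
    r2_max: float = 0.1,
    window_kb: float = 250.0,
) -> list[str]:
    """Greedy LD clumping restricted to a SNP subset.

    Repeatedly takes the remaining SNP with the smallest p-value as index
    SNP (ties broken by chromosome, position, then id) and removes every
    remaining SNP within ``window_kb`` whose squared Pearson genotype
    correlation with the index exceeds ``r2_max``.  Returns index SNP ids
    in selection order.  Every subset SNP must be present in both the
    summary statistics and the LD reference.
    """
    ids = list(snp_subset.snp_ids) if isinstance(snp_subset, SnpSet) else [str(s) for s in snp_subset]
    if not ids:
        return []
    tab = sumstats.table.set_index("id")
    missing = [s for s in ids if s not in tab.index]
    if missing:
        raise KeyError(f"subset SNPs absent from summary statistics: {missing[:5]}")
    missing = [s for s in ids if s not in ld_ref._index]
    if missing:
        raise KeyError(f"subset SNPs absent from LD reference: {missing[:5]}")

    sub = tab.loc[ids]
    order = sorted(
        range(len(ids)),
        key=lambda i: (sub["p"].iloc[i], sub["chrom"].iloc[i], sub["bp"].iloc[i], ids[i]),
    )
    chroms = sub["chrom"].to_numpy()
    bps = sub["bp"].to_numpy(dtype=np.int64)

    # standardized dosage columns (mean-imputed) for fast r^2
    G = ld_ref.columns(ids)
    G = np.where(np.isnan(G), np.nanmean(G, axis=0, keepdims=True), G)
    mu = G.mean(axis=0)
    sd = G.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (G - mu) / sd_safe
    zero_var = sd == 0

    window_bp = int(window_kb * 1000)
    alive = np.ones(len(ids), dtype=bool)
    kept: list[str] = []
    for i in order:
        if not alive[i]:
            continue
        alive[i] = False
        kept.append(ids[i])
        near = alive & (chroms == chroms[i]) & (np.abs(bps - bps[i]) <= window_bp)
        if not near.any() or zero_var[i]:
            continue
        cand = np.flatnonzero(near & ~zero_var)
        if len(cand) == 0:
            continue
        r = Z[:, cand].T @ Z[:, i] / len(Z)
        alive[cand[r**2 > r2_max]] = False
    return kept


# ----------------------------------------------------------------- scoring

def _harmonize(genos: GenotypeMatrix, sumstats: SumStats, snp_ids) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Reconcile effect alleles with genotype coding.

    Returns (kept ids, betas, flip mask).  ``flip`` marks SNPs whose GWAS
    effect allele is the genotype's *other* allele (dosage := 2 - dosage).
    Strand-ambiguous palindromic SNPs and irreconcilable allele pairs are
    dropped with a warning.
    """
    tab = sumstats.table.set_index("id")
    kept, betas, flips = [], [], []
    n_pal = n_mismatch = 0
    gsnps = genos.snps.set_index(genos.snps["id"].astype(str))
    for s in map(str, snp_ids):
        row = tab.loc[s]
        ga1 = str(gsnps.loc[s, "a1"]).upper()
        ga2 = str(gsnps.loc[s, "a2"]).upper()
        if (row["a1"], row["a2"]) in _PALINDROMIC:
            n_pal += 1
            continue
        if (row["a1"], row["a2"]) == (ga1, ga2):
            flip = False
        elif (row["a1"], row["a2"]) == (ga2, ga1):
            flip = True
        else:
            n_mismatch += 1
            continue
        kept.append(s)
        betas.append(float(row["beta"]))
        flips.append(flip)
    if n_pal:
        logger.warning("dropped %d strand-ambiguous palindromic SNPs", n_pal)
    if n_mismatch:
        logger.warning("dropped %d SNPs with irreconcilable alleles", n_mismatch)
    return kept, np.asarray(betas), np.asarray(flips, dtype=bool)


def _effect_dosages(genos: GenotypeMatrix, kept: list[str], flips: np.ndarray) -> np.ndarray:
    """Effect-allele dosages with allele flips applied and missing values
    imputed as twice the effect-allele frequency of non-missing individuals."""
    D = genos.columns(kept).copy()
    if len(kept):
        D[:, flips] = 2.0 - D[:, flips]
        col_mean = np.nanmean(D, axis=0)  # = 2 * effect-allele frequency
        nan_cols = np.isnan(col_mean)
        col_mean[nan_cols] = 0.0
        idx = np.where(np.isnan(D))
        D[idx] = col_mean[idx[1]]
    return D


def score(genos: GenotypeMatrix, sumstats: SumStats, snp_ids) -> np.ndarray:
    """Raw polygenic score sum(beta_j * dosage_ij) over the given SNPs."""
    kept, betas, flips = _harmonize(genos, sumstats, snp_ids)
    if not kept:
        return np.zeros(genos.n_individuals)
    D = _effect_dosages(genos, kept, flips)
    return D @ betas


def score_matrix(
    genos: GenotypeMatrix,
    sumstats: SumStats,
    clumped_snps,
    grid: ThresholdGrid,
    standardize: bool = True,
) -> ScoreMatrix:
    """Score every threshold of the grid with nested SNP subsets.

    Column k of the result uses exactly the clumped SNPs with p <= t_k.
    SNP contributions are accumulated once in p-value order, so nestedness
    and count monotonicity hold by construction.  With ``standardize`` each
    column is z-scored across individuals; zero-SNP or zero-variance
    columns are left all-zero and flagged degenerate.
    """
    kept, betas, flips = _harmonize(genos, sumstats, clumped_snps)
    n = genos.n_individuals
    K = len(grid)
    if not kept:
        sm = ScoreMatrix(
            individuals=list(genos.individuals), thresholds=grid,
            scores=np.zeros((n, K)), snp_counts=np.zeros(K, dtype=int),
            standardized=standardize,
            degenerate=np.ones(K, dtype=bool),
        )
        return sm

    tab = sumstats.table.set_index("id").loc[kept]
    p = tab["p"].to_numpy(dtype=float)
    order = np.lexsort((np.asarray(kept), tab["bp"].to_numpy(), tab["chrom"].to_numpy(), p))
    kept_sorted = [kept[i] for i in order]
    D = _effect_dosages(genos, kept_sorted, flips[order])
    contrib = D * betas[order]
    cum = np.cumsum(contrib, axis=1)

    counts = np.searchsorted(p[order], grid.thresholds, side="right")
    scores = np.zeros((n, K))
    nonzero = counts > 0
    scores[:, nonzero] = cum[:, counts[nonzero] - 1]

    degenerate = ~nonzero
    if standardize:
        mu = scores.mean(axis=0)
        sd = scores.std(axis=0)
        degenerate = degenerate | (sd <= 0)
        ok = ~degenerate
        scores[:, ok] = (scores[:, ok] - mu[ok]) / sd[ok]
        scores[:, degenerate] = 0.0
    return ScoreMatrix(
        individuals=list(genos.individuals),
        thresholds=grid,
        scores=scores,
        snp_counts=counts.astype(int),
        standardized=standardize,
        degenerate=degenerate,
        snp_order=kept_sorted,
    )


# ------------------------------------------------------- threshold selection

def _residual_projector(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Orthonormal basis Q of the covariate space (with intercept)."""
    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    Q, _ = np.linalg.qr(C)
    return Q


def _linear_abs_t(S_res: np.ndarray, y_res: np.ndarray, df: int) -> np.ndarray:
    """|t| of the score coefficient for each residualized score column.

    Uses the partial-correlation identity t = r*sqrt(df)/sqrt(1-r^2), which
    equals the OLS Wald t of the score term in y ~ score + covariates.
    """
    s_norm = np.linalg.norm(S_res, axis=0)
    y_norm = np.linalg.norm(y_res)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (S_res.T @ y_res) / (s_norm * y_norm)
    r = np.clip(np.nan_to_num(r, nan=0.0), -1 + 1e-15, 1 - 1e-15)
    return np.abs(r) * np.sqrt(df) / np.sqrt(1 - r**2)


def select_threshold(
    sm: ScoreMatrix,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    B: int = 1000,
    seed: int | None = 0,
    family: str = "auto",
) -> ThresholdSelection:
    """Pick the threshold maximising the score coefficient's |Wald stat|.

    Parameters
    ----------
    sm
        Score matrix over the threshold grid (degenerate columns ignored).
    phenotype
        Outcome vector; ``family='auto'`` treats a {0,1}-valued vector as
        binary (logistic model), anything else as continuous (linear).
    covariates
        Optional n x c covariate matrix, held fixed under permutation.
    B
        Number of phenotype-row permutations for the family-wise empirical
        p-value; ``B=0`` skips the permutation test (empirical_p None).
    seed
        RNG seed for the permutations.

    The empirical p is ``(1 + #{b : max_k |t|_bk >= max_k |t|_k}) / (B+1)``,
    counting the observed statistic once (so it lies in [1/(B+1), 1]).
    Ties in the best statistic resolve to the smallest threshold.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if n != len(sm.individuals):
        raise ValueError("phenotype length does not match score matrix")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    if family == "auto":
        family = "binary" if set(np.unique(y)) <= {0.0, 1.0} else "linear"
    usable = ~sm.degenerate
    if not usable.any():
        raise ValueError("no usable (non-degenerate) score columns")
    S = sm.scores[:, usable]
    thresholds = sm.thresholds.thresholds[usable]
    n_cov = 0
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        n_cov = covariates.shape[1]

    rng = np.random.default_rng(seed)

    if family == "linear":
        Q = _residual_projector(covariates, n)
        df = n - n_cov - 2
        S_res = S - Q @ (Q.T @ S)
        y_res = y - Q @ (Q.T @ y)
        stats_obs = _linear_abs_t(S_res, y_res, df)
        best = int(np.argmax(stats_obs))  # argmax takes the smallest threshold on ties
        emp_p = None
        if B >= 1:
            perms = np.empty((n, B))
            for b in range(B):
                perms[:, b] = y[rng.permutation(n)]
            P_res = perms - Q @ (Q.T @ perms)
            s_norm = np.linalg.norm(S_res, axis=0)
            p_norm = np.linalg.norm(P_res, axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                R = (S_res.T @ P_res) / np.outer(s_norm, p_norm)
            R = np.clip(np.nan_to_num(R, nan=0.0), -1 + 1e-15, 1 - 1e-15)
            T = np.abs(R) * np.sqrt(df) / np.sqrt(1 - R**2)
            max_perm = T.max(axis=0)
            obs = stats_obs[best]
            emp_p = (1 + np.sum(max_perm >= obs)) / (B + 1)
    elif family == "binary":
        stats_obs = np.array([_logit_abs_z(S[:, k], y, covariates) for k in range(S.shape[1])])
        best = int(np.argmax(stats_obs))
        emp_p = None
        if B >= 1:
            obs = stats_obs[best]
            count = 0
            for _ in range(B):
                yp = y[rng.permutation(n)]
                m = max(_logit_abs_z(S[:, k], yp, covariates) for k in range(S.shape[1]))
                count += m >= obs
            emp_p = (1 + count) / (B + 1)
    else:
        raise ValueError(f"unknown family {family!r}")

    full_stats = np.zeros(len(sm.thresholds))
    full_stats[usable] = stats_obs
    return ThresholdSelection(
        best_threshold=float(thresholds[best]),
        best_fit_statistic=float(stats_obs[best]),
        empirical_p=emp_p,
        n_permutations=B,
        seed=seed,
        statistics=full_stats,
    )


def _logit_abs_z(s: np.ndarray, y: np.ndarray, covariates: np.ndarray | None) -> float:
    import statsmodels.api as smapi

    X = np.column_stack([np.ones(len(y)), s]) if covariates is None else \
        np.column_stack([np.ones(len(y)), s, covariates])
    try:
        fit = smapi.Logit(y, X).fit(disp=0, maxiter=100)
        return float(np.abs(fit.params[1] / fit.bse[1]))
    except Exception:  # separation / non-convergence: no evidence either way
        return 0.0
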