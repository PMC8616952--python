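"""Model/Results facade over the pathway-PGS pipeline.

:class:`PathwayScoreModel` is built from data (genotypes, GWAS summary
statistics, gene annotation, a pathway gene set and a phenotype table);
``fit()`` runs the full pipeline — region construction, SNP assignment,
LD clumping, threshold-grid scoring, permutation threshold selection,
PC-PGS derivation, phenotype coding and clustering, association models
and FDR — and returns a :class:`PathwayScoreResults` carrying estimates,
uncertainties and a ``summary()`` table.  The random-gene-set specificity
test hangs off the results object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assoc, pcpgs, pheno, pgs, regions, specificity
from .regions import GeneSet

logger = logging.getLogger(__name__)

__all__ = ["PathwayScoreModel", "PathwayScoreResults"]

_BINARY_SOCIAL = ("loneliness", "confide", "social_contact", "social_activity")


class PathwayScoreModel:
    """Pathway-restricted polygenic score association model.

    Parameters
    ----------
    genotypes
        Cohort dosages; also serves as the LD reference for clumping.
    sumstats
        GWAS marginal effects supplying the scoring weights.
    gene_annot
        Transcript annotation table (gene, chrom, start, end; 1-based
        closed coordinates).
    pathway
        The gene set defining the pathway.
    phenotypes
        Phenotype table with continuous metabolic variables, raw social
        questionnaire answers, sex, age and (optionally) genetic PCs
        ``gpc1..gpc10``.
    reg_annot
        Optional regulatory-element annotation unioned with transcripts.
    grid
        P-value threshold grid (default: 5e-8 to 1 in steps of 1e-3).
    clump_r2, clump_kb
        Clumping parameters (defaults: r^2 > 0.1 removes, 250 kb window).
    include_genetic_pcs_continuous
        Adjust the linear (continuous-outcome) models for the genetic PCs
        as well; the logistic models always include them.
    """

    def __init__(
        self,
        genotypes: pgs.GenotypeMatrix,
        sumstats: pgs.SumStats,
        gene_annot: pd.DataFrame,
        pathway: GeneSet,
        phenotypes: pd.DataFrame,
        reg_annot: pd.DataFrame | None = None,
        grid: pgs.ThresholdGrid | None = None,
        clump_r2: float = 0.1,
        clump_kb: float = 250.0,
        covariates: tuple[str, ...] = ("sex", "age"),
        n_clusters: int = 3,
        n_components: int = 2,
        include_genetic_pcs_continuous: bool = True,
    ) -> None:
        self.genotypes = genotypes
        self.sumstats = sumstats
        self.gene_annot = gene_annot
        self.pathway = pathway
        self.phenotypes = phenotypes
        self.reg_annot = reg_annot
        self.grid = grid if grid is not None else pgs.make_grid()
        self.clump_r2 = clump_r2
        self.clump_kb = clump_kb
        self.covariates = tuple(covariates)
        self.n_clusters = n_clusters
        self.n_components = n_components
        self.include_genetic_pcs_continuous = include_genetic_pcs_continuous
        self.genetic_pcs = tuple(
            c for c in (f"gpc{k}" for k in range(1, 11)) if c in phenotypes.columns
        )

    @classmethod
    def from_study(cls, study, **kwargs) -> "PathwayScoreModel":
        """Build from a :class:`~pathpgs.synth.StudyData` bundle."""
        return cls(
            genotypes=study.genotypes,
            sumstats=study.sumstats,
            gene_annot=study.gene_annot,
            pathway=study.pathway,
            phenotypes=study.phenotypes,
            **kwargs,
        )

    # ------------------------------------------------------------ pipeline

    def _predictors_for(self, gene_set: GeneSet, strict: bool = True):
        """regions -> SNP assignment -> clumping -> threshold-grid scores.

        Returns (snp_set, clumped_ids, score_matrix) or None when the set
        yields no scorable SNPs (``strict=False``, used by the specificity
        null runs).
        """
        try:
            rset = regions.build_regions(gene_set, self.gene_annot, self.reg_annot)
        except ValueError:
            if strict:
                raise
            return None
        snp_set = regions.assign_snps(
            rset, self.genotypes.snps[["id", "chrom", "bp"]]
        )
        if len(snp_set) == 0:
            if strict:
                raise ValueError(f"no variant maps to gene set {gene_set.name!r}")
            return None
        clumped = pgs.clump(
            self.sumstats, self.genotypes, snp_set,
            r2_max=self.clump_r2, window_kb=self.clump_kb,
        )
        sm = pgs.score_matrix(
            self.genotypes, self.sumstats, clumped, self.grid, standardize=True
        )
        if sm.degenerate.all():
            if strict:
                raise ValueError(f"all score columns degenerate for {gene_set.name!r}")
            return None
        return snp_set, clumped, sm

    def _selection_inputs(self, data: pd.DataFrame, outcome: str):
        cols = [outcome, *self.covariates]
        mask = data[cols].notna().all(axis=1).to_numpy()
        y = data.loc[mask, outcome].to_numpy(dtype=float)
        C = data.loc[mask, list(self.covariates)].to_numpy(dtype=float)
        return mask, y, C

    def _select_and_project(self, sm, mask, y, C, B: int, seed: int | None):
        sub = pgs.ScoreMatrix(
            individuals=[iid for iid, m in zip(sm.individuals, mask) if m],
            thresholds=sm.thresholds,
            scores=sm.scores[mask],
            snp_counts=sm.snp_counts,
            standardized=sm.standardized,
            degenerate=sm.degenerate,
        )
        sel = pgs.select_threshold(sub, y, covariates=C, B=B, seed=seed,
                                   family="linear")
        return sel

    def fit(
        self,
        selection_outcome: str | None = None,
        B: int = 0,
        seed: int = 0,
        outcomes: list[str] | None = None,
        predictors: tuple[str, ...] = ("PGS", "PC1", "PC2"),
    ) -> "PathwayScoreResults":
        """Run the full pipeline and fit the association family.

        Parameters
        ----------
        selection_outcome
            Phenotype the optimal p-value threshold is selected against
            (default: the first cluster's principal component).
        B
            Permutations for the threshold-selection empirical p
            (0 skips the permutation test; the best threshold is still
            chosen by maximal |t|).
        seed
            Seed for the selection permutations.
        outcomes
            Outcome variables to model (default: all cluster PCs, all
            continuous variables and all coded social binaries).
        predictors
            Which derived predictors to model (best-threshold PGS and/or
            the first two PC-PGS components).
        """
        data = self.phenotypes.copy()
        if "loneliness_raw" in data.columns:
            data = pheno.code_social_variables(data)

        assignment = pheno.cluster_phenotypes(data, n_clusters=self.n_clusters)
        cpcs = pheno.cluster_pcs(data, assignment)
        data = pd.concat([data, cpcs.scores], axis=1)

        if selection_outcome is None:
            selection_outcome = cpcs.scores.columns[0]

        snp_set, clumped, sm = self._predictors_for(self.pathway, strict=True)
        mask, y_sel, C_sel = self._selection_inputs(data, selection_outcome)
        selection = self._select_and_project(sm, mask, y_sel, C_sel, B, seed)
        data["PGS"] = sm.column(selection.best_threshold)

        pc = None
        if {"PC1", "PC2"} & set(predictors):
            pc = pcpgs.fit_pc_pgs(sm, n_components=self.n_components)
            for j in range(pc.n_components):
                data[f"PC{j + 1}"] = pc.pc_scores[:, j]

        binaries = [b for b in _BINARY_SOCIAL if b in data.columns]
        chi2_rows = []
        dependent: dict[str, list[str]] = {b: [] for b in binaries}
        for i, a in enumerate(binaries):
            for b in binaries[i + 1:]:
                try:
                    stat, p = assoc.chi2_independence(data[a], data[b])
                except ValueError:
                    continue
                chi2_rows.append({"a": a, "b": b, "chi2": stat, "p": p})
                if p < 0.05:
                    dependent[a].append(b)
                    dependent[b].append(a)

        if outcomes is None:
            cont_vars = [v for v in pheno.CONTINUOUS_VARIABLES if v in data.columns]
            outcomes = list(cpcs.scores.columns) + cont_vars + binaries

        gpcs = self.genetic_pcs
        results: list[assoc.AssociationResult] = []
        for outcome in outcomes:
            is_binary = outcome in binaries
            if is_binary:
                covs = self.covariates + gpcs
                partners = tuple(dependent.get(outcome, ()))
            else:
                covs = self.covariates + (
                    gpcs if self.include_genetic_pcs_continuous else ()
                )
                partners = tuple(
                    v for v in assignment.labels
                    if outcome in assignment.labels
                    and assignment.labels[v] == assignment.labels[outcome]
                    and v != outcome
                )
            for predictor in predictors:
                if predictor not in data.columns:
                    continue
                spec = assoc.ModelSpec(
                    outcome=outcome,
                    outcome_kind="binary" if is_binary else "continuous",
                    predictor=predictor,
                    covariates=covs,
                    interactions=partners,
                )
                try:
                    results.append(assoc.fit_model(spec, data))
                except ValueError as exc:
                    logger.warning("skipping model %s ~ %s: %s",
                                   outcome, predictor, exc)
        assoc.fdr_adjust(results)

        return PathwayScoreResults(
            model=self,
            data=data,
            cluster_assignment=assignment,
            cluster_pcs=cpcs,
            snp_set=snp_set,
            clumped_snps=clumped,
            score_matrix=sm,
            selection=selection,
            pc_pgs=pc,
            associations=results,
            chi2_table=pd.DataFrame(chi2_rows),
            selection_outcome=selection_outcome,
        )


@dataclass
class PathwayScoreResults:
    """Fitted pipeline state: estimates, uncertainties and diagnostics."""

    model: PathwayScoreModel
    data: pd.DataFrame
    cluster_assignment: pheno.ClusterAssignment
    cluster_pcs: pheno.ClusterPcs
    snp_set: regions.SnpSet
    clumped_snps: list[str]
    score_matrix: pgs.ScoreMatrix
    selection: pgs.ThresholdSelection
    pc_pgs: pcpgs.PcPgs | None
    associations: list[assoc.AssociationResult]
    chi2_table: pd.DataFrame
    selection_outcome: str

    @property
    def table(self) -> pd.DataFrame:
        return assoc.results_table(self.associations)

    def get(self, outcome: str, predictor: str) -> assoc.AssociationResult:
        for r in self.associations:
            if r.spec.outcome == outcome and r.spec.predictor == predictor:
                return r
        raise KeyError(f"no fitted model for {outcome} ~ {predictor}")

    # --------------------------------------------------------- specificity

    def specificity(
        self,
        outcome: str,
        predictor: str = "PGS",
        n_sets: int = 100,
        seed: int = 0,
        match: str = "genes",
    ) -> tuple[specificity.NullDistribution, specificity.SpecificityVerdict]:
        """Rank the fitted effect against random gene-set PGS models.

        Draws ``n_sets`` random gene sets of equal gene count (or, with
        ``match='snps'``, sets whose assigned SNP count is within 10% of
        the pathway's), reruns the identical pipeline and model for each,
        and flags the observed beta when it falls in the top or bottom 5%
        of the null effect-size distribution.
        """
        obs = self.get(outcome, predictor)
        m = self.model
        universe = sorted(set(m.gene_annot["gene"].astype(str).str.upper()))
        size = len(m.pathway)
        sets = specificity.sample_gene_sets(
            universe, size, n=n_sets, exclude=m.pathway, seed=seed,
            exclude_genes=False,
        )
        if match == "snps":
            sets = self._match_snp_counts(sets, universe, size, seed)

        mask, y_sel, C_sel = m._selection_inputs(self.data, self.selection_outcome)
        spec = obs.spec
        seen = {frozenset(s.genes) for s in sets} | {frozenset(m.pathway.genes)}
        rng_extra = np.random.default_rng(None if seed is None else seed + 1)

        def runner(gene_set: GeneSet) -> float | None:
            built = m._predictors_for(gene_set, strict=False)
            if built is None:
                return None
            _, _, null_sm = built
            if predictor == "PGS":
                sel = m._select_and_project(null_sm, mask, y_sel, C_sel, 0, None)
                column = null_sm.column(sel.best_threshold)
            else:
                try:
                    null_pc = pcpgs.fit_pc_pgs(null_sm, n_components=m.n_components)
                except ValueError:
                    return None
                j = int(predictor[2:]) - 1
                if j >= null_pc.n_components:
                    return None
                column = null_pc.pc_scores[:, j]
            null_data = self.data.copy()
            null_data[predictor] = column
            return assoc.fit_model(spec, null_data).beta

        def resampler(_i: int) -> GeneSet:
            while True:
                draw = tuple(rng_extra.choice(universe, size=size, replace=False))
                key = frozenset(draw)
                if key not in seen:
                    seen.add(key)
                    return GeneSet(name=f"random_extra_{_i:03d}", genes=draw)

        null = specificity.null_effects(sets, runner, resampler, seed=seed)
        return null, specificity.verdict(obs.beta, null)

    def _match_snp_counts(self, sets, universe, size, seed):
        """Keep redrawing sets whose assigned SNP count strays >10% from
        the pathway's; preserves the number of sets."""
        target = len(self.snp_set)
        rng = np.random.default_rng(None if seed is None else seed + 7)
        seen = {frozenset(s.genes) for s in sets} | {frozenset(self.model.pathway.genes)}
        out = []
        for gs in sets:
            current = gs
            for _ in range(200):
                built = self.model._predictors_for(current, strict=False)
                if built is not None and abs(len(built[0]) - target) <= 0.1 * target:
                    break
                while True:
                    draw = tuple(rng.choice(universe, size=size, replace=False))
                    if frozenset(draw) not in seen:
                        seen.add(frozenset(draw))
                        current = GeneSet(name=current.name, genes=draw)
                        break
            out.append(current)
        return out

    # ------------------------------------------------------------- summary

    def summary(self) -> str:
        m = self.model
        lines = [
            "Pathway polygenic score analysis",
            "=" * 48,
            f"Pathway: {m.pathway.name} "
            f"({len(m.pathway)} genes, {len(self.snp_set)} SNPs assigned, "
            f"{len(self.clumped_snps)} after clumping)",
            f"Threshold grid: {len(m.grid)} cutoffs in "
            f"[{m.grid.thresholds[0]:.3g}, {m.grid.thresholds[-1]:.3g}]",
            f"Best threshold: p <= {self.selection.best_threshold:.4g} "
            f"({int(self.score_matrix.snp_counts[np.argmin(np.abs(self.score_matrix.thresholds.thresholds - self.selection.best_threshold))])} SNPs, "
            f"|t| = {self.selection.best_fit_statistic:.2f}, "
            f"selected against {self.selection_outcome!r})",
        ]
        if self.selection.empirical_p is not None:
            lines.append(
                f"Selection empirical p: {self.selection.empirical_p:.4g} "
                f"({self.selection.n_permutations} permutations)"
            )
        if self.pc_pgs is not None:
            fr = self.pc_pgs.explained_variance_fraction
            lines.append(
                "PC-PGS explained variance: "
                + ", ".join(f"PC{j + 1} {100 * fr[j]:.1f}%" for j in range(len(fr)))
            )
        lines.append("Phenotype clusters:")
        for label, members in enumerate(self.cluster_assignment.clusters(), start=1):
            name = f"cluster{label}_pc1"
            frac = self.cluster_pcs.explained_fraction.get(name)
            extra = f" (PC1 explains {100 * frac:.0f}%)" if frac else ""
            lines.append(f"  {label}: {', '.join(members)}{extra}")
        lines.append("")
        with pd.option_context("display.width", 120, "display.max_columns", 20):
            lines.append(
                self.table[
                    ["outcome", "kind", "predictor", "beta", "se",
                     "p_raw", "p_fdr", "n_used"]
                ].to_string(index=False, float_format=lambda v: f"{v:.4g}")
            )
        return "\n".join(lines)
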