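"""Covariate-adjusted association models with interactions and FDR.

Continuous outcomes are fitted by ordinary least squares, binary outcomes
by maximum-likelihood logistic regression; either way the model is

    outcome ~ predictor + covariates + partners + predictor x partners

with the predictor a z-scored polygenic score (or PC-PGS component), the
covariates sex, age and optionally the top genetic principal components,
and the interaction partners the phenotypes that cluster together with the
outcome (or, for binaries, the dependent binaries by the chi-square test).
Wald tests give the predictor and interaction p-values; Benjamini-Hochberg
FDR is applied once across the full family of fitted models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "AssociationResult",
    "fit_model",
    "chi2_independence",
    "fdr_adjust",
    "results_table",
]


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one association model."""

    outcome: str
    outcome_kind: str  # "continuous" | "binary"
    predictor: str
    covariates: tuple[str, ...] = ("sex", "age")
    interactions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.outcome_kind not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome kind {self.outcome_kind!r}")
        if not self.covariates:
            raise ValueError("covariate set must be non-empty")
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "interactions", tuple(self.interactions))


@dataclass
class AssociationResult:
    """Fitted predictor effect with raw and (later) FDR-adjusted p."""

    spec: ModelSpec
    beta: float
    se: float
    p_raw: float
    n_used: int
    p_fdr: float | None = None
    interaction_terms: list[tuple[str, float, float]] = field(default_factory=list)


def _design(spec: ModelSpec, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    cols = [spec.outcome, spec.predictor, *spec.covariates, *spec.interactions]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"data lacks columns {missing}")
    sub = data[list(dict.fromkeys(cols))].dropna()
    n = len(sub)
    names = ["const", spec.predictor, *spec.covariates]
    X = [np.ones(n), sub[spec.predictor].to_numpy(dtype=float)]
    X += [sub[c].to_numpy(dtype=float) for c in spec.covariates]
    for partner in spec.interactions:
        X.append(sub[partner].to_numpy(dtype=float))
        names.append(partner)
    for partner in spec.interactions:
        X.append(sub[spec.predictor].to_numpy(dtype=float) * sub[partner].to_numpy(dtype=float))
        names.append(f"{spec.predictor}:{partner}")
    Xm = np.column_stack(X)
    y = sub[spec.outcome].to_numpy(dtype=float)
    n_params = Xm.shape[1]
    if n < n_params + 5:
        raise ValueError(
            f"model {spec.outcome} ~ {spec.predictor}: only {n} complete cases "
            f"for {n_params} parameters"
        )
    rank = np.linalg.matrix_rank(Xm)
    if rank < n_params:
        # name the collinear columns via QR pivoting on the diagonal of R
        _, R = np.linalg.qr(Xm)
        bad = [names[j] for j in range(n_params) if abs(R[j, j]) < 1e-10 * abs(R[0, 0])]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return Xm, y, names, n


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> AssociationResult:
    """Fit one association model on complete cases.

    Returns the predictor's coefficient, standard error and Wald p
    (``p_fdr`` unset); interaction-term estimates ride along.  Perfect
    separation in the logistic model and rank-deficient designs raise.
    """
    Xm, y, names, n = _design(spec, data)
    if spec.outcome_kind == "continuous":
        fit = sm.OLS(y, Xm).fit()
    else:
        uniq = set(np.unique(y))
        if not uniq <= {0.0, 1.0}:
            raise ValueError(f"binary outcome {spec.outcome!r} has values {sorted(uniq)}")
        with np.errstate(all="ignore"):
            try:
                fit = sm.Logit(y, Xm).fit(disp=0, maxiter=200)
            except Exception as exc:  # statsmodels PerfectSeparationError etc.
                raise ValueError(
                    f"logistic model for {spec.outcome!r} failed: {exc}"
                ) from exc
        if not np.all(np.isfinite(fit.bse)):
            raise ValueError(
                f"logistic model for {spec.outcome!r}: non-finite standard errors "
                "(possible separation)"
            )
    j = names.index(spec.predictor)
    interactions = [
        (nm, float(fit.params[i]), float(fit.pvalues[i]))
        for i, nm in enumerate(names)
        if ":" in nm
    ]
    return AssociationResult(
        spec=spec,
        beta=float(fit.params[j]),
        se=float(fit.bse[j]),
        p_raw=float(fit.pvalues[j]),
        n_used=n,
        interaction_terms=interactions,
    )


def chi2_independence(a, b) -> tuple[float, float]:
    """Pearson chi-square test of independence of two binary vectors.

    Computed on the 2x2 table of complete pairs, without continuity
    correction (1 df).  All four margins must be positive.
    """
    a = pd.Series(a, dtype=float)
    b = pd.Series(b, dtype=float)
    ok = a.notna() & b.notna()
    table = pd.crosstab(a[ok], b[ok])
    if table.shape != (2, 2):
        raise ValueError(f"need a 2x2 table, got shape {table.shape}")
    arr = table.to_numpy()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-square test undefined: zero margin")
    chi2, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    assert dof == 1
    return float(chi2), float(p)


def fdr_adjust(results: list[AssociationResult]) -> list[AssociationResult]:
    """Benjamini-Hochberg adjustment across one family of fitted models.

    Sets ``p_fdr`` in place on every result and returns the list.
    """
    if not results:
        raise ValueError("no results to adjust")
    p = np.array([r.p_raw for r in results])
    _, q, _, _ = multipletests(p, method="fdr_bh")
    for r, qi in zip(results, q):
        r.p_fdr = float(qi)
    return results


def results_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Flatten association results into a tidy frame."""
    rows = []
    for r in results:
        rows.append(
            {
                "outcome": r.spec.outcome,
                "kind": r.spec.outcome_kind,
                "predictor": r.spec.predictor,
                "beta": r.beta,
                "se": r.se,
                "p_raw": r.p_raw,
                "p_fdr": r.p_fdr,
                "n_used": r.n_used,
                "interactions": "; ".join(
                    f"{nm}: beta={b:.4g}, p={p:.3g}" for nm, b, p in r.interaction_terms
                ),
            }
        )
    return pd.DataFrame(rows)
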