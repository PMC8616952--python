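"""Principal components over the polygenic-score threshold grid (PC-PGS).

Scores computed at many p-value thresholds are strongly inter-correlated;
a PCA across the threshold columns summarises them into a few components.
PC1 reweights the variants so as to capture maximum variation over the
whole threshold range, independently of any outcome, and PC2 captures the
dominant remaining contrast (typically low- vs high-threshold scores).
Using these components as predictors avoids picking a threshold with the
outcome in hand and thereby helps control type-1 error.

Columns are centered and scaled to unit variance before the eigen-
decomposition (correlation-matrix PCA); since score columns are already
z-scored this coincides with covariance PCA, but scaling is enforced for
safety.  Sign convention: each loading vector is flipped so that its sum
is positive, making PC1 correlate positively with the mean score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .pgs import ScoreMatrix

logger = logging.getLogger(__name__)

__all__ = ["PcPgs", "fit_pc_pgs"]


@dataclass
class PcPgs:
    """Per-individual PC scores over the threshold grid.

    ``pc_scores`` are z-scored (ready for downstream modeling);
    ``raw_pc_scores`` keeps the unscaled projections.  ``loadings`` has one
    row per usable threshold column (see ``kept_thresholds``).
    """

    pc_scores: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    kept_thresholds: np.ndarray
    raw_pc_scores: np.ndarray = field(default=None, repr=False)

    @property
    def n_components(self) -> int:
        return self.pc_scores.shape[1]


def fit_pc_pgs(sm: ScoreMatrix, n_components: int = 2) -> PcPgs:
    """PCA on the standardized threshold-score matrix.

    Degenerate (all-zero / zero-variance) columns are removed first and
    logged; at least two usable columns are required.  Components are the
    leading right singular vectors of the column-standardized matrix;
    explained fractions are eigenvalues of the correlation matrix divided
    by their total.
    """
    usable = ~sm.degenerate
    X = sm.scores[:, usable]
    sd = X.std(axis=0)
    keep = sd > 0
    if keep.sum() < usable.sum():
        logger.info("dropping %d zero-variance score columns before PCA",
                    int(usable.sum() - keep.sum()))
    X = X[:, keep]
    thresholds = sm.thresholds.thresholds[usable][keep]
    if X.shape[1] < 2:
        raise ValueError(
            f"need >= 2 usable score columns for PCA, have {X.shape[1]}"
        )
    n = X.shape[0]
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    U, S, Vt = np.linalg.svd(Z / np.sqrt(n), full_matrices=False)
    eigvals = S**2
    frac = eigvals / eigvals.sum()

    k = min(n_components, len(eigvals))
    loadings = Vt[:k].T.copy()
    # sign convention: loading sums positive
    for j in range(k):
        s = loadings[:, j].sum()
        if s < 0:
            loadings[:, j] = -loadings[:, j]
    raw = Z @ loadings
    sds = raw.std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    pc_scores = (raw - raw.mean(axis=0)) / sds
    return PcPgs(
        pc_scores=pc_scores,
        loadings=loadings,
        explained_variance_fraction=frac[:k],
        kept_thresholds=thresholds,
        raw_pc_scores=raw,
    )
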