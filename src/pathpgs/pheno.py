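"""Phenotype coding and clustering for biobank-style questionnaire data.

Four binary social variables are derived from raw questionnaire answers:

* loneliness — "Do you often feel lonely?": yes -> 1, no -> 0;
* ability to confide — responses from "almost daily" down to "about once a
  month" -> 0, "once every few months" down to "never" -> 1;
* social contact — living alone with never/no visits from friends or
  family -> 1; not living alone, or visited at least weekly -> 0;
  combinations the rules do not cover (e.g. lives alone, monthly visits)
  are treated as missing rather than guessed;
* social activity — habitual participation in at least one listed group
  activity -> 0, none -> 1.

Continuous metabolic variables are grouped by complete-linkage hierarchical
clustering on the distance 1 - |Pearson r| (pairwise-complete), and each
cluster is summarised by the first principal component of its z-scored
members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING",
    "code_loneliness",
    "code_confide",
    "code_social_contact",
    "code_social_activity",
    "code_social_variables",
    "ClusterAssignment",
    "ClusterPcs",
    "cluster_phenotypes",
    "cluster_pcs",
    "CONTINUOUS_VARIABLES",
]

MISSING = float("nan")

#: canonical continuous variable names produced by the simulator and used
#: by the clustering default
CONTINUOUS_VARIABLES = [
    "bmi",
    "bmi_impedance",
    "whole_body_fat_pct",
    "trunk_fat_pct",
    "energy_kj",
    "sugar_g",
    "food_weight_g",
    "grip_strength",
    "waist_hip_ratio",
]

_CONFIDE_LOW = {  # "almost daily" .. "about once a month" -> 0
    "almost daily",
    "2-4 times a week",
    "about once a week",
    "about once a month",
}
_CONFIDE_HIGH = {  # "once every few months" .. "never" -> 1
    "once every few months",
    "never or almost never",
    "never",
}
_NONRESPONSE = {"do not know", "prefer not to answer", "", "nan", "none"}

_VISIT_WEEKLY = {"almost daily", "2-4 times a week", "about once a week"}
_VISIT_NEVER = {"never or almost never", "never",
                "no friends/family outside household"}

_ACTIVITIES = {
    "sports club or gym",
    "pub or social club",
    "religious group",
    "adult education class",
    "other group activity",
}
_ACTIVITY_NONE = {"none of the above", "none", ""}


def _norm(answer) -> str | None:
    if answer is None or (isinstance(answer, float) and np.isnan(answer)):
        return None
    return str(answer).strip().lower()


def code_loneliness(answer) -> float:
    """'yes' -> 1, 'no' -> 0, anything else -> missing (NaN)."""
    a = _norm(answer)
    if a == "yes":
        return 1.0
    if a == "no":
        return 0.0
    return MISSING


def code_confide(freq) -> float:
    """Frequency of being able to confide in someone close.

    Responses from "almost daily" to "about once a month" code 0, from
    "once every few months" to "never" code 1.  Non-response markers and
    missing values code missing; an unrecognised category raises.
    """
    a = _norm(freq)
    if a is None or a in _NONRESPONSE:
        return MISSING
    if a in _CONFIDE_LOW:
        return 0.0
    if a in _CONFIDE_HIGH:
        return 1.0
    valid = sorted(_CONFIDE_LOW | _CONFIDE_HIGH)
    raise ValueError(f"unknown confide category {freq!r}; valid: {valid}")


def code_social_contact(household_n, visit_freq) -> float:
    """Composite isolation indicator from household size and visit frequency.

    Lives alone and never visited (or no friends/family who visit) -> 1;
    does not live alone, or visited at least weekly -> 0; combinations not
    covered by either rule -> missing.
    """
    visit = _norm(visit_freq)
    n = None
    if household_n is not None and not (
        isinstance(household_n, float) and np.isnan(household_n)
    ):
        n = int(household_n)
        if n < 1:
            raise ValueError(f"household size must be >= 1, got {n}")
    if n is not None and n == 1 and visit in _VISIT_NEVER:
        return 1.0
    if (n is not None and n > 1) or (visit in _VISIT_WEEKLY):
        return 0.0
    return MISSING


def code_social_activity(selections) -> float:
    """At least one weekly group activity -> 0, none -> 1, unknown -> missing.

    ``selections`` may be an iterable of option strings or a single
    string with options separated by '|' .
    """
    if selections is None or (
        isinstance(selections, float) and np.isnan(selections)
    ):
        return MISSING
    if isinstance(selections, str):
        items = [s for s in selections.split("|")]
    else:
        items = list(selections)
    normed = {_norm(s) for s in items if _norm(s) is not None}
    unknown = normed - _ACTIVITIES - _ACTIVITY_NONE - _NONRESPONSE
    if unknown:
        raise ValueError(f"unknown activity options {sorted(unknown)}")
    if normed & _ACTIVITIES:
        return 0.0
    if not normed or normed & _ACTIVITY_NONE:
        return 1.0
    return MISSING  # only non-response markers selected


def code_social_variables(table: pd.DataFrame) -> pd.DataFrame:
    """Code the four binary social variables from raw questionnaire columns.

    Expects columns ``loneliness_raw``, ``confide_raw``, ``household_n``,
    ``visit_freq_raw``, ``activities_raw``; returns a copy with coded
    columns ``loneliness``, ``confide``, ``social_contact``,
    ``social_activity`` (values 0/1/NaN).
    """
    out = table.copy()
    out["loneliness"] = table["loneliness_raw"].map(code_loneliness)
    out["confide"] = table["confide_raw"].map(code_confide)
    out["social_contact"] = [
        code_social_contact(h, v)
        for h, v in zip(table["household_n"], table["visit_freq_raw"])
    ]
    out["social_activity"] = table["activities_raw"].map(code_social_activity)
    return out


@dataclass
class ClusterAssignment:
    """Variable -> cluster label mapping from the dendrogram cut."""

    labels: dict[str, int]
    n_clusters: int
    linkage_height: float
    linkage_matrix: np.ndarray = None

    def members(self, label: int) -> list[str]:
        return [v for v, c in self.labels.items() if c == label]

    def clusters(self) -> list[list[str]]:
        return [self.members(c) for c in range(1, self.n_clusters + 1)]


@dataclass
class ClusterPcs:
    """First principal component per cluster."""

    scores: pd.DataFrame  # one column per cluster, index = table index
    explained_fraction: dict[str, float]


def cluster_phenotypes(
    table: pd.DataFrame,
    n_clusters: int = 3,
    variables: list[str] | None = None,
    absolute: bool = True,
) -> ClusterAssignment:
    """Complete-linkage hierarchical clustering of continuous variables.

    Distance is 1 - |Pearson r| (``absolute=False`` uses 1 - r) computed on
    pairwise-complete observations; the dendrogram is cut to ``n_clusters``.
    Cluster labels are deterministic: cluster 1 contains the first variable
    in column order, and so on.
    """
    if variables is None:
        variables = [v for v in CONTINUOUS_VARIABLES if v in table.columns]
    if len(variables) < 2:
        raise ValueError("need at least two continuous variables to cluster")
    sub = table[variables].astype(float)
    for v in variables:
        x = sub[v].dropna()
        if len(x) == 0 or x.std() == 0:
            raise ValueError(f"variable {v!r} has zero variance")
    counts = sub.notna().astype(int).T @ sub.notna().astype(int)
    if (counts.to_numpy()[~np.eye(len(variables), dtype=bool)] < 3).any():
        raise ValueError("need >= 3 pairwise-complete observations per variable pair")
    corr = sub.corr(method="pearson", min_periods=3).to_numpy()
    dist = 1 - (np.abs(corr) if absolute else corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0, None)
    Z = linkage(squareform(dist, checks=False), method="complete")
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")

    # relabel so labels follow first-member order
    relabel: dict[int, int] = {}
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
    labels = {v: relabel[r] for v, r in zip(variables, raw)}
    k = len(relabel)
    heights = Z[:, 2]
    cut = float(heights[-(n_clusters - 1) - 1]) if n_clusters > 1 and len(heights) >= n_clusters else float(heights[-1]) if len(heights) else 0.0
    return ClusterAssignment(labels=labels, n_clusters=k,
                             linkage_height=cut, linkage_matrix=Z)


def cluster_pcs(table: pd.DataFrame, assignment: ClusterAssignment) -> ClusterPcs:
    """First principal component of each cluster's z-scored members.

    Singleton clusters pass the z-scored variable through with explained
    fraction 1.  Rows with a missing member value get a missing PC score
    (complete-case within cluster).  The PC sign is fixed so it correlates
    positively with the cluster's first member variable.
    """
    scores = {}
    fractions = {}
    for label in range(1, assignment.n_clusters + 1):
        members = assignment.members(label)
        name = f"cluster{label}_pc1"
        sub = table[members].astype(float)
        complete = sub.dropna()
        Z = (complete - complete.mean()) / complete.std(ddof=0)
        if len(members) == 1:
            pc = Z.iloc[:, 0].to_numpy()
            fractions[name] = 1.0
        else:
            M = Z.to_numpy()
            _, S, Vt = np.linalg.svd(M / np.sqrt(len(M)), full_matrices=False)
            eig = S**2
            fractions[name] = float(eig[0] / eig.sum())
            v = Vt[0]
            pc = M @ v
            if np.corrcoef(pc, M[:, 0])[0, 1] < 0:
                pc = -pc
        col = pd.Series(np.nan, index=table.index, name=name)
        col.loc[complete.index] = pc
        scores[name] = col
    return ClusterPcs(scores=pd.DataFrame(scores), explained_fraction=fractions)
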