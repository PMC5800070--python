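"""Phenotype association statistics for CNV carrier status.

Single-feature Fisher exact comparisons of carriers vs non-carriers, the
phenotype-pair chi-square matrix (does the *co-occurrence* of two
phenotypes segregate with pathogenic-CNV status?), and the significance
network derived from it, whose highest-degree nodes are the cohort's core
phenotypes.

Phenotype values are True/False/None; None (not assessed) is excluded
from both the numerator and the denominator of every table, so each
feature keeps its own denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import PatientRecord
from .io import PHENOTYPE_PREFIX, cohort_frame

__all__ = [
    "ZeroMarginError",
    "ContingencyTable2x2",
    "fisher_exact_2x2",
    "feature_vs_pcnv",
    "PairAssociationMatrix",
    "pair_matrix",
    "PhenotypeNetwork",
    "build_network",
]


class ZeroMarginError(ValueError):
    """A contingency table has an empty row or column: test undefined."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table; rows = feature present/absent, columns = carrier/non-carrier."""

    a: int  # present & carrier
    b: int  # present & non-carrier
    c: int  # absent & carrier
    d: int  # absent & non-carrier

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)


def fisher_exact_2x2(
    table: ContingencyTable2x2, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Two-sided Fisher exact test; returns (sample odds ratio, p).

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins that are no more probable than the observed one. The
    odds ratio is the unconditional sample estimate ad/bc (infinite when
    bc = 0 with ad > 0).
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    if 0 in table.margins():
        raise ZeroMarginError(f"zero margin in table {table}")
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return table.odds_ratio, float(p)


def chi_square_2x2(
    table: ContingencyTable2x2, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table; returns (statistic, p)."""
    if 0 in table.margins():
        raise ZeroMarginError(f"zero margin in table {table}")
    stat, p, _, expected = stats.chi2_contingency(
        table.as_array(), correction=continuity_correction
    )
    return float(stat), float(p)


CohortLike = Union[pd.DataFrame, Sequence[PatientRecord]]


def _as_frame(cohort: CohortLike) -> pd.DataFrame:
    if isinstance(cohort, pd.DataFrame):
        return cohort
    return cohort_frame(cohort)


def _feature_column(df: pd.DataFrame, feature: str) -> pd.Series:
    col = PHENOTYPE_PREFIX + feature
    if col not in df.columns:
        if feature in df.columns:
            col = feature
        else:
            raise KeyError(f"unknown phenotype feature {feature!r}")
    return df[col].astype(float)


def feature_vs_pcnv(
    cohort: CohortLike, feature: str
) -> tuple[ContingencyTable2x2, float]:
    """Fisher comparison of one feature between carriers and non-carriers.

    Patients with unknown feature status are dropped from both margins;
    the table's total is therefore the feature's own denominator.
    """
    df = _as_frame(cohort)
    values = _feature_column(df, feature)
    carrier = df["pcnv"].astype(bool)
    known = values.notna()
    if not known.any():
        raise ZeroMarginError(f"feature {feature!r} has no assessed patients")
    present = values[known] > 0
    carrier = carrier[known]
    table = ContingencyTable2x2(
        a=int((present & carrier).sum()),
        b=int((present & ~carrier).sum()),
        c=int((~present & carrier).sum()),
        d=int((~present & ~carrier).sum()),
    )
    _, p = fisher_exact_2x2(table)
    return table, p


@dataclass
class PairAssociationMatrix:
    """Symmetric phenotype-pair association matrix.

    ``p[i, j]`` is the chi-square p-value for the 2x2 of the indicator
    "patient shows both feature i and feature j" against carrier status;
    pairs whose table has a zero margin are marked non-evaluable.
    """

    features: list[str]
    p: np.ndarray
    statistic: np.ndarray
    evaluable: np.ndarray
    tables: dict[tuple[str, str], ContingencyTable2x2] = field(default_factory=dict)

    def pair_p(self, a: str, b: str) -> float:
        i, j = self.features.index(a), self.features.index(b)
        return float(self.p[i, j])

    def n_evaluable(self) -> int:
        iu = np.triu_indices(len(self.features), k=1)
        return int(self.evaluable[iu].sum())

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str, float]]:
        out = []
        k = len(self.features)
        for i in range(k):
            for j in range(i + 1, k):
                if self.evaluable[i, j] and self.p[i, j] < alpha:
                    out.append((self.features[i], self.features[j], float(self.p[i, j])))
        return out

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        k = len(self.features)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    {
                        "feature_a": self.features[i],
                        "feature_b": self.features[j],
                        "statistic": float(self.statistic[i, j]),
                        "p": float(self.p[i, j]),
                        "evaluable": bool(self.evaluable[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def pair_matrix(
    cohort: CohortLike,
    features: Sequence[str],
    continuity_correction: bool = False,
    coding: str = "both",
) -> PairAssociationMatrix:
    """Chi-square matrix over all unordered feature pairs.

    ``coding="both"`` (default) tests the A-and-B co-occurrence indicator
    against carrier status. ``coding="three_level"`` is an alternative
    reading that scores both/one/neither as an ordered factor and tests
    the resulting 3x2 table.
    """
    if len(features) < 2:
        raise ValueError("need at least two features")
    if coding not in ("both", "three_level"):
        raise ValueError(f"unknown coding {coding!r}")
    df = _as_frame(cohort)
    carrier = df["pcnv"].astype(bool).to_numpy()
    cols = {f: _feature_column(df, f).to_numpy() for f in features}
    k = len(features)
    p = np.full((k, k), np.nan)
    statistic = np.full((k, k), np.nan)
    evaluable = np.zeros((k, k), dtype=bool)
    tables: dict[tuple[str, str], ContingencyTable2x2] = {}
    for i in range(k):
        for j in range(i + 1, k):
            vi, vj = cols[features[i]], cols[features[j]]
            known = ~(np.isnan(vi) | np.isnan(vj))
            if not known.any():
                continue
            ci = carrier[known]
            if coding == "both":
                co = (vi[known] > 0) & (vj[known] > 0)
                table = ContingencyTable2x2(
                    a=int((co & ci).sum()),
                    b=int((co & ~ci).sum()),
                    c=int((~co & ci).sum()),
                    d=int((~co & ~ci).sum()),
                )
                tables[(features[i], features[j])] = table
                try:
                    stat, pval = chi_square_2x2(table, continuity_correction)
                except ZeroMarginError:
                    continue
            else:
                level = (vi[known] > 0).astype(int) + (vj[known] > 0).astype(int)
                counts = np.zeros((3, 2), dtype=int)
                for lvl in range(3):
                    counts[lvl, 0] = int(((level == lvl) & ci).sum())
                    counts[lvl, 1] = int(((level == lvl) & ~ci).sum())
                counts = counts[counts.sum(axis=1) > 0]
                if counts.shape[0] < 2 or (counts.sum(axis=0) == 0).any():
                    continue
                res = stats.chi2_contingency(counts, correction=False)
                stat, pval = float(res[0]), float(res[1])
            p[i, j] = p[j, i] = pval
            statistic[i, j] = statistic[j, i] = stat
            evaluable[i, j] = evaluable[j, i] = True
    return PairAssociationMatrix(
        features=list(features), p=p, statistic=statistic, evaluable=evaluable,
        tables=tables,
    )


@dataclass
class PhenotypeNetwork:
    graph: nx.Graph
    alpha: float
    core: list[str]

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return sorted(
            (min(u, v), max(u, v), d["p"]) for u, v, d in self.graph.edges(data=True)
        )

    @property
    def connected_features(self) -> list[str]:
        return sorted(n for n, d in self.graph.degree if d > 0)

    @property
    def isolated_features(self) -> list[str]:
        return sorted(n for n, d in self.graph.degree if d == 0)

    def degree(self, node: str) -> int:
        return int(self.graph.degree[node])


def build_network(
    matrix: PairAssociationMatrix,
    alpha: float = 0.05,
    core_rule: str = "max_degree_quartile",
    top_k: int = 4,
) -> PhenotypeNetwork:
    """Significance network: edges where the pair p-value < alpha.

    The core is the most-connected phenotype set: nodes whose degree
    reaches the top quartile of positive degrees (default), or the
    ``top_k`` highest-degree nodes with ties kept.
    """
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(matrix.features)
    for a, b, pval in matrix.significant_pairs(alpha):
        graph.add_edge(a, b, p=pval)
    degrees = {n: d for n, d in graph.degree}
    positive = sorted((d for d in degrees.values() if d > 0), reverse=True)
    core: list[str] = []
    if positive:
        if core_rule == "max_degree_quartile":
            # quartile over the *distinct* positive degrees, rounded up,
            # so a single dominant hub is not diluted by many low-degree
            # nodes; ties at the cut are kept
            cut = float(
                np.quantile(sorted(set(positive)), 0.75, method="higher")
            )
        elif core_rule == "top_k":
            cut = positive[min(top_k, len(positive)) - 1]
        else:
            raise ValueError(f"unknown core rule {core_rule!r}")
        core = sorted(n for n, d in degrees.items() if d > 0 and d >= cut)
    return PhenotypeNetwork(graph=graph, alpha=alpha, core=core)
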