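"""Cheminformatic descriptor cleaning, redundancy reduction and graphical-LASSO network.

Pipeline for the drug side of the analysis:

1. :func:`clean_descriptors` removes descriptors with missing values and
   (near-)constant descriptors.
2. :func:`spearman_reduce` clusters descriptors on 1 - \\|Spearman rho\\| and keeps
   one representative per cluster.
3. :func:`graphical_lasso_network` estimates a sparse Gaussian precision matrix
   over the surviving descriptors; its nonzero off-diagonals are the edges of
   the feature network.
4. :func:`drug_distributions` min-max scales descriptors and normalizes each
   drug to a probability distribution over the feature network's largest
   connected component.  Unlike the cell-line side, no Markov-chain invariant
   measure is applied here: the feature network encodes statistical
   conditional dependence, not mass-action interaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

from .data_io import GeneNetwork, restrict_to_lcc
from .network_measure import MassDistribution

logger = logging.getLogger("drugsense")

__all__ = [
    "FeatureNetwork",
    "ReductionReport",
    "clean_descriptors",
    "spearman_reduce",
    "graphical_lasso_network",
    "select_lambda",
    "scale_descriptors",
    "drug_distribution",
    "drug_distributions",
]

_EDGE_TOL = 1e-8


@dataclass(frozen=True)
class FeatureNetwork:
    """Sparse conditional-dependence network over descriptors.

    Edges are nonzero off-diagonal entries of the estimated precision matrix
    ``precision`` (threshold 1e-8) at penalty ``lam``.
    """

    descriptors: tuple
    precision: np.ndarray
    lam: float
    network: GeneNetwork = field(init=False, compare=False)

    def __post_init__(self):
        theta = np.asarray(self.precision, dtype=float)
        object.__setattr__(self, "precision", theta)
        p = len(self.descriptors)
        if theta.shape != (p, p):
            raise ValueError("precision shape does not match descriptor count")
        graph = nx.Graph()
        graph.add_nodes_from(self.descriptors)
        for i in range(p):
            for j in range(i + 1, p):
                if abs(theta[i, j]) > _EDGE_TOL:
                    graph.add_edge(self.descriptors[i], self.descriptors[j])
        object.__setattr__(self, "network", GeneNetwork(graph))

    @property
    def n_edges(self) -> int:
        return self.network.n_edges


@dataclass(frozen=True)
class ReductionReport:
    """Outcome of Spearman redundancy reduction.

    ``membership`` maps each input descriptor to its cluster id;
    ``representatives`` maps cluster id to the chosen descriptor;
    ``representative_score`` is the representative's average absolute Spearman
    correlation to the other members of its cluster (NaN for singletons).
    """

    membership: dict
    representatives: dict
    representative_score: dict


def clean_descriptors(table: pd.DataFrame, near_constant_frac: float = 0.95) -> pd.DataFrame:
    """Drop descriptors with any missing value or a dominant single value.

    A descriptor is near-constant when its most frequent value occurs in at
    least ``near_constant_frac`` of the drugs (so exactly-constant descriptors
    are always dropped).
    """
    if table.empty:
        raise ValueError("empty descriptor table")
    has_na = table.columns[table.isna().any()]
    kept = table.drop(columns=has_na)
    n_drugs = len(table)
    near_const = [
        c for c in kept.columns if kept[c].value_counts().iloc[0] >= near_constant_frac * n_drugs
    ]
    kept = kept.drop(columns=near_const)
    if kept.shape[1] == 0:
        raise ValueError("all descriptors removed by cleaning")
    logger.info(
        "clean_descriptors: dropped %d with missing values, %d (near-)constant; %d remain",
        len(has_na), len(near_const), kept.shape[1],
    )
    return kept


def spearman_reduce(table: pd.DataFrame, target_count: int = 500) -> tuple[pd.DataFrame, ReductionReport]:
    """Reduce descriptors to ``target_count`` representatives of correlation clusters.

    Descriptors are hierarchically clustered (average linkage) on the
    dissimilarity 1 - |Spearman rho|, the tree is cut at exactly
    ``target_count`` clusters, and each cluster is represented by the member
    with the highest average absolute correlation to the other members
    (singletons represent themselves; ties go to the lowest column index).
    """
    p = table.shape[1]
    if target_count > p:
        raise ValueError("target_count exceeds the number of descriptors")
    if len(table) < 3:
        raise ValueError("need at least 3 drugs for rank correlation")
    stds = table.std(ddof=0)
    if (stds == 0).any():
        bad = list(stds.index[stds == 0])[:5]
        raise ValueError(f"constant descriptors reached spearman_reduce (clean first): {bad}")
    rho = table.corr(method="spearman").to_numpy()
    if target_count == p:
        labels = np.arange(1, p + 1)
    else:
        dissim = np.clip(1.0 - np.abs(rho), 0.0, None)
        np.fill_diagonal(dissim, 0.0)
        Z = linkage(squareform(dissim, checks=False), method="average")
        labels = fcluster(Z, t=target_count, criterion="maxclust")
    columns = list(table.columns)
    membership = {c: int(l) for c, l in zip(columns, labels)}
    representatives: dict[int, str] = {}
    scores: dict[int, float] = {}
    for cl in sorted(set(labels)):
        members = np.flatnonzero(labels == cl)
        if len(members) == 1:
            representatives[cl] = columns[members[0]]
            scores[cl] = float("nan")
            continue
        sub = np.abs(rho[np.ix_(members, members)])
        avg = (sub.sum(axis=1) - 1.0) / (len(members) - 1)
        best = members[int(np.argmax(avg))]  # argmax takes first max -> lowest index
        representatives[cl] = columns[best]
        scores[cl] = float(avg.max())
    rep_cols = [representatives[cl] for cl in sorted(representatives)]
    # preserve original column order among representatives
    rep_cols = [c for c in columns if c in set(rep_cols)]
    return table[rep_cols], ReductionReport(membership, representatives, scores)


def graphical_lasso_network(
    table: pd.DataFrame, lam: float, tol: float = 1e-6, max_iter: int = 200
) -> FeatureNetwork:
    """Estimate the sparse descriptor network via l1-penalized precision estimation.

    Descriptors are standardized internally (zero mean, unit variance across
    drugs) so the penalty acts on the correlation scale.
    """
    if lam <= 0:
        raise ValueError("penalty lambda must be positive")
    if len(table) < 3:
        raise ValueError("need at least 3 drugs to estimate a covariance")
    x = table.to_numpy(dtype=float)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    s = (x.T @ x) / len(x)
    try:
        _, precision = _sk_graphical_lasso(s, alpha=lam, tol=tol, max_iter=max_iter)
    except Exception as err:
        raise RuntimeError(f"graphical LASSO did not converge at lambda={lam}: {err}") from err
    return FeatureNetwork(descriptors=tuple(table.columns), precision=precision, lam=float(lam))


def select_lambda(
    table: pd.DataFrame,
    grid: np.ndarray | None = None,
    max_lcc_frac: float = 1 / 3,
) -> float:
    """Smallest grid penalty whose network LCC holds at most ``max_lcc_frac`` of features.

    Mirrors the reduction of the full descriptor set to a much smaller
    connected core; larger penalties give sparser networks, so the grid is
    scanned in increasing order.
    """
    if grid is None:
        grid = np.logspace(-2, 0, 15)
    p = table.shape[1]
    cap = max(2, int(np.floor(max_lcc_frac * p)))
    for lam in np.sort(np.asarray(grid, dtype=float)):
        net = graphical_lasso_network(table, lam)
        if net.network.n_edges == 0:
            continue
        lcc_size = max(len(c) for c in nx.connected_components(net.network.graph))
        if lcc_size <= cap:
            return float(lam)
    raise ValueError("no grid penalty produced a connected component small enough")


def scale_descriptors(table: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each descriptor to [0, 1] across drugs.

    Descriptors can be negative (e.g. electrotopological indices); scaling
    makes every value nonnegative so drugs can be normalized to probability
    vectors.
    """
    lo, hi = table.min(axis=0), table.max(axis=0)
    span = hi - lo
    if (span == 0).any():
        bad = list(span.index[span == 0])[:5]
        raise ValueError(f"constant descriptors cannot be min-max scaled: {bad}")
    return (table - lo) / span


def drug_distribution(scaled_row: pd.Series, lcc: GeneNetwork) -> MassDistribution:
    """Normalize one drug's scaled descriptor values over the LCC to sum 1."""
    values = scaled_row.reindex(list(lcc.nodes))
    if values.isna().any():
        missing = list(values.index[values.isna()])[:5]
        raise ValueError(f"drug lacks values for network descriptors: {missing}")
    v = values.to_numpy(dtype=float)
    if (v < 0).any():
        raise ValueError("scaled descriptor values must be nonnegative")
    total = v.sum()
    if total <= 0:
        raise ValueError("drug has zero mass on every network descriptor")
    return MassDistribution(index=lcc.nodes, p=v / total, z=float(total))


def drug_distributions(
    table: pd.DataFrame, feature_net: FeatureNetwork
) -> tuple[list[MassDistribution], GeneNetwork]:
    """Scale all drugs and place them on the feature network's largest component."""
    lcc = restrict_to_lcc(feature_net.network)
    scaled = scale_descriptors(table[list(lcc.nodes)])
    measures = []
    for drug, row in scaled.iterrows():
        try:
            measures.append(drug_distribution(row, lcc))
        except ValueError as err:
            raise ValueError(f"drug {drug!r}: {err}") from err
    return measures, lcc
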