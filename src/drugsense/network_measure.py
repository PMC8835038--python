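"""Expression-weighted Markov chain on the gene network and its invariant measure.

Each sample's expression profile turns the fixed interaction network into a
Markov chain: from gene i the signal moves to a neighbor j with probability
proportional to the neighbor's expression,

    p_ij = ge_j / sum_{k in N_i} ge_k        (j in N_i, else 0).

The chain's stationary distribution has the closed form

    pi_i = (1/Z) * ge_i * sum_{j in N_i} ge_j,

with Z the normalization constant making pi a probability vector.  pi is the
per-sample node distribution that feeds the optimal-transport distance; it
upweights highly expressed genes sitting in highly expressed neighborhoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import GeneNetwork

__all__ = ["MassDistribution", "transition_matrix", "invariant_measure", "all_invariant_measures"]

_ROW_TOL = 1e-12


@dataclass(frozen=True)
class MassDistribution:
    """Probability vector over the nodes of a fixed network.

    ``index`` is the node order (matching ``GeneNetwork.nodes``); ``p`` the
    probabilities; ``z`` the normalization constant that was divided out.
    """

    index: tuple
    p: np.ndarray
    z: float = 1.0

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if len(self.index) != p.shape[0]:
            raise ValueError("index and probability vector length differ")
        if (p < 0).any():
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > _ROW_TOL * max(1, len(p)):
            raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")


def _expression_vector(expr_row, network: GeneNetwork) -> np.ndarray:
    if isinstance(expr_row, pd.Series):
        missing = [n for n in network.nodes if n not in expr_row.index]
        if missing:
            raise ValueError(f"expression missing for network nodes: {missing[:5]}")
        ge = expr_row.reindex(list(network.nodes)).to_numpy(dtype=float)
    else:
        ge = np.asarray(expr_row, dtype=float)
        if ge.shape[0] != network.n_nodes:
            raise ValueError("expression vector length does not match network size")
    if np.isnan(ge).any():
        raise ValueError("expression contains NaN")
    if (ge < 0).any():
        raise ValueError("expression must be nonnegative (linear scale)")
    return ge


def _smooth(ge: np.ndarray, epsilon: float | None) -> np.ndarray:
    if epsilon is None:
        return ge
    positive = ge[ge > 0]
    if positive.size == 0:
        raise ValueError("all expression values are zero")
    return ge + epsilon * positive.mean()


def transition_matrix(
    expr_row, network: GeneNetwork, epsilon: float | None = None
) -> np.ndarray:
    """Row-stochastic transition matrix of the expression-weighted chain.

    Rows/columns follow ``network.nodes``.  ``epsilon`` optionally smooths
    zero expression by adding ``epsilon * mean(positive values)`` to every
    gene before normalization; by default a neighborhood with zero total
    expression is an error.
    """
    ge = _smooth(_expression_vector(expr_row, network), epsilon)
    nodes = list(network.nodes)
    pos = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    p = np.zeros((n, n))
    for i, node in enumerate(nodes):
        nbrs = [pos[j] for j in network.graph.neighbors(node)]
        if not nbrs:
            raise ValueError(f"node {node!r} has no neighbors (network must be connected)")
        total = ge[nbrs].sum()
        if total <= 0:
            raise ValueError(
                f"all neighbors of {node!r} have zero expression; "
                "enable epsilon smoothing or filter the input"
            )
        p[i, nbrs] = ge[nbrs] / total
    return p


def invariant_measure(
    expr_row, network: GeneNetwork, epsilon: float | None = None
) -> MassDistribution:
    """Stationary distribution pi with pi_i proportional to ge_i * (neighborhood total)."""
    ge = _smooth(_expression_vector(expr_row, network), epsilon)
    nodes = list(network.nodes)
    pos = {n: i for i, n in enumerate(nodes)}
    unnorm = np.empty(len(nodes))
    for i, node in enumerate(nodes):
        nbrs = [pos[j] for j in network.graph.neighbors(node)]
        unnorm[i] = ge[i] * ge[nbrs].sum()
    z = unnorm.sum()
    if z <= 0:
        raise ValueError("total unnormalized mass is zero; cannot form a probability vector")
    return MassDistribution(index=network.nodes, p=unnorm / z, z=float(z))


def all_invariant_measures(
    expr: pd.DataFrame, network: GeneNetwork, epsilon: float | None = None
) -> list[MassDistribution]:
    """One invariant measure per sample (row of ``expr``), in row order."""
    measures = []
    for sample, row in expr.iterrows():
        try:
            measures.append(invariant_measure(row, network, epsilon=epsilon))
        except ValueError as err:
            raise ValueError(f"sample {sample!r}: {err}") from err
    return measures
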