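"""Post-modeling gene significance and gene-set enrichment for a paired cluster.

Two-step gene selection: (1) rank genes by their random-forest permutation
importance (mean increase in out-of-bag squared error when the feature is
permuted, averaged over trees); (2) Welch t-test on the top-ranked genes
between two cell-line groups, Bonferroni-corrected over exactly the number of
tested genes.  Selected genes then go into a hypergeometric over-representation
test against user-supplied gene sets with Benjamini-Hochberg FDR control.

The paper-style contrast groups (sensitive vs. resistant) are formed by
:func:`response_groups`: cell lines split at the median of their mean observed
log(IC50) over the drugs of the paired drug cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, ttest_ind
from statsmodels.stats.multitest import multipletests

from .response_models import PairedClusterDesign, make_forest

__all__ = [
    "GeneImportance",
    "importance_rank",
    "response_groups",
    "select_significant",
    "hypergeom_enrich",
]


@dataclass(frozen=True)
class GeneImportance:
    gene: str
    importance: float
    rank: int


def _oob_permutation_importance(forest, X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mean increase in OOB MSE per feature when that feature is permuted, over trees."""
    n, p = X.shape
    increases = np.zeros(p)
    counts = np.zeros(p)
    for tree, sampled in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), sampled)
        if len(oob) < 2:
            continue
        base_mse = np.mean((y[oob] - tree.predict(X[oob])) ** 2)
        Xp = X[oob].copy()
        for j in range(p):
            saved = Xp[:, j].copy()
            Xp[:, j] = saved[rng.permutation(len(oob))]
            perm_mse = np.mean((y[oob] - tree.predict(Xp)) ** 2)
            increases[j] += perm_mse - base_mse
            counts[j] += 1
            Xp[:, j] = saved
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, increases / np.maximum(counts, 1), 0.0)


def importance_rank(
    design: PairedClusterDesign, trees: int = 100, min_leaf: int = 5, seed: int = 0
) -> list[GeneImportance]:
    """Genes of a paired-cluster design ranked by OOB permutation importance.

    The forest is trained on the full design with the same hyperparameters as
    cross-validation; descriptor features participate in the fit but are
    excluded from the returned ranking.
    """
    X = design.X.to_numpy(dtype=float)
    forest = make_forest(X.shape[1], trees=trees, min_leaf=min_leaf, seed=seed)
    forest.fit(X, design.y)
    rng = np.random.default_rng(seed)
    imp = _oob_permutation_importance(forest, X, design.y, rng)
    genes = design.gene_features
    gene_imp = imp[: len(genes)]
    order = np.argsort(-gene_imp, kind="stable")
    return [
        GeneImportance(gene=genes[i], importance=float(gene_imp[i]), rank=r + 1)
        for r, i in enumerate(order)
    ]


def response_groups(
    responses: pd.DataFrame, cell_members, drug_members
) -> tuple[list, list]:
    """Split cluster cell lines into sensitive/resistant halves.

    The split is at the median of each cell line's mean observed log(IC50)
    over the cluster's drugs; lower mean log(IC50) = more sensitive.
    """
    cells = sorted(cell_members)
    sub = responses.loc[cells, sorted(drug_members)]
    means = sub.mean(axis=1, skipna=True)
    if means.isna().any():
        cells = [c for c in cells if not np.isnan(means[c])]
        means = means[cells]
    med = means.median()
    sensitive = [c for c in cells if means[c] <= med]
    resistant = [c for c in cells if means[c] > med]
    if not sensitive or not resistant:
        raise ValueError("degenerate response split: one group is empty")
    return sensitive, resistant


def select_significant(
    ranked: list[GeneImportance],
    expr: pd.DataFrame,
    groups: tuple[list, list],
    top_n: int = 200,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-test the top-n ranked genes between two groups, Bonferroni over top_n.

    Returns one row per tested gene (importance, rank, t, raw p, adjusted p,
    selected flag), sorted by rank.
    """
    g1, g2 = groups
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least two cell lines")
    tested = ranked[:top_n]
    n_tests = len(tested)
    rows = []
    for gi in tested:
        a = expr.loc[g1, gi.gene].to_numpy(dtype=float)
        b = expr.loc[g2, gi.gene].to_numpy(dtype=float)
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = ttest_ind(a, b, equal_var=False)
        p_adj = min(1.0, float(p) * n_tests)
        rows.append(
            {
                "gene": gi.gene,
                "importance": gi.importance,
                "rank": gi.rank,
                "t": float(t),
                "p": float(p),
                "p_bonferroni": p_adj,
                "selected": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def hypergeom_enrich(
    selection: set, gene_sets: dict[str, set], universe: set
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selection`` in each gene set.

    Sets are intersected with the universe first; p = P[X >= overlap] for
    X ~ Hypergeometric(|universe|, |set|, |selection|); q = BH-FDR across all
    tested sets.  Rows sorted by q then p then set name.
    """
    if not universe:
        raise ValueError("empty universe")
    if not selection:
        raise ValueError("empty selection")
    if not set(selection) <= set(universe):
        raise ValueError("selection must be a subset of the universe")
    M, N = len(universe), len(selection)
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & set(universe)
        n = len(in_universe)
        if n == 0:
            continue
        k = len(in_universe & set(selection))
        p = float(hypergeom.sf(k - 1, M, n, N))
        rows.append(
            {"set": name, "overlap": k, "set_size": n, "universe": M, "selection": N, "p": p}
        )
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df.sort_values(["q", "p", "set"]).set_index("set")
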