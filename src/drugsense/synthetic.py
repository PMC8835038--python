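"""Seeded generators for all four pipeline inputs with planted structure.

The generators emulate the shapes of a pharmacogenomic study — an expression
matrix on a scale-free interaction network, a drug descriptor table from a
sparse Gaussian graphical model, and a log(IC50) response table — with known
ground truth: planted cell-line clusters (a multiplicative expression shift on
a cluster-specific gene module), planted drug clusters (mean offsets on
descriptor blocks), and a response surface whose informative features differ
per (cell cluster, drug cluster) pair.  That last property is what makes
per-paired-cluster regression genuinely better than pooled regression, and is
the planted analogue of the study's central empirical claim.

Everything is a pure function of (scenario, seed): per-stage RNG streams are
spawned deterministically from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import GeneNetwork

__all__ = [
    "SyntheticScenario",
    "SyntheticData",
    "make_ppi",
    "make_expression",
    "make_descriptors",
    "make_responses",
    "simulate",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for the synthetic benchmark.

    Defaults are the desk-scale analogue of the real study: 120 cell lines x
    40 drugs in 4 x 3 planted clusters, a 60-gene scale-free network, an
    effect size of delta = 1.0 (an e-fold expression shift on the cluster's
    gene module) and response noise sigma = 0.5 on the log(IC50) scale.
    """

    n_cells: int = 120
    n_drugs: int = 40
    n_genes: int = 60
    n_descriptors: int = 60
    k_cells: int = 4
    k_drugs: int = 3
    attachment: int = 2
    delta: float = 1.0  # log-scale expression shift of module genes
    expr_sd: float = 0.25  # lognormal baseline sd
    descriptor_offset: float = 2.0  # cluster mean shift of descriptor blocks, in sd units
    partial_corr: float = 0.45  # chain partial correlation of the descriptor GGM
    base_sd: float = 2.0  # sd of per-paired-cluster baseline responses
    effect_size: float = 1.0  # coefficient of cluster-specific feature effects
    n_effect_genes: int = 2
    n_effect_descriptors: int = 1
    sigma: float = 0.5  # response noise sd
    missing_rate: float = 0.1
    n_junk_constant: int = 2
    n_junk_near_constant: int = 2
    n_junk_missing: int = 2
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cells, self.n_drugs, self.n_genes, self.n_descriptors) < 2:
            raise ValueError("all counts must be at least 2")
        if self.k_cells < 2 or self.k_drugs < 2:
            raise ValueError("need at least two planted clusters per axis")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_genes < self.attachment + 1:
            raise ValueError("n_genes must exceed the attachment parameter")

    def rngs(self, n: int = 4) -> list[np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(n)
        return [np.random.default_rng(c) for c in children]


@dataclass(frozen=True)
class SyntheticData:
    scenario: SyntheticScenario
    network: GeneNetwork
    expression: pd.DataFrame  # cells x genes
    cell_labels: pd.Series  # planted cluster 1..k_cells per cell
    descriptors: pd.DataFrame  # drugs x descriptors (with injected junk columns)
    drug_labels: pd.Series
    true_precision: np.ndarray  # GGM precision of the clean descriptor block
    responses: pd.DataFrame  # cells x drugs log(IC50), NaN = missing
    clean_descriptor_names: tuple = field(default=())


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def make_ppi(n_genes: int, attachment: int = 2, seed: int = 0) -> GeneNetwork:
    """Connected scale-free network (preferential attachment), gene nodes G0001.."""
    raw = nx.barabasi_albert_graph(n_genes, attachment, seed=int(seed))
    names = _ids("G", n_genes)
    graph = nx.relabel_nodes(raw, dict(enumerate(names)))
    return GeneNetwork(graph)


def _blocks(items: list, k: int) -> list[list]:
    bounds = np.linspace(0, len(items), k + 1).astype(int)
    return [items[bounds[i] : bounds[i + 1]] for i in range(k)]


def make_expression(
    scenario: SyntheticScenario, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Lognormal baseline expression with an e^delta module shift per planted cluster."""
    sc = scenario
    if rng is None:
        rng = sc.rngs()[1]
    cells = _ids("C", sc.n_cells)
    genes = _ids("G", sc.n_genes)
    labels = pd.Series([(i % sc.k_cells) + 1 for i in range(sc.n_cells)], index=cells, name="cluster")
    log_expr = rng.normal(0.0, sc.expr_sd, size=(sc.n_cells, sc.n_genes))
    modules = _blocks(genes, sc.k_cells)
    gene_pos = {g: j for j, g in enumerate(genes)}
    for i, cell in enumerate(cells):
        module = modules[labels[cell] - 1]
        log_expr[i, [gene_pos[g] for g in module]] += sc.delta
    expr = pd.DataFrame(np.exp(log_expr), index=cells, columns=genes)
    return expr, labels


def _chain_precision(p: int, partial: float) -> np.ndarray:
    theta = np.eye(p)
    idx = np.arange(p - 1)
    theta[idx, idx + 1] = theta[idx + 1, idx] = -partial
    return theta


def make_descriptors(
    scenario: SyntheticScenario, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Descriptors from a chain GGM with cluster mean offsets, plus junk columns.

    The injected junk (constant, near-constant and missing-value descriptors)
    exercises the cleaning stage; the returned precision matrix is the ground
    truth for support-recovery checks on the clean block.
    """
    sc = scenario
    if rng is None:
        rng = sc.rngs()[2]
    drugs = _ids("D", sc.n_drugs)
    names = _ids("X", sc.n_descriptors)
    labels = pd.Series([(i % sc.k_drugs) + 1 for i in range(sc.n_drugs)], index=drugs, name="cluster")
    theta = _chain_precision(sc.n_descriptors, sc.partial_corr)
    cov = np.linalg.inv(theta)
    x = rng.multivariate_normal(np.zeros(sc.n_descriptors), cov, size=sc.n_drugs)
    sds = np.sqrt(np.diag(cov))
    blocks = _blocks(list(range(sc.n_descriptors)), sc.k_drugs)
    for i, drug in enumerate(drugs):
        cols = blocks[labels[drug] - 1]
        x[i, cols] += sc.descriptor_offset * sds[cols]
    table = pd.DataFrame(x, index=drugs, columns=names)
    for j in range(sc.n_junk_constant):
        table[f"JCONST{j}"] = 1.0
    for j in range(sc.n_junk_near_constant):
        col = np.zeros(sc.n_drugs)
        n_odd = max(1, int(np.ceil(0.02 * sc.n_drugs)))
        col[rng.choice(sc.n_drugs, size=n_odd, replace=False)] = rng.normal(size=n_odd)
        table[f"JNEAR{j}"] = col
    for j in range(sc.n_junk_missing):
        col = rng.normal(size=sc.n_drugs)
        col[rng.integers(sc.n_drugs)] = np.nan
        table[f"JMISS{j}"] = col
    return table, labels, theta


def make_responses(
    cell_labels: pd.Series,
    drug_labels: pd.Series,
    expression: pd.DataFrame,
    descriptors: pd.DataFrame,
    scenario: SyntheticScenario,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Cluster-pair baseline + cluster-specific feature effects + Gaussian noise.

    y(c,d) = B[g(c), h(d)] + sum_e beta * z_e(c,d) + N(0, sigma^2), where the
    effect features e (genes and clean descriptors, z-scored across items) are
    drawn separately for every paired cluster, so no single pooled model can
    represent all pairs.  Missingness is completely at random.
    """
    sc = scenario
    if rng is None:
        rng = sc.rngs()[3]
    cells, drugs = list(cell_labels.index), list(drug_labels.index)
    base = rng.normal(0.0, sc.base_sd, size=(sc.k_cells, sc.k_drugs))
    clean_cols = [c for c in descriptors.columns if not c.startswith("J")]
    z_expr = (expression - expression.mean()) / expression.std(ddof=0)
    desc = descriptors[clean_cols]
    z_desc = (desc - desc.mean()) / desc.std(ddof=0)
    gene_effects: dict[tuple, np.ndarray] = {}
    desc_effects: dict[tuple, np.ndarray] = {}
    for g in range(1, sc.k_cells + 1):
        for h in range(1, sc.k_drugs + 1):
            gene_effects[(g, h)] = rng.choice(expression.shape[1], size=sc.n_effect_genes, replace=False)
            desc_effects[(g, h)] = rng.choice(len(clean_cols), size=sc.n_effect_descriptors, replace=False)
    ze = z_expr.to_numpy()
    zd = z_desc.to_numpy()
    y = np.empty((len(cells), len(drugs)))
    for i, c in enumerate(cells):
        g = cell_labels[c]
        for j, d in enumerate(drugs):
            h = drug_labels[d]
            val = base[g - 1, h - 1]
            val += sc.effect_size * ze[i, gene_effects[(g, h)]].sum()
            val += sc.effect_size * zd[j, desc_effects[(g, h)]].sum()
            y[i, j] = val
    y += rng.normal(0.0, sc.sigma, size=y.shape)
    if sc.missing_rate > 0:
        mask = rng.random(y.shape) < sc.missing_rate
        y[mask] = np.nan
    return pd.DataFrame(y, index=cells, columns=drugs)


def simulate(scenario: SyntheticScenario) -> SyntheticData:
    """Generate a complete synthetic study from one scenario."""
    rng_ppi, rng_expr, rng_desc, rng_resp = scenario.rngs(4)
    net_seed = int(rng_ppi.integers(2**31 - 1))
    network = make_ppi(scenario.n_genes, scenario.attachment, seed=net_seed)
    expression, cell_labels = make_expression(scenario, rng_expr)
    descriptors, drug_labels, theta = make_descriptors(scenario, rng_desc)
    responses = make_responses(cell_labels, drug_labels, expression, descriptors, scenario, rng_resp)
    clean = tuple(c for c in descriptors.columns if not c.startswith("J"))
    return SyntheticData(
        scenario=scenario,
        network=network,
        expression=expression,
        cell_labels=cell_labels,
        descriptors=descriptors,
        drug_labels=drug_labels,
        true_precision=theta,
        responses=responses,
        clean_descriptor_names=clean,
    )
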