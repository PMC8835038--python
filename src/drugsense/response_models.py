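"""Per-paired-cluster random-forest regression of log(IC50) and the CDCN baseline.

For every (cell-line cluster, drug cluster) pair, the observed (cell, drug)
responses form a design whose features concatenate the cell line's gene
expression vector with the drug's scaled descriptor vector.  A random forest
(100 trees, min leaf 5, mtry = floor(p/3)) is evaluated by 3-fold
cross-validation at the pair level; predictions from all paired clusters are
concatenated before computing the overall Pearson R and coefficient of
determination R^2.

The baseline is the dual-layer cell-line-drug complex network (CDCN) closed
form: a pair's response is the similarity-weighted average of the same drug's
responses in other cell lines (cell layer) and the same cell line's responses
to other drugs (drug layer),

    yhat(c,d) = [sum_{c'!=c} w_cc' y(c',d) + sum_{d'!=d} v_dd' y(c,d')]
                / [sum_{c'!=c} w_cc' + sum_{d'!=d} v_dd'],

with sums over observed entries only.  Similarities come either from a
Gaussian kernel on W1 distances (median-heuristic bandwidth) or from
nonnegative-clipped Pearson correlations of the raw feature vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.ensemble import RandomForestRegressor

from .transport import DistanceMatrix

__all__ = [
    "PairedClusterDesign",
    "EvaluationResult",
    "SimilarityWeights",
    "assemble_design",
    "crossval_rf",
    "make_forest",
    "evaluate",
    "concat_evaluate",
    "similarity_weights",
    "cdcn_predict",
]


@dataclass(frozen=True)
class PairedClusterDesign:
    """Observed (cell, drug) pairs of one paired cluster with their feature rows."""

    cell_cluster: int
    drug_cluster: int
    pairs: tuple  # ((cell, drug), ...) sorted canonically
    X: pd.DataFrame  # one row per pair: gene block then descriptor block
    y: np.ndarray
    n_gene_features: int

    @property
    def n_rows(self) -> int:
        return len(self.pairs)

    @property
    def gene_features(self) -> list:
        return list(self.X.columns[: self.n_gene_features])


@dataclass(frozen=True)
class EvaluationResult:
    predicted: np.ndarray
    observed: np.ndarray
    r: float  # Pearson correlation; NaN when predictions are constant
    r2: float  # 1 - SS_res / SS_tot


@dataclass(frozen=True)
class SimilarityWeights:
    cell_ids: tuple
    w: np.ndarray
    drug_ids: tuple
    v: np.ndarray
    sigma_cells: float | None = None
    sigma_drugs: float | None = None


def assemble_design(
    cell_members,
    drug_members,
    expr: pd.DataFrame,
    descriptors: pd.DataFrame,
    responses: pd.DataFrame,
    cell_cluster: int = 0,
    drug_cluster: int = 0,
) -> PairedClusterDesign:
    """Design matrix for one paired cluster: one row per observed (cell, drug) pair."""
    cells = sorted(cell_members)
    drugs = sorted(drug_members)
    missing_c = [c for c in cells if c not in expr.index]
    missing_d = [d for d in drugs if d not in descriptors.index]
    if missing_c or missing_d:
        raise ValueError(f"feature tables do not cover members: {missing_c[:3] + missing_d[:3]}")
    pairs, ys = [], []
    for c, d in product(cells, drugs):
        if c in responses.index and d in responses.columns:
            y = responses.at[c, d]
            if pd.notna(y):
                pairs.append((c, d))
                ys.append(float(y))
    if not pairs:
        raise ValueError(
            f"no observed responses in paired cluster ({cell_cluster}, {drug_cluster})"
        )
    gene_block = expr.loc[[c for c, _ in pairs]].to_numpy(dtype=float)
    desc_block = descriptors.loc[[d for _, d in pairs]].to_numpy(dtype=float)
    if np.isnan(desc_block).any():
        raise ValueError("descriptor features contain missing values")
    X = pd.DataFrame(
        np.hstack([gene_block, desc_block]),
        columns=list(expr.columns) + list(descriptors.columns),
    )
    return PairedClusterDesign(
        cell_cluster=cell_cluster,
        drug_cluster=drug_cluster,
        pairs=tuple(pairs),
        X=X,
        y=np.asarray(ys),
        n_gene_features=expr.shape[1],
    )


def make_forest(p: int, trees: int = 100, min_leaf: int = 5, seed: int = 0) -> RandomForestRegressor:
    """Random forest with the regression defaults: mtry = floor(p/3), min 1."""
    return RandomForestRegressor(
        n_estimators=trees,
        min_samples_leaf=min_leaf,
        max_features=max(1, p // 3),
        random_state=seed,
        n_jobs=1,
    )


def crossval_rf(
    design: PairedClusterDesign,
    folds: int = 3,
    trees: int = 100,
    min_leaf: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold predictions from pair-level k-fold cross-validation.

    Rows are partitioned into ``folds`` folds by a seeded permutation; every
    row receives exactly one prediction from a forest trained on the other
    folds.  Fully deterministic given (design, seed).
    """
    n = design.n_rows
    if n < folds * 2:
        raise ValueError(
            f"paired cluster ({design.cell_cluster}, {design.drug_cluster}) has "
            f"{n} rows; need at least {folds * 2} for {folds}-fold CV"
        )
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    fold_of[rng.permutation(n)] = np.arange(n) % folds
    X = design.X.to_numpy(dtype=float)
    y = design.y
    preds = np.empty(n)
    for f in range(folds):
        test = fold_of == f
        forest = make_forest(X.shape[1], trees=trees, min_leaf=min_leaf, seed=seed + f)
        forest.fit(X[~test], y[~test])
        preds[test] = forest.predict(X[test])
    return preds


def evaluate(predicted, observed) -> EvaluationResult:
    """Pearson R and R^2 = 1 - SS_res/SS_tot of predictions against observations."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("predicted and observed must be 1-d arrays of equal length")
    if len(obs) < 3:
        raise ValueError("need at least 3 observations")
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("observed values are constant; R and R^2 undefined")
    ss_res = np.sum((obs - pred) ** 2)
    r2 = 1.0 - ss_res / ss_tot
    r = float("nan") if np.ptp(pred) == 0 else float(pearsonr(pred, obs)[0])
    return EvaluationResult(predicted=pred, observed=obs, r=r, r2=float(r2))


def concat_evaluate(results: list[EvaluationResult]) -> EvaluationResult:
    """Single evaluation over the concatenated predictions of all paired clusters."""
    if not results:
        raise ValueError("no per-cluster results to concatenate")
    pred = np.concatenate([r.predicted for r in results])
    obs = np.concatenate([r.observed for r in results])
    return evaluate(pred, obs)


def _kernel_weights(D: DistanceMatrix) -> tuple[np.ndarray, float]:
    off = D.values[~np.eye(D.n, dtype=bool)]
    sigma = float(np.median(off))
    if sigma <= 0:
        raise ValueError("median off-diagonal distance is zero; kernel bandwidth undefined")
    w = np.exp(-(D.values**2) / (2.0 * sigma**2))
    np.fill_diagonal(w, 0.0)
    return w, sigma


def _pearson_weights(features: pd.DataFrame) -> np.ndarray:
    rho = np.corrcoef(features.to_numpy(dtype=float))
    w = np.clip(rho, 0.0, None)
    np.fill_diagonal(w, 0.0)
    return w


def similarity_weights(cells, drugs, mode: str = "wasserstein-kernel") -> SimilarityWeights:
    """Cell-cell and drug-drug similarity matrices for the CDCN closed form.

    ``mode='wasserstein-kernel'``: ``cells``/``drugs`` are W1
    :class:`DistanceMatrix` objects; similarity is a Gaussian kernel with the
    median off-diagonal distance as bandwidth.  ``mode='pearson'``: they are
    raw feature tables (rows = items); similarity is Pearson correlation
    clipped at zero.  Diagonals are zeroed: an item never explains itself.
    """
    if mode == "wasserstein-kernel":
        w, sc = _kernel_weights(cells)
        v, sd = _kernel_weights(drugs)
        return SimilarityWeights(tuple(cells.ids), w, tuple(drugs.ids), v, sc, sd)
    if mode == "pearson":
        return SimilarityWeights(
            tuple(cells.index), _pearson_weights(cells), tuple(drugs.index), _pearson_weights(drugs)
        )
    raise ValueError(f"unknown similarity mode {mode!r}")


def cdcn_predict(
    responses: pd.DataFrame,
    weights: SimilarityWeights,
    cell_members=None,
    drug_members=None,
) -> pd.DataFrame:
    """Leave-one-out CDCN predictions for every pair of the (restricted) response table.

    Entries whose cell layer and drug layer both lack observed neighbors come
    back NaN.  Invariant to a common positive rescaling of all weights
    (numerator and denominator scale together).
    """
    cells = sorted(cell_members) if cell_members is not None else list(weights.cell_ids)
    drugs = sorted(drug_members) if drug_members is not None else list(weights.drug_ids)
    ci = [weights.cell_ids.index(c) for c in cells]
    di = [weights.drug_ids.index(d) for d in drugs]
    w = weights.w[np.ix_(ci, ci)]
    v = weights.v[np.ix_(di, di)]
    Y = responses.loc[cells, drugs].to_numpy(dtype=float)
    M = (~np.isnan(Y)).astype(float)
    Y0 = np.nan_to_num(Y, nan=0.0)
    num = w @ Y0 + Y0 @ v
    den = w @ M + M @ v
    with np.errstate(invalid="ignore", divide="ignore"):
        pred = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return pd.DataFrame(pred, index=cells, columns=drugs)
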