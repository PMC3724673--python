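"""Correlation-matrix PCA, complete-linkage clustering, and PC-covariate
regressions for genome frequency matrices.

Rows are genomes, columns are the 20 amino acids or 64 codons.  PCA is done
on the correlation matrix (columns standardised to unit variance), matching
the convention for compositional profiles whose columns live on very
different scales.  Heatmap ordering uses agglomerative complete-linkage
clustering with Euclidean distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import statsmodels.api as sm

from .errors import ContractViolation, DegenerateModelError

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    scores: pd.DataFrame           # genomes x components
    loadings: pd.DataFrame         # categories x components
    variance_fraction: np.ndarray  # per-component proportion of variance
    dropped_columns: list[str]
    column_means: pd.Series
    column_sds: pd.Series

    def reconstruct_standardized(self) -> pd.DataFrame:
        """scores @ loadings.T — the standardised data when all components
        are retained."""
        return self.scores @ self.loadings.T


@dataclass
class Dendrogram:
    ids: list[str]            # genome ids in the (sorted) input order
    linkage: np.ndarray       # scipy linkage matrix, complete/Euclidean
    leaf_order: list[str]     # genome ids in dendrogram leaf order

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def _validate_matrix(matrix: pd.DataFrame) -> None:
    if matrix.index.duplicated().any():
        raise ContractViolation("duplicate genome ids")
    if matrix.isna().any().any():
        raise ContractViolation("frequency matrix contains missing values")


def pca_correlation(matrix: pd.DataFrame, at_vector: pd.Series | None = None) -> PcaResult:
    """PCA of a frequency matrix estimated with a correlation matrix.

    Columns are centred and scaled to unit (sample) variance before the
    eigendecomposition; zero-variance columns are dropped with a warning.
    Component signs are fixed deterministically: PC1 is oriented to correlate
    positively with %AT when ``at_vector`` is supplied; any remaining
    component is oriented so its largest-magnitude loading is positive
    (first in column order on ties).
    """
    _validate_matrix(matrix)
    if len(matrix) < 3:
        raise ContractViolation("PCA requires at least 3 genomes")
    sds = matrix.std(ddof=1)
    dropped = list(matrix.columns[sds == 0])
    if dropped:
        logger.warning("dropping %d zero-variance columns: %s", len(dropped), dropped)
    kept = matrix.drop(columns=dropped)
    means = kept.mean()
    sds = kept.std(ddof=1)
    Xs = (kept - means) / sds
    u, s, vt = np.linalg.svd(Xs.to_numpy(), full_matrices=False)
    n_comp = min(Xs.shape)
    var = s**2
    variance_fraction = var / var.sum()
    scores = u * s
    loadings = vt.T  # columns are unit eigenvectors
    # deterministic sign convention
    for j in range(n_comp):
        flip = False
        if j == 0 and at_vector is not None:
            at = at_vector.reindex(matrix.index).to_numpy(dtype=float)
            c = np.corrcoef(scores[:, 0], at)[0, 1]
            flip = c < 0
        else:
            col = loadings[:, j]
            flip = col[np.argmax(np.abs(col))] < 0
        if flip:
            scores[:, j] *= -1
            loadings[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(n_comp)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=kept.columns, columns=comp_names),
        variance_fraction=variance_fraction,
        dropped_columns=dropped,
        column_means=means,
        column_sds=sds,
    )


def regress_component_on_covariate(
    scores: pd.Series, covariate: pd.Series
) -> tuple[float, float]:
    """OLS of component scores on a covariate; returns (R², overall F p-value).

    Categorical covariates are dummy-coded, so R² equals the between-group
    share of variance (the ANOVA decomposition).
    """
    y = scores.to_numpy(dtype=float)
    cov = covariate.reindex(scores.index)
    if cov.isna().any():
        raise ContractViolation("covariate missing for some genomes")
    if cov.dtype == object or isinstance(cov.dtype, pd.CategoricalDtype):
        if cov.nunique() < 2:
            raise DegenerateModelError("constant categorical covariate")
        X = pd.get_dummies(cov, drop_first=True, dtype=float).to_numpy()
    else:
        if float(np.ptp(cov.to_numpy(dtype=float))) == 0.0:
            raise DegenerateModelError("constant covariate")
        X = cov.to_numpy(dtype=float).reshape(-1, 1)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return float(fit.rsquared), float(fit.f_pvalue)


def cluster_genomes(matrix: pd.DataFrame) -> Dendrogram:
    """Agglomerative complete-linkage clustering on Euclidean row distances.

    Rows are sorted lexicographically by genome id before linkage so that
    ties are broken deterministically.
    """
    _validate_matrix(matrix)
    if len(matrix) < 2:
        raise ContractViolation("clustering requires at least 2 genomes")
    matrix = matrix.sort_index()
    Z = sch.linkage(matrix.to_numpy(dtype=float), method="complete", metric="euclidean")
    ids = list(matrix.index)
    leaves = sch.leaves_list(Z)
    return Dendrogram(ids=ids, linkage=Z, leaf_order=[ids[i] for i in leaves])


def cophenetic_matrix(dendrogram: Dendrogram) -> pd.DataFrame:
    """Pairwise cophenetic (merge-height) distances implied by the tree."""
    from scipy.spatial.distance import squareform

    coph = sch.cophenet(dendrogram.linkage)
    return pd.DataFrame(squareform(coph), index=dendrogram.ids, columns=dendrogram.ids)


def to_newick(dendrogram: Dendrogram) -> str:
    """Export the dendrogram in Newick format, branch lengths = height gaps."""
    tree = sch.to_tree(dendrogram.linkage)
    ids = dendrogram.ids

    def rec(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{ids[node.id]}:{parent_height:.10g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    left = rec(tree.left, tree.dist)
    right = rec(tree.right, tree.dist)
    return f"({left},{right});"


def export_heatmap_inputs(
    matrix: pd.DataFrame,
    dendrogram: Dendrogram,
    annotations: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Reorder the frequency matrix (and per-genome annotations such as %AT
    and phylum) to dendrogram leaf order, ready for heatmap rendering."""
    if set(matrix.index) != set(dendrogram.ids):
        raise ContractViolation("matrix ids do not match dendrogram ids")
    ordered = matrix.loc[dendrogram.leaf_order]
    side = None
    if annotations is not None:
        if not set(dendrogram.leaf_order) <= set(annotations.index):
            raise ContractViolation("annotation ids do not cover dendrogram ids")
        side = annotations.loc[dendrogram.leaf_order]
    return ordered, side
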