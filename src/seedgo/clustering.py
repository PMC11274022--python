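"""Hierarchical clustering of score-matrix rows with a GLM-based cut rule.

Terms (rows) are clustered agglomeratively (Euclidean distance, complete
linkage by default). The number of clusters is chosen from the merge
heights h_1 <= ... <= h_m (m = n_leaves - 1): a generalized linear model
with Gaussian family and logarithmic link is fit to height against merge
index,

    E[h_i] = exp(beta0 + beta1 * i),

and the scan looks for the first merge whose actual height sits above
the fitted curve — the first residual d_i = h_i - hhat_i exceeding a
small relative tolerance. Stopping just before that merge (performing
merges 1..i*-1) leaves

    k = n_leaves - (i* - 1)

clusters; if no residual qualifies the whole tree collapses to k = 1.
The intuition: heights that track the fitted exponential growth reflect
within-structure agglomeration, and the first height that breaks above
the trend marks the jump where genuinely separate clusters are forced
together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from .errors import SeedgoError

logger = logging.getLogger(__name__)


@dataclass
class Dendrogram:
    """Leaf labels plus a scipy-format merge sequence (left, right, height)."""

    labels: list[str]
    linkage_matrix: np.ndarray  # scipy (n-1, 4) linkage

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage_matrix]


@dataclass
class GlmFit:
    beta0: float
    beta1: float
    fitted: np.ndarray
    residuals: np.ndarray
    converged: bool
    n_iter: int


@dataclass
class ClusterAssignment:
    k: int
    assignment: dict[str, int]  # term -> cluster index in 1..k
    i_star: int | None  # 1-based index of the first above-trend merge


def hcluster_rows(matrix, distance: str = "euclidean", linkage: str = "complete") -> Dendrogram:
    """Agglomerative dendrogram over the rows of a score matrix.

    Accepts a :class:`~seedgo.scoring.ScoreMatrix` or a pandas DataFrame.
    Merge heights are non-decreasing for the default complete linkage.
    """
    df = matrix.values if hasattr(matrix, "kind") else matrix
    if len(df) < 2:
        raise SeedgoError("clustering needs >= 2 rows; skip clustering for this matrix")
    if df.isna().any().any():
        raise SeedgoError("score matrix has missing cells")
    data = df.to_numpy(dtype=float)
    Z = scipy_linkage(pdist(data, metric=distance), method=linkage)
    return Dendrogram(list(df.index), Z)


def fit_glm_log_link(heights, eps_factor: float = 1e-8) -> GlmFit:
    """Fit E[h_i] = exp(beta0 + beta1 * i) by IRLS (Gaussian family, log link).

    ``heights`` are the dendrogram merge heights in non-decreasing order,
    indexed i = 1..m. Initialization is OLS on log(h + eps) with
    eps = eps_factor * max(h); convergence when the relative coefficient
    change drops below 1e-8, at most 100 iterations.
    """
    h = np.asarray(heights, dtype=float)
    if h.ndim != 1 or h.size < 2:
        raise SeedgoError("GLM fit needs >= 2 merge heights")
    if np.all(h == 0):
        raise SeedgoError("all merge heights are zero (degenerate matrix upstream)")
    if np.any(h < 0):
        raise SeedgoError("negative merge height")
    m = h.size
    x = np.arange(1, m + 1, dtype=float)
    X = np.column_stack([np.ones(m), x])
    eps = eps_factor * h.max()
    beta = np.linalg.lstsq(X, np.log(h + eps), rcond=None)[0]

    def deviance(b):
        return float(np.sum((h - np.exp(X @ b)) ** 2))

    converged = False
    n_iter = 0
    dev = deviance(beta)
    for n_iter in range(1, 101):
        eta = X @ beta
        mu = np.exp(eta)
        # Gaussian family, log link: IRLS weights (dmu/deta)^2 = mu^2,
        # working response z = eta + (y - mu)/mu
        z = eta + (h - mu) / mu
        W = mu  # sqrt of the weight
        new_beta = np.linalg.lstsq(X * W[:, None], z * W, rcond=None)[0]
        step = new_beta - beta
        # step-halving keeps the non-canonical-link IRLS from overshooting
        for _ in range(30):
            cand = beta + step
            if deviance(cand) <= dev or np.allclose(step, 0):
                break
            step = step / 2
        new_beta = beta + step
        denom = max(np.max(np.abs(beta)), 1e-300)
        rel_change = np.max(np.abs(new_beta - beta)) / denom
        beta = new_beta
        dev = deviance(beta)
        if rel_change < 1e-8:
            converged = True
            break
    if not converged:
        logger.warning("GLM IRLS did not converge in %d iterations", n_iter)
    fitted = np.exp(X @ beta)
    return GlmFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        fitted=fitted,
        residuals=h - fitted,
        converged=converged,
        n_iter=n_iter,
    )


def choose_cluster_count(
    dend: Dendrogram,
    fit: GlmFit | None = None,
    tol_rel: float = 1e-6,
) -> ClusterAssignment:
    """Choose k from the first above-trend merge and cut the tree there.

    Scanning merges in ascending index order, i* is the first i with
    d_i > tol_rel * h_i (a pure sign test is numerically meaningless on
    well-fit data, hence the relative tolerance). Performing merges
    1..i*-1 yields k = n_leaves - (i* - 1) clusters; with no qualifying
    residual, k = 1.
    """
    n = dend.n_leaves
    h = dend.heights
    if fit is None:
        fit = fit_glm_log_link(h)
    if fit.residuals.size != h.size:
        raise SeedgoError("GLM fit does not match this dendrogram's height sequence")
    above = fit.residuals > tol_rel * h
    idx = np.flatnonzero(above)
    if idx.size == 0:
        i_star = None
        k = 1
    else:
        i_star = int(idx[0]) + 1  # 1-based merge index
        k = n - (i_star - 1)
    flat = cut_tree(dend.linkage_matrix, n_clusters=k).ravel()
    # renumber clusters 1..k in order of first appearance
    remap: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for label, c in zip(dend.labels, flat):
        if c not in remap:
            remap[c] = len(remap) + 1
        assignment[label] = remap[c]
    return ClusterAssignment(k, assignment, i_star)
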