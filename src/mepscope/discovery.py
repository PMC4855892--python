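"""PCA-based subpopulation discovery and drop-out handling.

The core of the analysis: principal component analysis of the
delta-Ct matrix (centered, unscaled, matching R's prcomp defaults),
k-means assignment of cells to three populations on the first two
components, marker-evidence naming of the clusters (Pre-MEP / E-MEP /
MK-MEP), the top-weighted-gene ranking on PC1/PC2, an agglomerative
clustering cross-check, and the gene-wise inversion transform that
prepares drop-out-laden Ct data for zero-inflated factor analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

from mepscope.panel import GenePanel
from mepscope.qc import CtMatrix, ExpressionMatrix, PipelineError

POPULATION_NAMES = ("Pre-MEP", "E-MEP", "MK-MEP")


class UnresolvedNamingError(ValueError):
    """Two population names resolved to the same k-means cluster."""

    def __init__(self, message: str, evidence: pd.DataFrame):
        super().__init__(message)
        self.evidence = evidence


@dataclass
class PCAResult:
    """Scores, loadings, and variance fractions of an exact SVD-based PCA."""

    scores: pd.DataFrame  # cells x components
    loadings: pd.DataFrame  # genes x components
    variance_fraction: np.ndarray
    mean_: pd.Series
    scaled: bool = False
    scale_: Optional[pd.Series] = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class PopulationAssignment:
    """Per-cell population labels with the marker evidence used for naming."""

    labels: pd.Series  # cell -> population name
    cluster_index: pd.Series  # cell -> raw k-means cluster
    evidence: pd.DataFrame  # cluster x marker-score table
    seed: int
    k: int = 3

    @property
    def cell_ids(self) -> pd.Index:
        return self.labels.index

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(POPULATION_NAMES, fill_value=0)


def run_pca(
    expr: ExpressionMatrix, center: bool = True, scale: bool = False
) -> PCAResult:
    """Exact SVD-based PCA of the normalized expression matrix.

    Centering is on by default and unit-variance scaling off, matching
    the prcomp defaults.  Component signs are fixed so that each
    loading vector's largest-magnitude entry is positive, making
    results reproducible across linear-algebra backends.
    """
    X = expr.norm_ct.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 cells and 2 genes for PCA")
    mean = X.mean(axis=0) if center else np.zeros(p)
    Xc = X - mean
    scale_vec = None
    if scale:
        scale_vec = Xc.std(axis=0, ddof=1)
        if np.any(scale_vec == 0):
            raise PipelineError("cannot scale: constant gene present")
        Xc = Xc / scale_vec
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    if not np.any(S > 1e-12):
        raise PipelineError("degenerate input: matrix has no variance")
    # sign convention: largest-|loading| entry of each component positive
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * S
    var_frac = S**2 / np.sum(S**2)
    comp_names = [f"PC{j + 1}" for j in range(len(S))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=expr.cell_ids, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=expr.gene_symbols, columns=comp_names),
        variance_fraction=var_frac,
        mean_=pd.Series(mean, index=expr.gene_symbols, name="mean"),
        scaled=scale,
        scale_=None
        if scale_vec is None
        else pd.Series(scale_vec, index=expr.gene_symbols, name="scale"),
    )


def _kmeans_order_invariant(
    points: np.ndarray, k: int, seed: int, n_init: int = 25
) -> np.ndarray:
    """k-means labels that do not depend on the ordering of input rows.

    The model is fitted on a canonically (lexicographically) sorted copy
    of the points; every original point is then assigned to its nearest
    converged centroid, which is exactly the fixed-point assignment of
    Lloyd's algorithm.
    """
    order = np.lexsort(points.T[::-1])
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    km.fit(points[order])
    d = ((points[:, None, :] - km.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d, axis=1)


def kmeans_on_scores(
    pca: PCAResult, k: int = 3, n_pcs: int = 2, seed: int = 0, n_init: int = 25
) -> pd.Series:
    """Raw k-means clusters on the first ``n_pcs`` PC scores."""
    if pca.n_components < n_pcs:
        raise ValueError(f"PCA has {pca.n_components} components, need {n_pcs}")
    pts = pca.scores.iloc[:, :n_pcs].to_numpy(dtype=float)
    if len(pts) < k:
        raise ValueError(f"cannot form {k} clusters from {len(pts)} cells")
    labels = _kmeans_order_invariant(pts, k=k, seed=int(seed) % (2**31), n_init=n_init)
    return pd.Series(labels, index=pca.scores.index, name="cluster")


def _category_mean_evidence(
    neg_dct: pd.DataFrame, clusters: pd.Series, genes: list[str]
) -> pd.Series:
    present = [g for g in genes if g in neg_dct.columns]
    if not present:
        return pd.Series(np.nan, index=sorted(clusters.unique()))
    return neg_dct[present].mean(axis=1).groupby(clusters).mean()


def assign_populations(
    pca: PCAResult,
    expr: ExpressionMatrix,
    panel: GenePanel,
    k: int = 3,
    n_pcs: int = 2,
    seed: int = 0,
) -> PopulationAssignment:
    """Cluster cells on PC1/PC2 and name the clusters from marker evidence.

    Clusters are found by k-means (k = 3, 25 restarts at a fixed seed) on
    the first two PC scores.  Names are attached from mean expression
    (-dCt) evidence: the cluster highest in CD44 and lowest in GATA1 is
    Pre-MEP, the cluster highest in the erythroid program (KLF1 et al.)
    is E-MEP, and the cluster highest in the megakaryocyte program
    (VWF, ITGA2B et al.) is MK-MEP.  If two names resolve to the same
    cluster an UnresolvedNamingError carrying the evidence table is
    raised rather than guessing.
    """
    if k != 3:
        raise ValueError("population naming is defined for k = 3")
    clusters = kmeans_on_scores(pca, k=k, n_pcs=n_pcs, seed=seed)
    neg_dct = -expr.norm_ct
    cluster_ids = sorted(clusters.unique())

    cd44 = (
        neg_dct["CD44"].groupby(clusters).mean()
        if "CD44" in neg_dct.columns
        else _category_mean_evidence(neg_dct, clusters, panel.genes_in_category("premep"))
    )
    gata1 = (
        neg_dct["GATA1"].groupby(clusters).mean()
        if "GATA1" in neg_dct.columns
        else pd.Series(0.0, index=cluster_ids)
    )
    evidence = pd.DataFrame(
        {
            "premep_score": cd44 - gata1,
            "erythroid_score": _category_mean_evidence(
                neg_dct, clusters, panel.genes_in_category("erythroid")
            ),
            "megakaryocyte_score": _category_mean_evidence(
                neg_dct, clusters, panel.genes_in_category("megakaryocyte")
            ),
        }
    ).reindex(cluster_ids)

    winner = {
        "Pre-MEP": int(evidence["premep_score"].idxmax()),
        "E-MEP": int(evidence["erythroid_score"].idxmax()),
        "MK-MEP": int(evidence["megakaryocyte_score"].idxmax()),
    }
    if len(set(winner.values())) != len(winner):
        raise UnresolvedNamingError(
            f"cluster naming conflict: {winner}", evidence=evidence
        )
    name_of = {c: name for name, c in winner.items()}
    labels = clusters.map(name_of).rename("population")
    return PopulationAssignment(
        labels=labels,
        cluster_index=clusters,
        evidence=evidence,
        seed=int(seed),
        k=k,
    )


def top_weighted_genes(pca: PCAResult, n: int = 18) -> list[str]:
    """Genes ranked by L2 norm of their (PC1, PC2) loadings, descending.

    Ties are broken alphabetically.
    """
    if n > pca.loadings.shape[0]:
        raise ValueError(
            f"requested {n} genes but only {pca.loadings.shape[0]} available"
        )
    w = np.hypot(pca.loadings["PC1"], pca.loadings["PC2"])
    ranked = sorted(w.index, key=lambda g: (-w[g], g))
    return ranked[:n]


def dropout_transform_for_zifa(ct: CtMatrix) -> pd.DataFrame:
    """Gene-wise inversion transform preparing Ct data for ZIFA.

    Zero-inflated factor analysis requires drop-outs to be represented
    by values near 0.  Per gene, the maximal detected Ct (Ct_max) is
    found, drop-outs are set two cycles beyond it, and the interval is
    inverted: y = (Ct_max + 2) - Ct.  Drop-outs therefore map exactly
    to 0 and detected values to positives, with within-gene ordering
    preserved (lower Ct, i.e. higher expression, gives larger y).

    Genes detected in no cell cannot be anchored and are excluded with
    a warning.
    """
    detected = ct.detected()
    out = {}
    excluded = []
    for gene in ct.assay_ids:
        det = detected[gene]
        if not det.any():
            excluded.append(gene)
            continue
        ct_max = ct.ct.loc[det, gene].max()
        anchor = ct_max + 2.0
        vals = ct.ct[gene].where(det, anchor)
        out[gene] = anchor - vals
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} all-drop-out gene(s) from ZIFA transform: "
            + ", ".join(excluded),
            stacklevel=2,
        )
    return pd.DataFrame(out, index=ct.cell_ids)


def hierarchical_clustering(
    expr: ExpressionMatrix,
    k: int = 3,
    method: str = "ward",
    metric: str = "euclidean",
) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering cross-check of the PCA populations.

    Euclidean distance with Ward linkage by default; the tree is cut at
    ``k`` clusters.  Returns the per-cell cluster labels (1..k) and the
    scipy linkage matrix.
    """
    n = expr.norm_ct.shape[0]
    if k > n:
        raise ValueError(f"cannot cut {k} clusters from {n} cells")
    Z = hierarchy.linkage(expr.norm_ct.to_numpy(dtype=float), method=method, metric=metric)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=expr.cell_ids, name="hcluster"), Z
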