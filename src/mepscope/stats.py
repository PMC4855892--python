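"""Per-gene population statistics and gene-gene correlation networks.

Population comparisons use the two-sample Kolmogorov-Smirnov test on
per-cell delta-Ct distributions with Benjamini-Hochberg FDR correction
across all gene x population-pair tests jointly; significance stars
follow the q-value thresholds * < 0.05, ** < 0.01, *** < 0.001.
Fold changes are reported on the linear 2^-dCt scale.  Gene networks
are signed Spearman correlations with average-rank tie handling;
drop-outs are retained at their imputed normalized values by default.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from mepscope.discovery import PopulationAssignment
from mepscope.qc import CtMatrix, ExpressionMatrix


def _stars(q: float) -> str:
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return "NS"  # boundary q = 0.05 is NS: "*" requires q strictly < 0.05


def _group_values(
    expr: ExpressionMatrix,
    assignment: PopulationAssignment,
    gene: str,
    pop: str,
    exclude_dropouts: bool,
) -> np.ndarray:
    cells = assignment.labels.index[assignment.labels == pop]
    vals = expr.norm_ct.loc[cells, gene]
    if exclude_dropouts:
        vals = vals[~expr.dropout.loc[cells, gene]]
    return vals.to_numpy(dtype=float)


def ks_fdr_table(
    expr: ExpressionMatrix,
    assignment: PopulationAssignment,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
    exclude_dropouts: bool = False,
) -> pd.DataFrame:
    """KS test per gene and population pair with joint BH correction.

    D is the exact two-sample KS statistic sup|F1 - F2|; p-values use
    the asymptotic distribution.  q-values are Benjamini-Hochberg
    adjusted across every gene x pair test in the table.
    """
    pops = list(assignment.counts().index[assignment.counts() > 0])
    if pairs is None:
        pairs = list(combinations(pops, 2))
    for a, b in pairs:
        for pop in (a, b):
            n = int((assignment.labels == pop).sum())
            if n < 2:
                raise ValueError(f"population {pop!r} has {n} cells (need >= 2)")
    rows = []
    for gene in expr.gene_symbols:
        for a, b in pairs:
            x = _group_values(expr, assignment, gene, a, exclude_dropouts)
            y = _group_values(expr, assignment, gene, b, exclude_dropouts)
            if len(x) == 0 or len(y) == 0:
                d, p = np.nan, np.nan
            else:
                res = sps.ks_2samp(x, y, method="asymp")
                d, p = float(res.statistic), float(res.pvalue)
            rows.append(
                {
                    "gene": gene,
                    "pop_a": a,
                    "pop_b": b,
                    "ks_D": d,
                    "p_value": p,
                    "mean_a": float(np.mean(x)) if len(x) else np.nan,
                    "mean_b": float(np.mean(y)) if len(y) else np.nan,
                }
            )
    table = pd.DataFrame(rows)
    ok = table["p_value"].notna()
    q = np.full(len(table), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(table.loc[ok, "p_value"], method="fdr_bh")[1]
    table["q_value"] = q
    table["stars"] = [_stars(v) if np.isfinite(v) else "NS" for v in q]
    return table


def detection_fraction(
    ct: CtMatrix, assignment: PopulationAssignment, gene: str
) -> pd.Series:
    """Fraction of cells with detectable amplification, per population.

    Returns one entry per population plus ``overall``; detection means
    the assay amplified (no drop-out, Ct below the limit of detection).
    """
    if gene not in ct.assay_ids:
        raise KeyError(f"gene {gene!r} not in matrix")
    detected = ~ct.dropout[gene]
    labels = assignment.labels.loc[ct.cell_ids]
    out = detected.groupby(labels).mean()
    out.loc["overall"] = detected.mean()
    return out.rename(gene)


def mean_fold_change(
    expr: ExpressionMatrix,
    assignment: PopulationAssignment,
    gene: str,
    target_pop: str,
) -> float:
    """Linear-scale fold change of ``gene`` in ``target_pop`` vs the rest.

    fold = 2^(mean dCt_rest - mean dCt_target); values above 1 mean
    higher expression in the target population.
    """
    if gene not in expr.gene_symbols:
        raise KeyError(f"gene {gene!r} not in matrix")
    in_target = assignment.labels == target_pop
    if not in_target.any():
        raise ValueError(f"target population {target_pop!r} is empty")
    if in_target.all():
        raise ValueError("complement of the target population is empty")
    vals = expr.norm_ct[gene]
    return float(
        2.0 ** (vals[~in_target].mean() - vals[in_target].mean())
    )


def spearman_network(
    expr: ExpressionMatrix,
    genes: Iterable[str],
    cells_subset: Optional[Iterable[str]] = None,
    min_abs_rho: float = 0.3,
    population: str = "",
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Signed Spearman co-expression edges among selected genes.

    Pairwise Spearman rho (average-rank ties; drop-outs enter at their
    imputed delta-Ct, producing ties at the detection limit) computed on
    the given cell subset.  Edges with |rho| >= ``min_abs_rho`` are
    returned once per unordered pair; pairs involving a constant gene
    have undefined rho and are skipped and reported.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    sub = expr.norm_ct[genes]
    if cells_subset is not None:
        sub = sub.loc[list(cells_subset)]
    if sub.shape[0] < 3:
        raise ValueError("need at least 3 cells")
    # correlate -dCt so a positive edge means co-expression
    mat = -sub
    constant = [g for g in genes if mat[g].std(ddof=0) == 0.0]
    rho = mat.corr(method="spearman").to_numpy()
    edges = []
    skipped = []
    for i, j in combinations(range(len(genes)), 2):
        a, b = genes[i], genes[j]
        if a in constant or b in constant:
            skipped.append((a, b))
            continue
        r = float(rho[i, j])
        if abs(r) >= min_abs_rho:
            edges.append(
                {
                    "gene_a": a,
                    "gene_b": b,
                    "spearman_rho": r,
                    "sign": "positive" if r > 0 else "negative",
                    "magnitude": abs(r),
                    "population": population,
                }
            )
    cols = ["gene_a", "gene_b", "spearman_rho", "sign", "magnitude", "population"]
    return pd.DataFrame(edges, columns=cols), skipped


def edges_to_graph(edges: pd.DataFrame):
    """networkx Graph from an edge table (for GraphML export)."""
    import networkx as nx

    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(
            row.gene_a,
            row.gene_b,
            rho=float(row.spearman_rho),
            sign=row.sign,
            magnitude=float(row.magnitude),
        )
    return g
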