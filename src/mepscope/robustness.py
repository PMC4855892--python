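"""Cluster stability under gene-subset permutation.

How strongly does the three-population structure depend on gene choice?
For random subsets of the assay panel (cardinality 10..G), PCA and
k-means are repeated and each new cluster is matched to the reference
populations by the mode of the reference labels among its members; the
congruence is the percentage of cells keeping their reference label.
A random-assignment baseline quantifies agreement expected by chance
under the same mode-matching rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from mepscope.discovery import PCAResult, PopulationAssignment, _kmeans_order_invariant
from mepscope.qc import ExpressionMatrix


@dataclass
class RobustnessCurve:
    """Mean congruence and chance baseline per gene-subset size."""

    table: pd.DataFrame  # size, n_subsets_evaluated, mean/sd congruence, baseline

    def congruence_at(self, size: int) -> float:
        row = self.table[self.table["size"] == size]
        if row.empty:
            raise KeyError(f"size {size} not in curve")
        return float(row["mean_congruence_pct"].iloc[0])


def sample_gene_subsets(
    genes: Sequence[str], size: int, max_subsets: int = 10000, seed: int = 0
) -> list[tuple[str, ...]]:
    """Distinct gene subsets of a given cardinality.

    Full enumeration when C(G, size) <= max_subsets; otherwise uniform
    rejection sampling of distinct combinations.
    """
    genes = list(genes)
    G = len(genes)
    if not 1 <= size <= G:
        raise ValueError(f"size must be in [1, {G}], got {size}")
    total = math.comb(G, size)
    if total <= max_subsets:
        from itertools import combinations

        return [tuple(c) for c in combinations(genes, size)]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[str, ...]] = []
    while len(out) < max_subsets:
        idx = tuple(sorted(rng.choice(G, size=size, replace=False).tolist()))
        if idx in seen:
            continue
        seen.add(idx)
        out.append(tuple(genes[i] for i in idx))
    return out


def match_clusters_by_mode(
    new_labels: pd.Series, reference_labels: pd.Series
) -> tuple[dict, float]:
    """Map each new cluster to the modal reference label of its members.

    Collisions are permitted (two new clusters may map to the same
    reference label); ties go to the smallest reference label in sorted
    order.  Returns the mapping and the congruence: the percentage of
    cells whose mapped label equals their reference label.
    """
    new_labels = pd.Series(new_labels)
    reference_labels = pd.Series(reference_labels)
    common = new_labels.index.intersection(reference_labels.index)
    if len(common) == 0:
        raise ValueError("new and reference labelings share no cells")
    new = new_labels.loc[common]
    ref = reference_labels.loc[common]
    ref_order = {lab: i for i, lab in enumerate(sorted(ref.unique(), key=str))}
    mapping = {}
    n_match = 0
    for cluster, members in ref.groupby(new, sort=True):
        counts = members.value_counts()
        best = max(counts.index, key=lambda lab: (counts[lab], -ref_order[lab]))
        mapping[cluster] = best
        n_match += int(counts[best])
    return mapping, 100.0 * n_match / len(common)


def random_assignment_baseline(
    reference: PopulationAssignment | pd.Series,
    n_perm: int = 100,
    seed: int = 0,
    k: int = 3,
) -> float:
    """Mode-matched congruence of uniformly random cluster assignments.

    Averaged over ``n_perm`` permutations; estimates the agreement
    attributable to chance alone under the mode-matching rule.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ref = reference.labels if isinstance(reference, PopulationAssignment) else reference
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    vals = []
    for _ in range(n_perm):
        rand = pd.Series(rng.integers(0, k, size=len(ref)), index=ref.index)
        _, pct = match_clusters_by_mode(rand, ref)
        vals.append(pct)
    return float(np.mean(vals))


def expected_random_congruence(
    proportions: Iterable[float],
    n: int,
    k: int = 3,
    n_sim: int = 4000,
    seed: int = 12345,
) -> float:
    """Expected mode-matched congruence of a uniformly random labeling.

    Under the mode rule the congruence equals (sum over new clusters of
    the largest reference-label count) / n.  With the reference label
    counts fixed, a uniform assignment scatters each label class over
    the k clusters as an independent multinomial; the expectation is
    computed directly from those class-wise allocations, independently
    of the per-cell labeling machinery, for use as an oracle.
    """
    p = np.asarray(list(proportions), dtype=float)
    p = p / p.sum()
    counts = np.rint(p * n).astype(int)
    rng = np.random.default_rng(seed)
    uniform = np.full(k, 1.0 / k)
    out = np.empty(n_sim)
    for s in range(n_sim):
        # cluster x class table: class c scatters multinomially over clusters
        table = np.column_stack([rng.multinomial(c, uniform) for c in counts])
        out[s] = 100.0 * table.max(axis=1).sum() / counts.sum()
    return float(out.mean())


def congruence_curve(
    expr: ExpressionMatrix,
    reference: PopulationAssignment,
    sizes: Sequence[int] | None = None,
    max_subsets: int = 100,
    seed: int = 0,
    k: int = 3,
    n_pcs: int = 2,
    n_init: int = 10,
) -> RobustnessCurve:
    """Congruence of cluster assignment across random gene subsets.

    For each subset: PCA restricted to the subset, k-means (k = 3) on
    the first two PCs with a per-subset seed derived from (seed, size,
    subset index), mode matching against the reference populations.  A
    random labeling is scored alongside each subset to form the chance
    baseline.  The full-panel subset reuses the reference seed so the
    reference computation is reproduced identically.
    """
    genes = list(expr.gene_symbols)
    G = len(genes)
    if sizes is None:
        sizes = list(range(10, G + 1))
    if not reference.cell_ids.equals(expr.cell_ids):
        raise ValueError("reference assignment must cover the expression cells")
    X = expr.norm_ct.to_numpy(dtype=float)
    col_of = {g: i for i, g in enumerate(genes)}
    ref = reference.labels
    rng_base = np.random.default_rng(np.random.SeedSequence([seed, 0xBA5E]))
    rows = []
    for size in sizes:
        if size > G:
            warnings.warn(f"subset size {size} exceeds gene count {G}; skipped")
            continue
        subsets = sample_gene_subsets(genes, size, max_subsets=max_subsets, seed=seed)
        cong = np.empty(len(subsets))
        base = np.empty(len(subsets))
        for i, subset in enumerate(subsets):
            cols = [col_of[g] for g in subset]
            Xs = X[:, cols]
            Xc = Xs - Xs.mean(axis=0)
            U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
            # same sign convention as run_pca so the full-panel subset
            # reproduces the reference scores exactly
            for j in range(min(n_pcs, Vt.shape[0])):
                if Vt[j, np.argmax(np.abs(Vt[j]))] < 0:
                    U[:, j] *= -1.0
            pcs = (U * S)[:, :n_pcs]
            if size == G:
                sub_seed = reference.seed
            else:
                sub_seed = int(
                    np.random.SeedSequence([seed, size, i]).generate_state(1)[0]
                    % (2**31)
                )
            labels = _kmeans_order_invariant(pcs, k=k, seed=sub_seed, n_init=n_init)
            _, cong[i] = match_clusters_by_mode(
                pd.Series(labels, index=expr.cell_ids), ref
            )
            rand = pd.Series(
                rng_base.integers(0, k, size=len(ref)), index=expr.cell_ids
            )
            _, base[i] = match_clusters_by_mode(rand, ref)
        rows.append(
            {
                "size": size,
                "n_subsets_evaluated": len(subsets),
                "mean_congruence_pct": float(cong.mean()),
                "sd_congruence_pct": float(cong.std(ddof=1)) if len(cong) > 1 else 0.0,
                "mean_random_baseline_pct": float(base.mean()),
            }
        )
    return RobustnessCurve(table=pd.DataFrame(rows))
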