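"""Index-sort fluorescence integration and surface-gate concordance.

Joins per-cell surface marker fluorescence (log2 MFI, recorded by the
index sorter) to the transcriptional population assignment, derives
per-marker positivity thresholds (manual, or the antimode of a
two-component Gaussian mixture when the marker is clearly bimodal),
classifies cells by the surface scheme

    Pre-MEP  = CD44-high, CD71-, CD41-
    E-MEP    = CD71+, CD41-
    MK-MEP   = CD71+, CD41+

(with cells between gates left unclassified), and scores one-vs-rest
sensitivity/specificity of the surface call against the transcriptional
populations.  Also tests Spearman correlation of each marker's MFI with
the mRNA of the same surface protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from mepscope.discovery import POPULATION_NAMES, PopulationAssignment
from mepscope.qc import ExpressionMatrix

#: transcript encoding each FACS marker in the default panel
MARKER_GENE = {
    "CD34": "CD34",
    "CD38": "CD38",
    "CD123": "IL3RA",
    "CD45RA": "PTPRC",
    "CD71": "TFRC",
    "CD41": "ITGA2B",
    "CD42": "GP1BA",
    "CD44": "CD44",
    "CD36": "CD36",
}

DEFAULT_MRNA_PAIRS = (
    ("CD34", "CD34"),
    ("CD38", "CD38"),
    ("CD71", "CD71"),
    ("CD41", "CD41"),
    ("CD42", "CD42"),
)


@dataclass
class GateSet:
    """Per-marker log2-MFI positivity thresholds (cells above are positive)."""

    thresholds: dict[str, float]
    source: dict[str, str] = field(default_factory=dict)  # manual | mixture

    def positive(self, index: pd.DataFrame, marker: str) -> pd.Series:
        return index[marker] > self.thresholds[marker]


@dataclass
class ConcordanceReport:
    """Confusion matrix and one-vs-rest metrics of surface vs transcriptome."""

    confusion: pd.DataFrame  # surface label (incl. unclassified) x population
    metrics: pd.DataFrame  # per population: sensitivity, specificity
    n_unclassified: int


def attach_index_data(
    expr: ExpressionMatrix, index: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inner-join index-sort fluorescence onto the expression cells.

    Returns the joined table (markers + delta-Ct columns) and a report
    of cells present on only one side.
    """
    if index.index.has_duplicates:
        dups = index.index[index.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated cell_id(s) in index table: {dups}")
    common = expr.cell_ids.intersection(index.index)
    if len(common) == 0:
        raise ValueError("no overlapping cell ids between expression and index data")
    unmatched = pd.DataFrame(
        [
            {"cell_id": c, "missing_from": "index"}
            for c in expr.cell_ids.difference(index.index)
        ]
        + [
            {"cell_id": c, "missing_from": "expression"}
            for c in index.index.difference(expr.cell_ids)
        ],
        columns=["cell_id", "missing_from"],
    )
    joined = index.loc[common].join(expr.norm_ct.loc[common], rsuffix="_dCt")
    return joined, unmatched


def _mixture_antimode(values: np.ndarray, min_separation: float = 2.0) -> float:
    """Threshold at the density minimum between two Gaussian components.

    Raises if the two-component fit does not indicate clear bimodality
    (components too close or one vanishingly small).
    """
    v = values.reshape(-1, 1)
    gm = GaussianMixture(n_components=2, n_init=5, random_state=0).fit(v)
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    w = gm.weights_.ravel()
    sep = abs(mu[0] - mu[1]) / np.sqrt((sd[0] ** 2 + sd[1] ** 2) / 2.0)
    if sep < min_separation or w.min() < 0.02:
        raise ValueError(
            f"marker does not look bimodal (separation {sep:.2f}, "
            f"min weight {w.min():.3f}); provide a manual threshold"
        )
    lo, hi = sorted(mu)
    grid = np.linspace(lo, hi, 512)
    dens = (
        w[0] * sps.norm.pdf(grid, mu[0], sd[0])
        + w[1] * sps.norm.pdf(grid, mu[1], sd[1])
    )
    return float(grid[np.argmin(dens)])


def derive_gates(
    index: pd.DataFrame,
    manual: Optional[dict[str, float]] = None,
    markers: Optional[Sequence[str]] = None,
) -> GateSet:
    """Per-marker positivity thresholds from manual values or mixtures.

    Manual thresholds are honored verbatim.  Otherwise the threshold is
    placed at the antimode of a two-component Gaussian mixture fitted to
    the marker's log2 MFI; markers that are constant or not clearly
    bimodal raise unless a manual threshold is supplied.  (Bench gating
    uses fluorescence-minus-one controls, which have no computational
    counterpart; this data-driven default is deterministic and
    auditable.)
    """
    manual = dict(manual or {})
    if markers is None:
        markers = [c for c in index.columns if c in MARKER_GENE]
    thresholds: dict[str, float] = {}
    source: dict[str, str] = {}
    for m in markers:
        if m in manual:
            thresholds[m] = float(manual[m])
            source[m] = "manual"
            continue
        if m not in index.columns:
            raise KeyError(f"marker {m!r} not in index table")
        vals = index[m].to_numpy(dtype=float)
        if np.std(vals) == 0:
            raise ValueError(f"marker {m!r} is constant; provide a manual threshold")
        thresholds[m] = _mixture_antimode(vals)
        source[m] = "mixture"
    return GateSet(thresholds=thresholds, source=source)


def classify_by_gates(index: pd.DataFrame, gates: GateSet) -> pd.Series:
    """Surface-phenotype labels from CD44/CD71/CD41 gates.

    Cells between gates (e.g. CD71- CD41+, or CD71- CD41- but not
    CD44-high) are labeled ``unclassified``.  If the panel variant
    without CD44 (CD36 swapped in) is used, Pre-MEP falls back to the
    purely negative CD71- CD41- definition.
    """
    for m in ("CD71", "CD41"):
        if m not in gates.thresholds:
            raise KeyError(f"gate for {m!r} required")
    cd71 = gates.positive(index, "CD71")
    cd41 = gates.positive(index, "CD41")
    if "CD44" in gates.thresholds and "CD44" in index.columns:
        pre_mask = gates.positive(index, "CD44") & ~cd71 & ~cd41
    else:
        pre_mask = ~cd71 & ~cd41
    labels = pd.Series("unclassified", index=index.index, name="surface_label")
    labels[pre_mask] = "Pre-MEP"
    labels[cd71 & ~cd41] = "E-MEP"
    labels[cd71 & cd41] = "MK-MEP"
    return labels


def concordance_metrics(
    surface_labels: pd.Series, assignment: PopulationAssignment
) -> ConcordanceReport:
    """Confusion matrix and one-vs-rest sensitivity/specificity.

    The surface label is treated as the test and the transcriptional
    population as truth.  Unclassified (between-gate) cells appear in
    the confusion matrix but are excluded from the per-population
    metrics; populations absent from the truth get NaN metrics.
    """
    common = surface_labels.index.intersection(assignment.cell_ids)
    if len(common) == 0:
        raise ValueError("no shared cells between surface labels and assignment")
    surf = surface_labels.loc[common]
    truth = assignment.labels.loc[common]
    confusion = pd.crosstab(surf, truth).reindex(
        index=list(POPULATION_NAMES) + ["unclassified"],
        columns=list(POPULATION_NAMES),
        fill_value=0,
    )
    classified = surf != "unclassified"
    rows = []
    for pop in POPULATION_NAMES:
        t = truth[classified] == pop
        s = surf[classified] == pop
        if t.sum() == 0:
            rows.append({"population": pop, "sensitivity": np.nan, "specificity": np.nan})
            continue
        tp = int((s & t).sum())
        fn = int((~s & t).sum())
        fp = int((s & ~t).sum())
        tn = int((~s & ~t).sum())
        rows.append(
            {
                "population": pop,
                "sensitivity": tp / (tp + fn),
                "specificity": tn / (tn + fp) if (tn + fp) else np.nan,
            }
        )
    return ConcordanceReport(
        confusion=confusion,
        metrics=pd.DataFrame(rows).set_index("population"),
        n_unclassified=int((surf == "unclassified").sum()),
    )


def mfi_mrna_correlation(
    index: pd.DataFrame,
    expr: ExpressionMatrix,
    pairs: Sequence[tuple[str, str]] = DEFAULT_MRNA_PAIRS,
) -> pd.DataFrame:
    """Spearman correlation of surface fluorescence with same-protein mRNA.

    For each (marker, protein) pair: rho between log2 MFI and -dCt of
    the encoding transcript, BH-adjusted over the tested pairs.
    """
    common = index.index.intersection(expr.cell_ids)
    rows = []
    for marker, protein in pairs:
        gene = MARKER_GENE.get(protein, protein)
        if marker not in index.columns:
            raise KeyError(f"marker {marker!r} not in index table")
        if gene not in expr.gene_symbols:
            raise KeyError(f"no transcript column {gene!r} for protein {protein!r}")
        res = sps.spearmanr(
            index.loc[common, marker], -expr.norm_ct.loc[common, gene]
        )
        rows.append(
            {
                "marker": marker,
                "gene": gene,
                "spearman_rho": float(res.statistic),
                "p_value": float(res.pvalue),
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
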