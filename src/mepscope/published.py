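"""Loaders for the deposited MEP single-cell qPCR tables (GEO GSE79331).

The study's raw and normalized Ct tables are distributed via GEO
accession GSE79331 and as supplementary tables alongside the article;
they are not bundled here.  Download them, export as CSV (cells as
rows, assay ids as columns, a ``sort_gate`` column distinguishing
unselected MEP from CD71+41+-selected cells, "Fail" for failed
assays), and point these helpers at the directory.
"""

from __future__ import annotations

from pathlib import Path

from mepscope import discovery, qc as qc_mod
from mepscope.panel import build_default_panel

RAW_NAME = "raw_ct.csv"


def load_published_ct_table(data_dir: str | Path, lod: float = 40.0) -> qc_mod.CtMatrix:
    """Read the deposited raw Ct matrix from ``data_dir / raw_ct.csv``."""
    path = Path(data_dir) / RAW_NAME
    if not path.exists():
        raise FileNotFoundError(
            f"deposited Ct table not found at {path}; download GSE79331 and "
            "export the raw table as CSV (see mepscope.published docstring)"
        )
    return qc_mod.read_ct_table(path, lod=lod)


def analyze_published(data_dir: str | Path, seed: int = 0) -> dict:
    """QC, PCA, and detection summaries of the deposited dataset.

    Returns retained cell/assay counts (overall and per sort gate), the
    PC1/PC2 variance percentages on all retained cells and on the
    unselected cells alone, and the number of cells with detectable MPO.
    """
    ct_raw = load_published_ct_table(data_dir)
    ct, _ = qc_mod.filter_assays(ct_raw)
    ct, cell_report = qc_mod.filter_cells(ct)
    expr = qc_mod.normalize_to_housekeeping(ct)
    pca_all = discovery.run_pca(expr)
    out = {
        "n_cells_retained": ct.n_cells,
        "n_assays_retained": ct.n_assays,
        "pc1_variance_pct_all": 100.0 * float(pca_all.variance_fraction[0]),
        "pc2_variance_pct_all": 100.0 * float(pca_all.variance_fraction[1]),
    }
    if "sort_gate" in ct.cell_meta.columns:
        gate = ct.cell_meta["sort_gate"]
        out["n_unselected"] = int((gate == "unselected_MEP").sum())
        out["n_selected"] = int((gate == "CD71+41+_selected").sum())
        unsel = ct.select_cells(gate.index[gate == "unselected_MEP"])
        pca_unsel = discovery.run_pca(qc_mod.normalize_to_housekeeping(unsel))
        out["pc1_variance_pct_unselected"] = 100.0 * float(
            pca_unsel.variance_fraction[0]
        )
    if "MPO" in ct.assay_ids:
        out["mpo_detected_cells"] = int((~ct.dropout["MPO"]).sum())
    return out


def robustness_at_size(data_dir: str | Path, size: int = 25, max_subsets: int = 200,
                       seed: int = 0) -> float:
    """Mean congruence at one gene-subset size on the deposited data."""
    from mepscope.robustness import congruence_curve

    ct_raw = load_published_ct_table(data_dir)
    ct, _ = qc_mod.filter_assays(ct_raw)
    ct, _ = qc_mod.filter_cells(ct)
    expr = qc_mod.normalize_to_housekeeping(ct)
    pca = discovery.run_pca(expr)
    reference = discovery.assign_populations(
        pca, expr, build_default_panel(), seed=seed
    )
    curve = congruence_curve(
        expr, reference, sizes=[size], max_subsets=max_subsets, seed=seed
    )
    return curve.congruence_at(size)
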