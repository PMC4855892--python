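"""End-to-end pipeline orchestration with manifests and report bundles.

Sequences the stages (simulate/read -> QC -> normalize -> PCA -> assign
-> robustness -> DE/networks -> gates -> concordance), writes each
module's tabular artifacts plus a summary.json, and records a manifest
with the config hash, seed, and artifact checksums so a rerun with an
unchanged config can be skipped (resume).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from mepscope import discovery, gates as gates_mod, qc as qc_mod, robustness as rob_mod
from mepscope import stats as stats_mod
from mepscope.panel import GenePanel, build_default_panel
from mepscope.qc import PipelineError
from mepscope.synthetic import PopulationParams, simulate_cells

log = logging.getLogger("mepscope")


@dataclass
class PipelineConfig:
    """Configuration for a full run; either input paths or a simulate block."""

    ct_path: Optional[str] = None
    index_path: Optional[str] = None
    titration_path: Optional[str] = None
    panel_path: Optional[str] = None
    simulate: Optional[dict[str, Any]] = None  # n_cells, n_selected, params...
    lod: float = 40.0
    max_failed: int = 70
    b2m_max_ct: float = 13.0
    gapdh_max_ct: float = 15.0
    mean_ct_max: float = 20.0
    n_pcs: int = 2
    k: int = 3
    robustness_sizes: tuple[int, ...] = (10, 25, 45, 87)
    max_subsets: int = 50
    n_perm_baseline: int = 50
    gate_thresholds: dict[str, float] = field(default_factory=dict)
    network_min_abs_rho: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.ct_path is None and self.simulate is None:
            raise ValueError("config needs either input paths or a simulate block")
        for name in ("max_failed", "b2m_max_ct", "gapdh_max_ct", "mean_ct_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["robustness_sizes"] = list(self.robustness_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "robustness_sizes" in d:
            d["robustness_sizes"] = tuple(d["robustness_sizes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class PipelineResult:
    config: PipelineConfig
    summary: dict[str, Any]
    assignment: Optional[discovery.PopulationAssignment] = None
    pca: Optional[discovery.PCAResult] = None
    expr: Optional[qc_mod.ExpressionMatrix] = None
    de_table: Optional[pd.DataFrame] = None
    curve: Optional[rob_mod.RobustnessCurve] = None
    concordance: Optional[gates_mod.ConcordanceReport] = None
    resumed: bool = False


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return out

        return wrapper

    return deco


def _build_params(cfg: PipelineConfig) -> tuple[PopulationParams, int, int]:
    sim = dict(cfg.simulate or {})
    n_cells = int(sim.pop("n_cells", 700))
    n_selected = int(sim.pop("n_selected", 0))
    sim.setdefault("seed", cfg.seed)
    if "proportions" in sim:
        sim["proportions"] = tuple(sim["proportions"])
    return PopulationParams(**sim), n_cells, n_selected


def run_full_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    resume: bool = False,
) -> PipelineResult:
    """Execute every stage and write the report bundle to ``outdir``.

    With ``resume=True`` and an existing manifest whose config hash and
    artifacts are unchanged, the run is skipped and the stored summary
    returned.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    chash = config.config_hash()
    if resume and manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        artifacts = manifest.get("artifacts", {})
        if manifest.get("config_hash") == chash and all(
            (outdir / name).exists() and _sha256(outdir / name) == digest
            for name, digest in artifacts.items()
        ):
            log.info("resume: config unchanged, skipping all stages")
            summary = json.loads((outdir / "summary.json").read_text())
            return PipelineResult(config=config, summary=summary, resumed=True)

    panel = (
        GenePanel.from_frame(pd.read_csv(config.panel_path))
        if config.panel_path
        else build_default_panel()
    )

    @_stage("input")
    def load_inputs():
        if config.simulate is not None:
            params, n_cells, n_selected = _build_params(config)
            ds = simulate_cells(panel, params, n_cells, n_selected=n_selected)
            return ds.ct, ds.index, ds.truth
        ct = qc_mod.read_ct_table(config.ct_path, lod=config.lod)
        index = (
            pd.read_csv(config.index_path, index_col=0)
            if config.index_path
            else None
        )
        return ct, index, None

    ct_raw, index, truth = load_inputs()
    log.info("input: %d cells x %d assays", ct_raw.n_cells, ct_raw.n_assays)

    @_stage("qc")
    def run_qc(ct):
        reports = []
        if panel.duplicate_groups:
            ct, rep = qc_mod.merge_duplicate_assays(ct, panel)
            reports.append(("duplicates", rep))
        ct, rep_a = qc_mod.filter_assays(ct)
        reports.append(("assays", rep_a))
        ct, rep_c = qc_mod.filter_cells(
            ct,
            max_failed=config.max_failed,
            b2m_max_ct=config.b2m_max_ct,
            gapdh_max_ct=config.gapdh_max_ct,
            mean_ct_max=config.mean_ct_max,
        )
        reports.append(("cells", rep_c))
        return ct, reports

    ct, qc_reports = run_qc(ct_raw)
    log.info("qc: retained %d cells x %d assays", ct.n_cells, ct.n_assays)

    expr = _stage("normalize")(qc_mod.normalize_to_housekeeping)(ct)

    @_stage("cluster")
    def cluster():
        pca = discovery.run_pca(expr)
        assignment = discovery.assign_populations(
            pca, expr, panel, k=config.k, n_pcs=config.n_pcs, seed=config.seed
        )
        top = discovery.top_weighted_genes(pca, n=min(18, len(expr.gene_symbols)))
        hlabels, _ = discovery.hierarchical_clustering(expr, k=config.k)
        zifa = discovery.dropout_transform_for_zifa(ct)
        return pca, assignment, top, hlabels, zifa

    pca, assignment, top_genes, hlabels, zifa = cluster()
    log.info("cluster: population sizes %s", assignment.counts().to_dict())

    @_stage("robustness")
    def robustness():
        sizes = [s for s in config.robustness_sizes if s <= len(expr.gene_symbols)]
        if len(expr.gene_symbols) not in sizes:
            sizes.append(len(expr.gene_symbols))
        curve = rob_mod.congruence_curve(
            expr,
            assignment,
            sizes=sizes,
            max_subsets=config.max_subsets,
            seed=config.seed,
            k=config.k,
            n_pcs=config.n_pcs,
        )
        baseline = rob_mod.random_assignment_baseline(
            assignment, n_perm=config.n_perm_baseline, seed=config.seed, k=config.k
        )
        return curve, baseline

    curve, baseline_pct = robustness()

    @_stage("stats")
    def run_stats():
        de = stats_mod.ks_fdr_table(expr, assignment)
        det = ct.detected()
        det_frac = det.groupby(assignment.labels).mean().T
        det_frac["overall"] = det.mean()
        net_genes = [
            g
            for g in panel.genes_in_category("erythroid")
            + panel.genes_in_category("megakaryocyte")
            if g in expr.gene_symbols
        ]
        edge_frames = []
        for pop in discovery.POPULATION_NAMES:
            cells = assignment.labels.index[assignment.labels == pop]
            if len(cells) < 3:
                continue
            edges, _ = stats_mod.spearman_network(
                expr,
                net_genes,
                cells_subset=cells,
                min_abs_rho=config.network_min_abs_rho,
                population=pop,
            )
            edge_frames.append(edges)
        edges = (
            pd.concat(edge_frames, ignore_index=True)
            if edge_frames
            else pd.DataFrame()
        )
        return de, det_frac, edges

    de_table, det_frac, edges = run_stats()

    @_stage("gates")
    def run_gates():
        if index is None:
            return None, None, None, None
        idx = index.drop(columns=["sort_gate"], errors="ignore")
        joined, unmatched = gates_mod.attach_index_data(expr, idx)
        markers = [m for m in ("CD44", "CD71", "CD41") if m in idx.columns]
        try:
            gateset = gates_mod.derive_gates(
                idx.loc[expr.cell_ids],
                manual=config.gate_thresholds or None,
                markers=markers,
            )
        except ValueError:
            # CD44 separates populations by a modest (~fivefold) shift and can
            # be unimodal in fluorescence; fall back to the CD71/CD41 scheme
            # where Pre-MEP is the double-negative fraction.
            gateset = gates_mod.derive_gates(
                idx.loc[expr.cell_ids],
                manual=config.gate_thresholds or None,
                markers=[m for m in markers if m != "CD44"],
            )
        surface = gates_mod.classify_by_gates(idx.loc[expr.cell_ids], gateset)
        conc = gates_mod.concordance_metrics(surface, assignment)
        mfi_corr = gates_mod.mfi_mrna_correlation(idx, expr)
        return gateset, surface, conc, mfi_corr

    gateset, surface_labels, concordance, mfi_corr = run_gates()

    results = PipelineResult(
        config=config,
        summary={},
        assignment=assignment,
        pca=pca,
        expr=expr,
        de_table=de_table,
        curve=curve,
        concordance=concordance,
    )
    summary: dict[str, Any] = {
        "seed": config.seed,
        "config_hash": chash,
        "n_cells_input": int(ct_raw.n_cells),
        "n_cells_retained": int(ct.n_cells),
        "n_assays_retained": int(ct.n_assays),
        "population_sizes": {k: int(v) for k, v in assignment.counts().items()},
        "variance_fraction_pct": [
            round(100.0 * float(v), 4) for v in pca.variance_fraction[:10]
        ],
        "top_weighted_genes": top_genes,
        "congruence": {
            str(int(r.size)): round(float(r.mean_congruence_pct), 3)
            for r in curve.table.itertuples(index=False)
        },
        "random_baseline_pct": round(float(baseline_pct), 3),
        "n_significant_q05": int((de_table["q_value"] < 0.05).sum()),
    }
    if truth is not None:
        from sklearn.metrics import adjusted_rand_score

        shared = assignment.labels.index
        summary["ari_vs_truth"] = round(
            float(adjusted_rand_score(truth.loc[shared], assignment.labels)), 4
        )
    if concordance is not None:
        summary["gate_concordance"] = {
            pop: {
                "sensitivity": round(float(row["sensitivity"]), 4),
                "specificity": round(float(row["specificity"]), 4),
            }
            for pop, row in concordance.metrics.iterrows()
        }
        summary["n_unclassified_by_gates"] = concordance.n_unclassified
    results.summary = summary

    write_report(
        results,
        outdir,
        extra_tables={
            "zifa_input.tsv": zifa,
            "hierarchical_labels.tsv": hlabels.to_frame(),
            "detection_fractions.tsv": det_frac,
            "edges.tsv": edges,
            "mfi_mrna_corr.tsv": mfi_corr,
            "surface_labels.tsv": None
            if surface_labels is None
            else surface_labels.to_frame(),
            "qc_excluded_cells.tsv": next(
                rep.excluded_cells for name, rep in qc_reports if name == "cells"
            ),
        },
        gateset=gateset,
    )
    return results


def write_report(
    results: PipelineResult,
    outdir: str | Path,
    extra_tables: Optional[dict[str, Optional[pd.DataFrame]]] = None,
    gateset: Optional[gates_mod.GateSet] = None,
) -> list[str]:
    """Write the TSV/JSON artifact bundle plus summary and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def emit(name: str, df: Optional[pd.DataFrame]):
        if df is None:
            return
        path = outdir / name
        df.to_csv(path, sep="\t")
        written.append(name)

    if results.pca is not None:
        emit("pca_scores.tsv", results.pca.scores)
        emit("pca_loadings.tsv", results.pca.loadings)
        emit(
            "variance_fractions.tsv",
            pd.DataFrame(
                {"variance_fraction": results.pca.variance_fraction},
                index=results.pca.scores.columns,
            ),
        )
    if results.assignment is not None and results.pca is not None:
        assignments = pd.DataFrame(
            {
                "population": results.assignment.labels,
                "PC1": results.pca.scores["PC1"],
                "PC2": results.pca.scores["PC2"],
            }
        )
        emit("assignments.tsv", assignments)
    if results.de_table is not None:
        emit("de_table.tsv", results.de_table)
    if results.curve is not None:
        emit("robustness_curve.tsv", results.curve.table)
    if results.concordance is not None:
        emit("confusion_matrix.tsv", results.concordance.confusion)
        emit("concordance.tsv", results.concordance.metrics)
    for name, df in (extra_tables or {}).items():
        emit(name, df)
    if gateset is not None:
        (outdir / "gates.json").write_text(
            json.dumps(
                {"thresholds": gateset.thresholds, "source": gateset.source},
                indent=2,
                sort_keys=True,
            )
        )
        written.append("gates.json")

    (outdir / "summary.json").write_text(
        json.dumps(results.summary, indent=2, sort_keys=True)
    )
    written.append("summary.json")
    manifest = {
        "config_hash": results.config.config_hash(),
        "seed": results.config.seed,
        "artifacts": {name: _sha256(outdir / name) for name in sorted(written)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return written
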