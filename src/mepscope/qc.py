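"""Quality control and normalization of single-cell qPCR Ct matrices.

Implements the ingest and exclusion rules of Biomark-style targeted
single-cell qPCR: "Fail" calls fixed at the limit of detection (Ct 40),
duplicate-assay merging, zero-variance assay removal, per-cell
exclusion on drop-out count / housekeeping level / mean Ct, delta-Ct
normalization to the mean of B2M and GAPDH, and linearity validation
of assays from serial-dilution titration data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from mepscope.panel import GenePanel

HOUSEKEEPING_REQUIRED = ("B2M", "GAPDH")


class FormatError(ValueError):
    """Input table does not have the expected layout or columns."""


class ParseError(ValueError):
    """A table entry could not be interpreted as Ct or a Fail flag."""


class ConfigurationError(ValueError):
    """Panel/matrix mismatch or invalid analysis configuration."""


class PipelineError(RuntimeError):
    """A stage produced an empty or degenerate result."""


@dataclass
class CtMatrix:
    """Cells x assays raw Ct values with a drop-out mask.

    Ct values lie in (0, lod]; flagged drop-outs are recorded at exactly
    the limit of detection.  ``cell_meta`` carries donor / plate / well /
    sort-gate annotations when available.
    """

    ct: pd.DataFrame
    dropout: pd.DataFrame
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    lod: float = 40.0

    def __post_init__(self) -> None:
        if self.ct.shape != self.dropout.shape:
            raise ValueError("ct and dropout shapes differ")
        if list(self.ct.index) != list(self.dropout.index) or list(
            self.ct.columns
        ) != list(self.dropout.columns):
            raise ValueError("ct and dropout must share index and columns")
        if self.ct.index.has_duplicates:
            raise ValueError("cell_ids must be unique")
        vals = self.ct.to_numpy(dtype=float)
        if np.any(vals <= 0) or np.any(vals > self.lod + 1e-9):
            raise ValueError("Ct values must lie in (0, lod]")
        mask = self.dropout.to_numpy(dtype=bool)
        if not np.allclose(vals[mask], self.lod):
            raise ValueError("drop-out entries must equal the lod exactly")
        if len(self.cell_meta) and list(self.cell_meta.index) != list(self.ct.index):
            raise ValueError("cell_meta index must match cell ids")

    @property
    def cell_ids(self) -> pd.Index:
        return self.ct.index

    @property
    def assay_ids(self) -> pd.Index:
        return self.ct.columns

    @property
    def n_cells(self) -> int:
        return self.ct.shape[0]

    @property
    def n_assays(self) -> int:
        return self.ct.shape[1]

    def detected(self) -> pd.DataFrame:
        """Boolean mask of detected (non-drop-out) entries."""
        return ~self.dropout

    def select_cells(self, cell_ids) -> "CtMatrix":
        meta = self.cell_meta.loc[cell_ids] if len(self.cell_meta) else self.cell_meta
        return CtMatrix(
            ct=self.ct.loc[cell_ids],
            dropout=self.dropout.loc[cell_ids],
            cell_meta=meta,
            lod=self.lod,
        )

    def select_assays(self, assay_ids) -> "CtMatrix":
        return CtMatrix(
            ct=self.ct[list(assay_ids)],
            dropout=self.dropout[list(assay_ids)],
            cell_meta=self.cell_meta,
            lod=self.lod,
        )


@dataclass
class ExpressionMatrix:
    """Housekeeping-normalized expression (delta-Ct; lower = more transcript)."""

    norm_ct: pd.DataFrame
    housekeeping_mean: pd.Series
    dropout: pd.DataFrame
    housekeeping: tuple[str, ...] = HOUSEKEEPING_REQUIRED
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    lod: float = 40.0

    @property
    def cell_ids(self) -> pd.Index:
        return self.norm_ct.index

    @property
    def gene_symbols(self) -> pd.Index:
        return self.norm_ct.columns

    def linear_expression(self) -> pd.DataFrame:
        """2^(-delta Ct) linear-scale expression values."""
        return 2.0 ** (-self.norm_ct)

    def select_genes(self, genes) -> "ExpressionMatrix":
        genes = list(genes)
        return ExpressionMatrix(
            norm_ct=self.norm_ct[genes],
            housekeeping_mean=self.housekeeping_mean,
            dropout=self.dropout[genes],
            housekeeping=tuple(g for g in self.housekeeping if g in genes),
            cell_meta=self.cell_meta,
            lod=self.lod,
        )


@dataclass
class QCReport:
    """Record of excluded cells/assays with reasons and before/after counts."""

    excluded_cells: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["cell_id", "reason"])
    )
    excluded_assays: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["assay_id", "reason"])
    )
    flagged_assays: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["assay_id", "reason"])
    )
    n_cells_before: int = 0
    n_cells_after: int = 0
    n_assays_before: int = 0
    n_assays_after: int = 0

    def validate_counts(self) -> None:
        if self.n_cells_before - len(self.excluded_cells) != self.n_cells_after:
            raise AssertionError("cell counts inconsistent with exclusions")
        if self.n_assays_before - len(self.excluded_assays) != self.n_assays_after:
            raise AssertionError("assay counts inconsistent with exclusions")


@dataclass
class TitrationFit:
    """Per-assay dilution slope/r2 and estimated between-pool offsets."""

    per_assay: pd.DataFrame  # index assay; columns slope, r_squared, n_points, unfit
    pool_offsets: pd.Series  # cycles, relative to the first pool


def read_ct_table(path: str | Path, lod: float = 40.0) -> CtMatrix:
    """Read a cells x assays Ct CSV/TSV with "Fail" flags.

    "Fail" tokens and values beyond ``lod`` become drop-outs recorded at
    the limit of detection.  Metadata columns (donor, plate, well,
    sort_gate), if present, are moved to ``cell_meta``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    meta_cols = [c for c in ("donor", "plate", "well", "sort_gate") if c in raw.columns]
    meta = raw[meta_cols].copy() if meta_cols else pd.DataFrame(index=raw.index)
    raw = raw.drop(columns=meta_cols)
    missing = [h for h in HOUSEKEEPING_REQUIRED if h not in raw.columns]
    if missing:
        raise FormatError(f"missing housekeeping columns: {', '.join(missing)}")

    ct = np.empty(raw.shape, dtype=float)
    drop = np.zeros(raw.shape, dtype=bool)
    for j, col in enumerate(raw.columns):
        for i, (cell, token) in enumerate(raw[col].items()):
            s = "" if token is None or (isinstance(token, float) and np.isnan(token)) else str(token).strip()
            if s.lower() == "fail" or s == "":
                ct[i, j], drop[i, j] = lod, True
                continue
            try:
                v = float(s)
            except ValueError as exc:
                raise ParseError(
                    f"non-numeric value {s!r} at cell {cell!r}, assay {col!r}"
                ) from exc
            if v >= lod:
                ct[i, j], drop[i, j] = lod, True
            else:
                ct[i, j] = v
    return CtMatrix(
        ct=pd.DataFrame(ct, index=raw.index, columns=raw.columns),
        dropout=pd.DataFrame(drop, index=raw.index, columns=raw.columns),
        cell_meta=meta,
        lod=lod,
    )


def merge_duplicate_assays(
    ct: CtMatrix,
    panel: GenePanel,
    min_rho: float = 0.8,
    min_co_detected: int = 3,
) -> tuple[CtMatrix, QCReport]:
    """Merge or reduce duplicated assays per their cross-correlation.

    Well-correlated duplicate pairs (Spearman rho >= ``min_rho`` across
    co-detected cells) are merged to the per-cell mean of detected
    member values; the merged entry is a drop-out only when every member
    dropped out.  Poorly correlated groups keep only the member with the
    most detections.
    """
    report = QCReport(
        n_cells_before=ct.n_cells,
        n_cells_after=ct.n_cells,
        n_assays_before=ct.n_assays,
    )
    ct_df = ct.ct.copy()
    drop_df = ct.dropout.copy()
    removed: list[dict] = []
    for group, members in panel.duplicate_groups.items():
        absent = [m for m in members if m not in ct_df.columns]
        if absent:
            raise ConfigurationError(
                f"duplicate_group {group!r}: members {absent} absent from matrix"
            )
        det = ~drop_df[members]
        co = det.all(axis=1)
        merged_ok = False
        if int(co.sum()) >= min_co_detected:
            vals = ct_df.loc[co, members]
            rho = stats.spearmanr(vals.to_numpy()).statistic
            if len(members) == 2:
                rho_min = float(rho)
            else:
                rho_min = float(np.min(rho[np.triu_indices(len(members), k=1)]))
            merged_ok = rho_min >= min_rho
        first = members[0]
        if merged_ok:
            detected_vals = ct_df[members].where(det)
            merged = detected_vals.mean(axis=1)
            all_drop = drop_df[members].all(axis=1)
            ct_df[first] = merged.where(~all_drop, ct.lod)
            drop_df[first] = all_drop
            for m in members[1:]:
                removed.append({"assay_id": m, "reason": "merged_duplicate"})
        else:
            keep = max(members, key=lambda m: (int(det[m].sum()), m))
            ct_df[keep] = ct_df[keep]
            for m in members:
                if m != keep:
                    removed.append({"assay_id": m, "reason": "bad_duplicate"})
        drop_cols = [r["assay_id"] for r in removed if r["assay_id"] in ct_df.columns]
        ct_df = ct_df.drop(columns=[c for c in drop_cols if c in ct_df.columns])
        drop_df = drop_df.drop(columns=[c for c in drop_cols if c in drop_df.columns])
    report.excluded_assays = pd.DataFrame(removed, columns=["assay_id", "reason"])
    report.n_assays_after = ct_df.shape[1]
    out = CtMatrix(ct=ct_df, dropout=drop_df, cell_meta=ct.cell_meta, lod=ct.lod)
    report.validate_counts()
    return out, report


def filter_assays(ct: CtMatrix) -> tuple[CtMatrix, QCReport]:
    """Drop non-informative assays (zero Ct standard deviation).

    Assays whose detected values show fewer than 2 distinct levels or
    >98 % drop-out are additionally *flagged* (not removed) as not
    showing the expected Ct distribution.
    """
    sd = ct.ct.std(axis=0, ddof=0)
    zero_var = list(ct.assay_ids[sd == 0.0])
    keep = [a for a in ct.assay_ids if a not in set(zero_var)]
    if not keep:
        raise PipelineError("all assays removed by zero-variance filter")
    flagged = []
    for a in keep:
        det = ~ct.dropout[a]
        frac_drop = 1.0 - det.mean()
        distinct = ct.ct.loc[det, a].nunique()
        if distinct < 2 or frac_drop > 0.98:
            flagged.append({"assay_id": a, "reason": "bad_distribution"})
    report = QCReport(
        excluded_assays=pd.DataFrame(
            [{"assay_id": a, "reason": "zero_variance"} for a in zero_var],
            columns=["assay_id", "reason"],
        ),
        flagged_assays=pd.DataFrame(flagged, columns=["assay_id", "reason"]),
        n_cells_before=ct.n_cells,
        n_cells_after=ct.n_cells,
        n_assays_before=ct.n_assays,
        n_assays_after=len(keep),
    )
    report.validate_counts()
    return ct.select_assays(keep), report


def filter_cells(
    ct: CtMatrix,
    max_failed: int = 70,
    b2m_max_ct: float = 13.0,
    gapdh_max_ct: float = 15.0,
    mean_ct_max: float = 20.0,
) -> tuple[CtMatrix, QCReport]:
    """Apply the per-cell technical exclusion rules.

    A cell is excluded when (in this order, first reason recorded):
    more than ``max_failed`` assays failed to amplify; B2M Ct above
    ``b2m_max_ct``; GAPDH Ct above ``gapdh_max_ct``; or mean Ct over
    the assays with detectable amplification above ``mean_ct_max``.
    All comparisons are strict, so boundary cells are retained.
    """
    for h in HOUSEKEEPING_REQUIRED:
        if h not in ct.assay_ids:
            raise ConfigurationError(f"housekeeping assay {h!r} missing")
    n_failed = ct.dropout.sum(axis=1)
    detected = ct.detected()
    mean_detected = ct.ct.where(detected).mean(axis=1)
    excluded = []
    keep = []
    for cell in ct.cell_ids:
        if n_failed[cell] > max_failed:
            excluded.append({"cell_id": cell, "reason": "too_many_failed"})
        elif ct.ct.at[cell, "B2M"] > b2m_max_ct:
            excluded.append({"cell_id": cell, "reason": "low_B2M"})
        elif ct.ct.at[cell, "GAPDH"] > gapdh_max_ct:
            excluded.append({"cell_id": cell, "reason": "low_GAPDH"})
        elif mean_detected[cell] > mean_ct_max:
            excluded.append({"cell_id": cell, "reason": "high_mean_ct"})
        else:
            keep.append(cell)
    report = QCReport(
        excluded_cells=pd.DataFrame(excluded, columns=["cell_id", "reason"]),
        n_cells_before=ct.n_cells,
        n_cells_after=len(keep),
        n_assays_before=ct.n_assays,
        n_assays_after=ct.n_assays,
    )
    report.validate_counts()
    return ct.select_cells(keep), report


def normalize_to_housekeeping(ct: CtMatrix) -> ExpressionMatrix:
    """Delta-Ct normalization to the per-cell mean of B2M and GAPDH.

    dCt(cell, gene) = Ct(cell, gene) - mean(Ct_B2M, Ct_GAPDH) for that
    cell.  Drop-outs are normalized from the limit of detection, and the
    housekeeping genes themselves are retained (their delta-Ct values are
    symmetric around 0 by construction).
    """
    for h in HOUSEKEEPING_REQUIRED:
        if h not in ct.assay_ids:
            raise ConfigurationError(f"housekeeping assay {h!r} missing")
    hk_mean = ct.ct[list(HOUSEKEEPING_REQUIRED)].mean(axis=1)
    norm = ct.ct.sub(hk_mean, axis=0)
    return ExpressionMatrix(
        norm_ct=norm,
        housekeeping_mean=hk_mean.rename("housekeeping_mean"),
        dropout=ct.dropout.copy(),
        housekeeping=HOUSEKEEPING_REQUIRED,
        cell_meta=ct.cell_meta,
        lod=ct.lod,
    )


def fit_titration(titration: pd.DataFrame, lod: float = 40.0) -> TitrationFit:
    """Two-stage linear validation of assay linearity from dilution series.

    Missing values and Ct beyond the limit of detection are removed and
    technical replicates merged by mean.  Stage 1 fits, per assay, a
    no-intercept model of Ct on log2(dilution) plus pool indicators to
    estimate and remove pool (starting concentration) effects.  Stage 2
    regresses pool-corrected Ct on log2(dilution) per assay, returning
    the dilution slope (cycles per log2 dilution) and r-squared.

    Assays with fewer than two surviving dilution points are flagged
    unfit (NaN slope) rather than raising.
    """
    required = {"pool", "log2_dilution", "assay", "ct"}
    if not required.issubset(titration.columns):
        raise FormatError(f"titration table needs columns {sorted(required)}")
    t = titration.dropna(subset=["ct"])
    t = t[t["ct"] <= lod]
    merged = (
        t.groupby(["assay", "pool", "log2_dilution"], sort=True)["ct"]
        .mean()
        .reset_index()
    )
    pools = sorted(merged["pool"].unique())
    rows = []
    pool_coefs = []
    for assay, sub in merged.groupby("assay", sort=True):
        x = sub["log2_dilution"].to_numpy(dtype=float)
        y = sub["ct"].to_numpy(dtype=float)
        n_dil = len(np.unique(x))
        if n_dil < 2:
            rows.append(
                {"assay": assay, "slope": np.nan, "r_squared": np.nan,
                 "n_points": len(sub), "unfit": True}
            )
            continue
        # stage 1: Ct ~ 0 + dilution + pool (pool dummies absorb the intercept)
        dummies = pd.get_dummies(sub["pool"]).reindex(columns=pools, fill_value=0)
        X1 = np.column_stack([x, dummies.to_numpy(dtype=float)])
        beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
        coef_by_pool = dict(zip(pools, beta[1:]))
        pool_coefs.append(coef_by_pool)
        y_adj = y - dummies.to_numpy(dtype=float) @ beta[1:]
        # stage 2: pool-corrected Ct ~ dilution
        res = stats.linregress(x, y_adj)
        rows.append(
            {"assay": assay, "slope": float(res.slope),
             "r_squared": float(np.clip(res.rvalue**2, 0.0, 1.0)),
             "n_points": len(sub), "unfit": False}
        )
    per_assay = pd.DataFrame(rows).set_index("assay")
    if pool_coefs:
        coef_df = pd.DataFrame(pool_coefs)
        offsets = (coef_df.sub(coef_df[pools[0]], axis=0)).mean(axis=0)
    else:
        offsets = pd.Series(dtype=float)
    return TitrationFit(per_assay=per_assay, pool_offsets=offsets.rename("offset"))
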