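"""Synthetic single-cell qPCR data with known ground truth.

Emulates the statistical structure of a targeted 87-assay single-cell
qPCR experiment on immunophenotypic MEP: three latent populations
(Pre-MEP, E-MEP, MK-MEP) with erythroid / megakaryocyte / primitive
expression programs, per-cell Gaussian Ct noise, logistic drop-out at
high Ct censored to the limit of detection, index-sort surface
fluorescence coupled to same-protein mRNA, and assay titration series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from mepscope.panel import GenePanel, build_default_panel
from mepscope.qc import CtMatrix

POPULATIONS = ("Pre-MEP", "E-MEP", "MK-MEP")

#: Default markers recorded by the index-sort table (CD44 FACS panel variant).
DEFAULT_MARKERS = (
    "CD34",
    "CD38",
    "CD123",
    "CD45RA",
    "CD71",
    "CD41",
    "CD42",
    "CD44",
)


def default_program_means(panel: GenePanel) -> pd.DataFrame:
    """Population x assay matrix of true mean Ct values (cycles).

    Program genes sit around Ct 15-16 in their own population and ~30
    (mostly below the detection limit once drop-out applies) elsewhere;
    housekeeping genes are strongly expressed everywhere; MPO is close
    to undetectable in all three populations, mimicking the negligible
    myeloid contamination of sorted MEP.
    """
    means = pd.DataFrame(
        index=list(POPULATIONS), columns=panel.assay_ids, dtype=float
    )
    special = {
        # assay: (Pre-MEP, E-MEP, MK-MEP)
        "B2M": (10.0, 10.0, 10.0),
        "GAPDH": (12.0, 12.0, 12.0),
        "ACTB": (14.0, 14.0, 14.0),
        "MPO": (35.0, 35.0, 35.0),
        # CD71 transcript: high in both primed populations (their defining
        # surface marker), absent from Pre-MEP
        "TFRC": (30.0, 15.0, 17.0),
        # CD44: ~fivefold (2.32 cycles) higher in Pre-MEP than the rest
        "CD44": (16.0, 18.32, 18.32),
        "CD34": (14.0, 17.0, 17.0),
        "CD38": (18.0, 15.0, 15.0),
        "CD36": (20.0, 16.0, 18.0),
        "CD9": (18.0, 18.0, 15.0),
        "ENG": (17.0, 17.0, 17.0),
        "CD47": (15.0, 15.0, 15.0),
        "GATA1": (24.0, 14.0, 15.0),
        "GATA2": (24.0, 16.0, 16.0),
        "ZFPM1": (23.0, 17.0, 17.0),
        "DHRS3": (18.0, 18.0, 18.0),
    }
    on_by_category = {"erythroid": "E-MEP", "megakaryocyte": "MK-MEP", "premep": "Pre-MEP"}
    for i, assay in enumerate(panel.assays):
        jitter = 0.4 * ((i % 5) - 2)
        if assay.assay_id in special:
            means[assay.assay_id] = special[assay.assay_id]
        elif assay.category in on_by_category:
            on_pop = on_by_category[assay.category]
            base = 16.0 if assay.category == "premep" else 15.0
            for pop in POPULATIONS:
                means.loc[pop, assay.assay_id] = (
                    base + jitter if pop == on_pop else 30.0 + jitter
                )
        else:  # housekeeping handled in special; remaining are 'other'
            means[assay.assay_id] = 19.0 + jitter
    return means


def default_mfi_coupling(
    markers: tuple[str, ...] = DEFAULT_MARKERS,
    slope: float = 1.0,
    noise_sd: float = 0.5,
    intercept: float = 22.0,
) -> dict[str, dict[str, float]]:
    """Per-marker linear coupling of log2 MFI to -dCt of the marker's gene."""
    return {
        m: {"slope": slope, "noise_sd": noise_sd, "intercept": intercept}
        for m in markers
    }


@dataclass
class PopulationParams:
    """Generative parameters for the three-population MEP model.

    Default proportions 0.51 / 0.43 / 0.06 follow the observed FACS
    frequencies of the CD71-41- / CD71+41- / CD71+41+ MEP subfractions
    (43.6, 37.4, and 5.1 % of total MEP, renormalized after excluding
    between-gate cells).
    """

    proportions: tuple[float, float, float] = (0.51, 0.43, 0.06)
    program_mean_ct: Optional[pd.DataFrame] = None
    cell_sd: float = 1.2
    dropout_midpoint: float = 28.0
    dropout_slope: float = 0.7
    lod_ct: float = 40.0
    mfi_coupling: dict[str, dict[str, float]] = field(
        default_factory=default_mfi_coupling
    )
    seed: int = 0

    def validate(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (3,):
            raise ValueError("proportions must be a 3-vector")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {p.sum()!r}, not 1")
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("each proportion must lie in (0, 1)")
        if self.cell_sd <= 0 or self.dropout_slope <= 0 or self.lod_ct <= 0:
            raise ValueError("cell_sd, dropout_slope and lod_ct must be positive")


@dataclass
class SyntheticDataset:
    """A simulated experiment: Ct matrix, index-sort table, and truth labels."""

    ct: CtMatrix
    index: pd.DataFrame
    truth: pd.Series
    params: PopulationParams

    def __post_init__(self) -> None:
        cells = list(self.ct.cell_ids)
        if list(self.index.index) != cells or list(self.truth.index) != cells:
            raise ValueError("ct, index and truth must share cell ids in order")

    def write_csv(self, outdir: str | Path, fail_token: bool = True) -> None:
        """Emit ct_matrix.csv, index_sort.csv and truth.csv under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ct = self.ct.ct.astype(object).copy()
        if fail_token:
            ct[self.ct.dropout] = "Fail"
        ct.index.name = "cell_id"
        ct.to_csv(outdir / "ct_matrix.csv")
        idx = self.index.copy()
        idx.index.name = "cell_id"
        idx.to_csv(outdir / "index_sort.csv")
        truth = self.truth.rename("population").to_frame()
        truth.index.name = "cell_id"
        truth.to_csv(outdir / "truth.csv")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cells(
    panel: GenePanel,
    params: PopulationParams,
    n_cells: int,
    n_selected: int = 0,
) -> SyntheticDataset:
    """Simulate single cells from the three-population MEP model.

    Each cell draws a population per ``params.proportions``; true Ct per
    assay is Normal(program mean, cell_sd); drop-out occurs with
    probability logistic((true Ct - midpoint) * slope) and is recorded
    at the limit of detection.  log2 surface fluorescence per marker is
    coupled linearly to -dCt of its transcript.  ``n_selected`` extra
    cells are drawn from the MK-MEP program and flagged with the
    CD71+41+ selection gate, mirroring enrichment sorts for rare cells.

    Identical params + seed reproduce the dataset exactly.
    """
    if n_cells < 3:
        raise ValueError("n_cells must be >= 3")
    params.validate()
    means = (
        params.program_mean_ct
        if params.program_mean_ct is not None
        else default_program_means(panel)
    )
    if list(means.columns) != panel.assay_ids:
        means = means.reindex(columns=panel.assay_ids)
        if means.isna().any().any():
            raise ValueError("program_mean_ct missing assays present in panel")

    ss = np.random.SeedSequence(params.seed)
    rng_label, rng_ct, rng_drop, rng_mfi = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    labels = rng_label.choice(3, size=n_cells, p=np.asarray(params.proportions))
    labels = np.concatenate([labels, np.full(n_selected, 2, dtype=labels.dtype)])
    n_total = n_cells + n_selected

    mu = means.to_numpy()[labels, :]  # n_total x n_assays
    true_ct = mu + rng_ct.normal(0.0, params.cell_sd, size=mu.shape)
    true_ct = np.clip(true_ct, 1.0, None)

    p_drop = _logistic(params.dropout_slope * (true_ct - params.dropout_midpoint))
    drop = rng_drop.uniform(size=true_ct.shape) < p_drop
    drop |= true_ct >= params.lod_ct
    obs_ct = np.where(drop, params.lod_ct, true_ct)

    cell_ids = [f"C{i:04d}" for i in range(n_total)]
    gate = ["unselected_MEP"] * n_cells + ["CD71+41+_selected"] * n_selected
    meta = pd.DataFrame(
        {
            "donor": [f"D{(i % 3) + 1}" for i in range(n_total)],
            "plate": [f"P{i // 96 + 1}" for i in range(n_total)],
            "well": [f"{chr(ord('A') + (i % 96) // 12)}{(i % 12) + 1:02d}" for i in range(n_total)],
            "sort_gate": gate,
        },
        index=cell_ids,
    )
    ct = CtMatrix(
        ct=pd.DataFrame(obs_ct, index=cell_ids, columns=panel.assay_ids),
        dropout=pd.DataFrame(drop, index=cell_ids, columns=panel.assay_ids),
        cell_meta=meta,
        lod=params.lod_ct,
    )

    # Surface fluorescence from true (pre-drop-out) expression: the sorter
    # measures protein regardless of whether the transcript amplified.
    hk = [a for a in ("B2M", "GAPDH") if a in means.columns]
    hk_idx = [panel.assay_ids.index(a) for a in hk]
    hk_mean = true_ct[:, hk_idx].mean(axis=1)
    mfi = {}
    for marker, coup in params.mfi_coupling.items():
        gene = panel.surface_marker_gene(marker)
        if gene is None:
            continue
        g = panel.assay_ids.index(gene)
        neg_dct = hk_mean - true_ct[:, g]
        mfi[marker] = (
            coup["slope"] * neg_dct
            + coup["intercept"]
            + rng_mfi.normal(0.0, coup["noise_sd"], size=n_total)
        )
    index = pd.DataFrame(mfi, index=cell_ids)
    index["sort_gate"] = gate

    truth = pd.Series(
        [POPULATIONS[k] for k in labels], index=cell_ids, name="population"
    )
    return SyntheticDataset(ct=ct, index=index, truth=truth, params=params)


def simulate_titration(
    panel: GenePanel,
    n_pools: int = 3,
    n_dilutions: int = 8,
    fold: float = 4.0,
    replicates: int = 3,
    noise_sd: float = 0.0,
    pool_offsets: Optional[list[float]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Serial-dilution titration series for assay linearity validation.

    Default geometry follows the validation design: eight fourfold serial
    dilutions from three bulk pools with technical triplicates.  The
    noiseless generative slope of Ct against log2(dilution) is exactly -1
    (one extra cycle per halving of input).
    """
    if n_dilutions < 2:
        raise ValueError("need at least 2 dilution levels")
    if pool_offsets is None:
        pool_offsets = [1.5 * p for p in range(n_pools)]
    if len(pool_offsets) != n_pools:
        raise ValueError("pool_offsets length must equal n_pools")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for ai, assay in enumerate(panel.assay_ids):
        base = 12.0 + (ai % 12)  # undiluted Ct, deterministic per assay
        for p in range(n_pools):
            for step in range(n_dilutions):
                log2_dil = -np.log2(fold) * step
                for rep in range(replicates):
                    ct = base + pool_offsets[p] - log2_dil
                    if noise_sd > 0:
                        ct += rng.normal(0.0, noise_sd)
                    rows.append(
                        {
                            "pool": f"pool{p + 1}",
                            "dilution_step": step,
                            "log2_dilution": log2_dil,
                            "assay": assay,
                            "replicate": rep + 1,
                            "ct": ct,
                        }
                    )
    return pd.DataFrame(rows)


def default_dataset(
    n_cells: int = 700, seed: int = 0, n_selected: int = 0
) -> SyntheticDataset:
    """Convenience wrapper: default panel + default params at ``n_cells``."""
    panel = build_default_panel()
    params = PopulationParams(seed=seed)
    return simulate_cells(panel, params, n_cells, n_selected=n_selected)
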