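"""Gene/assay panel description for the 87-assay MEP qPCR panel.

The panel mixes housekeeping assays, erythroid- and megakaryocyte-program
genes, genes associated with a more primitive "pre-MEP" phenotype, surface
antigen transcripts matched to the index-sort FACS panel, and general
hematopoietic regulators.  Each assay carries a category used by the
synthetic generator to build population-specific expression programs and
by the clustering stage to name clusters from marker evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

CATEGORIES = (
    "housekeeping",
    "erythroid",
    "megakaryocyte",
    "premep",
    "surface",
    "other",
)


@dataclass(frozen=True)
class Assay:
    assay_id: str
    gene_symbol: str
    category: str
    duplicate_group: Optional[str] = None
    is_surface_marker_of: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown assay category {self.category!r}")


@dataclass
class GenePanel:
    """An ordered collection of qPCR assays with program annotations."""

    assays: list[Assay] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [a.assay_id for a in self.assays]
        if len(ids) != len(set(ids)):
            raise ValueError("assay_ids must be unique")
        groups: dict[str, int] = {}
        for a in self.assays:
            if a.duplicate_group is not None:
                groups[a.duplicate_group] = groups.get(a.duplicate_group, 0) + 1
        for g, n in groups.items():
            if n < 2:
                raise ValueError(f"duplicate_group {g!r} has fewer than 2 members")

    def __len__(self) -> int:
        return len(self.assays)

    @property
    def assay_ids(self) -> list[str]:
        return [a.assay_id for a in self.assays]

    @property
    def gene_symbols(self) -> list[str]:
        return [a.gene_symbol for a in self.assays]

    def genes_in_category(self, category: str) -> list[str]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return [a.assay_id for a in self.assays if a.category == category]

    @property
    def housekeeping(self) -> list[str]:
        return self.genes_in_category("housekeeping")

    @property
    def duplicate_groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for a in self.assays:
            if a.duplicate_group is not None:
                out.setdefault(a.duplicate_group, []).append(a.assay_id)
        return out

    def surface_marker_gene(self, marker: str) -> Optional[str]:
        """Assay id of the transcript encoding FACS marker ``marker``."""
        for a in self.assays:
            if a.is_surface_marker_of == marker:
                return a.assay_id
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "assay_id": [a.assay_id for a in self.assays],
                "gene_symbol": [a.gene_symbol for a in self.assays],
                "category": [a.category for a in self.assays],
                "duplicate_group": [a.duplicate_group for a in self.assays],
                "is_surface_marker_of": [a.is_surface_marker_of for a in self.assays],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenePanel":
        assays = []
        for row in df.itertuples(index=False):
            dup = getattr(row, "duplicate_group", None)
            mk = getattr(row, "is_surface_marker_of", None)
            assays.append(
                Assay(
                    assay_id=row.assay_id,
                    gene_symbol=row.gene_symbol,
                    category=row.category,
                    duplicate_group=None if pd.isna(dup) else dup,
                    is_surface_marker_of=None if pd.isna(mk) else mk,
                )
            )
        return cls(assays)


# (gene symbol, FACS marker whose protein it encodes or None)
_HOUSEKEEPING = [("B2M", None), ("GAPDH", None), ("ACTB", None)]

_ERYTHROID = [
    ("KLF1", None),
    ("TMOD1", None),
    ("ANK1", None),
    ("LEF1", None),
    ("ADD2", None),
    ("CNRIP1", None),
    ("MYB", None),
    ("TFRC", "CD71"),
    ("EPOR", None),
    ("GYPA", None),
    ("AHSP", None),
    ("ALAS2", None),
    ("SLC4A1", None),
    ("EPB42", None),
]

_MEGAKARYOCYTE = [
    ("VWF", None),
    ("FLI1", None),
    ("NFIB", None),
    ("TGFB1", None),
    ("LOX", None),
    ("ITGA2B", "CD41"),
    ("GP1BA", "CD42"),
    ("ITGB3", None),
    ("MPL", None),
    ("CLU", None),
    ("PF4", None),
    ("NFE2", None),
    ("GP9", None),
    ("TUBB1", None),
]

_PREMEP = [
    ("CD44", "CD44"),
    ("KIT", None),
    ("CSF3R", None),
    ("FLT3", None),
    ("SOCS3", None),
    ("MPO", None),
    ("IL3RA", "CD123"),
    ("PTPRC", "CD45RA"),
]

_SURFACE = [
    ("CD34", "CD34"),
    ("CD38", "CD38"),
    ("CD36", "CD36"),
    ("CD9", None),
    ("ENG", None),
    ("CD47", None),
]

_OTHER = [
    "GATA1", "GATA2", "ZFPM1", "DHRS3", "TAL1", "LMO2", "GFI1B", "RUNX1",
    "ETV6", "SPI1", "CEBPA", "MYC", "MEIS1", "HHEX", "LDB1", "NFIA",
    "IKZF1", "ZEB2", "ERG", "TET2", "STAT5A", "JAK2", "PLEK", "F2R",
    "SELP", "THBS1", "RAP1B", "MYH9", "MYH10", "ITGA6", "CD63", "ESAM",
    "TIMP3", "TPM1", "FERMT3", "RGS18", "PBX1", "MINPP1", "TESPA1",
    "SLAMF1", "ANGPT1", "HBD",
]


def build_default_panel() -> GenePanel:
    """The default 87-assay panel used by the synthetic generator.

    Includes B2M and GAPDH (plus ACTB) flagged as housekeeping, the
    erythroid / megakaryocyte / pre-MEP program genes used for cluster
    naming, surface antigen transcripts linked to their FACS markers,
    and general hematopoietic regulators filling the remainder.
    """
    assays: list[Assay] = []

    def add(pairs, category):
        for sym, marker in pairs:
            assays.append(
                Assay(
                    assay_id=sym,
                    gene_symbol=sym,
                    category=category,
                    is_surface_marker_of=marker,
                )
            )

    add(_HOUSEKEEPING, "housekeeping")
    add(_ERYTHROID, "erythroid")
    add(_MEGAKARYOCYTE, "megakaryocyte")
    add(_PREMEP, "premep")
    add(_SURFACE, "surface")
    add([(g, None) for g in _OTHER], "other")
    panel = GenePanel(assays)
    assert len(panel) == 87
    return panel
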