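"""Built-in gene catalogs: the 24 m6A regulators and immune signature panels.

The m6A (N6-methyladenosine) machinery is conventionally split into three
functional roles: *writers* (methyltransferase complex members), *erasers*
(demethylases) and *readers* (m6A-binding proteins that execute the
downstream effect).  The 24-gene panel below is the standard regulator set
used for expression-based subtyping of tumor cohorts.

The signature registry holds the 11 immune/oncogenic process categories of
Mariathasan et al. (TGF-beta attenuates tumour response to PD-L1 blockade),
plus the CD8 T-cell effector and immune-checkpoint panels used for
score-group comparisons.  Panels are plain data; callers may override any of
them with user-supplied GMT files.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "Regulator",
    "RegulatorCatalog",
    "load_regulator_catalog",
    "signature_registry",
    "MARIATHASAN_CATEGORIES",
]

VALID_ROLES = ("writer", "eraser", "reader")

_WRITERS = ("METTL3", "METTL14", "WTAP", "ZC3H13", "VIRMA", "CBLL1", "RBM15", "RBM15B")
_ERASERS = ("ALKBH5", "FTO")
_READERS = (
    "YTHDC1",
    "YTHDC2",
    "YTHDF1",
    "YTHDF2",
    "YTHDF3",
    "IGF2BP1",
    "IGF2BP2",
    "IGF2BP3",
    "HNRNPA2B1",
    "HNRNPC",
    "RBMX",
    "LRPPRC",
    "ELAVL1",
    "FMR1",
)


@dataclass(frozen=True)
class Regulator:
    gene_symbol: str
    role: str


@dataclass(frozen=True)
class RegulatorCatalog:
    """The 24-gene m6A regulator panel with writer/eraser/reader roles."""

    entries: tuple[Regulator, ...]

    def __post_init__(self) -> None:
        symbols = [e.gene_symbol for e in self.entries]
        if len(set(symbols)) != len(symbols):
            raise ValueError("regulator symbols must be unique")
        for e in self.entries:
            if e.role not in VALID_ROLES:
                raise ValueError(f"unknown role {e.role!r}")
            if e.gene_symbol != e.gene_symbol.upper():
                raise ValueError(f"symbol {e.gene_symbol!r} must be upper-case")

    @property
    def symbols(self) -> list[str]:
        return [e.gene_symbol for e in self.entries]

    def filter(self, role: str) -> list[str]:
        """Gene symbols with the given role (writer/eraser/reader)."""
        if role not in VALID_ROLES:
            raise ValueError(f"unknown role {role!r}; expected one of {VALID_ROLES}")
        return [e.gene_symbol for e in self.entries if e.role == role]

    def __len__(self) -> int:
        return len(self.entries)


def load_regulator_catalog() -> RegulatorCatalog:
    """Return the built-in 24-regulator catalog (8 writers, 2 erasers, 14 readers)."""
    entries = tuple(
        [Regulator(g, "writer") for g in _WRITERS]
        + [Regulator(g, "eraser") for g in _ERASERS]
        + [Regulator(g, "reader") for g in _READERS]
    )
    return RegulatorCatalog(entries)


# ---------------------------------------------------------------------------
# Immune / oncogenic process signature registry
# ---------------------------------------------------------------------------

#: The 11 Mariathasan process categories, in the conventional order.
MARIATHASAN_CATEGORIES = (
    "antigen_processing_machinery",
    "cd8_t_effector",
    "immune_checkpoint",
    "nucleotide_excision_repair",
    "mismatch_repair",
    "dna_replication",
    "dna_damage_repair",
    "emt_markers",
    "wnt_targets",
    "pan_f_tbrs",
    "angiogenesis",
)

# Curated panels.  CD8 effector and checkpoint follow the published 8- and
# 7-gene lists; the remaining categories use the standard published panels
# (trimmed to representative members for the repair/replication modules).
_SIGNATURE_GENES: dict[str, tuple[str, ...]] = {
    "antigen_processing_machinery": (
        "B2M", "CALR", "NLRC5", "PSMB5", "PSMB6", "PSMB7", "PSMB8", "PSMB9",
        "PSME1", "PSME2", "PSME3", "TAP1", "TAP2", "TAPBP",
    ),
    "cd8_t_effector": (
        "CD8A", "GZMA", "GZMB", "IFNG", "CXCL9", "CXCL10", "PRF1", "TBX21",
    ),
    "immune_checkpoint": (
        "CD274", "PDCD1", "PDCD1LG2", "CTLA4", "HAVCR2", "LAG3", "TIGIT",
    ),
    "nucleotide_excision_repair": (
        "ERCC1", "ERCC2", "ERCC3", "ERCC4", "ERCC5", "XPA", "XPC", "DDB1", "DDB2",
    ),
    "mismatch_repair": ("MLH1", "MSH2", "MSH6", "PMS2", "PMS1", "MSH3"),
    "dna_replication": (
        "MCM2", "MCM3", "MCM4", "MCM5", "MCM6", "MCM7", "POLA1", "POLD1",
        "POLE", "PCNA", "RFC2", "RFC3",
    ),
    "dna_damage_repair": (
        "BRCA1", "BRCA2", "ATM", "ATR", "CHEK1", "CHEK2", "RAD51", "FANCA",
        "MDC1", "TP53BP1",
    ),
    "emt_markers": (
        "VIM", "CDH2", "FN1", "SNAI1", "SNAI2", "TWIST1", "ZEB1", "ZEB2",
    ),
    "wnt_targets": (
        "AXIN2", "MYC", "CCND1", "LGR5", "ASCL2", "TCF7", "LEF1", "NKD1",
    ),
    "pan_f_tbrs": (
        "ACTA2", "TAGLN", "COL4A1", "SH3PXD2A", "TNS1", "TGFB1", "TGFBR2",
        "CNN1", "TPM1",
    ),
    "angiogenesis": ("VEGFA", "KDR", "ESM1", "PECAM1", "ANGPTL4", "CD34", "FLT1"),
}


def signature_registry(include_extended: bool = False) -> dict[str, set[str]]:
    """The 11 Mariathasan category panels as ``name -> gene set``.

    With ``include_extended`` additional comparison panels used downstream
    (fibroblast / Treg immune-suppression sets) are appended.
    """
    reg = {name: set(_SIGNATURE_GENES[name]) for name in MARIATHASAN_CATEGORIES}
    if include_extended:
        reg["fibroblast_suppression"] = {
            "FAP", "PDGFRB", "PDPN", "THY1", "COL1A1", "COL1A2", "COL3A1",
        }
        reg["treg_suppression"] = {"FOXP3", "IL2RA", "IKZF2", "CCR8", "TNFRSF18"}
    return reg
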