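"""Absolute copy-number estimation per cell.

mRNA copies come from the fraction of uniquely mapped reads a transcript
captures, scaled by the bulk mRNA mass per cell converted to a total
nucleotide count:

    c = (r_transcript / r_total) * T_count / L

where T_count = (mass_per_cell / 339.5 g/mol) * N_A is the number of mRNA
nucleotides per cell and L the transcript length. Protein copies come from
iBAQ intensity fractions of the bulk protein mass per cell, divided by the
protein molecular weight.
"""

from __future__ import annotations

import pandas as pd

from .constants import AVOGADRO, NT_MW

__all__ = [
    "mrna_mass_per_cell",
    "total_nucleotides_per_cell",
    "mrna_copies",
    "mrna_copies_table",
    "ibaq_protein_mass",
    "protein_copies",
    "protein_copies_table",
]


def mrna_mass_per_cell(total_mass_g: float, n_cells: float) -> float:
    """Bulk mRNA yield per cell in grams."""
    if total_mass_g <= 0 or n_cells <= 0:
        raise ValueError("mass and cell count must be positive")
    return total_mass_g / n_cells


def total_nucleotides_per_cell(mass_per_cell_g: float, nt_mw: float = NT_MW) -> float:
    """Total mRNA nucleotide count per cell from the bulk mass."""
    if mass_per_cell_g <= 0 or nt_mw <= 0:
        raise ValueError("mass per cell and nucleotide MW must be positive")
    return mass_per_cell_g / nt_mw * AVOGADRO


def mrna_copies(
    read_fraction: float,
    length_nt: int,
    mass_per_cell_g: float,
    nt_mw: float = NT_MW,
) -> float:
    """Absolute transcript copies per cell from its mapped-read fraction."""
    if length_nt <= 0:
        raise ValueError("transcript length must be positive")
    if not 0.0 <= read_fraction <= 1.0:
        raise ValueError("read fraction must lie in [0, 1]")
    t_count = total_nucleotides_per_cell(mass_per_cell_g, nt_mw)
    return read_fraction * t_count / length_nt


def mrna_copies_table(
    counts: pd.Series,
    lengths: pd.Series,
    mass_per_cell_g: float,
    nt_mw: float = NT_MW,
) -> pd.Series:
    """Vectorized copies/cell for a whole sample (counts and lengths by gene)."""
    total = float(counts.sum())
    if total <= 0:
        raise ValueError("total mapped reads must be positive")
    t_count = total_nucleotides_per_cell(mass_per_cell_g, nt_mw)
    lengths = lengths.reindex(counts.index)
    return (counts / total) * t_count / lengths


def ibaq_protein_mass(i_protein: float, i_total: float, g_total: float) -> float:
    """Grams per cell of one protein from its iBAQ intensity fraction."""
    if i_total <= 0:
        raise ValueError("total iBAQ intensity must be positive")
    if i_protein < 0:
        raise ValueError("protein intensity must be non-negative")
    if i_protein > i_total:
        raise ValueError(
            "protein intensity exceeds the total — intensity fractions must "
            "be computed over the same universe"
        )
    return g_total * i_protein / i_total


def protein_copies(g_protein: float, mw: float) -> float:
    """Copies per cell from a protein's mass per cell and molecular weight."""
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    if g_protein < 0:
        raise ValueError("protein mass must be non-negative")
    return g_protein * AVOGADRO / mw


def protein_copies_table(ibaq: pd.DataFrame, g_total: float) -> pd.DataFrame:
    """Copies/cell for an iBAQ table with columns (protein, intensity, mw)."""
    i_total = float(ibaq["intensity"].sum())
    out = ibaq.copy()
    out["g_protein"] = [
        ibaq_protein_mass(v, i_total, g_total) for v in ibaq["intensity"]
    ]
    out["copies"] = [
        protein_copies(g, m) for g, m in zip(out["g_protein"], out["mw"])
    ]
    return out
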