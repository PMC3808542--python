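"""Protein-level quantification rules for the two MS layers.

iTRAQ: peptide filters (0-hr reporter signal > 300 cps, unique match),
protein quantification by summation over peptides, per-channel median
normalization on the log2 scale, and the increased-protein flag.

SRM: peptide intensity as the sum of transition peak areas, per-sample
scaling by a housekeeping geometric-mean index, replicate averaging, and
protein intensity by peptide summation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .constants import ITRAQ_CHANNEL_MAP

__all__ = [
    "ITRAQ_INTENSITY_COLS",
    "filter_itraq_peptides",
    "quantify_itraq_protein",
    "flag_increased",
    "quantify_srm",
    "correlate_layers",
]

ITRAQ_INTENSITY_COLS = tuple(f"i{ch}" for ch in ITRAQ_CHANNEL_MAP)
ZERO_HR_COL = ITRAQ_INTENSITY_COLS[0]  # channel 113 labels the 0-hr sample


def filter_itraq_peptides(
    peptides: pd.DataFrame, min_zero_hr_cps: float = 300.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the peptide-level quantification filters.

    Keeps peptides whose 0-hr reporter intensity is strictly greater than
    ``min_zero_hr_cps`` and whose ``unique_flag`` is set. Returns the
    retained table and a drop log with a reason code per removed peptide.
    """
    df = peptides.copy()
    reasons = pd.Series("", index=df.index, dtype=object)
    if ZERO_HR_COL not in df.columns:
        raise ValueError(f"missing 0-hr channel column {ZERO_HR_COL!r}")
    zero = pd.to_numeric(df[ZERO_HR_COL], errors="coerce")
    reasons[zero.isna()] = "missing_0hr_channel"
    reasons[(zero <= min_zero_hr_cps) & zero.notna()] = "low_0hr_signal"
    reasons[~df["unique_flag"].astype(bool)] = "non_unique"
    dropped = df[reasons != ""].assign(reason=reasons[reasons != ""])
    return df[reasons == ""], dropped


def quantify_itraq_protein(
    peptides: pd.DataFrame, min_peptides: int = 2
) -> tuple[pd.DataFrame, int]:
    """Sum retained peptides per protein, median-normalize, ratio to 0 hr.

    Per-time protein intensity is the plain sum of its peptides' reporter
    intensities. Each channel's log2 protein totals are then shifted so
    all channel medians equal the grand median (median normalization on
    the log2 scale), and relative abundance is the normalized intensity
    ratio vs 0 hr. Proteins with fewer than ``min_peptides`` unique
    peptides are excluded; the count of exclusions is returned.

    Returns a frame indexed by protein with columns ``n_peptides``,
    ``intensity_<ch>`` and ``ratio_<ch>``.
    """
    cols = [c for c in ITRAQ_INTENSITY_COLS if c in peptides.columns]
    grouped = peptides.groupby("protein")
    sums = grouped[cols].sum()
    n_pep = grouped["peptide"].nunique()
    keep = n_pep >= min_peptides
    n_excluded = int((~keep).sum())
    sums = sums[keep]

    log2 = np.log2(sums.where(sums > 0))
    channel_medians = log2.median(axis=0)
    grand = float(np.median(channel_medians))
    normalized = log2.sub(channel_medians - grand, axis=1)
    norm_lin = 2.0**normalized
    ratios = norm_lin.div(norm_lin[ZERO_HR_COL], axis=0)

    out = pd.DataFrame(index=sums.index)
    out["n_peptides"] = n_pep[keep]
    for c in cols:
        out[f"intensity_{c[1:]}"] = norm_lin[c]
    for c in cols:
        out[f"ratio_{c[1:]}"] = ratios[c]
    return out, n_excluded


def flag_increased(
    ratios: pd.DataFrame, fold: float = 1.5, min_timepoints: int = 2
) -> tuple[pd.Index, float]:
    """Flag proteins increased >=fold at >=min_timepoints post-treatment times.

    ``ratios``: proteins x times relative to 0 hr, with the baseline in
    the first column. The >50%-increase rule is applied inclusively
    (ratio >= 1.5 counts). Returns the flagged index and the flagged
    percentage of all tracked proteins, rounded to 2 decimals.
    """
    post = ratios.iloc[:, 1:]
    n_hits = (post >= fold).sum(axis=1)
    flagged = ratios.index[n_hits >= min_timepoints]
    pct = round(100.0 * len(flagged) / len(ratios), 2) if len(ratios) else 0.0
    return flagged, pct


def quantify_srm(
    transitions: pd.DataFrame, housekeeping_proteins: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate SRM transitions into normalized peptide and protein tables.

    Peptide intensity per (sample, replicate) is the sum of its transition
    peak areas. Each sample+replicate is scaled so a housekeeping index —
    the geometric mean of housekeeping peptide intensities — is brought to
    the median index across samples; replicate injections are then
    averaged and protein intensity is the sum of its scaled peptides.

    Returns (peptides, proteins): both wide tables with one column per
    sample.
    """
    pep = (
        transitions.groupby(["peptide", "protein", "sample", "replicate"])["area"]
        .sum()
        .reset_index()
    )
    wide = pep.pivot_table(
        index=["peptide", "protein"], columns=["sample", "replicate"],
        values="area", aggfunc="sum",
    )
    is_hk = wide.index.get_level_values("protein").isin(housekeeping_proteins)
    if not is_hk.any():
        raise ValueError("no housekeeping peptide found in the transition table")
    hk = wide[is_hk]
    if (hk <= 0).any().any() or hk.isna().any().any():
        bad = hk.columns[(hk <= 0).any() | hk.isna().any()].tolist()
        raise ValueError(
            f"zero/missing housekeeping intensity in sample(s) {bad}: "
            "geometric mean undefined"
        )
    index = np.exp(np.log(hk).mean(axis=0))  # per sample+replicate
    factors = float(np.median(index)) / index
    scaled = wide.mul(factors, axis=1)

    by_sample = scaled.T.groupby(level="sample").mean().T  # replicate average
    # preserve acquisition order of samples
    sample_order = list(dict.fromkeys(transitions["sample"]))
    by_sample = by_sample[[s for s in sample_order if s in by_sample.columns]]
    peptides = by_sample.reset_index()
    proteins = by_sample.groupby(level="protein").sum().reset_index()
    return peptides, proteins


def correlate_layers(
    srm_log2_ratios: pd.DataFrame, itraq_log2_ratios: pd.DataFrame
) -> float:
    """Pearson r between SRM and iTRAQ log2 ratios over matched cells."""
    srm, itraq = srm_log2_ratios.align(itraq_log2_ratios, join="inner")
    a = srm.to_numpy(float).ravel()
    b = itraq.to_numpy(float).ravel()
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 3:
        raise ValueError("need at least 3 matched protein x time cells")
    return float(pearsonr(a[mask], b[mask]).statistic)
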