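"""Seeded multi-omic apoptosis time course with a ground-truth ledger.

This module simulates every data layer the analysis consumes — paired
mRNA-seq / ribosome-footprint counts, bulk mRNA and protein masses, iTRAQ
reporter intensities with ratio compression, SRM transition areas, and
proteolytic-peptide appearance curves — from a single explicit ground
truth, so each downstream stage can be validated against known answers
without any external download.

The central confound the simulation reproduces: sequencing libraries
report *relative* pool composition only. Each sample is renormalized to a
target library size after sampling, so the global mRNA decay G(t) is
invisible to RPKM; a transcript whose relative abundance is flat is
nonetheless being lost from the cell as the total pool decays. Absolute
copies per cell are ``c0 * rel(t) * G(t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .constants import (
    ARCHETYPES,
    AVOGADRO,
    CLEAVAGE_CLUSTERS,
    FOOTPRINT_LEN_RANGE,
    ITRAQ_CHANNEL_MAP,
    MRNA_FRAG_LEN_RANGE,
    NT_MW,
    TIME_GRID_HR,
    TIME_LABELS,
)
from .transcripts import TranscriptModel

__all__ = [
    "GlobalDecayTruth",
    "NoiseSpec",
    "DensitySpec",
    "TruthLedger",
    "TimecourseBundle",
    "generate_transcriptome",
    "make_truth_ledger",
    "generate_timecourse",
    "generate_reads",
]

#: Printed global-decay scaling factors at the six time points.
DEFAULT_DECAY_VALUES = (1.0, 0.93, 0.91, 0.48, 0.17, 0.12)

#: Cleavage-onset midpoints (hr) per kinetic cluster; inf = never cleaved.
CLEAVAGE_ONSETS_HR = {
    "Fastest": 6.0,
    "Faster": 7.5,
    "Mid": 9.0,
    "Slow": 10.5,
    "Slowest/No Change": float("inf"),
}

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class GlobalDecayTruth:
    """Unitless fractions of baseline total mRNA mass at each time point."""

    times: tuple[float, ...] = TIME_GRID_HR
    values: tuple[float, ...] = DEFAULT_DECAY_VALUES

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if abs(self.values[0] - 1.0) > 1e-12:
            raise ValueError("G(0) must equal 1.0")

    def interpolator(self) -> PchipInterpolator:
        """Shape-preserving continuous G(t) through the truth values."""
        return PchipInterpolator(np.asarray(self.times), np.asarray(self.values))


@dataclass(frozen=True)
class NoiseSpec:
    """Stochastic components of the simulation.

    count_law : 'poisson' samples read counts; 'none' emits exact
        expectations (real-valued).
    intensity_cv : multiplicative lognormal CV on every MS intensity.
    sample_scale_cv : per-sample injection/labeling-efficiency drift CV
        applied uniformly within an SRM or degradomics sample (what the
        housekeeping / spike-in normalizations exist to remove).
    """

    count_law: str = "poisson"
    intensity_cv: float = 0.10
    sample_scale_cv: float = 0.10

    @classmethod
    def none(cls) -> "NoiseSpec":
        """Fully deterministic mode for exactness tests."""
        return cls(count_law="none", intensity_cv=0.0, sample_scale_cv=0.0)


@dataclass(frozen=True)
class DensitySpec:
    """Per-nucleotide Poisson-rate description for positioned-read sampling.

    The base profile is uniform over each transcript; optional features add
    3-nt periodicity (cosine with the given amplitude, phased to the CDS
    frame), start/stop-codon peaks, or a localized spike (e.g. over an
    implanted uORF).
    """

    layer: str = "footprint"
    n_reads: int = 10_000
    periodicity_amplitude: float = 0.0
    start_peak: float = 0.0
    stop_peak: float = 0.0
    spike: dict[str, tuple[int, int]] = field(default_factory=dict)
    spike_fold: float = 5.0

    def __post_init__(self) -> None:
        if self.layer not in ("footprint", "mRNA"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")


@dataclass
class TruthLedger:
    """Ground truth for every simulated gene and proteolytic peptide.

    genes : one row per gene — archetype, true baseline mRNA and protein
        copies/cell, true ksp (proteins per transcript per hr), true kdp
        (per hr), protein molecular weight (g/mol), uORF implantation
        coordinates, and the true TE multiplier at each time point.
    peptides : one row per proteolytic peptide — P1 residue, kinetic
        cluster label and true cleavage-onset time (hr; inf = never).
    """

    genes: pd.DataFrame
    peptides: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        g = self.genes
        if not g["ksp"].between(10, 270).all():
            raise ValueError("ksp outside [10, 270]")
        if not g["kdp"].between(0.010, 0.015).all():
            raise ValueError("kdp outside [0.010, 0.015]")
        if (g["mrna_copies0"] <= 0).any() or (g["protein_copies0"] <= 0).any():
            raise ValueError("baseline copies must be strictly positive")
        unknown = set(g["archetype"]) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")

    def save(self, path: str | Path) -> None:
        self.genes.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# transcriptome


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(np.array(list("ACGT")), size=n)


def generate_transcriptome(
    n_genes: int,
    seed: int,
    uorf_fraction: float = 0.2,
    utr5_range: tuple[int, int] = (60, 300),
    cds_codon_range: tuple[int, int] = (100, 1000),
    utr3_range: tuple[int, int] = (50, 400),
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Simulate canonical transcript structures with optional implanted uORFs.

    Exactly ``floor(uorf_fraction * n_genes)`` transcripts carry an upstream
    ORF: an ATG followed by an in-frame stop codon, both inside the 5'UTR.
    Returns the models (with sequences) and a uORF table
    (gene, has_uorf, uorf_start, uorf_stop) giving 0-based codon positions.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 <= uorf_fraction <= 1.0:
        raise ValueError("uorf_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_uorf = int(np.floor(uorf_fraction * n_genes))
    uorf_genes = set(rng.permutation(n_genes)[:n_uorf])

    models: list[TranscriptModel] = []
    rows = []
    width = max(4, len(str(n_genes)))
    for i in range(n_genes):
        tid = f"G{i:0{width}d}"
        utr5 = int(rng.integers(utr5_range[0], utr5_range[1] + 1))
        cds = 3 * int(rng.integers(cds_codon_range[0], cds_codon_range[1] + 1))
        utr3 = int(rng.integers(utr3_range[0], utr3_range[1] + 1))
        seq = _random_seq(rng, utr5 + cds + utr3)
        # canonical CDS boundaries
        seq[utr5 : utr5 + 3] = list("ATG")
        seq[utr5 + cds - 3 : utr5 + cds] = list("TAA")

        uorf_start = uorf_stop = -1
        if i in uorf_genes:
            # implant ATG ... TAA fully inside the 5'UTR, >= 2 codons apart
            max_start = utr5 - 9
            uorf_start = int(rng.integers(3, max(4, max_start + 1)))
            n_codons = int(rng.integers(2, max(3, (utr5 - 3 - uorf_start) // 3 + 1)))
            uorf_stop = uorf_start + 3 * n_codons
            seq[uorf_start : uorf_start + 3] = list("ATG")
            # scrub accidental in-frame stops inside the implanted ORF
            for p in range(uorf_start + 3, uorf_stop, 3):
                if "".join(seq[p : p + 3]) in STOP_CODONS:
                    seq[p] = "C"
            seq[uorf_stop : uorf_stop + 3] = list("TAA")
        models.append(TranscriptModel(tid, utr5, cds, utr3, "".join(seq)))
        rows.append(
            {"gene": tid, "has_uorf": i in uorf_genes,
             "uorf_start": uorf_start, "uorf_stop": uorf_stop}
        )
    return models, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trajectories and the ledger


def _logistic01(t: np.ndarray, midpoint: float, tau: float,
                t_end: float = 12.0) -> np.ndarray:
    """Logistic ramp rescaled to be exactly 0 at t=0 and 1 at t_end."""
    s = 1.0 / (1.0 + np.exp(-(np.asarray(t, float) - midpoint) / tau))
    s0 = 1.0 / (1.0 + np.exp(midpoint / tau))
    s1 = 1.0 / (1.0 + np.exp(-(t_end - midpoint) / tau))
    return (s - s0) / (s1 - s0)


#: Midpoint (hr) of the archetype transition ramp: between the 3 hr RPKM
#: plateau and the 6 hr onset of bulk decay and caspase activity.
ARCHETYPE_RAMP_MIDPOINT = 4.5


def archetype_mrna_log2(archetype: str, t: np.ndarray) -> np.ndarray:
    """True log2 relative-composition (RPKM-visible) mRNA trajectory."""
    ramp = _logistic01(t, midpoint=ARCHETYPE_RAMP_MIDPOINT, tau=1.5)
    if archetype == "Upreg":
        return 2.0 * ramp
    if archetype == "Downreg":
        return -2.0 * ramp
    return np.zeros_like(np.asarray(t, float))


def archetype_te_log2(archetype: str, t: np.ndarray) -> np.ndarray:
    """True log2 translational-efficiency multiplier trajectory."""
    ramp = _logistic01(t, midpoint=ARCHETYPE_RAMP_MIDPOINT, tau=1.5)
    if archetype == "TE_Up":
        return 1.0 * ramp
    if archetype == "TE_Down":
        return -1.0 * ramp
    return np.zeros_like(np.asarray(t, float))


def make_truth_ledger(
    models: Sequence[TranscriptModel],
    seed: int,
    uorf_table: pd.DataFrame | None = None,
    archetype_cycle: Sequence[str] = ARCHETYPES,
    time_grid: Sequence[float] = TIME_GRID_HR,
) -> TruthLedger:
    """Assign archetypes and true kinetic parameters to each gene.

    Archetypes cycle deterministically through the five classes so every
    class is populated at any n. Baseline mRNA copies are lognormal with
    median ~10 copies/cell; ksp is uniform on [10, 270] and kdp uniform on
    [0.010, 0.015]; baseline protein is the steady state ksp*c0/kdp, so an
    unperturbed gene starts in translational equilibrium.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(time_grid, float)
    n = len(models)
    archetypes = [archetype_cycle[i % len(archetype_cycle)] for i in range(n)]
    c0 = np.exp(rng.normal(np.log(10.0), 1.0, size=n))
    ksp = rng.uniform(10.0, 270.0, size=n)
    kdp = rng.uniform(0.010, 0.015, size=n)
    p0 = ksp * c0 / kdp
    mw = rng.uniform(20_000.0, 120_000.0, size=n)

    rows = []
    for i, m in enumerate(models):
        te_mult = 2.0 ** archetype_te_log2(archetypes[i], t)
        row = {
            "gene": m.transcript_id,
            "archetype": archetypes[i],
            "mrna_copies0": c0[i],
            "protein_copies0": p0[i],
            "ksp": ksp[i],
            "kdp": kdp[i],
            "protein_mw": mw[i],
        }
        row.update({f"te_mult_{lab}": te_mult[j] for j, lab in enumerate(TIME_LABELS)})
        rows.append(row)
    genes = pd.DataFrame(rows)
    if uorf_table is not None:
        genes = genes.merge(uorf_table, on="gene", how="left")
    return TruthLedger(genes=genes)


def make_cleavage_ledger(
    n_peptides: int,
    seed: int,
    cluster_weights: Sequence[float] = (0.17, 0.16, 0.24, 0.20, 0.23),
) -> pd.DataFrame:
    """Assign kinetic clusters, onsets and P1 residues to cleavage peptides.

    P1 residues favour Asp (caspase-like) in the fast clusters and
    Lys/Arg/other in the slow ones, mirroring the empirical pattern that
    caspase proteolysis precedes other apoptotic cleavage events.
    """
    rng = np.random.default_rng(seed)
    p1_pools = {
        "Fastest": ("D", "D", "D", "D", "E", "Q"),
        "Faster": ("D", "D", "D", "D", "P", "Q"),
        "Mid": ("D", "D", "D", "D", "E", "A"),
        "Slow": ("D", "K", "R", "E", "Q", "L"),
        "Slowest/No Change": ("K", "R", "D", "E", "N", "S"),
    }
    weights = np.asarray(cluster_weights, float)
    weights = weights / weights.sum()
    labels = rng.choice(np.array(CLEAVAGE_CLUSTERS, dtype=object), size=n_peptides, p=weights)
    rows = []
    for i, lab in enumerate(labels):
        rows.append(
            {
                "peptide": f"PEP{i:04d}",
                "protein": f"SUB{i % max(1, n_peptides // 2):04d}",
                "p1_residue": str(rng.choice(np.array(p1_pools[lab], dtype=object))),
                "cluster": lab,
                "onset_hr": CLEAVAGE_ONSETS_HR[lab],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the time course


@dataclass
class TimecourseBundle:
    """All simulated observation layers plus the ledger that produced them."""

    ledger: TruthLedger
    decay: GlobalDecayTruth
    time_grid: tuple[float, ...]
    counts_mrna: pd.DataFrame
    counts_fp: pd.DataFrame
    bulk: pd.DataFrame
    true_protein: pd.DataFrame
    true_mrna_abs: pd.DataFrame
    itraq_peptides: pd.DataFrame
    srm_transitions: pd.DataFrame
    cleavage_peptides: pd.DataFrame
    ibaq: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        """Persist every layer as TSV with deterministic formatting."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = {"float_format": "%.10g", "sep": "\t", "index": False}
        self.counts_mrna.to_csv(out / "counts_mrna.tsv", **fmt)
        self.counts_fp.to_csv(out / "counts_footprint.tsv", **fmt)
        self.bulk.to_csv(out / "bulk.tsv", **fmt)
        self.true_protein.to_csv(out / "true_protein.tsv", **fmt)
        self.itraq_peptides.to_csv(out / "itraq_peptides.tsv", **fmt)
        self.srm_transitions.to_csv(out / "srm_transitions.tsv", **fmt)
        self.cleavage_peptides.to_csv(out / "cleavage_peptides.tsv", **fmt)
        self.ibaq.to_csv(out / "ibaq_intensities.tsv", **fmt)
        self.ledger.genes.to_csv(out / "truth_ledger.tsv", **fmt)
        if len(self.ledger.peptides):
            self.ledger.peptides.to_csv(out / "truth_cleavage.tsv", **fmt)


def simulate_true_protein(
    ledger: TruthLedger,
    decay: GlobalDecayTruth,
    time_grid: Sequence[float],
) -> pd.DataFrame:
    """Integrate dP/dt = ksp * R(t) * G(t) - kdp * P for every gene.

    R(t) is the relative-composition trajectory times baseline copies, so
    R(t)*G(t) is the absolute transcript count per cell.
    """
    from scipy.integrate import solve_ivp

    t = np.asarray(time_grid, float)
    g_of = decay.interpolator()
    out = {}
    for row in ledger.genes.itertuples():
        arch, c0 = row.archetype, row.mrna_copies0

        def rhs(tt, p, arch=arch, c0=c0, ksp=row.ksp, kdp=row.kdp):
            r = c0 * 2.0 ** archetype_mrna_log2(arch, np.array([tt]))[0]
            return ksp * r * float(g_of(tt)) - kdp * p

        sol = solve_ivp(rhs, (t[0], t[-1]), [row.protein_copies0],
                        t_eval=t, rtol=1e-8, atol=1e-6)
        out[row.gene] = sol.y[0]
    df = pd.DataFrame(out).T
    df.columns = list(TIME_LABELS[: len(t)])
    df.index.name = "gene"
    return df.reset_index()


def generate_timecourse(
    models: Sequence[TranscriptModel],
    ledger: TruthLedger,
    decay: GlobalDecayTruth,
    noise: NoiseSpec,
    seed: int,
    time_grid: Sequence[float] = TIME_GRID_HR,
    library_size: int = 2_000_000,
    gamma: float = 0.6,
    n_cells: int = 4_000_000,
    n_cleavage_peptides: int = 60,
    n_spikein: int = 5,
) -> TimecourseBundle:
    """Emit every observation layer for the configured time course.

    gamma is the iTRAQ ratio-compression exponent
    (observed_ratio = true_ratio ** gamma); it must lie in (0, 1].
    """
    t = np.asarray(time_grid, float)
    if len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if not 0.0 < gamma <= 1.0:
        raise ValueError("gamma must be in (0, 1]")
    rng = np.random.default_rng(seed)
    labels = list(TIME_LABELS[: len(t)])
    genes = ledger.genes
    by_id = {m.transcript_id: m for m in models}
    lengths = np.array([by_id[g].length for g in genes["gene"]], float)
    cds_lengths = np.array([by_id[g].cds_len for g in genes["gene"]], float)

    g_vals = np.array([float(decay.interpolator()(tt)) for tt in t])
    # absolute copies per cell: c0 * rel(t) * G(t)
    rel = np.vstack(
        [2.0 ** archetype_mrna_log2(a, t) for a in genes["archetype"]]
    )
    c0 = genes["mrna_copies0"].to_numpy()
    abs_copies = c0[:, None] * rel * g_vals[None, :]
    te_mult = genes[[f"te_mult_{lab}" for lab in labels]].to_numpy()

    # --- sequencing layers: library composition is relative only -----------
    def layered_counts(weight: np.ndarray) -> pd.DataFrame:
        expected = weight / weight.sum(axis=0, keepdims=True) * library_size
        if noise.count_law == "poisson":
            counts = rng.poisson(expected).astype(float)
        elif noise.count_law == "none":
            counts = expected
        else:
            raise ValueError(f"unknown count law {noise.count_law!r}")
        df = pd.DataFrame(counts, columns=labels)
        df.insert(0, "gene", genes["gene"].to_numpy())
        return df

    counts_mrna = layered_counts(abs_copies * lengths[:, None])
    counts_fp = layered_counts(abs_copies * te_mult * cds_lengths[:, None])

    # --- bulk masses (the absolute anchor RPKM cannot see) ------------------
    mrna_mass_cell = (abs_copies * lengths[:, None]).sum(axis=0) * NT_MW / AVOGADRO
    true_protein = simulate_true_protein(ledger, decay, t)
    prot = true_protein[labels].to_numpy()
    mw = genes["protein_mw"].to_numpy()
    protein_mass_cell = (prot * mw[:, None]).sum(axis=0) / AVOGADRO
    bulk = pd.DataFrame(
        {
            "time_hr": t,
            "total_mrna_ug": mrna_mass_cell * n_cells * 1e6,
            "cells": n_cells,
            "total_protein_g": protein_mass_cell * n_cells,
        }
    )

    true_mrna_abs = pd.DataFrame(abs_copies, columns=labels)
    true_mrna_abs.insert(0, "gene", genes["gene"].to_numpy())

    def jitter(shape) -> np.ndarray:
        if noise.intensity_cv <= 0:
            return np.ones(shape)
        sigma = np.sqrt(np.log1p(noise.intensity_cv**2))
        return rng.lognormal(-sigma**2 / 2, sigma, size=shape)

    # --- iTRAQ layer: compressed ratios -------------------------------------
    channels = list(ITRAQ_CHANNEL_MAP)[: len(t)]
    itraq_rows = []
    ratios = prot / prot[:, [0]]
    observed = ratios**gamma
    for i, gene in enumerate(genes["gene"]):
        for k in range(2):  # two unique peptides per protein
            base = float(np.exp(rng.normal(np.log(5_000.0), 0.8)))
            inten = base * observed[i] * jitter(len(t))
            row = {"peptide": f"{gene}_pep{k}", "protein": gene, "unique_flag": True}
            row.update({f"i{ch}": inten[j] for j, ch in enumerate(channels)})
            itraq_rows.append(row)
    itraq_peptides = pd.DataFrame(itraq_rows)

    # --- SRM layer: uncompressed, with per-sample injection drift -----------
    hk_proteins = ("ACTB", "TUBB", "FLNA")
    srm_rows = []
    n_reps = 2
    drift = np.ones((n_reps, len(t)))
    if noise.sample_scale_cv > 0:
        sigma = np.sqrt(np.log1p(noise.sample_scale_cv**2))
        drift = rng.lognormal(-sigma**2 / 2, sigma, size=(n_reps, len(t)))

    def srm_peptide(pep: str, protein: str, profile: np.ndarray) -> None:
        shares = np.array([0.5, 0.3, 0.2])  # fixed transition split
        for tr, share in enumerate(shares, start=1):
            for rep in range(1, n_reps + 1):
                areas = share * profile * drift[rep - 1] * jitter(len(t))
                for j, lab in enumerate(labels):
                    srm_rows.append(
                        {"peptide": pep, "protein": protein,
                         "transition_id": f"{pep}_y{tr}", "sample": lab,
                         "replicate": rep, "area": areas[j]}
                    )

    for hk in hk_proteins:
        base = float(np.exp(rng.normal(np.log(50_000.0), 0.3)))
        srm_peptide(f"{hk}_pep0", hk, np.full(len(t), base))
    for i, gene in enumerate(genes["gene"]):
        base = float(np.exp(rng.normal(np.log(8_000.0), 0.8)))
        srm_peptide(f"{gene}_srm0", gene, base * ratios[i])
    srm_transitions = pd.DataFrame(srm_rows)

    # --- degradomics layer: logistic appearance curves ----------------------
    pep_ledger = make_cleavage_ledger(n_cleavage_peptides, seed=seed + 1)
    cleave_rows = []
    rise = 100.0
    tau = 1.0
    cl_drift = np.ones((n_reps, len(t)))
    if noise.sample_scale_cv > 0:
        sigma = np.sqrt(np.log1p(noise.sample_scale_cv**2))
        cl_drift = rng.lognormal(-sigma**2 / 2, sigma, size=(n_reps, len(t)))

    def appearance(onset: float) -> np.ndarray:
        base = 1.0
        if not np.isfinite(onset):
            return np.full(len(t), base)
        frac = 1.0 / (1.0 + np.exp(-(t - onset) / tau))
        return base + (rise - base) * frac

    for row in pep_ledger.itertuples():
        scale = float(np.exp(rng.normal(np.log(2_000.0), 0.5)))
        profile = scale * appearance(row.onset_hr)
        for rep in range(1, n_reps + 1):
            vals = profile * cl_drift[rep - 1] * jitter(len(t))
            for j, lab in enumerate(labels):
                cleave_rows.append(
                    {"peptide": row.peptide, "protein": row.protein,
                     "p1_residue": row.p1_residue, "sample": lab,
                     "replicate": rep, "intensity": vals[j]}
                )
    for s in range(n_spikein):
        scale = float(np.exp(rng.normal(np.log(10_000.0), 0.2)))
        for rep in range(1, n_reps + 1):
            vals = scale * cl_drift[rep - 1] * jitter(len(t))
            for j, lab in enumerate(labels):
                cleave_rows.append(
                    {"peptide": f"SPIKE{s}", "protein": "spikein",
                     "p1_residue": "D", "sample": lab,
                     "replicate": rep, "intensity": vals[j]}
                )
    cleavage_peptides = pd.DataFrame(cleave_rows)

    # --- baseline iBAQ table -------------------------------------------------
    ibaq_scale = 1e10 / (prot[:, 0] * mw).sum()  # arbitrary instrument scale
    ibaq = pd.DataFrame(
        {"protein": genes["gene"], "intensity": prot[:, 0] * mw * ibaq_scale,
         "mw": mw}
    )

    ledger_full = TruthLedger(genes=genes.copy(), peptides=pep_ledger)
    return TimecourseBundle(
        ledger=ledger_full,
        decay=decay,
        time_grid=tuple(t),
        counts_mrna=counts_mrna,
        counts_fp=counts_fp,
        bulk=bulk,
        true_protein=true_protein,
        true_mrna_abs=true_mrna_abs,
        itraq_peptides=itraq_peptides,
        srm_transitions=srm_transitions,
        cleavage_peptides=cleavage_peptides,
        ibaq=ibaq,
    )


# ---------------------------------------------------------------------------
# positioned reads


def _position_weights(model: TranscriptModel, spec: DensitySpec) -> np.ndarray:
    w = np.ones(model.length)
    if spec.periodicity_amplitude > 0:
        pos = np.arange(model.length)
        phase = (pos - model.cds_start) % 3
        w *= 1.0 + spec.periodicity_amplitude * (phase == 0)
    if spec.start_peak > 0:
        w[model.cds_start : model.cds_start + 3] += spec.start_peak
    if spec.stop_peak > 0:
        w[model.cds_end - 3 : model.cds_end] += spec.stop_peak
    interval = spec.spike.get(model.transcript_id)
    if interval is not None:
        a, b = interval
        w[a:b] *= spec.spike_fold
    return w


def generate_reads(
    models: Sequence[TranscriptModel],
    spec: DensitySpec,
    seed: int,
) -> pd.DataFrame:
    """Sample positioned reads whose assigned positions follow the density.

    Footprint reads are placed so their occupied-interval midpoint is the
    sampled position; mRNA reads so their 5' end is. Lengths are uniform on
    the layer's accepted range. Output columns: transcript, start, length,
    layer (0-based, half-open starts).
    """
    if not models:
        raise ValueError("model set is empty")
    rng = np.random.default_rng(seed)
    lo, hi = FOOTPRINT_LEN_RANGE if spec.layer == "footprint" else MRNA_FRAG_LEN_RANGE

    weights = [_position_weights(m, spec) for m in models]
    flat = np.concatenate(weights)
    flat = flat / flat.sum()
    offsets = np.cumsum([0] + [m.length for m in models])
    draws = rng.choice(flat.size, size=spec.n_reads, p=flat)
    lens = rng.integers(lo, hi + 1, size=spec.n_reads)

    tx_idx = np.searchsorted(offsets, draws, side="right") - 1
    pos = draws - offsets[tx_idx]
    rows = []
    for i in range(spec.n_reads):
        m = models[tx_idx[i]]
        length = int(min(lens[i], m.length))
        if spec.layer == "footprint":
            start = int(pos[i]) - (length - 1) // 2
        else:
            start = int(pos[i])
        start = max(0, min(start, m.length - length))
        rows.append((m.transcript_id, start, length, spec.layer))
    return pd.DataFrame(rows, columns=["transcript", "start", "length", "layer"])
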