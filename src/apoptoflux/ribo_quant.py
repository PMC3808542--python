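"""Transcript-level quantification of paired mRNA-seq / ribosome-footprint data.

Positions, RPKM, translational efficiency (TE), 5'UTR analysis, metagene
profiles, uORF candidate detection and the five-way hierarchical clustering
used to classify transcript behaviour over the apoptosis time course.

Conventions: all coordinates are 0-based half-open on the spliced
transcript; footprint reads are assigned to the midpoint of the occupied
interval (floored for even lengths), mRNA reads to their 5' end; only
footprint reads of length 26-36 nt are accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .constants import FOOTPRINT_LEN_RANGE
from .transcripts import TranscriptModel

__all__ = [
    "DensityTrack",
    "ExpressionMatrix",
    "assign_read_position",
    "build_density_tracks",
    "count_reads_per_gene",
    "compute_rpkm",
    "filter_tracked",
    "compute_te",
    "utr_cds_ratio",
    "flag_utr_shift",
    "metagene_profile",
    "detect_uorf_candidates",
    "cluster_genes",
    "te_shift_test",
]

NEAR_AUG = tuple(
    sorted(
        {
            f"{a}{b}{c}"
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
            if sum(x != y for x, y in zip(f"{a}{b}{c}", "ATG")) == 1
        }
    )
)
"""The nine single-mismatch (DNA-alphabet) variants of ATG."""

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class DensityTrack:
    """Per-nucleotide assigned-read counts on one transcript."""

    transcript_id: str
    layer: str
    counts: np.ndarray
    sample: str = ""
    time_hr: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class ExpressionMatrix:
    """Gene x sample raw counts with per-sample mapped-read totals.

    RPKM is always derived from the stored raw counts and totals, so the
    normalization is reproducible from what the object holds.
    """

    counts: pd.DataFrame  # genes x samples
    region_lengths: pd.Series  # nt per gene
    layer: str = ""
    totals: pd.Series | None = None

    def __post_init__(self) -> None:
        self.region_lengths = self.region_lengths.reindex(self.counts.index)
        if self.region_lengths.isna().any():
            missing = self.region_lengths[self.region_lengths.isna()].index.tolist()
            raise ValueError(f"missing region lengths for genes: {missing[:5]}")
        if self.totals is None:
            self.totals = self.counts.sum(axis=0)

    @property
    def rpkm(self) -> pd.DataFrame:
        len_kb = self.region_lengths / 1_000.0
        total_m = self.totals / 1e6
        return self.counts.div(len_kb, axis=0).div(total_m, axis=1)


def assign_read_position(
    start: int, length: int, layer: str, model: TranscriptModel
) -> int | None:
    """Map a read to its assigned transcript nucleotide, or None if rejected.

    Footprints outside the 26-36 nt window are rejected (returns None).
    Accepted footprints map to the floored midpoint of the occupied
    interval [start, start+length-1]; mRNA reads map to their 5' start.
    """
    if start < 0 or start + length > model.length:
        raise ValueError(
            f"read [{start}, {start + length}) extends past transcript "
            f"{model.transcript_id} of length {model.length}"
        )
    if layer == "footprint":
        lo, hi = FOOTPRINT_LEN_RANGE
        if not lo <= length <= hi:
            return None
        return (2 * start + length - 1) // 2
    if layer == "mRNA":
        return start
    raise ValueError(f"unknown layer {layer!r}")


def build_density_tracks(
    reads: pd.DataFrame,
    models: Mapping[str, TranscriptModel],
    sample: str = "",
    time_hr: float = 0.0,
) -> dict[tuple[str, str], DensityTrack]:
    """Accumulate a reads table (transcript, start, length, layer) into tracks.

    Returns a dict keyed by (transcript_id, layer). Rejected footprint
    lengths are silently dropped, as in the filtering step of a real run.
    """
    tracks: dict[tuple[str, str], DensityTrack] = {}
    for row in reads.itertuples():
        model = models[row.transcript]
        pos = assign_read_position(int(row.start), int(row.length), row.layer, model)
        if pos is None:
            continue
        key = (row.transcript, row.layer)
        if key not in tracks:
            tracks[key] = DensityTrack(
                row.transcript, row.layer, np.zeros(model.length, dtype=int),
                sample=sample, time_hr=time_hr,
            )
        tracks[key].counts[pos] += 1
    return tracks


def count_reads_per_gene(
    tracks: Mapping[tuple[str, str], DensityTrack], layer: str
) -> pd.Series:
    """Total assigned reads per transcript for one layer."""
    return pd.Series(
        {tid: tr.total for (tid, lay), tr in tracks.items() if lay == layer},
        dtype=float,
    )


def compute_rpkm(count: float, region_len_nt: int, total_mapped: int) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if region_len_nt <= 0:
        raise ValueError("region length must be positive")
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / ((region_len_nt / 1_000.0) * (total_mapped / 1e6))


def filter_tracked(
    mrna: ExpressionMatrix, fp: ExpressionMatrix, min_rpkm: float = 1.0
) -> pd.Index:
    """Genes with RPKM >= min_rpkm in every one of the 12 samples.

    The tracked-transcript rule: a gene must be well expressed in all six
    mRNA and all six footprint samples to enter the relative analysis.
    """
    if mrna.counts.shape[1] != fp.counts.shape[1]:
        raise ValueError(
            f"sample-count mismatch: {mrna.counts.shape[1]} mRNA vs "
            f"{fp.counts.shape[1]} footprint samples"
        )
    common = mrna.counts.index.intersection(fp.counts.index)
    ok_mrna = (mrna.rpkm.loc[common] >= min_rpkm).all(axis=1)
    ok_fp = (fp.rpkm.loc[common] >= min_rpkm).all(axis=1)
    return common[ok_mrna & ok_fp]


def compute_te(
    fp_rpkm: pd.DataFrame, mrna_rpkm: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Translational efficiency (footprint RPKM / mRNA RPKM) per gene and time.

    Cells with zero mRNA RPKM are missing (NaN), never 0 or inf. Returns
    (te, log2 ratio of te vs the first column); the baseline column of the
    ratio table is 0 wherever TE is defined.
    """
    fp_rpkm, mrna_rpkm = fp_rpkm.align(mrna_rpkm, join="inner")
    te = fp_rpkm / mrna_rpkm.where(mrna_rpkm > 0)
    baseline = te.iloc[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_ratio = np.log2(te.div(baseline.where(baseline > 0), axis=0))
    return te, log2_ratio


def utr_cds_ratio(
    track: DensityTrack, model: TranscriptModel, total_mapped: int
) -> dict:
    """Region RPKMs for the 5'UTR and CDS and their ratio.

    The ratio is length-normalized: equal per-nucleotide densities give
    1.0 regardless of region lengths. Missing when the transcript has no
    annotated 5'UTR or no CDS signal; a reason code says which.
    """
    out = {"gene": model.transcript_id, "utr5_rpkm": np.nan, "cds_rpkm": np.nan,
           "ratio": np.nan, "reason": ""}
    if model.utr5_len == 0:
        out["reason"] = "no_utr5"
        return out
    utr_count = float(track.counts[: model.cds_start].sum())
    cds_count = float(track.counts[model.cds_start : model.cds_end].sum())
    out["utr5_rpkm"] = compute_rpkm(utr_count, model.utr5_len, total_mapped)
    out["cds_rpkm"] = compute_rpkm(cds_count, model.cds_len, total_mapped)
    if out["cds_rpkm"] > 0:
        out["ratio"] = out["utr5_rpkm"] / out["cds_rpkm"]
    else:
        out["reason"] = "no_cds_signal"
    return out


def flag_utr_shift(
    ratio_table: pd.DataFrame,
    fold: float = 2.0,
    min_timepoints: int = 3,
) -> tuple[pd.Index, pd.Index, list[str]]:
    """Flag genes whose 5'UTR/CDS translation ratio shifts vs baseline.

    ratio_table: genes x times, first column the 0-hr baseline. A gene is
    flagged *increased* when ratio_t / ratio_0 >= fold at >= min_timepoints
    post-treatment times (inclusive thresholds), *decreased* symmetrically
    with <= 1/fold. Genes without a positive baseline are skipped and
    returned for logging.
    """
    baseline = ratio_table.iloc[:, 0]
    usable = baseline.notna() & (baseline > 0)
    skipped = ratio_table.index[~usable].tolist()
    rel = ratio_table.loc[usable].div(baseline[usable], axis=0).iloc[:, 1:]
    n_up = (rel >= fold).sum(axis=1)
    n_dn = (rel <= 1.0 / fold).sum(axis=1)
    increased = rel.index[n_up >= min_timepoints]
    decreased = rel.index[n_dn >= min_timepoints]
    return increased, decreased, skipped


def metagene_profile(
    tracks: Iterable[DensityTrack],
    models: Mapping[str, TranscriptModel],
    align_to: str = "start",
    window_nt: int = 100,
) -> tuple[pd.DataFrame, int]:
    """Average median-normalized read density aligned at the CDS start or stop.

    Each track's counts are scaled by (median of per-track totals) / (that
    track's total) before averaging, so samples of different depth are
    comparable. The window spans [-window_nt, +window_nt) around the
    alignment point; transcripts that cannot contain the window are
    excluded and counted in the second return value.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("empty track set")
    if align_to not in ("start", "stop"):
        raise ValueError("align_to must be 'start' or 'stop'")
    totals = np.array([tr.total for tr in tracks], float)
    med = float(np.median(totals[totals > 0])) if (totals > 0).any() else 1.0

    window = np.arange(-window_nt, window_nt)
    acc = np.zeros(window.size)
    n_used = 0
    n_excluded = 0
    for tr, total in zip(tracks, totals):
        model = models[tr.transcript_id]
        anchor = model.cds_start if align_to == "start" else model.cds_end
        lo, hi = anchor - window_nt, anchor + window_nt
        if lo < 0 or hi > model.length:
            n_excluded += 1
            continue
        scale = med / total if total > 0 else 0.0
        acc += tr.counts[lo:hi] * scale
        n_used += 1
    if n_used == 0:
        raise ValueError("no transcript can contain the requested window")
    profile = pd.DataFrame({"offset": window, "mean_density": acc / n_used})
    return profile, n_excluded


def detect_uorf_candidates(
    track: DensityTrack,
    model: TranscriptModel,
    background_fold: float = 2.0,
) -> pd.DataFrame:
    """Scan the 5'UTR for translated upstream ORFs.

    Candidate initiation sites are AUG plus the nine near-AUG single
    mismatch codons. A candidate is emitted when an in-frame stop codon
    lies downstream within the UTR (candidates whose frame instead runs
    into the CDS are reported with overlaps_cds=True and the stop position
    -1), and the mean footprint density over the putative ORF exceeds
    ``background_fold`` times the overall UTR background. Sorted by mean
    density, descending.
    """
    if model.sequence is None:
        raise ValueError(
            f"{model.transcript_id}: transcript sequence required for uORF "
            "scanning — provide FASTA input"
        )
    if track.layer != "footprint":
        raise ValueError("uORF detection requires the footprint layer")
    utr = model.sequence[: model.utr5_len].upper().replace("U", "T")
    counts = np.asarray(track.counts, float)

    rows = []
    for pos in range(0, model.utr5_len - 2):
        codon = utr[pos : pos + 3]
        if codon != "ATG" and codon not in NEAR_AUG:
            continue
        stop_pos = -1
        for p in range(pos + 3, model.utr5_len - 2, 3):
            if utr[p : p + 3] in STOP_CODONS:
                stop_pos = p
                break
        overlaps_cds = stop_pos < 0
        orf_end = (stop_pos + 3) if stop_pos >= 0 else model.utr5_len
        mean_density = counts[pos:orf_end].mean() if orf_end > pos else 0.0
        # background: UTR density outside the putative ORF itself
        outside = np.concatenate([counts[:pos], counts[orf_end : model.utr5_len]])
        background = outside.mean() if outside.size else 0.0
        if background > 0 and mean_density <= background_fold * background:
            continue
        if background == 0 and mean_density == 0:
            continue
        rows.append(
            {"start": pos, "codon": codon, "stop": stop_pos,
             "overlaps_cds": overlaps_cds, "mean_density": mean_density}
        )
    df = pd.DataFrame(
        rows, columns=["start", "codon", "stop", "overlaps_cds", "mean_density"]
    )
    return df.sort_values("mean_density", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# clustering


def _spearman_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - Spearman rank correlation, pairwise-complete over missing cells.

    Two constant profiles have identical ranks and are treated as
    perfectly concordant (distance 0); a constant against a varying
    profile is uncorrelated (distance 1). Ties take average ranks.
    """
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 2:
        return 1.0
    # differences below 1e-9 log2 units are numerical fuzz, not signal:
    # quantize so they rank as exact ties
    ra = rankdata(np.round(a[mask], 9))
    rb = rankdata(np.round(b[mask], 9))
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    va, vb = (ra**2).sum(), (rb**2).sum()
    if va == 0 and vb == 0:
        return 0.0
    if va == 0 or vb == 0:
        return 1.0
    return 1.0 - float(ra @ rb / np.sqrt(va * vb))


def _spearman_distance_matrix(profiles: pd.DataFrame) -> np.ndarray:
    x = profiles.to_numpy(float)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _spearman_distance(x[i], x[j])
    return d


def _centroid_spearman_linkage(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering with true profile centroids.

    Cluster centroids are the (nan-)mean member profiles; the merge
    criterion is the Spearman distance between centroids, re-evaluated
    after each merge — the behaviour of the classic gene-expression
    clustering tools, as opposed to a Euclidean Lance-Williams update,
    which is not valid for a correlation metric. Returns a scipy-style
    linkage matrix and the flat cluster ids (1..k) at the k-cluster cut.
    """
    n = x.shape[0]
    centroids: dict[int, np.ndarray] = {i: x[i].astype(float) for i in range(n)}
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    active = sorted(centroids)
    for i_pos, a in enumerate(active):
        for b in active[i_pos + 1:]:
            dist[(a, b)] = _spearman_distance(centroids[a], centroids[b])
    z = np.zeros((n - 1, 4))
    flat_ids: np.ndarray | None = None
    next_id = n
    for step in range(n - 1):
        if len(active) == k:
            flat_ids = np.empty(n, dtype=int)
            for rank, cid in enumerate(sorted(active), start=1):
                flat_ids[members[cid]] = rank
        (a, b) = min(dist, key=lambda ab: (dist[ab], ab))
        d_ab = dist[a, b]
        merged = members[a] + members[b]
        with np.errstate(invalid="ignore"):
            centroid = np.nanmean(x[merged], axis=0)
        z[step] = (a, b, d_ab, len(merged))
        for cid in (a, b):
            active.remove(cid)
            for other in active:
                dist.pop((min(cid, other), max(cid, other)), None)
            del centroids[cid], members[cid]
        dist.pop((a, b), None)
        centroids[next_id] = centroid
        members[next_id] = merged
        for other in active:
            dist[(other, next_id)] = _spearman_distance(centroid, centroids[other])
        active.append(next_id)
        next_id += 1
    if flat_ids is None:  # k >= n: every row its own cluster
        flat_ids = np.arange(1, n + 1)
    return z, flat_ids


def _name_clusters(
    membership: pd.Series,
    mrna_log2: pd.DataFrame,
    fp_log2: pd.DataFrame,
    te_log2: pd.DataFrame,
    threshold: float = 0.5,
) -> dict[int, str]:
    """Name each cluster from its centroid behaviour over post-treatment times.

    Upreg: mean mRNA and footprint both > +threshold; Downreg: both below
    -threshold; TE_Up / TE_Down: mRNA within the threshold band but TE
    beyond it; Stable otherwise.
    """
    names: dict[int, str] = {}
    for cid in sorted(membership.unique()):
        genes = membership.index[membership == cid]
        m = float(np.nanmean(mrna_log2.loc[genes].iloc[:, 1:].to_numpy()))
        f = float(np.nanmean(fp_log2.loc[genes].iloc[:, 1:].to_numpy()))
        t = float(np.nanmean(te_log2.loc[genes].iloc[:, 1:].to_numpy()))
        if m > threshold and f > threshold:
            names[cid] = "Upreg"
        elif m < -threshold and f < -threshold:
            names[cid] = "Downreg"
        elif abs(m) <= threshold and t > threshold:
            names[cid] = "TE_Up"
        elif abs(m) <= threshold and t < -threshold:
            names[cid] = "TE_Down"
        else:
            names[cid] = "Stable"
    return names


@dataclass
class ClusterAssignment:
    """Gene -> behavioural label plus the underlying linkage record."""

    labels: pd.Series
    linkage: np.ndarray
    cluster_ids: pd.Series

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()


def cluster_genes(
    mrna_log2: pd.DataFrame,
    fp_log2: pd.DataFrame,
    te_log2: pd.DataFrame,
    k: int = 5,
) -> ClusterAssignment:
    """Five-way hierarchical clustering of per-gene time-course behaviour.

    Each sample's log2 ratios are median-centered across genes first:
    RPKM sees relative library composition only, so a shift in the
    expression of one gene class displaces every other gene's observed
    ratio by a common per-sample offset, and the gene-median removes it.
    Per-gene profiles are then the concatenated mRNA, footprint and TE
    log2 ratio trajectories; distance is 1 - Spearman rank correlation
    (pairwise-complete over missing TE cells); linkage is centroid, with
    centroids computed as mean member profiles and inter-centroid
    distances re-evaluated after every merge; the tree is cut into k flat
    clusters which are then named by their centroid behaviour
    (Upreg / Downreg / Stable / TE_Up / TE_Down).
    """
    genes = mrna_log2.index
    if not (genes.equals(fp_log2.index) and genes.equals(te_log2.index)):
        raise ValueError("the three matrices must share the same gene index")
    if len(genes) < k:
        raise ValueError(f"need at least k={k} genes, got {len(genes)}")
    mrna_log2 = mrna_log2 - mrna_log2.median(axis=0)
    fp_log2 = fp_log2 - fp_log2.median(axis=0)
    te_log2 = te_log2 - te_log2.median(axis=0)
    profiles = pd.concat([mrna_log2, fp_log2, te_log2], axis=1)
    z, flat = _centroid_spearman_linkage(profiles.to_numpy(float), k)
    cluster_ids = pd.Series(flat, index=genes)
    names = _name_clusters(cluster_ids, mrna_log2, fp_log2, te_log2)
    labels = cluster_ids.map(names)
    return ClusterAssignment(labels=labels, linkage=z, cluster_ids=cluster_ids)


def te_shift_test(
    te_log2: pd.DataFrame, t_late: str, t_ref: str
) -> float:
    """Two-sided Mann-Whitney U comparing a group's log2 TE at two times."""
    a = te_log2[t_late].dropna().to_numpy()
    b = te_log2[t_ref].dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 genes at each time")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        warnings.warn("degenerate all-tied input; p set to 1", stacklevel=2)
        return 1.0
    return float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
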