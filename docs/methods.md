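# Methods

This note documents the models, the synthetic-data conditions, the
numerical choices and the known limitations of the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The quantitative model

Protein copy number per cell obeys a mass-action balance

    dP/dt = k_sp · R(t) · G(t) − k_dp · P(t)

* `R(t)` — transcript copies per cell as seen by *relative* sequencing:
  the baseline absolute copy number multiplied by the RPKM ratio versus
  0 hr, fitted as either a four-parameter sigmoid or a quadratic
  (`auto` picks the lower residual sum of squares, ties to the sigmoid).
* `G(t)` — global mRNA decay, a four-parameter sigmoid fitted to bulk
  total-mRNA fractions and renormalized so G(0) = 1. The product
  R(t)·G(t) is the absolute transcript count; with G ≡ 1 the model
  reduces to the classical two-term form.
* `k_sp` (proteins·transcript⁻¹·hr⁻¹) and `k_dp` (hr⁻¹) — translation
  and first-order protein degradation constants. Under proteasome
  blockade degradation is slow and assumed near-constant across
  proteins: fits constrain k_dp to [0.010, 0.015] hr⁻¹ and P0 to ±10% of
  the measured baseline, with k_sp ≥ 0 free — k_sp is the parameter the
  data primarily determine.

The sigmoid parameterization used everywhere is
y(t) = d + (a − d) / (1 + exp((t − t0)/τ)).

### Fitting and integration

`simulate_protein` integrates the ODE with adaptive Runge–Kutta (RK45,
rtol 1e-8); the test suite validates it against a dt = 1e-4 hr
forward-Euler oracle and against the closed form for constant R·G.

`fit_kinetics` exploits the linearity of the ODE: for fixed k_dp the
integrating-factor solution

    P(t) = e^(−k_dp·t) (P0 + k_sp ∫₀ᵗ e^(k_dp·s) R(s)G(s) ds)

is linear in (P0, k_sp), so the fit is separable — k_dp is scanned on a
25-point grid over its bounds and refined by bounded scalar minimization,
while the inner (P0, k_sp) problem is solved by bounded linear least
squares. The integral uses dense trapezoid quadrature (1201 points over
the 12-h window). This is exact in the same sense as a multi-start
nonlinear search but deterministic and start-independent. Identifiability
is summarized by the condition number of the numerically differentiated
residual Jacobian at the optimum; observations near translational steady
state leave (k_sp, k_dp) identified only through their ratio, and such
fits are flagged `low_identifiability` (the ratio itself is recovered).

The G(t) and R(t) sigmoid fits use bounded trust-region least squares
multistarted over midpoint and width; fewer than four time points cannot
support a sigmoid and fall back to the quadratic with a warning.

## Quantification conventions

* Coordinates are 0-based, half-open, on the spliced transcript.
* Footprint reads are accepted at lengths 26–36 nt and assigned to the
  floored midpoint of the occupied interval; mRNA reads (50–90 nt
  fragments) to their 5′ end.
* RPKM = count / (region kb × mapped-read millions); stored raw counts
  and totals make the normalization reproducible.
* Tracked transcripts require RPKM ≥ 1 in all 12 samples (6 mRNA + 6
  footprint).
* TE = footprint RPKM / mRNA RPKM; zero-mRNA cells are missing values,
  never 0 or ∞, and are handled pairwise-complete downstream.
* 5′UTR shift flags: ratio_t/ratio_0 ≥ 2 (or ≤ 1/2) at ≥ 3 of the five
  post-treatment times, thresholds inclusive.
* uORF candidates: AUG or one of the nine single-mismatch near-AUG
  codons in the 5′UTR, an in-frame downstream stop inside the UTR (or
  flagged as CDS-overlapping), and mean footprint density over the
  putative ORF above 2× the UTR background *outside* the candidate —
  excluding the ORF from its own background keeps the contrast estimate
  unbiased.
* iTRAQ: peptides need 0-hr reporter signal > 300 cps (strict) and a
  unique protein match; proteins need ≥ 2 unique peptides; protein
  intensity is the plain sum over peptides; per-channel log2 medians are
  equalized to the grand median; ">50% increase" is read inclusively as
  ratio ≥ 1.5 at ≥ 2 post-treatment times.
* SRM: peptide intensity = Σ transition areas; each sample+replicate is
  scaled so the geometric-mean housekeeping index matches the median
  index across samples; replicates are then averaged and proteins sum
  their peptides. Spike-in normalization in the degradomics layer is the
  same construction with spike-in peptides as the index.
* P1 classification: D → caspase-like; K/R → tryptic-like; all other
  standard residues → other.

## Clustering

Transcript clustering concatenates each gene's mRNA, footprint and TE
log2-ratio trajectories, after median-centering each sample's ratios
across genes. The centering matters: RPKM sees only relative library
composition, so a shift in one gene class displaces every other gene's
observed ratio by a common per-sample offset; the gene-median removes
that offset and restores the trajectory shapes the class-naming
thresholds assume.

Distance is 1 − Spearman rank correlation, pairwise-complete over
missing TE cells, with two conventions: values differing by < 1e-9 log2
units rank as exact ties, and two constant profiles are perfectly
concordant (distance 0) while a constant against a varying profile is
uncorrelated (distance 1). Linkage is centroid in the sense of the
classic gene-expression clustering tools: a cluster's centroid is the
mean member profile and inter-centroid distances are re-evaluated after
every merge. (The textbook Lance–Williams "centroid" update assumes
Euclidean geometry and mis-cuts trees built on correlation distances.)
The k = 5 cut is named by centroid means over post-treatment times:
Upreg / Downreg when mRNA and footprint both exceed ±0.5 log2, TE_Up /
TE_Down when mRNA is within ±0.5 but TE exceeds it, Stable otherwise.

Cleavage-kinetics clustering uses the same agglomeration but Euclidean
distance on the log2 intensity-ratio profiles. This is deliberate:
cleavage appearance curves are all monotone rises, so their *rank*
profiles are identical regardless of onset time — the feature that
separates speed groups is when the amplitude rises, which only a
magnitude-aware distance can see. Clusters are ordered fastest-to-slowest
by the linearly interpolated position at which their centroid first
exceeds +1 log2 (never → Slowest/No Change); interpolation breaks the
ties that arise when several centroids first cross within the same
sampling interval.

## Statistics

Fisher's exact test is two-sided by minimum-likelihood summation (the
convention under which the published cleavage-table p-value reproduces);
the one-sided variant tests the deficit of the top-left cell. Set
enrichment uses the uncorrected χ² test of each set against the pooled
remainder, warning on expected counts below 1. TE distribution shifts
use the two-sided Mann–Whitney U test; an all-tied degenerate input
returns p = 1 with a warning.

## Absolute copy numbers

Total mRNA nucleotides per cell T = (mass per cell / 339.5 g/mol) · N_A,
with 339.5 the mean RNA monophosphate nucleotide weight and N_A fixed at
6.02214076e23 mol⁻¹. A transcript's copies are
(read fraction) · T / length. The analogous relation for protein
equates iBAQ intensity fractions to mass fractions of the bulk protein
mass per cell, converted to copies via each protein's molecular weight
(taken from an input column). T is used as a *count*, the only
dimensionally consistent reading of the mass-fraction relation.

## Synthetic-data conditions

The generator emulates a 6-point time course (0, 1.5, 3, 6, 9, 12 hr)
with five transcript archetypes cycling over the gene list: Upreg and
Downreg (±2 log2 by 12 hr), Stable (flat), TE_Up and TE_Down (flat mRNA,
±1 log2 footprint shift). Trajectories are normalized logistic ramps
with midpoint 4.5 hr and width 1.5 hr — between the early RPKM plateau
and the 6-hr onset of bulk decay and caspase activity. Default global
decay is the printed scaling-factor sequence
(1.0, 0.93, 0.91, 0.48, 0.17, 0.12), interpolated shape-preservingly
(PCHIP) where a continuous G is needed inside the generator; the model
stage fits its own sigmoid to the emitted bulk data.

Conditions chosen once for realism where unstated: baseline mRNA copies
lognormal with median 10/cell; k_sp uniform on [10, 270]; k_dp uniform
on [0.010, 0.015] hr⁻¹; baseline protein at translational equilibrium
k_sp·c0/k_dp; protein MW uniform 20–120 kDa; library size 2×10⁶ reads;
4×10⁶ cells; two iTRAQ peptides per protein and 3-transition, duplicate-
injection SRM; iTRAQ compression observed = true^γ with γ = 0.6; noise
defaults Poisson counts, 10% lognormal intensity CV, 10% per-sample
injection/labeling drift. Cleavage peptides follow logistic appearance
curves (width 1 hr, 100-fold rise over baseline) with cluster onsets
{6, 7.5, 9, 10.5, ∞} hr and P1 residues biased toward Asp in fast
clusters. Bulk masses are computed exactly from the true copies, so mass
conservation holds to rounding.

Read-level simulation places footprint midpoints (or mRNA 5′ ends) by
per-nucleotide weights with optional 3-nt periodicity, start/stop peaks
and localized spikes; lengths are uniform on the layer's accepted window.

What the generator does **not** emulate: sequencing error, positional
bias within fragments, isoform structure, peptide-level missingness
patterns, between-replicate batch structure beyond a scalar drift, and
protein-specific degradation. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated generative
assumptions, not robustness to every artefact of real libraries.

## Acceptance-study design

The k_sp recovery study regenerates 200 genes with k_sp ~ U[10, 270] and
k_dp ~ U[0.010, 0.015] under the fitted G(t), transcripts rising 2–5-fold.
Baseline protein is drawn at 10–50% of translational equilibrium: any
protein that measurably accumulates within 12 h at k_dp ≈ 0.0125 hr⁻¹ is
necessarily below equilibrium (a steady-state baseline caps the relative
12-h change at a few percent), and the genes worth fitting are exactly
the induced ones. Noise, where applied, is 5% multiplicative lognormal
per observation.

Problem sizes throughout the tests and acceptance script — 50 genes, 60
cleavage peptides, 200 recovery genes — are the package's chosen
demonstration scale; all operations are vectorized or O(n²) in gene
count and run comfortably at 10–100× that size.

## Known limitations

* Centroid agglomeration is O(n³) in the worst case; at genome scale
  (~5,000 genes) it is slow in pure Python — a future optimization would
  memoize rank vectors.
* The (k_sp, k_dp) ridge near steady state is flagged, not resolved; only
  the ratio is meaningful there.
* The per-sample SRM scaling of late time points for falling total
  protein is exposed as an input (default 1), not estimated.
* uORF detection under elongation-inhibitor footprints assigns density
  peaks, not initiation events; near-AUG candidates are inherently
  lower-confidence than AUG ones.
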