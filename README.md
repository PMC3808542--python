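# apoptoflux

Integrated analysis of transcription, translation and proteolysis during
chemotherapy-induced apoptosis — the multi-omic setting in which a
proteasome inhibitor (e.g. bortezomib in multiple myeloma cells) triggers
a 12-hour cascade of transcriptional reprogramming, translational
shutdown, global mRNA degradation and caspase-driven proteolysis, each
observed by a different technology:

- paired **mRNA-seq and ribosome profiling** (transcript abundance and
  ribosome footprint density),
- **iTRAQ and SRM quantitative proteomics** (relative protein abundance),
- **iBAQ / bulk measurements** (absolute mRNA and protein copies per cell),
- **N-terminomics degradomics** (kinetics of proteolytic cleavage).

The package is aimed at computational biologists who want to reproduce,
stress-test or extend this style of integrated kinetic analysis. Every
stage runs on synthetic data with a known ground-truth ledger, so each
method's recovery behaviour is testable without any external download.

## The model at the core

Sequencing normalized as RPKM reports *relative* pool composition only.
When total mRNA decays globally, a transcript whose relative abundance is
flat is actually disappearing from the cell. The package therefore couples
three fitted components:

- **G(t)** — a four-parameter sigmoid fitted to bulk total-mRNA
  measurements, normalized so G(0) = 1: the fraction of baseline mRNA mass
  remaining at time t;
- **R(t)** — per-gene trajectories (sigmoid or quadratic) fitted to
  baseline absolute copies × RPKM ratio, so that R(t)·G(t) is the absolute
  transcript count per cell;
- the mass-action protein balance

  dP/dt = k_sp · R(t) · G(t) − k_dp · P(t)

  with k_sp the translation rate constant (proteins·transcript⁻¹·hr⁻¹,
  physiological range ~10–270) and k_dp the first-order protein
  degradation constant (0.010–0.015 hr⁻¹ under proteasome blockade).
  (P0, k_sp, k_dp) are estimated per gene by constrained least squares.

Around this core: translational efficiency TE = footprint RPKM / mRNA
RPKM, five-way hierarchical clustering of (mRNA, footprint, TE)
trajectories with Spearman distance and centroid linkage, 5′UTR/CDS
translation ratios and uORF candidate detection, absolute copy numbers
from read fractions (mRNA, via the 339.5 g/mol mean nucleotide weight)
and iBAQ intensity fractions (protein), iTRAQ reporter aggregation with
ratio compression, SRM transition aggregation with housekeeping
normalization, and kinetic clustering of cleavage peptides with
P1-residue (Asp = caspase-like) enrichment statistics.

## Worked example

```python
from apoptoflux.pipeline import RunConfig, run_pipeline

cfg = RunConfig(seed=7, n_genes=50)   # full simulate -> ... -> report run
run_pipeline(cfg, "runs/demo")
```

or equivalently `apoptoflux run --seed 7 --n-genes 50 --outdir runs/demo`.
The run directory contains every stage's TSV outputs, a resolved
`config.yaml`, a hash manifest and `report.md`:

```
## Transcript cluster sizes
Stable     28
Downreg    12
Upreg      10

## Increased proteins: 0 flagged (0.0%)

## Kinetic fits
genes fitted: 50
ksp range: 22.2 - 536.0
ksp median: 234.6

## Cleavage kinetic clusters
Slowest/No Change    17
Slow                 13
Mid                  12
Fastest               9
Faster                9
```

Reading the numbers: under default Poisson/intensity noise the clustering
recovers the strongly shifted transcript classes (Upreg/Downreg) while
the subtler TE-shift classes blend into Stable; no protein passes the
≥1.5-fold-at-≥2-time-points increase rule once iTRAQ ratio compression
(γ = 0.6) is applied — mirroring the biological finding that very few
proteins detectably accumulate during rapid apoptosis; and cleavage
peptides spread over the five kinetic speed groups, caspase-type (Asp-P1)
peptides concentrated in the fast ones. Fitted k_sp values scatter around
their true range; genes whose protein stays flat sit on the known
(k_sp, k_dp) identifiability ridge and are flagged as such in
`kinetics.tsv`.

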