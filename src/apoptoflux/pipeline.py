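"""End-to-end orchestration: simulate -> quantify -> copies -> proteomics
-> model -> degradomics -> report.

Every stage reads and writes plain TSV files in a run directory, so any
stage can be re-run from persisted intermediates with identical results.
A manifest records input/output hashes and wall times per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance, degradomics, proteo_quant, ribo_quant, synthetic_data
from . import translation_model as tm
from .constants import TIME_GRID_HR, TIME_LABELS
from .transcripts import load_transcript_table, save_fasta, save_transcript_table

log = logging.getLogger("apoptoflux")

ALL_STAGES = (
    "simulate", "quantify", "copies", "proteomics", "model", "degradomics", "report",
)


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run.

    Unknown keys in a config file are rejected; the resolved config is
    serialized alongside the outputs for provenance.
    """

    seed: int = 0
    n_genes: int = 100
    time_grid: tuple[float, ...] = TIME_GRID_HR
    stages: tuple[str, ...] = ALL_STAGES
    # synthetic-data conditions
    uorf_fraction: float = 0.2
    count_law: str = "poisson"
    intensity_cv: float = 0.10
    sample_scale_cv: float = 0.10
    gamma: float = 0.6
    library_size: int = 2_000_000
    n_cells: int = 4_000_000
    n_cleavage_peptides: int = 60
    # stage parameters
    min_rpkm: float = 1.0
    utr_fold: float = 2.0
    utr_min_timepoints: int = 3
    itraq_fold: float = 1.5
    itraq_min_timepoints: int = 2
    housekeeping: tuple[str, ...] = ("ACTB", "TUBB", "FLNA")
    spikein_peptides: tuple[str, ...] = tuple(f"SPIKE{i}" for i in range(5))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for st in cfg.stages:
            if st not in ALL_STAGES:
                raise ValueError(f"unknown stage {st!r}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("time_grid", "stages", "housekeeping", "spikein_peptides"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data = {k: list(v) if isinstance(v, tuple) else v for k, v in data.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    """One pipeline invocation over a run directory."""

    def __init__(self, config: RunConfig, outdir: str | Path):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: list[dict] = []
        self.labels = list(TIME_LABELS[: len(config.time_grid)])

    # -- helpers ------------------------------------------------------------
    def _write(self, df: pd.DataFrame, name: str) -> Path:
        path = self.outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        return path

    def _read(self, name: str) -> pd.DataFrame:
        return pd.read_csv(self.outdir / name, sep="\t")

    def _record(self, stage: str, inputs: list[Path], outputs: list[Path],
                elapsed: float) -> None:
        self.manifest.append(
            {
                "stage": stage,
                "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
                "outputs": {p.name: _sha256(p) for p in outputs},
                "wall_time_s": round(elapsed, 3),
            }
        )

    # -- stages -------------------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.config
        models, uorf_table = synthetic_data.generate_transcriptome(
            cfg.n_genes, seed=cfg.seed, uorf_fraction=cfg.uorf_fraction
        )
        ledger = synthetic_data.make_truth_ledger(
            models, seed=cfg.seed + 1, uorf_table=uorf_table,
            time_grid=cfg.time_grid,
        )
        noise = synthetic_data.NoiseSpec(
            count_law=cfg.count_law, intensity_cv=cfg.intensity_cv,
            sample_scale_cv=cfg.sample_scale_cv,
        )
        bundle = synthetic_data.generate_timecourse(
            models, ledger, synthetic_data.GlobalDecayTruth(),
            noise=noise, seed=cfg.seed + 2, time_grid=cfg.time_grid,
            library_size=cfg.library_size, gamma=cfg.gamma,
            n_cells=cfg.n_cells, n_cleavage_peptides=cfg.n_cleavage_peptides,
        )
        bundle.write(self.outdir)
        save_transcript_table(models, self.outdir / "transcripts.tsv")
        save_fasta(
            {m.transcript_id: m.sequence for m in models if m.sequence},
            self.outdir / "transcripts.fa",
        )

    def stage_quantify(self) -> None:
        cfg = self.config
        models = load_transcript_table(self.outdir / "transcripts.tsv")
        lengths = pd.Series({t: m.length for t, m in models.items()})
        cds_lengths = pd.Series({t: m.cds_len for t, m in models.items()})
        counts_m = self._read("counts_mrna.tsv").set_index("gene")[self.labels]
        counts_f = self._read("counts_footprint.tsv").set_index("gene")[self.labels]
        em_m = ribo_quant.ExpressionMatrix(counts_m, lengths, layer="mRNA")
        em_f = ribo_quant.ExpressionMatrix(counts_f, cds_lengths, layer="footprint")
        tracked = ribo_quant.filter_tracked(em_m, em_f, min_rpkm=cfg.min_rpkm)
        rpkm_m = em_m.rpkm.loc[tracked]
        rpkm_f = em_f.rpkm.loc[tracked]
        te, te_log2 = ribo_quant.compute_te(rpkm_f, rpkm_m)
        mrna_log2 = np.log2(rpkm_m.div(rpkm_m.iloc[:, 0], axis=0))
        fp_log2 = np.log2(rpkm_f.div(rpkm_f.iloc[:, 0], axis=0))
        assign = ribo_quant.cluster_genes(mrna_log2, fp_log2, te_log2, k=5)

        self._write(rpkm_m.reset_index(), "rpkm_mrna.tsv")
        self._write(rpkm_f.reset_index(), "rpkm_footprint.tsv")
        self._write(te.reset_index(), "te.tsv")
        self._write(te_log2.reset_index(), "te_log2.tsv")
        self._write(mrna_log2.reset_index(), "mrna_log2.tsv")
        self._write(fp_log2.reset_index(), "fp_log2.tsv")
        self._write(
            pd.DataFrame({"gene": assign.labels.index, "label": assign.labels.values}),
            "clusters.tsv",
        )

    def stage_copies(self) -> None:
        bulk = self._read("bulk.tsv")
        counts_m = self._read("counts_mrna.tsv").set_index("gene")[self.labels]
        models = load_transcript_table(self.outdir / "transcripts.tsv")
        lengths = pd.Series({t: m.length for t, m in models.items()})
        row0 = bulk.iloc[0]
        mass_cell = abundance.mrna_mass_per_cell(
            row0["total_mrna_ug"] * 1e-6, row0["cells"]
        )
        copies = abundance.mrna_copies_table(
            counts_m.iloc[:, 0], lengths, mass_cell
        )
        self._write(
            pd.DataFrame({"gene": copies.index, "copies": copies.values}),
            "copies_mrna.tsv",
        )
        ibaq = self._read("ibaq_intensities.tsv")
        g_total = row0["total_protein_g"] / row0["cells"]
        prot = abundance.protein_copies_table(ibaq, g_total)
        self._write(
            prot[["protein", "copies", "mw"]], "copies_protein.tsv"
        )

    def stage_proteomics(self) -> None:
        cfg = self.config
        peptides = self._read("itraq_peptides.tsv")
        retained, _dropped = proteo_quant.filter_itraq_peptides(peptides)
        proteins, _n_excl = proteo_quant.quantify_itraq_protein(retained)
        ratio_cols = [c for c in proteins.columns if c.startswith("ratio_")]
        ratios = proteins[ratio_cols]
        flagged, pct = proteo_quant.flag_increased(
            ratios, fold=cfg.itraq_fold, min_timepoints=cfg.itraq_min_timepoints
        )
        self._write(proteins.reset_index(), "itraq_proteins.tsv")
        self._write(
            pd.DataFrame({"protein": list(flagged), "flagged_pct": pct}),
            "increased.tsv",
        )
        srm = self._read("srm_transitions.tsv")
        _peps, prots = proteo_quant.quantify_srm(srm, list(cfg.housekeeping))
        self._write(prots, "srm_proteins.tsv")

    def stage_model(self) -> None:
        bulk = self._read("bulk.tsv")
        t = np.asarray(self.config.time_grid, float)
        mass_per_cell = bulk["total_mrna_ug"] / bulk["cells"]
        fractions = (mass_per_cell / mass_per_cell.iloc[0]).to_numpy()
        g = tm.fit_global_decay(t, fractions)
        self._write(
            pd.DataFrame(
                [{"a": g.a, "d": g.d, "t0": g.t0, "tau": g.tau, "rss": g.rss}]
            ),
            "gfit.tsv",
        )

        rpkm = self._read("rpkm_mrna.tsv").set_index("gene")[self.labels]
        copies = self._read("copies_mrna.tsv").set_index("gene")["copies"]
        srm = self._read("srm_proteins.tsv").set_index("protein")
        prot_copies = self._read("copies_protein.tsv").set_index("protein")["copies"]

        rows = []
        genes = rpkm.index.intersection(srm.index).intersection(copies.index)
        for gene in genes:
            ratios = (rpkm.loc[gene] / rpkm.loc[gene].iloc[0]).to_numpy()
            r = tm.fit_transcript_trajectory(t, ratios, c0=float(copies[gene]))
            srm_ratio = (srm.loc[gene, self.labels] / srm.loc[gene, self.labels].iloc[0]).to_numpy(float)
            p_obs = float(prot_copies[gene]) * srm_ratio
            fit = tm.fit_kinetics(p_obs, t, float(prot_copies[gene]), r, g)
            rows.append(
                {"gene": gene, "form": r.form, "P0": fit.p0, "ksp": fit.ksp,
                 "kdp": fit.kdp, "rss": fit.rss, "converged": fit.converged,
                 "condition_number": fit.condition_number,
                 "low_identifiability": fit.low_identifiability}
            )
        self._write(pd.DataFrame(rows), "kinetics.tsv")

    def stage_degradomics(self) -> None:
        cfg = self.config
        cleav = self._read("cleavage_peptides.tsv")
        norm = degradomics.normalize_spikein(cleav, list(cfg.spikein_peptides))
        labels = [c for c in self.labels if c in norm.columns]
        norm = norm[labels]
        with np.errstate(divide="ignore"):
            log2 = np.log2(norm.div(norm.iloc[:, 0], axis=0)).iloc[:, 1:]
        clusters = degradomics.cluster_cleavage_kinetics(log2, k=5)
        p1 = (
            cleav[~cleav["peptide"].isin(cfg.spikein_peptides)]
            .groupby("peptide")["p1_residue"].first()
        )
        classes = p1.map(degradomics.classify_p1)
        out = pd.DataFrame(
            {"peptide": clusters.index, "cluster": clusters.values,
             "p1_residue": p1.reindex(clusters.index).values,
             "p1_class": classes.reindex(clusters.index).values}
        )
        self._write(out, "cleavage_clusters.tsv")
        summary = (
            out.groupby(["cluster", "p1_class"]).size().unstack(fill_value=0)
        )
        self._write(summary.reset_index(), "p1_summary.tsv")
        enr = degradomics.chi2_set_enrichment(
            summary if not summary.empty else pd.DataFrame()
        )
        self._write(enr.reset_index(), "enrichment.tsv")

    def stage_report(self) -> None:
        lines = ["# Pipeline report", ""]
        clusters = self.outdir / "clusters.tsv"
        if clusters.exists():
            sizes = self._read("clusters.tsv")["label"].value_counts()
            lines += ["## Transcript cluster sizes", sizes.to_string(), ""]
        inc = self.outdir / "increased.tsv"
        if inc.exists():
            df = self._read("increased.tsv")
            pct = df["flagged_pct"].iloc[0] if len(df) else 0.0
            lines += [f"## Increased proteins: {len(df)} flagged ({pct}%)", ""]
        kin = self.outdir / "kinetics.tsv"
        if kin.exists():
            df = self._read("kinetics.tsv")
            if len(df):
                lines += [
                    "## Kinetic fits",
                    f"genes fitted: {len(df)}",
                    f"ksp range: {df['ksp'].min():.1f} - {df['ksp'].max():.1f}",
                    f"ksp median: {df['ksp'].median():.1f}",
                    "",
                ]
        cc = self.outdir / "cleavage_clusters.tsv"
        if cc.exists():
            sizes = self._read("cleavage_clusters.tsv")["cluster"].value_counts()
            lines += ["## Cleavage kinetic clusters", sizes.to_string(), ""]
        (self.outdir / "report.md").write_text("\n".join(lines))

    # -- driver -------------------------------------------------------------
    STAGE_IO: dict[str, tuple[list[str], list[str]]] = {
        "simulate": ([], ["counts_mrna.tsv", "counts_footprint.tsv", "bulk.tsv",
                          "itraq_peptides.tsv", "srm_transitions.tsv",
                          "cleavage_peptides.tsv", "ibaq_intensities.tsv",
                          "truth_ledger.tsv", "transcripts.tsv", "transcripts.fa"]),
        "quantify": (["counts_mrna.tsv", "counts_footprint.tsv", "transcripts.tsv"],
                     ["rpkm_mrna.tsv", "rpkm_footprint.tsv", "te.tsv", "te_log2.tsv",
                      "mrna_log2.tsv", "fp_log2.tsv", "clusters.tsv"]),
        "copies": (["bulk.tsv", "counts_mrna.tsv", "ibaq_intensities.tsv"],
                   ["copies_mrna.tsv", "copies_protein.tsv"]),
        "proteomics": (["itraq_peptides.tsv", "srm_transitions.tsv"],
                       ["itraq_proteins.tsv", "increased.tsv", "srm_proteins.tsv"]),
        "model": (["bulk.tsv", "rpkm_mrna.tsv", "copies_mrna.tsv",
                   "srm_proteins.tsv", "copies_protein.tsv"],
                  ["gfit.tsv", "kinetics.tsv"]),
        "degradomics": (["cleavage_peptides.tsv"],
                        ["cleavage_clusters.tsv", "p1_summary.tsv", "enrichment.tsv"]),
        "report": ([], ["report.md"]),
    }

    def run(self) -> Path:
        """Execute enabled stages in dependency order; return the run directory."""
        self.config.to_yaml(self.outdir / "config.yaml")
        order = [s for s in ALL_STAGES if s in self.config.stages]
        for stage in order:
            fn = getattr(self, f"stage_{stage}")
            ins, outs = self.STAGE_IO[stage]
            t0 = time.perf_counter()
            log.info("stage %s: starting", stage)
            try:
                fn()
            except Exception:
                log.error("stage %s failed; partial outputs retained", stage)
                raise
            elapsed = time.perf_counter() - t0
            self._record(
                stage,
                [self.outdir / n for n in ins],
                [self.outdir / n for n in outs if (self.outdir / n).exists()],
                elapsed,
            )
            log.info("stage %s: done in %.2fs", stage, elapsed)
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        return self.outdir


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Run the configured stages into ``outdir`` and write a manifest."""
    return PipelineRun(config, outdir).run()
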