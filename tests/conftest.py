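"""Shared fixtures: a small noise-free simulated time course and its pieces."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from apoptoflux import ribo_quant as rq
from apoptoflux import synthetic_data as sd
from apoptoflux.constants import TIME_LABELS

LABELS = list(TIME_LABELS)


@pytest.fixture(scope="session")
def small_models():
    models, uorf = sd.generate_transcriptome(50, seed=3, uorf_fraction=0.2)
    return models, uorf


@pytest.fixture(scope="session")
def ledger(small_models):
    models, uorf = small_models
    return sd.make_truth_ledger(models, seed=4, uorf_table=uorf)


@pytest.fixture(scope="session")
def clean_bundle(small_models, ledger):
    """Noise-free time course over 50 genes: exact expectations everywhere."""
    models, _ = small_models
    return sd.generate_timecourse(
        models, ledger, sd.GlobalDecayTruth(), sd.NoiseSpec.none(), seed=5,
        n_cleavage_peptides=60,
    )


@pytest.fixture(scope="session")
def expression(small_models, clean_bundle):
    """ExpressionMatrix pair (mRNA, footprint) from the clean bundle."""
    models, _ = small_models
    lengths = pd.Series({m.transcript_id: m.length for m in models})
    cds = pd.Series({m.transcript_id: m.cds_len for m in models})
    em_m = rq.ExpressionMatrix(
        clean_bundle.counts_mrna.set_index("gene")[LABELS], lengths, layer="mRNA"
    )
    em_f = rq.ExpressionMatrix(
        clean_bundle.counts_fp.set_index("gene")[LABELS], cds, layer="footprint"
    )
    return em_m, em_f


@pytest.fixture(scope="session")
def log2_tables(expression):
    """(mrna_log2, fp_log2, te_log2) ratio tables vs 0 hr."""
    em_m, em_f = expression
    rm, rf = em_m.rpkm, em_f.rpkm
    _te, te_log2 = rq.compute_te(rf, rm)
    with np.errstate(divide="ignore"):
        ml = np.log2(rm.div(rm.iloc[:, 0], axis=0))
        fl = np.log2(rf.div(rf.iloc[:, 0], axis=0))
    return ml, fl, te_log2
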