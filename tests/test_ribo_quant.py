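"""Quantification rules: positions, RPKM, TE, UTR analysis, metagene,
uORF scanning and clustering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apoptoflux import ribo_quant as rq
from apoptoflux import synthetic_data as sd
from apoptoflux.transcripts import TranscriptModel

LABELS = ["t0", "t1p5", "t3", "t6", "t9", "t12"]


@pytest.fixture()
def model():
    # 100 nt UTR5 + 1500 nt CDS + 200 nt UTR3
    return TranscriptModel("TX1", 100, 1500, 200)


class TestReadAssignment:
    @pytest.mark.parametrize(
        "start,length,layer,expected",
        [
            (100, 30, "footprint", 114),  # midpoint of [100,129] floored
            (0, 60, "mRNA", 0),  # 5'-end rule
            (10, 27, "footprint", 23),
            (0, 26, "footprint", 12),
        ],
    )
    def test_assigned_positions(self, model, start, length, layer, expected):
        assert rq.assign_read_position(start, length, layer, model) == expected

    @pytest.mark.parametrize("length", [25, 37])
    def test_footprints_outside_26_36_rejected(self, model, length):
        assert rq.assign_read_position(0, length, "footprint", model) is None

    def test_read_past_end_is_error_naming_transcript(self, model):
        with pytest.raises(ValueError, match="TX1"):
            rq.assign_read_position(1790, 30, "footprint", model)


class TestRpkm:
    @pytest.mark.parametrize(
        "count,length,total,expected",
        [
            (10, 1000, 10**6, 10.0),
            (0, 1000, 10**6, 0.0),
            # the 0-hr library size of the experiment this package models
            (50, 2500, 8_744_024, 2.287),
        ],
    )
    def test_values(self, count, length, total, expected):
        assert rq.compute_rpkm(count, length, total) == pytest.approx(expected, abs=5e-4)

    def test_zero_length_or_total_errors(self):
        with pytest.raises(ValueError):
            rq.compute_rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            rq.compute_rpkm(1, 100, 0)

    def test_downsampling_invariance(self):
        """Halving all counts and the total leaves RPKM unchanged exactly."""
        assert rq.compute_rpkm(500, 2000, 10**6) == rq.compute_rpkm(250, 2000, 5 * 10**5)


class TestTrackedFilter:
    def _matrices(self, rpkm_m, rpkm_f, lengths=None):
        genes = rpkm_m.index
        lengths = lengths if lengths is not None else pd.Series(1000.0, index=genes)
        # counts chosen so that rpkm reproduces exactly with total=1e6
        counts_m = rpkm_m * 1.0
        counts_f = rpkm_f * 1.0
        em = rq.ExpressionMatrix(counts_m, lengths, totals=pd.Series(10**6, index=rpkm_m.columns))
        ef = rq.ExpressionMatrix(counts_f, lengths, totals=pd.Series(10**6, index=rpkm_f.columns))
        return em, ef

    def test_single_dip_below_threshold_excludes(self):
        rpkm = pd.DataFrame(2.0, index=["A", "B"], columns=LABELS)
        dipped = rpkm.copy()
        dipped.loc["B", "t3"] = 0.99
        em, ef = self._matrices(rpkm, dipped)
        assert list(rq.filter_tracked(em, ef)) == ["A"]

    def test_threshold_is_inclusive(self):
        rpkm = pd.DataFrame(1.0, index=["A", "B", "C"], columns=LABELS)
        em, ef = self._matrices(rpkm, rpkm)
        assert len(rq.filter_tracked(em, ef)) == 3

    def test_engineered_fixture_counts_survivors(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(100)]
        rpkm = pd.DataFrame(
            rng.uniform(2, 50, size=(100, 6)), index=genes, columns=LABELS
        )
        low = rng.choice(100, size=7, replace=False)
        for i in low:
            rpkm.iloc[i, rng.integers(0, 6)] = 0.5
        em, ef = self._matrices(rpkm, pd.DataFrame(5.0, index=genes, columns=LABELS))
        assert len(rq.filter_tracked(em, ef)) == 93

    def test_sample_count_mismatch_errors(self):
        rpkm = pd.DataFrame(2.0, index=["A"], columns=LABELS)
        em, _ = self._matrices(rpkm, rpkm)
        short = pd.DataFrame(2.0, index=["A"], columns=LABELS[:5])
        ef = rq.ExpressionMatrix(short, pd.Series(1000.0, index=["A"]))
        with pytest.raises(ValueError, match="mismatch"):
            rq.filter_tracked(em, ef)


class TestTranslationalEfficiency:
    def test_values_and_missingness(self):
        fp = pd.DataFrame({"t0": [20.0, 5.0], "t6": [10.0, 5.0]}, index=["A", "B"])
        mrna = pd.DataFrame({"t0": [10.0, 5.0], "t6": [0.0, 5.0]}, index=["A", "B"])
        te, log2r = rq.compute_te(fp, mrna)
        assert te.loc["A", "t0"] == 2.0
        assert np.isnan(te.loc["A", "t6"])  # zero mRNA -> missing, not inf
        assert te.loc["B", "t0"] == 1.0
        assert log2r.loc["B", "t6"] == 0.0
        assert log2r.loc["B", "t0"] == 0.0

    def test_te_up_archetype_shifted_plus_one_log2_vs_stable(self, ledger, log2_tables):
        _, _, te_log2 = log2_tables
        truth = ledger.genes.set_index("gene")
        te_up = truth.query("archetype == 'TE_Up'").index
        stable = truth.query("archetype == 'Stable'").index
        # the generator's TE shift saturates at +1 log2 by 12 hr; comparing
        # against Stable genes cancels the per-sample composition offset
        diff = te_log2.loc[te_up, "t12"].mean() - te_log2.loc[stable, "t12"].mean()
        assert diff == pytest.approx(1.0, abs=1e-6)

    def test_te_invariant_to_consistent_library_scaling(self):
        rng = np.random.default_rng(5)
        fp = pd.DataFrame(rng.uniform(1, 10, (4, 6)), columns=LABELS)
        mrna = pd.DataFrame(rng.uniform(1, 10, (4, 6)), columns=LABELS)
        te1, _ = rq.compute_te(fp, mrna)
        te2, _ = rq.compute_te(fp * 3.0, mrna * 3.0)
        pd.testing.assert_frame_equal(te1, te2)


class TestUtrCdsRatio:
    def test_equal_density_gives_ratio_one(self, model):
        counts = np.full(model.length, 4)
        track = rq.DensityTrack("TX1", "footprint", counts)
        out = rq.utr_cds_ratio(track, model, total_mapped=10**6)
        assert out["ratio"] == pytest.approx(1.0)

    @given(
        utr5=st.integers(30, 500),
        cds_codons=st.integers(10, 400),
        density=st.integers(1, 20),
    )
    @settings(max_examples=25, deadline=None)
    def test_length_normalization_property(self, utr5, cds_codons, density):
        """Equal per-nt density gives ratio 1 for any region lengths."""
        m = TranscriptModel("T", utr5, 3 * cds_codons, 50)
        track = rq.DensityTrack("T", "footprint", np.full(m.length, density))
        out = rq.utr_cds_ratio(track, m, total_mapped=10**6)
        assert out["ratio"] == pytest.approx(1.0)

    def test_worked_example(self):
        m = TranscriptModel("T", 100, 1500, 0)
        counts = np.zeros(m.length, dtype=int)
        counts[:100] = 0
        # 30 reads on the 100-nt UTR, 300 on the 1500-nt CDS
        counts[10] = 30
        counts[200] = 300
        out = rq.utr_cds_ratio(rq.DensityTrack("T", "footprint", counts), m, 10**6)
        assert out["ratio"] == pytest.approx(1.5)

    def test_zero_utr_reads_gives_zero_ratio(self, model):
        counts = np.zeros(model.length, dtype=int)
        counts[model.cds_start + 10] = 50
        out = rq.utr_cds_ratio(rq.DensityTrack("TX1", "footprint", counts), model, 10**6)
        assert out["ratio"] == 0.0

    def test_missing_utr_reported_with_reason(self):
        m = TranscriptModel("T", 0, 300, 50)
        out = rq.utr_cds_ratio(rq.DensityTrack("T", "footprint", np.ones(350)), m, 10**6)
        assert np.isnan(out["ratio"])
        assert out["reason"] == "no_utr5"


class TestUtrShiftFlag:
    def test_three_inclusive_hits_flag_increase(self):
        table = pd.DataFrame(
            [[1.0, 2.1, 2.0, 2.5, 1.1, 1.0]], index=["A"], columns=LABELS
        )
        inc, dec, _ = rq.flag_utr_shift(table)
        assert list(inc) == ["A"] and len(dec) == 0

    def test_two_hits_not_flagged(self):
        table = pd.DataFrame(
            [[1.0, 2.1, 2.0, 1.1, 1.1, 1.0]], index=["A"], columns=LABELS
        )
        inc, _, _ = rq.flag_utr_shift(table)
        assert len(inc) == 0

    def test_engineered_fixture_count(self):
        """274 genes built to pass the increase rule are all flagged."""
        rng = np.random.default_rng(23)
        n_pass, n_fail = 274, 126
        rows = []
        for _ in range(n_pass):
            vals = np.ones(6)
            hits = rng.choice(5, size=3, replace=False) + 1
            vals[hits] = rng.uniform(2.0, 4.0, 3)
            rows.append(vals)
        for _ in range(n_fail):
            vals = np.ones(6)
            hits = rng.choice(5, size=2, replace=False) + 1
            vals[hits] = rng.uniform(2.0, 4.0, 2)
            rows.append(vals)
        table = pd.DataFrame(rows, columns=LABELS)
        inc, _, _ = rq.flag_utr_shift(table)
        assert len(inc) == 274

    def test_missing_baseline_skipped_and_logged(self):
        table = pd.DataFrame(
            [[np.nan, 2, 2, 2, 2, 2], [1, 2, 2, 2, 1, 1]],
            index=["A", "B"], columns=LABELS,
        )
        inc, _, skipped = rq.flag_utr_shift(table)
        assert skipped == ["A"] and list(inc) == ["B"]


class TestMetagene:
    def _models(self, n=5):
        return {f"T{i}": TranscriptModel(f"T{i}", 150, 600, 150) for i in range(n)}

    def test_uniform_density_gives_flat_profile(self):
        models = self._models()
        tracks = [
            rq.DensityTrack(t, "footprint", np.full(m.length, 7))
            for t, m in models.items()
        ]
        profile, n_exc = rq.metagene_profile(tracks, models, "start", 100)
        assert n_exc == 0
        assert profile["mean_density"].max() / profile["mean_density"].min() < 1.05

    def test_start_peak_recovered_at_offset_zero(self):
        models = self._models()
        tracks = []
        for t, m in models.items():
            counts = np.full(m.length, 2)
            counts[m.cds_start] = 200
            tracks.append(rq.DensityTrack(t, "footprint", counts))
        profile, _ = rq.metagene_profile(tracks, models, "start", 50)
        peak_offset = profile.loc[profile["mean_density"].idxmax(), "offset"]
        assert peak_offset == 0

    def test_periodic_density_has_period_three_spectrum(self):
        models = self._models()
        tracks = []
        for t, m in models.items():
            pos = np.arange(m.length)
            counts = (10 * (1 + 0.5 * ((pos - m.cds_start) % 3 == 0))).astype(int)
            tracks.append(rq.DensityTrack(t, "footprint", counts))
        profile, _ = rq.metagene_profile(tracks, models, "start", 60)
        y = profile["mean_density"].to_numpy()
        spec = np.abs(np.fft.rfft(y - y.mean()))
        freqs = np.fft.rfftfreq(y.size)
        dominant_period = 1.0 / freqs[1:][np.argmax(spec[1:])]
        assert dominant_period == pytest.approx(3.0, rel=0.05)

    def test_median_normalization_equalizes_depth(self):
        models = self._models(2)
        deep = rq.DensityTrack("T0", "footprint", np.full(models["T0"].length, 50))
        shallow = rq.DensityTrack("T1", "footprint", np.full(models["T1"].length, 5))
        profile, _ = rq.metagene_profile([deep, shallow], models, "start", 30)
        # both tracks are flat; after depth normalization the mean is flat too
        assert profile["mean_density"].std() < 1e-9

    def test_empty_track_set_errors(self):
        with pytest.raises(ValueError):
            rq.metagene_profile([], {}, "start", 10)


class TestUorfDetection:
    def _track(self, m, orf=None, background=2, fold=10):
        counts = np.full(m.length, background)
        if orf is not None:
            counts[orf[0] : orf[1]] = background * fold
        return rq.DensityTrack(m.transcript_id, "footprint", counts)

    def test_no_start_codon_gives_empty_list(self):
        seq = "CCC" * 20 + "ATG" + "C" * 294 + "TAA" + "C" * 50
        m = TranscriptModel("T", 60, 300, 50, seq)
        out = rq.detect_uorf_candidates(self._track(m), m)
        assert out.empty

    def test_implanted_orf_detected_at_start(self):
        utr = "CCC" * 5 + "ATG" + "CCA" * 4 + "TAA" + "CC"
        assert len(utr) == 35
        seq = utr + "ATG" + "C" * 294 + "TAA" + "G" * 30
        m = TranscriptModel("T", 35, 300, 30, seq)
        track = self._track(m, orf=(15, 33), fold=5)
        out = rq.detect_uorf_candidates(track, m)
        assert len(out) >= 1
        assert out.loc[0, "start"] == 15
        assert out.loc[0, "codon"] == "ATG"
        assert out.loc[0, "stop"] == 30

    def test_single_codon_uorf_22nt_from_five_prime_end(self):
        """An AUG immediately followed by a stop is a valid 1-codon uORF."""
        utr = "C" * 22 + "ATG" + "TAA" + "C" * 32
        m = TranscriptModel("T", 60, 300, 30, utr + "ATG" + "C" * 294 + "TAA" + "G" * 30)
        track = self._track(m, orf=(22, 28), fold=6)
        out = rq.detect_uorf_candidates(track, m)
        hit = out[out["start"] == 22]
        assert len(hit) == 1
        assert hit["stop"].iloc[0] == 25  # one codon then stop

    def test_near_aug_variants_are_nine(self):
        assert len(rq.NEAR_AUG) == 9
        assert "GTG" in rq.NEAR_AUG and "CTG" in rq.NEAR_AUG and "AAG" in rq.NEAR_AUG

    def test_missing_sequence_errors(self):
        m = TranscriptModel("T", 50, 300, 30)
        with pytest.raises(ValueError, match="FASTA"):
            rq.detect_uorf_candidates(
                rq.DensityTrack("T", "footprint", np.ones(380)), m
            )


class TestClustering:
    def test_identical_profiles_cocluster(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(5, 6))
        profiles = np.vstack([base, base[0]])  # gene 5 duplicates gene 0
        genes = [f"g{i}" for i in range(6)]
        df = pd.DataFrame(profiles, index=genes, columns=LABELS)
        out = rq.cluster_genes(df, df, df, k=5)
        assert out.cluster_ids["g0"] == out.cluster_ids["g5"]

    def test_permutation_invariance(self, log2_tables):
        ml, fl, tl = log2_tables
        out1 = rq.cluster_genes(ml, fl, tl, k=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ml.index)
        out2 = rq.cluster_genes(ml.loc[perm], fl.loc[perm], tl.loc[perm], k=5)
        assert (out2.labels.loc[ml.index] == out1.labels).all()

    def test_archetype_naming(self, ledger, log2_tables):
        ml, fl, tl = log2_tables
        out = rq.cluster_genes(ml, fl, tl, k=5)
        truth = ledger.genes.set_index("gene")["archetype"]
        assert (out.labels == truth.loc[out.labels.index]).all()

    def test_fewer_genes_than_k_errors(self):
        df = pd.DataFrame(np.zeros((3, 6)), columns=LABELS)
        with pytest.raises(ValueError):
            rq.cluster_genes(df, df, df, k=5)


class TestTeShiftTest:
    def test_identical_distributions_p_near_one(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=40)
        df = pd.DataFrame({"t1p5": vals, "t12": vals})
        assert rq.te_shift_test(df, "t12", "t1p5") > 0.9

    def test_disjoint_supports_highly_significant(self):
        df = pd.DataFrame(
            {"t1p5": np.linspace(0, 1, 20), "t12": np.linspace(5, 6, 20)}
        )
        assert rq.te_shift_test(df, "t12", "t1p5") < 1e-4

    def test_shift_detected_in_simulation(self):
        """1-SD location shift at n=100: median p over 50 runs is < 0.01."""
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(50):
            a = rng.normal(0, 1, 100)
            b = rng.normal(1, 1, 100)
            ps.append(rq.te_shift_test(pd.DataFrame({"a": a, "b": b}), "b", "a"))
        assert np.median(ps) < 0.01

    def test_degenerate_all_tied_warns_p_one(self):
        df = pd.DataFrame({"a": np.zeros(5), "b": np.zeros(5)})
        with pytest.warns(UserWarning):
            assert rq.te_shift_test(df, "b", "a") == 1.0
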