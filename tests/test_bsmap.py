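import numpy as np
import pandas as pd
import pytest

from bsfoot.bsmap import (
    BaseCountMatrix,
    align_bisulfite_reads,
    conversion_profile,
    count_bases,
    filter_alignments,
    read_conversion_table,
)
from bsfoot.seqcore import NucleotideSequence
from bsfoot.synthetic import (
    ExposureModel,
    ReadSimConfig,
    inject_indel_reads,
    simulate_bisulfite_reads,
)

from _oracles import brute_align, revcomp
from conftest import random_seq


class TestAligner:
    def test_fully_converted_top_read_aligns_uniquely_at_origin(self, small_reference):
        ref, _ = small_reference
        read = ref.bases[100:160].replace("C", "T")
        (aln,) = align_bisulfite_reads([("r1", read)], ref)
        assert aln.ref_start == 101
        assert aln.mapped_strand == "top"
        assert not aln.reverse_complemented
        assert not aln.ambiguity_flag
        assert aln.n_mismatch == 0

    def test_reverse_complemented_read_aligns_at_same_locus(self, small_reference):
        ref, _ = small_reference
        read = ref.bases[100:160].replace("C", "T")
        (aln,) = align_bisulfite_reads([("r1", revcomp(read))], ref)
        assert aln.ref_start == 101
        assert aln.reverse_complemented
        assert aln.n_mismatch == 0

    def test_bottom_strand_read_maps_to_bottom_partition(self, small_reference):
        ref, _ = small_reference
        bottom = revcomp(ref.bases[100:160]).replace("C", "T")  # converted bottom read
        (aln,) = align_bisulfite_reads([("r1", bottom)], ref)
        assert aln.ref_start == 101
        assert aln.mapped_strand == "bottom"
        assert aln.reverse_complemented

    def test_unconverted_read_is_not_ambiguous_and_keeps_orientation_strand(
        self, small_reference
    ):
        ref, _ = small_reference
        fwd = ref.bases[50:110]
        (a,) = align_bisulfite_reads([("f", fwd)], ref)
        assert not a.ambiguity_flag and a.mapped_strand == "top"
        (b,) = align_bisulfite_reads([("r", revcomp(fwd))], ref)
        assert not b.ambiguity_flag and b.mapped_strand == "bottom"

    def test_read_longer_than_reference_raises(self):
        ref = NucleotideSequence("r", "ACGTACGTAC")
        with pytest.raises(ValueError):
            align_bisulfite_reads([("x", "A" * 11)], ref)

    def test_duplicated_locus_sets_ambiguity_flag(self, rng):
        block = random_seq(rng, 50, gc=0.5)
        ref = NucleotideSequence("dup", block + random_seq(rng, 40) + block)
        (aln,) = align_bisulfite_reads([("r", block[5:45])], ref)
        assert aln.ambiguity_flag

    def test_realignment_accuracy_on_simulated_reads(self, small_simulation):
        ref, model, reads, truth = small_simulation
        alignments = {a.read_id: a for a in align_bisulfite_reads(reads, ref)}
        tr = truth.reads.set_index("read_id")
        n_close = 0
        for rid, a in alignments.items():
            if abs(a.ref_start - tr.loc[rid, "origin_pos"]) <= 1:
                n_close += 1
        assert n_close / len(reads) >= 0.99

    def test_equals_brute_force_scan(self, rng):
        ref_s = random_seq(rng, 150, gc=0.5)
        ref = NucleotideSequence("small", ref_s)
        model = ExposureModel(boundary_pos=75, p_up=0.3, p_down=0.05, seq_error=0.02)
        reads, _ = simulate_bisulfite_reads(
            ref, model, ReadSimConfig(n_reads=40, read_length=40, seed=8)
        )
        reads += [("junk0", random_seq(rng, 40)), ("junk1", random_seq(rng, 40))]
        got = {a.read_id: a for a in align_bisulfite_reads(reads, ref)}
        max_mm = int(0.1 * 40)
        for rid, seq in reads:
            best, placements = brute_align(seq, ref_s)
            if best > max_mm:
                assert rid not in got
                continue
            a = got[rid]
            assert a.n_mismatch == best
            assert (a.ref_start - 1, a.reverse_complemented, a.mapped_strand) in placements
            assert a.ambiguity_flag == (len(placements) > 1)

    def test_gapped_mode_recovers_indel_reads_with_indel_ops(self, small_simulation):
        ref, model, reads, truth = small_simulation
        corrupted, ids = inject_indel_reads(reads[:60], fraction=0.5, seed=3)
        alignments = align_bisulfite_reads(corrupted, ref, gapped=True)
        by_id = {a.read_id: a for a in alignments}
        hit = [rid for rid in ids if rid in by_id and by_id[rid].has_indel]
        assert len(hit) >= 0.8 * len(ids)


class TestFilters:
    def test_ambiguous_and_indel_alignments_removed(self, small_simulation):
        ref, model, reads, truth = small_simulation
        corrupted, ids = inject_indel_reads(reads, fraction=0.05, seed=5)
        alignments = align_bisulfite_reads(corrupted, ref, gapped=True)
        kept = filter_alignments(alignments)
        assert all(not a.ambiguity_flag and not a.has_indel for a in kept)
        assert {a.read_id for a in kept}.isdisjoint(
            {a.read_id for a in alignments if a.has_indel}
        )

    def test_clean_alignments_pass_through_in_order(self, small_simulation):
        ref, model, reads, truth = small_simulation
        alignments = align_bisulfite_reads(reads[:100], ref)
        clean = [a for a in alignments if not a.ambiguity_flag]
        assert filter_alignments(clean) == clean


class TestCounting:
    def test_single_read_counts(self):
        ref = NucleotideSequence("r", "CCAAAAAAAA")
        (aln,) = align_bisulfite_reads([("x", "TTAAAAAAAA")], ref)
        counts = count_bases([aln], ref)
        t = counts.counts["top"]
        assert t[0, 3] == 1 and t[1, 3] == 1  # T at both C positions
        assert counts.counts["bottom"].sum() == 0

    def test_no_alignments_zero_matrix(self, small_reference):
        ref, _ = small_reference
        counts = count_bases([], ref)
        assert counts.counts["top"].sum() == 0 and counts.counts["bottom"].sum() == 0

    def test_counts_match_truth_table_exactly_on_error_free_data(self, small_simulation):
        ref, model, reads, truth = small_simulation
        kept = filter_alignments(align_bisulfite_reads(reads, ref))
        counts = count_bases(kept, ref)
        profile = conversion_profile(counts, ref, min_depth=1)
        merged = profile.table.merge(truth.per_position, on=["pos", "strand"])
        kept_ids = {a.read_id for a in kept}
        if len(kept_ids) == len(reads):  # all reads kept: exact equality
            assert (merged["n_converted"] == merged["converted"]).all()
            assert (merged["depth"] == merged["covered"]).all()

    def test_read_order_invariance(self, small_simulation):
        ref, model, reads, truth = small_simulation
        fwd = count_bases(filter_alignments(align_bisulfite_reads(reads, ref)), ref)
        rev = count_bases(filter_alignments(align_bisulfite_reads(reads[::-1], ref)), ref)
        for s in ("top", "bottom"):
            np.testing.assert_array_equal(fwd.counts[s], rev.counts[s])


class TestConversionProfile:
    def _matrix(self, ref, top=None, bottom=None):
        L = len(ref)
        counts = {s: np.zeros((L, 4), dtype=np.int64) for s in ("top", "bottom")}
        for strand, spec in (("top", top), ("bottom", bottom)):
            for pos, row in (spec or {}).items():
                counts[strand][pos - 1] = row
        return BaseCountMatrix(ref.id, counts)

    def test_formula_arithmetic(self):
        ref = NucleotideSequence("r", "CGGA")
        m = self._matrix(
            ref,
            top={1: [0, 80, 0, 20]},          # C=80 T=20 -> 20%
            bottom={2: [5, 0, 95, 0]},        # A=5 G=95 -> 5%
        )
        prof = conversion_profile(m, ref, min_depth=1).table.set_index(["pos", "strand"])
        assert prof.loc[(1, "top"), "rate_pct"] == pytest.approx(20.0)
        assert prof.loc[(2, "bottom"), "rate_pct"] == pytest.approx(5.0)

    def test_zero_depth_is_na_not_zero(self):
        ref = NucleotideSequence("r", "CAGT")
        prof = conversion_profile(self._matrix(ref), ref, min_depth=1).table
        assert prof["rate_pct"].isna().all()
        assert (prof["depth"] == 0).all()

    def test_rows_only_at_c_and_g_reference_positions(self, small_simulation):
        ref, model, reads, truth = small_simulation
        counts = count_bases(filter_alignments(align_bisulfite_reads(reads, ref)), ref)
        prof = conversion_profile(counts, ref).table
        for _, row in prof.iterrows():
            base = ref.bases[row["pos"] - 1]
            assert base == ("C" if row["strand"] == "top" else "G")

    def test_rates_bounded_and_min_depth_na(self, rng):
        ref = NucleotideSequence("r", random_seq(rng, 30, gc=0.5))
        counts = {
            s: rng.integers(0, 20, size=(30, 4)).astype(np.int64) for s in ("top", "bottom")
        }
        prof = conversion_profile(BaseCountMatrix("r", counts), ref, min_depth=10).table
        valid = prof["rate_pct"].dropna()
        assert ((valid >= 0) & (valid <= 100)).all()
        assert prof.loc[prof["depth"] < 10, "rate_pct"].isna().all()

    def test_fuzz_formula_fidelity_1000_matrices(self, rng):
        """top rate = T/(C+T)*100 at C positions; bottom = A/(G+A)*100 at G."""
        ref = NucleotideSequence("r", random_seq(rng, 25, gc=0.5))
        codes = np.frombuffer(ref.bases.encode(), dtype=np.uint8)
        c_pos = np.where(codes == ord("C"))[0]
        g_pos = np.where(codes == ord("G"))[0]
        for _ in range(1000):
            counts = {
                s: rng.integers(0, 50, size=(25, 4)).astype(np.int64)
                for s in ("top", "bottom")
            }
            prof = conversion_profile(BaseCountMatrix("r", counts), ref, min_depth=1).table
            top = prof[prof["strand"] == "top"].set_index("pos")
            bot = prof[prof["strand"] == "bottom"].set_index("pos")
            for p in c_pos:
                c, t = counts["top"][p, 1], counts["top"][p, 3]
                expect = 100.0 * t / (c + t) if c + t > 0 else None
                got = top.loc[p + 1, "rate_pct"]
                assert (expect is None and np.isnan(got)) or got == expect
            for p in g_pos:
                g, a = counts["bottom"][p, 2], counts["bottom"][p, 0]
                expect = 100.0 * a / (g + a) if g + a > 0 else None
                got = bot.loc[p + 1, "rate_pct"]
                assert (expect is None and np.isnan(got)) or got == expect


class TestConversionTableReader:
    def test_roundtrip_and_column_mapping(self, tmp_path, small_simulation):
        ref, model, reads, truth = small_simulation
        counts = count_bases(filter_alignments(align_bisulfite_reads(reads, ref)), ref)
        prof = conversion_profile(counts, ref, min_depth=1)
        p = tmp_path / "profile.tsv"
        p.write_text(prof.to_tsv())
        back = read_conversion_table(p, min_depth=1)
        a = prof.table.reset_index(drop=True)
        b = back.table.reset_index(drop=True)
        pd.testing.assert_series_equal(a["depth"], b["depth"])
        np.testing.assert_allclose(a["rate_pct"], b["rate_pct"], rtol=1e-4)

        # external headers through a column map
        q = tmp_path / "external.tsv"
        df = prof.table.rename(
            columns={"pos": "Position", "strand": "Strand", "rate_pct": "CT_pct", "depth": "Depth"}
        )
        df[["Position", "Strand", "CT_pct", "Depth"]].to_csv(q, sep="\t", index=False)
        ext = read_conversion_table(
            q,
            column_map={"pos": "Position", "strand": "Strand",
                        "rate_pct": "CT_pct", "depth": "Depth"},
            min_depth=1,
        )
        pd.testing.assert_series_equal(ext.table["depth"], b["depth"])

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("pos\tstrand\trate_pct\n1\ttop\t5.0\n")
        with pytest.raises(ValueError, match="depth"):
            read_conversion_table(p)
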