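"""Read-processing contracts: demultiplex, trim, assign, extract, count."""

import numpy as np
import pytest

import treclineage as tl
from treclineage.germline import GermlineReference, GermlineSegment, InvalidConfiguration
from treclineage.processing import (
    DEFAULT_SCORING,
    demultiplex,
    make_aligner,
    subsample_table,
    pool_tables,
    build_clonotype_table,
    trim_race_ends,
)
from treclineage.synthetic import ReadRecord

from oracles import fit_score, translate_standard


def _reads(tables, reference, bm, **kw):
    return list(tl.emit_reads(tables, reference, bm, **kw))


class TestDemultiplex:
    def test_error_free_reads_all_assigned_to_true_sample(self, reference, small_cohort):
        _, tables = small_cohort
        sub = {k: tables[k] for k in list(tables)[:4]}
        bm = dict(zip(sub, tl.design_barcodes(4, seed=6)))
        reads = _reads(sub, reference, bm, depth_per_clonotype_cell=0.05,
                       error_rate=0.0, seed=6)
        result = demultiplex(reads, bm, max_mismatch=1)
        assert not result.undetermined
        for sample, assigned in result.by_sample.items():
            assert all(r.true_sample == sample for r in assigned)
        assert sum(len(v) for v in result.by_sample.values()) == len(reads)

    def test_two_mismatch_prefix_routed_to_undetermined(self):
        bm = {"s1": "AAAAAAAA", "s2": "AAAATTTT"}
        read = ReadRecord("r1", "AAAAAACCGGGG", "I" * 12)
        result = demultiplex([read], bm, max_mismatch=1)
        assert result.by_sample["s1"] == [] and result.by_sample["s2"] == []
        assert len(result.undetermined) == 1

    def test_one_mismatch_assigned_and_barcode_trimmed(self):
        bm = {"s1": "AAAAAAAA", "s2": "AAAATTTT"}
        read = ReadRecord("r1", "AAAAAAACGGGG", "I" * 12)
        result = demultiplex([read], bm, max_mismatch=1)
        assert [r.sequence for r in result.by_sample["s1"]] == ["GGGG"]

    def test_max_mismatch_must_stay_below_half_barcode_distance(self):
        bm = {"s1": "AAAAAAAA", "s2": "AAAATTTT"}  # distance 4
        with pytest.raises(InvalidConfiguration):
            demultiplex([], bm, max_mismatch=2)

    def test_unassigned_rate_matches_binomial_tail(self, reference):
        # P(>=2 errors in an 8 nt barcode) = 1 - (1-p)^8 - 8 p (1-p)^7
        model = tl.SharingModel(patients=1, clone_pool_size=100,
                                cells_per_compartment=1200, seed=8)
        tables = tl.simulate_cohort(model, reference)
        bm = dict(zip(tables, tl.design_barcodes(len(tables), length=8, seed=8)))
        p = 0.01
        reads = _reads(tables, reference, bm, depth_per_clonotype_cell=1.0,
                       error_rate=p, seed=8)
        assert len(reads) >= 10_000
        result = demultiplex(reads, bm, max_mismatch=1)
        expected = 1 - (1 - p) ** 8 - 8 * p * (1 - p) ** 7
        observed = len(result.undetermined) / len(reads)
        se = np.sqrt(expected * (1 - expected) / len(reads))
        assert abs(observed - expected) < 3 * se
        misassigned = sum(
            r.true_sample != sample
            for sample, rs in result.by_sample.items()
            for r in rs
        )
        assert misassigned == 0


class TestTrim:
    def test_error_free_trim_recovers_amplicon_body(self, reference, small_cohort):
        _, tables = small_cohort
        sub = {"P1_TI_naive": tables["P1_TI_naive"]}
        bm = {"P1_TI_naive": "ACGTACGT"}
        for read in _reads(sub, reference, bm, depth_per_clonotype_cell=0.05,
                           error_rate=0.0, seed=9):
            v_name, j_name, junction = read.true_clonotype.split("|")
            v, j = reference.v_by_name(v_name), reference.j_by_name(j_name)
            trimmed = trim_race_ends(read.sequence[8:], reference)
            assert trimmed.status == "ok"
            expected = (v.sequence[: v.anchor_offset] + junction
                        + j.sequence[j.anchor_offset + 3:])
            assert trimmed.sequence == expected

    def test_missing_primer_site_flagged_but_sequence_retained(self, reference):
        body = "ACGT" * 20
        seq = reference.adapter + body
        trimmed = trim_race_ends(seq, reference)
        assert trimmed.status == "no_c_primer"
        assert trimmed.sequence == body

    def test_primer_found_with_one_substitution(self, reference):
        site = reference.c_primer_sites[-1]
        mutated = ("G" if site[5] != "G" else "C").join([site[:5], site[6:]])
        seq = reference.adapter + "ACGT" * 15 + mutated + "AAAA"
        trimmed = trim_race_ends(seq, reference)
        assert trimmed.status == "ok"
        assert trimmed.sequence == "ACGT" * 15

    def test_too_short_read_filtered(self, reference):
        trimmed = trim_race_ends("ACGTACGT", reference)
        assert trimmed.status == "too_short"


class TestAssignVJ:
    def test_error_free_reads_recover_planted_calls(self, reference, small_cohort):
        _, tables = small_cohort
        sub = {"P2_TI_Treg": tables["P2_TI_Treg"]}
        bm = {"P2_TI_Treg": "ACGTACGT"}
        for read in _reads(sub, reference, bm, depth_per_clonotype_cell=0.03,
                           error_rate=0.0, seed=10):
            v_name, j_name, _ = read.true_clonotype.split("|")
            trimmed = trim_race_ends(read.sequence[8:], reference)
            res = tl.assign_vj(trimmed.sequence, reference)
            assert res.passed
            assert (res.v_call, res.j_call) == (v_name, j_name)

    def test_single_substitution_scores_match_minus_one_mismatch(self, reference):
        v = reference.v_segments[2]
        seq = list(v.sequence)
        seq[10] = "A" if seq[10] != "A" else "C"
        res = tl.assign_vj("".join(seq), reference)
        assert res.v_call == v.name
        assert res.v_score == 2 * (len(v.sequence) - 1) - 3

    def test_identical_segments_under_two_names_fail_as_tie(self):
        seq_v = "ACGT" * 12 + "TGT"
        vs = (GermlineSegment("TRBV1-1", "V", seq_v, len(seq_v) - 3),
              GermlineSegment("TRBV2-1", "V", seq_v, len(seq_v) - 3))
        seq_j = "TTTGGCATAGGC" + "ACGTACGTACGT"
        js = (GermlineSegment("TRBJ1-1", "J", seq_j, 0),
              GermlineSegment("TRBJ2-1", "J", "AGT" + seq_j, 3))
        ref = GermlineReference(vs, js)
        res = tl.assign_vj(seq_v + "GGG" + seq_j, ref)
        assert res.v_score == res.v_second_score
        assert not res.passed

    def test_agrees_with_exhaustive_dp_scorer_on_random_reads(self, reference):
        rng = np.random.default_rng(17)
        bases = "ACGT"
        aligner = make_aligner(DEFAULT_SCORING)
        segments = reference.v_segments + reference.j_segments
        for _ in range(100):
            n = int(rng.integers(30, 120))
            read = "".join(bases[b] for b in rng.integers(0, 4, n))
            if rng.random() < 0.5:  # embed a mutated segment
                seg = segments[rng.integers(len(segments))]
                s = list(seg.sequence)
                for _ in range(int(rng.integers(0, 5))):
                    s[rng.integers(len(s))] = bases[rng.integers(4)]
                pos = int(rng.integers(0, n))
                read = read[:pos] + "".join(s) + read[pos:]
            for seg in segments:
                assert float(aligner.score(read, seg.sequence)) == fit_score(
                    read, seg.sequence
                )


class TestExtractJunction:
    @pytest.fixture()
    def crafted_reference(self):
        # V ends on the Cys codon; the J prefix up to and including the
        # FGXG Phe codon (offset 12) is TTCGGGCAAGGGTTC, so with the 9 nt
        # insert GCCAGCAGC the planted junction is exactly
        # TGT GCC AGC AGC TTC GGG CAA GGG TTC -> CASSFGQGF
        v_seq = "GATCGGAAGCTTGACCTGGACCAGTACCTT" + "TGT"
        j_seq = "TTCGGGCAAGGG" + "TTCGGTACAGGA" + "CTGACCGTTGGC"
        v = GermlineSegment("TRBV12-4", "V", v_seq, len(v_seq) - 3)
        v2 = GermlineSegment("TRBV9-1", "V", "TACGGATTCAGGTACCGAGTCCAAGCTAGC" + "TGC", 30)
        j = GermlineSegment("TRBJ1-2", "J", j_seq, 12)
        j2 = GermlineSegment("TRBJ2-2", "J", "AGGTCCAAGATA" + "TTTGGACTAGGC" + "ATCGGATCCAAG", 12)
        return GermlineReference((v, v2), (j, j2))

    def test_planted_junction_recovered_and_translated(self, crafted_reference):
        ref = crafted_reference
        v, j = ref.v_segments[0], ref.j_segments[0]
        read = v.sequence + "GCCAGCAGC" + j.sequence
        res = tl.assign_vj(read, ref)
        assert res.passed and res.v_call == "TRBV12-4" and res.j_call == "TRBJ1-2"
        jr = tl.extract_junction(read, res, ref)
        assert jr.status == "ok"
        assert jr.junction == "TGTGCCAGCAGCTTCGGGCAAGGGTTC"
        assert jr.junction_aa == "CASSFGQGF"
        assert jr.junction_aa == translate_standard(jr.junction)
        assert jr.productive

    def test_out_of_frame_junction_unproductive_but_retained(self, crafted_reference):
        ref = crafted_reference
        v, j = ref.v_segments[0], ref.j_segments[0]
        read = v.sequence + "GCCAGCAGCCA" + j.sequence  # 29 nt junction
        res = tl.assign_vj(read, ref)
        jr = tl.extract_junction(read, res, ref)
        assert jr.status == "ok"
        assert len(jr.junction) % 3 != 0
        assert not jr.productive
        assert jr.junction_aa == ""

    def test_alignment_ending_before_anchor_filtered(self, crafted_reference):
        ref = crafted_reference
        v, j = ref.v_segments[0], ref.j_segments[0]
        # V anchor region cut out of the read; the bases that follow all
        # mismatch the lost V tail, so the optimum pays the segment end gap
        # and the anchor codon maps to nothing
        read = v.sequence[:-4] + "ACAC" + j.sequence
        res = tl.assign_vj(read, ref)
        assert res.passed
        jr = tl.extract_junction(read, res, ref)
        assert jr.status == "anchor_missing"


class TestTables:
    def test_grouping_and_min_count(self):
        cl = [tl.Clonotype("V1", "J1", "TGTTTT", "CF", False, 1) for _ in range(3)]
        cl += [tl.Clonotype("V2", "J1", "TGTTTC", "CF", False, 1)]
        t1 = build_clonotype_table(cl, "s", min_count=1)
        assert t1.counts().to_dict() == {("V1", "J1", "TGTTTT"): 3,
                                         ("V2", "J1", "TGTTTC"): 1}
        assert t1.total_count == 4
        t2 = build_clonotype_table(cl, "s", min_count=2)
        assert t2.counts().to_dict() == {("V1", "J1", "TGTTTT"): 3}
        assert t2.total_count == 3

    def test_zero_surviving_clonotypes_returns_flagged_empty_table(self):
        t = build_clonotype_table([], "s")
        assert len(t) == 0 and t.meta.get("empty_table")

    def test_airr_round_trip(self, small_cohort, tmp_path):
        _, tables = small_cohort
        t = tables["P1_LN_Treg"]
        path = tmp_path / "t.airr.tsv"
        t.to_airr_tsv(path)
        back = tl.ClonotypeTable.from_airr_tsv(path)
        assert back.keys() == t.keys()
        assert back.total_count == t.total_count
        assert (back.patient, back.site, back.subset) == ("P1", "LN", "Treg")


class TestSubsample:
    def test_identity_at_full_depth(self, table_pair):
        a, _ = table_pair
        assert subsample_table(a, a.total_count) is a

    def test_single_clone(self):
        t = tl.ClonotypeTable.from_clonotypes(
            [tl.Clonotype("V1", "J1", "TGTTTT", "CF", False, 10)], "s")
        sub = subsample_table(t, 4, seed=0)
        assert sub.counts().to_dict() == {("V1", "J1", "TGTTTT"): 4}

    def test_depth_above_total_rejected(self, table_pair):
        a, _ = table_pair
        with pytest.raises(ValueError):
            subsample_table(a, a.total_count + 1)

    def test_hypergeometric_mean(self):
        t = tl.ClonotypeTable.from_clonotypes(
            [tl.Clonotype("V1", "J1", "TGTTTT", "CF", False, 50),
             tl.Clonotype("V2", "J1", "TGTTTC", "CF", False, 50)], "s")
        n_rep = 10_000
        draws = np.array([
            subsample_table(t, 10, seed=s).counts().get(("V1", "J1", "TGTTTT"), 0)
            for s in range(n_rep)
        ])
        # mean 5, variance n*K/N*(1-K/N)*(N-n)/(N-1) = 10*.25*90/99
        se = np.sqrt(10 * 0.25 * 90 / 99 / n_rep)
        assert abs(draws.mean() - 5.0) < 4 * se


class TestPool:
    def test_empty_table_is_identity_element(self, table_pair):
        a, _ = table_pair
        empty = tl.ClonotypeTable(a.sample_id, a.df.iloc[0:0].copy())
        pooled = pool_tables([a, empty], force=True)
        assert pooled.counts().to_dict() == a.counts().to_dict()

    def test_counts_add_over_union_of_keys(self, table_pair):
        a, b = table_pair
        pooled = pool_tables([a, b], force=True)
        expected = a.counts().add(b.counts(), fill_value=0)
        assert pooled.counts().to_dict() == expected.to_dict()
        assert pooled.total_count == a.total_count + b.total_count

    def test_pooling_compartment_across_patients_conserves_totals(self, small_cohort):
        _, tables = small_cohort
        group = [t for t in tables.values() if (t.site, t.subset) == ("TI", "Treg")]
        pooled = pool_tables(group)
        assert pooled.total_count == sum(t.total_count for t in group)

    def test_mixed_compartments_require_force(self, small_cohort):
        _, tables = small_cohort
        with pytest.raises(ValueError):
            pool_tables([tables["P1_TI_Treg"], tables["P1_PB_naive"]])


class TestConservation:
    def test_read_accounting_is_exact(self, reference, tmp_path):
        model = tl.SharingModel(patients=1, clone_pool_size=60,
                                cells_per_compartment=600, seed=21)
        tables = tl.simulate_cohort(model, reference)
        bm = dict(zip(tables, tl.design_barcodes(len(tables), seed=21)))
        path = tmp_path / "r.fastq"
        n = tl.write_fastq(
            tl.emit_reads(tables, reference, bm, error_rate=0.02, seed=21), path)
        out, report = tl.process_run(path, bm, reference)
        assert report["reads_in"] == n
        assert report["assigned"] + report["undetermined"] == n
        for sample, rec in report["samples"].items():
            tallies = rec["tallies"]
            assert (tallies.get("trim_too_short", 0) + tallies.get("assignment_failed", 0)
                    + tallies.get("anchor_missing", 0) + tallies.get("min_count_dropped", 0)
                    + out[sample].total_count) == rec["reads"]

    def test_noisy_round_trip_recovers_well_covered_clonotypes(self, reference, tmp_path):
        # per-base error 0.005: >= 95% of ground-truth keys with >= 5 reads recovered
        model = tl.SharingModel(patients=1, clone_pool_size=200,
                                cells_per_compartment=2000, seed=22)
        tables = tl.simulate_cohort(model, reference)
        bm = dict(zip(tables, tl.design_barcodes(len(tables), seed=22)))
        path = tmp_path / "r.fastq"
        tl.write_fastq(
            tl.emit_reads(tables, reference, bm, error_rate=0.005, seed=22), path)
        out, _ = tl.process_run(path, bm, reference)
        covered = recovered = 0
        for sample, truth in tables.items():
            well = set(map(tuple, truth.df.loc[truth.df["duplicate_count"] >= 5,
                                               ["v_call", "j_call", "junction"]]
                           .itertuples(index=False)))
            covered += len(well)
            recovered += len(well & out[sample].keys())
        assert recovered / covered >= 0.95
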