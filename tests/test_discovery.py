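"""K-mer search and locus assembly against planted truth."""

import io

import pytest

from ervscape import (
    AlignmentRecord,
    InsertionPlan,
    SearchParams,
    assemble_loci,
    kmer_search,
    plant_loci,
    read_psl,
    write_psl,
)

SENSITIVE = SearchParams(min_identity=0.90, min_len=100)


def _record(match, mismatch=0, q_gap=0, t_start=1000, q_start=0, q_name="cons",
            t_name="chr1", strand="+", t_gap=0):
    length = match + mismatch
    return AlignmentRecord(
        q_name=q_name, t_name=t_name, strand=strand,
        match=match, mismatch=mismatch,
        q_gap_count=1 if q_gap else 0, q_gap_bases=q_gap,
        t_gap_count=1 if t_gap else 0, t_gap_bases=t_gap,
        q_size=10485, q_start=q_start, q_end=q_start + length,
        t_size=500000, t_start=t_start, t_end=t_start + length + t_gap,
        blocks=((q_start, t_start, length),),
    )


class TestKmerSearch:
    def test_exact_copy_found_with_full_coverage(self, reference, tmp_path):
        plan = InsertionPlan(chrom="chr1", position=20_000, divergence=0.0)
        bundle = plant_loci(reference, [plan], {"chr1": 60_000}, seed=5,
                            out_dir=tmp_path, gene_density=0)
        records = kmer_search(bundle.chromosomes, reference)
        assert len(records) == 1
        rec = records[0]
        assert rec.mismatch == 0
        assert rec.match == len(reference)
        assert (rec.t_start + 1, rec.t_end) == (20_000, 20_000 + 10484)

    def test_diverged_copy_overlaps_truth(self, reference, tmp_path):
        plan = InsertionPlan(chrom="chr1", position=20_000, divergence=0.05)
        bundle = plant_loci(reference, [plan], {"chr1": 60_000}, seed=6,
                            out_dir=tmp_path, gene_density=0)
        records = kmer_search(bundle.chromosomes, reference, SENSITIVE)
        assert len(records) == 1
        row = bundle.truth[0]
        rec = records[0]
        overlap = min(rec.t_end, row["end"]) - max(rec.t_start + 1, row["start"]) + 1
        assert overlap / (row["end"] - row["start"] + 1) >= 0.95

    def test_empty_genome(self, reference):
        assert kmer_search({}, reference) == []

    def test_oversized_k_rejected(self):
        with pytest.raises(ValueError, match="seed width"):
            SearchParams(k=33)

    @pytest.mark.parametrize("seed", range(10))
    def test_no_hits_in_random_genome(self, reference, seed):
        import numpy as np

        rng = np.random.default_rng(1000 + seed)
        genome = {"chrR": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100_000)])}
        assert kmer_search(genome, reference) == []

    def test_minus_strand_copy_found(self, reference, tmp_path):
        plan = InsertionPlan(chrom="chr1", position=20_000, strand="-", divergence=0.02)
        bundle = plant_loci(reference, [plan], {"chr1": 60_000}, seed=7,
                            out_dir=tmp_path, gene_density=0)
        records = kmer_search(bundle.chromosomes, reference, SENSITIVE)
        assert len(records) == 1
        assert records[0].strand == "-"


class TestAssembleLoci:
    def test_coverage_fraction_printed_convention(self, reference):
        # 8881 aligned bases over the 10485-bp consensus -> 84.70%
        loci = assemble_loci([_record(match=8881)], reference)
        assert f"{loci[0].coverage_fraction * 100:.2f}%" == "84.70%"
        assert loci[0].range_bin == "[80%-90%)"

    def test_qgap_threshold_sets_deletion_flag(self, reference):
        # q_gap fraction 0.12 with no target insert -> Deletion
        rec = _record(match=880, q_gap=120)
        locus = assemble_loci([rec], reference)[0]
        assert locus.q_gap_fraction == pytest.approx(0.12)
        assert locus.indel_flags == frozenset({"Deletion"})

    def test_kb_scale_extra_genomic_sequence_sets_insertion_flag(self, reference):
        rec = _record(match=3000, t_gap=1500)
        locus = assemble_loci([rec], reference)[0]
        assert locus.insertion_bases >= 1000
        assert "Insertion" in locus.indel_flags

    def test_collinear_records_within_merge_gap_merge(self, reference):
        first = _record(match=2000, t_start=1000, q_start=0)
        second = _record(match=2000, t_start=3100, q_start=2100)  # 100 bp apart
        loci = assemble_loci([first, second], reference, merge_gap=1000)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (1001, 5100)
        assert loci[0].coverage_fraction == pytest.approx(4000 / 10485)

    def test_distant_records_stay_separate(self, reference):
        first = _record(match=2000, t_start=1000, q_start=0)
        second = _record(match=2000, t_start=10_000, q_start=2100)
        assert len(assemble_loci([first, second], reference, merge_gap=1000)) == 2

    def test_mixed_references_rejected(self, reference):
        records = [_record(match=100), _record(match=100, q_name="other")]
        with pytest.raises(ValueError, match="multiple references"):
            assemble_loci(records, reference)

    def test_coverage_monotone_under_compatible_record(self, reference):
        first = _record(match=2000, t_start=1000, q_start=0)
        second = _record(match=1000, t_start=3100, q_start=2100)
        single = assemble_loci([first], reference)[0]
        merged = assemble_loci([first, second], reference, merge_gap=1000)[0]
        assert merged.coverage_fraction >= single.coverage_fraction
        assert merged.coverage_fraction <= 1.0

    def test_skipped_consensus_between_records_counts_as_qgap(self, reference):
        first = _record(match=2000, t_start=1000, q_start=0)
        second = _record(match=2000, t_start=3100, q_start=3000)  # skips q 2000-3000
        locus = assemble_loci([first, second], reference, merge_gap=1000)[0]
        assert locus.q_gap_bases == 1000
        assert locus.q_gap_fraction == pytest.approx(1000 / 5000)


class TestRecallOnSyntheticBundle:
    def test_all_planted_loci_recovered_no_false_calls(self, reference, tmp_path):
        divergences = [0.0, 0.02, 0.04, 0.06, 0.08]
        plans, lengths = [], {}
        for i, d in enumerate(divergences):
            chrom = f"chr{i + 1}"
            lengths[chrom] = 40_000
            plans.append(
                InsertionPlan(chrom=chrom, position=12_000,
                              kept_intervals=((1422, 7032),), divergence=d,
                              name=f"p{i}")
            )
        bundle = plant_loci(reference, plans, lengths, seed=13, out_dir=tmp_path,
                            gene_density=0)
        loci = assemble_loci(
            kmer_search(bundle.chromosomes, reference, SENSITIVE), reference
        )
        truth = {row["chrom"]: (row["start"], row["end"]) for row in bundle.truth}
        assert len(loci) == len(plans)
        for locus in loci:
            start, end = truth[locus.chrom]
            assert abs(locus.start - start) <= 25 and abs(locus.end - end) <= 25


class TestPslInterop:
    def test_search_records_survive_psl_roundtrip(self, reference, tmp_path):
        plan = InsertionPlan(chrom="chr1", position=20_000, strand="-", divergence=0.03)
        bundle = plant_loci(reference, [plan], {"chr1": 60_000}, seed=9,
                            out_dir=tmp_path, gene_density=0)
        records = kmer_search(bundle.chromosomes, reference, SENSITIVE)
        buf = io.StringIO()
        write_psl(records, buf)
        buf.seek(0)
        assert read_psl(buf) == records
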