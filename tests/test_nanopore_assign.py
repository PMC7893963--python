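import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import edlib
from oracles import seed_oracle, sw_oracle

from nucleolong import (
    AlignedLongRead,
    AlignmentScoreScheme,
    GuideRecord,
    assign_all,
    assign_read,
    build_bin_index,
    consensus_per_molecule,
    filter_long_reads,
    revcomp,
    seed_scan,
    smith_waterman,
)
from nucleolong.nanopore_assign import (
    STATUS_AMBIGUOUS,
    STATUS_ASSIGNED,
    STATUS_NO_CANDIDATE,
    STATUS_OVER_THRESHOLD,
)

RNG = np.random.default_rng(2024)


def rand_seq(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), size=n))


def make_read(flank5="", flank3="", blocks=((1000, 1400),), read_id="r1", strand="+", **kw):
    body = rand_seq(sum(e - s for s, e in blocks))
    return AlignedLongRead(
        read_id=read_id,
        chrom="chr1",
        strand=strand,
        blocks=tuple(blocks),
        clip5=len(flank5),
        clip3=len(flank3),
        seq=flank5 + body + flank3,
        **kw,
    )


def mutate(seq, n_subs, rng=RNG):
    seq = list(seq)
    pos = rng.choice(np.arange(1, len(seq) - 1), size=n_subs, replace=False)
    for p in pos:
        seq[p] = "ACGT".replace(seq[p], "")[rng.integers(0, 3)]
    return "".join(seq)


class TestFilter:
    def test_chimera_boundary_is_strict(self):
        kept, dropped = filter_long_reads(
            [make_read(flank5=rand_seq(150))], structural_allowance=0
        )
        assert len(kept) == 1
        kept, dropped = filter_long_reads(
            [make_read(flank5=rand_seq(151))], structural_allowance=0
        )
        assert kept == [] and dropped[0][1] == "chimeric"

    def test_non_barcode_end_gets_no_allowance(self):
        # larger flank gets the structural allowance, the smaller does not
        r = make_read(flank5=rand_seq(190), flank3=rand_seq(160))
        kept, dropped = filter_long_reads([r], structural_allowance=56)
        assert kept == [] and dropped[0][1] == "chimeric"
        r = make_read(flank5=rand_seq(190), flank3=rand_seq(150))
        kept, _ = filter_long_reads([r], structural_allowance=56)
        assert len(kept) == 1

    def test_supplementary_record_drops_the_read(self):
        primary = make_read(read_id="rA")
        supp = make_read(read_id="rA", is_supplementary=True)
        kept, dropped = filter_long_reads([primary, supp])
        assert kept == [] and dropped[0][1] == "multimapped"

    def test_reasons_attached_to_every_drop(self):
        reads = [
            make_read(read_id="ok"),
            make_read(read_id="chim", flank5=rand_seq(400)),
        ]
        kept, dropped = filter_long_reads(reads)
        assert [r.read_id for r in kept] == ["ok"]
        assert all(reason in {"chimeric", "multimapped"} for _, reason in dropped)


class TestSeedScan:
    def test_verbatim_query_yields_full_seed_ladder(self):
        query = rand_seq(26)
        flank = rand_seq(20) + query + rand_seq(20)
        assert len(seed_scan(flank, query)) >= len(query) - 6

    def test_disjoint_alphabet_regions_yield_no_seeds(self):
        assert seed_scan("A" * 40, "C" * 26) == []

    @settings(max_examples=100, derandomize=True)
    @given(
        flank=st.text(alphabet="ACGT", min_size=7, max_size=60),
        query=st.text(alphabet="ACGT", min_size=7, max_size=26),
    )
    def test_matches_brute_force_table_join(self, flank, query):
        assert seed_scan(flank, query) == seed_oracle(flank, query)


class TestSmithWaterman:
    def test_identity_scores_length(self):
        score, _, bc, umi = smith_waterman("ACGTACGTACGTACGT", "ACGTACGTACGTACGT")
        assert (score, bc + umi) == (16, 0)

    def test_single_interior_substitution(self):
        a = "ACGTACGTACGTACGT"
        b = a[:8] + ("A" if a[8] != "A" else "C") + a[9:]
        score, _, bc, umi = smith_waterman(a, b)
        assert (score, bc + umi) == (14, 1)

    def test_terminal_mismatch_counts_as_unaligned_base(self):
        a = "ACGTACGTACGTACGA"
        b = "ACGTACGTACGTACGT"
        score, _, bc, umi = smith_waterman(a, b)
        assert (score, bc + umi) == (15, 1)

    def test_truncated_query_counts_missing_bases(self):
        # only the first 20 nt of the query are present in the target
        b = rand_seq(26)
        a = rand_seq(15) + b[:20]
        score, _, bc, umi = smith_waterman(a, b, boundary=16)
        assert score == 20
        assert (bc, umi) == (0, 6)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("", "ACGT")

    def test_matches_full_matrix_oracle_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            a = rand_seq(int(rng.integers(5, 31)), rng)
            b = rand_seq(int(rng.integers(5, 31)), rng)
            boundary = int(rng.integers(0, len(b) + 1))
            score, _, bc, umi = smith_waterman(a, b, boundary=boundary)
            o_score, o_bc, o_umi = sw_oracle(a, b, boundary=boundary)
            assert (score, bc, umi) == (o_score, o_bc, o_umi), (a, b, boundary)


class TestAssignRead:
    def guide(self, bc, umi, pos=1100):
        return GuideRecord(bc, umi, "g1", "chr1", pos)

    def read_with(self, flank_payload):
        flank = rand_seq(30) + flank_payload + "T" * 20
        return make_read(flank5=flank)

    def test_exact_match_assigns_with_zero_errors(self):
        bc, umi = rand_seq(16), rand_seq(10)
        idx = build_bin_index([self.guide(bc, umi)])
        asn = assign_read(self.read_with(bc + umi), idx)
        assert (asn.status, asn.barcode, asn.umi) == (STATUS_ASSIGNED, bc, umi)
        assert (asn.barcode_errors, asn.umi_errors) == (0, 0)

    def test_barcode_with_four_errors_is_over_threshold(self):
        bc, umi = rand_seq(16), rand_seq(10)
        payload = mutate(bc, 4) + umi
        idx = build_bin_index([self.guide(bc, umi)])
        asn = assign_read(self.read_with(payload), idx)
        assert asn.status == STATUS_OVER_THRESHOLD
        assert asn.barcode_errors >= 4

    def test_three_errors_still_assigned(self):
        bc, umi = rand_seq(16), rand_seq(10)
        payload = mutate(bc, 3) + umi
        idx = build_bin_index([self.guide(bc, umi)])
        asn = assign_read(self.read_with(payload), idx)
        assert asn.status == STATUS_ASSIGNED
        assert asn.barcode_errors == 3

    def test_tie_between_distinct_pairs_is_ambiguous(self):
        umi = rand_seq(10)
        bc1 = "A" + "C" * 14 + "A"
        bc2 = "G" + "C" * 14 + "G"
        hybrid = "A" + "C" * 14 + "G"  # one substitution from each barcode
        idx = build_bin_index([self.guide(bc1, umi), self.guide(bc2, umi)])
        asn = assign_read(self.read_with(hybrid + umi), idx)
        assert asn.status == STATUS_AMBIGUOUS
        assert asn.n_best_candidates == 2

    def test_same_pair_in_many_bins_is_not_ambiguous(self):
        bc, umi = rand_seq(16), rand_seq(10)
        idx = build_bin_index([self.guide(bc, umi, pos=1100), self.guide(bc, umi, pos=1300)])
        asn = assign_read(self.read_with(bc + umi), idx)
        assert asn.status == STATUS_ASSIGNED

    def test_no_candidates_in_bins(self):
        idx = build_bin_index([self.guide(rand_seq(16), rand_seq(10), pos=900_000)])
        asn = assign_read(self.read_with(rand_seq(26)), idx)
        assert asn.status == STATUS_NO_CANDIDATE

    def test_barcode_found_on_reverse_complement_flank(self):
        bc, umi = rand_seq(16), rand_seq(10)
        flank = revcomp(rand_seq(30) + bc + umi + "T" * 20)
        idx = build_bin_index([self.guide(bc, umi)])
        asn = assign_read(make_read(flank5=flank), idx)
        assert (asn.status, asn.barcode) == (STATUS_ASSIGNED, bc)

    def test_raising_error_cap_never_loses_assignments(self, noisy_ds):
        idx = build_bin_index(noisy_ds.guide_records)
        reads = noisy_ds.aligned_reads()[:300]
        kept, _ = filter_long_reads(reads)
        counts = []
        for cap in (0, 1, 2, 3, 5):
            n = sum(assign_read(r, idx, max_errors=cap).status == STATUS_ASSIGNED for r in kept)
            counts.append(n)
        assert counts == sorted(counts)

    def test_one_assignment_per_read_id(self, noisy_ds):
        idx = build_bin_index(noisy_ds.guide_records)
        results = list(assign_all(noisy_ds.aligned_reads()[:200], idx))
        ids = [a.read_id for a, _ in results]
        assert len(ids) == len(set(ids)) == 200


class TestConsensus:
    def test_single_read_is_its_own_consensus(self):
        seq = rand_seq(100)
        assert consensus_per_molecule([("r1", seq)]) == seq

    def test_identical_reads_return_the_read(self):
        seq = rand_seq(150)
        assert consensus_per_molecule([("r1", seq), ("r2", seq), ("r3", seq)]) == seq

    def test_majority_vote_fixes_a_single_read_error(self):
        seq = rand_seq(100)
        bad = mutate(seq, 2)
        assert consensus_per_molecule([("r1", seq), ("r2", seq), ("r3", bad)]) == seq

    def test_consensus_closer_to_truth_than_any_single_copy(self):
        # five 5%-error copies of a 200-nt template, 100 seeded trials
        from nucleolong.synth import _mutate_free

        rng = np.random.default_rng(42)
        wins = 0
        trials = 100
        for _ in range(trials):
            truth = rand_seq(200, rng)
            copies = [
                (f"r{i}", _mutate_free(truth, rng, 0.025, 0.0125, 0.0125)[0]) for i in range(5)
            ]
            cons = consensus_per_molecule(copies)
            d_cons = edlib.align(cons, truth)["editDistance"]
            d_best = min(edlib.align(s, truth)["editDistance"] for _, s in copies)
            if d_cons < d_best:
                wins += 1
        assert wins >= 95
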