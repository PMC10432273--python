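"""Locus miner: translation, seed scans, aggregation, classification and
IR consensus, cross-checked against brute-force oracles."""

import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from fzkit import mining, simulate
from fzkit import templates as T
from fzkit._seq import random_dna, revcomp
from conftest import small_genome_spec
import oracles

BLOSUM62 = substitution_matrices.load("BLOSUM62")
AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _mutate_nt(seq, positions):
    swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
    out = list(seq)
    for p in positions:
        out[p] = swap[out[p]]
    return "".join(out)


class TestSixFrameTranslate:
    def test_atgaaa_frame1_is_MK(self):
        frames = dict(mining.six_frame_translate("ATGAAA"))
        assert frames[1] == "MK"

    def test_forward_frames_of_revcomp_are_reverse_frames(self):
        rng = np.random.default_rng(0)
        contig = random_dna(rng, 301)
        a = dict(mining.six_frame_translate(contig))
        b = dict(mining.six_frame_translate(revcomp(contig)))
        assert a[1] == b[-1] and a[-1] == b[1]

    def test_matches_codon_table_oracle_on_random_contig(self):
        rng = np.random.default_rng(1)
        contig = random_dna(rng, 3000)
        got = dict(mining.six_frame_translate(contig))
        expected = oracles.six_frames_oracle(contig)
        assert got == expected

    def test_n_codons_translate_to_X_and_empty_contig_ok(self):
        frames = dict(mining.six_frame_translate("ATGNNNAAA"))
        assert frames[1] == "MXK"
        assert all(p == "" for _, p in mining.six_frame_translate(""))


class TestScanProteinSeed:
    def test_verbatim_planted_seed_exact_hit(self):
        rng = np.random.default_rng(2)
        seed = "".join(rng.choice(list(AA20), 50))
        seed_nt = "".join({
            "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
            "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
            "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
            "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
        }[a] for a in seed)
        contig = random_dna(rng, 300) + seed_nt + random_dna(rng, 200)
        hits = mining.scan_protein_seed("c", contig, seed)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (300, 300 + 3 * len(seed), "+")
        assert h.score == align_self_score(seed)
        assert h.coverage_len == 3 * len(seed)

    def test_random_contig_has_no_hits(self):
        rng = np.random.default_rng(3)
        seed = "".join(rng.choice(list(AA20), 60))
        contig = random_dna(rng, 5000)
        assert mining.scan_protein_seed("c", contig, seed) == []

    def test_mutated_seed_retained_and_matches_dp_oracle(self):
        rng = np.random.default_rng(4)
        seed = "".join(rng.choice(list(AA20), 60))
        mutated = list(seed)
        for p in rng.choice(60, 12, replace=False):  # 20% substitutions
            mutated[p] = rng.choice(list(AA20))
        seed_nt = _encode_protein("".join(mutated))
        contig = random_dna(rng, 240) + seed_nt + random_dna(rng, 240)
        hits = mining.scan_protein_seed("c", contig, seed)
        assert len(hits) == 1
        self_score = align_self_score(seed)
        assert hits[0].score >= 0.25 * self_score
        frames = oracles.six_frames_oracle(contig)
        oracle_best = max(
            oracles.gotoh_local(seed, pep, lambda x, y: BLOSUM62[x, y], 12, 1)
            for pep in frames.values())
        assert hits[0].score == oracle_best

    def test_invalid_seed_characters_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            mining.scan_protein_seed("c", "ACGT" * 30, "MKLV8" * 5)


def align_self_score(seed: str) -> float:
    return float(sum(BLOSUM62[a, a] for a in seed))


def _encode_protein(pep: str) -> str:
    table = {
        "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
        "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
        "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
        "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    }
    return "".join(table[a] for a in pep)


class TestFindIrHits:
    def test_direct_and_inverted_copy_found_on_opposite_strands(self):
        rng = np.random.default_rng(5)
        ir = T.IR_CANONICAL
        contig = (random_dna(rng, 200) + ir + random_dna(rng, 400)
                  + revcomp(ir) + random_dna(rng, 200))
        hits = mining.find_ir_hits("c", contig, ir)
        assert len(hits) == 2
        assert {h.strand for h in hits} == {"+", "-"}
        assert all(h.coverage_len == 30 and h.score == 30 for h in hits)
        assert hits[0].start == 200 and hits[1].start == 630

    def test_gc_seed_on_polyA_contig_is_empty(self):
        assert mining.find_ir_hits("c", "A" * 2000, "GCGCGCGCGCGCGCGCGC") == []

    def test_three_substitutions_score_21_retained(self):
        # interior substitutions where the full-span alignment is optimal
        ir = T.IR_CANONICAL
        planted = _mutate_nt(ir, (7, 14, 22))
        contig = "A" * 100 + planted + "A" * 100
        hits = mining.find_ir_hits("c", contig, ir)
        assert len(hits) == 1 and hits[0].score == 27 - 3 * 2 == 21
        oracle = oracles.gotoh_local(ir, contig, oracles.nt_score, 3, 1)
        assert hits[0].score == oracle

    def test_four_substitutions_score_18_discarded(self):
        ir = T.IR_CANONICAL
        planted = _mutate_nt(ir, (6, 12, 18, 24))
        contig = "A" * 100 + planted + "A" * 100
        assert mining.find_ir_hits("c", contig, ir) == []
        # independent confirmation that the best local score is 26 - 8 = 18
        oracle = oracles.gotoh_local(ir, contig, oracles.nt_score, 3, 1)
        assert oracle == 18 <= 20

    def test_seed_shorter_than_word_is_an_error(self):
        with pytest.raises(ValueError):
            mining.find_ir_hits("c", "ACGTACGT", "ACGTA", word_len=7)


def _hit(cid, start, end, strand="+", kind="ir", score=30.0):
    return mining.SeedHit(cid, start, end, strand, kind, score, end - start)


class TestAggregateLoci:
    def test_hits_19kb_apart_form_one_locus(self):
        hits = [_hit("c", 1000, 1100), _hit("c", 20000, 20100, "-")]
        loci = mining.aggregate_loci(hits)
        assert len(loci) == 1 and loci[0].span == (1000, 20100)

    def test_single_hit_single_locus(self):
        loci = mining.aggregate_loci([_hit("c", 5, 35)])
        assert len(loci) == 1 and loci[0].hits[0].start == 5

    def test_24kb_chain_aggregates_but_26kb_gap_splits(self):
        chain = [_hit("c", i * 24_100, i * 24_100 + 100) for i in range(5)]
        assert len(mining.aggregate_loci(chain)) == 1
        broken = chain[:3] + [_hit("c", chain[2].end + 26_000,
                                   chain[2].end + 26_100)]
        assert len(mining.aggregate_loci(broken)) == 2

    def test_never_merges_across_contigs(self):
        hits = [_hit("a", 0, 50), _hit("b", 10, 60)]
        assert len(mining.aggregate_loci(hits)) == 2

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            mining.aggregate_loci([_hit("c", 0, 10)], max_gap=-1)

    def test_order_independent_and_matches_transitive_closure_oracle(self):
        rng = random.Random(9)
        for _ in range(25):
            hits = []
            for i in range(rng.randint(1, 12)):
                cid = rng.choice("ab")
                s = rng.randrange(0, 100_000)
                hits.append(_hit(cid, s, s + rng.randint(10, 2000)))
            gap = rng.choice([1000, 10_000, 25_000])
            loci = mining.aggregate_loci(hits, max_gap=gap)
            partition = {frozenset(hits.index(h) for h in l.hits)
                         for l in loci}
            assert partition == set(oracles.aggregate_oracle(hits, gap))
            shuffled = hits[:]
            rng.shuffle(shuffled)
            loci2 = mining.aggregate_loci(shuffled, max_gap=gap)
            assert sorted(l.span for l in loci2) == sorted(l.span
                                                           for l in loci)


class TestClassifyLocus:
    def _locus(self, hits, pair=None):
        locus = mining.Locus("c", min(h.start for h in hits),
                             max(h.end for h in hits), sorted(
                                 hits, key=lambda h: h.start))
        locus.ir_pair = pair
        return locus

    def test_full_partial_ghost_unresolved(self):
        left = _hit("c", 100, 130, "+")
        right = _hit("c", 2200, 2230, "-")
        pair = mining.IRPair(left, right)
        prot_full = _hit("c", 200, 2000, "+", kind="protein", score=900)
        prot_full.coverage_len = 1800
        prot_part = _hit("c", 200, 1100, "+", kind="protein", score=400)
        prot_part.coverage_len = 900

        full = self._locus([left, right, prot_full], pair)
        assert mining.classify_locus(full, 600) == "full"
        partial = self._locus([left, right, prot_part], pair)
        assert mining.classify_locus(partial, 600) == "partial"
        ghost = self._locus([left, right], pair)
        assert mining.classify_locus(ghost, 600) == "ghost"
        lone = self._locus([left])
        assert mining.classify_locus(lone, 600) == "unresolved"

    def test_labels_partition_the_locus_set(self, small_genome):
        contigs, truth = small_genome
        loci = mining.mine_genome(
            contigs, T.spu1_protein_seed(),
            {"c": T.IR_CANONICAL, "g": T.IR_GHOST},
            mining.MiningParams(max_gap=1500))  # desk-scale element spacing
        allowed = {"full", "partial", "ghost", "unresolved"}
        assert all(l.classification in allowed for l in loci)
        assert len(loci) == len(truth)


class TestDetectCaMotif:
    def _toy(self, upstream, strand="+"):
        ir = T.IR_CANONICAL
        rng = np.random.default_rng(12)
        left_flank = random_dna(rng, 80)
        insert = upstream + ir + random_dna(rng, 40) + revcomp(ir)
        if strand == "-":
            insert = revcomp(insert)
        contig = left_flank + insert + random_dna(rng, 60)
        hits = mining.find_ir_hits("c", contig, ir)
        locus = mining.aggregate_loci(hits, max_gap=1000)[0]
        locus.ir_pair = mining.resolve_ir_pair(locus)
        locus.strand = strand
        return locus, contig

    def test_plus_strand_ca_true_and_non_ca_false(self):
        locus, contig = self._toy("CA")
        assert mining.detect_ca_motif(locus, contig) is True
        locus2, contig2 = self._toy("GG")
        assert mining.detect_ca_motif(locus2, contig2) is False

    def test_minus_strand_ca_detected_via_revcomp(self):
        locus, contig = self._toy("CA", strand="-")
        assert mining.detect_ca_motif(locus, contig) is True

    def test_ir_at_contig_edge_reports_absent(self):
        ir = T.IR_CANONICAL
        contig = ir + "ACGT" * 20 + revcomp(ir)
        hits = mining.find_ir_hits("c", contig, ir)
        locus = mining.aggregate_loci(hits, max_gap=1000)[0]
        locus.ir_pair = mining.resolve_ir_pair(locus)
        locus.strand = "+"
        assert mining.detect_ca_motif(locus, contig) is None


class TestIrConsensus:
    def _loci_from_copies(self, copies):
        contigs = {}
        loci = []
        rng = np.random.default_rng(13)
        for i, ir in enumerate(copies):
            cid = f"c{i}"
            contigs[cid] = ("GGCA" + ir + random_dna(rng, 60)
                            + revcomp(T.IR_CANONICAL))
            left = _hit(cid, 4, 4 + len(ir))
            right = _hit(cid, 4 + len(ir) + 60,
                         4 + len(ir) + 60 + 30, "-")
            locus = mining.Locus(cid, left.start, right.end, [left, right])
            locus.ir_pair = mining.IRPair(left, right)
            locus.strand = "+"
            loci.append(locus)
        return loci, contigs

    def test_two_identical_copies_full_agreement(self):
        loci, contigs = self._loci_from_copies([T.IR_CANONICAL] * 2)
        cons = mining.ir_consensus(loci, contigs)
        assert cons.length == 30
        assert cons.consensus == T.IR_CANONICAL
        assert all(a == 1.0 for a in cons.agreement)

    def test_minority_column_agreement_is_fraction(self):
        mutated = _mutate_nt(T.IR_CANONICAL, (10,))
        loci, contigs = self._loci_from_copies([T.IR_CANONICAL] * 3
                                               + [mutated] * 2)
        cons = mining.ir_consensus(loci, contigs)
        assert cons.consensus == T.IR_CANONICAL
        assert cons.agreement[10] == pytest.approx(0.6)
        assert cons.n_members == 5

    def test_fewer_than_two_members_is_an_error(self):
        loci, contigs = self._loci_from_copies([T.IR_CANONICAL])
        with pytest.raises(ValueError, match=">= 2"):
            mining.ir_consensus(loci, contigs)

    def test_recovered_from_mined_planted_genome(self):
        spec = small_genome_spec(n_contigs=5, contig_length=5000, n_full=0,
                                 n_partial=0, n_ghost=10, mutation_rate=0.01,
                                 min_separation=200, rng_seed=21)
        contigs, _ = simulate.generate_genome(spec)
        loci = mining.mine_genome(contigs, None, {"g": T.IR_GHOST})
        with_pairs = [l for l in loci if l.ir_pair]
        cons = mining.ir_consensus(with_pairs, contigs)
        assert cons.length == 30
        assert cons.consensus == T.IR_GHOST


class TestIrDivergence:
    def test_identical_zero(self):
        assert mining.ir_divergence("ACGTACGT", "ACGTACGT") == 0

    def test_acgt_tgca_is_4(self):
        assert mining.ir_divergence("ACGT", "TGCA") == 4

    def test_canonical_vs_ghost_template_is_7(self):
        assert mining.ir_divergence(T.IR_CANONICAL, T.IR_GHOST) == 7

    def test_length_mismatch_refused(self):
        with pytest.raises(ValueError):
            mining.ir_divergence("ACGT", "ACG")


class TestStrandSymmetry:
    def test_mirrored_genome_gives_mirrored_loci(self):
        spec = small_genome_spec(n_contigs=2, contig_length=9000, n_full=1,
                                 n_partial=0, n_ghost=1, mutation_rate=0.0,
                                 min_separation=300, rng_seed=31)
        contigs, _ = simulate.generate_genome(spec)
        mirrored = {cid: revcomp(s) for cid, s in contigs.items()}
        seeds = {"c": T.IR_CANONICAL, "g": T.IR_GHOST}
        fwd = mining.mine_genome(contigs, T.spu1_protein_seed(), seeds)
        rev = mining.mine_genome(mirrored, T.spu1_protein_seed(), seeds)
        flip = {"+": "-", "-": "+", None: None}
        expect = sorted(
            (l.contig_id, len(contigs[l.contig_id]) - l.end,
             len(contigs[l.contig_id]) - l.start, l.classification,
             flip[l.strand]) for l in fwd)
        got = sorted((l.contig_id, l.start, l.end, l.classification,
                      l.strand) for l in rev)
        assert expect == got


class TestPlantedRecoveryNoMutation:
    def test_default_small_genome_perfect_recovery(self, small_genome):
        contigs, truth = small_genome
        loci = mining.mine_genome(
            contigs, T.spu1_protein_seed(),
            {"c": T.IR_CANONICAL, "g": T.IR_GHOST},
            mining.MiningParams(max_gap=1500))
        matched = set()
        for locus in loci:
            hit = [r for r in truth
                   if r.contig_id == locus.contig_id
                   and min(locus.end, r.end) - max(locus.start, r.start) > 0]
            assert len(hit) == 1
            assert locus.classification == hit[0].label
            matched.add(id(hit[0]))
        assert len(matched) == len(truth)
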