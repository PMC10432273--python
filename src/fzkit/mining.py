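"""Fz-like locus discovery.

Pipeline: six-frame translation + protein-seed Smith-Waterman scan, IR-seed
nucleotide scan (word length 7, score > 20, coverage >= 17 nt), aggregation of
hits into loci at a 25-kb single-linkage gap, IR-pair resolution, and
classification into full / partial / ghost / unresolved, with CA-motif
detection and IR consensus reporting.

The published protein step is a translated BLAST with an e-value cutoff;
without a database-size-dependent e-value this scan keeps hits scoring at
least ``min_score_fraction`` (default 0.25) of the seed's BLOSUM62 self-score,
a monotone proxy calibrated so exact planted seeds always pass and random
contigs essentially never do.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio.Seq import Seq

from . import align
from ._seq import revcomp

DEFAULT_WORD_LEN = 7
DEFAULT_MIN_IR_SCORE = 20.0
DEFAULT_MIN_IR_COV = 17
DEFAULT_MAX_GAP = 25_000
DEFAULT_FULL_COVERAGE_FRAC = 0.90
DEFAULT_MIN_SCORE_FRACTION = 0.25
RESCAN_RADIUS = 50_000
RESCAN_MIN_SCORE = 14.0
RESCAN_MIN_COV = 12


@dataclass
class SeedHit:
    """A scored seed hit on the forward strand of a contig (0-based,
    half-open). ``coverage_len`` is in nt (3x aligned residues for protein
    hits)."""

    contig_id: str
    start: int
    end: int
    strand: str  # orientation of the seed match
    kind: str  # "protein" | "ir"
    score: float
    coverage_len: int
    frame: int | None = None
    seed_id: str | None = None
    rescan: bool = False

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid hit interval [{self.start},{self.end})")


@dataclass
class IRPair:
    left: SeedHit
    right: SeedHit

    def __post_init__(self):
        if self.left.contig_id != self.right.contig_id:
            raise ValueError("IR pair must be on one contig")
        if self.left.end > self.right.start:
            raise ValueError("IR pair hits must not overlap")
        if self.left.strand == self.right.strand:
            raise ValueError("IR pair must be in inverted orientation")


@dataclass
class Locus:
    contig_id: str
    start: int
    end: int
    hits: list[SeedHit]
    ir_pair: IRPair | None = None
    classification: str = "unresolved"
    strand: str | None = None  # element strand, if resolvable
    ca_motif: bool | None = None  # None = abuts contig edge / undetermined
    rescan: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class IRConsensus:
    consensus: str
    length: int  # modal aligned IR length
    agreement: list[float]
    n_members: int


# --- translation --------------------------------------------------------------

def six_frame_translate(contig: str) -> list[tuple[int, str]]:
    """Translate all six frames; returns [(frame, peptide)] with frames
    +1..+3 from the forward strand and -1..-3 from the reverse complement.
    Codons containing N translate to X; trailing partial codons are dropped."""
    contig = contig.upper()
    out: list[tuple[int, str]] = []
    for strand_label, seq in ((1, contig), (-1, revcomp(contig))):
        for off in range(3):
            sub = seq[off:]
            sub = sub[:len(sub) - (len(sub) % 3)]
            pep = str(Seq(sub).translate()) if sub else ""
            out.append((strand_label * (off + 1), pep))
    return out


def _frame_to_contig_coords(frame: int, aa_start: int, aa_end: int,
                            contig_len: int) -> tuple[int, int, str]:
    off = abs(frame) - 1
    nt_start = off + 3 * aa_start
    nt_end = off + 3 * aa_end
    if frame > 0:
        return nt_start, nt_end, "+"
    return contig_len - nt_end, contig_len - nt_start, "-"


# --- protein seed scan --------------------------------------------------------

def scan_protein_seed(
    contig_id: str,
    contig: str,
    protein_seed: str,
    min_score_fraction: float = DEFAULT_MIN_SCORE_FRACTION,
    word_len: int = 3,
) -> list[SeedHit]:
    """Word-seeded Smith-Waterman (BLOSUM62, gap 11/1) of a protein seed
    against all six frames; overlapping hits across frames are merged keeping
    the best score, then the longest, then the lowest start."""
    seed = protein_seed.upper()
    bad = set(seed) - align.PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"protein seed contains non-amino-acid characters: "
                         f"{sorted(bad)}")
    if len(seed) < 20:
        raise ValueError("protein seed must be >= 20 aa")
    threshold = min_score_fraction * align.protein_self_score(seed)
    hits: list[SeedHit] = []
    for frame, pep in six_frame_translate(contig):
        for lh in align.seeded_local_search(seed, pep, protein=True,
                                            word_len=word_len,
                                            min_score=threshold):
            s, e, strand = _frame_to_contig_coords(
                frame, lh.subject_start, lh.subject_end, len(contig))
            hits.append(SeedHit(contig_id, s, e, strand, "protein",
                                lh.score, 3 * lh.seed_coverage, frame=frame))
    return _merge_overlapping(hits)


def _merge_overlapping(hits: list[SeedHit]) -> list[SeedHit]:
    hits = sorted(hits, key=lambda h: (-h.score, h.start - h.end, h.start))
    kept: list[SeedHit] = []
    for h in hits:
        if any(min(h.end, k.end) - max(h.start, k.start) > 0 for k in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


# --- IR scan ------------------------------------------------------------------

def find_ir_hits(
    contig_id: str,
    contig: str,
    ir_seed: str,
    word_len: int = DEFAULT_WORD_LEN,
    min_score: float = DEFAULT_MIN_IR_SCORE,
    min_cov: int = DEFAULT_MIN_IR_COV,
    seed_id: str | None = None,
    region: tuple[int, int] | None = None,
    rescan: bool = False,
) -> list[SeedHit]:
    """Exact-word-seeded nucleotide local alignment of an IR seed on both
    strands. Hits kept when score > ``min_score`` (strict) and aligned seed
    coverage >= ``min_cov`` nt. ``strand`` records the seed orientation."""
    if len(ir_seed) < word_len:
        raise ValueError("IR seed shorter than the word length")
    if min_score < 0 or word_len < 1:
        raise ValueError("invalid IR scan parameters")
    off = 0
    subject = contig.upper()
    if region is not None:
        off = max(0, region[0])
        subject = subject[off:region[1]]
    hits: list[SeedHit] = []
    for strand, seed in (("+", ir_seed.upper()), ("-", revcomp(ir_seed.upper()))):
        for lh in align.seeded_local_search(seed, subject, protein=False,
                                            word_len=word_len,
                                            min_score=min_score):
            if lh.score > min_score and lh.seed_coverage >= min_cov:
                hits.append(SeedHit(contig_id, off + lh.subject_start,
                                    off + lh.subject_end, strand, "ir",
                                    lh.score, lh.seed_coverage,
                                    seed_id=seed_id, rescan=rescan))
    hits.sort(key=lambda h: h.start)
    return hits


def scan_ir_seeds(contig_id: str, contig: str, ir_seeds: dict[str, str],
                  **kwargs) -> list[SeedHit]:
    """Scan several IR seed variants and keep the best hit per location."""
    hits: list[SeedHit] = []
    for sid in sorted(ir_seeds):
        hits.extend(find_ir_hits(contig_id, contig, ir_seeds[sid],
                                 seed_id=sid, **kwargs))
    hits.sort(key=lambda h: (h.start, -h.score, h.end))
    kept: list[SeedHit] = []
    for h in hits:
        dup = False
        for k in kept:
            inter = min(h.end, k.end) - max(h.start, k.start)
            if inter > 0 and inter >= 0.5 * min(h.end - h.start,
                                                k.end - k.start):
                if h.score > k.score:
                    k.start, k.end, k.strand = h.start, h.end, h.strand
                    k.score, k.coverage_len = h.score, h.coverage_len
                    k.seed_id = h.seed_id
                dup = True
                break
        if not dup:
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


# --- aggregation and classification -------------------------------------------

def aggregate_loci(hits: list[SeedHit],
                   max_gap: int = DEFAULT_MAX_GAP) -> list[Locus]:
    """Single-linkage aggregation: hits on one contig whose interval gap is
    strictly less than ``max_gap`` join one locus. Order-independent."""
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    by_contig: dict[str, list[SeedHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append(h)
    loci: list[Locus] = []
    for cid in sorted(by_contig):
        chits = sorted(by_contig[cid], key=lambda h: (h.start, h.end))
        cluster: list[SeedHit] = []
        cluster_end = None
        for h in chits:
            if cluster and h.start - cluster_end >= max_gap:
                loci.append(_locus_from(cid, cluster))
                cluster = []
                cluster_end = None
            cluster.append(h)
            cluster_end = h.end if cluster_end is None else max(cluster_end,
                                                                h.end)
        if cluster:
            loci.append(_locus_from(cid, cluster))
    return loci


def _locus_from(cid: str, hits: list[SeedHit]) -> Locus:
    return Locus(cid, min(h.start for h in hits), max(h.end for h in hits),
                 sorted(hits, key=lambda h: (h.start, h.end)))


def resolve_ir_pair(locus: Locus) -> IRPair | None:
    """Pick the IR pair: inverted-orientation, non-overlapping pair of IR
    hits maximizing combined score, then span, breaking ties leftward."""
    irs = [h for h in locus.hits if h.kind == "ir"]
    best = None
    key = None
    for i, l in enumerate(irs):
        for r in irs[i + 1:]:
            if l.strand == r.strand or l.end > r.start:
                continue
            k = (l.score + r.score, r.end - l.start, -l.start)
            if key is None or k > key:
                key, best = k, IRPair(l, r)
    return best


def classify_locus(locus: Locus, protein_seed_len: int,
                   full_coverage_frac: float = DEFAULT_FULL_COVERAGE_FRAC
                   ) -> str:
    """full: near-complete protein hit flanked by an IR pair; partial: any
    protein hit short of that; ghost: IR pair with no protein hit;
    unresolved: anything else (e.g. a lone IR hit)."""
    prot = [h for h in locus.hits if h.kind == "protein"]
    pair = locus.ir_pair
    need = full_coverage_frac * 3 * protein_seed_len
    if prot:
        full = any(
            h.coverage_len >= need
            and pair is not None
            and pair.left.start <= h.start and h.end <= pair.right.end
            for h in prot)
        return "full" if full else "partial"
    if pair is not None:
        return "ghost"
    return "unresolved"


def _element_strand(locus: Locus, contig: str) -> str | None:
    prot = [h for h in locus.hits if h.kind == "protein"]
    if prot:
        return max(prot, key=lambda h: h.score).strand
    if locus.ir_pair is None:
        return None
    # Ghost loci: IR orientation alone is strand-symmetric; the conserved CA
    # immediately upstream of the element-sense 5' IR breaks the tie.
    plus = _ca_at(contig, locus.ir_pair, "+")
    minus = _ca_at(contig, locus.ir_pair, "-")
    if plus is True and minus is not True:
        return "+"
    if minus is True and plus is not True:
        return "-"
    return None


def _ca_at(contig: str, pair: IRPair, strand: str) -> bool | None:
    if strand == "+":
        s = pair.left.start
        if s < 2:
            return None
        return contig[s - 2:s].upper() == "CA"
    e = pair.right.end
    if e + 2 > len(contig):
        return None
    return revcomp(contig[e:e + 2].upper()) == "CA"


def detect_ca_motif(locus: Locus, contig: str) -> bool | None:
    """True iff the 2 nt immediately upstream (element sense) of the 5' IR are
    CA; None when the check would run off the contig edge or the element
    strand is unresolved."""
    if locus.ir_pair is None:
        return None
    strand = locus.strand or _element_strand(locus, contig)
    if strand is None:
        # strand-ambiguous ghost: report CA if either orientation shows it
        plus = _ca_at(contig, locus.ir_pair, "+")
        minus = _ca_at(contig, locus.ir_pair, "-")
        if plus is None and minus is None:
            return None
        return bool(plus) or bool(minus)
    return _ca_at(contig, locus.ir_pair, strand)


def ir_consensus(loci: list[Locus], contigs: dict[str, str]) -> IRConsensus:
    """Majority-rule column consensus over element-sense 5' IR copies of loci
    with resolved IR pairs; reports the modal aligned length."""
    seqs: list[str] = []
    for locus in loci:
        if locus.ir_pair is None:
            continue
        strand = locus.strand or _element_strand(locus,
                                                 contigs[locus.contig_id])
        if strand is None:
            strand = "+"
        pair = locus.ir_pair
        hit = pair.left if strand == "+" else pair.right
        s = contigs[locus.contig_id][hit.start:hit.end].upper()
        seqs.append(s if strand == "+" else revcomp(s))
    if len(seqs) < 2:
        raise ValueError("ir_consensus needs >= 2 loci with IR pairs")
    lengths = Counter(len(s) for s in seqs)
    modal_len = max(lengths, key=lambda L: (lengths[L], L))
    members = [s for s in seqs if len(s) == modal_len]
    consensus = []
    agreement = []
    for col in range(modal_len):
        counts = Counter(s[col] for s in members)
        base = max(sorted(counts), key=counts.get)
        consensus.append(base)
        agreement.append(counts[base] / len(members))
    return IRConsensus("".join(consensus), modal_len, agreement, len(members))


def ir_divergence(consensus_a: str, consensus_b: str) -> int:
    """Hamming distance between two equal-length consensus strings."""
    if len(consensus_a) != len(consensus_b):
        raise ValueError("consensus lengths differ; refusing implicit "
                         "alignment")
    return sum(a != b for a, b in zip(consensus_a.upper(),
                                      consensus_b.upper()))


# --- orchestration ------------------------------------------------------------

@dataclass
class MiningParams:
    word_len: int = DEFAULT_WORD_LEN
    min_ir_score: float = DEFAULT_MIN_IR_SCORE
    min_ir_cov: int = DEFAULT_MIN_IR_COV
    max_gap: int = DEFAULT_MAX_GAP
    min_score_fraction: float = DEFAULT_MIN_SCORE_FRACTION
    full_coverage_frac: float = DEFAULT_FULL_COVERAGE_FRAC
    rescan: bool = True


def mine_genome(
    contigs: dict[str, str],
    protein_seed: str | None,
    ir_seeds: dict[str, str],
    params: MiningParams | None = None,
) -> list[Locus]:
    """Run the full locus-mining pipeline over a genome."""
    params = params or MiningParams()
    all_hits: list[SeedHit] = []
    for cid in sorted(contigs):
        seq = contigs[cid]
        if protein_seed:
            all_hits.extend(scan_protein_seed(
                cid, seq, protein_seed,
                min_score_fraction=params.min_score_fraction))
        all_hits.extend(scan_ir_seeds(
            cid, seq, ir_seeds, word_len=params.word_len,
            min_score=params.min_ir_score, min_cov=params.min_ir_cov))
    loci = aggregate_loci(all_hits, max_gap=params.max_gap)

    for locus in loci:
        locus.ir_pair = resolve_ir_pair(locus)
        if (params.rescan and locus.ir_pair is None
                and any(h.kind == "protein" for h in locus.hits)):
            _widened_rescan(locus, contigs[locus.contig_id], ir_seeds, params)
        contig = contigs[locus.contig_id]
        locus.strand = _element_strand(locus, contig)
        plen = len(protein_seed) if protein_seed else 0
        locus.classification = classify_locus(
            locus, plen, params.full_coverage_frac) if protein_seed else (
            "ghost" if locus.ir_pair else "unresolved")
        locus.ca_motif = detect_ca_motif(locus, contig)
    return loci


def _widened_rescan(locus: Locus, contig: str, ir_seeds: dict[str, str],
                    params: MiningParams) -> None:
    """Stand-in for the published manual curation: re-scan +/- 50 kb around a
    locus that has a protein hit but no IR pair, at relaxed thresholds, and
    flag recovered hits with rescan=True."""
    region = (max(0, locus.start - RESCAN_RADIUS),
              min(len(contig), locus.end + RESCAN_RADIUS))
    extra = scan_ir_seeds(locus.contig_id, contig, ir_seeds,
                          word_len=params.word_len,
                          min_score=RESCAN_MIN_SCORE,
                          min_cov=RESCAN_MIN_COV, region=region, rescan=True)
    known = [(h.start, h.end) for h in locus.hits]
    new = [h for h in extra
           if all(min(h.end, e) - max(h.start, s) <= 0 for s, e in known)]
    if not new:
        return
    locus.hits = sorted(locus.hits + new, key=lambda h: (h.start, h.end))
    locus.start = min(locus.start, min(h.start for h in new))
    locus.end = max(locus.end, max(h.end for h in new))
    locus.rescan = True
    locus.ir_pair = resolve_ir_pair(locus)
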