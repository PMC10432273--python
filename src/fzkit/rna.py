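"""Small-RNA mapping, ncRNA transcript calling, and scaffold/guide partition.

Reads (20-90 nt) are aligned full-length against kilobase locus windows with
an exact index plus a <=1-mismatch scan; a heuristic external aligner is
unnecessary at these sizes and the package must run self-contained. Reads
matching several windows equally well are assigned fractionally (1/n) because
the loci are near-identical repeats and discarding multimappers would zero
out coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, revcomp


@dataclass
class Window:
    """A locus-anchored mapping window (forward-strand contig coordinates)."""

    locus_id: str
    contig_id: str
    start: int
    end: int
    seq: str
    element_strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


def windows_from_loci(loci, contigs: dict[str, str], pad: int = 200
                      ) -> list[Window]:
    """Build mapping windows (span +/- pad) from mined loci or truth records."""
    wins = []
    for i, locus in enumerate(loci):
        cid = locus.contig_id
        start, end = locus.span
        s = max(0, start - pad)
        e = min(len(contigs[cid]), end + pad)
        strand = getattr(locus, "strand", None) or "+"
        wins.append(Window(f"locus_{i}", cid, s, e, contigs[cid][s:e], strand))
    return wins


@dataclass
class CoverageProfile:
    """Strand-resolved per-base arrays over one window. ``starts``/``ends``
    count (possibly fractional) read 5'/3' termini in window coordinates on
    the forward strand; ``coverage`` counts read bodies."""

    window: Window
    coverage: dict[str, np.ndarray] = field(default_factory=dict)
    starts: dict[str, np.ndarray] = field(default_factory=dict)
    ends: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        n = self.window.length
        for strand in "+-":
            self.coverage.setdefault(strand, np.zeros(n))
            self.starts.setdefault(strand, np.zeros(n + 1))
            self.ends.setdefault(strand, np.zeros(n + 1))


@dataclass
class MappingResult:
    profiles: dict[str, CoverageProfile]
    mapped: float
    unmapped: int
    skipped_too_long: int


def _placements(read_codes: np.ndarray, win_fwd: np.ndarray,
                win_rev: np.ndarray, max_mismatch: int):
    """All (strand, start, n_mismatches) full-length placements of a read in
    one window, at most ``max_mismatch`` substitutions (no indels)."""
    L = len(read_codes)
    out = []
    for strand, codes in (("+", win_fwd), ("-", win_rev)):
        n = len(codes) - L + 1
        if n <= 0:
            continue
        view = np.lib.stride_tricks.sliding_window_view(codes, L)
        mm = (view != read_codes).sum(axis=1)
        for pos in np.nonzero(mm <= max_mismatch)[0]:
            out.append((strand, int(pos), int(mm[pos])))
    return out


def map_small_reads(
    reads: list[tuple[str, str]],
    windows: list[Window],
    max_mismatch: int = 1,
) -> MappingResult:
    """Assign each read to its best full-length match (either strand, any
    window); equally good placements share the read fractionally."""
    profiles = {w.locus_id: CoverageProfile(w) for w in windows}
    enc = [(w.locus_id, encode(w.seq), encode(revcomp(w.seq)))
           for w in windows]
    mapped = 0.0
    unmapped = 0
    skipped = 0
    for _rid, seq in reads:
        if not seq:
            unmapped += 1
            continue
        if all(len(seq) > w.length for w in windows):
            skipped += 1
            continue
        rc = encode(seq)
        best_mm = None
        best: list[tuple[str, str, int]] = []
        for lid, fwd, rev in enc:
            if len(seq) > len(fwd):
                continue
            for strand, pos, mm in _placements(rc, fwd, rev, max_mismatch):
                if best_mm is None or mm < best_mm:
                    best_mm, best = mm, [(lid, strand, pos)]
                elif mm == best_mm:
                    best.append((lid, strand, pos))
        if not best:
            unmapped += 1
            continue
        frac = 1.0 / len(best)
        mapped += 1.0
        L = len(seq)
        for lid, strand, pos in best:
            prof = profiles[lid]
            n = prof.window.length
            if strand == "+":
                s, e = pos, pos + L
            else:
                # position on the reverse-complement scan -> forward coords
                s, e = n - pos - L, n - pos
            prof.coverage[strand][s:e] += frac
            prof.starts[strand][s] += frac
            prof.ends[strand][e] += frac
    return MappingResult(profiles, mapped, unmapped, skipped)


@dataclass
class NcRnaCall:
    locus_id: str
    start: int  # window-local forward coordinates, 0-based half-open
    end: int
    strand: str
    length: int
    mean_coverage: float

    def contig_span(self, window: Window) -> tuple[int, int]:
        return (window.start + self.start, window.start + self.end)


def call_transcripts(
    profile: CoverageProfile,
    min_cov: float | None = None,
    min_len: int = 40,
    refine_radius: int = 3,
) -> list[NcRnaCall]:
    """Call expressed transcript units per strand as maximal runs of coverage
    at or above threshold (default: 10x the window median, floor 5), with
    boundaries refined to the modal read start/end within +/- 3 nt."""
    calls: list[NcRnaCall] = []
    for strand in "+-":
        cov = profile.coverage[strand]
        if not cov.any():
            continue
        thr = min_cov if min_cov is not None else max(5.0,
                                                      10.0 * np.median(cov))
        above = cov >= thr
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8),
                                                       [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            s, e = int(s), int(e)
            s_ref = _modal_boundary(profile.starts[strand], s, refine_radius,
                                    prefer_low=True)
            e_ref = _modal_boundary(profile.ends[strand], e, refine_radius,
                                    prefer_low=False)
            if e_ref - s_ref < min_len:
                continue
            calls.append(NcRnaCall(profile.window.locus_id, s_ref, e_ref,
                                   strand, e_ref - s_ref,
                                   float(cov[s_ref:e_ref].mean())))
    calls.sort(key=lambda c: (c.start, c.strand))
    return calls


def _modal_boundary(counts: np.ndarray, pos: int, radius: int,
                    prefer_low: bool) -> int:
    lo = max(0, pos - radius)
    hi = min(len(counts), pos + radius + 1)
    window = counts[lo:hi]
    if window.max() <= 0:
        return pos
    candidates = np.flatnonzero(window == window.max()) + lo
    return int(candidates[0] if prefer_low else candidates[-1])


@dataclass
class ScaffoldGuidePartition:
    scaffold_len: int
    guide_len: dict[str, int]  # per locus id
    column_identity: list[float]
    degenerate: bool = False


class PartitionError(ValueError):
    pass


def partition_scaffold_guide(
    transcripts: dict[str, str],
    identity_threshold: float = 0.9,
    min_common_prefix: int = 20,
) -> ScaffoldGuidePartition:
    """Split 5'-anchored transcripts into a shared scaffold prefix and
    per-locus guide suffixes.

    The scaffold is the maximal prefix over which the cross-locus per-column
    identity (fraction of covering transcripts sharing the modal base) stays
    at or above ``identity_threshold``."""
    if len(transcripts) < 2:
        raise PartitionError("partition needs transcripts from >= 2 loci")
    ids = sorted(transcripts)
    seqs = [transcripts[i].upper() for i in ids]
    max_len = max(len(s) for s in seqs)
    identity: list[float] = []
    scaffold_len = 0
    for col in range(max_len):
        bases = [s[col] for s in seqs if col < len(s)]
        if len(bases) < 2:
            break
        best = max(bases.count(b) for b in set(bases))
        ident = best / len(bases)
        if ident < identity_threshold:
            break
        identity.append(ident)
        scaffold_len = col + 1
    if scaffold_len < min_common_prefix:
        raise PartitionError(
            f"no common prefix >= {min_common_prefix} nt across loci "
            f"(got {scaffold_len}); transcripts may be unrelated")
    guide_len = {i: max(0, len(transcripts[i]) - scaffold_len) for i in ids}
    degenerate = all(g == 0 for g in guide_len.values())
    return ScaffoldGuidePartition(scaffold_len, guide_len, identity,
                                  degenerate)


def compute_cds_overlap(orf_span: tuple[int, int],
                        transcript_span: tuple[int, int]) -> tuple[int, int]:
    """Intersection of an ORF and a transcript on one strand, as (nt, aa);
    aa = floor(nt / 3). Disjoint spans give (0, 0)."""
    nt = min(orf_span[1], transcript_span[1]) - max(orf_span[0],
                                                    transcript_span[0])
    nt = max(0, nt)
    return nt, nt // 3
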