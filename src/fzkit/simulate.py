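"""Seeded synthetic-data generators.

Every generator is a pure function of its spec (including ``rng_seed``):
identical spec + seed give byte-identical outputs. The generators plant
truth-labeled structure with the statistics the downstream stages assume:

* genomes with full / partial / ghost elements (``generate_genome``),
* small-RNA reads covering the 89-90-nt scaffold+guide transcript of each
  expressed locus (``generate_small_rna_reads``),
* TAM-screen input/cleaved read pairs with an optional planted enriched motif
  (``generate_tam_screen_reads``),
* per-strand run-off terminal-position samples with the polymerase
  non-templated-addition artifact (``generate_runoff_samples``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import DNA, mutate, random_dna, revcomp
from . import templates as T


class PlacementError(RuntimeError):
    """Raised when planted elements cannot be placed without overlap."""


class SizingError(ValueError):
    """Raised when a contig cannot hold an element with the required flanks."""


@dataclass
class TruthRecord:
    """Ground truth for one planted element (coordinates 0-based half-open,
    forward strand; ``guide`` is in element sense)."""

    contig_id: str
    start: int
    end: int
    strand: str
    label: str  # full | partial | ghost
    guide: str | None = None
    orf_start: int | None = None   # forward coords, None for ghost/absent
    orf_end: int | None = None
    transcript_start: int | None = None  # scaffold+guide window, forward coords
    transcript_end: int | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class PlantedGenomeSpec:
    """Defaults are the desk-scale benchmark genome: 5 x 200-kb contigs with
    3 full, 2 partial and 4 ghost elements at 1% per-copy substitutions."""

    n_contigs: int = 5
    contig_length: int = 200_000
    gc_content: float = 0.5
    n_full: int = 3
    n_partial: int = 2
    n_ghost: int = 4
    mutation_rate: float = 0.01
    guide_length_range: tuple[int, int] = (14, 15)
    partial_delete_range: tuple[float, float] = (0.3, 0.6)
    min_flank: int = 100
    #: minimum gap between planted elements on one contig; the default keeps
    #: distinct elements distinct under the 25-kb locus-aggregation rule
    min_separation: int = 30_000
    fixture_guide: str | None = None  # planted into the first full element
    rng_seed: int = 0

    def validate(self) -> None:
        if min(self.n_full, self.n_partial, self.n_ghost, self.n_contigs) < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        lo, hi = self.guide_length_range
        if not (1 <= lo <= hi):
            raise ValueError("guide_length_range must be 1 <= min <= max")
        dl, dh = self.partial_delete_range
        if not (0.3 <= dl <= dh < 1.0):
            raise ValueError("partial deletions must remove >= 30% of the ORF")


def _build_element(rng: np.random.Generator, template: T.ElementTemplate,
                   label: str, spec: PlantedGenomeSpec,
                   guide: str | None) -> tuple[str, dict]:
    """Assemble one element (element-sense, forward orientation) and local
    sub-feature coordinates relative to the element start."""
    up = template.upstream_motif
    if label == "ghost":
        seq = up + template.ir5 + template.ghost_core + template.ir3
        return seq, {}
    orf = template.orf
    if label == "partial":
        frac = rng.uniform(*spec.partial_delete_range)
        keep = int(round(len(orf) * (1.0 - frac)))
        keep -= keep % 3
        orf = orf[:keep]  # 3'-truncation
    if guide is None:
        glen = int(rng.integers(spec.guide_length_range[0],
                                spec.guide_length_range[1] + 1))
        guide = random_dna(rng, glen)
    t_start = len(up) + len(template.ir5) + len(orf)
    t_end = t_start + len(template.scaffold) + len(guide)
    seq = (up + template.ir5 + orf + template.scaffold + guide + template.ir3)
    feats = {
        "guide": guide,
        "orf_start": len(up) + len(template.ir5),
        "orf_end": len(up) + len(template.ir5) + len(orf),
        "transcript_start": t_start,
        "transcript_end": t_end,
    }
    return seq, feats


def generate_genome(
    spec: PlantedGenomeSpec,
    template: T.ElementTemplate | None = None,
    ghost_template: T.ElementTemplate | None = None,
) -> tuple[dict[str, str], list[TruthRecord]]:
    """Plant truth-labeled elements into i.i.d. background contigs.

    Returns ``(contigs, truth)`` where ``contigs`` maps contig id to sequence.
    Substitutions at ``spec.mutation_rate`` are applied per element copy,
    sparing the scaffold+guide transcript window (the cross-locus conservation
    of the scaffold is the feature being emulated). Elements are assigned to
    contigs round-robin and placed by distributing the remaining slack
    uniformly between them, so any feasible layout always succeeds.
    """
    spec.validate()
    template = template or T.spu1_template()
    ghost_template = ghost_template or T.spu1_ghost_template()
    rng = np.random.default_rng(spec.rng_seed)

    labels = (["full"] * spec.n_full + ["partial"] * spec.n_partial
              + ["ghost"] * spec.n_ghost)
    contig_ids = [f"contig_{i + 1}" for i in range(spec.n_contigs)]
    contigs = {cid: random_dna(rng, spec.contig_length, spec.gc_content)
               for cid in contig_ids}

    # build every element first (rng draws in label order), then place
    built: dict[str, list[tuple[str, str, str, dict]]] = {
        cid: [] for cid in contig_ids}
    first_full_seen = False
    for k, label in enumerate(labels):
        tmpl = ghost_template if label == "ghost" else template
        guide = None
        if label == "full" and not first_full_seen and spec.fixture_guide:
            guide = spec.fixture_guide
            first_full_seen = True
        el, feats = _build_element(rng, tmpl, label, spec, guide)
        el = mutate(rng, el, spec.mutation_rate,
                    protect=(feats["transcript_start"], feats["transcript_end"])
                    if feats else None)
        if feats:
            feats["guide"] = el[feats["transcript_start"]
                                + len(tmpl.scaffold):feats["transcript_end"]]
        strand = "+" if rng.random() < 0.5 else "-"
        built[contig_ids[k % spec.n_contigs]].append((label, el, strand,
                                                      feats))

    truth: list[TruthRecord] = []
    L = spec.contig_length
    sep = max(spec.min_flank, spec.min_separation)
    for cid in contig_ids:
        elements = built[cid]
        if not elements:
            continue
        total = sum(len(el) for _, el, _, _ in elements)
        if L < total + 2 * spec.min_flank:
            raise SizingError(
                f"contig length {L} cannot hold {len(elements)} elements "
                f"({total} nt) with {spec.min_flank}-nt flanks")
        slack = L - total - 2 * spec.min_flank - sep * (len(elements) - 1)
        if slack < 0:
            raise PlacementError(
                f"contig length {L} cannot separate {len(elements)} elements "
                f"by {sep} nt")
        cuts = np.sort(rng.integers(0, slack + 1, size=len(elements)))
        gaps = np.diff(np.concatenate(([0], cuts)))
        pos = spec.min_flank
        seq = contigs[cid]
        for (label, el, strand, feats), extra in zip(elements, gaps):
            start = pos + int(extra)
            end = start + len(el)
            ins = el if strand == "+" else revcomp(el)
            seq = seq[:start] + ins + seq[end:]
            rec = TruthRecord(cid, start, end, strand, label,
                              guide=feats.get("guide"))
            if feats:
                if strand == "+":
                    rec.orf_start = start + feats["orf_start"]
                    rec.orf_end = start + feats["orf_end"]
                    rec.transcript_start = start + feats["transcript_start"]
                    rec.transcript_end = start + feats["transcript_end"]
                else:
                    rec.orf_start = start + (len(el) - feats["orf_end"])
                    rec.orf_end = start + (len(el) - feats["orf_start"])
                    rec.transcript_start = start + (len(el)
                                                    - feats["transcript_end"])
                    rec.transcript_end = start + (len(el)
                                                  - feats["transcript_start"])
            truth.append(rec)
            pos = end + sep
        contigs[cid] = seq
    return contigs, truth


# --- small-RNA reads ---------------------------------------------------------

def transcript_sequence(contigs: dict[str, str], rec: TruthRecord) -> str:
    """Element-sense scaffold+guide transcript of one expressed locus."""
    s = contigs[rec.contig_id][rec.transcript_start:rec.transcript_end]
    return s if rec.strand == "+" else revcomp(s)


def generate_small_rna_reads(
    contigs: dict[str, str],
    truth: list[TruthRecord],
    depth: int = 500,
    background_rate: float = 0.05,
    read_length: int | None = None,
    rng_seed: int = 0,
) -> list[tuple[str, str]]:
    """Simulate small-RNA reads as ``(read_id, sequence)`` pairs.

    Each expressed (full) locus contributes ``depth`` element-sense reads of
    its scaffold+guide transcript, with independent uniform jitter of at most
    1 nt at each boundary. ``read_length=None`` emits full transcripts;
    otherwise uniformly placed sub-reads of that length. Background reads are
    drawn uniformly from the genome at ``background_rate`` x (locus reads).
    """
    eligible = [r for r in truth
                if r.label == "full" and r.transcript_start is not None]
    if depth > 0 and not eligible:
        raise ValueError("no eligible expressed loci (need >= 1 full element)")
    rng = np.random.default_rng(rng_seed)
    # boundary raggedness: at most 1 nt, modal at the true terminus (half the
    # reads start/end exactly there), so transcript ends stay well-defined
    jitter = [-1, 0, 0, 1]
    reads: list[tuple[str, str]] = []
    for li, rec in enumerate(eligible):
        tseq_full = contigs[rec.contig_id]
        for i in range(depth):
            j5 = jitter[rng.integers(4)]
            j3 = jitter[rng.integers(4)]
            if rec.strand == "+":
                s = rec.transcript_start + j5
                e = rec.transcript_end + j3
            else:
                s = rec.transcript_start - j3
                e = rec.transcript_end - j5
            frag = tseq_full[s:e]
            if rec.strand == "-":
                frag = revcomp(frag)
            if read_length is not None and read_length < len(frag):
                off = int(rng.integers(0, len(frag) - read_length + 1))
                frag = frag[off:off + read_length]
            reads.append((f"locus{li}_read{i}", frag))
    n_bg = int(round(background_rate * len(reads)))
    cids = sorted(contigs)
    bg_len = read_length or 89
    for i in range(n_bg):
        cid = cids[int(rng.integers(len(cids)))]
        seq = contigs[cid]
        start = int(rng.integers(0, max(1, len(seq) - bg_len)))
        frag = seq[start:start + bg_len]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        reads.append((f"background_read{i}", frag))
    return reads


# --- TAM screen --------------------------------------------------------------

@dataclass
class TamLibrarySpec:
    """Randomized-TAM cleavage-screen read generator parameters.

    ``planted_motif`` uses ``.`` as a wildcard (e.g. ``"CATA...."``); cleaved
    reads draw motif-matching TAMs with probability
    ``E*q / (1 + (E-1)*q)`` where ``q`` is the motif's probability under the
    uniform library and ``E = planted_enrichment``.
    """

    target_sequence: str = T.PSP1_TARGET
    tam_length: int = 8
    n_input_reads: int = 50_000
    n_cleaved_reads: int = 50_000
    planted_motif: str | None = "CATA...."
    planted_enrichment: float = 10.0
    constant_tail: str = T.TAM_CONSTANT_TAIL
    rng_seed: int = 0

    def validate(self) -> None:
        if self.planted_motif is not None:
            if len(self.planted_motif) != self.tam_length:
                raise ValueError("planted_motif length must equal tam_length")
            bad = set(self.planted_motif) - set("ACGT.")
            if bad:
                raise ValueError(f"planted_motif has invalid characters: {bad}")
        if self.planted_enrichment < 1:
            raise ValueError("planted_enrichment must be >= 1")


def _uniform_tams(rng: np.random.Generator, n: int, length: int) -> list[str]:
    codes = rng.integers(0, 4, size=(n, length))
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return np.char.decode(
        lut[codes].view(f"S{length}").ravel(), "ascii").tolist()


def _matches(tam: str, motif: str) -> bool:
    return all(m == "." or m == b for b, m in zip(tam, motif))


def generate_tam_screen_reads(
    spec: TamLibrarySpec,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Return ``(input_reads, cleaved_reads)`` as ``(id, seq)`` pairs; every
    read is ``TAM + target_sequence + constant_tail``."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    L = spec.tam_length

    input_tams = _uniform_tams(rng, spec.n_input_reads, L)

    motif = spec.planted_motif
    E = spec.planted_enrichment
    if motif is None or E == 1.0:
        cleaved_tams = _uniform_tams(rng, spec.n_cleaved_reads, L)
    else:
        fixed = [(i, b) for i, b in enumerate(motif) if b != "."]
        q = 0.25 ** len(fixed)
        p_match = E * q / (1.0 + (E - 1.0) * q)
        draws = rng.random(spec.n_cleaved_reads) < p_match
        pool = _uniform_tams(rng, spec.n_cleaved_reads, L)
        cleaved_tams = []
        for matched, tam in zip(draws, pool):
            if matched:
                t = list(tam)
                for i, b in fixed:
                    t[i] = b
                cleaved_tams.append("".join(t))
            else:
                while _matches(tam, motif):
                    tam = _uniform_tams(rng, 1, L)[0]
                cleaved_tams.append(tam)

    body = spec.target_sequence + spec.constant_tail
    input_reads = [(f"input_{i}", t + body) for i, t in enumerate(input_tams)]
    cleaved_reads = [(f"cleaved_{i}", t + body)
                     for i, t in enumerate(cleaved_tams)]
    return input_reads, cleaved_reads


# --- run-off terminal-position samples ---------------------------------------

@dataclass
class CutProfileSpec:
    """Parameters for per-strand run-off terminal-position sampling.

    Positions are 1-based from the TAM-proximal first protospacer base. With
    probability ``artifact_rate`` a sample is recorded one base beyond its
    true position carrying the polymerase artifact base (A on the target
    strand, T on the NTS)."""

    nts_positions: dict[int, float] = field(default_factory=dict)
    ts_positions: dict[int, float] = field(default_factory=dict)
    n_samples: int = 5000
    artifact_rate: float = 0.2
    target_sequence: str = T.PSP1_TARGET
    rng_seed: int = 0

    def validate(self) -> None:
        for name, d in (("nts", self.nts_positions), ("ts", self.ts_positions)):
            if not d:
                raise ValueError(f"{name}_positions must be non-empty")
            if min(d) < 1:
                raise ValueError("positions must be >= 1")
            if abs(sum(d.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} weights must sum to 1")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be in [0, 1]")

    @classmethod
    def from_fixture(cls, fixture: T.CutProfileFixture, n_samples: int = 5000,
                     artifact_rate: float = 0.2, rng_seed: int = 0
                     ) -> "CutProfileSpec":
        return cls(nts_positions=dict(fixture.nts_positions),
                   ts_positions=dict(fixture.ts_positions),
                   n_samples=n_samples, artifact_rate=artifact_rate,
                   rng_seed=rng_seed)


_ARTIFACT_BASE = {"TS": "A", "NTS": "T"}
_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _templated_base(target: str, strand: str, position: int) -> str:
    base = target[position - 1] if position - 1 < len(target) else "N"
    return base if strand == "NTS" else _COMP1.get(base, "N")


def generate_runoff_samples(spec: CutProfileSpec) -> pd.DataFrame:
    """Sample terminal positions per strand.

    Returns a DataFrame with columns ``strand`` (TS/NTS), ``position``
    (recorded, i.e. artifact-shifted where flagged), ``terminal_base`` and
    ``artifact`` (ground-truth flag)."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    rows = []
    for strand, profile in (("TS", spec.ts_positions),
                            ("NTS", spec.nts_positions)):
        pos = sorted(profile)
        w = np.array([profile[p] for p in pos], dtype=float)
        w = w / w.sum()
        draws = rng.choice(pos, size=spec.n_samples, p=w)
        artifacts = rng.random(spec.n_samples) < spec.artifact_rate
        for p, a in zip(draws, artifacts):
            p = int(p)
            if a:
                rows.append((strand, p + 1, _ARTIFACT_BASE[strand], True))
            else:
                rows.append((strand, p,
                             _templated_base(spec.target_sequence, strand, p),
                             False))
    return pd.DataFrame(rows,
                        columns=["strand", "position", "terminal_base",
                                 "artifact"])
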