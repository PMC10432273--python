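"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ parsing is delegated to Bio.SeqIO with validation layered on top
(duplicate-id and non-IUPAC checks, lowercase normalization with a logged
count, gzip auto-detection by magic bytes). Locus tables go out as BED6
(0-based half-open) and GFF3 (1-based closed); matrices as TSV; PWMs in MEME
minimal motif format; every run writes a JSON manifest sufficient to
reproduce it.
"""

from __future__ import annotations

import gzip
import json
import logging
from pathlib import Path

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("fzkit")

IUPAC_DNA = set("ACGTRYSWKMBDHVN")
GZIP_MAGIC = b"\x1f\x8b"


def _open_text(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered {id: sequence} dict.

    Lowercase is normalized to uppercase (count logged); duplicate ids and
    non-IUPAC characters raise with context."""
    records: dict[str, str] = {}
    lowered = 0
    dupes = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq)
            lowered += sum(1 for c in seq if c.islower())
            seq = seq.upper()
            bad = [(i, c) for i, c in enumerate(seq) if c not in IUPAC_DNA]
            if bad:
                i, c = bad[0]
                raise ValueError(
                    f"non-IUPAC character {c!r} at position {i} "
                    f"of record {rec.id!r} in {path}")
            if rec.id in records:
                dupes.append(rec.id)
            records[rec.id] = seq
    if dupes:
        raise ValueError(f"duplicate FASTA ids in {path}: {sorted(set(dupes))}")
    if lowered:
        logger.info("normalized %d lowercase bases to uppercase in %s",
                    lowered, path)
    return records


def write_fasta(path: str | Path, records: dict[str, str],
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid in records:
            fh.write(f">{rid}\n")
            seq = records[rid]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read 4-line Phred+33 FASTQ (gzip auto-detected) as (id, seq) pairs."""
    reads: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        try:
            for idx, (title, seq, qual) in enumerate(
                    SeqIO.QualityIO.FastqGeneralIterator(fh)):
                if len(seq) != len(qual):
                    raise ValueError(
                        f"sequence/quality length mismatch in record {idx} "
                        f"({title.split()[0]!r}) of {path}")
                reads.append((title.split()[0], seq.upper()))
        except ValueError as err:
            raise ValueError(f"malformed FASTQ {path} at record "
                             f"{len(reads)}: {err}") from err
    return reads


def write_fastq(path: str | Path, reads: list[tuple[str, str]],
                quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


# --- locus tables -------------------------------------------------------------

def write_loci_bed(path: str | Path, loci) -> None:
    """BED6: name = classification, score = best hit score, strand column."""
    with open(path, "w") as fh:
        for locus in loci:
            score = int(max((h.score for h in locus.hits), default=0))
            strand = locus.strand or "."
            fh.write(f"{locus.contig_id}\t{locus.start}\t{locus.end}\t"
                     f"{locus.classification}\t{score}\t{strand}\n")


def write_loci_gff3(path: str | Path, loci, source: str = "fzkit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, locus in enumerate(loci):
            attrs = (f"ID=locus_{i};classification={locus.classification};"
                     f"ca_motif={locus.ca_motif};rescan={locus.rescan}")
            strand = locus.strand or "."
            fh.write(f"{locus.contig_id}\t{source}\tmobile_genetic_element\t"
                     f"{locus.start + 1}\t{locus.end}\t.\t{strand}\t.\t"
                     f"{attrs}\n")


def write_truth_bed(path: str | Path, truth) -> None:
    with open(path, "w") as fh:
        for rec in truth:
            fh.write(f"{rec.contig_id}\t{rec.start}\t{rec.end}\t{rec.label}"
                     f"\t0\t{rec.strand}\n")


def read_bed(path: str | Path) -> list[dict]:
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            rows.append({"contig_id": f[0], "start": int(f[1]),
                         "end": int(f[2]),
                         "name": f[3] if len(f) > 3 else ".",
                         "strand": f[5] if len(f) > 5 else "."})
    return rows


# --- motif / matrix formats ---------------------------------------------------

def write_meme_pwm(path: str | Path, pwm: np.ndarray, name: str = "TAM",
                   nsites: int = 20) -> None:
    """MEME minimal motif format; letter-probability columns A C G T."""
    pwm = np.asarray(pwm, dtype=float)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A 0.25 C 0.25 G 0.25 T 0.25\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                 f"nsites= {nsites} E= 0\n")
        for row in pwm:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_meme_pwm(path: str | Path) -> np.ndarray:
    rows = []
    in_matrix = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("letter-probability matrix"):
                in_matrix = True
                continue
            if in_matrix:
                parts = line.split()
                if len(parts) != 4:
                    break
                rows.append([float(x) for x in parts])
    return np.asarray(rows)


# --- manifest -----------------------------------------------------------------

def write_manifest(path: str | Path, config: dict, seed: int,
                   command: str) -> None:
    from . import __version__

    payload = {"tool": "fzkit", "version": __version__, "command": command,
               "seed": seed, "config": config}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
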