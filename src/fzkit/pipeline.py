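"""High-level stage runners tying the modules together.

Each runner consumes in-memory objects and/or paths, writes the standard
output files for its stage, and returns its results so callers (the CLI, the
reproduction script, tests) can chain stages without re-reading files. All
randomness flows from one integer seed per run; stage sub-seeds are derived
deterministically from it.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from . import cuts as cuts_mod
from . import io, mining, rna, simulate, tam
from . import templates as T

_SEED_MOD = 2 ** 31


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (kept below 2^31)."""
    offsets = {"genome": 1, "smallrna": 2, "tam": 3, "runoff": 4}
    return (seed * 7919 + offsets[stage]) % _SEED_MOD


def run_simulate(outdir: str | Path, seed: int,
                 genome_spec: simulate.PlantedGenomeSpec | None = None,
                 tam_spec: simulate.TamLibrarySpec | None = None,
                 depth: int = 500,
                 runoff_n: int = 5000,
                 artifact_rate: float = 0.2) -> dict:
    """Generate the full synthetic input set into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    gspec = genome_spec or simulate.PlantedGenomeSpec(
        fixture_guide=T.GUIDE_CRYO_EM)
    gspec.rng_seed = stage_seed(seed, "genome")
    contigs, truth = simulate.generate_genome(gspec)
    io.write_fasta(outdir / "genome.fasta", contigs)
    io.write_truth_bed(outdir / "truth.bed", truth)
    with open(outdir / "truth.json", "w") as fh:
        json.dump([dataclasses.asdict(r) for r in truth], fh, indent=2)

    reads = simulate.generate_small_rna_reads(
        contigs, truth, depth=depth, rng_seed=stage_seed(seed, "smallrna"))
    io.write_fastq(outdir / "smallrna.fastq", reads)

    tspec = tam_spec or simulate.TamLibrarySpec()
    tspec.rng_seed = stage_seed(seed, "tam")
    tam_in, tam_clv = simulate.generate_tam_screen_reads(tspec)
    io.write_fastq(outdir / "tam_input.fastq", tam_in)
    io.write_fastq(outdir / "tam_cleaved.fastq", tam_clv)

    for i, (name, fixture) in enumerate(sorted(T.CUT_PROFILES.items())):
        cspec = simulate.CutProfileSpec.from_fixture(
            fixture, n_samples=runoff_n, artifact_rate=artifact_rate,
            rng_seed=(stage_seed(seed, "runoff") + i) % _SEED_MOD)
        df = simulate.generate_runoff_samples(cspec)
        df.to_csv(outdir / f"runoff_{name}.tsv", sep="\t", index=False)

    config = {"genome": dataclasses.asdict(gspec),
              "tam": dataclasses.asdict(tspec),
              "smallrna_depth": depth, "runoff_n": runoff_n,
              "artifact_rate": artifact_rate}
    io.write_manifest(outdir / "manifest.json", config, seed, "simulate")
    return {"contigs": contigs, "truth": truth, "smallrna": reads,
            "tam_input": tam_in, "tam_cleaved": tam_clv, "config": config}


def default_ir_seeds() -> dict[str, str]:
    return {"left_end": T.IR_CANONICAL, "left_end_ghost": T.IR_GHOST}


def run_mine(contigs: dict[str, str], outdir: str | Path, seed: int,
             protein_seed: str | None = None,
             ir_seeds: dict[str, str] | None = None,
             params: mining.MiningParams | None = None) -> list[mining.Locus]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    protein_seed = protein_seed or T.spu1_protein_seed()
    ir_seeds = ir_seeds or default_ir_seeds()
    params = params or mining.MiningParams()
    loci = mining.mine_genome(contigs, protein_seed, ir_seeds, params)
    io.write_loci_bed(outdir / "loci.bed", loci)
    io.write_loci_gff3(outdir / "loci.gff3", loci)
    with_pairs = [l for l in loci if l.ir_pair is not None]
    if len(with_pairs) >= 2:
        cons = mining.ir_consensus(with_pairs, contigs)
        pd.DataFrame({"column": range(cons.length),
                      "base": list(cons.consensus),
                      "agreement": cons.agreement}).to_csv(
            outdir / "ir_consensus.tsv", sep="\t", index=False)
        with open(outdir / "ir_consensus.json", "w") as fh:
            json.dump({"consensus": cons.consensus, "length": cons.length,
                       "n_members": cons.n_members}, fh, indent=2)
    io.write_manifest(outdir / "manifest.json",
                      {"params": dataclasses.asdict(params),
                       "ir_seeds": ir_seeds}, seed, "mine")
    return loci


def run_rna(contigs: dict[str, str], loci, reads, outdir: str | Path,
            seed: int, max_mismatch: int = 1, min_len: int = 40,
            pad: int = 200) -> dict:
    """Map reads onto locus windows, call transcripts, partition
    scaffold/guide across loci. ``loci`` may be mined loci or truth records
    (anything with contig_id and span)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    windows = rna.windows_from_loci(loci, contigs, pad=pad)
    result = rna.map_small_reads(reads, windows, max_mismatch=max_mismatch)
    calls_rows = []
    transcripts: dict[str, str] = {}
    for w in windows:
        prof = result.profiles[w.locus_id]
        calls = rna.call_transcripts(prof, min_len=min_len)
        if not calls:
            continue
        best = max(calls, key=lambda c: c.mean_coverage)
        seq = w.seq[best.start:best.end]
        if best.strand == "-":
            from ._seq import revcomp
            seq = revcomp(seq)
        transcripts[w.locus_id] = seq
        s, e = best.contig_span(w)
        calls_rows.append({"locus_id": w.locus_id, "contig_id": w.contig_id,
                           "start": s, "end": e, "strand": best.strand,
                           "length": best.length,
                           "mean_coverage": best.mean_coverage})
    pd.DataFrame(calls_rows).to_csv(outdir / "transcripts.tsv", sep="\t",
                                    index=False)
    out = {"mapping": result, "transcripts": transcripts, "partition": None}
    if len(transcripts) >= 2:
        part = rna.partition_scaffold_guide(transcripts)
        out["partition"] = part
        with open(outdir / "partition.json", "w") as fh:
            json.dump({"scaffold_len": part.scaffold_len,
                       "guide_len": part.guide_len,
                       "degenerate": part.degenerate}, fh, indent=2)
    io.write_manifest(outdir / "manifest.json",
                      {"max_mismatch": max_mismatch, "min_len": min_len,
                       "pad": pad}, seed, "rna")
    return out


def run_tam(input_reads, cleaved_reads, outdir: str | Path, seed: int,
            target_sequence: str = T.PSP1_TARGET, tam_length: int = 8,
            pwm_method: str = "corrected",
            log_enrichment: bool = False) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, pwm, call = tam.analyze_tam_screen(
        input_reads, cleaved_reads, target_sequence, tam_length=tam_length,
        pwm_method=pwm_method, log_enrichment=log_enrichment)
    table.table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    io.write_meme_pwm(outdir / "pwm.meme", pwm,
                      nsites=len(table.table))
    with open(outdir / "consensus.txt", "w") as fh:
        fh.write((call.motif or "no TAM detected") + "\n")
    io.write_manifest(outdir / "manifest.json",
                      {"tam_length": tam_length, "pwm_method": pwm_method,
                       "log_enrichment": log_enrichment}, seed, "tam")
    return {"table": table, "pwm": pwm, "consensus": call}


def run_cuts(samples: pd.DataFrame, outdir: str | Path, seed: int,
             mode_frac: float = cuts_mod.DEFAULT_MODE_FRAC,
             name: str = "sample") -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profile = cuts_mod.call_cut_positions(samples, mode_frac=mode_frac)
    call = cuts_mod.classify_overhang(profile)
    payload = {"name": name,
               "ts_positions": profile.support.get("TS", []),
               "nts_positions": profile.support.get("NTS", []),
               "artifact_trimmed": profile.artifact_trimmed,
               "end_type": call.end_type,
               "overhang_range": list(call.overhang_range)}
    with open(outdir / f"cutsites_{name}.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    rows = []
    for strand, counter in sorted(profile.counts.items()):
        for pos, cnt in sorted(counter.items()):
            rows.append({"strand": strand, "position": pos, "count": cnt})
    pd.DataFrame(rows).to_csv(outdir / f"cutsites_{name}.tsv", sep="\t",
                              index=False)
    io.write_manifest(outdir / "manifest.json", {"mode_frac": mode_frac},
                      seed, "cuts")
    return {"profile": profile, "overhang": call}


def run_all(outdir: str | Path, seed: int, **simulate_kwargs) -> dict:
    """simulate -> mine -> rna -> tam -> cuts, all under one seed."""
    outdir = Path(outdir)
    sim = run_simulate(outdir / "simulate", seed, **simulate_kwargs)
    loci = run_mine(sim["contigs"], outdir / "mine", seed)
    expressed = [l for l in loci if l.classification == "full"]
    rna_out = run_rna(sim["contigs"], expressed or loci, sim["smallrna"],
                      outdir / "rna", seed)
    tam_out = run_tam(sim["tam_input"], sim["tam_cleaved"], outdir / "tam",
                      seed)
    cut_out = {}
    for name in sorted(T.CUT_PROFILES):
        df = pd.read_csv(outdir / "simulate" / f"runoff_{name}.tsv", sep="\t")
        cut_out[name] = run_cuts(df, outdir / "cuts", seed, name=name)
    io.write_manifest(outdir / "manifest.json", {"stages": ["simulate",
                      "mine", "rna", "tam", "cuts"]}, seed, "all")
    return {"simulate": sim, "loci": loci, "rna": rna_out, "tam": tam_out,
            "cuts": cut_out}
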