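"""Packaged element templates and biochemical fixtures.

These constants define the *Spu-1*-style element architecture the synthetic
genome generator plants, and the per-orthologue cleavage profiles used by the
run-off sample generator:

* a 30-nt inverted repeat (IR) pair with a conserved ``CA`` dinucleotide
  immediately upstream of the 5' IR,
* a single-ORF Fz gene body (~1.9 kb) for full elements,
* a ~550-nt conserved core for ghost elements, whose IRs diverge from the
  canonical IRs at seven positions,
* a 75-nt ncRNA scaffold template between the ORF stop and the 3' IR, ending
  in a variable 14-15-nt guide slot (the expressed ncRNA is scaffold + guide,
  89-90 nt).

All long sequences are generated deterministically from fixed seeds at import
time rather than stored as literals; they are synthetic stand-ins with the
documented architecture, not genomic sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import DNA, random_dna, revcomp

IR_LENGTH = 30
SCAFFOLD_LENGTH = 75
GHOST_CORE_LENGTH = 550
GHOST_IR_DIVERGENT_POSITIONS = (0, 1, 2, 3, 4, 5, 6)  # 7 columns, clustered at the 5' end

#: Canonical Spu-1 left-end IR (30 nt). Fixed, arbitrary composition.
IR_CANONICAL = "GGTGACCTAGCAATGCGTACTGGACCTTCA"

#: Ghost-element IR: canonical IR with the 7 divergent columns substituted.
#: Clustering the divergence at one end keeps the conserved 23-nt block
#: alignable as a single local hit (score 23 > 20, coverage 23 >= 17 under the
#: miner's +1/-2 scheme), which is what makes ghost IRs discoverable with a
#: canonical seed at the published thresholds.
IR_GHOST = "TTCAGTA" + IR_CANONICAL[7:]

UPSTREAM_MOTIF = "CA"

_rng_core = np.random.default_rng(20230628)
GHOST_CORE = random_dna(_rng_core, GHOST_CORE_LENGTH)
SCAFFOLD_TEMPLATE = random_dna(np.random.default_rng(751475), SCAFFOLD_LENGTH)

#: 15-nt guide used by the structural (cryo-EM) construct fixture locus.
#: Synthetic stand-in with the construct's guide length.
GUIDE_CRYO_EM = "GACCTGAGCGATCAA"
assert len(GUIDE_CRYO_EM) == 15


def _make_orf(n_codons: int, seed: int) -> str:
    """Deterministic protein-coding body: ATG + sense codons + TAA stop."""
    rng = np.random.default_rng(seed)
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < n_codons - 2:
        c = "".join(DNA[i] for i in rng.integers(0, 4, size=3))
        if c not in stops:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


#: Fz ORF body, 1,920 nt (640 codons) -> a ~2.07-kb full element, matching the
#: "roughly 2.1-kbp" single-ORF locus scale.
ORF_SPU1 = _make_orf(640, seed=404142)


@dataclass(frozen=True)
class ElementTemplate:
    """Sequence parts of one plantable element family.

    ``ir3`` defaults to the exact reverse complement of ``ir5``; templates may
    declare within-element IR mismatches by passing an explicit ``ir3``.
    """

    ir5: str = IR_CANONICAL
    ir3: str | None = None
    upstream_motif: str = UPSTREAM_MOTIF
    orf: str = ""
    ghost_core: str = ""
    scaffold: str = ""

    def __post_init__(self):
        if self.ir3 is None:
            object.__setattr__(self, "ir3", revcomp(self.ir5))
        if not self.upstream_motif:
            raise ValueError("upstream_motif must be non-empty")

    @property
    def ir_mismatch_positions(self) -> tuple[int, ...]:
        """Columns where ir5 and revcomp(ir3) disagree (element-internal)."""
        rc = revcomp(self.ir3)
        return tuple(i for i, (a, b) in enumerate(zip(self.ir5, rc)) if a != b)


def spu1_template() -> ElementTemplate:
    """Canonical full/partial Spu-1 element template."""
    return ElementTemplate(ir5=IR_CANONICAL, orf=ORF_SPU1, scaffold=SCAFFOLD_TEMPLATE)


def spu1_ghost_template() -> ElementTemplate:
    """Ghost Spu-1 element: divergent IRs (7 columns), 550-nt core, no ORF."""
    return ElementTemplate(ir5=IR_GHOST, ghost_core=GHOST_CORE)


#: Protein seed used by the miner: the translated canonical ORF (stop removed).
def spu1_protein_seed() -> str:
    from Bio.Seq import Seq

    return str(Seq(ORF_SPU1).translate())[:-1]


# --- TAM screen fixtures ----------------------------------------------------

#: 30-nt protospacer analogue ("PSP1 guide" target). Positions 9-21 (1-based)
#: deliberately contain no T so that templated run-off terminal bases in the
#: profiled cut window never collide with the polymerase artifact bases
#: (terminal A on the target strand / T on the NTS).
PSP1_TARGET = "GACCGTAGGACAGGCAAGGCAGACGCATTG"
assert len(PSP1_TARGET) == 30 and "T" not in PSP1_TARGET[8:21]

#: Constant backbone tail 3' of the protospacer in screen reads.
TAM_CONSTANT_TAIL = "GTCGACTCTAGAGGATCC"

#: Published consensus TAMs of the four characterized orthologues.
KNOWN_TAMS = {
    "SpuFz1": "CATA",
    "GtFz1": "TTAAN",
    "NlovFz2": "CCG",
    "MmeFz2": "TAG",
}


# --- run-off cleavage-profile fixtures --------------------------------------

@dataclass(frozen=True)
class CutProfileFixture:
    """Per-strand cut-position weights for one orthologue (positions are
    1-based, counted from the TAM-proximal first protospacer base; a cut
    'after the Nth base')."""

    name: str
    nts_positions: dict[int, float] = field(default_factory=dict)
    ts_positions: dict[int, float] = field(default_factory=dict)


CUT_PROFILES = {
    # 5' overhangs: NTS after 16/17, TS after 20/21
    "SpuFz1": CutProfileFixture("SpuFz1", {16: 0.5, 17: 0.5}, {20: 0.5, 21: 0.5}),
    # sticky and blunt mixture: NTS 14-17, TS 14-16
    "GtFz1": CutProfileFixture(
        "GtFz1",
        {p: 0.25 for p in (14, 15, 16, 17)},
        {p: 1.0 / 3.0 for p in (14, 15, 16)},
    ),
    # blunt: both strands after the 19th base
    "NlovFz2": CutProfileFixture("NlovFz2", {19: 1.0}, {19: 1.0}),
    # 3' overhangs: NTS 17/18, TS 9-14
    "MmeFz2": CutProfileFixture(
        "MmeFz2", {17: 0.5, 18: 0.5}, {p: 1.0 / 6.0 for p in range(9, 15)}
    ),
}
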