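import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from fzkit import simulate
from fzkit import templates as T


def small_genome_spec(**overrides) -> simulate.PlantedGenomeSpec:
    """A fast desk-scale genome: short contigs, small separation."""
    kwargs = dict(n_contigs=3, contig_length=12_000, n_full=2, n_partial=1,
                  n_ghost=2, mutation_rate=0.0, min_separation=2_000,
                  rng_seed=42, fixture_guide=T.GUIDE_CRYO_EM)
    kwargs.update(overrides)
    return simulate.PlantedGenomeSpec(**kwargs)


@pytest.fixture(scope="session")
def small_genome():
    """(contigs, truth) for a mutation-free miniature genome."""
    return simulate.generate_genome(small_genome_spec())


@pytest.fixture(scope="session")
def expressed_genome():
    """4 expressed (full) loci for small-RNA tests; first carries the
    structural-construct 15-nt guide."""
    spec = small_genome_spec(n_contigs=4, contig_length=8_000, n_full=4,
                             n_partial=0, n_ghost=0, mutation_rate=0.01,
                             min_separation=100, rng_seed=11)
    return simulate.generate_genome(spec)


def short_orf_template(scaffold_len: int = 75) -> T.ElementTemplate:
    """Element template with a short ORF (and optionally non-default scaffold
    length) to keep mapping-heavy property tests fast."""
    from fzkit._seq import random_dna
    import numpy as np

    scaffold = (T.SCAFFOLD_TEMPLATE if scaffold_len == 75 else
                random_dna(np.random.default_rng(900 + scaffold_len),
                           scaffold_len))
    orf = T._make_orf(100, seed=3210)
    return T.ElementTemplate(ir5=T.IR_CANONICAL, orf=orf, scaffold=scaffold)
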