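import numpy as np
import pytest

from modscape.io_core import GenomeSeq, ModCall, ModTable
from modscape.synthetic_data import MotifSpec, gen_genome, plant_motif_mods


@pytest.fixture
def tiny_genome():
    return GenomeSeq([("c1", "GAGGACGTACGTGAGG"), ("c2", "CCTCATTTAAAGCGCG")])


@pytest.fixture
def small_genome():
    """200 kb AT-rich random genome, fixed seed."""
    return gen_genome(200_000, gc=0.38, n_contigs=2, seed=11)


@pytest.fixture
def gagg_mods(small_genome):
    """GAGG-planted 6mA calls with a light uniform background."""
    mods, truth = plant_motif_mods(
        small_genome, [MotifSpec("GAGG", 1, "6mA", 0.5)],
        background_rate=1e-4, seed=3)
    return mods, truth


def make_call(contig="c1", pos=1, strand="+", mod_class="6mA", **kw):
    base = "A" if mod_class in ("modA", "6mA") else "C"
    return ModCall(contig, pos, strand, base, mod_class, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
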