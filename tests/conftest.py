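from __future__ import annotations

import random

import pytest

from gendemarc.homology import AlignParams, Proteome
from gendemarc.io import SequenceRecord, read_newick
from gendemarc.simulate import SimConfig, simulate_all

AA = "ACDEFGHIKLMNPQRSTVWY"

EXHAUSTIVE = AlignParams(min_shared_kmers=0)  # disable the k-mer prefilter


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA) for _ in range(length))


def mutate(seq: str, n_subs: int, rng: random.Random) -> str:
    """Plant exactly n_subs substitutions at distinct positions."""
    pos = rng.sample(range(len(seq)), n_subs)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([c for c in AA if c != out[p]])
    return "".join(out)


@pytest.fixture(scope="session")
def caterpillar():
    """((A:1,B:1)X:1,C:2); -- the hand-traceable RED example tree."""
    return read_newick("((A:1,B:1)X:1,C:2);")


@pytest.fixture(scope="session")
def toy_proteomes():
    """Two related proteomes, <= 20 proteins x <= 60 aa, with shared
    families at planted divergences plus unrelated proteins."""
    rng = random.Random(42)
    fams = [random_protein(rng, 60) for _ in range(12)]
    a_prots = [SequenceRecord(f"a{k:02d}", "", fams[k]) for k in range(12)]
    # b: diverged copies of 10 families (k subs each) + 4 unrelated proteins
    b_prots = [SequenceRecord(f"b{k:02d}", "", mutate(fams[k], k, rng))
               for k in range(10)]
    b_prots += [SequenceRecord(f"u{k}", "", random_protein(rng, 60))
                for k in range(4)]
    return (Proteome("toyA", a_prots), Proteome("toyB", b_prots))


@pytest.fixture(scope="session")
def small_sim():
    """A reduced synthetic dataset shared by unit tests (fast)."""
    return simulate_all(SimConfig(seed=11, n_families=60))
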