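from __future__ import annotations

import numpy as np
import pytest

import translink as tl


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate_seq(rng: np.random.Generator, seq: str, n_subs: int,
               lo: int = 0, hi: int | None = None) -> str:
    """Introduce exactly n_subs substitutions at distinct positions in
    [lo, hi)."""
    hi = hi if hi is not None else len(seq)
    positions = rng.choice(np.arange(lo, hi), size=n_subs, replace=False)
    out = list(seq)
    for pos in positions:
        out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
    return "".join(out)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def scoring():
    return tl.AlignmentScoring()


@pytest.fixture(scope="session")
def sim_bundle_nr():
    """Session-scoped bundle without rearrangements (2 x 20 genes)."""
    cfg = tl.SimConfig(seed=7, n_chromosomes=2, genes_per_chromosome=20)
    return tl.simulate_bundle(cfg)
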