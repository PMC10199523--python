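import numpy as np
import pandas as pd
import pytest

from radseq_gs.simulate import (
    ChromosomePlan,
    MatingPlan,
    SimConfig,
    TraitPlan,
    simulate_all,
)


def small_config(seed: int = 11) -> SimConfig:
    """Fast, small population for unit tests (not the study conditions)."""
    plan = [
        ChromosomePlan("chr1", "macro", 400_000, 0.40),
        ChromosomePlan("chr2", "macro", 300_000, 0.41),
        ChromosomePlan("chr6", "intermediate", 200_000, 0.46),
        ChromosomePlan("chr11", "micro", 80_000, 0.53),
        ChromosomePlan("chrZ", "Z", 150_000, 0.40),
    ]
    traits = [
        TraitPlan("EW", 0.50, mean=60.0),
        TraitPlan("ESC", 0.35, mean=25.0),
    ]
    return SimConfig(
        seed=seed,
        chromosome_plan=plan,
        n_founders=60,
        generations=4,
        mating=MatingPlan(8, 24, 4),
        marker_density=400.0,
        ld_decay_bp=60_000.0,
        trait_plan=traits,
        panel_fraction=0.5,
        site_variant_rate=0.1,
    )


@pytest.fixture(scope="session")
def sim_small():
    return simulate_all(small_config())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def naive_scan(sequence: str, recognition: str) -> list[int]:
    """Independent per-position IUPAC comparison oracle (pure python)."""
    from radseq_gs.enzymes import allowed_bases

    seq = sequence.upper()
    L = len(recognition)
    allowed = [allowed_bases(c) for c in recognition]
    hits = []
    for i in range(len(seq) - L + 1):
        if all(seq[i + j] in allowed[j] for j in range(L)):
            hits.append(i)
    return hits


def random_dna(rng, n: int, gc: float = 0.45, n_frac: float = 0.0) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(list("ACGT"), size=n, p=probs)
    if n_frac > 0:
        mask = rng.random(n) < n_frac
        seq[mask] = "N"
    return "".join(seq)
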