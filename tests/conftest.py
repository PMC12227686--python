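import numpy as np
import pandas as pd
import pytest

import polyscreen as ps


@pytest.fixture(scope="session")
def amplicon_design():
    return ps.example_amplicon_design(seed=11)


@pytest.fixture(scope="session")
def small_screen(amplicon_design):
    """A two-replicate screen with lethal stops at modest depth."""
    config = ps.ScreenSimConfig(
        codon_fitness=ps.neutral_fitness(lethal_stops=True),
        depth=4000,
        replicates=2,
        editing_fraction=0.6,
        seed=7,
    )
    return ps.simulate_screen(config, amplicon_design)


@pytest.fixture(scope="session")
def small_screen_counts(small_screen, amplicon_design):
    table, qc = ps.count_samples(small_screen.samples, amplicon_design)
    return table, qc


@pytest.fixture(scope="session")
def polycistrome():
    return ps.simulate_polycistrome(ps.GenomeSimConfig(n_polycistrons=40, seed=13))


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random CDS with no internal stops and a non-stop final codon."""
    stops = set(ps.STOP_CODONS)
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in stops:
            codons.append(c)
    return "".join(codons)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def simple_sites():
    """Two forward units in tandem on one chromosome."""
    tss = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [100, 10_000], "end": [101, 10_001],
         "name": ["TSS1", "TSS2"], "score": [0, 0], "strand": ["+", "+"]}
    )
    tts = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [8_000, 20_000], "end": [8_001, 20_001],
         "name": ["TTS1", "TTS2"], "score": [0, 0], "strand": ["+", "+"]}
    )
    return tss, tts
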