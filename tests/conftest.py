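from __future__ import annotations

import numpy as np
import pytest

from abtscore import make_synthetic_proteome

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def random_sequence(rng: np.random.Generator, length: int, alphabet: str = AMINO_ACIDS) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def random_track(rng: np.random.Generator, length: int) -> np.ndarray:
    """A disorder track with block structure so thresholded runs of many
    lengths occur, not just noise."""
    scores = np.empty(length)
    i = 0
    while i < length:
        span = int(rng.integers(1, 60))
        level = float(rng.uniform(0.0, 1.0))
        scores[i : i + span] = level
        i += span
    scores += rng.normal(0.0, 0.05, size=length)
    return np.clip(scores, 0.0, 1.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_101)


@pytest.fixture(scope="session")
def small_proteome(tmp_path_factory):
    """A 20-protein synthetic proteome with the default archetype mix."""
    outdir = tmp_path_factory.mktemp("proteome")
    fasta, tracks, manifest = make_synthetic_proteome(20, seed=7, outdir=outdir)
    return fasta, tracks, manifest
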