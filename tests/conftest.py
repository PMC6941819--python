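from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from endofilter.io import write_fasta
from endofilter.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20_240)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A small but complete simulated cohort shared across test modules."""
    cfg = SimulationConfig(
        seed=7,
        ref_len=80_000,
        n_palindromes=60,
        n_samples=3,
        n_artifact=30,
        n_genuine=10,
        depth=40,
    )
    return simulate_cohort(cfg, tmp_path_factory.mktemp("cohort"))


@pytest.fixture
def tiny_fasta(tmp_path):
    """One 80-base contig with a known hairpin (arm 3) centered at 1-based 41."""
    left = "ACGTACGTACGTACGTACGTACGTACGTACGTACGT"  # 36 bases
    arm5, center, arm3 = "TAC", "G", "GTA"  # arm3 = revcomp(arm5)
    right = "CCATGGCCATGGCCATGGCCATGGCCATGGCCATGG"[:36]
    seq = left + "A" + arm5 + center + arm3 + right  # center at 0-based index 40
    path = tmp_path / "ref.fa"
    write_fasta(path, {"chr1": seq})
    return path, seq
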