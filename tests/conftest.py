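import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from alignscan import (PlantSpec, build_frequency_table, generate_msa,
                       make_alignment, slice_ends)


@pytest.fixture
def dna4():
    """Four DNA sequences with one 2/2-split column (column 5, 0-based)."""
    return make_alignment([
        ("s1", "ACGTAAGGTACC"),
        ("s2", "ACGTAAGGTACC"),
        ("s3", "ACGTACGGTACC"),
        ("s4", "ACGTACGGTACC"),
    ])


@pytest.fixture
def protein3():
    return make_alignment([
        ("p1", "MKLVWPQRSTED"),
        ("p2", "MKLVWPQRSTED"),
        ("p3", "MKIVWPQRSTED"),
    ])


@pytest.fixture
def planted():
    """Standard synthetic scan fixture with ground truth."""
    spec = PlantSpec(
        nseq=8, length=500,
        blocks=((100, 106, 0.5, 2), (240, 250, 0.5, 2), (380, 395, 0.5, 2)),
        seed=11)
    return generate_msa(spec)


@pytest.fixture
def freq_table(dna4):
    return build_frequency_table(dna4, slice_ends(dna4))


def random_alignment(rng, nseq, length, alphabet="DNA", gap_rate=0.05):
    """Random gapped alignment for property tests."""
    pool = list("ACGT" if alphabet == "DNA" else "ACDEFGHIKLMNPQRSTVWY")
    rows = rng.choice(pool, size=(nseq, length))
    mask = rng.random((nseq, length)) < gap_rate
    rows[mask] = "-"
    # keep first and last two columns gap-free so slicing is a no-op
    for col in (0, 1, length - 2, length - 1):
        gappy = rows[:, col] == "-"
        rows[gappy, col] = rng.choice(pool, size=int(gappy.sum()))
    return make_alignment(
        [(f"r{i}", "".join(rows[i])) for i in range(nseq)],
        alphabet=alphabet)
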