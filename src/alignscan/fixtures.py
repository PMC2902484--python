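"""Synthetic MSA generation with known planted structure.

Generates alignments of closely related DNA sequences in which the
truth is known by construction: outside designated blocks all sequences
are identical; inside a block, each column independently receives a
planted variant with a given probability, the variant being one
alternative base assigned to at least ``min_variant_copies`` sequences
(so every planted column satisfies the two-copies putative-SNP rule).
Terminal gap wedges can be added to exercise end slicing.

This is deliberately *not* an evolutionary simulator: no substitution
model, no indel evolution — just the ingredients the scan pipeline's
assumptions are written in, with an exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa_io import GAP, Alignment, make_alignment


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for a synthetic alignment.

    blocks:
        ``(start, end, variant_fraction, min_variant_copies)`` tuples in
        0-based half-open column coordinates.  ``variant_fraction`` is
        the per-column probability that a variant is planted.
    gap_blocks:
        ``(side, depth)`` with side ``"LEFT"`` or ``"RIGHT"``: every
        column within ``depth`` of that end receives a gap in one
        sequence, so the gap-free core starts exactly past the wedge.
    """

    nseq: int
    length: int
    blocks: tuple[tuple[int, int, float, int], ...] = ()
    gap_blocks: tuple[tuple[str, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nseq < 2 or self.length < 1:
            raise FixtureError("need nseq >= 2 and length >= 1")
        for start, end, vf, copies in self.blocks:
            if not (0 <= start < end <= self.length):
                raise FixtureError(f"block [{start},{end}) out of range")
            if not 0.0 <= vf <= 1.0:
                raise FixtureError("variant_fraction must be in [0,1]")
            if copies > self.nseq - 2:
                raise FixtureError(
                    f"min_variant_copies={copies} infeasible for "
                    f"nseq={self.nseq} (needs <= nseq-2)")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a generated alignment."""

    blocks: tuple[tuple[int, int], ...]     # 0-based half-open intervals
    snp_columns: tuple[int, ...]            # 0-based planted variant columns
    core: tuple[int, int]                   # gap-free window after wedges


BASES = "ACGT"


def generate_msa(spec: PlantSpec) -> tuple[Alignment, GroundTruth]:
    """Deterministically generate an alignment and its ground truth.

    The first sequence is the reference row and never mutated.  In a
    planted column, one alternative base (uniform over the three
    non-reference bases) is assigned to a uniformly sized subset of the
    other rows — between ``min_variant_copies`` and ``(nseq-1)//2``
    sequences, so the reference base stays the plurality symbol.
    """
    rng = np.random.default_rng(spec.seed)
    ref = rng.choice(list(BASES), size=spec.length)
    rows = np.tile(ref, (spec.nseq, 1))

    snp_columns: list[int] = []
    for start, end, vf, copies in spec.blocks:
        hi = max(copies, (spec.nseq - 1) // 2)
        for col in range(start, end):
            if rng.random() >= vf:
                continue
            alt = rng.choice([b for b in BASES if b != ref[col]])
            size = int(rng.integers(copies, hi + 1))
            carriers = rng.choice(np.arange(1, spec.nseq), size=size,
                                  replace=False)
            rows[carriers, col] = alt
            if size >= 2:
                snp_columns.append(col)

    left = right = 0
    for side, depth in spec.gap_blocks:
        if depth >= spec.length // 2:
            raise FixtureError("gap wedge too deep for alignment length")
        cols = (range(depth) if side == "LEFT"
                else range(spec.length - depth, spec.length))
        for k, col in enumerate(cols):
            rows[1 + k % (spec.nseq - 1), col] = GAP
        if side == "LEFT":
            left = max(left, depth)
        else:
            right = max(right, depth)

    records = [(f"seq{r + 1}", "".join(rows[r])) for r in range(spec.nseq)]
    aln = make_alignment(records, alphabet="DNA")
    truth = GroundTruth(
        blocks=tuple((s, e) for s, e, _, _ in spec.blocks),
        snp_columns=tuple(sorted(snp_columns)),
        core=(left, spec.length - right),
    )
    return aln, truth
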