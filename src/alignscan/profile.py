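"""Alignment pre-processing: end slicing, column frequencies, reference track.

The analysis operates on a sliced window of the alignment (gappy ends
removed), a per-column symbol frequency table, and a single reference
symbol per column — the plurality consensus by default, or a
user-designated master sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .msa_io import GAP, Alignment


class ProfileError(ValueError):
    pass


@dataclass(frozen=True)
class SliceBounds:
    """Analysed column window, 0-based half-open."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ProfileError(f"invalid slice bounds [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start


def slice_ends(a: Alignment) -> SliceBounds:
    """Trim gappy alignment ends.

    Scanning inward from each end independently, the kept window starts
    at the first pair of contiguous entirely gap-free columns and ends
    after the last such pair.  Alignment ends are typically gap-rich and
    unreliable, so frequencies there would mislead the scores.
    """
    L = a.length
    gap_free = np.array(
        [GAP not in a.column(i) for i in range(L)], dtype=bool)
    pair_ok = gap_free[:-1] & gap_free[1:] if L >= 2 else np.zeros(0, bool)
    idx = np.nonzero(pair_ok)[0]
    if idx.size == 0:
        raise ProfileError(
            "alignment too gappy: no two contiguous gap-free columns")
    return SliceBounds(start=int(idx[0]), end=int(idx[-1]) + 2)


@dataclass(frozen=True)
class FrequencyTable:
    """Per-column symbol counts over the sliced window.

    ``counts[j, s]`` is the number of sequences carrying symbol
    ``symbols[s]`` at window column ``j`` (column ``bounds.start + j`` of
    the alignment).  The gap is an ordinary symbol class here; the
    scoring methods decide how to weight it.
    """

    counts: np.ndarray          # (width, nsymbols) int array
    symbols: tuple[str, ...]    # sorted, may include GAP
    nseq: int
    bounds: SliceBounds

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def distinct(self) -> np.ndarray:
        """D(i): number of distinct symbols per column (gap included)."""
        return (self.counts > 0).sum(axis=1)

    def column(self, j: int) -> dict[str, int]:
        return {s: int(c) for s, c in zip(self.symbols, self.counts[j])
                if c > 0}

    def count(self, j: int, symbol: str) -> int:
        try:
            return int(self.counts[j, self.symbols.index(symbol)])
        except ValueError:
            return 0

    @property
    def residue_symbols(self) -> tuple[str, ...]:
        return tuple(s for s in self.symbols if s != GAP)


def build_frequency_table(a: Alignment, bounds: SliceBounds) -> FrequencyTable:
    if bounds.end > a.length:
        raise ProfileError("slice bounds exceed alignment length")
    symbols = sorted({ch for _, seq in a.records
                      for ch in seq[bounds.start:bounds.end]})
    index = {s: k for k, s in enumerate(symbols)}
    counts = np.zeros((bounds.width, len(symbols)), dtype=np.int64)
    for _, seq in a.records:
        for j, ch in enumerate(seq[bounds.start:bounds.end]):
            counts[j, index[ch]] += 1
    return FrequencyTable(counts=counts, symbols=tuple(symbols),
                          nseq=a.nseq, bounds=bounds)


@dataclass(frozen=True)
class ReferenceTrack:
    """Reference symbol C(i) per window column: consensus or master row."""

    symbols: str
    mode: str                       # "CONSENSUS" | "MASTER"
    bounds: SliceBounds
    master_id: Optional[str] = None

    def __getitem__(self, j: int) -> str:
        return self.symbols[j]


def call_consensus(ft: FrequencyTable,
                   plurality_threshold: float = 0.0) -> ReferenceTrack:
    """Plurality consensus per column.

    Gaps are never eligible as the consensus symbol (an all-gap column
    yields the gap).  Ties break lexicographically.  A symbol must also
    reach ``plurality_threshold`` as a fraction of nseq (default 0:
    plain plurality).
    """
    out = []
    for j in range(ft.width):
        best, best_count = GAP, 0
        for s, c in zip(ft.symbols, ft.counts[j]):
            if s == GAP or c == 0:
                continue
            if c > best_count or (c == best_count and s < best):
                best, best_count = s, int(c)
        if best_count < plurality_threshold * ft.nseq:
            best = GAP
        out.append(best)
    return ReferenceTrack(symbols="".join(out), mode="CONSENSUS",
                          bounds=ft.bounds)


def select_reference(a: Alignment, ft: FrequencyTable,
                     master_id: Optional[str] = None,
                     plurality_threshold: float = 0.0) -> ReferenceTrack:
    """Master row (its own residues, gaps included) or consensus."""
    if master_id is None:
        return call_consensus(ft, plurality_threshold)
    try:
        seq = a.sequence(master_id)
    except KeyError:
        raise ProfileError(f"unknown master sequence {master_id!r}")
    return ReferenceTrack(symbols=seq[ft.bounds.start:ft.bounds.end],
                          mode="MASTER", bounds=ft.bounds,
                          master_id=master_id)
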