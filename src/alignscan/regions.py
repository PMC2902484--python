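"""Putative-SNP and conserved/divergent region calling.

Two branches read the same score track:

* SNPs come off the **raw** track: a DNA column is a putative SNP when
  its raw score falls below the low cutoff and every non-reference
  symbol present occurs in at least two sequences (so alignments of
  fewer than four sequences can never yield a SNP).
* Regions come off the **smoothed** track: maximal runs of columns
  below the low cutoff (divergent) or above the high cutoff
  (conserved).  DNA divergent regions must additionally contain at
  least two putative SNPs.  A region's characteristic score is the
  arithmetic mean of the raw scores it spans.

All user-facing coordinates are 1-based inclusive alignment columns;
SNP synonymy and effect prediction are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .msa_io import GAP
from .profile import FrequencyTable, ReferenceTrack
from .scoring import ScoreTrack
from .signal import CutoffPair, SmoothedTrack


class RegionError(ValueError):
    pass


@dataclass(frozen=True)
class PutativeSNP:
    """A variant alignment column (1-based) with its supporting counts."""

    column: int
    reference_symbol: str
    variants: dict[str, int]        # non-reference symbols only
    raw_score: float


@dataclass(frozen=True)
class Region:
    """A called conserved or divergent interval, 1-based inclusive."""

    start: int
    end: int
    kind: str                       # "CONSERVED" | "DIVERGENT"
    score: float                    # mean raw score over [start, end]
    snp_count: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise RegionError(f"invalid region {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def call_snps(raw: ScoreTrack, cut: CutoffPair, ft: FrequencyTable,
              ref: ReferenceTrack, alphabet: str = "DNA",
              allow_gap_variants: bool = True) -> list[PutativeSNP]:
    """Putative SNPs from the raw track (DNA alignments only).

    A column qualifies iff its raw score is strictly below the low
    cutoff, at least one non-reference symbol is present, and *every*
    non-reference symbol present has count >= 2.  With
    ``allow_gap_variants`` off, gap-only variation is ignored and gap
    counts are dropped from the variant map.
    """
    if alphabet != "DNA":
        raise RegionError("SNP calling is DNA-only")
    out: list[PutativeSNP] = []
    offset = ft.bounds.start
    for j in range(ft.width):
        if raw.values[j] >= cut.low:
            continue
        c = ref[j]
        variants = {s: n for s, n in ft.column(j).items() if s != c}
        if not allow_gap_variants:
            variants.pop(GAP, None)
        if not variants:
            continue
        if any(n < 2 for n in variants.values()):
            continue
        out.append(PutativeSNP(column=offset + j + 1, reference_symbol=c,
                               variants=variants,
                               raw_score=float(raw.values[j])))
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as 0-based half-open (start, end) pairs."""
    runs = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def extract_regions(smoothed: SmoothedTrack, raw: ScoreTrack,
                    cut: CutoffPair, snps: list[PutativeSNP],
                    alphabet: str = "DNA",
                    min_snps: int = 2,
                    min_length: int = 1) -> list[Region]:
    """Conserved/divergent regions from the smoothed track.

    Divergent candidates are maximal runs below the low cutoff;
    conserved candidates maximal runs above the high cutoff (none when
    the high cutoff is disabled).  DNA divergent candidates containing
    fewer than ``min_snps`` putative SNPs are discarded.
    """
    if smoothed.bounds != raw.bounds:
        raise RegionError("smoothed and raw tracks cover different bounds")
    offset = raw.bounds.start
    snp_cols = sorted(s.column for s in snps)
    out: list[Region] = []

    def emit(lo: int, hi: int, kind: str) -> None:
        start1 = offset + lo + 1
        end1 = offset + hi            # hi is exclusive window index
        if end1 - start1 + 1 < min_length:
            return
        n_snps = sum(start1 <= c <= end1 for c in snp_cols)
        if kind == "DIVERGENT" and alphabet == "DNA" and n_snps < min_snps:
            return
        score = float(np.mean(raw.values[lo:hi]))
        out.append(Region(start=start1, end=end1, kind=kind, score=score,
                          snp_count=n_snps))

    for lo, hi in _runs(smoothed.values < cut.low):
        emit(lo, hi, "DIVERGENT")
    if cut.high is not None:
        for lo, hi in _runs(smoothed.values > cut.high):
            emit(lo, hi, "CONSERVED")
    out.sort(key=lambda r: r.start)
    return out


#: Region length classes used in reporting.
def bucket_length(region_or_length) -> str:
    """SHORT (< 6 columns), MEDIUM (6-11) or LONG (> 11)."""
    n = (region_or_length.length if isinstance(region_or_length, Region)
         else int(region_or_length))
    if n < 6:
        return "SHORT"
    if n <= 11:
        return "MEDIUM"
    return "LONG"


@dataclass(frozen=True)
class RegionSummary:
    n_divergent: int
    n_conserved: int
    divergent_columns: int
    pct_divergent: float            # 100 * divergent columns / window length
    buckets: dict[str, int] = field(default_factory=dict)


def summarize(regions: list[Region], alignment_length: int) -> RegionSummary:
    """Counts and coverage of divergent regions over the analysed window."""
    divergent = [r for r in regions if r.kind == "DIVERGENT"]
    conserved = [r for r in regions if r.kind == "CONSERVED"]
    cols = sum(r.length for r in divergent)
    buckets = {"SHORT": 0, "MEDIUM": 0, "LONG": 0}
    for r in divergent:
        buckets[bucket_length(r)] += 1
    pct = 100.0 * cols / alignment_length if alignment_length else 0.0
    return RegionSummary(n_divergent=len(divergent),
                         n_conserved=len(conserved),
                         divergent_columns=cols,
                         pct_divergent=pct,
                         buckets=buckets)
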