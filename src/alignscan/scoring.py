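"""Per-column conservation/divergence scores.

Four scoring methods, all driven by the column frequency table so the
per-column cost is independent of the number of sequences:

``WEIGHTED``
    Mean substitution-matrix weight of the observed symbols against the
    reference symbol; positive for conserved columns, negative where the
    matrix penalises the observed differences.
``DNAW``
    Fraction of sequences matching the reference symbol (DNA only), the
    Weighted score with 1/0 identity weights; ranges over [0, 1].
``ENTROPY``
    Sign-switched Shannon entropy of the column's symbol frequencies in
    bits, so divergent columns score negative and uniform columns 0.
``VARIABILITY``
    ``1 - D(i)`` where D(i) counts distinct symbols: 0 for invariant
    columns, more negative as more symbol classes appear.

The formulas are documented reconstructions of the method's published
behaviour (the score ranges, signs and gap conventions); gaps score as
the lowest conservative substitution in Weighted and count as ordinary
symbol classes elsewhere.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .msa_io import GAP
from .profile import FrequencyTable, ReferenceTrack, SliceBounds


class ScoringError(ValueError):
    pass


class UnknownSymbolError(ScoringError):
    pass


METHODS = ("WEIGHTED", "DNAW", "ENTROPY", "VARIABILITY")

#: Expansions of IUPAC nucleotide ambiguity codes.
IUPAC_EXPANSION = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class WeightMatrix:
    """Symmetric substitution weights plus a gap penalty.

    ``gap_weight`` is the matrix minimum off-diagonal entry: a gap is
    treated as the lowest conservative substitution.
    """

    name: str
    weights: dict[tuple[str, str], float]
    gap_weight: float

    def get(self, b1: str, b2: str) -> float:
        if b1 == GAP or b2 == GAP:
            return self.gap_weight
        try:
            return self.weights[(b1, b2)]
        except KeyError:
            missing = b1 if (b1, b1) not in self.weights else b2
            raise UnknownSymbolError(
                f"symbol {missing!r} not covered by matrix {self.name!r}")


def _identity_core(match: float, mismatch: float) -> dict:
    w = {}
    for b1 in "ACGT":
        for b2 in "ACGT":
            w[(b1, b2)] = match if b1 == b2 else mismatch
    return w


def builtin_matrix(name: str, match: float = 5.0,
                   mismatch: float = -4.0) -> WeightMatrix:
    """Built-in weight matrices.

    ``IDENTITY_DNA``
        +5 match / -4 mismatch over {A,C,G,T} (the conventional
        nucleotide identity scheme; configurable).
    ``SIMPLE_DNA``
        The identity scheme extended to IUPAC ambiguity codes: an
        ambiguous symbol scores the mean of its expansion against the
        other symbol (both expanded when both are ambiguous).
    ``BLOSUM62``
        The standard published protein matrix.

    ``gap_weight`` is always the minimum off-diagonal entry.
    """
    key = name.upper()
    if key in ("IDENTITY", "IDENTITY_DNA"):
        w = _identity_core(match, mismatch)
        return WeightMatrix("IDENTITY_DNA", w, gap_weight=mismatch)
    if key in ("SIMPLE", "SIMPLE_DNA"):
        core = _identity_core(match, mismatch)
        symbols = list(IUPAC_EXPANSION)
        w = {}
        for b1, b2 in itertools.product(symbols, repeat=2):
            vals = [core[(x, y)]
                    for x in IUPAC_EXPANSION[b1]
                    for y in IUPAC_EXPANSION[b2]]
            w[(b1, b2)] = float(np.mean(vals))
        return WeightMatrix("SIMPLE_DNA", w, gap_weight=mismatch)
    if key == "BLOSUM62":
        blosum = substitution_matrices.load("BLOSUM62")
        w = {}
        offdiag = []
        for b1 in blosum.alphabet:
            for b2 in blosum.alphabet:
                if "*" in (b1, b2):
                    continue
                w[(b1, b2)] = float(blosum[b1, b2])
                if b1 != b2:
                    offdiag.append(float(blosum[b1, b2]))
        return WeightMatrix("BLOSUM62", w, gap_weight=min(offdiag))
    raise ScoringError(f"unknown matrix name {name!r}")


def load_matrix(path: str) -> WeightMatrix:
    """Load a custom symmetric matrix from a whitespace-delimited table.

    First row lists the symbols; each following row is a symbol followed
    by its weights against every column symbol.
    """
    with open(path) as fh:
        rows = [line.split() for line in fh
                if line.strip() and not line.startswith("#")]
    header = [s.upper() for s in rows[0]]
    w: dict[tuple[str, str], float] = {}
    for row in rows[1:]:
        b1 = row[0].upper()
        for b2, val in zip(header, row[1:]):
            w[(b1, b2)] = float(val)
    offdiag = [v for (a, b), v in w.items() if a != b]
    if not offdiag:
        raise ScoringError("matrix must cover at least two symbols")
    return WeightMatrix(name=path, weights=w, gap_weight=min(offdiag))


@dataclass(frozen=True)
class ScoreTrack:
    """Raw per-column scores X(i) for one method over the sliced window."""

    method: str
    values: np.ndarray
    bounds: SliceBounds

    def __post_init__(self) -> None:
        if len(self.values) != self.bounds.width:
            raise ScoringError("score track length does not match bounds")
        if not np.all(np.isfinite(self.values)):
            raise ScoringError("score track contains non-finite values")


def score_weighted(ft: FrequencyTable, ref: ReferenceTrack,
                   m: WeightMatrix) -> ScoreTrack:
    """Mean matrix weight of each column against the reference symbol.

    S(i) = (1/nseq) * sum_b gamma(i,b) * M(C(i), b), with gaps on either
    side scoring ``m.gap_weight``.
    """
    values = np.empty(ft.width)
    for j in range(ft.width):
        c = ref[j]
        total = 0.0
        for s, cnt in zip(ft.symbols, ft.counts[j]):
            if cnt:
                total += cnt * m.get(c, s)
        values[j] = total / ft.nseq
    return ScoreTrack("WEIGHTED", values, ft.bounds)


def _require_dna(ft: FrequencyTable) -> None:
    extra = set(ft.residue_symbols) - set("ACGT")
    if extra:
        raise ScoringError(
            "DNAW applies only to DNA sequences over {A,C,G,T}; "
            f"found symbols {sorted(extra)}")


def score_dnaw(ft: FrequencyTable, ref: ReferenceTrack) -> ScoreTrack:
    """Fraction of sequences matching the reference: gamma(i, C(i))/nseq."""
    _require_dna(ft)
    values = np.array([ft.count(j, ref[j]) / ft.nseq
                       for j in range(ft.width)])
    return ScoreTrack("DNAW", values, ft.bounds)


def score_entropy(ft: FrequencyTable, base: float = 2.0) -> ScoreTrack:
    """Sign-switched column entropy: S(i) = -H(i) <= 0, 0 iff uniform."""
    freqs = ft.counts / ft.nseq
    logf = np.zeros_like(freqs)
    np.log(freqs, out=logf, where=freqs > 0)
    values = (freqs * logf).sum(axis=1) / np.log(base)
    # a uniform column is exactly 0, not -0.0 noise
    values[ft.distinct == 1] = 0.0
    return ScoreTrack("ENTROPY", values, ft.bounds)


def score_variability(ft: FrequencyTable) -> ScoreTrack:
    """S(i) = 1 - D(i): any symbol change marks a difference."""
    values = (1 - ft.distinct).astype(float)
    return ScoreTrack("VARIABILITY", values, ft.bounds)


def compute_score(method: str, ft: FrequencyTable, ref: ReferenceTrack,
                  matrix: WeightMatrix | None = None) -> ScoreTrack:
    """Dispatch a scoring method by name."""
    key = method.upper()
    if key == "WEIGHTED":
        if matrix is None:
            matrix = (builtin_matrix("BLOSUM62")
                      if set(ft.residue_symbols) - set(IUPAC_EXPANSION)
                      else builtin_matrix("SIMPLE_DNA"))
        return score_weighted(ft, ref, matrix)
    if key == "DNAW":
        return score_dnaw(ft, ref)
    if key == "ENTROPY":
        return score_entropy(ft)
    if key == "VARIABILITY":
        return score_variability(ft)
    raise ScoringError(f"unknown scoring method {method!r}")
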