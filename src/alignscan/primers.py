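"""Primer windows over divergent regions and oligonucleotide grading.

A divergent region plus five nucleotides of flank on each side defines a
default primer window on the ungapped reference sequence.  Candidate
primers are then measured (length, GC%, melting temperature, 3'-end GC
clamp, repeats, self-dimer and hairpin free energies) and each property
graded PASS / WARN / FAIL against the usual oligo design rules:

* GC content between 40% and 60%,
* melting temperature above 52 degC,
* two to three G/C among the five 3'-terminal bases,
* no mononucleotide run >= 4 or dinucleotide motif repeated >= 4 times,
* dimer dG above -4 kcal/mol, hairpin dG above -3 kcal/mol.

Tm uses nearest-neighbor thermodynamics (unified parameters, 50 mM
monovalent salt, 500 nM primer) with a Wallace-rule fallback.  The
dimer/hairpin free energies are simplified nearest-neighbor stack sums
over perfect complementary stretches (no internal loops or bulges) —
adequate for threshold grading, not for duplex structure prediction.
Degenerate-primer design is deliberately not supported: windows are
graded against one specific reference sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional

from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp

from .msa_io import GAP
from .regions import Region


class PrimerError(ValueError):
    pass


IUPAC_DNA = set("ACGTURYSWKMBDHVN")

#: Unified nearest-neighbor stack free energies at 37 degC (kcal/mol),
#: keyed by the 5'->3' doublet of the top strand (bottom strand is its
#: complement).  SantaLucia (1998) unified parameter set.
NN_STACK_DG37 = {
    "AA": -1.00, "TT": -1.00,
    "AT": -0.88,
    "TA": -0.58,
    "CA": -1.45, "TG": -1.45,
    "GT": -1.44, "AC": -1.44,
    "CT": -1.28, "AG": -1.28,
    "GA": -1.30, "TC": -1.30,
    "CG": -2.17,
    "GC": -2.24,
    "GG": -1.84, "CC": -1.84,
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def reverse_complement(seq: str) -> str:
    """Reversed, base-complemented sequence (IUPAC codes allowed)."""
    s = seq.upper()
    bad = set(s) - IUPAC_DNA
    if bad:
        raise PrimerError(f"unrecognized nucleotide(s) {sorted(bad)}")
    return str(Seq(s).reverse_complement())


@dataclass(frozen=True)
class PrimerWindow:
    """A candidate primer interval on the ungapped reference sequence."""

    start: int                  # 1-based inclusive, ungapped coordinates
    end: int
    strand: str                 # "FORWARD" | "REVERSE"
    sequence: str               # ungapped; reverse-complemented if REVERSE


def default_window(r: Region, reference_row: str, flank: int = 5,
                   strand: str = "FORWARD") -> PrimerWindow:
    """Region plus ``flank`` nucleotides each side, on the ungapped reference.

    ``reference_row`` is the reference/master sequence *as aligned*
    (gaps included, full alignment coordinates); alignment columns are
    mapped to ungapped positions by skipping reference gaps, and the
    window is clamped to the sequence ends.
    """
    ungapped: list[str] = []
    col_to_pos: dict[int, int] = {}       # 1-based column -> 1-based position
    for col, ch in enumerate(reference_row, start=1):
        if ch != GAP:
            ungapped.append(ch)
            col_to_pos[col] = len(ungapped)
    positions = [col_to_pos[c] for c in range(r.start, r.end + 1)
                 if c in col_to_pos]
    if not positions:
        raise PrimerError(
            f"region {r.start}..{r.end} lies entirely within reference gaps")
    start = max(1, positions[0] - flank)
    end = min(len(ungapped), positions[-1] + flank)
    seq = "".join(ungapped[start - 1:end])
    if strand == "REVERSE":
        seq = reverse_complement(seq)
    return PrimerWindow(start=start, end=end, strand=strand, sequence=seq)


@dataclass(frozen=True)
class PrimerReport:
    """Measured primer properties plus per-property grade levels."""

    sequence: str
    length: int
    gc_pct: float
    tm_c: float
    gc3_count: int              # G/C among the 5 3'-terminal bases
    repeat_flag: bool
    dimer_dg: float             # kcal/mol, <= 0
    hairpin_dg: float           # kcal/mol, <= 0
    grades: dict[str, str] = field(default_factory=dict)

    @property
    def gc_pct_rounded(self) -> int:
        """GC% to the nearest integer, as printed in reports."""
        return round(self.gc_pct)


_MONO_RUN = re.compile(r"(.)\1{3,}")
_DI_RUN = re.compile(r"(..)\1{3}")


def _has_repeats(seq: str) -> bool:
    return bool(_MONO_RUN.search(seq) or _DI_RUN.search(seq))


def _stack_sum(top: str) -> float:
    """dG of a fully complementary duplex stretch given the top strand."""
    return sum(NN_STACK_DG37[top[i:i + 2]] for i in range(len(top) - 1))


def dimer_dg(seq: str) -> float:
    """Minimum self-dimer free energy over all antiparallel offsets.

    For each ungapped offset of the primer against a second copy of
    itself (antiparallel), every perfectly paired stretch is scored as a
    nearest-neighbor stack sum, and the most negative stretch across all
    offsets is returned (0 if nothing pairs).  Stretches interrupted by
    mismatches are scored separately rather than summed, since the
    simplified model carries no internal-loop penalty to join them.
    """
    n = len(seq)
    rev = seq[::-1]
    best = 0.0
    for offset in range(-(n - 1), n):
        run: list[int] = []
        for i in range(n):
            j = i + offset
            paired = (0 <= j < n and _COMPLEMENT[seq[i]] == rev[j])
            if paired:
                run.append(i)
            if (not paired or i == n - 1) and len(run) >= 2:
                best = min(best, _stack_sum(seq[run[0]:run[-1] + 1]))
            if not paired:
                run = []
    return best


def hairpin_dg(seq: str, min_loop: int = 3) -> float:
    """Minimum hairpin free energy over all stems with loop >= ``min_loop``.

    Stems are perfect complementary runs folding the sequence back on
    itself; stack dG is summed along the stem.
    """
    n = len(seq)
    best = 0.0
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            if _COMPLEMENT[seq[i]] != seq[j]:
                continue
            # grow the stem inward from the outermost pair (i, j)
            dg = 0.0
            k = 0
            while ((j - k - 1) - (i + k + 1) - 1 >= min_loop
                   and _COMPLEMENT[seq[i + k + 1]] == seq[j - k - 1]):
                dg += NN_STACK_DG37[seq[i + k:i + k + 2]]
                k += 1
            best = min(best, dg)
    return best


def evaluate_primer(seq: str, salt_mM: float = 50.0,
                    primer_nM: float = 500.0,
                    tm_method: str = "nn") -> PrimerReport:
    """Measure a primer's design-relevant properties (grades not filled)."""
    s = seq.upper()
    if not s:
        raise PrimerError("empty primer sequence")
    bad = set(s) - set("ACGT")
    if bad:
        raise PrimerError(
            f"primer contains non-ACGT character(s) {sorted(bad)}")
    n = len(s)
    gc = s.count("G") + s.count("C")
    if tm_method == "nn":
        tm = float(MeltingTemp.Tm_NN(s, Na=salt_mM, dnac1=primer_nM,
                                     dnac2=0.0))
    elif tm_method == "wallace":
        tm = float(MeltingTemp.Tm_Wallace(s))
    else:
        raise PrimerError(f"unknown Tm method {tm_method!r}")
    tail = s[-5:]
    return PrimerReport(
        sequence=s,
        length=n,
        gc_pct=100.0 * gc / n,
        tm_c=tm,
        gc3_count=tail.count("G") + tail.count("C"),
        repeat_flag=_has_repeats(s),
        dimer_dg=dimer_dg(s),
        hairpin_dg=hairpin_dg(s),
    )


#: Default WARN margins around each PASS threshold.
GRADE_MARGINS = {"gc": 2.0, "tm": 1.0, "dimer": 0.5, "hairpin": 0.5}


def grade(rep: PrimerReport,
          margins: Optional[dict[str, float]] = None) -> PrimerReport:
    """Fill per-property PASS / WARN / FAIL grades.

    PASS thresholds: 40 <= GC% <= 60 (boundaries pass); Tm > 52 degC;
    2-3 G/C in the 3' clamp; dimer dG > -4 and hairpin dG > -3 kcal/mol;
    no repeats.  Values outside a threshold but within its WARN margin
    grade WARN, further out FAIL.
    """
    m = dict(GRADE_MARGINS)
    if margins:
        m.update(margins)
    g: dict[str, str] = {}

    def band(ok: bool, near: bool) -> str:
        return "PASS" if ok else ("WARN" if near else "FAIL")

    g["gc"] = band(40.0 <= rep.gc_pct <= 60.0,
                   40.0 - m["gc"] <= rep.gc_pct <= 60.0 + m["gc"])
    g["tm"] = band(rep.tm_c > 52.0, rep.tm_c > 52.0 - m["tm"])
    g["clamp"] = band(2 <= rep.gc3_count <= 3,
                      1 <= rep.gc3_count <= 4)
    g["repeats"] = "PASS" if not rep.repeat_flag else "FAIL"
    g["dimer"] = band(rep.dimer_dg > -4.0, rep.dimer_dg > -4.0 - m["dimer"])
    g["hairpin"] = band(rep.hairpin_dg > -3.0,
                        rep.hairpin_dg > -3.0 - m["hairpin"])
    return replace(rep, grades=g)
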