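"""Alignment input/output.

Reads multiple sequence alignments in the five common text formats
(FASTA, Clustal, PHYLIP, MSF, NEXUS), identifying the format from the
file *contents* rather than the file name, and writes the analysis
results as GFF3, TSV or a versioned JSON bundle.

Parsing is delegated to :mod:`Bio.AlignIO`; this module adds content
sniffing, validation (equal lengths, >=2 sequences, recognised residue
symbols) and normalisation (upper case, ``.`` gaps rewritten to ``-``).
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"

#: IUPAC nucleotide symbols (unambiguous + ambiguity codes).
DNA_SYMBOLS = frozenset("ACGTUNRYSWKMBDHV")
#: Amino acid symbols (20 standard + ambiguity/rare codes).
PROTEIN_SYMBOLS = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO")

#: Fraction of non-gap characters that must look like nucleotides for an
#: alignment to be classed as DNA.
DNA_FRACTION_THRESHOLD = 0.90


class AlignmentError(ValueError):
    """Base class for alignment loading/validation failures."""


class UnknownFormatError(AlignmentError):
    """Raised when no known format signature matches the content."""


class RaggedAlignmentError(AlignmentError):
    """Raised when sequences in an alignment have unequal lengths."""


@dataclass(frozen=True)
class Alignment:
    """A validated, normalised multiple sequence alignment.

    Attributes
    ----------
    records:
        Ordered ``(identifier, residues)`` pairs.  Residues are upper
        case; the gap symbol is ``-``.
    alphabet:
        ``"DNA"`` or ``"PROTEIN"``, auto-detected on load.
    """

    records: tuple[tuple[str, str], ...]
    alphabet: str

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def nseq(self) -> int:
        return len(self.records)

    @property
    def identifiers(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.records)

    def sequence(self, identifier: str) -> str:
        for name, seq in self.records:
            if name == identifier:
                return seq
        raise KeyError(f"no sequence named {identifier!r} in alignment")

    def column(self, i: int) -> str:
        """Residues of column ``i`` (0-based), one per sequence."""
        return "".join(seq[i] for _, seq in self.records)


def make_alignment(records: Iterable[tuple[str, str]],
                   alphabet: Optional[str] = None) -> Alignment:
    """Normalise and validate raw records into an :class:`Alignment`."""
    normed = tuple((name, seq.upper().replace(".", GAP))
                   for name, seq in records)
    if len(normed) < 2:
        raise AlignmentError(
            f"an alignment needs at least 2 sequences, got {len(normed)}")
    lengths = {len(seq) for _, seq in normed}
    if len(lengths) != 1:
        raise RaggedAlignmentError(
            f"unequal sequence lengths: {sorted(lengths)}")
    if lengths == {0}:
        raise AlignmentError("alignment has zero columns")
    names = [name for name, _ in normed]
    if len(set(names)) != len(names) or any(not n for n in names):
        raise AlignmentError("sequence identifiers must be unique and non-empty")
    if alphabet is None:
        alphabet = detect_alphabet(seq for _, seq in normed)
    allowed = (DNA_SYMBOLS if alphabet == "DNA" else PROTEIN_SYMBOLS) | {GAP}
    for name, seq in normed:
        bad = set(seq) - allowed
        if bad:
            raise AlignmentError(
                f"unrecognized residue symbol(s) {sorted(bad)} in {name!r}")
    return Alignment(records=normed, alphabet=alphabet)


def detect_alphabet(records: Iterable[str],
                    threshold: float = DNA_FRACTION_THRESHOLD) -> str:
    """Classify sequences as DNA or protein.

    DNA iff the fraction of non-gap characters that are IUPAC nucleotide
    symbols exceeds ``threshold`` (case-insensitive).
    """
    total = 0
    dna_like = 0
    for seq in records:
        for ch in seq.upper():
            if ch in (GAP, "."):
                continue
            total += 1
            if ch in DNA_SYMBOLS:
                dna_like += 1
    if total == 0:
        raise AlignmentError("cannot detect alphabet of an all-gap alignment")
    return "DNA" if dna_like / total > threshold else "PROTEIN"


# ---------------------------------------------------------------------------
# Format sniffing and reading
# ---------------------------------------------------------------------------

def sniff_format(text: str) -> Optional[str]:
    """Identify the alignment format from content signatures.

    Returns one of ``fasta``, ``clustal``, ``nexus``, ``msf``, ``phylip``
    or ``None`` when no signature matches.  The file name plays no role.
    """
    stripped = text.lstrip()
    if not stripped:
        return None
    first = stripped.splitlines()[0].strip()
    if stripped[:6].upper() == "#NEXUS":
        return "nexus"
    if first.upper().startswith(("CLUSTAL", "MUSCLE (")):
        return "clustal"
    head = "\n".join(text.splitlines()[:40])
    if "MSF:" in head and ".." in head:
        return "msf"
    if stripped.startswith(">"):
        return "fasta"
    parts = first.split()
    if len(parts) == 2 and all(p.isdigit() for p in parts):
        return "phylip"
    return None


def _parse_with(text: str, fmt: str) -> MultipleSeqAlignment:
    if fmt == "phylip":
        # Cover relaxed/strict interleaved and sequential dialects.
        last: Exception | None = None
        for dialect in ("phylip-relaxed", "phylip", "phylip-sequential"):
            try:
                return AlignIO.read(io.StringIO(text), dialect)
            except Exception as exc:  # noqa: BLE001 - collected and re-raised
                last = exc
        raise UnknownFormatError(f"could not parse PHYLIP content: {last}")
    return AlignIO.read(io.StringIO(text), fmt)


def read_alignment(source, format_hint: Optional[str] = None) -> Alignment:
    """Read an alignment from a path, file object or text.

    The format is determined by content signatures; ``format_hint`` is
    only consulted when sniffing is inconclusive, so a misleading hint
    cannot misparse a recognisable file.

    Raises
    ------
    UnknownFormatError
        for faulty, corrupted or unknown file content.
    RaggedAlignmentError
        when sequences have unequal lengths.
    """
    if hasattr(source, "read"):
        text = source.read()
        if isinstance(text, bytes):
            text = text.decode("utf-8", errors="replace")
    elif isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source, "r", encoding="utf-8", errors="replace") as fh:
            text = fh.read()
    else:
        text = str(source)
    if not text.strip():
        raise UnknownFormatError("empty input")
    fmt = sniff_format(text)
    if fmt is None:
        fmt = format_hint.lower() if format_hint else None
    if fmt is None:
        raise UnknownFormatError(
            "unrecognized format: no known alignment signature found")
    try:
        msa = _parse_with(text, fmt)
    except UnknownFormatError:
        raise
    except Exception as exc:
        msg = str(exc)
        if "same length" in msg or "length" in msg.lower() and fmt == "fasta":
            raise RaggedAlignmentError(f"unequal sequence lengths: {msg}")
        raise UnknownFormatError(f"corrupt {fmt} content: {msg}")
    return make_alignment((rec.id, str(rec.seq)) for rec in msa)


def _to_biopython(a: Alignment) -> MultipleSeqAlignment:
    return MultipleSeqAlignment(
        SeqRecord(Seq(seq), id=name, description="") for name, seq in a.records)


def write_alignment(a: Alignment, fmt: str = "fasta") -> str:
    """Render an alignment as FASTA or Clustal text."""
    out = io.StringIO()
    AlignIO.write(_to_biopython(a), out, fmt)
    return out.getvalue()


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_TYPES = {"DIVERGENT": "divergent_region", "CONSERVED": "conserved_region"}


def write_gff(regions, snps, landmark: str, source_tag: str = "alignscan",
              alignment_length: Optional[int] = None) -> str:
    """Render called regions and putative SNPs as a GFF3 document.

    Coordinates are 1-based inclusive, as GFF3 requires; features must
    lie within ``[1, alignment_length]`` when a length is given.
    """
    lines = ["##gff-version 3"]
    if alignment_length is not None:
        lines.append(f"##sequence-region {landmark} 1 {alignment_length}")

    def check(start: int, end: int) -> None:
        if start < 1 or start > end:
            raise ValueError(f"invalid feature interval {start}..{end}")
        if alignment_length is not None and end > alignment_length:
            raise ValueError(
                f"feature {start}..{end} exceeds alignment length "
                f"{alignment_length}")

    counter = 0
    for r in regions:
        check(r.start, r.end)
        counter += 1
        ftype = _GFF_TYPES[r.kind]
        attrs = (f"ID=region{counter};length={r.length}"
                 f";snp_count={r.snp_count}")
        lines.append("\t".join([
            landmark, source_tag, ftype, str(r.start), str(r.end),
            f"{r.score:.3f}", ".", ".", attrs]))
    for s in snps:
        check(s.column, s.column)
        counter += 1
        variants = ",".join(f"{b}:{c}" for b, c in sorted(s.variants.items()))
        attrs = (f"ID=snp{counter};reference={s.reference_symbol}"
                 f";variants={variants}")
        lines.append("\t".join([
            landmark, source_tag, "sequence_variant", str(s.column),
            str(s.column), f"{s.raw_score:.3f}", ".", ".", attrs]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# JSON bundle (versioned schema, extensible via a type registry)
# ---------------------------------------------------------------------------

_SCHEMA_ALIGNMENT = "alignscan/alignment/1"

#: schema tag -> (matches(obj), encode(obj) -> dict, decode(dict) -> obj)
_JSON_TYPES: dict[str, tuple[Callable, Callable, Callable]] = {}


def register_json_type(schema: str, matches: Callable, encode: Callable,
                       decode: Callable) -> None:
    _JSON_TYPES[schema] = (matches, encode, decode)


register_json_type(
    _SCHEMA_ALIGNMENT,
    lambda obj: isinstance(obj, Alignment),
    lambda a: {"alphabet": a.alphabet,
               "records": [[name, seq] for name, seq in a.records]},
    lambda d: make_alignment(((name, seq) for name, seq in d["records"]),
                             alphabet=d["alphabet"]),
)


def to_json(obj, indent: Optional[int] = None) -> str:
    """Serialise a registered object (alignment or results bundle)."""
    for schema, (matches, encode, _) in _JSON_TYPES.items():
        if matches(obj):
            doc = {"schema": schema}
            doc.update(encode(obj))
            return json.dumps(doc, indent=indent, sort_keys=True)
    raise TypeError(f"no JSON schema registered for {type(obj).__name__}")


def from_json(text: str):
    """Inverse of :func:`to_json`; round-trips field by field."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed JSON document: {exc}")
    schema = doc.get("schema")
    if schema not in _JSON_TYPES:
        raise ValueError(f"unknown JSON schema tag: {schema!r}")
    return _JSON_TYPES[schema][2](doc)
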