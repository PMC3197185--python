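"""Nucleotide and peptide sequence primitives.

Reverse complementation, per-frame conceptual translation, and extraction of
stop-delimited amino-acid segments from all six reading frames.  These are
the building blocks for turning an assembled transcriptome into a protein
search database: every transcript is translated in frames +1..+3 (forward)
and -1..-3 (reverse complement), the translations are split at stop codons,
and segments long enough to yield searchable tryptic peptides become
database entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqIO import SeqRecord

FRAMES = (1, 2, 3, -1, -2, -3)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Standard genetic code (NCBI table 1) with explicit stop codons. Codons
# containing N translate to 'X' unconditionally — degenerate codons are
# never resolved even when unambiguous, so translation depends only on
# called bases.
_TABLE1 = unambiguous_dna_by_id[1]
_CODON_TABLE: dict[str, str] = dict(_TABLE1.forward_table)
_CODON_TABLE.update({codon: "*" for codon in _TABLE1.stop_codons})

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class Transcript:
    """One assembled transcript (isoform) from a de novo assembly."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        _validate_nt(self.sequence)
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FrameTranslation:
    """Conceptual translation of one reading frame.

    ``frame`` is one of +1, +2, +3 (forward, offsets 0/1/2) or -1, -2, -3
    (same offsets on the reverse complement).  ``aa_sequence`` includes stop
    symbols '*' and 'X' for codons with uncalled bases.
    """

    frame: int
    aa_sequence: str


def _validate_nt(sequence: str) -> None:
    for pos, base in enumerate(sequence):
        if base.upper() not in _VALID_BASES:
            raise ValueError(
                f"invalid nucleotide {base!r} at position {pos} "
                f"(expected one of A, C, G, T, N)"
            )


def reverse_complement(sequence: str) -> str:
    """Reverse-complement a nucleotide sequence; N maps to N.

    Involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    _validate_nt(sequence)
    return sequence.translate(_COMPLEMENT)[::-1]


def _frame_offset(frame: int) -> int:
    if frame not in FRAMES:
        raise ValueError(f"invalid frame {frame!r}; expected one of {FRAMES}")
    return abs(frame) - 1


def translate_frame(sequence: str, frame: int) -> FrameTranslation:
    """Translate one reading frame with the standard genetic code.

    Negative frames translate the reverse complement.  The trailing partial
    codon is dropped; stop codons render as '*'; any codon containing an N
    yields 'X'.
    """
    offset = _frame_offset(frame)
    nt = sequence.upper()
    _validate_nt(nt)
    if frame < 0:
        nt = nt.translate(_COMPLEMENT)[::-1]
    nt = nt[offset:]
    aa = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        aa.append(_CODON_TABLE.get(codon, "X"))
    return FrameTranslation(frame=frame, aa_sequence="".join(aa))


def _split_segments(
    aa_sequence: str, min_len: int, max_x_fraction: float
) -> Iterator[tuple[int, str]]:
    """Yield (1-based aa start, segment) for stop-free runs of min length.

    Segments consisting of more than ``max_x_fraction`` 'X' residues are
    dropped: runs of uncalled bases cannot yield informative peptides.
    """
    start = 0
    for seg in aa_sequence.split("*"):
        if len(seg) >= min_len:
            if seg.count("X") <= max_x_fraction * len(seg):
                yield start + 1, seg
        start += len(seg) + 1


def six_frame_segments(
    transcript: Transcript, min_len: int = 7, max_x_fraction: float = 0.5
) -> list[tuple[int, int, str]]:
    """Stop-delimited amino-acid segments from all six reading frames.

    Returns (frame, start_aa, segment) tuples in frame order +1, +2, +3,
    -1, -2, -3, then by position within the frame.  ``start_aa`` is the
    1-based amino-acid position within the frame translation.  Segments
    shorter than ``min_len`` or consisting of more than ``max_x_fraction``
    'X' are excluded; no segment contains '*'.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    out: list[tuple[int, int, str]] = []
    for frame in FRAMES:
        aa = translate_frame(transcript.sequence, frame).aa_sequence
        for start, seg in _split_segments(aa, min_len, max_x_fraction):
            out.append((frame, start, seg))
    return out


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file as (header, sequence) pairs.

    The header is everything after '>' on the defline, whitespace included.
    """
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.description, str(rec.seq)))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    """Write (header, sequence) pairs as wrapped 60-column FASTA."""
    from Bio import SeqIO

    # id = first token, description = full header: the writer then emits the
    # header verbatim after '>'
    seq_records = (
        SeqRecord(Seq(seq), id=header.split()[0] if header.split() else "seq",
                  description=header)
        for header, seq in records
    )
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(seq_records)
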