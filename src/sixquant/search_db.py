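"""Concatenated target/decoy/contaminant protein search database assembly.

Targets are the six-frame stop-delimited segments of the annotated
transcriptome; decoys are whole-sequence reversals (one per target and per
contaminant, giving an exact 1:1 decoy:target ratio for FDR estimation);
contaminants are commonly observed background proteins (cRAP: keratins,
trypsin, ...) appended so that their peptides are not falsely assigned to
biological proteins.  Entry order is deterministic so the database is
reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Optional

from sixquant.annotation import AnnotatedTranscript
from sixquant.seq_core import FRAMES, read_fasta, six_frame_segments, write_fasta

logger = logging.getLogger(__name__)

DECOY_PREFIX = "REV_"
CONTAMINANT_PREFIX = "CONT_"

Category = Literal["target", "decoy", "contaminant"]


@dataclass(frozen=True)
class ProteinEntry:
    """One database sequence: a target segment, a decoy, or a contaminant."""

    entry_id: str
    header: str
    aa_sequence: str
    category: Category
    source_transcript: Optional[str] = None
    frame: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.aa_sequence:
            raise ValueError(f"empty sequence for entry {self.entry_id!r}")
        if "*" in self.aa_sequence:
            raise ValueError(f"stop symbol in entry {self.entry_id!r}")
        if self.category == "decoy" and not self.entry_id.startswith(DECOY_PREFIX):
            raise ValueError(
                f"decoy entry id must start with {DECOY_PREFIX!r}: {self.entry_id!r}"
            )

    @property
    def length(self) -> int:
        return len(self.aa_sequence)


def build_target_db(
    annotated: Iterable[AnnotatedTranscript],
    min_len: int = 7,
    annotated_only: bool = False,
) -> list[ProteinEntry]:
    """One target entry per six-frame segment passing ``min_len``.

    Entry ids follow ``<final_header>|frame=<f>|seg=<n>`` with segments
    numbered per transcript in frame order +1..+3, -1..-3 then position.
    With ``annotated_only`` transcripts lacking a qualifying hit are
    skipped; by default they are retained under their assembly-id headers.
    """
    entries: list[ProteinEntry] = []
    for a in annotated:
        if annotated_only and not a.annotated:
            continue
        frame_order = {f: i for i, f in enumerate(FRAMES)}
        segments = sorted(
            six_frame_segments(a.transcript, min_len=min_len),
            key=lambda s: (frame_order[s[0]], s[1]),
        )
        for n, (frame, _start, seg) in enumerate(segments, start=1):
            frame_str = f"{frame:+d}"
            entry_id = f"{a.header}|frame={frame_str}|seg={n}"
            entries.append(
                ProteinEntry(
                    entry_id=entry_id,
                    header=entry_id,
                    aa_sequence=seg,
                    category="target",
                    source_transcript=a.transcript.id,
                    frame=frame,
                )
            )
    return entries


def make_decoys(targets: Iterable[ProteinEntry]) -> list[ProteinEntry]:
    """One reversed-sequence decoy per target/contaminant entry.

    Reversal preserves amino-acid composition and length, so decoy matches
    model chance matches at the same score scale.  Self-identical
    (palindromic) decoys are logged.
    """
    decoys: list[ProteinEntry] = []
    for entry in targets:
        if entry.category == "decoy":
            raise ValueError(f"refusing to decoy a decoy entry: {entry.entry_id!r}")
        rev = entry.aa_sequence[::-1]
        if rev == entry.aa_sequence:
            logger.warning(
                "decoy of %s is identical to its source (palindromic sequence)",
                entry.entry_id,
            )
        decoys.append(
            ProteinEntry(
                entry_id=DECOY_PREFIX + entry.entry_id,
                header=DECOY_PREFIX + entry.header,
                aa_sequence=rev,
                category="decoy",
                source_transcript=entry.source_transcript,
                frame=entry.frame,
            )
        )
    return decoys


def append_contaminants(
    db: list[ProteinEntry], contaminants_fasta
) -> list[ProteinEntry]:
    """Append contaminant (cRAP) entries with ``CONT_``-prefixed headers."""
    existing = {e.header for e in db}
    out = list(db)
    for header, seq in read_fasta(contaminants_fasta):
        final = CONTAMINANT_PREFIX + header
        if final in existing or header in existing:
            raise ValueError(f"contaminant header collides with database: {header!r}")
        existing.add(final)
        out.append(
            ProteinEntry(
                entry_id=final.split()[0],
                header=final,
                aa_sequence=seq.upper(),
                category="contaminant",
            )
        )
    return out


def assemble_db(
    annotated: Iterable[AnnotatedTranscript],
    contaminants_fasta=None,
    min_len: int = 7,
    annotated_only: bool = False,
) -> list[ProteinEntry]:
    """Full database: targets, contaminants, then decoys of both."""
    db = build_target_db(annotated, min_len=min_len, annotated_only=annotated_only)
    if contaminants_fasta is not None:
        db = append_contaminants(db, contaminants_fasta)
    db = db + make_decoys(db)
    counts = {}
    for e in db:
        counts[e.category] = counts.get(e.category, 0) + 1
    logger.info("assembled database: %s", counts)
    return db


def write_concatenated_db(entries: list[ProteinEntry], path) -> None:
    """Write the database as one FASTA: targets, contaminants, then decoys."""
    order = {"target": 0, "contaminant": 1, "decoy": 2}
    idx = sorted(range(len(entries)), key=lambda i: (order[entries[i].category], i))
    if not entries:
        warnings.warn(f"writing empty database to {path}")
    write_fasta(((entries[i].header, entries[i].aa_sequence) for i in idx), path)


def read_db(path) -> list[ProteinEntry]:
    """Read a concatenated database FASTA back into entries.

    Category is recovered from the header prefix (``REV_`` decoy, ``CONT_``
    contaminant, otherwise target); target provenance is recovered from the
    ``|frame=`` entry-id convention when present.
    """
    entries = []
    for header, seq in read_fasta(path):
        if header.startswith(DECOY_PREFIX):
            category: Category = "decoy"
        elif header.startswith(CONTAMINANT_PREFIX):
            category = "contaminant"
        else:
            category = "target"
        entry_id = header if "|frame=" in header else header.split()[0]
        frame = None
        source = None
        if "|frame=" in header:
            for p in header.split("|")[1:]:
                if p.startswith("frame="):
                    frame = int(p[len("frame="):])
        entries.append(
            ProteinEntry(
                entry_id=entry_id,
                header=header,
                aa_sequence=seq,
                category=category,
                source_transcript=source,
                frame=frame,
            )
        )
    return entries
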