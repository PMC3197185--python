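"""BLAST best-hit annotation transfer onto assembled transcripts.

Parses tabular (outfmt-6-style) BLAST results, selects the best hit per
transcript under an E-value significance rule (default E < 1e-03), rewrites
transcript FASTA headers with the best hit's header, and deduplicates
redundant headers by appending ascending numbers — several isoforms can
share a top hit, and downstream search engines reject duplicate deflines.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from sixquant.seq_core import Transcript

#: outfmt-6 canonical column order
BLAST6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

DEFAULT_MAX_EVALUE = 1e-3


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    subject_title: str
    percent_identity: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue} for {self.query_id}")
        if not math.isfinite(self.bitscore):
            raise ValueError(f"non-finite bitscore for {self.query_id}")


@dataclass
class AnnotatedTranscript:
    """A transcript carrying its final (possibly transferred) header."""

    transcript: Transcript
    header: str
    annotated: bool
    best_hit: Optional[BlastHit] = None


def parse_blast_tab(stream: Iterable[str]) -> list[BlastHit]:
    """Parse tabular BLAST output (outfmt 6, >= 12 columns).

    Lines beginning '#' are skipped.  An optional 13th column is taken as
    the subject title (outfmt "6 std stitle").  Raises ValueError naming the
    line number on a short line or an unparseable numeric field.
    """
    hits: list[BlastHit] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ValueError(
                f"line {lineno}: expected >=12 tab-separated fields, "
                f"got {len(fields)}"
            )
        try:
            pident = float(fields[2])
            evalue = float(fields[10])
            bitscore = float(fields[11])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: unparseable numeric field: {exc}")
        hits.append(
            BlastHit(
                query_id=fields[0],
                subject_id=fields[1],
                subject_title=fields[12] if len(fields) > 12 else "",
                percent_identity=pident,
                evalue=evalue,
                bitscore=bitscore,
            )
        )
    return hits


def best_hit(
    hits: Iterable[BlastHit], max_evalue: float = DEFAULT_MAX_EVALUE
) -> Optional[BlastHit]:
    """Best hit for one query: minimum E-value strictly below ``max_evalue``.

    Ties on E-value are broken by higher bitscore, then lexicographically
    smallest subject_id, making the result independent of input order.
    Returns None when no hit qualifies.
    """
    hits = list(hits)
    if not hits:
        return None
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")
    qualifying = [h for h in hits if h.evalue < max_evalue]
    if not qualifying:
        return None
    return min(qualifying, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))


def best_hits_by_query(
    hits: Iterable[BlastHit], max_evalue: float = DEFAULT_MAX_EVALUE
) -> dict[str, BlastHit]:
    """Group hits by query and select the best qualifying hit for each."""
    by_query: dict[str, list[BlastHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out: dict[str, BlastHit] = {}
    for query, query_hits in by_query.items():
        bh = best_hit(query_hits, max_evalue)
        if bh is not None:
            out[query] = bh
    return out


def _hit_header(hit: BlastHit) -> str:
    if hit.subject_title:
        return f"{hit.subject_id} {hit.subject_title}"
    return hit.subject_id


def annotate_headers(
    transcripts: Iterable[Transcript],
    best_hits: Mapping[str, BlastHit],
) -> list[AnnotatedTranscript]:
    """Transfer best-hit headers onto transcripts and deduplicate.

    Annotated transcripts take ``subject_id + " " + subject_title`` (or the
    subject_id alone when the tabular input carried no titles); transcripts
    with no qualifying hit keep their assembly id.  Duplicate headers get
    ascending-number suffixes: the first occurrence is unchanged, the k-th
    duplicate becomes ``<header>_k`` with k starting at 2.
    """
    seen: Counter[str] = Counter()
    out: list[AnnotatedTranscript] = []
    for t in transcripts:
        hit = best_hits.get(t.id)
        header = _hit_header(hit) if hit is not None else t.id
        seen[header] += 1
        if seen[header] > 1:
            final = f"{header}_{seen[header]}"
        else:
            final = header
        out.append(
            AnnotatedTranscript(
                transcript=t,
                header=final,
                annotated=hit is not None,
                best_hit=hit,
            )
        )
    return out


def annotation_summary(annotated: Iterable[AnnotatedTranscript]) -> dict:
    """Annotation counts and percentages.

    ``percent_annotated`` is over all transcripts; ``percent_evalue_zero``
    (hits scored E = 0.0, the best possible alignments) is over annotated
    transcripts.  Percentages are rounded to one decimal.
    """
    annotated = list(annotated)
    n_total = len(annotated)
    n_annotated = sum(1 for a in annotated if a.annotated)
    n_zero = sum(
        1 for a in annotated if a.best_hit is not None and a.best_hit.evalue == 0.0
    )
    return summary_from_counts(n_total, n_annotated, n_zero)


def summary_from_counts(n_total: int, n_annotated: int, n_evalue_zero: int) -> dict:
    """Summary percentages from raw counts (also usable on published counts)."""
    return {
        "n_total": n_total,
        "n_annotated": n_annotated,
        "n_evalue_zero": n_evalue_zero,
        "percent_annotated": percentage(n_annotated, n_total),
        "percent_evalue_zero": percentage(n_evalue_zero, n_annotated),
    }


def percentage(part: int, whole: int, ndigits: int = 1) -> float:
    """part/whole as a percentage rounded to ``ndigits`` decimals; 0 if whole==0."""
    if whole == 0:
        return 0.0
    return round(100.0 * part / whole, ndigits)


def write_header_map(annotated: Iterable[AnnotatedTranscript], path) -> None:
    """TSV sidecar mapping original transcript ids to final headers."""
    with open(path, "w") as fh:
        fh.write("original_id\tfinal_header\tevalue\tbitscore\n")
        for a in annotated:
            ev = a.best_hit.evalue if a.best_hit else ""
            bs = a.best_hit.bitscore if a.best_hit else ""
            fh.write(f"{a.transcript.id}\t{a.header}\t{ev}\t{bs}\n")
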