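"""Synthetic transcriptome / annotation / PSM generator.

Builds fully synthetic inputs for end-to-end runs and calibration studies:
transcripts with one stop-free coding region embedded in a known reading
frame flanked by random UTR, a best-hit annotation table in tabular BLAST
format, and replicate peptide-spectrum-match tables whose spectral counts
are multinomially sampled from ground-truth molar abundance x protein
length.  Because NSAF divides counts by length, NSAF computed from these
tables estimates the planted molar abundances, and planted fold changes
between conditions are recoverable — which is what makes the simulator a
clean benchmark for the quantification stack.

All randomness flows from one explicit seed; generated tables carry the
seed in a '#'-comment header line.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from sixquant.annotation import DEFAULT_MAX_EVALUE
from sixquant.peptide_map import (
    DEFAULT_LEN_MAX,
    DEFAULT_LEN_MIN,
    DEFAULT_MISSED_MAX,
    digest,
)
from sixquant.search_db import ProteinEntry
from sixquant.seq_core import Transcript, reverse_complement, six_frame_segments

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: synonymous codon choices per amino acid (standard genetic code)
_CODONS: dict[str, list[str]] = {}
from Bio.Data.CodonTable import unambiguous_dna_by_id as _tables  # noqa: E402

for _codon, _aa in _tables[1].forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)

_STOPS = tuple(_tables[1].stop_codons)


@dataclass(frozen=True)
class GroundTruth:
    """What was planted for one synthetic protein."""

    protein_id: str
    transcript_id: str
    aa_sequence: str
    cds_frame: int
    length: int
    abundance: dict  # condition -> relative molar abundance (sums to 1)
    planted_fold_change: float  # deplete/replete; inf = deplete-only


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _random_observable_protein(rng: np.random.Generator, length: int) -> str:
    """Random protein guaranteed to yield tryptic peptides at default bounds.

    Rejection-samples until the fully cleaved digest has >= 3 products in
    the default search length window, as any real observable protein does.
    """
    from sixquant.peptide_map import cleavage_sites

    while True:
        protein = _random_protein(rng, length)
        sites = cleavage_sites(protein)
        bounds = [0] + [s + 1 for s in sites] + [len(protein)]
        n_ok = sum(
            1
            for a, b in zip(bounds, bounds[1:])
            if DEFAULT_LEN_MIN <= b - a <= DEFAULT_LEN_MAX
        )
        if n_ok >= 3:
            return protein


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(rng.choice(_CODONS[aa]) for aa in protein)


def _random_utr(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def generate_transcriptome(
    n: int,
    seed: int,
    aa_len_range: tuple[int, int] = (80, 260),
    utr_len_range: tuple[int, int] = (30, 150),
    gc: float = 0.5,
    fold_changes: Optional[Mapping[int, float]] = None,
    deplete_only: Sequence[int] = (),
    conditions: tuple[str, str] = ("replete", "deplete"),
) -> tuple[list[Transcript], list[GroundTruth]]:
    """Synthetic transcripts, each embedding one coding region.

    Each transcript carries one stop-free CDS flanked by in-frame stop
    codons and random UTR; roughly half are placed on the reverse strand.
    ``fold_changes`` maps protein index -> planted deplete/replete
    abundance ratio (default 1.0); indices in ``deplete_only`` get zero
    replete abundance (ratio = inf).  Per-condition abundances are drawn
    log-normally around the planted ratios and normalized to sum to 1.
    Deterministic for a given seed; every ground-truth protein is
    recovered verbatim by six-frame segmentation of its transcript.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = aa_len_range
    if lo < 10 or hi < lo:
        raise ValueError(f"infeasible aa_len_range {aa_len_range}")
    rng = np.random.default_rng(seed)
    fold_changes = dict(fold_changes or {})
    deplete_only = set(deplete_only)
    replete_cond, deplete_cond = conditions

    transcripts: list[Transcript] = []
    truths: list[GroundTruth] = []
    base_weight = rng.lognormal(mean=0.0, sigma=0.6, size=n)
    for i in range(n):
        aa_len = int(rng.integers(lo, hi + 1))
        protein = _random_observable_protein(rng, aa_len)
        cds = _back_translate(rng, protein)
        u5 = _random_utr(rng, int(rng.integers(*utr_len_range)), gc)
        u3 = _random_utr(rng, int(rng.integers(*utr_len_range)), gc)
        stop5 = str(rng.choice(_STOPS))
        stop3 = str(rng.choice(_STOPS))
        # pad the 5' UTR so both flanking stops sit in a chosen reading frame
        target_offset = int(rng.integers(0, 3))
        pad = (target_offset - len(u5)) % 3
        sense = u5 + "A" * pad + stop5 + cds + stop3 + u3
        if rng.random() < 0.5:
            sense = reverse_complement(sense)
        tid = f"TR_{i + 1:05d}"
        transcript = Transcript(tid, sense)
        transcripts.append(transcript)
        # recover the planted frame from the construction
        frame = next(
            f
            for f, _start, seg in six_frame_segments(transcript, min_len=aa_len)
            if seg == protein
        )
        fc = float("inf") if i in deplete_only else float(fold_changes.get(i, 1.0))
        truths.append(
            GroundTruth(
                protein_id=f"PROT_{i + 1:05d}",
                transcript_id=tid,
                aa_sequence=protein,
                cds_frame=frame,
                length=aa_len,
                abundance={},  # filled below
                planted_fold_change=fc,
            )
        )

    # per-condition molar abundances: replete from the base weights, deplete
    # scaled by the planted ratio; both normalized to 1
    rep = np.array(
        [0.0 if i in deplete_only else base_weight[i] for i in range(n)]
    )
    dep = np.array(
        [
            base_weight[i] * (truths[i].planted_fold_change if i not in deplete_only else 1.0)
            for i in range(n)
        ]
    )
    rep = rep / rep.sum()
    dep = dep / dep.sum()
    for i, t in enumerate(truths):
        t.abundance[replete_cond] = float(rep[i])
        t.abundance[deplete_cond] = float(dep[i])
    return transcripts, truths


def generate_annotations(
    truths: Iterable[GroundTruth],
    seed: int,
    hit_rate: float = 0.8,
    zero_evalue_rate: float = 0.045,
    duplicate_pairs: int = 2,
    titles: Optional[Mapping[str, str]] = None,
) -> list[str]:
    """Mock tabular BLAST lines (outfmt 6 + subject title column).

    A ``hit_rate`` fraction of transcripts get a qualifying best hit
    (E below 1e-03, a ``zero_evalue_rate`` share of them scored exactly
    0.0); the rest get either no line or a non-qualifying one.
    ``duplicate_pairs`` transcripts deliberately share a subject header to
    exercise downstream deduplication.  ``titles`` overrides subject
    titles per transcript id (used to plant enzyme annotations).  The first
    line is a '# seed=' comment.
    """
    if not 0 <= hit_rate <= 1:
        raise ValueError("hit_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    titles = dict(titles or {})
    truths = list(truths)
    lines = [f"# seed={seed} generator=sixquant.synth.generate_annotations"]
    dup_assigned = 0
    for i, t in enumerate(truths):
        roll = rng.random()
        subject = f"SUBJ_{i + 1:05d}"
        has_title = t.transcript_id in titles
        title = titles.get(t.transcript_id, f"hypothetical protein {subject}")
        if dup_assigned < 2 * duplicate_pairs and not has_title:
            subject = f"SUBJ_DUP_{dup_assigned // 2 + 1:03d}"
            title = f"duplicated subject {subject}"
            dup_assigned += 1
        if has_title:
            roll = 0.0  # planted titles always receive a qualifying hit
        if roll < hit_rate:
            if rng.random() < zero_evalue_rate:
                evalue = 0.0
            else:
                evalue = 10.0 ** rng.uniform(-180, -4)
            bitscore = rng.uniform(80, 2000)
        elif roll < hit_rate + 0.5 * (1 - hit_rate):
            evalue = 10.0 ** rng.uniform(-2.9, 1)  # present but not qualifying
            bitscore = rng.uniform(20, 50)
        else:
            continue  # no hit line at all
        pident = rng.uniform(70, 100)
        lines.append(
            "\t".join(
                [
                    t.transcript_id,
                    subject,
                    f"{pident:.2f}",
                    "100", "5", "1", "1", "100", "1", "100",
                    f"{evalue:.3g}",
                    f"{bitscore:.1f}",
                    title,
                ]
            )
        )
    return lines


def true_entry_ids(
    db: Iterable[ProteinEntry], truths: Iterable[GroundTruth]
) -> set[str]:
    """Target entry ids whose sequence equals a planted protein."""
    planted = {t.aa_sequence for t in truths}
    return {
        e.entry_id
        for e in db
        if e.category == "target" and e.aa_sequence in planted
    }


def incorrect_target_fraction(groups, db, truths) -> float:
    """True planted-incorrect share of distinct filtered target groups.

    A target group is incorrect when none of its member entries carries a
    planted protein sequence — the ground-truth quantity the decoy-based
    FDR estimate is supposed to track.  Returns 0.0 when no target groups.
    """
    true_ids = true_entry_ids(db, truths)
    seen: set[frozenset] = set()
    n_target = n_incorrect = 0
    for g in groups:
        if g.category != "target" or g.entry_ids in seen:
            continue
        seen.add(g.entry_ids)
        n_target += 1
        if not (set(g.entry_ids) & true_ids):
            n_incorrect += 1
    return n_incorrect / n_target if n_target else 0.0


def simulate_counts(
    truths: Sequence[GroundTruth],
    depth: int,
    conditions: Sequence[str],
    replicates: int,
    seed: int,
) -> dict[tuple[str, int], np.ndarray]:
    """Multinomial spectral counts per sample, weighted abundance x length.

    Returns ``(condition, replicate) -> counts`` aligned with ``truths``.
    Longer proteins yield proportionally more observable peptides, so the
    sampling weight is molar abundance x length; NSAF inverts the length
    factor and recovers abundance.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = np.array([t.length for t in truths], dtype=float)
    out: dict[tuple[str, int], np.ndarray] = {}
    for cond in conditions:
        ab = np.array([t.abundance.get(cond, 0.0) for t in truths])
        w = ab * lengths
        w = w / w.sum()
        for rep in range(1, replicates + 1):
            out[(cond, rep)] = rng.multinomial(depth, w)
    return out


def _entry_peptides(entry: ProteinEntry, digestion) -> list[str]:
    missed, lmin, lmax = digestion
    return [p.aa_sequence for p in digest(entry, missed, lmin, lmax)]


def simulate_psms(
    db: Sequence[ProteinEntry],
    truths: Sequence[GroundTruth],
    depth: int,
    seed: int,
    conditions: Sequence[str] = ("replete", "deplete"),
    replicates: int = 3,
    decoy_hit_rate: float = 0.0,
    junk_target_rate: Optional[float] = None,
    incorrect_pool_size: int = 40,
    correct_pep_prob: tuple[float, float] = (0.90, 1.0),
    correct_prot_prob: tuple[float, float] = (0.95, 1.0),
    incorrect_pep_prob: tuple[float, float] = (0.20, 0.90),
    incorrect_prot_prob: tuple[float, float] = (0.50, 1.0),
    digestion: tuple[int, int, int] = (
        DEFAULT_MISSED_MAX, DEFAULT_LEN_MIN, DEFAULT_LEN_MAX,
    ),
) -> list[dict]:
    """Simulate PSM rows for every sample of a two-condition experiment.

    Correct spectra are allocated to planted proteins by multinomial
    sampling (weights abundance x length) and spread uniformly over each
    protein's tryptic peptides, with high peptide/protein probabilities.
    A ``decoy_hit_rate`` fraction of spectra are incorrect matches to
    decoy entries, and a ``junk_target_rate`` fraction (defaulting to the
    same value) to non-planted target entries (spurious six-frame
    segments), both with low probabilities — the two pools are sampled
    symmetrically, which is what makes the decoy-based FDR estimator
    calibrated against the true planted-incorrect rate.  Returns rows as
    dicts matching the PSM TSV column contract.
    """
    if not 0 <= decoy_hit_rate < 1:
        raise ValueError("decoy_hit_rate must lie in [0, 1)")
    if junk_target_rate is None:
        junk_target_rate = decoy_hit_rate
    rng = np.random.default_rng(seed)
    truths = list(truths)

    planted = {t.aa_sequence for t in truths}
    true_ids = true_entry_ids(db, truths)
    by_seq = {}
    for e in db:
        if e.entry_id in true_ids:
            by_seq[e.aa_sequence] = e
    true_entries = []
    for t in truths:
        e = by_seq.get(t.aa_sequence)
        if e is None:
            raise ValueError(f"planted protein {t.protein_id} not found in database")
        true_entries.append(e)
    true_peps = []
    for t, e in zip(truths, true_entries):
        peps = _entry_peptides(e, digestion)
        if not peps and max(t.abundance.values()) > 0:
            raise ValueError(
                f"protein {t.protein_id} has positive abundance but no peptide "
                "within the digestion length bounds"
            )
        true_peps.append(peps)

    decoy_pool = [
        e for e in db if e.category == "decoy" and _entry_peptides(e, digestion)
    ]
    junk_pool = [
        e
        for e in db
        if e.category == "target"
        and e.entry_id not in true_ids
        and e.aa_sequence not in planted
        and _entry_peptides(e, digestion)
    ]

    counts = simulate_counts(
        truths, depth, conditions, replicates, seed=int(rng.integers(2**31))
    )
    rows: list[dict] = []
    spectrum_no = 0
    for (cond, rep), cvec in sorted(counts.items()):
        sample = f"{cond}_{rep}"
        # correct PSMs
        for i, c in enumerate(cvec):
            if c == 0:
                continue
            peps = true_peps[i]
            prot_prob = rng.uniform(*correct_prot_prob)
            choices = rng.integers(0, len(peps), size=int(c))
            for j in choices:
                spectrum_no += 1
                rows.append(
                    {
                        "spectrum_id": f"sp{spectrum_no:07d}",
                        "peptide": peps[j],
                        "peptide_prob": round(rng.uniform(*correct_pep_prob), 4),
                        "protein_prob": round(prot_prob, 4),
                        "sample": sample,
                        "condition": cond,
                        "replicate": rep,
                    }
                )
        # incorrect PSMs: symmetric decoy / junk-target pools
        for pool, rate in ((decoy_pool, decoy_hit_rate), (junk_pool, junk_target_rate)):
            if rate <= 0 or not pool:
                continue
            n_bad = rng.binomial(depth, rate)
            if n_bad == 0:
                continue
            k = min(incorrect_pool_size // 2, len(pool))
            chosen = rng.choice(len(pool), size=k, replace=False)
            alloc = rng.multinomial(n_bad, np.full(k, 1.0 / k))
            for idx, c in zip(chosen, alloc):
                if c == 0:
                    continue
                entry = pool[idx]
                peps = _entry_peptides(entry, digestion)
                prot_prob = rng.uniform(*incorrect_prot_prob)
                choices = rng.integers(0, len(peps), size=int(c))
                for j in choices:
                    spectrum_no += 1
                    rows.append(
                        {
                            "spectrum_id": f"sp{spectrum_no:07d}",
                            "peptide": peps[j],
                            "peptide_prob": round(
                                rng.uniform(*incorrect_pep_prob), 4
                            ),
                            "protein_prob": round(prot_prob, 4),
                            "sample": sample,
                            "condition": cond,
                            "replicate": rep,
                        }
                    )
    return rows


def write_psm_tables(rows: list[dict], out_dir, seed: int) -> list[Path]:
    """Write one PSM TSV per sample, each with a seed comment header."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_sample: dict[str, list[dict]] = {}
    for r in rows:
        by_sample.setdefault(r["sample"], []).append(r)
    paths = []
    cols = (
        "spectrum_id", "peptide", "peptide_prob", "protein_prob",
        "sample", "condition", "replicate",
    )
    for sample in sorted(by_sample):
        path = out_dir / f"psms_{sample}.tsv"
        with open(path, "w") as fh:
            fh.write(f"# seed={seed} generator=sixquant.synth.simulate_psms\n")
            fh.write("\t".join(cols) + "\n")
            for r in by_sample[sample]:
                fh.write("\t".join(str(r[c]) for c in cols) + "\n")
        paths.append(path)
    return paths


def write_ground_truth(truths: Iterable[GroundTruth], path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} generator=sixquant.synth\n")
        fh.write(
            "protein_id\ttranscript_id\tcds_frame\tlength\t"
            "planted_fold_change\tabundances\n"
        )
        for t in truths:
            ab = ";".join(f"{k}={v:.6g}" for k, v in sorted(t.abundance.items()))
            fh.write(
                f"{t.protein_id}\t{t.transcript_id}\t{t.cds_frame:+d}\t"
                f"{t.length}\t{t.planted_fold_change:g}\t{ab}\n"
            )


def write_transcripts(transcripts: Iterable[Transcript], path) -> None:
    from sixquant.seq_core import write_fasta

    write_fasta(((t.id, t.sequence) for t in transcripts), path)


def default_contaminants() -> list[tuple[str, str]]:
    """A tiny synthetic stand-in for a contaminant (cRAP-style) FASTA.

    These are synthetic sequences playing the role of common background
    proteins (keratins, trypsin); they are not the real cRAP entries.
    """
    rng = np.random.default_rng(20110915)
    names = [
        "synthetic keratin-like contaminant 1",
        "synthetic keratin-like contaminant 2",
        "synthetic trypsin-like contaminant",
    ]
    return [
        (f"sCRAP_{i + 1:03d} {name}", _random_protein(rng, int(rng.integers(120, 300))))
        for i, name in enumerate(names)
    ]
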