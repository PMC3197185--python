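"""Protein inference, confidence filtering, and target-decoy FDR.

Consumes peptide-spectrum-match (PSM) tables, groups database entries that
are indistinguishable by their observed peptide sets, applies the standard
acceptance thresholds (>= 2 unique peptides per protein, >= 95% protein
probability, >= 50% peptide probability), and estimates the false discovery
rate from decoy matches in the concatenated search.

The PSM TSV contract is one row per PSM with columns: spectrum_id, peptide,
peptide_prob, protein_prob, sample, condition, replicate.  Probabilities
are consumed as inputs (PeptideProphet/ProteinProphet-style scores from the
upstream validation tool), never recomputed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import pandas as pd

from sixquant.peptide_map import map_peptides
from sixquant.search_db import DECOY_PREFIX, CONTAMINANT_PREFIX

logger = logging.getLogger(__name__)

PSM_COLUMNS = (
    "spectrum_id", "peptide", "peptide_prob", "protein_prob",
    "sample", "condition", "replicate",
)


@dataclass(frozen=True)
class PSM:
    spectrum_id: str
    peptide: str
    peptide_probability: float
    protein_probability: float
    sample_id: str
    condition: str
    replicate: int
    assigned_entry_ids: frozenset[str] = frozenset()


@dataclass(frozen=True)
class ProteinIdentification:
    """A group of database entries indistinguishable by peptide evidence."""

    group_id: str
    entry_ids: frozenset[str]
    peptides: frozenset[str]
    spectral_count: int
    protein_probability: float
    category: str
    sample_id: str
    condition: str
    replicate: int

    @property
    def n_unique_peptides(self) -> int:
        return len(self.peptides)


def parse_psm_table(stream) -> list[PSM]:
    """Parse a PSM TSV into typed records.

    ``stream`` is a path or open file.  Missing required columns and
    probabilities outside [0, 1] are rejected with the offending column or
    line numbers.
    """
    df = pd.read_csv(stream, sep="\t", comment="#")
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table is missing required columns: {missing}")
    bad = df.index[
        ~df["peptide_prob"].between(0, 1) | ~df["protein_prob"].between(0, 1)
    ]
    if len(bad):
        # +2: header line plus 1-based numbering
        lines = [int(i) + 2 for i in bad[:10]]
        raise ValueError(f"probabilities outside [0, 1] at lines {lines}")
    return [
        PSM(
            spectrum_id=str(row.spectrum_id),
            peptide=str(row.peptide),
            peptide_probability=float(row.peptide_prob),
            protein_probability=float(row.protein_prob),
            sample_id=str(row.sample),
            condition=str(row.condition),
            replicate=int(row.replicate),
        )
        for row in df.itertuples()
    ]


def assign_psms(
    psms: Iterable[PSM], index: Mapping[str, frozenset[str]]
) -> tuple[list[PSM], list[PSM]]:
    """Attach database parent sets to PSMs via the peptide index.

    Returns (assigned, unassigned); unassigned PSMs matched nothing in the
    database and are excluded from inference but reported.
    """
    psms = list(psms)
    mapped, _ = map_peptides({p.peptide for p in psms}, index)
    assigned, unassigned = [], []
    for p in psms:
        parents = mapped.get(p.peptide)
        if parents:
            assigned.append(replace(p, assigned_entry_ids=parents))
        else:
            unassigned.append(p)
    if unassigned:
        logger.info("%d PSMs did not map to the database", len(unassigned))
    return assigned, unassigned


def _entry_category(entry_id: str) -> str:
    if entry_id.startswith(DECOY_PREFIX):
        return "decoy"
    if entry_id.startswith(CONTAMINANT_PREFIX):
        return "contaminant"
    return "target"


def _group_category(entry_ids: frozenset[str]) -> str:
    cats = {_entry_category(e) for e in entry_ids}
    if cats == {"decoy"}:
        return "decoy"
    if "contaminant" in cats:
        return "contaminant"
    return "target"


def infer_proteins(psms: Iterable[PSM]) -> list[ProteinIdentification]:
    """Group indistinguishable entries and count spectra, per sample.

    Entries whose observed peptide sets are identical are merged into one
    group; a shared peptide counts toward every group containing it.  The
    spectral count is the number of PSMs (spectra) whose peptide maps to
    the group in that sample; the group probability is the maximum
    protein probability seen among its supporting PSMs.  Output order is
    deterministic (sample, then group id), independent of PSM input order.
    """
    by_sample: dict[tuple[str, str, int], list[PSM]] = {}
    for p in psms:
        if not p.assigned_entry_ids:
            raise ValueError(
                f"PSM {p.spectrum_id!r} has no assigned entries; run assign_psms first"
            )
        by_sample.setdefault((p.sample_id, p.condition, p.replicate), []).append(p)

    groups: list[ProteinIdentification] = []
    for (sample, condition, replicate), sample_psms in sorted(by_sample.items()):
        entry_peptides: dict[str, set[str]] = {}
        for p in sample_psms:
            for e in p.assigned_entry_ids:
                entry_peptides.setdefault(e, set()).add(p.peptide)
        # merge entries with identical peptide sets
        by_pepset: dict[frozenset[str], set[str]] = {}
        for e, peps in entry_peptides.items():
            by_pepset.setdefault(frozenset(peps), set()).add(e)
        for pepset, entries in by_pepset.items():
            members = frozenset(entries)
            spc = sum(1 for p in sample_psms if p.peptide in pepset)
            prob = max(
                p.protein_probability for p in sample_psms if p.peptide in pepset
            )
            group_id = min(entries)
            groups.append(
                ProteinIdentification(
                    group_id=group_id,
                    entry_ids=members,
                    peptides=pepset,
                    spectral_count=spc,
                    protein_probability=prob,
                    category=_group_category(members),
                    sample_id=sample,
                    condition=condition,
                    replicate=replicate,
                )
            )
    groups.sort(key=lambda g: (g.sample_id, g.group_id))
    return groups


def filter_identifications(
    groups: Iterable[ProteinIdentification],
    psms: Optional[Iterable[PSM]] = None,
    min_peptides: int = 2,
    min_protein_prob: float = 0.95,
    min_peptide_prob: float = 0.50,
) -> list[ProteinIdentification]:
    """Apply peptide- then protein-level acceptance thresholds.

    When ``psms`` is given, PSMs below ``min_peptide_prob`` are removed
    first and groups are re-inferred from the survivors, so peptide and
    spectral counts reflect only accepted evidence.  Groups are then
    retained iff they have >= ``min_peptides`` unique peptides and
    protein probability >= ``min_protein_prob``.
    """
    if not 0 <= min_peptide_prob <= 1 or not 0 <= min_protein_prob <= 1:
        raise ValueError("probability thresholds must lie in [0, 1]")
    if min_peptides < 1:
        raise ValueError("min_peptides must be >= 1")
    if psms is not None:
        kept = [p for p in psms if p.peptide_probability >= min_peptide_prob]
        groups = infer_proteins(kept)
    return [
        g
        for g in groups
        if g.n_unique_peptides >= min_peptides
        and g.protein_probability >= min_protein_prob
    ]


def estimate_fdr(
    groups: Iterable[ProteinIdentification],
    formula: str = "decoy_over_target",
) -> float:
    """Target-decoy FDR of a filtered identification list, as a fraction.

    Decoy and target groups are counted once per distinct group (a group
    quantified in several samples counts once); contaminant groups are
    excluded from both counts.  The default estimator is #decoys/#targets;
    ``formula="doubled"`` gives the 2D/(T+D) alternative.
    """
    seen: set[frozenset[str]] = set()
    n_target = n_decoy = 0
    for g in groups:
        if g.category == "contaminant" or g.entry_ids in seen:
            continue
        seen.add(g.entry_ids)
        if g.category == "decoy":
            n_decoy += 1
        elif g.category == "target":
            n_target += 1
    if n_target == 0:
        if n_decoy == 0:
            return 0.0
        logger.warning("no target groups but %d decoy groups; FDR = 1.0", n_decoy)
        return 1.0
    if formula == "doubled":
        return 2 * n_decoy / (n_target + n_decoy)
    if formula != "decoy_over_target":
        raise ValueError(f"unknown FDR formula {formula!r}")
    return n_decoy / n_target


def write_identifications(groups: Iterable[ProteinIdentification], path) -> None:
    """Filtered-identification TSV, one row per group per sample."""
    with open(path, "w") as fh:
        fh.write(
            "group_id\tentries\tn_peptides\tspectral_count\tprotein_prob\t"
            "category\tsample\tcondition\treplicate\n"
        )
        for g in groups:
            fh.write(
                f"{g.group_id}\t{';'.join(sorted(g.entry_ids))}\t"
                f"{g.n_unique_peptides}\t{g.spectral_count}\t"
                f"{g.protein_probability:.4f}\t{g.category}\t"
                f"{g.sample_id}\t{g.condition}\t{g.replicate}\n"
            )
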