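"""Spectral-count quantification: NSAF, fold changes, and ANOVA.

The normalized spectral abundance factor of protein k in one sample is

    NSAF_k = (SpC_k / L_k) / sum_i (SpC_i / L_i)

where SpC is the spectral count and L the protein length in amino acids.
Dividing by length corrects for the larger number of observable peptides of
long proteins, and the per-sample normalization makes NSAF values sum to 1,
comparable across runs of different depth.  Differential abundance between
conditions is expressed as the ratio of mean NSAF values (deplete/replete),
with significance from a one-way ANOVA on log-transformed NSAF across
replicates.  Proteins detected in only one condition get sentinel fold
changes with a pseudo-count lower bound instead of infinities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from sixquant.ident_filter import ProteinIdentification
from sixquant.search_db import ProteinEntry

#: epsilon added before the log transform so zero counts stay finite
LOG_EPSILON = 1e-9
#: pseudo spectral count used for one-condition-only fold-change bounds
DEFAULT_PSEUDO_SPC = 0.5
#: spectral-count threshold for the "abundant" annotation
ABUNDANT_SPC = 10
#: detection limit in spectral counts
DETECTION_LIMIT_SPC = 1


@dataclass(frozen=True)
class QuantRecord:
    group_id: str
    sample_id: str
    condition: str
    replicate: int
    spc: float
    length: int
    saf: float
    nsaf: float


@dataclass(frozen=True)
class FoldChange:
    """Numeric ratio or a sentinel for one-condition-only proteins.

    ``sentinel`` is one of None (numeric), "deplete_only", "replete_only",
    "absent".  For sentinel cases ``value`` is a lower (deplete_only) or
    upper-reciprocal (replete_only) bound obtained by substituting a
    pseudo-count into the missing condition.
    """

    value: Optional[float]
    sentinel: Optional[str] = None

    @property
    def is_numeric(self) -> bool:
        return self.sentinel is None

    def render(self) -> str:
        if self.sentinel == "absent":
            return "absent"
        if self.sentinel == "deplete_only":
            return f">{self.value:.1f}"
        if self.sentinel == "replete_only":
            return f"<{1.0 / self.value:.3g}" if self.value else "replete_only"
        return f"{self.value:.2f}"


@dataclass(frozen=True)
class DifferentialResult:
    group_id: str
    nsaf_mean_replete: float
    nsaf_mean_deplete: float
    fold_change: FoldChange
    p_value: float
    significant: bool
    abundant: bool


def protein_length(group: ProteinIdentification, db: Mapping[str, ProteinEntry]) -> int:
    """Representative length of a group: its longest member entry.

    Grouped entries are indistinguishable by peptide evidence; some single
    length must stand for the group in SAF, and the longest member is the
    conservative (abundance-deflating) choice.
    """
    if not group.entry_ids:
        raise ValueError(f"group {group.group_id!r} has no member entries")
    lengths = []
    for e in group.entry_ids:
        if e not in db:
            raise KeyError(f"group member {e!r} not found in database")
        lengths.append(db[e].length)
    return max(lengths)


def normalize_counts(
    totals: Mapping[str, float],
    sample_conditions: Mapping[str, str],
    reference_condition: str,
) -> dict[str, float]:
    """Per-sample scale factors anchoring totals to the reference condition.

    Each sample's counts are multiplied by (mean total SpC over
    reference-condition samples) / (that sample's total SpC), so the
    reference-condition mean total is preserved and all samples are brought
    to a common depth.
    """
    ref_totals = [
        t for s, t in totals.items() if sample_conditions.get(s) == reference_condition
    ]
    if not ref_totals:
        raise ValueError(
            f"reference condition {reference_condition!r} has no samples"
        )
    zero = [s for s, t in totals.items() if t <= 0]
    if zero:
        raise ValueError(f"samples with zero total spectral count: {zero}")
    ref_mean = float(np.mean(ref_totals))
    return {s: ref_mean / t for s, t in totals.items()}


def nsaf(spc: Sequence[float], lengths: Sequence[int]) -> np.ndarray:
    """NSAF values for one sample: (SpC/L) normalized to sum to 1."""
    spc = np.asarray(spc, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(spc < 0):
        raise ValueError("spectral counts must be >= 0")
    if np.any(lengths <= 0):
        raise ValueError("protein lengths must be > 0")
    saf = spc / lengths
    total = saf.sum()
    if total == 0:
        raise ValueError("all spectral counts are zero; NSAF undefined")
    return saf / total


def quantify(
    groups: Iterable[ProteinIdentification],
    db: Mapping[str, ProteinEntry],
) -> list[QuantRecord]:
    """Per-sample NSAF table from filtered identifications.

    Groups are keyed by group id; a group absent from one sample gets SpC 0
    there so every sample quantifies the same roster.
    """
    groups = list(groups)
    if not groups:
        return []
    samples = sorted({(g.sample_id, g.condition, g.replicate) for g in groups})
    lengths: dict[str, int] = {}
    spc: dict[tuple[str, str], float] = {}
    for g in groups:
        lengths[g.group_id] = max(
            lengths.get(g.group_id, 0), protein_length(g, db)
        )
        spc[(g.group_id, g.sample_id)] = spc.get((g.group_id, g.sample_id), 0) + (
            g.spectral_count
        )
    roster = sorted(lengths)
    records: list[QuantRecord] = []
    for sample, condition, replicate in samples:
        counts = [spc.get((gid, sample), 0.0) for gid in roster]
        lens = [lengths[gid] for gid in roster]
        nsafs = nsaf(counts, lens)
        safs = np.asarray(counts, dtype=float) / np.asarray(lens, dtype=float)
        for gid, c, L, s, n in zip(roster, counts, lens, safs, nsafs):
            records.append(
                QuantRecord(
                    group_id=gid,
                    sample_id=sample,
                    condition=condition,
                    replicate=replicate,
                    spc=c,
                    length=L,
                    saf=float(s),
                    nsaf=float(n),
                )
            )
    return records


def fold_change(
    nsaf_deplete_mean: float,
    nsaf_replete_mean: float,
    pseudo_nsaf_replete: Optional[float] = None,
    pseudo_nsaf_deplete: Optional[float] = None,
) -> FoldChange:
    """Deplete/replete NSAF ratio, or a sentinel with a pseudo-count bound.

    When one condition's mean is zero the ratio is undefined; substituting
    the NSAF a pseudo-count (default 0.5 spectra) would have produced in
    the zero condition gives a conservative bound, reported as
    ">bound" (deplete_only) or the reciprocal (replete_only).
    """
    d, r = nsaf_deplete_mean, nsaf_replete_mean
    if d < 0 or r < 0:
        raise ValueError("NSAF means must be >= 0")
    if d == 0 and r == 0:
        return FoldChange(value=None, sentinel="absent")
    if r == 0:
        bound = d / pseudo_nsaf_replete if pseudo_nsaf_replete else None
        return FoldChange(value=bound, sentinel="deplete_only")
    if d == 0:
        bound = pseudo_nsaf_deplete / r if pseudo_nsaf_deplete else None
        return FoldChange(value=bound, sentinel="replete_only")
    return FoldChange(value=d / r)


def anova_oneway(
    groups_of_values: Sequence[Sequence[float]],
    log_transform: bool = True,
) -> tuple[float, float]:
    """Classical one-way ANOVA across conditions.

    Values are ln(NSAF + eps)-transformed by default (spectral-count data
    are right-skewed; the log brings replicate noise closer to normal).
    Returns (F, p) with (k-1, N-k) degrees of freedom.  All-identical
    groups give F = 0, p = 1; perfect separation with zero within-group
    variance gives p -> 0.
    """
    if len(groups_of_values) < 2:
        raise ValueError("ANOVA needs >= 2 condition groups")
    for g in groups_of_values:
        if len(g) < 2:
            raise ValueError("each condition needs >= 2 replicates")
    arrays = [np.asarray(g, dtype=float) for g in groups_of_values]
    if log_transform:
        arrays = [np.log(a + LOG_EPSILON) for a in arrays]
    grand = np.concatenate(arrays)
    if np.allclose(grand, grand[0]):
        return 0.0, 1.0
    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    if ssw == 0.0:
        return math.inf, 0.0
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def _pseudo_nsaf(
    records: list[QuantRecord], condition: str, gid: str, pseudo_spc: float
) -> float:
    """Mean NSAF a pseudo-count would have had in ``condition`` samples."""
    by_sample: dict[str, list[QuantRecord]] = {}
    for r in records:
        if r.condition == condition:
            by_sample.setdefault(r.sample_id, []).append(r)
    vals = []
    for sample_records in by_sample.values():
        length = next(r.length for r in sample_records if r.group_id == gid)
        saf_total = sum(r.saf for r in sample_records)
        pseudo_saf = pseudo_spc / length
        vals.append(pseudo_saf / (saf_total + pseudo_saf))
    return float(np.mean(vals))


def differential_table(
    records: Iterable[QuantRecord],
    deplete_condition: str = "deplete",
    replete_condition: str = "replete",
    alpha: float = 0.05,
    pseudo_spc: float = DEFAULT_PSEUDO_SPC,
    log_transform: bool = True,
    p_adjust: str = "none",
) -> list[DifferentialResult]:
    """Per-group differential abundance between two conditions.

    One row per group: condition means, fold change (or sentinel with
    pseudo-count bound), ANOVA p-value on log NSAF across replicates, and
    a significance flag at ``alpha`` (boundary inclusive: p == alpha is
    significant).  Rows are sorted sentinels first, then by descending
    fold change magnitude.  ``abundant`` flags groups with summed SpC
    above the high-abundance threshold of 10 spectra.

    ``log_transform=False`` runs the ANOVA on raw NSAF.  ``p_adjust="bh"``
    applies Benjamini-Hochberg control across groups before the
    significance call; the default is uncorrected per-protein testing.
    """
    if p_adjust not in ("none", "bh"):
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    records = list(records)
    gids = sorted({r.group_id for r in records})
    results: list[DifferentialResult] = []
    for gid in gids:
        mine = [r for r in records if r.group_id == gid]
        dep = [r.nsaf for r in mine if r.condition == deplete_condition]
        rep = [r.nsaf for r in mine if r.condition == replete_condition]
        dep_mean = float(np.mean(dep)) if dep else 0.0
        rep_mean = float(np.mean(rep)) if rep else 0.0
        fc = fold_change(
            dep_mean,
            rep_mean,
            pseudo_nsaf_replete=_pseudo_nsaf(records, replete_condition, gid, pseudo_spc)
            if rep_mean == 0 and dep_mean > 0
            else None,
            pseudo_nsaf_deplete=_pseudo_nsaf(records, deplete_condition, gid, pseudo_spc)
            if dep_mean == 0 and rep_mean > 0
            else None,
        )
        if len(dep) >= 2 and len(rep) >= 2:
            _, p = anova_oneway([dep, rep], log_transform=log_transform)
        else:
            p = float("nan")
        total_spc = sum(r.spc for r in mine)
        results.append(
            DifferentialResult(
                group_id=gid,
                nsaf_mean_replete=rep_mean,
                nsaf_mean_deplete=dep_mean,
                fold_change=fc,
                p_value=p,
                significant=False,  # set below, after optional adjustment
                abundant=total_spc > ABUNDANT_SPC,
            )
        )

    decision_p = [r.p_value for r in results]
    if p_adjust == "bh":
        finite = [i for i, p in enumerate(decision_p) if not math.isnan(p)]
        if finite:
            adjusted = stats.false_discovery_control(
                [decision_p[i] for i in finite], method="bh"
            )
            for i, q in zip(finite, adjusted):
                decision_p[i] = float(q)
    results = [
        replace(
            r,
            significant=bool(decision_p[i] <= alpha)
            if not math.isnan(decision_p[i])
            else False,
        )
        for i, r in enumerate(results)
    ]

    def sort_key(r: DifferentialResult):
        fc = r.fold_change
        if not fc.is_numeric:
            return (0, -(fc.value or math.inf))
        return (1, -fc.value)

    results.sort(key=sort_key)
    return results


def write_quant_table(records: Iterable[QuantRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "group_id": r.group_id,
                "sample": r.sample_id,
                "condition": r.condition,
                "replicate": r.replicate,
                "SpC": r.spc,
                "L": r.length,
                "NSAF": r.nsaf,
            }
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def write_differential_table(results: Iterable[DifferentialResult], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "group_id\tnsaf_mean_replete\tnsaf_mean_deplete\tfold_change\t"
            "p_value\tsignificant\tabundant\n"
        )
        for r in results:
            fh.write(
                f"{r.group_id}\t{r.nsaf_mean_replete:.6g}\t"
                f"{r.nsaf_mean_deplete:.6g}\t{r.fold_change.render()}\t"
                f"{r.p_value:.4g}\t{r.significant}\t{r.abundant}\n"
            )
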