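"""In-silico tryptic digestion and peptide-to-protein mapping.

Trypsin cleaves C-terminal to lysine (K) or arginine (R) except when the
next residue is proline.  The digest enumerates all products with up to a
configured number of missed cleavages inside configurable length bounds;
the peptide index maps each product back to every database entry that can
produce it, which is what protein inference needs to resolve shared
peptides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from sixquant.search_db import ProteinEntry

#: defaults: typical shotgun search settings
DEFAULT_MISSED_MAX = 2
DEFAULT_LEN_MIN = 6
DEFAULT_LEN_MAX = 50


@dataclass(frozen=True)
class Peptide:
    aa_sequence: str
    missed_cleavages: int
    parent_entry_ids: frozenset[str]


def cleavage_sites(sequence: str) -> list[int]:
    """0-based positions after which trypsin cleaves (K/R not before P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    entry: ProteinEntry,
    missed_max: int = DEFAULT_MISSED_MAX,
    len_min: int = DEFAULT_LEN_MIN,
    len_max: int = DEFAULT_LEN_MAX,
) -> list[Peptide]:
    """Tryptic products of one entry with <= ``missed_max`` missed cleavages.

    A product identical in sequence but produced at several positions in the
    same protein is reported once (smallest missed-cleavage count wins).
    """
    if missed_max < 0:
        raise ValueError("missed_max must be >= 0")
    if len_min > len_max:
        raise ValueError("len_min must be <= len_max")
    seq = entry.aa_sequence
    # fragment boundaries: start positions of fully cleaved fragments
    sites = cleavage_sites(seq)
    bounds = [0] + [s + 1 for s in sites] + [len(seq)]
    seen: dict[str, int] = {}
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for j in range(i + 1, min(i + 1 + missed_max + 1, n_frag + 1)):
            pep = seq[bounds[i] : bounds[j]]
            if not (len_min <= len(pep) <= len_max):
                continue
            mc = j - i - 1
            if pep not in seen or mc < seen[pep]:
                seen[pep] = mc
    return [
        Peptide(
            aa_sequence=pep,
            missed_cleavages=mc,
            parent_entry_ids=frozenset({entry.entry_id}),
        )
        for pep, mc in sorted(seen.items())
    ]


def build_peptide_index(
    db: Iterable[ProteinEntry],
    missed_max: int = DEFAULT_MISSED_MAX,
    len_min: int = DEFAULT_LEN_MIN,
    len_max: int = DEFAULT_LEN_MAX,
    collapse_il: bool = False,
) -> dict[str, frozenset[str]]:
    """Map every digestible peptide to the set of entries producing it.

    With ``collapse_il`` isoleucine and leucine are treated as equivalent
    (both keyed as 'L') for cross-engine inputs; by default they are
    distinct, matching engine-resolved sequences exactly.
    """
    index: dict[str, set[str]] = {}
    for entry in db:
        for pep in digest(entry, missed_max, len_min, len_max):
            key = pep.aa_sequence.replace("I", "L") if collapse_il else pep.aa_sequence
            index.setdefault(key, set()).add(entry.entry_id)
    return {k: frozenset(v) for k, v in index.items()}


def map_peptides(
    observed: Iterable[str],
    index: Mapping[str, frozenset[str]],
    collapse_il: bool = False,
) -> tuple[dict[str, frozenset[str]], list[str]]:
    """Exact-match observed peptides against the index.

    Returns (peptide -> parent entry ids, unmatched peptides).  Unmatched
    peptides are reported, never dropped silently.
    """
    mapped: dict[str, frozenset[str]] = {}
    unmatched: list[str] = []
    for pep in observed:
        key = pep.replace("I", "L") if collapse_il else pep
        parents = index.get(key)
        if parents:
            mapped[pep] = parents
        else:
            unmatched.append(pep)
    return mapped, unmatched


def write_peptide_index(index: Mapping[str, frozenset[str]], path) -> None:
    """TSV dump: peptide, n_parents, parent ids semicolon-joined."""
    with open(path, "w") as fh:
        fh.write("peptide\tn_parents\tparent_ids\n")
        for pep in sorted(index):
            parents = sorted(index[pep])
            fh.write(f"{pep}\t{len(parents)}\t{';'.join(parents)}\n")
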