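"""Pathway-level abundance reporting and pipeline orchestration.

Maps quantified protein groups onto a configurable enzyme roster (by
default the core fatty-acid and triacylglycerol biosynthesis enzymes of
oleaginous microalgae) via keyword matching against annotated headers, and
renders per-enzyme NSAF x 10^5 values for each condition together with
fold changes and significance — the table a lipid-pathway figure is built
from.  ``run_pipeline`` strings the whole toolkit together:

    annotation -> search_db -> peptide_map -> ident_filter -> quant -> report
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import yaml

from sixquant import annotation as ann
from sixquant import ident_filter as idf
from sixquant import quant as qn
from sixquant import search_db as sdb
from sixquant.peptide_map import build_peptide_index
from sixquant.seq_core import Transcript, read_fasta

NSAF_REPORT_SCALE = 1e5


@dataclass(frozen=True)
class PathwayEnzyme:
    abbrev: str
    full_name: str
    pathway: str
    match_keywords: tuple[str, ...]
    ec_numbers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.match_keywords and not self.ec_numbers:
            raise ValueError(
                f"enzyme {self.abbrev!r} needs at least one keyword or EC number"
            )


def _parse_config(doc: dict) -> list[PathwayEnzyme]:
    if not doc or "enzymes" not in doc or not doc["enzymes"]:
        raise ValueError("pathway config has no enzymes")
    enzymes = []
    seen: set[str] = set()
    for item in doc["enzymes"]:
        abbrev = item["abbrev"]
        if abbrev in seen:
            raise ValueError(f"duplicate enzyme abbreviation {abbrev!r}")
        seen.add(abbrev)
        enzymes.append(
            PathwayEnzyme(
                abbrev=abbrev,
                full_name=item.get("full_name", abbrev),
                pathway=item.get("pathway", "unassigned"),
                match_keywords=tuple(item.get("match_keywords", ())),
                ec_numbers=tuple(item.get("ec_numbers", ())),
            )
        )
    return enzymes


def load_pathway_config(path) -> list[PathwayEnzyme]:
    """Load and validate a YAML pathway definition."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _parse_config(doc)


def default_pathway_config() -> list[PathwayEnzyme]:
    """The packaged fatty-acid/TAG/regulatory enzyme roster."""
    ref = resources.files("sixquant.data") / "fatty_acid_tag_pathway.yaml"
    return _parse_config(yaml.safe_load(ref.read_text()))


def match_enzymes(
    group_headers: Mapping[str, str],
    enzymes: Iterable[PathwayEnzyme],
) -> dict[str, set[str]]:
    """Assign groups to enzymes by keyword containment in their headers.

    Matching is case-insensitive; a group is assigned to at most one
    enzyme — when several keywords match, the longest keyword wins, so a
    header naming a specific acyltransferase is not also counted under a
    broader term.  Unmatched enzymes map to empty sets.
    """
    enzymes = list(enzymes)
    out: dict[str, set[str]] = {e.abbrev: set() for e in enzymes}
    for gid, header in group_headers.items():
        text = header.lower()
        best: Optional[tuple[int, str]] = None
        for e in enzymes:
            for kw in e.match_keywords:
                if kw.lower() in text:
                    cand = (len(kw), e.abbrev)
                    if best is None or cand > best:
                        best = cand
        if best is not None:
            out[best[1]].add(gid)
    return out


def pathway_table(
    results: Iterable[qn.DifferentialResult],
    enzyme_map: Mapping[str, set[str]],
    enzymes: Iterable[PathwayEnzyme],
) -> list[dict]:
    """One report row per enzyme with NSAF x 10^5 per condition.

    When several groups match one enzyme their NSAF means are summed (they
    are disjoint fractions of the same sample total).  Enzymes with no
    matched quantified group are reported as not identified.
    """
    by_gid = {r.group_id: r for r in results}
    rows = []
    for e in enzymes:
        gids = sorted(g for g in enzyme_map.get(e.abbrev, ()) if g in by_gid)
        if not gids:
            rows.append(
                {
                    "abbrev": e.abbrev,
                    "full_name": e.full_name,
                    "pathway": e.pathway,
                    "identified": False,
                    "groups": [],
                    "nsaf_replete_x1e5": None,
                    "nsaf_deplete_x1e5": None,
                    "fold_change": "not identified",
                    "p_value": None,
                    "significant": None,
                }
            )
            continue
        rep = sum(by_gid[g].nsaf_mean_replete for g in gids)
        dep = sum(by_gid[g].nsaf_mean_deplete for g in gids)
        # fold change / p from the dominant (most abundant) matched group
        lead = max(
            gids,
            key=lambda g: by_gid[g].nsaf_mean_deplete + by_gid[g].nsaf_mean_replete,
        )
        r = by_gid[lead]
        rows.append(
            {
                "abbrev": e.abbrev,
                "full_name": e.full_name,
                "pathway": e.pathway,
                "identified": True,
                "groups": gids,
                "nsaf_replete_x1e5": rep * NSAF_REPORT_SCALE,
                "nsaf_deplete_x1e5": dep * NSAF_REPORT_SCALE,
                "fold_change": r.fold_change.render(),
                "p_value": r.p_value,
                "significant": r.significant,
            }
        )
    return rows


def write_pathway_report(rows: list[dict], tsv_path, text_path=None) -> None:
    with open(tsv_path, "w") as fh:
        fh.write(
            "abbrev\tfull_name\tpathway\tidentified\tgroups\t"
            "nsaf_replete_x1e5\tnsaf_deplete_x1e5\tfold_change\tp_value\t"
            "significant\n"
        )
        for r in rows:
            rep = "" if r["nsaf_replete_x1e5"] is None else f"{r['nsaf_replete_x1e5']:.2f}"
            dep = "" if r["nsaf_deplete_x1e5"] is None else f"{r['nsaf_deplete_x1e5']:.2f}"
            p = "" if r["p_value"] is None else f"{r['p_value']:.4g}"
            fh.write(
                f"{r['abbrev']}\t{r['full_name']}\t{r['pathway']}\t"
                f"{r['identified']}\t{';'.join(r['groups'])}\t{rep}\t{dep}\t"
                f"{r['fold_change']}\t{p}\t{r['significant']}\n"
            )
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(render_pathway_text(rows))


def render_pathway_text(rows: list[dict]) -> str:
    lines = [
        f"{'enzyme':8s} {'pathway':12s} {'NSAF(rep)x1e5':>14s} "
        f"{'NSAF(dep)x1e5':>14s} {'fold':>10s}  p"
    ]
    for r in rows:
        if not r["identified"]:
            lines.append(
                f"{r['abbrev']:8s} {r['pathway']:12s} {'—':>14s} {'—':>14s} "
                f"{'not identified':>10s}"
            )
            continue
        lines.append(
            f"{r['abbrev']:8s} {r['pathway']:12s} "
            f"{r['nsaf_replete_x1e5']:14.2f} {r['nsaf_deplete_x1e5']:14.2f} "
            f"{r['fold_change']:>10s}  {r['p_value']:.3g}"
        )
    return "\n".join(lines) + "\n"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    transcripts_fasta,
    blast_tsv,
    psm_tsvs: list,
    out_dir,
    contaminants_fasta=None,
    pathway_config=None,
    max_evalue: float = ann.DEFAULT_MAX_EVALUE,
    min_seg_len: int = 7,
    missed_max: int = 2,
    pep_len_min: int = 6,
    pep_len_max: int = 50,
    min_peptides: int = 2,
    min_protein_prob: float = 0.95,
    min_peptide_prob: float = 0.50,
    alpha: float = 0.05,
    deplete_condition: str = "deplete",
    replete_condition: str = "replete",
) -> dict:
    """End-to-end run from transcripts + BLAST + PSM tables to the report.

    Writes annotated FASTA, the concatenated database, filtered
    identifications, quant and differential tables, the pathway report, and
    a manifest JSON with parameters and per-stage record counts.  Any stage
    failure aborts naming the stage.  Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            "max_evalue": max_evalue,
            "min_seg_len": min_seg_len,
            "missed_max": missed_max,
            "pep_len_bounds": [pep_len_min, pep_len_max],
            "min_peptides": min_peptides,
            "min_protein_prob": min_protein_prob,
            "min_peptide_prob": min_peptide_prob,
            "alpha": alpha,
        },
        "stages": {},
        "outputs": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(name, exc) from exc
        return deco

    @stage("annotation")
    def annotated():
        transcripts = [Transcript(h.split()[0], s) for h, s in read_fasta(transcripts_fasta)]
        with open(blast_tsv) as fh:
            hits = ann.parse_blast_tab(fh)
        best = ann.best_hits_by_query(hits, max_evalue)
        annotated = ann.annotate_headers(transcripts, best)
        from sixquant.seq_core import write_fasta

        write_fasta(
            ((a.header, a.transcript.sequence) for a in annotated),
            out_dir / "annotated_transcripts.fasta",
        )
        ann.write_header_map(annotated, out_dir / "header_map.tsv")
        return annotated

    manifest["stages"]["annotation"] = ann.annotation_summary(annotated)

    @stage("search_db")
    def db():
        db = sdb.assemble_db(
            annotated, contaminants_fasta=contaminants_fasta, min_len=min_seg_len
        )
        sdb.write_concatenated_db(db, out_dir / "search_db.fasta")
        return db

    manifest["stages"]["search_db"] = {
        "n_entries": len(db),
        "n_target": sum(1 for e in db if e.category == "target"),
        "n_decoy": sum(1 for e in db if e.category == "decoy"),
        "n_contaminant": sum(1 for e in db if e.category == "contaminant"),
    }

    @stage("peptide_map")
    def index():
        return build_peptide_index(
            db, missed_max=missed_max, len_min=pep_len_min, len_max=pep_len_max
        )

    manifest["stages"]["peptide_map"] = {"n_peptides": len(index)}

    @stage("ident_filter")
    def filtered():
        psms = []
        for p in psm_tsvs:
            psms.extend(idf.parse_psm_table(p))
        assigned, unassigned = idf.assign_psms(psms, index)
        filtered = idf.filter_identifications(
            None,
            psms=assigned,
            min_peptides=min_peptides,
            min_protein_prob=min_protein_prob,
            min_peptide_prob=min_peptide_prob,
        )
        idf.write_identifications(filtered, out_dir / "filtered_identifications.tsv")
        manifest["stages"]["ident_filter"] = {
            "n_psms": len(psms),
            "n_unassigned_psms": len(unassigned),
            "n_filtered_groups": len(filtered),
            "fdr": idf.estimate_fdr(filtered),
        }
        return filtered

    @stage("quant")
    def diff():
        db_map = {e.entry_id: e for e in db}
        biological = [g for g in filtered if g.category == "target"]
        records = qn.quantify(biological, db_map)
        qn.write_quant_table(records, out_dir / "quant.tsv")
        results = qn.differential_table(
            records,
            deplete_condition=deplete_condition,
            replete_condition=replete_condition,
            alpha=alpha,
        )
        qn.write_differential_table(results, out_dir / "differential.tsv")
        manifest["stages"]["quant"] = {
            "n_quantified_groups": len({r.group_id for r in records}),
            "n_significant": sum(1 for r in results if r.significant),
        }
        return records, results

    @stage("pathway_report")
    def rows():
        records, results = diff
        enzymes = (
            load_pathway_config(pathway_config)
            if pathway_config is not None
            else default_pathway_config()
        )
        # group headers: member entry ids carry the transferred annotation
        headers = {}
        for g in filtered:
            headers[g.group_id] = " ".join(sorted(g.entry_ids))
        emap = match_enzymes(headers, enzymes)
        rows = pathway_table(results, emap, enzymes)
        write_pathway_report(
            rows, out_dir / "pathway_report.tsv", out_dir / "pathway_report.txt"
        )
        manifest["stages"]["pathway_report"] = {
            "n_enzymes": len(rows),
            "n_identified": sum(1 for r in rows if r["identified"]),
        }
        return rows

    manifest["outputs"] = {
        "annotated_fasta": str(out_dir / "annotated_transcripts.fasta"),
        "header_map": str(out_dir / "header_map.tsv"),
        "search_db": str(out_dir / "search_db.fasta"),
        "filtered_identifications": str(out_dir / "filtered_identifications.tsv"),
        "quant": str(out_dir / "quant.tsv"),
        "differential": str(out_dir / "differential.tsv"),
        "pathway_report": str(out_dir / "pathway_report.tsv"),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
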