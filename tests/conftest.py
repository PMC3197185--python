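import pytest

from sixquant import annotation as ann
from sixquant import search_db as sdb
from sixquant import synth
from sixquant.seq_core import write_fasta


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small synthetic experiment: transcripts, annotations, db, PSMs.

    Plants fold changes 2/5/10, one deplete-only protein, and enzyme
    annotations for pathway matching; includes contaminants and a modest
    incorrect-match rate so decoy groups exist.
    """
    out = tmp_path_factory.mktemp("bundle")
    transcripts, truths = synth.generate_transcriptome(
        50, seed=11, fold_changes={0: 2.0, 1: 5.0, 2: 10.0}, deplete_only=[3]
    )
    titles = {
        truths[0].transcript_id: "acetyl-CoA carboxylase, chloroplastic",
        truths[1].transcript_id: "3-ketoacyl-ACP reductase",
        truths[3].transcript_id: "diacylglycerol acyltransferase 1",
    }
    synth.write_transcripts(transcripts, out / "transcripts.fasta")
    lines = synth.generate_annotations(truths, seed=12, hit_rate=0.9, titles=titles)
    (out / "blast.tsv").write_text("\n".join(lines) + "\n")
    write_fasta(synth.default_contaminants(), out / "contaminants.fasta")

    with open(out / "blast.tsv") as fh:
        best = ann.best_hits_by_query(ann.parse_blast_tab(fh))
    annotated = ann.annotate_headers(transcripts, best)
    db = sdb.assemble_db(annotated, contaminants_fasta=out / "contaminants.fasta")
    rows = synth.simulate_psms(db, truths, depth=3000, seed=13, decoy_hit_rate=0.04)
    psm_paths = synth.write_psm_tables(rows, out, seed=13)
    return {
        "dir": out,
        "transcripts": transcripts,
        "truths": truths,
        "annotated": annotated,
        "db": db,
        "psm_rows": rows,
        "psm_paths": psm_paths,
    }
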