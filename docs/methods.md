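# Methods

This note documents the models, defaults, and design choices behind
`sixquant`, and what the synthetic benchmarks do and do not demonstrate.

## Six-frame translation and segmentation

Transcripts are translated with the standard genetic code in frames +1, +2,
+3 and, on the reverse complement, −1, −2, −3. The trailing partial codon
is dropped. Any codon containing an uncalled base (N) translates to `X`
unconditionally — degenerate codons are never resolved even when the
ambiguity is synonymous, so a translated residue always reflects called
bases only. Each frame translation is split at stop codons (`*`), with no
read-through: this is the standard construction for six-frame search
databases, which does not attempt ORF calling or start-codon modelling.
Segments shorter than 7 aa (configurable) are discarded, 7 aa being about
the shortest tryptic peptide a search engine will confidently match.
Segments that are more than 50 % `X` are also discarded: runs of uncalled
bases cannot produce informative peptides, and keeping them would only
inflate the decoy space.

## Annotation transfer

The best hit for a transcript is the tabular-BLAST hit with the smallest
E-value strictly below 10⁻³, with ties broken by higher bitscore and then
lexicographic subject id — the tie-break makes the choice independent of
input order. Transcripts without a qualifying hit are retained in the
database under their assembly ids; a flag restricts the database to
annotated transcripts only. Retention is the conservative superset: an
unannotated transcript can still carry a real, taxon-specific protein, and
dropping it would silently remove exactly the identifications a de novo
search model exists to gain. Duplicate headers (several isoforms sharing a
top hit) are suffixed `_2`, `_3`, … from the second occurrence, keeping the
first occurrence verbatim; the original→final mapping is written to a
sidecar TSV, which is also the only place the source-transcript linkage of
a database entry survives a FASTA round trip.

## Decoys and FDR

Decoys are whole-sequence reversals, one per target and per contaminant
entry, so the decoy:target ratio is exactly 1:1 and amino-acid composition
is preserved. Contaminants are decoyed too: in a concatenated search the
contaminant entries compete for spectra like any target, so excluding them
from the decoy model would bias the null. The FDR of a filtered
identification list is `#decoy groups / #target groups` (the concatenated
search estimator; `2D/(T+D)` is available behind a flag), with
contaminant-matching groups excluded from both counts and reported
separately. Protein and peptide probabilities are consumed from the input
PSM tables; re-deriving Bayesian validation models is out of scope.

Protein grouping merges entries whose observed peptide sets are identical
(maximal indistinguishable sets), per sample; a shared peptide counts
toward every group containing it. A group is a decoy group only when all
members are decoys, and a contaminant group when any member is a
contaminant (the conservative rule for exclusion from biological tables).
Group ids are the lexicographically smallest member entry id, which keeps
ids stable across samples as long as the observed peptide sets are; at very
low coverage a group can split differently between samples, which the
quantification layer tolerates by keying on group id.

The filter applies the peptide-level pass first (PSMs below the peptide
probability threshold are removed and groups re-inferred), then the
group-level thresholds (≥ 2 unique peptides, protein probability ≥ 0.95).
"Two peptides" means two distinct peptide sequences, not two spectra.
Filtering is monotone in all three thresholds by construction.

## Digestion

Trypsin cleaves C-terminal to K or R except before P. The digest
enumerates all products with ≤ 2 missed cleavages (default) and length in
[6, 50] aa; these are conventional search settings, configurable per run.
I and L are distinct in exact matching because PSM tables carry
engine-resolved sequences; an `I=L` collapse flag exists for cross-engine
inputs. N-terminal methionine is not removed: six-frame segments are not
genuine protein N-termini, so Met-excision rules do not apply.

## Quantification

NSAF for protein k in one sample is `(SpC_k/L_k) / Σ_i (SpC_i/L_i)`. The
group length L is the longest member's length — members are
indistinguishable, and the longest is the abundance-deflating
(conservative) representative. Groups absent from a sample enter with
SpC = 0 so every sample quantifies the same roster and Σ NSAF = 1 holds per
sample (to 1 × 10⁻⁹; in practice to machine precision). Depth
normalization scale factors anchor each sample's total spectral count to
the mean total of a chosen reference condition (mean-of-replicates was
chosen over pooled total; the two differ only when replicate depths differ,
and the mean keeps the factors interpretable per sample). NSAF itself is
invariant under uniform count scaling, so this normalization matters for
raw-count reporting, not for NSAF ratios.

Fold change is deplete-mean NSAF over replete-mean NSAF. When one
condition has zero counts the ratio is undefined; the report substitutes a
pseudo-count of 0.5 spectra into the zero condition's NSAF and reports the
resulting ratio as a lower bound (`>bound`), or its reciprocal for
replete-only proteins. This mirrors how condition-absent enzymes are
conventionally reported (e.g. "greater than 100-fold") and keeps the table
sortable — sentinels sort first, then descending fold change.

Significance is a classical one-way ANOVA across condition replicates on
`ln(NSAF + ε)` with ε = 10⁻⁹; log transformation because spectral-count
data are strongly right-skewed. Raw-scale ANOVA is available behind a
flag. p ≤ 0.05 is significant, boundary inclusive. No multiple-testing
correction is applied by default, matching the per-protein decision rule
this style of analysis uses; a Benjamini–Hochberg option exists. Groups
with more than 10 summed spectral counts carry an `abundant` flag (the
limit of detection being a single spectral count). Degenerate inputs are
handled explicitly: identical values in all groups give F = 0, p = 1;
perfect separation with zero within-group variance gives p → 0.

## Pathway matching

Groups are assigned to enzymes by case-insensitive keyword containment
against their annotated headers; the longest matching keyword wins and a
group is assigned to at most one enzyme, preventing double counting across
the fatty-acid and TAG rosters. Keyword matching is a reconstruction of
what is usually a manual, annotation-driven assignment, and the shipped
roster is a configuration default, not a claim about any particular
organism's gene complement. Report NSAF values are scaled ×10⁵ exactly.

## Synthetic data generator

Each synthetic transcript embeds one stop-free coding region, back-
translated with uniformly random synonymous codons, flanked by in-frame
stop codons and random UTR; about half the coding regions are placed on the
reverse strand, with the reading-frame offset drawn uniformly. Protein
lengths are uniform on [80, 260] aa and base abundances log-normal
(σ = 0.6), normalized per condition; planted fold changes multiply the
deplete-condition weight, and deplete-only proteins get zero replete
abundance. Proteins are rejection-sampled to guarantee at least three
fully cleaved tryptic peptides inside the default length window, as any
real observable protein has.

Spectra are allocated to proteins per sample by multinomial sampling with
weights abundance × length — longer proteins present more observable
peptides — and spread uniformly over each protein's tryptic peptides.
Because NSAF divides by length, it inverts the length factor and estimates
molar abundance, which is what makes planted fold changes a clean recovery
benchmark. Correct PSMs draw peptide probabilities from U(0.90, 1.0) and
protein probabilities from U(0.95, 1.0); incorrect PSMs draw from
U(0.20, 0.90) and U(0.50, 1.0) respectively, so a realistic minority of
incorrect groups survives the 95 % protein filter. Incorrect spectra are
split between two symmetric pools — decoy entries and spurious six-frame
target segments — sampled identically, which is precisely the symmetry the
decoy-based FDR estimator assumes; the generator therefore provides both
the estimate and the ground truth it should track. All randomness flows
from one seed, recorded in a comment line of every generated table.

What the generator does not emulate: spectrum-level physics (m/z, retention
time, dynamic-exclusion effects), peptide detectability differences
(ionization efficiency, missed-cleavage bias), protein inference ambiguity
from homologous families, and assembly artifacts (chimeras, fragmented
transcripts). Passing benchmarks therefore demonstrate the correctness of
the statistical machinery under its own assumptions, not performance on
real LC-MS/MS data.

## Benchmark sizes and calibration checks

The FDR calibration study runs 20–25 independent simulations (30
transcripts, depth 2,000, 6 % decoy hit rate) and compares the pooled decoy
count against the pooled planted-incorrect count. Both are binomial draws
around the same rate, so the comparison uses the two-sample binomial 95 %
interval (sd = √(2·T·p·(1−p))), not the one-sample interval.

The fold-change recovery study plants ratios 2, 5, and 10 among 200
proteins at 5,000 spectra per sample and 3 replicates per condition, 50
seeds. Recovery within ±25 % depends on the planted protein's own
(randomly drawn) abundance: a protein at the low tail of the abundance
distribution yields few spectra and a noisy ratio, so the pooled recovery
rate sits near 90 % rather than comfortably above it. The end-to-end
ranking check (40 seeds, 25 transcripts, depth 3,000) verifies the ordering
10× > 2× > 1× and the sentinel classification of a deplete-only protein
through the full inference/filter/quantification stack.

## Known limitations

- Annotation transfer is nucleotide-BLAST-driven; protein-level (blastx)
  annotations can be supplied as a second tabular input but are mapped with
  the same best-hit logic, not integrated by alignment coordinates.
- Protein inference implements maximal indistinguishable-set grouping
  only; subset/subsumable-protein logic and parsimony covers are not
  implemented.
- The FASTA database round trip preserves header, sequence, category, and
  frame; source-transcript provenance lives in the header-map sidecar.
- Quantification assumes spectral counts; intensity-based quantification
  and imputation beyond the pseudo-count sentinel policy are out of scope.
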