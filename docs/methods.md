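# Methods

This note records the models, evidence rules, parameter defaults and design
choices behind `tfaudit`, and what the synthetic benchmark does and does not
demonstrate about real data.

## Coordinate and format conventions

All internal coordinates are 1-based inclusive (the GFF3 convention);
bedGraph input, which is 0-based half-open, is converted at the boundary
and the conversion is exercised at positions 1 and chromosome-end in the
test suite. Splice-junction evidence is a 5-column TSV (chromosome, intron
first base, intron last base, strand, unique spliced reads), mirroring the
junction tabs of spliced aligners. Minus-strand sequence is
reverse-complemented before translation. Missing table values serialize as
`.`; FASTA wraps at 60 columns. GFF3/FASTA/TSV parsing is deliberately
restricted to the small dialect the pipeline writes (gene/mRNA/exon/CDS),
which keeps read→write→read round-trips byte-faithful; sequence handling
(FASTA I/O, translation, reverse complement) uses Biopython.

## Inventory

A TF record is a gene with at least one annotated regulatory/DNA-binding
domain instance (IPD). Percentages round half-away-from-zero to one
decimal; this rounding reproduces standard pie-chart arithmetic (331 of
520 → 63.7). Dual-specificity TFs (domains of ≥2 families) count once in
the TF total but once in every family's TF count, so family TF counts may
sum to more than the total; IPD counts are strictly per-domain and sum
exactly. This repetition policy is recorded in the summary metadata because
the alternative (assigning each dual TF to a single slice) is equally
defensible for pie charts; tables downstream (per-family expression) use
the same repetition rule for consistency. Signal-peptide and transmembrane
predictions are consumed as per-predictor inputs and never merged, so
disagreements between predictors stay visible.

## Gene-model reconciliation

The evidence model per predicted intron: `s` = spliced reads exactly
matching the intron boundaries (summed over samples), `u` = mean depth over
the intron interior (averaged over samples), `f = s/(s+u)`.

| status | rule |
|---|---|
| AMBIGUOUS | `s + u < min_intron_depth` (5) |
| ABSENT | `s < min_spliced` (3) |
| SUPPORTED | `f >= spliced_supported_frac` (0.9) |
| RETAINED | otherwise |

A gene is assessable when any single sample covers its exons at mean depth
≥ 5 — the depth floor mirrors the FPKM/TPM < 5 silence convention. These
thresholds formalize judgements that are otherwise made by eye in a genome
browser; they were chosen to reproduce the qualitative taxonomy
(retention vs absence vs support) with a wide margin at depth ~100 and all
live in `ReconciliationConfig`. Summing `s` while averaging `u` makes
pooled evidence lean toward splicing when samples disagree, which matches
how a curator reads stacked browser tracks.

ORF recomputation builds the mature transcript as exons plus the interiors
of RETAINED/ABSENT introns (AMBIGUOUS introns are treated as annotated) and
translates from the annotated start. A premature in-frame stop yields a
truncation with a stop-revision event when the truncated ORF has at least
`min_orf_codons` (50) codons; otherwise the transcript is rescanned 3′-ward
for the first ATG opening an ORF of ≥ 50 codons ending at a stop inside the
covered sequence (start revision). The first-qualifying-ATG rule is the
natural mechanization of picking "the next plausible Met" during manual
curation. A retained intron whose length is a multiple of three and whose
interior is stop-free is reported as an in-frame insertion with no
start/stop event. If no qualifying ORF exists the gene is flagged UTR-only
with an empty protein, never an exception.

A gene split is proposed when an internal run of ≥ 100 bases below depth 2
separates two flanks of mean depth ≥ 5 with no observed junction spanning
the run (a spanning junction means the dead zone is an intron, which
vetoes the split). The split takes precedence over a plain start revision;
the 5′ model keeps the annotated start and the 3′ model's ORF comes from
the start rescan. Duplicate loci are pairs of genes with byte-identical
full-length annotated proteins, flagged on both.

Domain impact maps each annotated domain onto the revised protein through
the matching blocks of a `difflib` anchored alignment (shared prefix,
suffix and conserved internal runs). This generalizes plain prefix/suffix
anchoring so that a protein with both a revised start and an internal
insertion still maps its conserved middle correctly; a domain is RETAINED
when every residue maps, LOST when none does, TRUNCATED otherwise.

A gene is CONCORDANT exactly when its event set is empty; AMBIGUOUS
introns alone never trigger re-annotation, so weakly covered introns in
otherwise expressed genes do not inflate the re-annotation count.

## Expression analysis

Silence is strict: a gene is silent when every value in every supplied
matrix is < 5 (a value of exactly 5 survives, matching a "values below 5
removed" masking rule). FPKM and TPM matrices are never mixed implicitly.
The fold-change screen uses `r = (b + 1)/(a + 1)` — the pseudocount of 1
guards zero denominators — with up-regulation `r >= 3` and down-regulation
`r <= 1/3`; "FC ≤ 3" is read as down-regulation and this reading is
recorded in the output metadata. The source experiments are single-run
(no biological replicates), so no variance model or significance test is
fitted anywhere: fold-change counting is deliberately the strongest claim
made. The shift score `(n_up − n_down)/(n_up + n_down)` is flagged as a
condition-wide shift at |score| ≥ 0.5 (configurable).

## Paralog evolution

Pairwise identity is counted over a global alignment with free end gaps
(BLOSUM62, gap open 11 / extend 1, via Biopython's `PairwiseAligner`) and
divided by the shorter sequence's length, so a perfect sub-sequence scores
1.0 — the CD-HIT convention. The two sequences are put in a canonical
order before aligning, which makes the value exactly symmetric even when
several alignments tie on score. Clustering is greedy longest-first
against cluster representatives at cutoff 0.3; CD-HIT's word-count
prefilter is not reproduced because at TF-family scale (hundreds of
proteins) exact alignment against every representative is affordable and
has no heuristic corner cases. Exact reproduction of a specific CD-HIT
run's memberships is not guaranteed (its non-default parameters are not
part of the contract); the greedy rule, cutoff semantics and partition
invariants are.

Duplication modes are classified from gene order: different chromosomes →
dispersed; adjacent (0 intervening genes) → tandem; ≤ 10 intervening genes
(an MCScanX-style proximal window, configurable) → proximal; else
dispersed. The cluster-level mode is the modal pair mode with dispersed on
ties. Reciprocal-best-hit confirmation takes the forward best hit by
bitscore (ties: lower E-value, then lexicographic subject id) and requires
the subject's reverse best hit to equal the original query. The
contact-residue report consumes an existing alignment (alignment tools are
out of scope) and names the outlier residues at divergent contact columns.

## Synthetic data: what it emulates, and what it does not

The generator plants, per 100-gene default dataset: 10 intron retentions,
8 absent introns, 6 start revisions, 4 gene splits, 2 duplicate-locus
pairs, 10 silent genes, a 20% fold-change shift (three quarters upward,
giving a shift score at the flag boundary), and three Zn2Cys6 paralog
families of sizes 2/3/6 placed tandem / proximal / dispersed. Exonic depth
is a rounded Gamma(shape = 4) draw scaled to the configured base depth of
100 (floored at 20 so every expressed gene is unambiguous); retained
introns carry an unspliced fraction of 0.55–0.85 of the flanking depth and
a correspondingly reduced spliced count, reproducing the mixed
spliced/unspliced pattern of real retention loci. Non-silent expression is
log-uniform on [5, 500], silent on [0.05, 4.9]; the two designated
fold-change samples are equal for unshifted genes so planted counts are
recovered exactly. Introns are always GT..AG; regions that must not
contain spurious start codons or stops (5′ extensions, dead zones) are
built from a three-letter alphabet without adenine, which excludes both
ATG and all stop codons by construction. Family members are 25%-mutated
copies of a per-family seed protein (identity ≈ 0.6–0.75 to the
representative, far above the 0.3 cutoff), while unrelated random proteins
align at ≈ 0.05–0.2 identity, far below it.

Passing the planted-recovery suite therefore shows that the evidence rules
and bookkeeping are implemented correctly under clean, well-separated
signals. It does not show robustness to the things real RNA-seq has and
the generator deliberately omits: read-level noise, coverage ramps at
exon boundaries, partial intron retention gradients, overlapping genes,
alternative donors/acceptors (detected only as a note), GC bias or
mapping artifacts. Threshold sensitivity on real data remains the user's
responsibility; every threshold is exposed in configuration and logged
when used.

Five hand-built reference fixtures complement the bulk benchmark, one per
canonical re-annotation outcome: retention truncating the protein to its
first domain; a start revision combined with a frame-preserving 17-codon
insertion; an absent intron with a downstream Met retaining only a
bZIP-like domain; a two-gene split at a coverage dead zone; and a
duplicate-locus pair.

## Numerical and reporting choices

Percentages round half-away-from-zero to one decimal via `decimal`, never
binary-float rounding. Ratios of up/down counts round the same way; a zero
down-count yields an undefined (null) ratio rather than infinity. Reports
serialize with sorted keys and no timestamps, so identical inputs give
byte-identical reports; the report schema (pydantic-generated JSON schema)
ships with the package and the written report validates against it. The
problem sizes used by the test suite and the acceptance script (100 genes,
3 samples, depth 100) are the generator's defaults, chosen as a realistic
small-genome workload that keeps every planted event class populated.

## Known limitations

- Reconciliation trusts exact junction-boundary matches; junctions that
  almost match an annotated intron (alternative donors/acceptors) are
  surfaced as notes, not model revisions.
- The split detector proposes at most one split per gene (the first
  qualifying dead zone) and requires both flanks to be expressed in the
  pooled view.
- Domain mapping by anchored alignment can under-map heavily diverged
  revised proteins; for the truncation/suffix/insertion cases that occur
  here it is exact.
- RBH confirmation assumes the hit tables are complete for the queries of
  interest; a missing query is reported as unconfirmed ("no hits"), not an
  error.
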