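"""Reconciliation of annotated gene models with RNA-seq evidence.

Each gene is classified as CONCORDANT (the transcriptome matches the
annotation), REANNOTATE (the evidence contradicts the model) or UNASSESSABLE
(expression too low to judge). The evidence is splice-junction counts and
per-base coverage; the analysis mirrors what a curator does by eye in a
genome browser, made explicit and thresholded.

Event vocabulary
----------------
INTRON_RETENTION   a predicted intron is mostly unspliced in the reads
ABSENT_INTRON      a predicted intron has no splicing support at all
START_REVISION     the coding sequence starts at a downstream Met
STOP_REVISION      the stop codon moves (premature or displaced by frameshift)
GENE_SPLIT         one model covers two separately expressed coding regions
DUPLICATE_LOCUS    two loci encode byte-identical annotated proteins
UTR_ONLY           no qualifying ORF remains in the covered sequence

Multi-sample evidence is pooled by summing spliced-read counts and averaging
intron interior depths across samples; a gene is assessable when any single
sample expresses it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from difflib import SequenceMatcher

import numpy as np

from .io_formats import (CoverageTrack, GeneModel, GenomicInterval,
                         JunctionRecord, extract_spliced)

# intron status
SUPPORTED = "SUPPORTED"
RETAINED = "RETAINED"
ABSENT = "ABSENT"
AMBIGUOUS = "AMBIGUOUS"

# gene category
CONCORDANT = "CONCORDANT"
REANNOTATE = "REANNOTATE"
UNASSESSABLE = "UNASSESSABLE"

# events
INTRON_RETENTION = "INTRON_RETENTION"
ABSENT_INTRON = "ABSENT_INTRON"
START_REVISION = "START_REVISION"
STOP_REVISION = "STOP_REVISION"
GENE_SPLIT = "GENE_SPLIT"
DUPLICATE_LOCUS = "DUPLICATE_LOCUS"
UTR_ONLY = "UTR_ONLY"

# domain impact
DOMAIN_RETAINED = "RETAINED"
DOMAIN_TRUNCATED = "TRUNCATED"
DOMAIN_LOST = "LOST"

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"

_CODON_TABLE = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table
        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


@dataclass
class ReconciliationConfig:
    """Evidence thresholds.

    min_spliced            spliced reads below which an intron counts unspliced
    spliced_supported_frac spliced fraction at/above which an intron is SUPPORTED
    min_intron_depth       total evidence (s+u) below which an intron is AMBIGUOUS
    min_gene_depth         mean exonic depth required (in >= 1 sample) to assess
                           a gene; mirrors the FPKM/TPM < 5 silence convention
    split_gap_min          minimum internal low-coverage run proposing a split
    split_gap_depth        depth below which a base counts as uncovered
    min_orf_codons         minimum ORF length (codons, excluding the stop) for
                           truncation reports and start-codon rescans
    """

    min_spliced: int = 3
    spliced_supported_frac: float = 0.9
    min_intron_depth: int = 5
    min_gene_depth: float = 5.0
    split_gap_min: int = 100
    split_gap_depth: float = 2.0
    min_orf_codons: int = 50

    def __post_init__(self) -> None:
        if min(self.min_spliced, self.min_intron_depth, self.min_gene_depth,
               self.split_gap_min, self.split_gap_depth, self.min_orf_codons) <= 0:
            raise ValueError("all thresholds must be positive")
        if not 0 < self.spliced_supported_frac <= 1:
            raise ValueError("spliced_supported_frac must be in (0, 1]")


@dataclass
class IntronStatus:
    intron: GenomicInterval
    status: str
    spliced_reads: int
    unspliced_depth: float

    @property
    def spliced_fraction(self) -> float | None:
        tot = self.spliced_reads + self.unspliced_depth
        return self.spliced_reads / tot if tot > 0 else None


@dataclass
class ReannotationCall:
    gene_id: str
    category: str
    events: set[str] = field(default_factory=set)
    intron_statuses: list[IntronStatus] = field(default_factory=list)
    revised_models: list[GeneModel] = field(default_factory=list)
    revised_proteins: list[str] = field(default_factory=list)
    domain_impact: dict[tuple[str, int, int], str] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# evidence primitives
# ---------------------------------------------------------------------------


def assess_expression(gene: GeneModel, coverage_tracks: list[CoverageTrack],
                      config: ReconciliationConfig) -> bool:
    """True when at least one sample covers the gene's exons at or above
    ``min_gene_depth`` mean depth."""
    for track in coverage_tracks:
        if gene.chrom not in track:
            raise KeyError(f"chromosome {gene.chrom!r} missing from coverage track")
    return any(track.mean_depth(gene.chrom, gene.exons) >= config.min_gene_depth
               for track in coverage_tracks)


def classify_intron(intron: GenomicInterval,
                    junction_sets: list[list[JunctionRecord]],
                    coverage_tracks: list[CoverageTrack],
                    config: ReconciliationConfig) -> IntronStatus:
    """Status of one predicted intron from pooled evidence.

    s = spliced reads whose junction matches the intron's exact boundaries,
    summed over samples; u = intron-interior mean depth averaged over
    samples. AMBIGUOUS when s+u is below ``min_intron_depth``; ABSENT when s
    is below ``min_spliced``; SUPPORTED when the spliced fraction s/(s+u)
    reaches ``spliced_supported_frac``; RETAINED otherwise.
    """
    key = (intron.chrom, intron.start, intron.end)
    s = sum(j.spliced_reads for js in junction_sets for j in js
            if (j.intron.chrom, j.intron.start, j.intron.end) == key)
    depths = [t.mean_depth(intron.chrom, [intron]) for t in coverage_tracks]
    u = float(np.mean(depths)) if depths else 0.0
    if s + u < config.min_intron_depth:
        status = AMBIGUOUS
    elif s < config.min_spliced:
        status = ABSENT
    elif s / (s + u) >= config.spliced_supported_frac:
        status = SUPPORTED
    else:
        status = RETAINED
    return IntronStatus(intron, status, s, u)


# ---------------------------------------------------------------------------
# ORF recomputation
# ---------------------------------------------------------------------------


def _merge_intervals(ivs: list[GenomicInterval]) -> list[GenomicInterval]:
    ivs = sorted(ivs, key=lambda iv: iv.start)
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and iv.start <= out[-1].end + 1:
            prev = out[-1]
            out[-1] = GenomicInterval(prev.chrom, prev.start,
                                      max(prev.end, iv.end), prev.strand)
        else:
            out.append(iv)
    return out


def _transcript(genome: dict[str, str], model: GeneModel,
                statuses: list[IntronStatus],
                span: tuple[int, int] | None = None) -> tuple[str, list[int]]:
    """Mature-transcript sequence (5'->3') and the genomic position of each
    transcript base. Exons plus the interiors of RETAINED/ABSENT introns;
    SUPPORTED and AMBIGUOUS introns are spliced out as annotated. ``span``
    optionally clips to a genomic sub-interval (used for gene splits)."""
    keep = list(model.exons)
    keep += [st.intron for st in statuses if st.status in (RETAINED, ABSENT)]
    merged = _merge_intervals(keep)
    if span is not None:
        lo, hi = span
        clipped = []
        for iv in merged:
            s, t = max(iv.start, lo), min(iv.end, hi)
            if s <= t:
                clipped.append(GenomicInterval(iv.chrom, s, t, iv.strand))
        merged = clipped
    positions: list[int] = []
    for iv in merged:
        positions.extend(range(iv.start, iv.end + 1))
    comp = str.maketrans("ACGTN", "TGCAN")
    seq = "".join(genome[model.chrom][p - 1] for p in positions)
    if model.strand == "-":
        seq = seq.translate(comp)[::-1]
        positions = positions[::-1]
    return seq, positions


def translate(seq: str) -> str:
    """Translate codons until (excluding) the first stop; standard code."""
    table = _codon_table()
    out = []
    for i in range(0, len(seq) - 2, 3):
        aa = table.get(seq[i : i + 3], "X")
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def _first_stop(seq: str, start: int) -> int | None:
    """Transcript index of the first in-frame stop codon at/after ``start``."""
    for i in range(start, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return i
    return None


def _scan_start(seq: str, from_idx: int, min_codons: int) -> tuple[int, int] | None:
    """First ATG at/after ``from_idx`` opening an ORF of >= ``min_codons``
    codons that ends at a stop within the sequence. Returns (atg_idx,
    stop_idx) or None."""
    i = seq.find(START_CODON, from_idx)
    while i != -1:
        stop = _first_stop(seq, i)
        if stop is not None and (stop - i) // 3 >= min_codons:
            return i, stop
        i = seq.find(START_CODON, i + 1)
    return None


def recompute_orf(genome: dict[str, str], model: GeneModel,
                  statuses: list[IntronStatus], config: ReconciliationConfig,
                  span: tuple[int, int] | None = None,
                  force_start_scan: bool = False,
                  ) -> tuple[GeneModel | None, str, set[str]]:
    """Recompute the coding sequence on the evidence-corrected transcript.

    The mature transcript keeps the interiors of RETAINED/ABSENT introns and
    splices out SUPPORTED (and AMBIGUOUS) ones. Translation starts from the
    annotated start codon. A premature in-frame stop yields a truncated
    protein with a STOP_REVISION event when the truncated ORF is long enough
    (>= ``min_orf_codons``); otherwise the transcript is rescanned 3'-ward
    for the first ATG opening a qualifying ORF (START_REVISION). A retained
    intron that preserves frame and reaches the annotated stop is an in-frame
    insertion: no start/stop event. When no qualifying ORF exists the gene is
    flagged UTR_ONLY with an empty protein.

    Returns (revised model or None, revised protein, events).
    """
    events: set[str] = set()
    for st in statuses:
        if st.status == RETAINED:
            events.add(INTRON_RETENTION)
        elif st.status == ABSENT:
            events.add(ABSENT_INTRON)

    seq, positions = _transcript(genome, model, statuses, span=span)
    if not seq:
        return None, "", {UTR_ONLY}
    pos_index = {p: i for i, p in enumerate(positions)}
    anno_start_pos = model.cds_start if model.strand == "+" else model.cds_end
    anno_stop_last = model.cds_end if model.strand == "+" else model.cds_start
    anno_stop_idx = pos_index.get(anno_stop_last)  # last base of stop codon

    start_idx = pos_index.get(anno_start_pos)
    scanned = False
    if force_start_scan or start_idx is None or seq[start_idx : start_idx + 3] != START_CODON:
        hit = _scan_start(seq, 0, config.min_orf_codons)
        if hit is None:
            return None, "", events | {UTR_ONLY}
        start_idx, stop_idx = hit
        scanned = True
    else:
        stop_idx = _first_stop(seq, start_idx)
        if stop_idx is None:
            # frame runs off the covered sequence: report to transcript end
            events.add(STOP_REVISION)
            protein = translate(seq[start_idx:])
            return _revised_model(model, positions, start_idx,
                                  len(seq) - 1, statuses, span), protein, events
        n_codons = (stop_idx - start_idx) // 3
        premature = anno_stop_idx is None or stop_idx + 2 < anno_stop_idx
        if premature and n_codons < config.min_orf_codons:
            hit = _scan_start(seq, start_idx + 1, config.min_orf_codons)
            if hit is None:
                return None, "", events | {UTR_ONLY}
            start_idx, stop_idx = hit
            scanned = True

    if scanned:
        events.add(START_REVISION)
    if anno_stop_idx is not None and stop_idx + 2 != anno_stop_idx:
        events.add(STOP_REVISION)
    protein = translate(seq[start_idx:])
    revised = _revised_model(model, positions, start_idx, stop_idx + 2, statuses, span)
    return revised, protein, events


def _revised_model(model: GeneModel, positions: list[int], start_idx: int,
                   end_idx: int, statuses: list[IntronStatus],
                   span: tuple[int, int] | None) -> GeneModel:
    """Gene model for a recomputed ORF: exon structure with RETAINED/ABSENT
    introns promoted to exon sequence, CDS spanning the new start..stop."""
    keep = list(model.exons)
    keep += [st.intron for st in statuses if st.status in (RETAINED, ABSENT)]
    merged = _merge_intervals(keep)
    if span is not None:
        lo, hi = span
        merged = [GenomicInterval(iv.chrom, max(iv.start, lo), min(iv.end, hi), iv.strand)
                  for iv in merged if max(iv.start, lo) <= min(iv.end, hi)]
    g1, g2 = positions[start_idx], positions[min(end_idx, len(positions) - 1)]
    cds_start, cds_end = min(g1, g2), max(g1, g2)
    return GeneModel(model.gene_id, merged, cds_start, cds_end)


# ---------------------------------------------------------------------------
# gene splits and duplicate loci
# ---------------------------------------------------------------------------


@dataclass
class SplitProposal:
    gap: GenomicInterval
    five_prime_span: tuple[int, int]
    three_prime_span: tuple[int, int]


def detect_gene_split(gene: GeneModel, coverage_tracks: list[CoverageTrack],
                      junction_sets: list[list[JunctionRecord]],
                      config: ReconciliationConfig) -> SplitProposal | None:
    """Propose splitting a gene in two at an internal expression dead zone.

    A split requires an internal run of >= ``split_gap_min`` bases with
    pooled depth below ``split_gap_depth`` that separates two flanks each
    with mean depth >= ``min_gene_depth``, and no observed junction spanning
    the run (a spanning junction means the dead zone is an intron).
    """
    pooled = np.mean([t.slice(gene.chrom, gene.start, gene.end)
                      for t in coverage_tracks], axis=0)
    low = pooled < config.split_gap_depth
    # maximal low-coverage runs
    idx = np.flatnonzero(np.diff(np.concatenate([[0], low.view(np.int8), [0]])))
    for run_start, run_end in zip(idx[::2], idx[1::2]):  # half-open, 0-based
        if run_end - run_start < config.split_gap_min:
            continue
        if run_start == 0 or run_end == pooled.size:
            continue  # not internal
        gap = GenomicInterval(gene.chrom, gene.start + run_start,
                              gene.start + run_end - 1, gene.strand)
        left = pooled[:run_start]
        right = pooled[run_end:]
        if left.mean() < config.min_gene_depth or right.mean() < config.min_gene_depth:
            continue
        spanned = any(j.intron.start <= gap.start and j.intron.end >= gap.end
                      and j.spliced_reads > 0
                      for js in junction_sets for j in js
                      if j.intron.chrom == gene.chrom)
        if spanned:
            continue
        left_span = (gene.start, gap.start - 1)
        right_span = (gap.end + 1, gene.end)
        if gene.strand == "+":
            return SplitProposal(gap, left_span, right_span)
        return SplitProposal(gap, right_span, left_span)
    return None


def annotated_protein(genome: dict[str, str], model: GeneModel) -> str:
    """Protein encoded by the annotated CDS with all predicted introns
    spliced out."""
    seq = extract_spliced(genome, model.chrom, model.strand, model.cds_intervals())
    return translate(seq)


def detect_duplicate_loci(proteins: dict[str, str]) -> dict[str, set[str]]:
    """Map each gene whose full-length annotated protein is byte-identical to
    another locus's onto the set of its duplicate partners."""
    groups: dict[str, list[str]] = {}
    for gid, prot in proteins.items():
        groups.setdefault(prot, []).append(gid)
    out: dict[str, set[str]] = {}
    for members in groups.values():
        if len(members) > 1:
            for gid in members:
                out[gid] = set(members) - {gid}
    return out


# ---------------------------------------------------------------------------
# domain impact
# ---------------------------------------------------------------------------


def domain_impact(revised_protein: str, annotated_protein: str,
                  domains: list) -> dict[tuple[str, int, int], str]:
    """Fate of each annotated domain on the revised protein.

    Annotated positions are mapped onto the revised protein through the
    matching blocks of an anchored alignment of the two sequences (shared
    prefixes/suffixes and any conserved internal runs). A domain is RETAINED
    when every residue maps, LOST when none does, TRUNCATED otherwise.
    """
    matcher = SequenceMatcher(None, annotated_protein, revised_protein, autojunk=False)
    mapped = np.zeros(len(annotated_protein) + 1, dtype=bool)
    for block in matcher.get_matching_blocks():
        mapped[block.a + 1 : block.a + block.size + 1] = True  # 1-based aa
    out = {}
    for dom in domains:
        inside = mapped[dom.aa_start : dom.aa_end + 1]
        if inside.size and inside.all():
            status = DOMAIN_RETAINED
        elif inside.any():
            status = DOMAIN_TRUNCATED
        else:
            status = DOMAIN_LOST
        out[(dom.family, dom.aa_start, dom.aa_end)] = status
    return out


# ---------------------------------------------------------------------------
# per-gene classification and summary
# ---------------------------------------------------------------------------


def classify_gene(genome: dict[str, str], model: GeneModel,
                  junction_sets: list[list[JunctionRecord]],
                  coverage_tracks: list[CoverageTrack],
                  config: ReconciliationConfig,
                  duplicate_partners: set[str] | None = None,
                  domains: list | None = None) -> ReannotationCall:
    """Run the full evidence check for one gene and emit its call.

    UNASSESSABLE genes (no sample reaches ``min_gene_depth``) are returned
    immediately. Otherwise intron statuses, the split test and ORF
    recomputation decide the event set; a gene is CONCORDANT only when the
    event set is empty (AMBIGUOUS introns alone never trigger reannotation).
    A passing split-gap test takes precedence over a plain start revision.
    """
    if not assess_expression(model, coverage_tracks, config):
        return ReannotationCall(model.gene_id, UNASSESSABLE)

    statuses = [classify_intron(iv, junction_sets, coverage_tracks, config)
                for iv in model.introns]
    events: set[str] = set()
    revised_models: list[GeneModel] = []
    revised_proteins: list[str] = []

    split = detect_gene_split(model, coverage_tracks, junction_sets, config)
    if split is not None:
        events.add(GENE_SPLIT)
        for st in statuses:
            if st.status == RETAINED:
                events.add(INTRON_RETENTION)
            elif st.status == ABSENT:
                events.add(ABSENT_INTRON)
        for i, side in enumerate((split.five_prime_span, split.three_prime_span)):
            side_statuses = [st for st in statuses
                             if st.intron.start <= side[1] and st.intron.end >= side[0]]
            m, prot, _ = recompute_orf(genome, model, side_statuses, config,
                                       span=side, force_start_scan=(i == 1))
            if m is not None:
                m = GeneModel(f"{model.gene_id}.{i + 1}", m.exons, m.cds_start, m.cds_end)
                revised_models.append(m)
                revised_proteins.append(prot)
    else:
        revised, protein, orf_events = recompute_orf(genome, model, statuses, config)
        events |= orf_events
        if events and revised is not None:
            revised_models.append(revised)
            revised_proteins.append(protein)

    if duplicate_partners:
        events.add(DUPLICATE_LOCUS)

    category = CONCORDANT if not events else REANNOTATE
    call = ReannotationCall(model.gene_id, category, events, statuses,
                            revised_models, revised_proteins)

    if domains and revised_proteins:
        anno = model.protein or annotated_protein(genome, model)
        # for splits, judge domains against the concatenated revised peptides
        revised_cat = "".join(revised_proteins)
        call.domain_impact = domain_impact(revised_cat, anno, domains)

    annotated_keys = {(iv.chrom, iv.start, iv.end) for iv in model.introns}
    for js in junction_sets:
        for j in js:
            if (j.intron.chrom == model.chrom and j.spliced_reads >= config.min_spliced
                    and j.intron.start >= model.start and j.intron.end <= model.end
                    and (j.intron.chrom, j.intron.start, j.intron.end) not in annotated_keys):
                note = (f"novel junction {j.intron.start}-{j.intron.end} "
                        f"({j.spliced_reads} reads) not matching any annotated intron")
                if note not in call.notes:
                    call.notes.append(note)
    return call


def summarize_reconciliation(calls: list[ReannotationCall]) -> dict:
    """Category counts and one-decimal percentages over all calls."""
    from .inventory import family_share

    counts = {CONCORDANT: 0, REANNOTATE: 0, UNASSESSABLE: 0}
    event_counts: dict[str, int] = {}
    for c in calls:
        counts[c.category] += 1
        for ev in c.events:
            event_counts[ev] = event_counts.get(ev, 0) + 1
    total = len(calls)
    pct = {k: family_share(v, total) for k, v in counts.items()} if total else {}
    return {"n_genes": total, "counts": counts, "percentages": pct,
            "event_counts": dict(sorted(event_counts.items()))}
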