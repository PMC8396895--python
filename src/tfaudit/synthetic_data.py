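"""Synthetic genome, annotation, RNA-seq evidence and table generator with
planted, machine-readable ground truth.

The generator emulates the statistical structure of a fungal TFome audit:
genes with 0-5 spliceosomal introns (GT..AG), a minority of introns retained
or absent in the transcriptome, mis-annotated start codons, split loci,
identical duplicate loci, silent genes (all expression values below 5),
condition-wide fold-change shifts between two designated samples, and
paralog families placed tandemly, proximally or dispersed across
chromosomes. Every planted event is recorded in a truth manifest so each
downstream stage can be scored exactly.

Evidence is generated at the summary level a spliced aligner would report
(exact junction counts, per-base depth), not at the read level. Exonic
depth is a rounded Gamma(shape=4) draw scaled to the configured base depth;
a retained intron carries an unspliced fraction of the flanking depth plus a
correspondingly reduced spliced-read count, which reproduces the mixed
spliced/unspliced coverage pattern of real intron-retention loci.

All randomness flows from one seeded generator; a fixed seed fixes every
output byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inventory import DomainAnnotation
from .io_formats import (CoverageTrack, GeneModel, GenomicInterval,
                         JunctionRecord, write_bedgraph, write_genome_fasta,
                         write_gff3, write_junctions, write_protein_fasta,
                         write_tsv)
from .paralogs import DISPERSED, PROXIMAL, TANDEM
from .reconciliation import (ABSENT, ABSENT_INTRON, CONCORDANT,
                             DUPLICATE_LOCUS, GENE_SPLIT, INTRON_RETENTION,
                             REANNOTATE, RETAINED, START_REVISION,
                             STOP_REVISION, SUPPORTED, UNASSESSABLE,
                             translate)

_CODONS61: list[str] = []
_AA2CODONS: dict[str, list[str]] = {}


def _codon_tables() -> tuple[list[str], dict[str, list[str]]]:
    if not _CODONS61:
        from Bio.Data.CodonTable import standard_dna_table
        for codon, aa in sorted(standard_dna_table.forward_table.items()):
            _CODONS61.append(codon)
            _AA2CODONS.setdefault(aa, []).append(codon)
    return _CODONS61, _AA2CODONS


AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# configuration and truth manifest
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Event fractions are fractions of ``n_genes``; the event sets are
    disjoint by construction (each gene carries at most one planted event
    class). ``paralog_families`` lists (size, mode) with mode TANDEM,
    PROXIMAL or DISPERSED; family members are generated by mutating a seed
    protein well below the clustering divergence ceiling. ``fc_shift`` is
    the fraction of genes shifted at least 3-fold between the two designated
    samples (S1 vs S2), three quarters of them upward so the comparison
    carries a condition-wide shift.
    """

    seed: int
    n_chromosomes: int = 2
    n_genes: int = 100
    frac_intron_retention: float = 0.10
    frac_absent_intron: float = 0.08
    frac_start_revision: float = 0.06
    frac_gene_split: float = 0.04
    frac_duplicate_locus: float = 0.04
    frac_silent: float = 0.10
    n_samples: int = 3
    base_depth: float = 100.0
    paralog_families: list[tuple[int, str]] = field(
        default_factory=lambda: [(2, TANDEM), (3, PROXIMAL), (6, DISPERSED)])
    fc_shift: float = 0.20
    fc_up_share: float = 0.75
    proximal_window: int = 10
    named_fraction: float = 0.25
    dual_fraction: float = 0.15
    unconfirmed_ortholog_fraction: float = 0.10

    def __post_init__(self) -> None:
        fracs = [self.frac_intron_retention, self.frac_absent_intron,
                 self.frac_start_revision, self.frac_gene_split,
                 self.frac_duplicate_locus, self.frac_silent, self.fc_shift]
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("event fractions must lie in [0, 1]")
        if self.n_genes < 1 or self.n_chromosomes < 1 or self.n_samples < 1:
            raise ValueError("n_genes, n_chromosomes, n_samples must be >= 1")
        for size, mode in self.paralog_families:
            if size < 2 or mode not in (TANDEM, PROXIMAL, DISPERSED):
                raise ValueError(f"bad paralog family spec ({size}, {mode})")
        if self.fc_shift > 0 and self.n_samples < 2:
            raise ValueError("fc_shift needs at least two samples")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "paralog_families" in raw:
            raw["paralog_families"] = [tuple(x) for x in raw["paralog_families"]]
        return cls(**raw)


@dataclass
class TruthManifest:
    """Planted ground truth: one entry per generated gene plus dataset
    totals and the planted paralog-family table."""

    genes: dict[str, dict]
    families: dict[str, dict]
    totals: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"genes": self.genes, "families": self.families,
                       "totals": self.totals}, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(raw["genes"], raw["families"], raw["totals"])


@dataclass
class SimulationResult:
    out_dir: Path
    paths: dict[str, Path]
    manifest: TruthManifest


# ---------------------------------------------------------------------------
# local gene construction (1-based coordinates within the gene, 5'->3')
# ---------------------------------------------------------------------------


@dataclass
class _LocalGene:
    seq: str = ""
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: tuple[int, int] = (0, 0)
    covered: list[tuple[int, int]] = field(default_factory=list)
    retained_intervals: list[tuple[int, int]] = field(default_factory=list)
    #: (intron local interval, "supported" | "retained")
    junctions: list[tuple[tuple[int, int], str]] = field(default_factory=list)
    annotated_protein: str = ""
    events: set[str] = field(default_factory=set)
    true_statuses: list[str] = field(default_factory=list)
    revised_proteins: list[str] = field(default_factory=list)
    revised_start_local: int | None = None


class _Writer:
    """Sequential sequence writer tracking local 1-based intervals."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.pos = 0

    def add(self, seq: str) -> tuple[int, int]:
        start = self.pos + 1
        self.parts.append(seq)
        self.pos += len(seq)
        return (start, self.pos)

    @property
    def seq(self) -> str:
        return "".join(self.parts)


def _no_a(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("CGT"), n)) if n else ""


def _random_codons(rng: np.random.Generator, n: int) -> str:
    codons, _ = _codon_tables()
    return "".join(rng.choice(codons, n)) if n else ""


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    _, aa2 = _codon_tables()
    return "".join(rng.choice(aa2[aa]) for aa in protein)


def _stop(rng: np.random.Generator) -> str:
    return str(rng.choice(["TAA", "TAG", "TGA"]))


def _supported_intron(rng: np.random.Generator) -> str:
    n = int(rng.integers(50, 81))
    return "GT" + _no_a(rng, n - 4) + "AG"


def _stop_intron(rng: np.random.Generator) -> str:
    """Intron whose retention reads a premature stop: inserted at a codon
    boundary, its first codon is GTx and its second the planted TAA."""
    n = int(rng.integers(50, 81))
    return "GT" + _no_a(rng, 1) + "TAA" + _no_a(rng, n - 9) + "AG"


def _build_coding(rng: np.random.Generator, role: str,
                  protein_body: str | None = None) -> _LocalGene:
    """A gene whose introns all fall inside the CDS.

    role: concordant | silent | duplicate | paralog | retention | absent.
    For retention/absent, one intron carries the event with an in-frame
    premature stop (placed after >= 55 codons so the truncated ORF clears
    the minimum ORF length and the call is a stop revision, not a rescue
    scan).
    """
    if protein_body is None:
        k = int(rng.integers(120, 201))
        body = _random_codons(rng, k)
    else:
        body = _reverse_translate(rng, protein_body)
        k = len(protein_body)

    if role in ("retention", "absent"):
        n_introns = int(rng.integers(1, 4))
        event_idx = int(rng.integers(0, n_introns))
    else:
        hi = 3 if role == "paralog" else 6
        n_introns = int(rng.integers(0, hi))
        event_idx = -1

    # distinct codon boundaries, event intron late enough for a long ORF
    boundaries: list[int] = []
    tries = 0
    while len(boundaries) < n_introns and tries < 200:
        tries += 1
        lo = 55 if len(boundaries) == 0 and event_idx >= 0 else 8
        c = int(rng.integers(lo, k - 8))
        if all(abs(c - b) >= 4 for b in boundaries):
            boundaries.append(c)
    boundaries = sorted(boundaries[:n_introns])
    if event_idx >= 0:
        event_idx = max(i for i, b in enumerate(boundaries) if b >= 55) \
            if any(b >= 55 for b in boundaries) else 0

    g = _LocalGene()
    w = _Writer()
    utr5 = w.add(_no_a(rng, int(rng.integers(25, 60))))
    cds_pieces: list[tuple[int, int]] = []
    introns: list[tuple[tuple[int, int], str]] = []

    cursor = 0  # bases of CDS written so far
    cds_seq = "ATG" + body + _stop(rng)
    exon_open = utr5[0]
    for i, c in enumerate(boundaries):
        cut = 3 + 3 * c
        piece = w.add(cds_seq[cursor:cut])
        cds_pieces.append(piece)
        cursor = cut
        if i == event_idx:
            iv = w.add(_stop_intron(rng))
            status = RETAINED if role == "retention" else ABSENT
        else:
            iv = w.add(_supported_intron(rng))
            status = SUPPORTED
        introns.append((iv, status))
        g.exons.append((exon_open, piece[1]))
        exon_open = iv[1] + 1
    last = w.add(cds_seq[cursor:])
    utr3 = w.add(_no_a(rng, int(rng.integers(25, 60))))
    g.exons.append((exon_open, utr3[1]))

    g.seq = w.seq
    g.cds = (utr5[1] + 1, last[1])
    g.annotated_protein = "M" + translate_body(body)
    g.true_statuses = [st for _, st in introns]

    for iv, status in introns:
        if status == SUPPORTED:
            g.junctions.append((iv, "supported"))
        elif status == RETAINED:
            g.junctions.append((iv, "retained"))
            g.retained_intervals.append(iv)
    # covered regions: exons always; ABSENT intron interiors too
    g.covered = list(g.exons)
    for iv, status in introns:
        if status == ABSENT:
            g.covered.append(iv)

    if event_idx >= 0:
        ev_iv, ev_status = introns[event_idx]
        # mature prefix: exonic CDS pieces up to the event intron (upstream
        # supported introns spliced out), then read into the event intron
        prefix = "".join(g.seq[p0 - 1 : p1]
                         for p0, p1 in cds_pieces[: event_idx + 1])
        prot = translate(prefix + g.seq[ev_iv[0] - 1 : ev_iv[1]])
        g.revised_proteins = [prot]
        g.events = ({INTRON_RETENTION if ev_status == RETAINED else ABSENT_INTRON,
                     STOP_REVISION})
    return g


def translate_body(body: str) -> str:
    """Translate a stop-free codon string (helper for annotated proteins)."""
    return translate(body + "TAA")


def _build_start_revision(rng: np.random.Generator) -> _LocalGene:
    """Annotated start is wrong: the predicted first intron is actually
    absent and reads a premature stop; the real ORF begins at a downstream
    Met. The region between the annotated and the real start contains no ATG
    and no stop in the annotated spliced frame, so the annotated protein is
    clean and the rescan lands exactly on the planted Met."""
    g = _LocalGene()
    w = _Writer()
    a = _no_a(rng, 9)
    b = _no_a(rng, 9)
    k = int(rng.integers(100, 161))
    body = _random_codons(rng, k)

    utr5 = w.add(_no_a(rng, int(rng.integers(25, 60))))
    atg0 = w.add("ATG")
    a_iv = w.add(a)
    intron = w.add(_stop_intron(rng))
    b_iv = w.add(b)
    orf = w.add("ATG" + body + _stop(rng))
    utr3 = w.add(_no_a(rng, int(rng.integers(25, 60))))

    g.seq = w.seq
    g.exons = [(utr5[0], a_iv[1]), (b_iv[0], utr3[1])]
    g.cds = (atg0[0], orf[1])
    g.annotated_protein = ("M" + translate_body(a + b)[: len(a + b) // 3]
                           + "M" + translate_body(body))
    g.true_statuses = [ABSENT]
    g.covered = [g.exons[0], intron, g.exons[1]]
    g.events = {ABSENT_INTRON, START_REVISION}
    g.revised_proteins = ["M" + translate_body(body)]
    g.revised_start_local = orf[0]
    return g


def _build_split(rng: np.random.Generator) -> _LocalGene:
    """One annotated model over two separately expressed ORFs.

    The single predicted intron (GT..AG) hides the first ORF's stop codon
    and the second ORF's promoter region, so the annotated protein is one
    clean peptide; the transcriptome shows two covered blocks separated by a
    dead zone of ~150 uncovered bases with no spanning junction."""
    g = _LocalGene()
    w = _Writer()
    kA = int(rng.integers(55, 76))
    j = int(rng.integers(35, kA - 12))
    bodyA = _random_codons(rng, j) + "GTT" + _random_codons(rng, kA - j - 1)
    kB = int(rng.integers(55, 76))
    bodyB = _random_codons(rng, kB)

    utrA = w.add(_no_a(rng, int(rng.integers(25, 50))))
    exon1 = w.add("ATG" + bodyA[: 3 * j])
    rest1 = w.add(bodyA[3 * j :] + "TAA" + _no_a(rng, 20))
    dead = w.add(_no_a(rng, int(rng.integers(140, 181))))
    pre_b = w.add(_no_a(rng, 8) + "AG")
    exon2 = w.add("ATG" + bodyB + "TAA" + _no_a(rng, int(rng.integers(20, 40))))

    g.seq = w.seq
    g.exons = [(utrA[0], exon1[1]), (exon2[0], exon2[1])]
    g.cds = (utrA[1] + 1, exon2[0] + 3 * kB + 5)
    g.annotated_protein = ("M" + translate_body(bodyA[: 3 * j])
                           + "M" + translate_body(bodyB))
    g.true_statuses = [ABSENT]
    g.covered = [g.exons[0], rest1, (pre_b[0], exon2[1])]
    g.events = {GENE_SPLIT, ABSENT_INTRON}
    g.revised_proteins = ["M" + translate_body(bodyA),
                          "M" + translate_body(bodyB)]
    g.revised_start_local = exon2[0]
    g.dead_zone = dead  # type: ignore[attr-defined]
    return g


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _map_iv(local: tuple[int, int], g0: int, length: int, strand: str,
            chrom: str) -> GenomicInterval:
    s, e = local
    if strand == "+":
        return GenomicInterval(chrom, g0 + s - 1, g0 + e - 1, strand)
    return GenomicInterval(chrom, g0 + length - e, g0 + length - s, strand)


def _map_pos(p: int, g0: int, length: int, strand: str) -> int:
    return g0 + p - 1 if strand == "+" else g0 + length - p


@dataclass
class _Placed:
    gene_id: str
    local: _LocalGene
    chrom: str
    g0: int
    strand: str
    role: str
    slot: int
    family_id: str | None = None
    duplicate_partner: str | None = None

    @property
    def length(self) -> int:
        return len(self.local.seq)

    def interval(self, local_iv: tuple[int, int]) -> GenomicInterval:
        return _map_iv(local_iv, self.g0, self.length, self.strand, self.chrom)

    def model(self) -> GeneModel:
        exons = sorted((self.interval(e) for e in self.local.exons),
                       key=lambda iv: iv.start)
        c1 = _map_pos(self.local.cds[0], self.g0, self.length, self.strand)
        c2 = _map_pos(self.local.cds[1], self.g0, self.length, self.strand)
        return GeneModel(self.gene_id, exons, min(c1, c2), max(c1, c2),
                         protein=self.local.annotated_protein)


def _plan_slots(cfg: SimulationConfig, rng: np.random.Generator) -> dict:
    """Assign roles, paralog families and duplicate pairs to gene slots.

    Slots are numbered in genomic order (chromosome-major); the slot index
    is also the gene-order index used by duplication-mode classification.
    Raises on infeasible configurations before anything is written.
    """
    n = cfg.n_genes
    per_chrom = [n // cfg.n_chromosomes + (1 if i < n % cfg.n_chromosomes else 0)
                 for i in range(cfg.n_chromosomes)]
    chrom_of: list[int] = []
    for ci, cnt in enumerate(per_chrom):
        chrom_of += [ci] * cnt
    free = set(range(n))

    def take(slots: list[int], what: str) -> None:
        if any(s not in free for s in slots) or any(s >= n for s in slots):
            raise ValueError(f"infeasible config: cannot place {what}")
        free.difference_update(slots)

    chrom_slots = {ci: [s for s in range(n) if chrom_of[s] == ci]
                   for ci in range(cfg.n_chromosomes)}

    families: dict[str, dict] = {}
    for fi, (size, mode) in enumerate(cfg.paralog_families):
        fam_id = f"fam{fi + 1}"
        if mode == TANDEM:
            base = None
            for ci in range(cfg.n_chromosomes):
                runs = [s for s in chrom_slots[ci]
                        if all(s + k in free and chrom_of[min(s + k, n - 1)] == ci
                               for k in range(size))]
                if runs:
                    base = [runs[0] + k for k in range(size)]
                    break
            if base is None:
                raise ValueError("infeasible config: no room for tandem family")
            slots = base
        elif mode == PROXIMAL:
            step = max(2, cfg.proximal_window // (size - 1))
            if step * (size - 1) - 1 > cfg.proximal_window:
                raise ValueError("infeasible config: proximal family too large")
            slots = None
            for ci in range(cfg.n_chromosomes):
                cand = [s for s in chrom_slots[ci]
                        if all(s + k * step in free
                               and s + k * step < n
                               and chrom_of[s + k * step] == ci
                               for k in range(size))]
                if cand:
                    slots = [cand[0] + k * step for k in range(size)]
                    break
            if slots is None:
                raise ValueError("infeasible config: no room for proximal family")
        else:  # DISPERSED: spread across chromosomes, far apart within one
            slots = []
            gap = cfg.proximal_window + 2
            for k in range(size):
                ci = k % cfg.n_chromosomes
                cand = [s for s in chrom_slots[ci] if s in free
                        and all(abs(s - t) >= gap or chrom_of[t] != ci
                                for t in slots)]
                if not cand:
                    raise ValueError("infeasible config: no room for dispersed family")
                slots.append(cand[len(cand) // 2])
        take(slots, f"paralog family {fam_id}")
        families[fam_id] = {"slots": slots, "size": size, "mode": mode}

    n_dup_pairs = round(cfg.frac_duplicate_locus * n / 2)
    dup_pairs: list[tuple[int, int]] = []
    for _ in range(n_dup_pairs):
        c_first = sorted(free)
        if len(c_first) < 2:
            raise ValueError("infeasible config: no room for duplicate loci")
        a = c_first[0]
        others = [s for s in c_first[1:] if chrom_of[s] != chrom_of[a]] or c_first[1:]
        b = others[-1]
        take([a, b], "duplicate pair")
        dup_pairs.append((a, b))

    roles: dict[int, str] = {}
    counts = {"retention": round(cfg.frac_intron_retention * n),
              "absent": round(cfg.frac_absent_intron * n),
              "start_revision": round(cfg.frac_start_revision * n),
              "split": round(cfg.frac_gene_split * n),
              "silent": round(cfg.frac_silent * n)}
    need = sum(counts.values())
    if need > len(free):
        raise ValueError(f"infeasible config: {need} planted events for "
                         f"{len(free)} remaining genes")
    pool = sorted(free)
    picks = rng.choice(len(pool), size=need, replace=False)
    picked = [pool[i] for i in picks]
    i = 0
    for role, cnt in counts.items():
        for s in picked[i : i + cnt]:
            roles[s] = role
        i += cnt
    return {"chrom_of": chrom_of, "families": families,
            "dup_pairs": dup_pairs, "roles": roles}


# ---------------------------------------------------------------------------
# top-level simulate
# ---------------------------------------------------------------------------


def simulate(config: SimulationConfig, out_dir: str | Path) -> SimulationResult:
    """Generate the full synthetic dataset and its truth manifest.

    Writes genome FASTA, GFF3 annotation, per-sample junction TSVs and
    bedGraph coverage, expression / domain / name / SP / TM / homology-hit /
    gene-coordinate tables, annotated-protein FASTA and ``truth.json`` under
    ``out_dir``. Deterministic for a given config.
    """
    rng = np.random.default_rng(config.seed)
    plan = _plan_slots(config, rng)  # raises before any file is written
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = config.n_genes

    slot_family = {}
    for fam_id, fam in plan["families"].items():
        for s in fam["slots"]:
            slot_family[s] = fam_id
    slot_dup = {}
    for a, b in plan["dup_pairs"]:
        slot_dup[a], slot_dup[b] = b, a

    # paralog family proteins: mutated copies of a per-family seed protein;
    # the representative carries a C-terminal extension so it is longest
    fam_proteins: dict[int, str] = {}
    for fam_id, fam in plan["families"].items():
        L = int(rng.integers(260, 341))
        seed_prot = "M" + "".join(rng.choice(list(AA20), L - 1))
        for k, s in enumerate(fam["slots"]):
            if k == 0:
                fam_proteins[s] = seed_prot + "".join(rng.choice(list(AA20), 25))
            else:
                mutant = list(seed_prot)
                n_mut = int(0.25 * L)
                for i in rng.choice(np.arange(1, L), size=n_mut, replace=False):
                    mutant[i] = str(rng.choice([a for a in AA20 if a != mutant[i]]))
                fam_proteins[s] = "".join(mutant)
        fam["representative_slot"] = fam["slots"][0]

    # build local genes slot by slot
    placed: list[_Placed] = []
    dup_cache: dict[int, _LocalGene] = {}
    chrom_writers = {ci: _Writer() for ci in range(config.n_chromosomes)}
    for slot in range(n):
        gid = f"SG{slot + 1:04d}"
        role = plan["roles"].get(slot, "concordant")
        fam_id = slot_family.get(slot)
        if fam_id is not None:
            role = "paralog"
        if slot in slot_dup:
            role = "duplicate"

        if role == "duplicate" and slot_dup[slot] in dup_cache:
            local = dup_cache[slot_dup[slot]]
            strand = "+"
        elif role == "start_revision":
            local = _build_start_revision(rng)
            strand = str(rng.choice(["+", "-"]))
        elif role == "split":
            local = _build_split(rng)
            strand = str(rng.choice(["+", "-"]))
        elif role == "paralog":
            local = _build_coding(rng, "paralog",
                                  protein_body=fam_proteins[slot][1:])
            strand = str(rng.choice(["+", "-"]))
        else:
            local = _build_coding(rng, role if role in ("retention", "absent")
                                  else "concordant")
            strand = "+" if role == "duplicate" else str(rng.choice(["+", "-"]))
        if role == "duplicate":
            dup_cache[slot] = local
            local.events = {DUPLICATE_LOCUS}
            strand = "+"

        ci = plan["chrom_of"][slot]
        w = chrom_writers[ci]
        w.add("".join(rng.choice(list("ACGT"), int(rng.integers(200, 401)))))
        gseq = local.seq if strand == "+" else _revcomp(local.seq)
        span = w.add(gseq)
        placed.append(_Placed(gid, local, f"chr{ci + 1}", span[0], strand,
                              role, slot, fam_id,
                              f"SG{slot_dup[slot] + 1:04d}" if slot in slot_dup else None))
    for ci, w in chrom_writers.items():
        w.add("".join(rng.choice(list("ACGT"), 200)))
    genome = {f"chr{ci + 1}": w.seq for ci, w in chrom_writers.items()}

    models = [p.model() for p in placed]

    # ---------------- evidence per sample ----------------
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    sample_names = [f"S{i + 1}" for i in range(config.n_samples)]
    junction_paths, coverage_paths = [], []
    for si, sample in enumerate(sample_names):
        depth_arrays = {c: np.zeros(L) for c, L in chrom_lengths.items()}
        junctions: list[JunctionRecord] = []
        for p in placed:
            if p.role == "silent":
                continue
            d = max(20, int(round(rng.gamma(4.0, config.base_depth / 4.0))))
            for iv in p.local.covered:
                g = p.interval(iv)
                depth_arrays[p.chrom][g.start - 1 : g.end] = d
            for iv in p.local.retained_intervals:
                uf = rng.uniform(0.55, 0.85)
                g = p.interval(iv)
                depth_arrays[p.chrom][g.start - 1 : g.end] = int(round(uf * d))
            for iv, mode in p.local.junctions:
                g = p.interval(iv)
                if mode == "supported":
                    s_reads = d
                else:
                    interior = int(depth_arrays[p.chrom][g.start - 1])
                    s_reads = max(3, d - interior)
                junctions.append(JunctionRecord(g, s_reads))
        junctions.sort(key=lambda j: (j.intron.chrom, j.intron.start, j.intron.end))
        jp = out_dir / f"junctions_{sample}.tsv"
        cp = out_dir / f"coverage_{sample}.bedGraph"
        write_junctions(junctions, jp)
        write_bedgraph(CoverageTrack(depth_arrays), cp)
        junction_paths.append(jp)
        coverage_paths.append(cp)

    # ---------------- expression matrix ----------------
    n_shift = round(config.fc_shift * n)
    non_silent = [p for p in placed if p.role != "silent"]
    shift_idx = rng.choice(len(non_silent), size=min(n_shift, len(non_silent)),
                           replace=False)
    n_up = round(config.fc_up_share * len(shift_idx))
    fc_class = {non_silent[i].gene_id: ("up" if k < n_up else "down")
                for k, i in enumerate(shift_idx)}
    expr = {}
    for p in placed:
        if p.role == "silent":
            v = float(np.exp(rng.uniform(np.log(0.05), np.log(4.9))))
            row = [round(v, 2), round(v, 2)] + [
                round(float(np.exp(rng.uniform(np.log(0.05), np.log(4.9)))), 2)
                for _ in range(config.n_samples - 2)]
        else:
            cls = fc_class.get(p.gene_id)
            v1 = float(np.exp(rng.uniform(np.log(5.0), np.log(100.0 if cls else 500.0))))
            if cls == "up":
                f = rng.uniform(3.2, 6.0)
                v2 = (v1 + 1.0) * f - 1.0
            elif cls == "down":
                f = rng.uniform(3.2, 6.0)
                v2 = max(0.0, (v1 + 1.0) / f - 1.0)
            else:
                v2 = v1
            row = [round(v1, 2), round(v2, 2)] + [
                round(float(np.exp(rng.uniform(np.log(5.0), np.log(500.0)))), 2)
                for _ in range(config.n_samples - 2)]
        expr[p.gene_id] = row[: config.n_samples]
    expr_df = pd.DataFrame.from_dict(expr, orient="index",
                                     columns=sample_names[: config.n_samples])
    expr_df.index.name = "gene_id"

    # ---------------- domains, names, SP/TM ----------------
    other_families = ["Zn2Cys6", "FungalSpecific", "C2H2", "bZIP", "bHLH",
                      "GATA", "Myb", "Velvet", "WOPR", "CopperFist",
                      "Forkhead", "APSES", "HMG"]
    weights = np.array([0.34, 0.14, 0.14, 0.06, 0.05, 0.05, 0.05, 0.03, 0.03,
                        0.03, 0.03, 0.03, 0.02])
    weights = weights / weights.sum()
    dom_rows, truth_families_by_gene = [], {}
    for p in placed:
        plen = len(p.local.annotated_protein)
        if p.family_id is not None:
            fams = ["Zn2Cys6"]
        elif p.role == "duplicate":
            fams = ["Homeodomain"]
        else:
            first = str(rng.choice(other_families, p=weights))
            fams = [first]
            if rng.random() < config.dual_fraction:
                second = str(rng.choice([f for f in other_families if f != first]))
                fams.append(second)
        truth_families_by_gene[p.gene_id] = sorted(set(fams))
        pos = 2
        for fam in fams:
            dlen = int(rng.integers(30, 46))
            start = min(pos, max(1, plen - dlen - 1))
            end = min(plen, start + dlen)
            dom_rows.append({"gene_id": p.gene_id, "family": fam,
                             "aa_start": start, "aa_end": end})
            pos = end + 10
    dom_df = pd.DataFrame(dom_rows)

    named = {p.gene_id: f"tf{p.slot + 1}" for p in placed
             if rng.random() < config.named_fraction}
    name_df = pd.DataFrame([{"gene_id": g, "standard_name": nm}
                            for g, nm in named.items()])
    if name_df.empty:
        name_df = pd.DataFrame(columns=["gene_id", "standard_name"])

    sp_rates = {"FungiDB": 0.031, "SignalP": 0.008}
    tm_rates = {"FungiDB": 0.046, "TMHMM": 0.046, "Phobius": 0.275}
    sp_rows, tm_rows = [], []
    sp_truth = {k: 0 for k in sp_rates}
    tm_truth = {k: 0 for k in tm_rates}
    for p in placed:
        for pred, rate in sp_rates.items():
            flag = int(rng.random() < rate)
            sp_truth[pred] += flag
            sp_rows.append({"gene_id": p.gene_id, "predictor": pred, "value": flag})
        for pred, rate in tm_rates.items():
            cnt = int(rng.integers(1, 8)) if rng.random() < rate else 0
            tm_truth[pred] += int(cnt > 0)
            tm_rows.append({"gene_id": p.gene_id, "predictor": pred, "value": cnt})

    # ---------------- homology hit tables ----------------
    n_unconf = round(config.unconfirmed_ortholog_fraction * n)
    unconf = {placed[i].gene_id for i in rng.choice(n, size=n_unconf, replace=False)}
    fwd_rows, rev_rows, ortho_truth = [], [], {}
    for i, p in enumerate(placed):
        subj = f"Aspor_{p.gene_id}"
        score = round(float(rng.uniform(250, 600)), 1)
        fwd_rows.append({"query": p.gene_id, "subject": subj,
                         "bitscore": score, "evalue": 1e-90})
        fwd_rows.append({"query": p.gene_id, "subject": f"Aspor_decoy{i}",
                         "bitscore": round(score * 0.6, 1), "evalue": 1e-40})
        if p.gene_id in unconf:
            back = placed[(i + 1) % n].gene_id
        else:
            back = p.gene_id
        rev_rows.append({"query": subj, "subject": back,
                         "bitscore": score, "evalue": 1e-90})
        rev_rows.append({"query": subj, "subject": placed[(i + 2) % n].gene_id,
                         "bitscore": round(score * 0.5, 1), "evalue": 1e-30})
        ortho_truth[p.gene_id] = {"ortholog": subj,
                                  "confirmed": p.gene_id not in unconf}

    coords_df = pd.DataFrame([{"gene_id": m.gene_id, "chrom": m.chrom,
                               "start": m.start, "end": m.end,
                               "strand": m.strand} for m in models])

    # ---------------- truth manifest ----------------
    genes_truth: dict[str, dict] = {}
    fam_by_slot = {}
    for fam_id, fam in plan["families"].items():
        for s in fam["slots"]:
            fam_by_slot[s] = fam_id
    for p in placed:
        loc = p.local
        statuses = loc.true_statuses if p.strand == "+" else loc.true_statuses[::-1]
        if p.role == "silent":
            category = UNASSESSABLE
            events: set[str] = set()
        elif loc.events:
            category = REANNOTATE
            events = set(loc.events)
        else:
            category = CONCORDANT
            events = set()
        revised_start = None
        if loc.revised_start_local is not None and p.role != "silent":
            revised_start = _map_pos(loc.revised_start_local, p.g0, p.length, p.strand)
        genes_truth[p.gene_id] = {
            "role": p.role, "category": category,
            "events": sorted(events),
            "silent": p.role == "silent",
            "intron_statuses": statuses,
            "revised_proteins": sorted(loc.revised_proteins) if p.role != "silent" else [],
            "revised_start": revised_start,
            "families": truth_families_by_gene[p.gene_id],
            "named": p.gene_id in named,
            "cluster": fam_by_slot.get(p.slot),
            "duplicate_partner": p.duplicate_partner,
            "fc": fc_class.get(p.gene_id),
            "protein_length": len(loc.annotated_protein),
            **ortho_truth[p.gene_id],
        }
    families_truth = {
        fam_id: {"members": [f"SG{s + 1:04d}" for s in fam["slots"]],
                 "representative": f"SG{fam['representative_slot'] + 1:04d}",
                 "mode": fam["mode"], "family": "Zn2Cys6"}
        for fam_id, fam in plan["families"].items()}
    event_counts: dict[str, int] = {}
    for t in genes_truth.values():
        for ev in t["events"]:
            event_counts[ev] = event_counts.get(ev, 0) + 1
    totals = {
        "n_genes": n,
        "n_silent": sum(t["silent"] for t in genes_truth.values()),
        "n_ipds": len(dom_rows),
        "sum_family_memberships": sum(len(t["families"]) for t in genes_truth.values()),
        "n_named": len(named),
        "n_dual": sum(len(t["families"]) > 1 for t in genes_truth.values()),
        "event_counts": dict(sorted(event_counts.items())),
        "category_counts": {c: sum(t["category"] == c for t in genes_truth.values())
                            for c in (CONCORDANT, REANNOTATE, UNASSESSABLE)},
        "fc_up": sum(1 for v in fc_class.values() if v == "up"),
        "fc_down": sum(1 for v in fc_class.values() if v == "down"),
        "sp_counts": sp_truth, "tm_counts": tm_truth,
        "n_confirmed_orthologs": sum(t["confirmed"] for t in ortho_truth.values()),
    }
    manifest = TruthManifest(genes_truth, families_truth, totals)

    # ---------------- write everything ----------------
    paths = {
        "genome": out_dir / "genome.fasta",
        "annotation": out_dir / "annotation.gff3",
        "expression": out_dir / "expression.tsv",
        "domains": out_dir / "domains.tsv",
        "names": out_dir / "names.tsv",
        "sp_flags": out_dir / "sp_flags.tsv",
        "tm_flags": out_dir / "tm_flags.tsv",
        "forward_hits": out_dir / "forward_hits.tsv",
        "reverse_hits": out_dir / "reverse_hits.tsv",
        "gene_coords": out_dir / "gene_coords.tsv",
        "proteins": out_dir / "proteins.fasta",
        "truth": out_dir / "truth.json",
    }
    write_genome_fasta(genome, paths["genome"])
    write_gff3(models, paths["annotation"])
    out_expr = expr_df.reset_index()
    with open(paths["expression"], "w") as fh:
        fh.write("# unit=FPKM\n")
        out_expr.to_csv(fh, sep="\t", index=False)
    write_tsv(dom_df, paths["domains"])
    write_tsv(name_df, paths["names"])
    write_tsv(pd.DataFrame(sp_rows), paths["sp_flags"])
    write_tsv(pd.DataFrame(tm_rows), paths["tm_flags"])
    write_tsv(pd.DataFrame(fwd_rows), paths["forward_hits"])
    write_tsv(pd.DataFrame(rev_rows), paths["reverse_hits"])
    write_tsv(coords_df, paths["gene_coords"])
    write_protein_fasta({m.gene_id: m.protein for m in models}, paths["proteins"])
    manifest.to_json(paths["truth"])
    for i, sample in enumerate(sample_names):
        paths[f"junctions_{sample}"] = junction_paths[i]
        paths[f"coverage_{sample}"] = coverage_paths[i]
    return SimulationResult(out_dir, paths, manifest)


# ---------------------------------------------------------------------------
# reference scenarios: five hand-built mini-genes reproducing the canonical
# re-annotation outcomes (truncating intron retention; start revision with an
# in-frame insertion; absent intron with a downstream start; a gene split;
# and a duplicate locus)
# ---------------------------------------------------------------------------


@dataclass
class ScenarioFixture:
    name: str
    description: str
    genome: dict[str, str]
    models: list[GeneModel]
    junction_sets: list[list[JunctionRecord]]
    coverage_tracks: list[CoverageTrack]
    domains: dict[str, list[DomainAnnotation]]
    expected: dict[str, dict]


def _place_single_sample(genes: list[tuple[str, _LocalGene]], depth: int = 100,
                         retained_depth: int = 90, retained_reads: int = 10,
                         ) -> tuple[dict, list, list, CoverageTrack]:
    """Lay genes on one plus-strand chromosome and emit one sample of
    evidence: exons (and absent-intron interiors) at ``depth``, retained
    interiors at ``retained_depth`` with ``retained_reads`` spliced reads,
    supported introns fully spliced."""
    rng = np.random.default_rng(7)
    w = _Writer()
    placements = []
    for gid, local in genes:
        w.add(_no_a(rng, 150))
        span = w.add(local.seq)
        placements.append(_Placed(gid, local, "chrI", span[0], "+", "scenario", 0))
    w.add(_no_a(rng, 150))
    genome = {"chrI": w.seq}
    depths = {"chrI": np.zeros(len(w.seq))}
    junctions: list[JunctionRecord] = []
    models = []
    for p in placements:
        models.append(p.model())
        for iv in p.local.covered:
            g = p.interval(iv)
            depths["chrI"][g.start - 1 : g.end] = depth
        for iv in p.local.retained_intervals:
            g = p.interval(iv)
            depths["chrI"][g.start - 1 : g.end] = retained_depth
        for iv, mode in p.local.junctions:
            g = p.interval(iv)
            junctions.append(JunctionRecord(
                g, depth if mode == "supported" else retained_reads))
    junctions.sort(key=lambda j: j.intron.start)
    return genome, models, junctions, CoverageTrack(depths)


def _scenario_retention_truncation() -> ScenarioFixture:
    """Both predicted introns are mostly retained; retention of the first
    reads a premature stop, truncating the protein to its first domain."""
    rng = np.random.default_rng(101)
    g = _LocalGene()
    w = _Writer()
    body = _random_codons(rng, 119)  # annotated protein: 120 aa
    utr5 = w.add(_no_a(rng, 40))
    p1 = w.add("ATG" + body[:180])
    i1 = w.add(_stop_intron(rng))
    p2 = w.add(body[180:270])
    i2 = w.add("GT" + _no_a(rng, 56) + "AG")
    p3 = w.add(body[270:] + "TAA")
    utr3 = w.add(_no_a(rng, 40))
    g.seq = w.seq
    g.exons = [(utr5[0], p1[1]), (p2[0], p2[1]), (p3[0], utr3[1])]
    g.cds = (p1[0], p3[1])
    g.annotated_protein = "M" + translate_body(body)
    g.retained_intervals = [i1, i2]
    g.junctions = [(i1, "retained"), (i2, "retained")]
    g.covered = list(g.exons)
    revised = translate(g.seq[p1[0] - 1 : p1[1]] + g.seq[i1[0] - 1 : i1[1]])
    genome, models, junctions, track = _place_single_sample([("REF1", g)])
    doms = [DomainAnnotation("REF1", "Zn2Cys6", 5, 40),
            DomainAnnotation("REF1", "FungalSpecific", 75, 110)]
    return ScenarioFixture(
        "retention_truncation",
        "intron retention reads a premature stop; only the first (Zn2Cys6) "
        "domain survives in the truncated peptide",
        genome, models, [junctions], [track], {"REF1": doms},
        {"REF1": {"category": REANNOTATE,
                  "events": {INTRON_RETENTION, STOP_REVISION},
                  "revised_proteins": [revised],
                  "domain_impact": {("Zn2Cys6", 5, 40): "RETAINED",
                                    ("FungalSpecific", 75, 110): "LOST"}}})


def _scenario_start_revision_insertion() -> ScenarioFixture:
    """Start moves to an internal Met (retention of the first intron reads an
    early stop) and a second retained intron adds 17 in-frame codons without
    changing the reading frame or the stop."""
    rng = np.random.default_rng(102)
    a, b = _no_a(rng, 9), _no_a(rng, 9)
    body = _random_codons(rng, 100)
    i2_seq = "GTC" + "".join(_no_a(rng, 3) for _ in range(15)) + "CAG"  # 17 codons
    g = _LocalGene()
    w = _Writer()
    utr5 = w.add(_no_a(rng, 40))
    atg0 = w.add("ATG")
    a_iv = w.add(a)
    i1 = w.add(_stop_intron(rng))
    b_iv = w.add(b)
    orf1 = w.add("ATG" + body[:120])
    i2 = w.add(i2_seq)
    orf2 = w.add(body[120:] + "TAA")
    utr3 = w.add(_no_a(rng, 40))
    g.seq = w.seq
    g.exons = [(utr5[0], a_iv[1]), (b_iv[0], orf1[1]), (orf2[0], utr3[1])]
    g.cds = (atg0[0], orf2[0] + (len(body) - 120) + 2)  # end of the TAA stop
    g.annotated_protein = ("M" + translate_body(a + b) + "M" + translate_body(body))
    g.retained_intervals = [i1, i2]
    g.junctions = [(i1, "retained"), (i2, "retained")]
    g.covered = list(g.exons)
    revised = translate("ATG" + body[:120] + i2_seq + body[120:] + "TAA")
    genome, models, junctions, track = _place_single_sample([("REF2", g)])
    doms = [DomainAnnotation("REF2", "C2H2", 2, 7),
            DomainAnnotation("REF2", "Zn2Cys6", 60, 95)]
    return ScenarioFixture(
        "start_revision_with_insertion",
        "revised start at an internal Met plus a frame-preserving retained "
        "intron adding 17 extra codons",
        genome, models, [junctions], [track], {"REF2": doms},
        {"REF2": {"category": REANNOTATE,
                  "events": {INTRON_RETENTION, START_REVISION},
                  "revised_proteins": [revised],
                  "annotated_protein": g.annotated_protein,
                  "inserted_codons": 17,
                  "domain_impact": {("C2H2", 2, 7): "LOST",
                                    ("Zn2Cys6", 60, 95): "RETAINED"}}})


def _scenario_absent_intron_start() -> ScenarioFixture:
    """The predicted first intron is absent; the real start is a downstream
    Met and only the bZIP-like domain survives."""
    rng = np.random.default_rng(103)
    a, b = _no_a(rng, 45), _no_a(rng, 45)
    body = _random_codons(rng, 100)
    g = _LocalGene()
    w = _Writer()
    utr5 = w.add(_no_a(rng, 40))
    atg0 = w.add("ATG")
    a_iv = w.add(a)
    i1 = w.add(_stop_intron(rng))
    b_iv = w.add(b)
    orf = w.add("ATG" + body + "TAA")
    utr3 = w.add(_no_a(rng, 40))
    g.seq = w.seq
    g.exons = [(utr5[0], a_iv[1]), (b_iv[0], utr3[1])]
    g.cds = (atg0[0], orf[1])
    g.annotated_protein = ("M" + translate_body(a + b) + "M" + translate_body(body))
    g.covered = [g.exons[0], i1, g.exons[1]]
    revised = "M" + translate_body(body)
    genome, models, junctions, track = _place_single_sample([("REF3", g)])
    revised_start = models[0].start + (orf[0] - 1)
    doms = [DomainAnnotation("REF3", "C2H2", 3, 25),
            DomainAnnotation("REF3", "bZIP", 40, 90)]
    return ScenarioFixture(
        "absent_intron_start_revision",
        "absent first intron; start revised to a downstream Met retaining "
        "only the bZIP-like domain",
        genome, models, [junctions], [track], {"REF3": doms},
        {"REF3": {"category": REANNOTATE,
                  "events": {ABSENT_INTRON, START_REVISION},
                  "revised_proteins": [revised],
                  "revised_start": revised_start,
                  "domain_impact": {("C2H2", 3, 25): "LOST",
                                    ("bZIP", 40, 90): "RETAINED"}}})


def _scenario_gene_split() -> ScenarioFixture:
    """An expressed 3' block separated by a coverage dead zone: the model is
    split into two ORFs."""
    rng = np.random.default_rng(104)
    g = _build_split(rng)
    genome, models, junctions, track = _place_single_sample([("REF4", g)])
    j = len(g.revised_proteins[0]) - 1  # codons in the first true ORF body
    anno_len = len(g.annotated_protein)
    doms = [DomainAnnotation("REF4", "Zn2Cys6", anno_len - 40, anno_len - 5)]
    return ScenarioFixture(
        "gene_split",
        "internal expression dead zone with no spanning junction splits one "
        "model into two coding genes",
        genome, models, [junctions], [track], {"REF4": doms},
        {"REF4": {"category": REANNOTATE,
                  "events": {GENE_SPLIT, ABSENT_INTRON},
                  "revised_proteins": sorted(g.revised_proteins),
                  "n_models": 2,
                  "domain_impact": {("Zn2Cys6", anno_len - 40, anno_len - 5):
                                    "RETAINED"}}})


def _scenario_duplicate_locus() -> ScenarioFixture:
    """Two loci with byte-identical annotated proteins: an assembly or
    annotation artifact, flagged on both."""
    rng = np.random.default_rng(105)
    g = _build_coding(rng, "concordant")
    genome, models, junctions, track = _place_single_sample(
        [("REF5A", g), ("REF5B", g)])
    doms = {gid: [DomainAnnotation(gid, "Homeodomain", 5, 40)]
            for gid in ("REF5A", "REF5B")}
    expected = {gid: {"category": REANNOTATE, "events": {DUPLICATE_LOCUS},
                      "revised_proteins": []} for gid in ("REF5A", "REF5B")}
    return ScenarioFixture(
        "duplicate_locus",
        "identical annotated proteins at two loci are flagged as a "
        "duplicate-locus artifact",
        genome, models, [junctions], [track], doms, expected)


def reference_scenarios() -> list[ScenarioFixture]:
    """The five canonical re-annotation fixtures, deterministic constants."""
    return [_scenario_retention_truncation(),
            _scenario_start_revision_insertion(),
            _scenario_absent_intron_start(),
            _scenario_gene_split(),
            _scenario_duplicate_locus()]
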