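"""Readers and writers for every external representation the pipeline touches.

All internal coordinates are 1-based inclusive (GFF3 convention). bedGraph
input, which is 0-based half-open, is converted at the boundary. Strand is
``+`` or ``-``; sequence extraction for minus-strand genes reverse-complements
before translation.

Formats handled: GFF3 (gene/mRNA/exon/CDS subset), protein FASTA (60-column
wrap), bedGraph coverage, a 5-column splice-junction TSV mirroring the
junction tabs emitted by spliced aligners, and generic header-ed TSV tables
with ``.`` for missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = "."


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A closed genomic interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneModel:
    """An annotated gene: ordered exons, a CDS span and (optionally) the
    annotated protein.

    Exons are non-overlapping, sorted by start, and all on one chromosome and
    strand. Introns are the gaps between consecutive exons. ``cds_start`` and
    ``cds_end`` are genomic positions (cds_start <= cds_end regardless of
    strand; on the minus strand translation begins at ``cds_end``).
    """

    gene_id: str
    exons: list[GenomicInterval]
    cds_start: int
    cds_end: int
    protein: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene model needs >= 1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"{self.gene_id}: exons span chromosomes/strands")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
        if not (self.exons[0].start <= self.cds_start <= self.cds_end <= self.exons[-1].end):
            raise ValueError(f"{self.gene_id}: CDS span outside exon union")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in genomic order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.chrom, a.end + 1, b.start - 1, self.strand))
        return out

    def cds_intervals(self) -> list[GenomicInterval]:
        """Exon pieces intersected with the CDS span, in genomic order."""
        out = []
        for e in self.exons:
            s, t = max(e.start, self.cds_start), min(e.end, self.cds_end)
            if s <= t:
                out.append(GenomicInterval(self.chrom, s, t, self.strand))
        return out


@dataclass(frozen=True)
class JunctionRecord:
    """One splice junction: the intron it removes and its spliced-read count."""

    intron: GenomicInterval
    spliced_reads: int

    def __post_init__(self) -> None:
        if self.spliced_reads < 0:
            raise ValueError("spliced_reads must be >= 0")
        if self.intron.length < 4:
            raise ValueError(f"intron shorter than 4 bases: {self.intron}")


class CoverageTrack:
    """Dense per-base read depth per chromosome, 1-based position semantics.

    position p of chromosome c is ``track[c][p - 1]``.
    """

    def __init__(self, depths: dict[str, np.ndarray]):
        for chrom, arr in depths.items():
            if (np.asarray(arr) < 0).any():
                raise ValueError(f"{chrom}: negative depth")
        self.depths = {c: np.asarray(a, dtype=float) for c, a in depths.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.depths

    def slice(self, chrom: str, start: int, end: int) -> np.ndarray:
        if chrom not in self.depths:
            raise KeyError(f"chromosome {chrom!r} missing from coverage track")
        return self.depths[chrom][start - 1 : end]

    def mean_depth(self, chrom: str, intervals: Sequence[GenomicInterval]) -> float:
        """Mean depth over the union of (non-overlapping) intervals."""
        total = sum(self.slice(chrom, iv.start, iv.end).sum() for iv in intervals)
        n = sum(iv.length for iv in intervals)
        return float(total) / n if n else 0.0


# ---------------------------------------------------------------------------
# genome FASTA
# ---------------------------------------------------------------------------


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(genome: dict[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(recs, str(path), "fasta")


def write_protein_fasta(records: dict[str, str], path: str | Path) -> None:
    """Write proteins with ``>gene_id`` headers, wrapped at 60 columns."""
    recs = [SeqRecord(Seq(seq), id=gid, description="") for gid, seq in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def extract_spliced(genome: dict[str, str], chrom: str, strand: str,
                    intervals: Sequence[GenomicInterval]) -> str:
    """Concatenate interval sequences in genomic order; reverse-complement the
    result for minus-strand features so it reads 5'->3'."""
    seq = "".join(genome[chrom][iv.start - 1 : iv.end] for iv in intervals)
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _attrs(text: str) -> dict[str, str]:
    out = {}
    for piece in text.strip().rstrip(";").split(";"):
        if not piece:
            continue
        if "=" not in piece:
            raise FormatError(f"malformed attribute {piece!r}")
        k, v = piece.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file with gene/mRNA/exon/CDS features into gene models,
    one per mRNA.

    Raises :class:`FormatError` (naming the offending line) on a malformed
    feature hierarchy, and ``ValueError`` if a CDS span falls outside its
    mRNA's exons.
    """
    mrna_parent: dict[str, str] = {}
    genes: set[str] = set()
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            chrom, _, ftype, start, end, _, strand, _, attr_text = cols
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            attrs = _attrs(attr_text)
            if ftype == "gene":
                genes.add(attrs.get("ID", ""))
            elif ftype == "mRNA":
                mid, parent = attrs.get("ID"), attrs.get("Parent")
                if mid is None or parent is None or parent not in genes:
                    raise FormatError(f"{path}:{lineno}: mRNA without known gene parent")
                mrna_parent[mid] = parent
                exons.setdefault(mid, [])
                cds.setdefault(mid, [])
                order.append(mid)
            elif ftype in ("exon", "CDS"):
                parent = attrs.get("Parent")
                if parent not in mrna_parent:
                    raise FormatError(f"{path}:{lineno}: {ftype} without known mRNA parent")
                (exons if ftype == "exon" else cds)[parent].append(iv)

    models = []
    for mid in order:
        ex = sorted(exons[mid], key=lambda iv: iv.start)
        cd = cds[mid]
        if not cd:
            raise FormatError(f"{path}: mRNA {mid} has no CDS features")
        cds_start = min(iv.start for iv in cd)
        cds_end = max(iv.end for iv in cd)
        model = GeneModel(mrna_parent[mid], ex, cds_start, cds_end)
        covered = {iv for iv in cd}
        expect = set(model.cds_intervals())
        if covered != expect:
            raise ValueError(f"{mid}: CDS features do not tile the exonic CDS span")
        models.append(model)
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            mid = f"{m.gene_id}.t1"
            fh.write("\t".join([m.chrom, "tfaudit", "gene", str(m.start), str(m.end),
                                ".", m.strand, ".", f"ID={m.gene_id}"]) + "\n")
            fh.write("\t".join([m.chrom, "tfaudit", "mRNA", str(m.start), str(m.end),
                                ".", m.strand, ".", f"ID={mid};Parent={m.gene_id}"]) + "\n")
            for e in m.exons:
                fh.write("\t".join([m.chrom, "tfaudit", "exon", str(e.start), str(e.end),
                                    ".", m.strand, ".", f"Parent={mid}"]) + "\n")
            for c in m.cds_intervals():
                fh.write("\t".join([m.chrom, "tfaudit", "CDS", str(c.start), str(c.end),
                                    ".", m.strand, "0", f"Parent={mid}"]) + "\n")


# ---------------------------------------------------------------------------
# junction TSV
# ---------------------------------------------------------------------------


def read_junctions(path: str | Path) -> list[JunctionRecord]:
    """Read a 5-column junction TSV: chrom, intron first base, intron last
    base, strand, unique spliced reads."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            chrom, start, end, strand, count = cols
            n = int(count)
            if n < 0:
                raise FormatError(f"{path}:{lineno}: negative spliced-read count")
            out.append(JunctionRecord(GenomicInterval(chrom, int(start), int(end), strand), n))
    return out


def write_junctions(records: Iterable[JunctionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.intron.chrom}\t{r.intron.start}\t{r.intron.end}"
                     f"\t{r.intron.strand}\t{r.spliced_reads}\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def read_bedgraph(path: str | Path, chrom_lengths: dict[str, int]) -> CoverageTrack:
    """Read bedGraph (0-based half-open) into a dense 1-based coverage track.

    Uncovered bases get depth 0. Overlapping intervals, intervals past the
    chromosome end and unknown chromosomes are format errors.
    """
    depths = {c: np.zeros(n, dtype=float) for c, n in chrom_lengths.items()}
    seen = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, value = cols[0], int(cols[1]), int(cols[2]), float(cols[3])
            if chrom not in depths:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start < 0 or end > chrom_lengths[chrom] or end <= start:
                raise FormatError(f"{path}:{lineno}: interval outside chromosome bounds")
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative depth")
            if seen[chrom][start:end].any():
                raise FormatError(f"{path}:{lineno}: overlapping bedGraph intervals")
            seen[chrom][start:end] = True
            depths[chrom][start:end] = value
    return CoverageTrack(depths)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a coverage track as run-length bedGraph lines (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom in track.depths:
            arr = track.depths[chrom]
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                if arr[s] != 0:
                    v = arr[s]
                    vtxt = str(int(v)) if float(v).is_integer() else repr(float(v))
                    fh.write(f"{chrom}\t{s}\t{e}\t{vtxt}\n")


# ---------------------------------------------------------------------------
# generic TSV tables
# ---------------------------------------------------------------------------


def read_expression_tsv(path: str | Path) -> tuple[pd.DataFrame, str]:
    """Read a gene x sample expression table tagged with its unit.

    First line is ``# unit=FPKM`` (or TPM), then a header-ed TSV with
    gene_id as the first column. Returns (values indexed by gene_id, unit).
    """
    with open(path) as fh:
        first = fh.readline().strip()
        unit = "FPKM"
        if first.startswith("#"):
            for piece in first.lstrip("#").split():
                if piece.startswith("unit="):
                    unit = piece.split("=", 1)[1]
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t", na_values=MISSING, keep_default_na=False)
    return df.set_index("gene_id"), unit


def write_expression_tsv(values: pd.DataFrame, unit: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# unit={unit}\n")
        out = values.copy()
        out.index.name = "gene_id"
        out.reset_index().to_csv(fh, sep="\t", na_rep=MISSING, index=False)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a header-ed TSV with ``.`` as the missing-value marker."""
    return pd.read_csv(path, sep="\t", na_values=MISSING, keep_default_na=False, **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", na_rep=MISSING, index=index)
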