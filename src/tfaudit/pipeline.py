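"""End-to-end audit pipeline and the consolidated report.

Stages run in a fixed order — inventory, reconciliation, expression,
paralogs — over a directory holding the standard input set (genome FASTA,
GFF3, per-sample junction TSVs and bedGraph coverage, expression / domain /
name / prediction / homology tables). The consolidated
:class:`AuditReport` is a single JSON document whose schema ships with the
package (``report_schema.json``); every percentage in it is recomputable
from its counts with one-decimal half-away-from-zero rounding.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from . import io_formats as io
from .expression import (ExpressionMatrix, call_silent_genes,
                         fold_change_counts, global_shift_stat, mask_low)
from .inventory import (build_inventory, characterization_fraction,
                        family_share, summarize_inventory)
from .paralogs import (build_gene_order, classify_duplication_mode,
                       greedy_cluster, paralogy_fraction, reciprocal_best_hit)
from .reconciliation import (ReconciliationConfig, annotated_protein,
                             classify_gene, detect_duplicate_loci,
                             summarize_reconciliation)

logger = logging.getLogger("tfaudit.pipeline")


# ---------------------------------------------------------------------------
# report schema (pydantic models; JSON schema shipped alongside)
# ---------------------------------------------------------------------------


class InventoryBlock(BaseModel):
    n_tfs: int
    n_ipds: int
    tf_counts_by_family: dict[str, int]
    ipd_counts_by_family: dict[str, int]
    n_named: int
    pct_named: float
    pct_unnamed: float
    sp_counts: dict[str, int]
    tm_counts: dict[str, int]
    dual_specificity_policy: str = "repeated-per-family"


class ReconciliationBlock(BaseModel):
    n_genes: int
    counts: dict[str, int]
    percentages: dict[str, float]
    event_counts: dict[str, int]


class SilenceBlock(BaseModel):
    n_genes: int
    n_silent: int
    pct_silent: float
    threshold: float
    strict: bool
    silent_genes: list[str]


class ShiftBlock(BaseModel):
    sample_a: str
    sample_b: str
    fc: float
    n_up: int
    n_down: int
    ratio: float | None
    score: float
    global_shift: bool


class FamilyParalogyBlock(BaseModel):
    family: str
    n_members: int
    n_in_clusters: int
    pct_paralogs: float
    n_clusters: int
    multi_cluster_sizes: list[int]
    cluster_modes: dict[str, str]
    mode_tally: dict[str, int]


class OrthologyBlock(BaseModel):
    n_queries: int
    n_confirmed: int
    pct_confirmed: float


class AuditReport(BaseModel):
    """Consolidated audit of a TFome: inventory composition, gene-model
    reconciliation, silence and shift statistics, and paralogy."""

    schema_version: str = Field(default="1.0")
    inventory: InventoryBlock
    reconciliation: ReconciliationBlock
    silence: SilenceBlock
    shift: ShiftBlock | None
    paralogy: list[FamilyParalogyBlock]
    orthology: OrthologyBlock | None
    thresholds: dict[str, float]


def report_schema() -> dict:
    return AuditReport.model_json_schema()


def validate_report(path: str | Path) -> AuditReport:
    """Parse and validate a report JSON against the report schema."""
    with open(path) as fh:
        return AuditReport.model_validate(json.load(fh))


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    ``data_dir`` holds the standard input file set (the layout the
    synthetic-data generator writes); ``out_dir`` receives per-stage TSVs
    and the consolidated report. All evidence thresholds surface here.
    """

    data_dir: Path
    out_dir: Path
    reconciliation: ReconciliationConfig = dc_field(default_factory=ReconciliationConfig)
    silence_threshold: float = 5.0
    silence_strict: bool = True
    fc: float = 3.0
    pseudocount: float = 1.0
    shift_flag_at: float = 0.5
    fc_samples: tuple[str, str] | None = ("S1", "S2")
    cluster_cutoff: float = 0.3
    proximal_window: int = 10
    cluster_families: tuple[str, ...] = ("Zn2Cys6", "C2H2")

    def __post_init__(self) -> None:
        self.data_dir = Path(self.data_dir)
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        recon = ReconciliationConfig(**raw.pop("reconciliation", {}))
        if "fc_samples" in raw and raw["fc_samples"] is not None:
            raw["fc_samples"] = tuple(raw["fc_samples"])
        if "cluster_families" in raw:
            raw["cluster_families"] = tuple(raw["cluster_families"])
        return cls(reconciliation=recon, **raw)


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path}")
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def run_inventory(cfg: PipelineConfig) -> tuple[list, InventoryBlock]:
    d = cfg.data_dir
    domain_table = io.read_tsv(_require(d / "domains.tsv"))
    names = io.read_tsv(d / "names.tsv") if (d / "names.tsv").exists() else None
    sp = io.read_tsv(d / "sp_flags.tsv") if (d / "sp_flags.tsv").exists() else None
    tm = io.read_tsv(d / "tm_flags.tsv") if (d / "tm_flags.tsv").exists() else None
    records = build_inventory(domain_table, names, sp, tm)
    if not records:
        block = InventoryBlock(n_tfs=0, n_ipds=0, tf_counts_by_family={},
                               ipd_counts_by_family={}, n_named=0, pct_named=0.0,
                               pct_unnamed=0.0, sp_counts={}, tm_counts={})
        return records, block
    s = summarize_inventory(records)
    _, pct_named, _, pct_unnamed = characterization_fraction(records)
    block = InventoryBlock(
        n_tfs=s.n_tfs, n_ipds=s.n_ipds,
        tf_counts_by_family=s.tf_counts_by_family,
        ipd_counts_by_family=s.ipd_counts_by_family,
        n_named=s.n_named, pct_named=pct_named, pct_unnamed=pct_unnamed,
        sp_counts=s.sp_counts, tm_counts=s.tm_counts)
    logger.info("inventory: %d TFs, %d IPDs", s.n_tfs, s.n_ipds)
    return records, block


def run_reconciliation(cfg: PipelineConfig) -> tuple[list, ReconciliationBlock]:
    d = cfg.data_dir
    genome = io.read_genome_fasta(_require(d / "genome.fasta"))
    models = io.read_gff3(_require(d / "annotation.gff3"))
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    junction_paths = sorted(d.glob("junctions_*.tsv"))
    coverage_paths = sorted(d.glob("coverage_*.bedGraph"))
    if not junction_paths or not coverage_paths:
        raise FileNotFoundError(f"missing junction/coverage evidence in {d}")
    junction_sets = [io.read_junctions(p) for p in junction_paths]
    tracks = [io.read_bedgraph(p, chrom_lengths) for p in coverage_paths]

    proteins = {m.gene_id: (m.protein or annotated_protein(genome, m))
                for m in models}
    dup = detect_duplicate_loci(proteins)

    domains_path = d / "domains.tsv"
    dom_by_gene: dict[str, list] = {}
    if domains_path.exists():
        from .inventory import DomainAnnotation
        for r in io.read_tsv(domains_path).itertuples():
            dom_by_gene.setdefault(str(r.gene_id), []).append(
                DomainAnnotation(str(r.gene_id), str(r.family),
                                 int(r.aa_start), int(r.aa_end)))

    rc = cfg.reconciliation
    logger.info("reconciliation thresholds: min_spliced=%d supported_frac=%.2f "
                "min_intron_depth=%d min_gene_depth=%.1f split_gap=%d/%.1f "
                "min_orf=%d", rc.min_spliced, rc.spliced_supported_frac,
                rc.min_intron_depth, rc.min_gene_depth, rc.split_gap_min,
                rc.split_gap_depth, rc.min_orf_codons)
    calls = []
    for m in models:
        m.protein = proteins[m.gene_id]
        calls.append(classify_gene(genome, m, junction_sets, tracks, rc,
                                   duplicate_partners=dup.get(m.gene_id),
                                   domains=dom_by_gene.get(m.gene_id)))
    summary = summarize_reconciliation(calls)
    block = ReconciliationBlock(**summary)

    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    revised_models, revised_proteins = [], {}
    for c in calls:
        rows.append({
            "gene_id": c.gene_id, "category": c.category,
            "events": ",".join(sorted(c.events)) or None,
            "revised_cds": ";".join(f"{m.cds_start}-{m.cds_end}"
                                    for m in c.revised_models) or None,
            "notes": ";".join(c.notes) or None})
        revised_models.extend(c.revised_models)
        for m, p in zip(c.revised_models, c.revised_proteins):
            revised_proteins[m.gene_id] = p
    io.write_tsv(pd.DataFrame(rows), cfg.out_dir / "reannotation_calls.tsv")
    io.write_gff3(revised_models, cfg.out_dir / "revised_models.gff3")
    io.write_protein_fasta({k: v for k, v in revised_proteins.items() if v},
                           cfg.out_dir / "revised_proteins.fasta")
    logger.info("reconciliation: %s", summary["counts"])
    return calls, block


def run_expression(cfg: PipelineConfig) -> tuple[SilenceBlock, ShiftBlock | None]:
    d = cfg.data_dir
    values, unit = io.read_expression_tsv(_require(d / "expression.tsv"))
    matrix = ExpressionMatrix(values, unit=unit)
    report = call_silent_genes([matrix], threshold=cfg.silence_threshold,
                               strict=cfg.silence_strict)
    n = len(matrix.genes)
    silence = SilenceBlock(
        n_genes=n, n_silent=len(report.silent_genes),
        pct_silent=family_share(len(report.silent_genes), n) if n else 0.0,
        threshold=report.threshold, strict=report.strict,
        silent_genes=sorted(report.silent_genes))
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    masked = mask_low(matrix, cfg.silence_threshold)
    io.write_expression_tsv(masked.values, unit, cfg.out_dir / "masked_expression.tsv")

    shift = None
    if cfg.fc_samples and all(s in matrix.samples for s in cfg.fc_samples):
        a, b = cfg.fc_samples
        n_up, n_down, ratio = fold_change_counts(matrix, a, b, cfg.fc, cfg.pseudocount)
        score, flagged = global_shift_stat(matrix, a, b, cfg.fc, cfg.pseudocount,
                                           cfg.shift_flag_at)
        shift = ShiftBlock(sample_a=a, sample_b=b, fc=cfg.fc, n_up=n_up,
                           n_down=n_down, ratio=ratio, score=round(score, 3),
                           global_shift=flagged)
        logger.info("expression shift %s->%s: up=%d down=%d", a, b, n_up, n_down)
    logger.info("expression: %d/%d silent", silence.n_silent, n)
    return silence, shift


def run_paralogs(cfg: PipelineConfig, tf_records: list,
                 proteins: dict[str, str]) -> tuple[list[FamilyParalogyBlock],
                                                    OrthologyBlock | None]:
    d = cfg.data_dir
    coords = io.read_tsv(_require(d / "gene_coords.tsv"))
    gene_order = build_gene_order(coords)
    fams_by_gene = {r.gene_id: r.families for r in tf_records}

    blocks = []
    cluster_rows, mode_rows = [], []
    for family in cfg.cluster_families:
        members = {gid: seq for gid, seq in proteins.items()
                   if family in fams_by_gene.get(gid, ())}
        if not members:
            continue
        clusters = greedy_cluster(members, cutoff=cfg.cluster_cutoff)
        n_in, pct = paralogy_fraction(clusters, len(members))
        cluster_modes, tally = {}, {}
        for cl in clusters:
            for gid, ident in sorted(cl.members.items()):
                cluster_rows.append({"family": family, "cluster_id": cl.cluster_id,
                                     "representative": cl.representative,
                                     "member": gid, "identity": round(ident, 3)})
            if cl.size >= 2:
                call = classify_duplication_mode(cl, gene_order, cfg.proximal_window)
                cluster_modes[cl.cluster_id] = call.cluster_mode
                tally[call.cluster_mode] = tally.get(call.cluster_mode, 0) + 1
                mode_rows.append({"family": family, "cluster_id": cl.cluster_id,
                                  "mode": call.cluster_mode, "size": cl.size})
        blocks.append(FamilyParalogyBlock(
            family=family, n_members=len(members), n_in_clusters=n_in,
            pct_paralogs=pct, n_clusters=len(clusters),
            multi_cluster_sizes=sorted((cl.size for cl in clusters
                                        if cl.size >= 2), reverse=True),
            cluster_modes=cluster_modes, mode_tally=dict(sorted(tally.items()))))
        logger.info("paralogs[%s]: %d/%d in clusters", family, n_in, len(members))
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    io.write_tsv(pd.DataFrame(cluster_rows), cfg.out_dir / "paralog_clusters.tsv")
    io.write_tsv(pd.DataFrame(mode_rows), cfg.out_dir / "duplication_modes.tsv")

    orthology = None
    fpath, rpath = d / "forward_hits.tsv", d / "reverse_hits.tsv"
    if fpath.exists() and rpath.exists():
        fwd, rev = io.read_tsv(fpath), io.read_tsv(rpath)
        results = [reciprocal_best_hit(fwd, rev, gid) for gid in sorted(proteins)]
        n_conf = sum(r.confirmed for r in results)
        orthology = OrthologyBlock(
            n_queries=len(results), n_confirmed=n_conf,
            pct_confirmed=family_share(n_conf, len(results)) if results else 0.0)
        io.write_tsv(pd.DataFrame(
            [{"query": r.query, "forward_best": r.forward_best,
              "reverse_best": r.reverse_best, "confirmed": r.confirmed,
              "reason": r.reason or None} for r in results]),
            cfg.out_dir / "rbh_results.tsv")
    return blocks, orthology


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_pipeline(cfg: PipelineConfig) -> AuditReport:
    """Run all stages in order and write ``audit_report.json``.

    Any stage failure propagates (no partial report is left behind);
    reports are byte-identical across runs on identical inputs.
    """
    logger.info("stage inventory: start")
    tf_records, inventory = run_inventory(cfg)
    logger.info("stage reconciliation: start")
    calls, reconciliation = run_reconciliation(cfg)
    logger.info("stage expression: start")
    silence, shift = run_expression(cfg)
    logger.info("stage paralogs: start")
    genome = io.read_genome_fasta(cfg.data_dir / "genome.fasta")
    models = io.read_gff3(cfg.data_dir / "annotation.gff3")
    prot_path = cfg.data_dir / "proteins.fasta"
    proteins = (io.read_protein_fasta(prot_path) if prot_path.exists()
                else {m.gene_id: annotated_protein(genome, m) for m in models})
    paralogy, orthology = run_paralogs(cfg, tf_records, proteins)

    report = AuditReport(
        inventory=inventory, reconciliation=reconciliation, silence=silence,
        shift=shift, paralogy=paralogy, orthology=orthology,
        thresholds={
            "min_spliced": cfg.reconciliation.min_spliced,
            "spliced_supported_frac": cfg.reconciliation.spliced_supported_frac,
            "min_intron_depth": cfg.reconciliation.min_intron_depth,
            "min_gene_depth": cfg.reconciliation.min_gene_depth,
            "split_gap_min": cfg.reconciliation.split_gap_min,
            "split_gap_depth": cfg.reconciliation.split_gap_depth,
            "min_orf_codons": cfg.reconciliation.min_orf_codons,
            "silence_threshold": cfg.silence_threshold,
            "fc": cfg.fc, "pseudocount": cfg.pseudocount,
            "cluster_cutoff": cfg.cluster_cutoff,
            "proximal_window": cfg.proximal_window,
        })
    out_path = cfg.out_dir / "audit_report.json"
    tmp = out_path.with_suffix(".json.tmp")
    with open(tmp, "w") as fh:
        json.dump(report.model_dump(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    tmp.rename(out_path)
    logger.info("report written to %s", out_path)
    return report
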