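"""Transcription-factor inventory: families, domain (IPD) counts and summary
arithmetic.

A TF is a gene with at least one annotated DNA-binding / regulatory domain
("IPD": an InterPro-style domain instance). A TF whose domains belong to more
than one family is *dual-specificity*; it is counted once in the TF total but
once in each family's TF count, so per-family TF counts may sum to more than
the TF total. IPD counts are per-domain.

Percentages are rounded half-away-from-zero to one decimal, which is the
rounding that reproduces the published-style pie-chart arithmetic
(e.g. 331 of 520 -> 63.7).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

logger = logging.getLogger("tfaudit.inventory")

#: Controlled vocabulary of DNA-binding / regulatory domain families.
FAMILY_VOCABULARY = frozenset({
    "Zn2Cys6", "FungalSpecific", "C2H2", "bZIP", "bHLH", "GATA", "Myb",
    "Homeodomain", "Velvet", "WOPR", "CopperFist", "Forkhead", "APSES",
    "HMG", "Other",
})


@dataclass(frozen=True)
class DomainAnnotation:
    """One domain instance on a protein, in 1-based amino-acid coordinates."""

    protein_id: str
    family: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if self.family not in FAMILY_VOCABULARY:
            raise ValueError(f"unknown domain family {self.family!r}")
        if not (1 <= self.aa_start <= self.aa_end):
            raise ValueError(f"bad domain coordinates {self.aa_start}..{self.aa_end}")


@dataclass
class TFRecord:
    gene_id: str
    domains: list[DomainAnnotation]
    standard_name: str | None = None
    sp_flags: dict[str, bool] = field(default_factory=dict)
    tm_counts: dict[str, int] = field(default_factory=dict)

    @property
    def families(self) -> frozenset[str]:
        return frozenset(d.family for d in self.domains)

    @property
    def dual_specificity(self) -> bool:
        return len(self.families) >= 2


@dataclass
class InventorySummary:
    n_tfs: int
    n_ipds: int
    tf_counts_by_family: dict[str, int]
    ipd_counts_by_family: dict[str, int]
    n_named: int
    sp_counts: dict[str, int]
    tm_counts: dict[str, int]
    #: how dual-specificity TFs are counted (metadata for downstream readers)
    dual_specificity_policy: str = "repeated-per-family"


def family_share(count: int, total: int) -> float:
    """Percentage 100*count/total, rounded half-away-from-zero to 1 decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError(f"count {count} outside [0, {total}]")
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def build_inventory(domain_table: pd.DataFrame,
                    name_table: pd.DataFrame | None = None,
                    sp_table: pd.DataFrame | None = None,
                    tm_table: pd.DataFrame | None = None,
                    pseudogenes: set[str] | None = None) -> list[TFRecord]:
    """Assemble TF records from a domain table plus optional name and
    signal-peptide / transmembrane prediction tables.

    ``domain_table`` needs columns gene_id, family, aa_start, aa_end; the
    name table gene_id, standard_name; the SP/TM tables gene_id, predictor,
    value. Predictions are inputs, never computed here, and each predictor
    column is kept separate. Genes listed in ``pseudogenes`` are dropped with
    a logged count. Ids present in side tables but absent from the domain
    table produce a warning, not an error.
    """
    pseudogenes = pseudogenes or set()
    names: dict[str, str] = {}
    if name_table is not None:
        names = {str(r.gene_id): str(r.standard_name)
                 for r in name_table.itertuples()
                 if pd.notna(r.standard_name)}

    by_gene: dict[str, list[DomainAnnotation]] = {}
    n_pseudo = 0
    for row in domain_table.itertuples():
        gid = str(row.gene_id)
        if gid in pseudogenes:
            n_pseudo += 1
            continue
        by_gene.setdefault(gid, []).append(
            DomainAnnotation(gid, str(row.family), int(row.aa_start), int(row.aa_end)))
    if n_pseudo:
        logger.info("dropped %d pseudogene domain rows", n_pseudo)

    orphans = set(names) - set(by_gene) - pseudogenes
    if orphans:
        logger.warning("%d named ids absent from domain table: %s",
                       len(orphans), sorted(orphans)[:5])

    records = [TFRecord(gid, sorted(doms, key=lambda d: d.aa_start),
                        standard_name=names.get(gid))
               for gid, doms in sorted(by_gene.items())]
    rec_by_id = {r.gene_id: r for r in records}
    for table, attr in ((sp_table, "sp_flags"), (tm_table, "tm_counts")):
        if table is None:
            continue
        for row in table.itertuples():
            rec = rec_by_id.get(str(row.gene_id))
            if rec is None:
                logger.warning("prediction for unknown gene %s ignored", row.gene_id)
                continue
            cast = bool if attr == "sp_flags" else int
            getattr(rec, attr)[str(row.predictor)] = cast(row.value)
    return records


def summarize_inventory(records: list[TFRecord]) -> InventorySummary:
    """Family-composition arithmetic over TF records.

    n_ipds is the total number of domain instances; per-family IPD counts sum
    to n_ipds exactly. Dual-specificity TFs appear in every family they
    belong to.
    """
    if not records:
        raise ValueError("no TF records")
    tf_by_family: dict[str, int] = {}
    ipd_by_family: dict[str, int] = {}
    n_ipds = 0
    for rec in records:
        for fam in sorted(rec.families):
            tf_by_family[fam] = tf_by_family.get(fam, 0) + 1
        for dom in rec.domains:
            ipd_by_family[dom.family] = ipd_by_family.get(dom.family, 0) + 1
            n_ipds += 1
    sp_counts: dict[str, int] = {}
    tm_counts: dict[str, int] = {}
    for rec in records:
        for pred, flag in rec.sp_flags.items():
            sp_counts[pred] = sp_counts.get(pred, 0) + int(bool(flag))
        for pred, n in rec.tm_counts.items():
            tm_counts[pred] = tm_counts.get(pred, 0) + int(n > 0)
    return InventorySummary(
        n_tfs=len(records),
        n_ipds=n_ipds,
        tf_counts_by_family=dict(sorted(tf_by_family.items())),
        ipd_counts_by_family=dict(sorted(ipd_by_family.items())),
        n_named=sum(1 for r in records if r.standard_name),
        sp_counts=dict(sorted(sp_counts.items())),
        tm_counts=dict(sorted(tm_counts.items())),
    )


def characterization_fraction(records: list[TFRecord]) -> tuple[int, float, int, float]:
    """(n_named, pct_named, n_unnamed, pct_unnamed) over the TF set; a TF is
    'characterized' when it carries a standard name."""
    n = len(records)
    n_named = sum(1 for r in records if r.standard_name)
    return (n_named, family_share(n_named, n),
            n - n_named, family_share(n - n_named, n))
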