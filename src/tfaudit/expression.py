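"""Expression-matrix analyses: silent-gene calling, low-value masking,
per-family tables, and the two-sample fold-change screen.

Expression values are FPKM or TPM; values below 5 are treated as noise. A
gene is *silent* when every value in every supplied matrix is strictly below
the threshold (a value of exactly 5 survives). The source experiments carry
no biological replicates, so no variance model or significance test is
fitted anywhere here — fold-change counting with a pseudocount is as far as
single-sample data can honestly be pushed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inventory import TFRecord, family_share

logger = logging.getLogger("tfaudit.expression")

SILENCE_THRESHOLD = 5.0


@dataclass
class ExpressionMatrix:
    """genes x samples matrix of non-negative FPKM or TPM values."""

    values: pd.DataFrame
    unit: str = "FPKM"
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unit not in ("FPKM", "TPM"):
            raise ValueError(f"unit must be FPKM or TPM, got {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SilenceReport:
    silent_genes: set[str]
    threshold: float
    max_values: dict[str, float]
    strict: bool = True


def call_silent_genes(matrices: list[ExpressionMatrix],
                      threshold: float = SILENCE_THRESHOLD,
                      strict: bool = True) -> SilenceReport:
    """Genes silent across every supplied matrix.

    Silent means every value in every matrix is below ``threshold``
    (strictly, by default). All matrices must share one gene universe;
    mismatches raise with the missing ids listed. FPKM and TPM matrices are
    only combined when the caller passes both explicitly.
    """
    if not matrices:
        raise ValueError("no expression matrices supplied")
    universe = set(matrices[0].genes)
    for m in matrices[1:]:
        missing = universe.symmetric_difference(m.genes)
        if missing:
            raise ValueError(f"gene sets differ between matrices: "
                             f"{sorted(missing)[:10]}")
    maxima = pd.concat([m.values.max(axis=1) for m in matrices], axis=1).max(axis=1)
    below = maxima < threshold if strict else maxima <= threshold
    return SilenceReport(set(maxima.index[below]), threshold,
                         maxima.to_dict(), strict)


def mask_low(matrix: ExpressionMatrix,
             threshold: float = SILENCE_THRESHOLD) -> ExpressionMatrix:
    """Replace values below ``threshold`` with NaN (the masked marker,
    serialized as '.'); shape and surviving values are untouched."""
    masked = matrix.values.where(matrix.values >= threshold)
    return ExpressionMatrix(masked, unit=matrix.unit, metadata=matrix.metadata)


def fold_change_counts(matrix: ExpressionMatrix, sample_a: str, sample_b: str,
                       fc: float = 3.0, pseudocount: float = 1.0,
                       ) -> tuple[int, int, float | None]:
    """Count genes up/down between two samples at a fold-change threshold.

    The per-gene ratio is (b + pseudocount) / (a + pseudocount); up when the
    ratio is >= ``fc``, down when <= 1/``fc`` (read as down-regulation). The
    returned ratio n_up/n_down is rounded half-away-from-zero to one decimal
    and None when nothing is down-regulated.
    """
    a = matrix.values[sample_a].to_numpy(dtype=float)
    b = matrix.values[sample_b].to_numpy(dtype=float)
    r = (b + pseudocount) / (a + pseudocount)
    n_up = int((r >= fc).sum())
    n_down = int((r <= 1.0 / fc).sum())
    ratio = _round1(n_up / n_down) if n_down else None
    return n_up, n_down, ratio


def _round1(x: float) -> float:
    from decimal import ROUND_HALF_UP, Decimal
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def global_shift_stat(matrix: ExpressionMatrix, sample_a: str, sample_b: str,
                      fc: float = 3.0, pseudocount: float = 1.0,
                      flag_at: float = 0.5) -> tuple[float, bool]:
    """Signed condition-wide shift score (n_up - n_down)/(n_up + n_down).

    +1 means everything responding went up, -1 everything down. The
    comparison is flagged as a global shift when |score| >= ``flag_at``.
    Returns (score, flagged); score 0 and no flag when nothing responds.
    """
    n_up, n_down, _ = fold_change_counts(matrix, sample_a, sample_b, fc, pseudocount)
    if n_up + n_down == 0:
        return 0.0, False
    score = (n_up - n_down) / (n_up + n_down)
    return score, abs(score) >= flag_at


def family_expression_table(matrix: ExpressionMatrix,
                            tf_records: list[TFRecord]) -> pd.DataFrame:
    """Per-family gene x sample table with dual-specificity repetition.

    Each gene appears once per family it belongs to (a dual-specificity TF
    is repeated), ordered by family then gene id. Genes in the matrix but
    missing from the records land in family 'Other' with a warning.
    """
    fam_by_gene = {r.gene_id: sorted(r.families) for r in tf_records}
    rows = []
    for gid in matrix.genes:
        fams = fam_by_gene.get(gid)
        if fams is None:
            logger.warning("gene %s absent from TF records; filed under Other", gid)
            fams = ["Other"]
        for fam in fams:
            rows.append((fam, gid))
    rows.sort()
    out = pd.DataFrame(
        [matrix.values.loc[gid] for _, gid in rows],
        index=pd.MultiIndex.from_tuples(rows, names=["family", "gene_id"]),
    )
    return out
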