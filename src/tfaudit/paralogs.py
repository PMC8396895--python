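"""Paralog clustering, duplication-mode classification, reciprocal-best-hit
orthology and DNA-contact-residue comparison for TF families.

Clustering is greedy and identity-based in the style of CD-HIT: sequences
are processed longest-first and each joins the first cluster whose
representative it matches at or above the identity cutoff (default 0.3),
else founds its own cluster. Identity is counted over a global alignment
with free end gaps (BLOSUM62, gap open 11 / extend 1) and divided by the
length of the shorter sequence, so a perfect sub-sequence scores 1.0.
CD-HIT's word-count prefilter is deliberately not reproduced: at the scale
of a TF family (hundreds of proteins) exact alignment against every
representative is affordable and removes the heuristic's corner cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd

TANDEM = "TANDEM"
PROXIMAL = "PROXIMAL"
DISPERSED = "DISPERSED"


@dataclass
class ParalogCluster:
    cluster_id: str
    representative: str
    #: gene_id -> identity to the representative
    members: dict[str, float] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class DuplicationCall:
    cluster_id: str
    pair_modes: dict[tuple[str, str], str]
    cluster_mode: str | None


@dataclass
class RBHResult:
    query: str
    forward_best: str | None
    reverse_best: str | None
    confirmed: bool
    reason: str = ""


@lru_cache(maxsize=1)
def _aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    al.end_insertion_score = 0.0
    al.end_deletion_score = 0.0
    return al


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical aligned residues over the shorter sequence's
    length, from a global BLOSUM62 alignment with free end gaps.

    The two sequences are put in a canonical order before aligning so the
    result is exactly symmetric even when several alignments tie on score.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    a, b = sorted((seq_a, seq_b), key=lambda s: (len(s), s))
    aln = _aligner().align(a, b)[0]
    identities = aln.counts().identities
    return identities / min(len(seq_a), len(seq_b))


def greedy_cluster(records: dict[str, str], cutoff: float = 0.3) -> list[ParalogCluster]:
    """Greedy longest-first identity clustering of proteins.

    ``records`` maps gene_id -> protein sequence. Sequences are sorted by
    descending length (ties broken by id) and each joins the first cluster
    whose representative it matches at >= ``cutoff`` identity, else founds a
    new cluster with itself as representative. Deterministic and invariant
    to input order.
    """
    if not records:
        raise ValueError("no sequences to cluster")
    order = sorted(records, key=lambda gid: (-len(records[gid]), gid))
    clusters: list[ParalogCluster] = []
    for gid in order:
        seq = records[gid]
        for cl in clusters:
            ident = pairwise_identity(seq, records[cl.representative])
            if ident >= cutoff:
                cl.members[gid] = ident
                break
        else:
            clusters.append(ParalogCluster(f"cluster{len(clusters) + 1}", gid, {gid: 1.0}))
    return clusters


def paralogy_fraction(clusters: list[ParalogCluster],
                      family_size: int) -> tuple[int, float]:
    """Members of multi-member clusters and their share of the family.

    The count is the number of proteins sitting in clusters of two or more
    (i.e. proteins that could have arisen by duplication); the percentage is
    one-decimal over ``family_size``.
    """
    from .inventory import family_share

    n = sum(cl.size for cl in clusters if cl.size >= 2)
    if family_size < n:
        raise ValueError(f"family_size {family_size} < clustered members {n}")
    return n, family_share(n, family_size)


def build_gene_order(coords: pd.DataFrame) -> dict[str, tuple[str, int]]:
    """gene_id -> (chrom, ordinal along the chromosome) from a coordinate
    table with columns gene_id, chrom, start."""
    out: dict[str, tuple[str, int]] = {}
    for chrom, sub in coords.groupby("chrom"):
        for i, gid in enumerate(sub.sort_values("start")["gene_id"]):
            out[str(gid)] = (str(chrom), i)
    return out


def classify_duplication_mode(cluster: ParalogCluster,
                              gene_order: dict[str, tuple[str, int]],
                              proximal_window: int = 10) -> DuplicationCall:
    """Duplication mode per member pair and for the cluster.

    Pairs on different chromosomes are DISPERSED. Same-chromosome pairs are
    TANDEM when adjacent in gene order (no intervening genes), PROXIMAL with
    up to ``proximal_window`` intervening genes, DISPERSED beyond. The
    cluster mode is the modal pair mode, DISPERSED on ties; singleton
    clusters have no mode.
    """
    members = sorted(cluster.members)
    for gid in members:
        if gid not in gene_order:
            raise KeyError(f"no coordinates for cluster member {gid}")
    pair_modes: dict[tuple[str, str], str] = {}
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            (ca, ia), (cb, ib) = gene_order[a], gene_order[b]
            if ca != cb:
                mode = DISPERSED
            else:
                intervening = abs(ia - ib) - 1
                if intervening == 0:
                    mode = TANDEM
                elif intervening <= proximal_window:
                    mode = PROXIMAL
                else:
                    mode = DISPERSED
            pair_modes[(a, b)] = mode
    if not pair_modes:
        return DuplicationCall(cluster.cluster_id, {}, None)
    tally: dict[str, int] = {}
    for mode in pair_modes.values():
        tally[mode] = tally.get(mode, 0) + 1
    top = max(tally.values())
    winners = [m for m, n in tally.items() if n == top]
    cluster_mode = winners[0] if len(winners) == 1 else DISPERSED
    return DuplicationCall(cluster.cluster_id, pair_modes, cluster_mode)


def _best_hit(hits: pd.DataFrame, query: str) -> str | None:
    """Best subject for ``query``: highest bitscore, then lowest E-value,
    then lexicographically first subject id."""
    sub = hits[hits["query"] == query]
    if sub.empty:
        return None
    sub = sub.sort_values(["bitscore", "evalue", "subject"],
                          ascending=[False, True, True], kind="mergesort")
    return str(sub.iloc[0]["subject"])


def reciprocal_best_hit(forward_hits: pd.DataFrame, reverse_hits: pd.DataFrame,
                        query: str) -> RBHResult:
    """Confirm orthology by reverse retrieval.

    The forward best hit's reverse best hit must be the original query.
    Tables need columns query, subject, bitscore, evalue. A query with no
    forward hits is unconfirmed with reason 'no hits'.
    """
    fwd = _best_hit(forward_hits, query)
    if fwd is None:
        return RBHResult(query, None, None, False, reason="no hits")
    rev = _best_hit(reverse_hits, fwd)
    confirmed = rev == query
    reason = "" if confirmed else f"reverse best of {fwd} is {rev}"
    return RBHResult(query, fwd, rev, confirmed, reason)


def contact_residue_report(aligned_sequences: dict[str, str],
                           contact_columns: list[int]) -> pd.DataFrame:
    """Compare predicted DNA-contacting alignment columns across sequences.

    ``aligned_sequences`` maps id -> gapped sequence, all the same length;
    ``contact_columns`` are 1-based alignment column indices. Each report
    row carries the per-sequence residue, a conserved/divergent flag, and
    for divergent columns the ids of the sequences deviating from the
    majority residue.
    """
    if not aligned_sequences:
        raise ValueError("no sequences")
    lengths = {len(s) for s in aligned_sequences.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    (length,) = lengths
    ids = sorted(aligned_sequences)
    rows = []
    for col in contact_columns:
        if not 1 <= col <= length:
            raise ValueError(f"contact column {col} outside alignment (1..{length})")
        residues = {sid: aligned_sequences[sid][col - 1] for sid in ids}
        distinct = set(residues.values())
        conserved = len(distinct) == 1
        outliers = ""
        if not conserved:
            tally: dict[str, int] = {}
            for r in residues.values():
                tally[r] = tally.get(r, 0) + 1
            majority = max(tally, key=lambda r: (tally[r], r))
            outliers = ",".join(f"{sid}:{residues[sid]}" for sid in ids
                                if residues[sid] != majority)
        rows.append({"column": col, "conserved": conserved, "outliers": outliers,
                     **residues})
    return pd.DataFrame(rows, columns=["column", "conserved", "outliers", *ids])
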