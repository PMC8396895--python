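"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive results with naive string/array code
(explicit transcript assembly, full AUG scans, direct matrix scans) so the
pipeline implementations are checked against an independent path.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from tfaudit.io_formats import GeneModel
from tfaudit.pipeline import PipelineConfig, run_pipeline
from tfaudit.synthetic_data import (SimulationConfig, reference_scenarios,
                                    simulate)

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """Seed-fixed default synthetic dataset (100 genes, depth 100)."""
    out = tmp_path_factory.mktemp("sim")
    return simulate(SimulationConfig(seed=1), out)


@pytest.fixture(scope="session")
def audit(sim, tmp_path_factory):
    """Full pipeline run over the session dataset."""
    out = tmp_path_factory.mktemp("audit")
    cfg = PipelineConfig(data_dir=sim.out_dir, out_dir=out)
    report = run_pipeline(cfg)
    return report, out


@pytest.fixture(scope="session")
def scenarios():
    return reference_scenarios()


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def oracle_transcript(genome: dict[str, str], model: GeneModel,
                      statuses: list[str]) -> tuple[str, list[int]]:
    """Base-by-base mature transcript: exon bases plus RETAINED/ABSENT
    intron bases, 5'->3'."""
    from Bio.Seq import Seq

    keep = set()
    for iv in model.exons:
        keep.update(range(iv.start, iv.end + 1))
    for iv, st in zip(model.introns, statuses):
        if st in ("RETAINED", "ABSENT"):
            keep.update(range(iv.start, iv.end + 1))
    positions = sorted(keep)
    seq = "".join(genome[model.chrom][p - 1] for p in positions)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
        positions = positions[::-1]
    return seq, positions


def _orf_at(seq: str, i: int) -> tuple[str, int | None]:
    """Translate from index i to the first in-frame stop (Biopython)."""
    from Bio.Seq import Seq

    prot = []
    for j in range(i, len(seq) - 2, 3):
        codon = seq[j : j + 3]
        if codon in _STOPS:
            return "".join(prot), j
        prot.append(str(Seq(codon).translate()))
    return "".join(prot), None


def oracle_orf(genome: dict[str, str], model: GeneModel, statuses: list[str],
               min_orf_codons: int = 50) -> str:
    """Brute-force revised protein: full scan of AUG-initiated ORFs on the
    explicitly assembled transcript, applying the start/stop revision rule."""
    seq, positions = oracle_transcript(genome, model, statuses)
    idx = {p: i for i, p in enumerate(positions)}
    start_pos = model.cds_start if model.strand == "+" else model.cds_end
    stop_last = model.cds_end if model.strand == "+" else model.cds_start
    i0 = idx.get(start_pos)
    anno_end = idx.get(stop_last)
    if i0 is not None and seq[i0 : i0 + 3] == "ATG":
        prot, stop = _orf_at(seq, i0)
        if stop is None:
            return prot
        premature = anno_end is None or stop + 2 < anno_end
        if not premature or len(prot) >= min_orf_codons:
            return prot
        scan_from = i0 + 1
    else:
        scan_from = 0
    i = seq.find("ATG", scan_from)
    while i != -1:
        prot, stop = _orf_at(seq, i)
        if stop is not None and len(prot) >= min_orf_codons:
            return prot
        i = seq.find("ATG", i + 1)
    return ""
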