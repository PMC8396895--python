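"""Gene-model reconciliation: intron status calls, ORF recomputation,
splits, duplicates, domain impact and the three-way classification."""

import numpy as np
import pytest

from conftest import oracle_orf

from tfaudit.inventory import DomainAnnotation
from tfaudit.io_formats import (CoverageTrack, GeneModel, GenomicInterval,
                                JunctionRecord, read_bedgraph,
                                read_genome_fasta, read_gff3, read_junctions)
from tfaudit.reconciliation import (ABSENT, ABSENT_INTRON, AMBIGUOUS,
                                    CONCORDANT, DUPLICATE_LOCUS, GENE_SPLIT,
                                    INTRON_RETENTION, REANNOTATE, RETAINED,
                                    START_REVISION, STOP_REVISION, SUPPORTED,
                                    UNASSESSABLE, ReannotationCall,
                                    ReconciliationConfig, assess_expression,
                                    classify_gene, classify_intron,
                                    detect_duplicate_loci, detect_gene_split,
                                    domain_impact, recompute_orf,
                                    summarize_reconciliation)

CFG = ReconciliationConfig()


def iv(s, e, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, s, e, strand)


def flat_track(length, depth, chrom="chr1"):
    return CoverageTrack({chrom: np.full(length, float(depth))})


class TestClassifyIntron:
    def make(self, s, interior_depth, intron=(101, 200)):
        junctions = [[JunctionRecord(iv(*intron), s)]] if s else [[]]
        arr = np.zeros(400)
        arr[intron[0] - 1 : intron[1]] = interior_depth
        return classify_intron(iv(*intron), junctions,
                               [CoverageTrack({"chr1": arr})], CFG)

    @pytest.mark.parametrize("s,u,expected", [
        (10, 0, SUPPORTED),      # fully spliced
        (0, 10, ABSENT),         # covered but never spliced
        (3, 27, RETAINED),       # spliced fraction 0.1
        (2, 1, AMBIGUOUS),       # total evidence below the floor
        (2, 30, ABSENT),         # spliced support below min_spliced
        (45, 5, SUPPORTED),      # f = 0.9 exactly reaches the threshold
        (44, 6, RETAINED),       # f = 0.88 just below
    ])
    def test_status_taxonomy(self, s, u, expected):
        st = self.make(s, u)
        assert st.status == expected

    def test_spliced_fraction_value(self):
        st = self.make(3, 27)
        assert st.spliced_fraction == pytest.approx(0.1)

    def test_evidence_pooled_across_samples(self):
        # two samples: reads summed, interior depth averaged
        arr = np.zeros(400)
        arr[100:200] = 30
        tracks = [CoverageTrack({"chr1": arr}), CoverageTrack({"chr1": np.zeros(400)})]
        jsets = [[JunctionRecord(iv(101, 200), 3)], [JunctionRecord(iv(101, 200), 4)]]
        st = classify_intron(iv(101, 200), jsets, tracks, CFG)
        assert st.spliced_reads == 7
        assert st.unspliced_depth == pytest.approx(15.0)


class TestAssessExpression:
    def gene(self):
        return GeneModel("g", [iv(11, 110)], 11, 110)

    def test_zero_coverage_unassessable(self):
        assert not assess_expression(self.gene(), [flat_track(200, 0)], CFG)

    def test_any_single_expressed_sample_suffices(self):
        tracks = [flat_track(200, 100), flat_track(200, 0)]
        assert assess_expression(self.gene(), tracks, CFG)

    def test_boundary_just_below_threshold(self):
        assert not assess_expression(self.gene(), [flat_track(200, 4.9)], CFG)
        assert assess_expression(self.gene(), [flat_track(200, 5.0)], CFG)

    def test_missing_chromosome_raises(self):
        with pytest.raises(KeyError):
            assess_expression(self.gene(), [flat_track(200, 5, chrom="other")], CFG)


class TestRecomputeORF:
    """Two-exon toy gene: exon ATGGCC, intron GTATGCTAACAG, exon TGCTAA."""

    GENOME = {"chr1": "ATGGCC" + "GTATGCTAACAG" + "TGCTAA"}
    MODEL = GeneModel("toy", [iv(1, 6), iv(19, 24)], 1, 24)
    TOY_CFG = ReconciliationConfig(min_orf_codons=2, min_intron_depth=1,
                                   min_gene_depth=1)

    def status(self, st):
        from tfaudit.reconciliation import IntronStatus
        return [IntronStatus(iv(7, 18), st, 10 if st == SUPPORTED else 0,
                             0 if st == SUPPORTED else 10.0)]

    def test_supported_intron_translates_as_annotated(self):
        _, prot, events = recompute_orf(self.GENOME, self.MODEL,
                                        self.status(SUPPORTED), self.TOY_CFG)
        assert prot == "MAC"
        assert events == set()

    def test_retained_intron_reads_premature_stop(self):
        _, prot, events = recompute_orf(self.GENOME, self.MODEL,
                                        self.status(RETAINED), self.TOY_CFG)
        assert prot == "MAVC"
        assert events == {INTRON_RETENTION, STOP_REVISION}

    def test_matches_oracle_on_toy(self):
        for st in (SUPPORTED, RETAINED, ABSENT):
            _, prot, _ = recompute_orf(self.GENOME, self.MODEL,
                                       self.status(st), self.TOY_CFG)
            assert prot == oracle_orf(self.GENOME, self.MODEL, [st],
                                      min_orf_codons=2)


class TestOracleEquivalence:
    def test_every_simulated_gene_matches_brute_force(self, sim):
        genome = read_genome_fasta(sim.paths["genome"])
        models = read_gff3(sim.paths["annotation"])
        lengths = {c: len(s) for c, s in genome.items()}
        jsets = [read_junctions(sim.paths[f"junctions_S{i}"]) for i in (1, 2, 3)]
        tracks = [read_bedgraph(sim.paths[f"coverage_S{i}"], lengths)
                  for i in (1, 2, 3)]
        n_checked = 0
        for m in models:
            truth = sim.manifest.genes[m.gene_id]
            if truth["category"] == UNASSESSABLE or "GENE_SPLIT" in truth["events"]:
                continue  # splits are recomputed per block, not whole-gene
            statuses = [classify_intron(i, jsets, tracks, CFG) for i in m.introns]
            _, prot, _ = recompute_orf(genome, m, statuses, CFG)
            assert prot == oracle_orf(genome, m, [s.status for s in statuses])
            n_checked += 1
        assert n_checked > 50

    def test_scenario_fixtures_match_brute_force(self, scenarios):
        for sc in scenarios:
            for m in sc.models:
                statuses = [classify_intron(i, sc.junction_sets,
                                            sc.coverage_tracks, CFG)
                            for i in m.introns]
                if detect_gene_split(m, sc.coverage_tracks, sc.junction_sets, CFG):
                    continue
                _, prot, _ = recompute_orf(sc.genome, m, statuses, CFG)
                assert prot == oracle_orf(sc.genome, m,
                                          [s.status for s in statuses])


class TestGeneSplit:
    def test_continuous_coverage_gives_no_split(self):
        gene = GeneModel("g", [iv(1, 500)], 1, 498)
        assert detect_gene_split(gene, [flat_track(600, 50)], [[]], CFG) is None

    def test_scenario_dead_zone_splits(self, scenarios):
        sc = next(s for s in scenarios if s.name == "gene_split")
        m = sc.models[0]
        prop = detect_gene_split(m, sc.coverage_tracks, sc.junction_sets, CFG)
        assert prop is not None
        assert prop.gap.length >= CFG.split_gap_min

    def test_spanning_junction_vetoes_split(self, scenarios):
        sc = next(s for s in scenarios if s.name == "gene_split")
        m = sc.models[0]
        prop = detect_gene_split(m, sc.coverage_tracks, sc.junction_sets, CFG)
        spanning = [JunctionRecord(
            GenomicInterval(m.chrom, prop.gap.start - 5, prop.gap.end + 5,
                            m.strand), 50)]
        assert detect_gene_split(m, sc.coverage_tracks,
                                 [sc.junction_sets[0] + spanning], CFG) is None


class TestDuplicates:
    def test_identical_proteins_flagged_on_both(self):
        dup = detect_duplicate_loci({"a": "MKLV", "b": "MKLV", "c": "MXYZ"})
        assert dup == {"a": {"b"}, "b": {"a"}}

    def test_one_residue_difference_not_flagged(self):
        assert detect_duplicate_loci({"a": "MKLV", "b": "MKLX"}) == {}

    def test_self_comparison_never_flags(self):
        assert detect_duplicate_loci({"a": "MKLV"}) == {}


class TestDomainImpact:
    DOMS = [DomainAnnotation("g", "Zn2Cys6", 5, 40),
            DomainAnnotation("g", "C2H2", 60, 100)]

    def test_identical_proteins_retain_everything(self):
        p = "M" + "A" * 119
        impact = domain_impact(p, p, self.DOMS)
        assert set(impact.values()) == {"RETAINED"}

    def test_truncation_after_first_domain(self):
        anno = "M" + "ACDEFGHIKL" * 12
        revised = anno[:50]
        impact = domain_impact(revised, anno, self.DOMS)
        assert impact[("Zn2Cys6", 5, 40)] == "RETAINED"
        assert impact[("C2H2", 60, 100)] == "LOST"

    def test_domain_straddling_truncation_point_is_truncated(self):
        anno = "M" + "ACDEFGHIKL" * 12
        impact = domain_impact(anno[:80], anno, self.DOMS)
        assert impact[("C2H2", 60, 100)] == "TRUNCATED"

    def test_start_revision_loses_upstream_domain(self, scenarios):
        sc = next(s for s in scenarios if s.name == "absent_intron_start_revision")
        exp = sc.expected["REF3"]
        anno = sc.models[0].protein
        impact = domain_impact(exp["revised_proteins"][0], anno,
                               sc.domains["REF3"])
        assert impact == exp["domain_impact"]


class TestClassification:
    def test_category_counts_sum_to_gene_count(self, audit, sim):
        report, _ = audit
        assert sum(report.reconciliation.counts.values()) == \
            sim.manifest.totals["n_genes"]

    def test_published_style_three_way_percentages(self):
        calls = ([ReannotationCall(f"c{i}", CONCORDANT) for i in range(338)]
                 + [ReannotationCall(f"r{i}", REANNOTATE, {STOP_REVISION})
                    for i in range(159)]
                 + [ReannotationCall(f"u{i}", UNASSESSABLE) for i in range(23)])
        s = summarize_reconciliation(calls)
        assert s["percentages"] == {CONCORDANT: 65.0, REANNOTATE: 30.6,
                                    UNASSESSABLE: 4.4}

    def test_all_concordant(self):
        calls = [ReannotationCall(f"c{i}", CONCORDANT) for i in range(10)]
        s = summarize_reconciliation(calls)
        assert s["percentages"][CONCORDANT] == 100.0

    def test_ambiguous_introns_alone_never_trigger_reannotation(self):
        # expressed exons, but intron evidence below the ambiguity floor
        genome = {"chr1": "C" * 10 + "ATGGCC" + "GTATGCTAACAG" + "TGCTAA" + "C" * 10}
        model = GeneModel("g", [iv(11, 16), iv(29, 34)], 11, 34)
        arr = np.zeros(60)
        arr[10:16] = 10.0
        arr[28:34] = 10.0  # exons expressed; intron interior depth 0, no reads
        cfg = ReconciliationConfig(min_orf_codons=2)
        call = classify_gene(genome, model, [[]], [CoverageTrack({"chr1": arr})], cfg)
        assert call.intron_statuses[0].status == AMBIGUOUS
        assert call.category == CONCORDANT

    def test_raising_depth_floor_never_decreases_unassessable(self, sim):
        genome = read_genome_fasta(sim.paths["genome"])
        models = read_gff3(sim.paths["annotation"])[:40]
        lengths = {c: len(s) for c, s in genome.items()}
        tracks = [read_bedgraph(sim.paths["coverage_S1"], lengths)]
        prev = -1
        for floor in (1, 5, 30, 1000):
            cfg = ReconciliationConfig(min_gene_depth=floor)
            n = sum(not assess_expression(m, tracks, cfg) for m in models)
            assert n >= prev
            prev = n
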