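"""Paralog clustering, duplication modes, RBH orthology, contact residues."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tfaudit.paralogs import (DISPERSED, PROXIMAL, TANDEM, build_gene_order,
                              classify_duplication_mode,
                              contact_residue_report, greedy_cluster,
                              pairwise_identity, paralogy_fraction,
                              reciprocal_best_hit)

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n):
    return "".join(rng.choice(list(AA), n))


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("MKLVAA", "MKLVAA") == 1.0

    def test_totally_different_residues(self):
        assert pairwise_identity("AAAA", "TTTT") == 0.0

    def test_shorter_sequence_denominator(self):
        # the shorter sequence is fully contained: 4 matches / 4
        assert pairwise_identity("MKLVAA", "MKLV") == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "MKLV")

    @given(st.integers(0, 2 ** 31 - 1))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = random_protein(rng, int(rng.integers(5, 40)))
        b = random_protein(rng, int(rng.integers(5, 40)))
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_containment_scores_one(self):
        rng = np.random.default_rng(3)
        s = random_protein(rng, 60)
        assert pairwise_identity(s, s[10:40]) == 1.0


class TestGreedyCluster:
    def test_two_identical_sequences_one_cluster(self):
        clusters = greedy_cluster({"a": "MKLVAEQW", "b": "MKLVAEQW"})
        assert len(clusters) == 1
        assert set(clusters[0].members) == {"a", "b"}

    def test_cutoff_boundary_is_inclusive(self):
        rng = np.random.default_rng(5)
        a = random_protein(rng, 100)
        b = list(a)
        for i in rng.choice(100, 60, replace=False):
            b[i] = str(rng.choice([x for x in AA if x != b[i]]))
        b = "".join(b)
        ident = pairwise_identity(a, b)
        assert 0 < ident < 1
        merged = greedy_cluster({"a": a, "b": b}, cutoff=ident)
        split = greedy_cluster({"a": a, "b": b}, cutoff=ident + 1e-9)
        assert len(merged) == 1 and len(split) == 2

    def test_input_order_invariance(self):
        rng = np.random.default_rng(11)
        seqs = {f"g{i}": random_protein(rng, int(rng.integers(40, 90)))
                for i in range(12)}
        fwd = greedy_cluster(seqs)
        rev = greedy_cluster(dict(reversed(list(seqs.items()))))
        as_sets = lambda cs: {frozenset(c.members) for c in cs}
        assert as_sets(fwd) == as_sets(rev)

    def test_clusters_partition_the_input(self, sim):
        from tfaudit.io_formats import read_protein_fasta, read_tsv
        proteins = read_protein_fasta(sim.paths["proteins"])
        doms = read_tsv(sim.paths["domains"])
        zn = {g for g in doms[doms.family == "Zn2Cys6"].gene_id}
        subset = {g: proteins[g] for g in sorted(zn)}
        clusters = greedy_cluster(subset)
        seen = [g for c in clusters for g in c.members]
        assert sorted(seen) == sorted(subset)
        for c in clusters:
            assert c.representative in c.members

    def test_memberships_agree_with_brute_force_reimplementation(self, sim):
        """Independent greedy pass: explicit all-vs-representative identity
        checks in processing order must give identical memberships."""
        from tfaudit.io_formats import read_protein_fasta, read_tsv
        proteins = read_protein_fasta(sim.paths["proteins"])
        doms = read_tsv(sim.paths["domains"])
        zn = sorted({g for g in doms[doms.family == "Zn2Cys6"].gene_id})
        subset = {g: proteins[g] for g in zn}
        clusters = greedy_cluster(subset)

        order = sorted(subset, key=lambda g: (-len(subset[g]), g))
        brute: list[list[str]] = []
        for gid in order:
            for members in brute:
                if pairwise_identity(subset[gid], subset[members[0]]) >= 0.3:
                    members.append(gid)
                    break
            else:
                brute.append([gid])
        assert {frozenset(c.members) for c in clusters} == \
            {frozenset(m) for m in brute}

    def test_planted_families_recovered(self, sim):
        from tfaudit.io_formats import read_protein_fasta, read_tsv
        proteins = read_protein_fasta(sim.paths["proteins"])
        doms = read_tsv(sim.paths["domains"])
        zn = sorted({g for g in doms[doms.family == "Zn2Cys6"].gene_id})
        clusters = greedy_cluster({g: proteins[g] for g in zn})
        multi = {frozenset(c.members) for c in clusters if c.size >= 2}
        planted = {frozenset(f["members"])
                   for f in sim.manifest.families.values()}
        assert multi == planted


class TestParalogyFraction:
    @pytest.mark.parametrize("n_in,size,pct", [(139, 331, 42.0), (16, 73, 21.9)])
    def test_published_style_fractions(self, n_in, size, pct):
        from tfaudit.paralogs import ParalogCluster
        clusters = [ParalogCluster("c1", "r", {f"m{i}": 0.5
                                               for i in range(n_in)})]
        assert paralogy_fraction(clusters, size) == (n_in, pct)

    def test_all_singletons_give_zero(self):
        from tfaudit.paralogs import ParalogCluster
        clusters = [ParalogCluster(f"c{i}", f"g{i}", {f"g{i}": 1.0})
                    for i in range(5)]
        assert paralogy_fraction(clusters, 5) == (0, 0.0)


class TestDuplicationMode:
    def cluster(self, members):
        from tfaudit.paralogs import ParalogCluster
        return ParalogCluster("c1", members[0], {m: 0.8 for m in members})

    def order(self, spec):
        """spec: gene -> (chrom, index)"""
        return dict(spec)

    @pytest.mark.parametrize("idx_b,expected", [
        (1, TANDEM),        # adjacent
        (5, PROXIMAL),      # 3 intervening
        (11, PROXIMAL),     # 10 intervening: window boundary
        (12, DISPERSED),    # 11 intervening
        (21, DISPERSED),    # 20 intervening
    ])
    def test_same_chromosome_window_rule(self, idx_b, expected):
        call = classify_duplication_mode(
            self.cluster(["a", "b"]),
            self.order({"a": ("chrI", 0), "b": ("chrI", idx_b)}))
        assert call.cluster_mode == expected

    def test_different_chromosomes_always_dispersed(self):
        call = classify_duplication_mode(
            self.cluster(["a", "b"]),
            self.order({"a": ("chrI", 0), "b": ("chrVIII", 1)}))
        assert call.cluster_mode == DISPERSED

    def test_tie_between_modes_resolves_dispersed(self):
        # one tandem pair + one dispersed pair + one proximal pair is a tie
        call = classify_duplication_mode(
            self.cluster(["a", "b", "c"]),
            self.order({"a": ("chrI", 0), "b": ("chrI", 1), "c": ("chrII", 0)}))
        assert sorted(call.pair_modes.values()) == [DISPERSED, DISPERSED, TANDEM]
        assert call.cluster_mode == DISPERSED

    def test_missing_coordinates_raise(self):
        with pytest.raises(KeyError):
            classify_duplication_mode(self.cluster(["a", "b"]),
                                      self.order({"a": ("chrI", 0)}))

    def test_singleton_cluster_has_no_mode(self):
        call = classify_duplication_mode(self.cluster(["a"]),
                                         self.order({"a": ("chrI", 0)}))
        assert call.cluster_mode is None and call.pair_modes == {}

    def test_invariant_under_relabeling_and_translation(self):
        base = classify_duplication_mode(
            self.cluster(["a", "b"]),
            self.order({"a": ("chrI", 3), "b": ("chrI", 8)}))
        shifted = classify_duplication_mode(
            self.cluster(["x", "y"]),
            self.order({"x": ("chrQ", 103), "y": ("chrQ", 108)}))
        assert base.cluster_mode == shifted.cluster_mode

    def test_planted_modes_recovered(self, sim, audit):
        report, _ = audit
        zn = next(b for b in report.paralogy if b.family == "Zn2Cys6")
        assert sorted(zn.cluster_modes.values()) == sorted(
            f["mode"] for f in sim.manifest.families.values())

    def test_gene_order_follows_coordinates(self):
        coords = pd.DataFrame([
            {"gene_id": "b", "chrom": "chrI", "start": 500},
            {"gene_id": "a", "chrom": "chrI", "start": 100},
            {"gene_id": "c", "chrom": "chrII", "start": 50}])
        assert build_gene_order(coords) == {
            "a": ("chrI", 0), "b": ("chrI", 1), "c": ("chrII", 0)}


def hits(rows):
    return pd.DataFrame(rows, columns=["query", "subject", "bitscore", "evalue"])


class TestRBH:
    def test_symmetric_pair_confirmed(self):
        fwd = hits([("q1", "s1", 500.0, 1e-90)])
        rev = hits([("s1", "q1", 480.0, 1e-85)])
        r = reciprocal_best_hit(fwd, rev, "q1")
        assert r.confirmed and r.forward_best == "s1"

    def test_reverse_best_elsewhere_unconfirmed(self):
        # the forward best maps back to a different gene
        fwd = hits([("q1", "s1", 500.0, 1e-90)])
        rev = hits([("s1", "other", 600.0, 1e-99), ("s1", "q1", 480.0, 1e-85)])
        r = reciprocal_best_hit(fwd, rev, "q1")
        assert not r.confirmed and r.reverse_best == "other"

    def test_bitscore_tie_broken_by_evalue_then_id(self):
        fwd = hits([("q1", "sB", 500.0, 1e-80), ("q1", "sA", 500.0, 1e-90)])
        rev = hits([("sA", "q1", 500.0, 1e-90)])
        r = reciprocal_best_hit(fwd, rev, "q1")
        assert r.forward_best == "sA" and r.confirmed
        fwd2 = hits([("q1", "sB", 500.0, 1e-80), ("q1", "sA", 500.0, 1e-80)])
        assert reciprocal_best_hit(fwd2, rev, "q1").forward_best == "sA"

    def test_absent_query_unconfirmed_with_reason(self):
        r = reciprocal_best_hit(hits([]), hits([]), "q1")
        assert not r.confirmed and r.reason == "no hits"

    def test_planted_ortholog_confirmations_recovered(self, sim):
        from tfaudit.io_formats import read_tsv
        fwd = read_tsv(sim.paths["forward_hits"])
        rev = read_tsv(sim.paths["reverse_hits"])
        for gid, truth in sim.manifest.genes.items():
            r = reciprocal_best_hit(fwd, rev, gid)
            assert r.confirmed == truth["confirmed"]
            assert r.forward_best == truth["ortholog"]


class TestContactResidues:
    ALN = {"BrlA": "MQ-ALR", "AbaA": "MQ-QLR", "FlbC": "MQ-QLR"}

    def test_conserved_column(self):
        table = contact_residue_report(self.ALN, [2])
        assert bool(table.loc[0, "conserved"]) is True

    def test_divergent_column_names_outlier(self):
        # an Ala where the others carry Gln
        table = contact_residue_report(self.ALN, [4])
        row = table.loc[0]
        assert not row["conserved"] and row["outliers"] == "BrlA:A"

    def test_empty_contact_set_gives_empty_table(self):
        assert len(contact_residue_report(self.ALN, [])) == 0

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            contact_residue_report({"a": "MQA", "b": "MQ"}, [1])

    def test_out_of_range_column_rejected(self):
        with pytest.raises(ValueError):
            contact_residue_report(self.ALN, [99])
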