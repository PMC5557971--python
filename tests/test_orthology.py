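"""BRBH rule, COG formation and pangenome partition against oracles."""

import itertools

import numpy as np
import pytest

from panani.errors import InputError
from panani.io import HitRecord
from panani.orthology import (BrbhParams, best_hit_per_target_genome,
                              build_cogs, partition_pangenome,
                              reciprocal_pairs)


def hit(q, s, score, evalue=1e-30):
    return HitRecord(q, s, 50.0, 100, 10, 0, 1, 100, 1, 100, evalue, score)


GENOME_OF_2 = {"a1": "A", "b1": "B", "b2": "B"}


class TestSecondBestRule:
    def test_clear_best_accepted(self):
        hits = [hit("a1", "b1", 100), hit("a1", "b2", 85)]
        best = best_hit_per_target_genome(hits, GENOME_OF_2)
        assert best[("a1", "B")] == "b1"

    def test_boundary_ninety_percent_rejected(self):
        # 90 == 0.90 * 100: the strict "<" comparison fails
        hits = [hit("a1", "b1", 100), hit("a1", "b2", 90)]
        best = best_hit_per_target_genome(hits, GENOME_OF_2)
        assert ("a1", "B") not in best

    def test_evalue_gate_rejects_single_hit(self):
        hits = [hit("a1", "b1", 100, evalue=1e-4)]
        best = best_hit_per_target_genome(hits, GENOME_OF_2)
        assert best == {}

    def test_evalue_boundary_inclusive(self):
        # the gate is e-value <= 1e-5
        hits = [hit("a1", "b1", 100, evalue=1e-5)]
        best = best_hit_per_target_genome(hits, GENOME_OF_2)
        assert best[("a1", "B")] == "b1"

    def test_within_genome_hits_ignored(self):
        genome_of = {"a1": "A", "a2": "A", "b1": "B"}
        hits = [hit("a1", "a2", 500), hit("a1", "b1", 100)]
        best = best_hit_per_target_genome(hits, genome_of)
        assert best == {("a1", "B"): "b1"}

    def test_internal_mode_uses_score_floor_not_evalue(self):
        h = hit("a1", "b1", 400, evalue=1.0)
        h.internal_mode = True
        best = best_hit_per_target_genome([h], GENOME_OF_2)
        assert best[("a1", "B")] == "b1"
        weak = hit("a1", "b1", 100, evalue=0.0)
        weak.internal_mode = True
        assert best_hit_per_target_genome([weak], GENOME_OF_2) == {}


class TestReciprocity:
    def test_mutual_bests_form_one_pair(self):
        hits = [hit("a1", "b1", 100), hit("b1", "a1", 100)]
        best = best_hit_per_target_genome(hits, GENOME_OF_2)
        assert reciprocal_pairs(best, GENOME_OF_2) == {("a1", "b1")}

    def test_non_reciprocal_best_excluded(self):
        genome_of = {"a1": "A", "a2": "A", "b1": "B"}
        hits = [hit("a1", "b1", 100), hit("b1", "a2", 100)]
        best = best_hit_per_target_genome(hits, genome_of)
        assert reciprocal_pairs(best, genome_of) == set()


def brbh_oracle(hits, genome_of, max_evalue=1e-5, ratio=0.90):
    """Literal restatement of the acceptance rule, written independently:
    gate on e-value, rank each query's hits per target genome, demand the
    second best from that genome be strictly below ratio x best, then keep
    mutually-best pairs."""
    best = {}
    queries = {h.query_gene_id for h in hits}
    for q in queries:
        for genome in set(genome_of.values()):
            if genome == genome_of[q]:
                continue
            candidates = {}
            for h in hits:
                if (h.query_gene_id == q
                        and genome_of[h.subject_gene_id] == genome
                        and h.e_value <= max_evalue):
                    prev = candidates.get(h.subject_gene_id)
                    if prev is None or h.bit_score > prev:
                        candidates[h.subject_gene_id] = h.bit_score
            if not candidates:
                continue
            ranked = sorted(candidates.items(), key=lambda t: (-t[1], t[0]))
            if len(ranked) > 1 and not (ranked[1][1] < ratio * ranked[0][1]):
                continue
            best[(q, genome)] = ranked[0][0]
    pairs = set()
    for (q, genome), s in best.items():
        if best.get((s, genome_of[q])) == q:
            pairs.add(tuple(sorted((q, s))))
    return pairs


class TestBrbhOracleEquivalence:
    @pytest.mark.parametrize("batch", range(4))
    def test_random_three_genome_tables(self, batch):
        """100 random hit tables (3 genomes x <=5 genes) against the
        literal brute-force application of the rule."""
        rng = np.random.default_rng(500 + batch)
        for _ in range(25):
            genome_of = {}
            for genome in "ABC":
                for i in range(rng.integers(1, 6)):
                    genome_of[f"{genome.lower()}{i}"] = genome
            genes = sorted(genome_of)
            cross = [(q, s) for q in genes for s in genes
                     if genome_of[q] != genome_of[s]]
            n_hits = int(rng.integers(0, len(cross) + 1))
            chosen = [cross[i] for i in
                      rng.choice(len(cross), size=n_hits, replace=False)]
            hits = [
                hit(q, s,
                    score=float(rng.integers(40, 120)),
                    evalue=float(10.0 ** -rng.integers(2, 12)))
                for q, s in chosen
            ]
            best = best_hit_per_target_genome(hits, genome_of)
            assert reciprocal_pairs(best, genome_of) == \
                brbh_oracle(hits, genome_of)


class UnionFind:
    """Independent oracle for connected components."""

    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


class TestCogFormation:
    GENOME_OF = {f"{g.lower()}{i}": g for g in "ABC" for i in range(5)}

    def test_transitive_closure_single_cog(self):
        cogs = build_cogs([("a1", "b1"), ("b1", "c1")], self.GENOME_OF)
        assert len(cogs) == 1
        assert cogs[0].gene_ids == {"a1", "b1", "c1"}

    def test_disjoint_pairs_two_cogs(self):
        cogs = build_cogs([("a1", "b1"), ("a2", "b2")], self.GENOME_OF)
        assert len(cogs) == 2

    def test_component_count_matches_union_find_oracle(self):
        rng = np.random.default_rng(123)
        genes = sorted(self.GENOME_OF)
        for _ in range(100):
            n_pairs = int(rng.integers(0, 15))
            pairs = set()
            while len(pairs) < n_pairs:
                a, b = rng.choice(genes, size=2, replace=False)
                if self.GENOME_OF[a] != self.GENOME_OF[b]:
                    pairs.add(tuple(sorted((a, b))))
            uf = UnionFind()
            for a, b in pairs:
                uf.union(a, b)
            roots = {uf.find(g) for pair in pairs for g in pair}
            assert len(build_cogs(pairs, self.GENOME_OF)) == len(roots)

    def test_strict_clique_mode_splits_paths(self):
        # a1-b1-c1 path is not a clique: falls back to its two edges
        pairs = [("a1", "b1"), ("b1", "c1")]
        cogs = build_cogs(pairs, self.GENOME_OF, strict_clique=True)
        assert sorted(c.gene_ids for c in cogs) == [{"a1", "b1"}, {"b1", "c1"}]


class TestPartition:
    def test_planted_truth_recovered(self, small_pangenome):
        from panani.align import all_vs_all_protein_hits
        config, genomes, genes, proteomes, truth = small_pangenome
        hits = all_vs_all_protein_hits(proteomes)
        genome_of = {g.gene_id: g.genome_id for g in genes}
        best = best_hit_per_target_genome(hits, genome_of)
        pairs = reciprocal_pairs(best, genome_of)
        cogs = build_cogs(pairs, genome_of)
        partition = partition_pangenome(
            cogs, genome_of, best, [g.genome_id for g in genomes])
        assert len(partition.core_cogs) == config.n_core
        assert all(len(c.members) == config.n_genomes
                   for c in partition.core_cogs)
        assert set(partition.specific_genes) == truth.specific_gene_ids
        assert partition.unresolved_genes == []

    def test_core_requires_exactly_one_member_per_genome(self):
        genome_of = {"a1": "A", "a2": "A", "b1": "B"}
        cogs = build_cogs([("a1", "b1"), ("a2", "b1")], genome_of)
        partition = partition_pangenome(cogs, genome_of, set(), ["A", "B"])
        assert partition.core_cogs == []
        assert len(partition.accessory_cogs) == 1

    def test_single_genome_rejected(self):
        with pytest.raises(InputError):
            partition_pangenome([], {"a1": "A"}, set(), ["A"])

    def test_core_count_non_increasing_with_added_genome(self):
        """Adding a genome can only shrink (or keep) the core."""
        from panani.align import all_vs_all_protein_hits
        from panani.synthetic import PangenomeConfig, simulate_pangenome
        config = PangenomeConfig(n_genomes=4, n_core=10, n_accessory=6,
                                 n_specific_per_genome=1, divergence=0.03,
                                 gene_length=300, seed=3)
        genomes, genes, proteomes, truth = simulate_pangenome(config)
        genome_of = {g.gene_id: g.genome_id for g in genes}

        def core_count(genome_subset):
            sub_prot = {g: proteomes[g] for g in genome_subset}
            sub_of = {gene: genome for gene, genome in genome_of.items()
                      if genome in genome_subset}
            hits = all_vs_all_protein_hits(sub_prot)
            best = best_hit_per_target_genome(hits, sub_of)
            cogs = build_cogs(reciprocal_pairs(best, sub_of), sub_of)
            return len(partition_pangenome(
                cogs, sub_of, best, sorted(genome_subset)).core_cogs)

        ids = [g.genome_id for g in genomes]
        counts = [core_count(ids[:k]) for k in (2, 3, 4)]
        assert counts[0] >= counts[1] >= counts[2]
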