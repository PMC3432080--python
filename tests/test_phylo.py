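"""Distances, NJ, bootstrap supports and group extraction."""

import numpy as np
import pytest

from serprot.phylo import (
    DistanceMatrix,
    Msa,
    PhyloConfig,
    TreeNode,
    bipartitions,
    bootstrap_support,
    extract_groups,
    midpoint_root,
    neighbor_joining,
    pairwise_distance,
    progressive_msa,
)
from serprot.synth import (
    EvolutionSpec,
    evolve_sequences,
    path_distance_matrix,
    random_binary_tree,
    random_protein,
    two_clade_family_tree,
)


class TestPairwiseDistance:
    def test_identical_rows(self):
        m = Msa(["a", "b"], ["ACDE", "ACDE"])
        assert pairwise_distance(m).d[0, 1] == 0.0

    def test_p_distance_closed_form(self):
        m = Msa(["a", "b"], ["AAAAAAAAAA", "AAAAAAAAAC"])
        assert pairwise_distance(m).d[0, 1] == pytest.approx(0.1)

    def test_poisson_correction(self):
        m = Msa(["a", "b"], ["AAAAAAAAAA", "AAAAAAAAAC"])
        assert pairwise_distance(m, "poisson").d[0, 1] == pytest.approx(-np.log(0.9), abs=1e-9)

    def test_pairwise_deletion(self):
        m = Msa(["a", "b"], ["AC-E", "ACD-"])
        # only 2 shared non-gap columns, both matching
        assert pairwise_distance(m).d[0, 1] == 0.0

    def test_no_shared_columns_error(self):
        m = Msa(["a", "b"], ["A-", "-A"])
        with pytest.raises(ValueError, match="shared"):
            pairwise_distance(m)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        t = neighbor_joining(dm)
        lengths = {c.name: c.length for c in t.children}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    def test_recovers_additive_tree_exactly(self, rng):
        for _ in range(30):
            names = [f"t{k}" for k in range(int(rng.integers(6, 11)))]
            truth = random_binary_tree(names, rng)
            rec = neighbor_joining(path_distance_matrix(truth))
            assert set(bipartitions(truth)) == set(bipartitions(rec))

    def test_matches_scikit_bio_topology(self, rng):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        for _ in range(20):
            names = [f"t{k}" for k in range(5)]
            x = rng.uniform(0.1, 1.0, (5, 5))
            d = (x + x.T) / 2
            np.fill_diagonal(d, 0.0)
            mine = neighbor_joining(DistanceMatrix(names, d))
            theirs = sk_nj(SkDM(d, names))
            anchor = min(names)
            sk_splits = set()
            for node in theirs.non_tips():
                side = frozenset(t.name for t in node.tips())
                if 2 <= len(side) <= len(names) - 2:
                    sk_splits.add(side if anchor not in side else frozenset(set(names) - side))
            assert set(bipartitions(mine)) == sk_splits


class TestProgressiveMsa:
    def test_identical_pair_gap_free(self):
        m = progressive_msa([("a", "IVGGHD"), ("b", "IVGGHD")])
        assert m.rows == ["IVGGHD", "IVGGHD"]

    def test_gap_at_deleted_column(self):
        m = progressive_msa([("a", "ACDE"), ("b", "ACE")])
        assert m.rows[0] == "ACDE" and m.rows[1] == "AC-E"

    def test_planted_cysteine_columns_stay_aligned(self, anchors):
        from serprot.synth import ProteaseSpec, synth_protease_cdna

        proteins = []
        for seed in range(8):
            _, _, p = synth_protease_cdna(ProteaseSpec(family="trypsin", seed=seed), anchors)
            proteins.append((p.id, p.sequence))
        m = progressive_msa(proteins)
        ref = {a.family: a for a in anchors}["trypsin"]
        # six cysteine anchors must land in six shared all-Cys columns
        cys_cols = [j for j in range(m.ncol) if all(row[j] == "C" for row in m.rows)]
        assert len(cys_cols) >= 6

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            progressive_msa([("a", "ACDE")])


class TestBootstrapAndGroups:
    def test_identical_columns_give_full_support(self):
        seqs = {f"A{k}": "AAAA" + "C" * 6 for k in range(2)}
        seqs |= {f"B{k}": "TTTT" + "C" * 6 for k in range(2)}
        # 4-taxon tree has one internal edge; every resample contains the split
        m = Msa(list(seqs), list(seqs.values()))
        t = bootstrap_support(m, PhyloConfig(bootstrap_replicates=50, seed=1))
        sup = [n.support for n in t.walk() if n is not t and not n.is_leaf]
        assert sup and all(s == 100.0 for s in sup)

    def test_single_replicate_reproducible(self):
        rng = np.random.default_rng(0)
        seqs = {f"s{k}": random_protein(50, rng) for k in range(5)}
        m = Msa(list(seqs), list(seqs.values()))
        t1 = bootstrap_support(m, PhyloConfig(bootstrap_replicates=1, seed=7))
        t2 = bootstrap_support(m, PhyloConfig(bootstrap_replicates=1, seed=7))
        assert t1.to_newick() == t2.to_newick()

    def test_supports_invariant_to_leaf_order(self):
        rng = np.random.default_rng(3)
        tree = two_clade_family_tree(3)
        seqs = evolve_sequences(EvolutionSpec(tree, random_protein(120, rng), seed=3))
        items = list(seqs.items())
        m1 = Msa([i for i, _ in items], [s for _, s in items])
        rev = items[::-1]
        m2 = Msa([i for i, _ in rev], [s for _, s in rev])
        cfg = PhyloConfig(bootstrap_replicates=80, seed=11)
        sup1 = {k: n.support for k, n in bipartitions(bootstrap_support(m1, cfg)).items()}
        sup2 = {k: n.support for k, n in bipartitions(bootstrap_support(m2, cfg)).items()}
        assert set(sup1) == set(sup2)
        # resampling the same columns in a different taxon order must not
        # change which splits are strongly supported
        for k in sup1:
            assert (sup1[k] >= 75) == (sup2[k] >= 75)

    def test_extract_groups_threshold_boundary(self):
        leaves_a = [TreeNode(name=f"A{k}", length=1.0) for k in range(2)]
        leaves_b = [TreeNode(name=f"B{k}", length=1.0) for k in range(2)]
        na = TreeNode(length=1.0, support=75.0, children=leaves_a)
        nb = TreeNode(length=1.0, support=50.0, children=leaves_b)
        root = TreeNode(children=[na, nb])
        groups = extract_groups(root, 75.0)
        assert groups["A0"] == groups["A1"] != "ungrouped"  # support == threshold grouped
        assert groups["B0"] == "ungrouped"  # low support stays out

    def test_grouping_requires_supports(self):
        root = TreeNode(children=[TreeNode(name="a", length=1), TreeNode(
            length=1, children=[TreeNode(name="b", length=1), TreeNode(name="c", length=1)])])
        with pytest.raises(ValueError, match="support"):
            extract_groups(root)

    def test_midpoint_rooting_preserves_splits_and_supports(self):
        rng = np.random.default_rng(5)
        tree = two_clade_family_tree()
        seqs = evolve_sequences(EvolutionSpec(tree, random_protein(200, rng), seed=5))
        m = Msa(list(seqs), list(seqs.values()))
        t = bootstrap_support(m, PhyloConfig(bootstrap_replicates=50, seed=5))
        before = {k: n.support for k, n in bipartitions(t).items()}
        rooted = midpoint_root(t)
        after = {k: n.support for k, n in bipartitions(rooted).items()}
        assert before == {k: after[k] for k in before}

    def test_two_planted_clades_recovered(self):
        rng = np.random.default_rng(42)
        tree = two_clade_family_tree()
        seqs = evolve_sequences(EvolutionSpec(tree, random_protein(300, rng), seed=42))
        m = Msa(list(seqs), list(seqs.values()))
        t = midpoint_root(bootstrap_support(m, PhyloConfig(bootstrap_replicates=100, seed=42)))
        groups = extract_groups(t, 75.0)
        sets = {}
        for leaf, g in groups.items():
            sets.setdefault(g, set()).add(leaf)
        assert {f"A{k}" for k in range(4)} in sets.values()
        assert {f"B{k}" for k in range(4)} in sets.values()

    def test_newick_is_parseable(self):
        from skbio import TreeNode as SkTree
        import io

        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        t = neighbor_joining(dm)
        parsed = SkTree.read(io.StringIO(t.to_newick()))
        assert {tip.name for tip in parsed.tips()} == {"A", "B", "C"}
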