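import io
import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phyloconv import (
    GeneratorConfig,
    GroupedAlignment,
    bootstrap_support,
    congruent,
    generate_panel,
    group_topology,
    k2p_distances,
    nj_tree,
)
from phyloconv.phylo_congruence import DistanceMatrix, complete_deletion, k2p_from_counts


def _unrooted_splits(tree):
    """Nontrivial bipartitions as frozensets of leaf-label frozensets."""
    labels = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(side) < len(labels) - 1:
            splits.add(frozenset({side, labels - side}))
    return splits


class TestK2P:
    def test_identical_sequences_zero(self):
        aln = GroupedAlignment(
            segment_id="s",
            sequences={f"s{i}": "ACGT" * 25 for i in range(3)},
            groups={f"s{i}": "A" for i in range(3)},
        )
        dm = k2p_distances(aln)
        assert np.allclose(dm.matrix, 0.0)
        assert dm.n_sites_used == 100

    def test_closed_form_ten_transitions(self):
        # 100 sites, 10 transitions (A<->G), no transversions
        base = "A" * 100
        other = "G" * 10 + "A" * 90
        aln = GroupedAlignment(
            segment_id="s",
            sequences={"s1": base, "s2": other, "s3": base},
            groups={"s1": "A", "s2": "A", "s3": "A"},
        )
        dm = k2p_distances(aln)
        assert dm.distance("s1", "s2") == pytest.approx(-0.5 * math.log(0.8))
        assert dm.distance("s1", "s2") == pytest.approx(0.11157, abs=1e-5)

    def test_random_pairs_match_textbook_formula(self):
        rng = np.random.default_rng(3)
        bases = "ACGT"
        L = 400
        s1 = "".join(rng.choice(list(bases), L))

        def mutate(s, p):
            # substitute ~p of sites with a random different base
            out = list(s)
            for i in np.flatnonzero(rng.random(L) < p):
                out[i] = rng.choice([b for b in bases if b != out[i]])
            return "".join(out)

        s2 = mutate(s1, 0.10)
        s3 = mutate(s1, 0.20)
        aln = GroupedAlignment(
            segment_id="s",
            sequences={"s1": s1, "s2": s2, "s3": s3},
            groups={"s1": "A", "s2": "A", "s3": "A"},
        )
        dm = k2p_distances(aln, cap_saturated=True)
        ts_pairs = {frozenset("AG"), frozenset("CT")}
        for a, b in [("s1", "s2"), ("s1", "s3")]:
            sa, sb = aln.sequences[a], aln.sequences[b]
            P = sum(
                1 for x, y in zip(sa, sb) if x != y and frozenset({x, y}) in ts_pairs
            ) / L
            Q = sum(
                1 for x, y in zip(sa, sb) if x != y and frozenset({x, y}) not in ts_pairs
            ) / L
            want = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
            assert dm.distance(a, b) == pytest.approx(want)

    def test_complete_deletion_drops_gap_columns_order_invariant(self):
        seqs = {"s1": "AC-TA", "s2": "ACGTN", "s3": "ACGTA"}
        aln = GroupedAlignment(
            segment_id="s", sequences=seqs, groups={s: "A" for s in seqs}
        )
        _, keep = complete_deletion(aln)
        assert keep.tolist() == [0, 1, 3]
        reordered = GroupedAlignment(
            segment_id="s",
            sequences=dict(reversed(list(seqs.items()))),
            groups={s: "A" for s in seqs},
        )
        _, keep2 = complete_deletion(reordered)
        assert keep2.tolist() == keep.tolist()

    def test_all_gap_columns_error(self):
        aln = GroupedAlignment(
            segment_id="s",
            sequences={"s1": "A-", "s2": "-C", "s3": "AC"},
            groups={"s1": "A", "s2": "A", "s3": "A"},
        )
        with pytest.raises(ValueError, match="complete deletion"):
            k2p_distances(aln)

    def test_saturated_pair_raises_unless_capped(self):
        assert math.isinf(k2p_from_counts(0.5, 0.3))


class TestNJ:
    # additive distances from the tree ((a:1,b:2):1,c:3,d:4)
    TOY = DistanceMatrix(
        strains=("a", "b", "c", "d"),
        matrix=np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        ),
        n_sites_used=1,
    )

    def test_recovers_additive_topology(self):
        tree = nj_tree(self.TOY)
        assert _unrooted_splits(tree) == {
            frozenset({frozenset({"a", "b"}), frozenset({"c", "d"})})
        }

    def test_matches_independent_nj_implementation(self):
        rng = np.random.default_rng(8)
        for rep in range(5):
            n = 7
            names = tuple(f"t{i}" for i in range(n))
            # random additive-ish matrix: random points + noise keeps it generic
            pts = rng.uniform(0, 1, (n, 4))
            D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            dm = DistanceMatrix(strains=names, matrix=D, n_sites_used=1)
            mine = nj_tree(dm)
            csv = "x," + ",".join(names) + "\n"
            for i, nm in enumerate(names):
                csv += nm + "," + ",".join(f"{D[i, j]:.10f}" for j in range(n)) + "\n"
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                io.StringIO(csv), delimiter=","
            )
            ref = pdm.nj_tree()
            assert _unrooted_splits(mine) == _unrooted_splits(ref)

    def test_three_taxa_unique_topology(self):
        dm = DistanceMatrix(
            strains=("a", "b", "c"),
            matrix=np.array([[0, 1, 2], [1, 0, 2.5], [2, 2.5, 0]]),
            n_sites_used=1,
        )
        tree = nj_tree(dm)
        assert len(list(tree.leaf_node_iter())) == 3

    def test_input_order_invariance(self):
        perm = ("d", "b", "a", "c")
        idx = [self.TOY.strains.index(s) for s in perm]
        dm2 = DistanceMatrix(
            strains=perm,
            matrix=self.TOY.matrix[np.ix_(idx, idx)],
            n_sites_used=1,
        )
        assert _unrooted_splits(nj_tree(self.TOY)) == _unrooted_splits(nj_tree(dm2))

    def test_outgroup_rooting(self):
        tree = nj_tree(self.TOY, outgroup="d")
        root_children = tree.seed_node.child_nodes()
        labels = [
            c.taxon.label if c.is_leaf() else None for c in root_children
        ]
        assert "d" in labels


class TestBootstrap:
    def test_two_clean_clades_get_full_support(self):
        a = "ACGT" * 15
        b = ("GCGT" + "ACGT" + "ATGT") * 5  # transitions at 2 of every 12 sites
        seqs = {"x1": a, "x2": a, "y1": b, "y2": b}
        aln = GroupedAlignment(
            segment_id="s", sequences=seqs, groups={s: "A" for s in seqs}
        )
        tree = bootstrap_support(aln, n_reps=50, seed=1)
        supports = [
            float(n.label)
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None and n.label
        ]
        assert supports and all(s == 1.0 for s in supports)

    def test_supports_in_unit_interval_and_reproducible(self, small_panel):
        alignments, _ = small_panel
        aln = alignments[0]
        t1 = bootstrap_support(aln, outgroup="OUT", n_reps=30, seed=5)
        t2 = bootstrap_support(aln, outgroup="OUT", n_reps=30, seed=5)
        s1 = [n.label for n in t1.preorder_node_iter() if n.label]
        s2 = [n.label for n in t2.preorder_node_iter() if n.label]
        assert s1 == s2
        assert all(0.0 <= float(x) <= 1.0 for x in s1)

    def test_strong_signal_recovers_generating_groups(self):
        cfg = GeneratorConfig(
            groups={"A": 3, "B1": 3},
            n_segments=1,
            segment_length=4000,
            seed=21,
        )
        alignments, _ = generate_panel(cfg)
        tree = bootstrap_support(alignments[0], outgroup="OUT", n_reps=40, seed=2)
        splits = _unrooted_splits(tree)
        want = frozenset(
            {
                frozenset({"A_01", "A_02", "A_03"}),
                frozenset({"B1_01", "B1_02", "B1_03", "OUT"}),
            }
        )
        assert want in splits


def _tree(newick, tns):
    return dendropy.Tree.get(
        data=newick, schema="newick", taxon_namespace=tns, rooting="force-rooted"
    )


class TestGroupTopology:
    GROUPS = {
        "a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "d1": "D", "d2": "D",
    }

    def test_identical_trees_congruent(self):
        tns = dendropy.TaxonNamespace()
        t = _tree("((a1,a2),((b1,b2),c1));", tns)
        g = group_topology(t, self.GROUPS)
        assert congruent(g, g)

    def test_within_group_rearrangement_is_congruent(self):
        tns = dendropy.TaxonNamespace()
        g1 = group_topology(_tree("((a1,a2),((b1,b2),c1));", tns), self.GROUPS)
        g2 = group_topology(_tree("((a2,a1),((b2,b1),c1));", tns), self.GROUPS)
        assert congruent(g1, g2)
        assert g1.monophyletic == {"A": True, "B": True, "C": True}

    def test_between_group_rearrangement_is_incongruent(self):
        tns = dendropy.TaxonNamespace()
        g1 = group_topology(_tree("((a1,a2),((b1,b2),c1));", tns), self.GROUPS)
        g2 = group_topology(_tree("(((a1,a2),(b1,b2)),c1);", tns), self.GROUPS)
        assert not congruent(g1, g2)

    def test_paraphyletic_group_split_into_suffixed_leaves(self):
        tns = dendropy.TaxonNamespace()
        t = _tree("((d1,c1),((d2,b1),(a1,a2)));", tns)
        g = group_topology(t, self.GROUPS)
        assert g.monophyletic["D"] is False
        assert g.newick.count("D.") == 2

    def test_label_mismatch_is_error(self):
        tns = dendropy.TaxonNamespace()
        g1 = group_topology(_tree("((a1,a2),c1);", tns), self.GROUPS)
        g2 = group_topology(_tree("((b1,b2),c1);", tns), self.GROUPS)
        with pytest.raises(ValueError, match="differ"):
            congruent(g1, g2)

    @settings(max_examples=30, derandomize=True)
    @given(st.permutations(["a1", "a2", "b1", "b2", "c1"]))
    def test_congruence_is_an_equivalence_on_caterpillars(self, leaves):
        """Reflexive + symmetric on randomized caterpillar trees."""
        tns = dendropy.TaxonNamespace()
        nwk = "(" * (len(leaves) - 1) + leaves[0]
        for leaf in leaves[1:]:
            nwk += f",{leaf})"
        g1 = group_topology(_tree(nwk + ";", tns), self.GROUPS)
        g2 = group_topology(_tree(nwk + ";", dendropy.TaxonNamespace()), self.GROUPS)
        assert congruent(g1, g1)
        assert congruent(g1, g2) == congruent(g2, g1)
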