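import math
import random

import numpy as np
import pytest

from cladeprimer.errors import ZeroUsableSitesError
from cladeprimer.phylo_classify import (
    DistanceMatrix,
    Tree,
    TreeNode,
    assign_taxon,
    bootstrap_supports,
    build_distance_matrix,
    nj_tree,
    tn93_distance,
)
from cladeprimer.seq_io import Alignment, SequenceRecord, TaxonEntry, TaxonMap
from cladeprimer.synthetic_fixtures import (
    classification_panel_config,
    generate_pcr_templates,
    generate_reference_panel,
    reference_amplicon_alignment,
    simulate_vesicle_clones,
)


def tn93_oracle(a: str, b: str) -> float:
    """Direct transcription of the distance formula, coded independently of
    the implementation (vectorized, no shared helpers)."""
    arr = np.array([list(a), list(b)])
    ok = np.isin(arr, list("ACGT")).all(axis=0)
    x, y = arr[0, ok], arr[1, ok]
    n = x.size
    pooled = np.concatenate([x, y])
    pi = {c: float(np.mean(pooled == c)) for c in "ACGT"}
    pR, pY = pi["A"] + pi["G"], pi["C"] + pi["T"]
    diff = x != y
    P1 = float(np.mean(diff & np.isin(x, ["A", "G"]) & np.isin(y, ["A", "G"])))
    P2 = float(np.mean(diff & np.isin(x, ["C", "T"]) & np.isin(y, ["C", "T"])))
    Q = float(np.mean(diff)) - P1 - P2
    k1 = 2 * pi["A"] * pi["G"] / pR
    k2 = 2 * pi["T"] * pi["C"] / pY
    k3 = 2 * (pR * pY - pi["A"] * pi["G"] * pY / pR - pi["T"] * pi["C"] * pR / pY)
    terms = []
    for k, w in ((k1, 1 - (P1 / k1 if k1 else 0) - Q / (2 * pR)),
                 (k2, 1 - (P2 / k2 if k2 else 0) - Q / (2 * pY)),
                 (k3, 1 - Q / (2 * pR * pY))):
        if k == 0:
            continue
        if w <= 0:
            return math.inf
        terms.append(-k * math.log(w))
    return max(sum(terms), 0.0)


class TestTN93:
    def test_identical_sequences(self):
        d, comp = tn93_distance("ACGTACGT", "ACGTACGT")
        assert d == 0.0
        assert (comp.p1, comp.p2, comp.q) == (0, 0, 0)

    def test_gap_and_ambiguity_sites_excluded(self):
        d, comp = tn93_distance("ACGT-N", "ACGTAA")
        assert comp.usable_sites == 4
        assert d == 0.0

    def test_zero_usable_sites(self):
        with pytest.raises(ZeroUsableSitesError):
            tn93_distance("----", "ACGT")

    def test_reduces_to_jukes_cantor_in_symmetric_limit(self):
        # equal base composition; the 12 substitution types planted once
        # each, so both transition proportions and the transversion
        # proportion match the equal-rates model exactly
        a = "ACGT" * 30
        b = list(a)
        subs = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
                ("A", "C"), ("C", "A"), ("G", "T"), ("T", "G"),
                ("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
        idx, used = 0, set()
        for orig, new in subs:
            while b[idx] != orig or idx in used:
                idx += 1
            b[idx] = new
            used.add(idx)
            idx = 0
        d, _ = tn93_distance(a, "".join(b))
        p = 12 / 120
        assert abs(d - (-0.75 * math.log(1 - 4 * p / 3))) < 1e-9

    def test_agrees_with_independent_oracle_on_random_pairs(self):
        rng = np.random.default_rng(23)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            n = int(rng.integers(50, 400))
            a = "".join(rng.choice(bases, n))
            b = list(a)
            # mutate a random fraction
            k = int(rng.integers(0, n // 3 + 1))
            for i in rng.choice(n, size=k, replace=False):
                b[i] = rng.choice([c for c in "ACGT" if c != b[i]])
            b = "".join(b)
            d, _ = tn93_distance(a, b)
            expected = tn93_oracle(a, b)
            if math.isinf(expected):
                assert math.isinf(d)
            else:
                assert abs(d - expected) <= 1e-12

    def test_saturation_flagged_infinite(self):
        d, _ = tn93_distance("A" * 50, "G" * 50)
        assert math.isinf(d)


class TestDistanceMatrix:
    def test_identical_rows_all_zero(self):
        aln = Alignment((SequenceRecord("a", "ACGT"), SequenceRecord("b", "ACGT")))
        m = build_distance_matrix(aln)
        assert np.array_equal(m.values, np.zeros((2, 2)))

    def test_permutation_consistency_and_pair_oracle(self):
        aln, _, _ = generate_reference_panel(classification_panel_config(seed=5))
        small = Alignment(aln.records[:5])
        m = build_distance_matrix(small)
        assert np.allclose(m.values, m.values.T)
        for i in range(5):
            for j in range(5):
                d, _ = tn93_distance(small.records[i], small.records[j]) if i != j else (0.0, None)
                assert m.values[i, j] == pytest.approx(d, abs=1e-15)
        perm = Alignment(tuple(reversed(small.records)))
        mp = build_distance_matrix(perm)
        assert np.allclose(mp.values, m.values[::-1, ::-1])


def random_additive_matrix(n_leaves: int, seed: int):
    """Random binary tree by sequential joins; returns (ids, path matrix)."""
    rnd = random.Random(seed)
    nodes = [TreeNode(name=f"t{i}") for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rnd.sample(range(len(nodes)), 2))
        a, b = nodes[i], nodes[j]
        a.length = rnd.uniform(0.05, 1.0)
        b.length = rnd.uniform(0.05, 1.0)
        parent = TreeNode(children=[a, b])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    for node in nodes:
        node.length = rnd.uniform(0.05, 1.0)
    tree = Tree(TreeNode(children=nodes))
    m = tree.path_length_matrix()
    return m


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        m = DistanceMatrix(("A", "B", "C"),
                           np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float))
        tree = nj_tree(m)
        lengths = {lf.name: lf.length for lf in tree.root.leaves()}
        # three-point formulas: a=(dAB+dAC-dBC)/2 etc.
        assert lengths == {"A": 0.0, "B": 2.0, "C": 3.0}

    @pytest.mark.parametrize("n,seed", [(5, 1), (6, 2), (8, 3), (10, 4)])
    def test_additive_matrix_round_trip(self, n, seed):
        m = random_additive_matrix(n, seed)
        tree = nj_tree(m)
        recovered = tree.path_length_matrix()
        order = [recovered.ids.index(i) for i in m.ids]
        assert np.abs(recovered.values[np.ix_(order, order)] - m.values).max() <= 1e-9

    def test_leaf_label_permutation_gives_isomorphic_tree(self):
        m = random_additive_matrix(6, 9)
        perm = list(reversed(range(len(m.ids))))
        m2 = DistanceMatrix(tuple(m.ids[i] for i in perm),
                            m.values[np.ix_(perm, perm)])
        t1, t2 = nj_tree(m), nj_tree(m2)
        assert t1.bipartitions() == t2.bipartitions()

    def test_fewer_than_three_taxa_rejected(self):
        m = DistanceMatrix(("a", "b"), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            nj_tree(m)

    def test_matches_dendropy_on_additive_matrix(self):
        dendropy = pytest.importorskip("dendropy")
        m = random_additive_matrix(7, 12)
        csv = "," + ",".join(m.ids) + "\n" + "\n".join(
            m.ids[i] + "," + ",".join(f"{v:.10f}" for v in m.values[i])
            for i in range(len(m.ids))
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv)
        )
        ref = pdm.nj_tree()
        ref_parts = set()
        leaves = frozenset(t.label for t in ref.taxon_namespace)
        anchor = min(leaves)
        ref.encode_bipartitions()
        for edge in ref.preorder_edge_iter():
            side = frozenset(
                t.label for t in edge.bipartition.leafset_taxa(ref.taxon_namespace)
            )
            if 1 < len(side) < len(leaves) - 1:
                ref_parts.add(side if anchor not in side else leaves - side)
        assert nj_tree(m).bipartitions() == ref_parts


class TestBootstrap:
    def strong_alignment(self, seed=5):
        cfg = classification_panel_config(seed)
        aln, taxa, truth = generate_reference_panel(cfg)
        return reference_amplicon_alignment(aln, truth, taxa,
                                            roles=("target", "outgroup")), taxa

    @staticmethod
    def support_by_bipartition(tree):
        all_leaves = tree.leaf_names
        anchor = min(all_leaves)
        out = {}

        def walk(node):
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not tree.root and 1 < len(below) < len(all_leaves) - 1:
                key = below if anchor not in below else all_leaves - below
                out[key] = node.support
            return below

        walk(tree.root)
        return out

    def test_class_separating_bipartitions_strongly_supported(self):
        refs, taxa = self.strong_alignment()
        tree = bootstrap_supports(refs, replicates=100, seed=7)
        supports = self.support_by_bipartition(tree)
        anchor = min(tree.leaf_names)
        checked = 0
        for klass, members in taxa.groups().items():
            members = frozenset(m for m in members if m in tree.leaf_names)
            if len(members) < 2 or len(members) > len(tree.leaf_names) - 2:
                continue
            key = members if anchor not in members else tree.leaf_names - members
            assert key in supports, f"class {klass} not monophyletic in NJ tree"
            assert supports[key] >= 90, f"class {klass} support {supports[key]}"
            checked += 1
        assert checked >= 2

    def test_single_replicate_supports_are_binary(self):
        refs, _ = self.strong_alignment(seed=8)
        tree = bootstrap_supports(refs, replicates=1, seed=3)
        def collect(node):
            out = [node.support] if node.support is not None else []
            for c in node.children:
                out += collect(c)
            return out
        assert set(collect(tree.root)) <= {0.0, 100.0}

    def test_same_seed_byte_identical_newick(self):
        refs, _ = self.strong_alignment(seed=9)
        a = bootstrap_supports(refs, replicates=20, seed=42).to_newick(with_support=True)
        b = bootstrap_supports(refs, replicates=20, seed=42).to_newick(with_support=True)
        assert a == b

    def test_leaf_order_invariance(self):
        refs, _ = self.strong_alignment(seed=10)
        shuffled = Alignment(tuple(reversed(refs.records)))
        a = bootstrap_supports(refs, replicates=10, seed=1)
        b = bootstrap_supports(shuffled, replicates=10, seed=1)
        assert a.bipartitions() == b.bipartitions()


class TestAssignTaxon:
    def test_query_equal_to_reference(self):
        panel, taxa, truth = generate_pcr_templates(classification_panel_config(21))
        refs = reference_amplicon_alignment(panel, truth, taxa, roles=("target",))
        ref0 = refs.records[0]
        query = SequenceRecord("q", ref0.sequence)
        a = assign_taxon(query, refs, taxa)
        assert a.assigned_class == taxa[ref0.id].klass
        assert a.distance == 0.0
        assert a.margin > 0

    def test_equidistant_query_flagged_ambiguous(self):
        backbone = "AAAACCCCGGGGTTTT" * 2
        # x and y each differ from the query by one A->G transition at
        # symmetric positions, so both TN93 distances are exactly equal
        q = backbone
        x = backbone[:1] + "G" + backbone[2:]
        y = backbone[:17] + "G" + backbone[18:]
        refs = Alignment((SequenceRecord("x", x), SequenceRecord("y", y)))
        taxa = TaxonMap({
            "x": TaxonEntry("P", "ClassX", "target"),
            "y": TaxonEntry("P", "ClassY", "target"),
        })
        a = assign_taxon(SequenceRecord("q", q), refs, taxa)
        assert a.ambiguous
        assert a.margin == pytest.approx(0.0, abs=1e-15)

    def test_generative_recovery_of_clone_classes(self):
        panel, taxa, truth = generate_pcr_templates(classification_panel_config(31))
        refs = reference_amplicon_alignment(panel, truth, taxa, roles=("target",))
        mixture = {"Glomeromycetes": 0.4, "Mortierellomycetes": 0.3,
                   "Endogonomycetes": 0.3}
        clones, ctruth = simulate_vesicle_clones(
            panel, taxa, truth, mixture, n_clones=60, error_rate=0.005, seed=13
        )
        hits = sum(
            assign_taxon(c, refs, taxa).assigned_class
            == ctruth[c.id].generating_class
            for c in clones
        )
        assert hits / len(clones) >= 0.95
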