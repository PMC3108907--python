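"""NJ surrogate, monophyly, RF distance, parsimony steps and CI/RI/RC."""

import itertools

import dendropy
import numpy as np
import pytest

from mitolineage import (
    Alignment,
    Partition,
    PartitionMap,
    fitch_steps,
    is_monophyletic,
    nj_tree,
    parse_newick,
    rf_distance,
    site_indices,
)
from mitolineage.diversity import DistanceMatrix
from mitolineage.trees import bipartitions, tip_labels


def _dm(labels, d):
    d = np.asarray(d, dtype=float)
    z = np.zeros_like(d)
    return DistanceMatrix(list(labels), d, "p", z, z)


def brute_force_steps(tree: dendropy.Tree, states: dict[str, str]) -> int:
    """Exhaustive minimum over all internal labelings (oracle)."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = None
    for labels in itertools.product("ACGT", repeat=len(internals)):
        assign = dict(zip(internals, labels))
        cost = 0
        ok = True
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            parent = assign[node.parent_node]
            if node.is_leaf():
                s = states[node.taxon.label].upper()
                if s in ("N", "-"):
                    continue  # free
                child = s
            else:
                child = assign[node]
            cost += parent != child
        if best is None or cost < best:
            best = cost
    return best


class TestNJ:
    def test_additive_four_taxon_recovers_topology(self):
        # additive matrix for ((a,b),(c,d)) with internal edge 3
        #   a-b: 2+2, a-c: 2+3+2 ... four-point condition holds strictly
        d = np.array(
            [
                [0, 4, 7, 7],
                [4, 0, 7, 7],
                [7, 7, 0, 4],
                [7, 7, 4, 0],
            ],
            dtype=float,
        )
        t = nj_tree(_dm(list("abcd"), d))
        assert frozenset("ab") in bipartitions(t) or frozenset("cd") in bipartitions(t)

    def test_matches_reference_nj_on_additive_matrix(self):
        """Cross-check topology against scikit-bio's NJ on a random additive matrix."""
        import skbio

        rng = np.random.default_rng(5)
        true = parse_newick("((a:1,b:2):1,((c:1,d:1):2,e:3):1,f:2);")
        pdm = true.phylogenetic_distance_matrix()
        labels = sorted(tip_labels(true))
        n = len(labels)
        taxa = {t.label: t for t in pdm.taxon_iter()}
        d = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    d[i, j] = pdm.distance(taxa[a], taxa[b])
        ours = nj_tree(_dm(labels, d))
        ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        ref_dp = parse_newick(str(ref).strip())
        assert bipartitions(ours) == bipartitions(ref_dp)
        assert bipartitions(ours) == bipartitions(true)

    def test_three_taxa_unique_topology(self):
        t = nj_tree(_dm(list("abc"), [[0, 1, 2], [1, 0, 2], [2, 2, 0]]))
        assert tip_labels(t) == {"a", "b", "c"}
        assert bipartitions(t) == set()

    def test_ultrametric_two_clades_recovered(self):
        d = np.array(
            [
                [0, 1, 5, 5, 5],
                [1, 0, 5, 5, 5],
                [5, 5, 0, 1, 1],
                [5, 5, 1, 0, 1],
                [5, 5, 1, 1, 0],
            ],
            dtype=float,
        )
        t = nj_tree(_dm(list("abcde"), d))
        assert is_monophyletic(t, {"a", "b"})
        assert is_monophyletic(t, {"c", "d", "e"})

    def test_branch_lengths_non_negative(self, study_sim):
        from mitolineage import pairwise_distances

        aln, _, _, _ = study_sim
        t = nj_tree(pairwise_distances(aln, "p"))
        for node in t.preorder_node_iter():
            if node.parent_node is not None:
                assert node.edge.length >= 0


class TestMonophyly:
    def test_clade_and_non_clade(self):
        t = parse_newick("((a,b),(c,d));")
        assert is_monophyletic(t, {"a", "b"})
        assert not is_monophyletic(t, {"a", "c"})

    def test_empty_and_full_sets_rejected(self):
        t = parse_newick("((a,b),(c,d));")
        with pytest.raises(ValueError):
            is_monophyletic(t, set())
        with pytest.raises(ValueError):
            is_monophyletic(t, {"a", "b", "c", "d"})

    def test_planted_population_clade_recovered(self, study_sim):
        aln, truth, cfg, table = study_sim
        for pop in ("S_California", "GreatLakes_MN"):
            tips = {s for s in aln.samples if s.startswith(pop)}
            assert is_monophyletic(truth.tree, tips)


class TestRF:
    def test_identical_trees_zero(self):
        t1 = parse_newick("((a,b),(c,d),(e,f));")
        t2 = parse_newick("((a,b),(c,d),(e,f));")
        assert rf_distance(t1, t2) == 0

    def test_four_tip_swap_is_two(self):
        t1 = parse_newick("((a,b),(c,d));")
        t2 = parse_newick("((a,c),(b,d));")
        assert rf_distance(t1, t2) == 2

    def test_symmetry_and_upper_bound(self):
        t1 = parse_newick("(((a,b),c),((d,e),(f,g)));")
        t2 = parse_newick("(((a,g),d),((b,e),(f,c)));")
        n = 7
        assert rf_distance(t1, t2) == rf_distance(t2, t1) <= 2 * (n - 3)

    def test_agrees_with_dendropy(self):
        from dendropy.calculate import treecompare

        tns = dendropy.TaxonNamespace()
        s1 = "(((a,b),c),((d,e),(f,g)));"
        s2 = "(((a,c),b),((d,g),(f,e)));"
        t1 = dendropy.Tree.get(data=s1, schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=s2, schema="newick", taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        expected = treecompare.symmetric_difference(t1, t2)
        assert rf_distance(parse_newick(s1), parse_newick(s2)) == expected

    def test_mismatched_tip_sets_rejected(self):
        with pytest.raises(ValueError):
            rf_distance(parse_newick("((a,b),(c,d));"), parse_newick("((a,b),(c,e));"))


class TestFitch:
    def test_forced_two_step_site(self):
        t = parse_newick("((A,B),(C,D));")
        assert fitch_steps(t, {"A": "T", "B": "A", "C": "A", "D": "T"}) == 2

    def test_monomorphic_site_zero_steps(self):
        t = parse_newick("((A,B),(C,D));")
        assert fitch_steps(t, {x: "G" for x in "ABCD"}) == 0

    def test_missing_tip_state_rejected(self):
        t = parse_newick("((A,B),(C,D));")
        with pytest.raises(ValueError):
            fitch_steps(t, {"A": "T", "B": "A", "C": "A"})

    def test_rooting_invariance(self):
        base = "((a,b),((c,d),(e,f)));"
        rerooted = "(((a,b),(c,d)),(e,f));"
        states = {"a": "A", "b": "G", "c": "A", "d": "G", "e": "G", "f": "A"}
        assert fitch_steps(parse_newick(base), states) == fitch_steps(
            parse_newick(rerooted), states
        )

    @pytest.mark.parametrize("n_tips", [4, 5, 6, 7])
    def test_equals_brute_force_minimum(self, n_tips):
        rng = np.random.default_rng(n_tips)
        for rep in range(8):
            # random binary tree by sequential attachment
            labels = [f"t{i}" for i in range(n_tips)]
            nwk = f"({labels[0]},{labels[1]})"
            for lab in labels[2:]:
                nwk = f"({nwk},{lab})" if rng.random() < 0.5 else f"({lab},{nwk})"
            tree = parse_newick(nwk + ";")
            for _ in range(5):
                states = {
                    lab: "ACGTN"[rng.integers(0, 5)] for lab in labels
                }
                tree2 = parse_newick(nwk + ";")
                assert fitch_steps(tree2, states) == brute_force_steps(tree, states)


class TestSiteIndices:
    @pytest.fixture
    def forced(self):
        """4 tips, forced topology, three site archetypes."""
        #          pos1: homoplasious binary (T,A,A,T) -> s=2, CI=0.5, RI=0
        #          pos2: singleton -> CI=RI=RC=1
        #          pos3: clean shared site -> CI=1
        aln = Alignment(
            ["A", "B", "C", "D"],
            ["TGC", "AAC", "AAA", "TAA"],
        )
        tree = parse_newick("((A,B),(C,D));")
        return aln, tree

    def test_index_conventions(self, forced):
        aln, tree = forced
        sites = {s.position: s for s in site_indices(tree, aln)}
        homopl = sites[1]
        assert (homopl.steps, homopl.ci, homopl.hi) == (2, 0.5, 0.5)
        assert homopl.ri == 0.0 and homopl.rc == 0.0  # minor count 2, s = 2
        singleton = sites[2]
        assert singleton.uninformative
        assert (singleton.ci, singleton.ri, singleton.rc) == (1, 1, 1)
        clean = sites[3]
        assert clean.ci == 1 and clean.ri == 1

    def test_retention_index_with_genome_weights(self):
        """g from genome counts: minor state in 7 genomes, s=2 -> RI = 5/6."""
        tree = parse_newick("((A,B),(C,D));")
        aln = Alignment(["A", "B", "C", "D"], ["T", "A", "A", "T"])
        weights = {"A": 5, "B": 16, "C": 17, "D": 2}  # minor T in 5+2=7 of 40
        (site,) = site_indices(tree, aln, weights=weights)
        assert site.max_steps == 7
        assert site.ri == pytest.approx((7 - 2) / (7 - 1), abs=5e-4)  # 0.833
        assert site.rc == pytest.approx(0.417, abs=5e-4)

    def test_locus_lookup(self, forced):
        aln, tree = forced
        parts = PartitionMap([Partition("dl", "dloop", 1, 2)], 3)
        sites = {s.position: s for s in site_indices(tree, aln, parts)}
        assert sites[1].locus == "dl" and sites[1].locus_position == 1
        assert sites[2].locus == "dl" and sites[2].locus_position == 2
        assert sites[3].locus == "other"

    def test_planted_hotspots_become_homoplasious_with_weight(self):
        """P(CI < 1 at a hotspot) grows toward 1 with hotspot weight."""
        from mitolineage import pairwise_distances
        from mitolineage.datasets import STUDY_HOTSPOT_COLUMNS, simulate_study

        hits = {1.0: 0, 4.0: 0}
        hot = set(STUDY_HOTSPOT_COLUMNS.values())
        for level in hits:
            for seed in range(8):
                aln, truth, cfg, _ = simulate_study(seed, hotspot_changes=level)
                tree = nj_tree(pairwise_distances(aln, "p"))
                sites = site_indices(tree, aln, cfg.partitions)
                if any(s.ci < 1 and s.position in hot for s in sites):
                    hits[level] += 1
        assert hits[4.0] >= hits[1.0]
        assert hits[4.0] >= 6  # high weight: homoplasy almost surely visible
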