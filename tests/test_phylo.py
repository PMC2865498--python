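"""Progressive alignment, Fitch parsimony, bootstrap consensus, rooting."""

import itertools

import numpy as np
import pytest

import degradomics.phylo as phylo
from degradomics._scoring import AA20
from degradomics.orthomap import pairwise_protein_score
from degradomics.phylo import (
    Alignment,
    Clade,
    Tree,
    bootstrap_resample,
    majority_consensus,
    parsimony_score,
    parsimony_search,
    progressive_align,
    root_with_outgroup,
)
from degradomics.phylo import _enumerate_topologies
from degradomics.seqforge import forge_seed_set, mutate_protein


def tree_of(newick_like):
    """Tiny builder: nested tuples of names -> Tree."""

    def build(x):
        if isinstance(x, str):
            return Clade(name=x)
        return Clade(children=[build(c) for c in x])

    return Tree(build(newick_like))


class TestProgressiveAlign:
    def test_identical_pair_is_gapless(self):
        aln = progressive_align({"a": "MKTAYW", "b": "MKTAYW"})
        assert aln.rows == ["MKTAYW", "MKTAYW"]

    def test_pairwise_case_equals_global_alignment_score(self, rng):
        a = "".join(AA20[i] for i in rng.integers(0, 20, 40))
        b = "".join(AA20[i] for i in rng.integers(0, 20, 40))
        from degradomics.phylo import _merge_profiles

        _, _, score = _merge_profiles([a], [b])
        assert int(score) == pairwise_protein_score(a, b)

    def test_substitution_only_family_aligns_without_gaps(self):
        seed = forge_seed_set([("F", "serine")], rng_seed=31)[0]
        rng = np.random.default_rng(31)
        seqs = {
            f"t{i}": mutate_protein(seed.sequence, 0.2, rng) for i in range(6)
        }
        aln = progressive_align(seqs)
        assert aln.ncol == len(seed.sequence)
        assert all("-" not in row for row in aln.rows)
        # input-order independence: same result from reversed insertion order
        aln2 = progressive_align(dict(reversed(list(seqs.items()))))
        assert dict(zip(aln.ids, aln.rows)) == dict(zip(aln2.ids, aln2.rows))

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            progressive_align({"a": "MKT"})


class TestBootstrap:
    def test_replicates_preserve_shape(self):
        aln = Alignment(["a", "b"], ["MKTAY", "MKTAW"])
        reps = bootstrap_resample(aln, 100, rng_seed=1)
        assert len(reps) == 100
        assert all(r.ncol == 5 and r.ids == ["a", "b"] for r in reps)

    def test_single_column_replicates_identical(self):
        aln = Alignment(["a", "b"], ["M", "K"])
        for rep in bootstrap_resample(aln, 10, rng_seed=2):
            assert rep.rows == ["M", "K"]

    def test_seeded_determinism(self):
        aln = Alignment(["a", "b", "c"], ["MKTAY", "MKTAW", "MATAW"])
        r1 = bootstrap_resample(aln, 20, rng_seed=7)
        r2 = bootstrap_resample(aln, 20, rng_seed=7)
        assert [r.rows for r in r1] == [r.rows for r in r2]

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_resample(Alignment([], []), 10, 1)


class TestParsimonyScore:
    def test_identical_rows_cost_zero(self):
        aln = Alignment(list("abcd"), ["MKT"] * 4)
        t = tree_of((("a", "b"), ("c", "d")))
        assert parsimony_score(t, aln) == 0

    def test_single_informative_column_costs_one(self):
        aln = Alignment(list("abcd"), ["L", "L", "V", "V"])
        t = tree_of((("a", "b"), ("c", "d")))
        assert parsimony_score(t, aln) == 1

    def test_gap_is_missing_data(self):
        aln = Alignment(list("abcd"), ["L", "-", "V", "V"])
        t = tree_of((("a", "b"), ("c", "d")))
        assert parsimony_score(t, aln) == 1

    def test_leaf_mismatch_rejected(self):
        aln = Alignment(list("abc"), ["M", "K", "T"])
        with pytest.raises(ValueError):
            parsimony_score(tree_of((("a", "b"), ("c", "d"))), aln)

    def test_invariant_under_rerooting_and_leaf_order(self, rng):
        taxa = list("abcde")
        rows = ["".join(AA20[i] for i in rng.integers(0, 5, 30)) for _ in taxa]
        aln = Alignment(taxa, rows)
        shapes = [
            ((("a", "b"), "c"), ("d", "e")),
            (("d", "e"), ("c", ("a", "b"))),
            ((("b", "a"), "c"), ("e", "d")),
        ]
        scores = {parsimony_score(tree_of(s), aln) for s in shapes}
        assert len(scores) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_internal_state_brute_force(self, seed):
        # 5 taxa, random alignments; enumerate all internal labelings
        rng = np.random.default_rng(seed)
        taxa = list("abcde")
        ncol = 12
        rows = ["".join(AA20[i] for i in rng.integers(0, 4, ncol)) for _ in taxa]
        aln = Alignment(taxa, rows)
        shape = ((("a", "b"), "c"), ("d", "e"))
        t = tree_of(shape)
        # rooted version has internal nodes: root, (ab)c node, ab node, de node
        def brute_column(col):
            states = sorted(set(col))
            leaf = dict(zip(taxa, col))
            best = None
            # internal nodes: n1=(a,b), n2=(n1,c), de=(d,e), root=(n2,de)
            for assign in itertools.product(states, repeat=4):
                n1, n2, nde, root = assign
                cost = (
                    (leaf["a"] != n1) + (leaf["b"] != n1) + (n1 != n2)
                    + (leaf["c"] != n2) + (leaf["d"] != nde) + (leaf["e"] != nde)
                    + (n2 != root) + (nde != root)
                )
                best = cost if best is None else min(best, cost)
            return best

        expected = sum(
            brute_column([r[j] for r in rows]) for j in range(ncol)
        )
        assert parsimony_score(t, aln) == expected


class TestParsimonySearch:
    def test_topology_counts(self):
        assert len(list(_enumerate_topologies(list("abcd")))) == 3
        assert len(list(_enumerate_topologies(list("abcdef")))) == 105

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            parsimony_search(Alignment(["a", "b"], ["M", "K"]))

    def test_exhaustive_result_is_global_minimum(self, rng):
        taxa = list("abcdef")
        rows = ["".join(AA20[i] for i in rng.integers(0, 4, 20)) for _ in taxa]
        aln = Alignment(taxa, rows)
        found = parsimony_search(aln)
        best = parsimony_score(found[0], aln)
        all_scores = [
            phylo._fitch_from_masks(adj, phylo._leaf_masks(aln))
            for adj in _enumerate_topologies(taxa)
        ]
        assert best == min(all_scores)
        assert len(found) == all_scores.count(best)
        for t in found:
            assert parsimony_score(t, aln) == best

    def test_heuristic_matches_exhaustive_on_forged_families(self, monkeypatch):
        # force the stepwise+NNI path on 7-taxon forged families and
        # compare with the exhaustive minimum
        agree = 0
        trials = 25
        for rep in range(trials):
            rng = np.random.default_rng(700 + rep)
            seed = forge_seed_set([("F", "serine")], rng_seed=rep)[0]
            anc1 = mutate_protein(seed.sequence, 0.1, rng)
            anc2 = mutate_protein(seed.sequence, 0.1, rng)
            seqs = {
                "a1": mutate_protein(anc1, 0.07, rng),
                "a2": mutate_protein(anc1, 0.07, rng),
                "b1": mutate_protein(anc2, 0.07, rng),
                "b2": mutate_protein(anc2, 0.07, rng),
                "c": mutate_protein(seed.sequence, 0.15, rng),
                "d": mutate_protein(seed.sequence, 0.15, rng),
                "e": mutate_protein(seed.sequence, 0.15, rng),
            }
            aln = progressive_align(seqs)
            exact = parsimony_score(parsimony_search(aln)[0], aln)
            monkeypatch.setattr(phylo, "EXHAUSTIVE_MAX_TAXA", 4)
            heur = parsimony_score(parsimony_search(aln)[0], aln)
            monkeypatch.setattr(phylo, "EXHAUSTIVE_MAX_TAXA", 8)
            agree += heur == exact
        assert agree >= 0.95 * trials

    def test_clean_signal_recovers_true_topology(self):
        seed = forge_seed_set([("F", "serine")], rng_seed=41)[0]
        rng = np.random.default_rng(41)
        anc_ab = mutate_protein(seed.sequence, 0.15, rng)
        seqs = {
            "a": mutate_protein(anc_ab, 0.08, rng),
            "b": mutate_protein(anc_ab, 0.08, rng),
            "c": mutate_protein(seed.sequence, 0.2, rng),
            "d": mutate_protein(seed.sequence, 0.2, rng),
        }
        aln = progressive_align(seqs)
        best = parsimony_search(aln)
        assert len(best) == 1
        # the a+b sister pair, canonicalized as the side excluding taxon 'a'
        assert frozenset({"c", "d"}) in best[0].bipartitions()


class TestConsensus:
    def _rep_trees(self, n_ab, n_ac, taxa=("a", "b", "c", "d")):
        ab = tree_of((("a", "b"), ("c", "d")))
        ac = tree_of((("a", "c"), ("b", "d")))
        return [ab] * n_ab + [ac] * n_ac

    def test_51_of_100_retained_with_count(self):
        t = majority_consensus(self._rep_trees(51, 49), threshold=50)
        bps = t.bipartitions()
        assert bps.get(frozenset({"c", "d"})) == pytest.approx(51)

    def test_50_of_100_collapsed(self):
        t = majority_consensus(self._rep_trees(50, 50), threshold=50)
        assert t.bipartitions() == {}

    def test_unanimity_fully_resolved(self):
        t = majority_consensus(self._rep_trees(100, 0), threshold=50)
        bps = t.bipartitions()
        assert len(bps) == 1  # 4 taxa: a single internal edge
        assert list(bps.values())[0] == pytest.approx(100)

    def test_tied_minimal_trees_weighted_fractionally(self):
        ab = tree_of((("a", "b"), ("c", "d")))
        ac = tree_of((("a", "c"), ("b", "d")))
        # four replicates tie between two trees (half weight each),
        # six are resolved: support = 4 * 0.5 + 6 = 8
        reps = [[ab, ac]] * 4 + [[ab]] * 6
        t = majority_consensus(reps, threshold=5)
        bps = t.bipartitions()
        assert bps.get(frozenset({"c", "d"})) == pytest.approx(8.0)

    def test_threshold_antimonotone(self):
        trees = self._rep_trees(70, 30)
        lo = majority_consensus(trees, threshold=50).bipartitions()
        hi = majority_consensus(trees, threshold=75).bipartitions()
        assert set(hi) <= set(lo)

    def test_inconsistent_leaf_sets_rejected(self):
        with pytest.raises(ValueError):
            majority_consensus(
                [tree_of((("a", "b"), ("c", "d"))), tree_of((("a", "b"), ("c", "e")))],
                threshold=0,
            )


class TestRooting:
    def test_single_taxon_outgroup(self):
        t = majority_consensus([tree_of((("a", "b"), ("c", "d")))] * 3, threshold=2)
        rooted = root_with_outgroup(t, ["d"])
        assert rooted.rooted
        assert len(rooted.root.children) == 2
        sides = [frozenset(c.leaves()) for c in rooted.root.children]
        assert frozenset({"d"}) in sides

    def test_outgroup_clade(self):
        t = tree_of((("a", "b"), ("c", "d")))
        rooted = root_with_outgroup(t, ["c", "d"])
        sides = [frozenset(c.leaves()) for c in rooted.root.children]
        assert frozenset({"c", "d"}) in sides and frozenset({"a", "b"}) in sides

    def test_complement_of_one_taxon(self):
        t = tree_of((("a", "b"), ("c", "d")))
        rooted = root_with_outgroup(t, ["a", "b", "c"])
        sides = [frozenset(c.leaves()) for c in rooted.root.children]
        assert frozenset({"d"}) in sides

    def test_non_monophyletic_outgroup_diagnosed(self):
        t = tree_of((("a", "b"), ("c", "d")))
        with pytest.raises(ValueError, match="not monophyletic"):
            root_with_outgroup(t, ["a", "c"])

    def test_supports_preserved_through_rooting(self):
        t = majority_consensus([tree_of((("a", "b"), ("c", "d")))] * 10, threshold=5)
        rooted = root_with_outgroup(t, ["a", "b"])
        supports = [
            c.support for c in rooted.root.children if c.support is not None
        ]
        assert supports and all(s == pytest.approx(10) for s in supports)


class TestNewickOutput:
    def test_dendropy_parses_and_leafset_matches(self, tmp_path):
        import dendropy

        t = majority_consensus([tree_of((("a", "b"), ("c", "d")))] * 100, threshold=50)
        nwk = t.to_newick()
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert {x.taxon.label for x in parsed.leaf_node_iter()} == {"a", "b", "c", "d"}
        assert "100" in nwk  # the support label survives

    def test_phylip_and_fasta_round_trip(self, tmp_path):
        aln = Alignment(["t1", "t2"], ["MKTA-", "MKTAW"])
        aln.to_fasta(tmp_path / "a.fasta")
        from degradomics.phylo import read_fasta_alignment

        back = read_fasta_alignment(tmp_path / "a.fasta")
        assert back.ids == aln.ids and back.rows == aln.rows
        aln.to_phylip(tmp_path / "a.phy")
        body = (tmp_path / "a.phy").read_text().splitlines()
        assert body[0].split() == ["2", "5"]
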