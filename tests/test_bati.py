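"""Locus clustering, exon chaining, splice tuning, and the iterate loop."""

import itertools

import numpy as np
import pytest

from degradomics._scoring import AA20, pair_score
from degradomics.bati import (
    BatiConfig,
    Locus,
    bati_iterate,
    bgmix_report,
    chain_hsps,
    cluster_hsps,
    read_models_gff3,
    tune_boundaries,
    write_models_gff3,
    write_proteins_fasta,
)
from degradomics.seqforge import (
    CopyPlan,
    ForgeConfig,
    SeedProtein,
    forge_genome,
    forge_seed_set,
    mutate_protein,
)
from degradomics.transearch import HSP, SearchConfig, search


def make_hsp(qspan, gspan, residues=None, contig="c1", strand="+", score=None):
    """Ungapped synthetic HSP whose alignment columns are explicit."""
    n = qspan[1] - qspan[0]
    assert gspan[1] - gspan[0] == 3 * n
    rng = np.random.default_rng(qspan[0] * 1000 + gspan[0])
    if residues is None:
        residues = "".join(AA20[i] for i in rng.integers(0, 20, n))
    sc = sum(pair_score(c, c) for c in residues)
    return HSP(
        query_id="q",
        contig_id=contig,
        contig_length=1_000_000,
        strand=strand,
        frame=0,
        query_span=tuple(qspan),
        genome_span=tuple(gspan),
        score=score if score is not None else sc,
        evalue=1e-10,
        query_aln=residues,
        subject_aln=residues,
    )


class TestClusterHsps:
    def test_close_hsps_share_a_locus(self):
        hs = [make_hsp((0, 30), (0, 90)), make_hsp((40, 70), (1090, 1180))]
        assert len(cluster_hsps(hs, max_intron=5000)) == 1

    def test_distant_hsps_split(self):
        hs = [make_hsp((0, 30), (0, 90)), make_hsp((40, 70), (10_090, 10_180))]
        assert len(cluster_hsps(hs, max_intron=5000)) == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_partition_matches_connected_components(self, seed):
        rng = np.random.default_rng(seed)
        hs = []
        for _ in range(12):
            start = int(rng.integers(0, 60_000))
            n = int(rng.integers(5, 20))
            hs.append(make_hsp((0, n), (start, start + 3 * n)))
        max_intron = 3000
        loci = cluster_hsps(hs, max_intron)
        # brute force: connected components on the pairwise gap graph
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(len(hs)))
        for i, j in itertools.combinations(range(len(hs)), 2):
            (s1, e1), (s2, e2) = hs[i].genome_span, hs[j].genome_span
            gap = max(s1, s2) - min(e1, e2)
            if gap <= max_intron:
                g.add_edge(i, j)
        expected = {
            frozenset((hs[i].genome_span for i in comp))
            for comp in nx.connected_components(g)
        }
        got = {frozenset(h.genome_span for h in l.members) for l in loci}
        assert got == expected

    def test_every_hsp_assigned_once(self):
        rng = np.random.default_rng(3)
        hs = [
            make_hsp((0, 10), (int(s), int(s) + 30))
            for s in rng.integers(0, 100_000, 20)
        ]
        loci = cluster_hsps(hs, 2000)
        assert sum(len(l.members) for l in loci) == len(hs)


def locus_of(hsps, strand="+"):
    return Locus(
        contig_id="c1",
        contig_length=1_000_000,
        strand=strand,
        extent=(
            min(h.genome_span[0] for h in hsps),
            max(h.genome_span[1] for h in hsps),
        ),
        members=list(hsps),
    )


def oracle_best_chain(hsps):
    """Exhaustive subset enumeration mirroring the chain rules.

    Every subset is ordered by genome start and checked for colinearity
    (strictly increasing query spans, no genome overlap); query overlaps
    between consecutive members are resolved by searching all valid
    trim splits, with the constraint that a member's two trims leave at
    least one residue.  Columns are ungapped in these fixtures, so trim
    costs are simple column sums.
    """

    def col_sum(h, a, b):
        return sum(
            pair_score(x, y) for x, y in zip(h.query_aln[a:b], h.subject_aln[a:b])
        )

    best = 0
    for r in range(1, len(hsps) + 1):
        for subset in itertools.combinations(range(len(hsps)), r):
            chain = sorted((hsps[i] for i in subset), key=lambda h: h.genome_span)
            ok = True
            for a, b in zip(chain, chain[1:]):
                if (
                    b.query_span[0] <= a.query_span[0]
                    or b.query_span[1] <= a.query_span[1]
                    or b.genome_span[0] < a.genome_span[1]
                ):
                    ok = False
                    break
            if not ok:
                continue
            lens = [h.query_span[1] - h.query_span[0] for h in chain]
            overlaps = [
                max(0, a.query_span[1] - b.query_span[0])
                for a, b in zip(chain, chain[1:])
            ]
            memo = {}

            def tail(k, left):
                if (k, left) in memo:
                    return memo[(k, left)]
                if k == len(chain) - 1:
                    out = col_sum(chain[k], left, lens[k])
                else:
                    o = overlaps[k]
                    out = None
                    lo = max(0, o - (lens[k + 1] - 1))
                    hi = min(o, lens[k] - 1 - left)
                    for o1 in range(lo, hi + 1):
                        rest = tail(k + 1, o - o1)
                        if rest is None:
                            continue
                        val = col_sum(chain[k], left, lens[k] - o1) + rest
                        out = val if out is None else max(out, val)
                memo[(k, left)] = out
                return out

            total = tail(0, 0)
            if total is not None:
                best = max(best, total)
    return best


class TestChainHsps:
    def test_single_hsp_single_exon(self):
        h = make_hsp((0, 30), (100, 190))
        model = chain_hsps(locus_of([h]))
        assert model.exons == [(100, 190)]
        assert model.chain_score == h.score
        assert model.status == "intact"

    def test_colinear_pair_chains_to_two_exons(self):
        a = make_hsp((0, 40), (0, 120))
        b = make_hsp((45, 90), (1000, 1135))
        model = chain_hsps(locus_of([a, b]))
        assert model.exons == [(0, 120), (1000, 1135)]
        assert model.chain_score == a.score + b.score

    def test_empty_locus_rejected(self):
        empty = Locus("c1", 1000, "+", (0, 0), [])
        with pytest.raises(ValueError):
            chain_hsps(empty)

    @pytest.mark.parametrize("seed", range(10))
    def test_dp_matches_exhaustive_subset_oracle(self, seed):
        rng = np.random.default_rng(seed)
        hsps = []
        n = int(rng.integers(3, 9))
        for _ in range(n):
            q0 = int(rng.integers(0, 60))
            qlen = int(rng.integers(5, 30))
            g0 = int(rng.integers(0, 4000))
            hsps.append(make_hsp((q0, q0 + qlen), (g0, g0 + 3 * qlen)))
        model = chain_hsps(locus_of(hsps))
        assert model.chain_score == oracle_best_chain(hsps)

    def test_chain_score_is_sum_minus_penalties(self):
        a = make_hsp((0, 40), (0, 120))
        b = make_hsp((30, 80), (600, 750))  # 10-residue query overlap
        model = chain_hsps(locus_of([a, b]))
        assert len(model.exons) == 2
        assert model.chain_score <= a.score + b.score
        # penalty equals what the trimmed columns were worth
        assert model.chain_score == oracle_best_chain([a, b])


@pytest.fixture(scope="module")
def forged_gene():
    seeds = forge_seed_set([("FAMT", "serine")], rng_seed=51)
    cfg = ForgeConfig(
        species=["sp1"], plan={"sp1": [CopyPlan("FAMT", 1)]},
        divergence=0.0, rng_seed=51,
    )
    genomes, truth = forge_genome(seeds, cfg)
    models = bati_iterate(seeds, genomes, BatiConfig(tune_window=0))
    model = [m for m in models if len(m.exons) >= 2][0]
    return genomes[0], truth[0], model, seeds[0]


class TestTuneBoundaries:
    def test_true_boundaries_are_a_fixed_point(self, forged_gene):
        genome, truth, model, seed = forged_gene
        assert model.exons == truth.exons
        tuned = tune_boundaries(model, genome, window=12, query=seed.sequence)
        assert tuned.exons == model.exons

    def test_displaced_boundaries_recovered(self, forged_gene):
        genome, truth, model, seed = forged_gene
        assert model.exons == truth.exons
        # displace one junction by 2+2 nt and ask the tuner to restore it
        exons = list(model.exons)
        s0, e0 = exons[0]
        s1, e1 = exons[1]
        if model.strand == "+":
            exons[0] = (s0, e0 + 2)
            exons[1] = (s1 + 2, e1)
        else:
            exons[0] = (s0 - 2, e0)
            exons[1] = (s1, e1 - 2)
        model2 = type(model)(**{**model.__dict__, "exons": exons})
        tuned = tune_boundaries(model2, genome, window=12, query=seed.sequence)
        assert tuned.exons == truth.exons
        assert tuned.protein == truth.protein

    def test_window_zero_is_identity(self, forged_gene):
        genome, _, model, seed = forged_gene
        assert tune_boundaries(model, genome, window=0) is model


class TestBatiIterate:
    def test_no_homologs_means_no_models(self):
        rng = np.random.default_rng(77)
        seeds = forge_seed_set([("FAMX", "serine")], rng_seed=77)
        bg = "".join("ACGT"[i] for i in rng.integers(0, 4, 50_000))
        from degradomics.transearch import GenomeSequence

        models = bati_iterate(seeds, [GenomeSequence("bg", "sp", bg)], BatiConfig())
        assert models == []

    def test_max_iterations_validated(self, two_family_seeds, small_forge):
        genomes, _ = small_forge
        with pytest.raises(ValueError):
            bati_iterate(two_family_seeds, genomes, BatiConfig(max_iterations=0))

    def test_divergence_ladder_found_across_iterations(self):
        # gene A is detectable from the seed; gene A' only from A's
        # prediction — the iterate loop must pick it up in round 2
        rng = np.random.default_rng(8)
        base = forge_seed_set([("FAML", "serine")], rng_seed=8, length_range=(60, 60))[0]
        prot_a = mutate_protein(base.sequence, 0.50, rng, protected=base.catalytic_positions)
        prot_a2 = mutate_protein(prot_a, 0.50, rng, protected=base.catalytic_positions)
        implant_seeds = [
            SeedProtein("A", "A", "serine", base.catalytic_positions, prot_a),
            SeedProtein("A2", "A2", "serine", base.catalytic_positions, prot_a2),
        ]
        cfg = ForgeConfig(
            species=["sp1"],
            plan={"sp1": [CopyPlan("A", 1), CopyPlan("A2", 1)]},
            divergence=0.0,
            n_exons=1,
            rng_seed=8,
        )
        genomes, truth = forge_genome(implant_seeds, cfg)
        # precondition: the seed set alone sees A but not A'
        direct = search([base], genomes, SearchConfig())
        spans = {t.family: (min(s for s, _ in t.exons), max(e for _, e in t.exons)) for t in truth}
        hits_a = [h for h in direct if spans["A"][0] < h.genome_span[1] and h.genome_span[0] < spans["A"][1]]
        hits_a2 = [h for h in direct if spans["A2"][0] < h.genome_span[1] and h.genome_span[0] < spans["A2"][1]]
        assert hits_a and not hits_a2
        models = bati_iterate([base], genomes, BatiConfig())
        iters = {}
        for m in models:
            for fam, (lo, hi) in spans.items():
                if m.extent[0] < hi and lo < m.extent[1]:
                    iters[fam] = m.iteration_found
        assert iters == {"A": 1, "A2": 2}

    def test_zero_divergence_truth_recovery(self, two_family_seeds, small_forge):
        genomes, truth = small_forge
        models = bati_iterate(two_family_seeds, genomes, BatiConfig())
        assert sorted(m.protein for m in models) == sorted(t.protein for t in truth)
        fams = sorted(m.family for m in models)
        assert fams == sorted(t.family for t in truth)


class TestBgmixReport:
    def test_position_sorted_across_queries(self):
        hs = [
            make_hsp((0, 10), (5000, 5030)),
            make_hsp((0, 10), (100, 130)),
            make_hsp((0, 10), (100, 130), score=999),
        ]
        df = bgmix_report(hs)
        assert list(df["start"]) == [100, 100, 5000]
        assert df.iloc[0]["score"] == 999  # descending score at equal position

    def test_empty_input_keeps_header(self):
        df = bgmix_report([])
        assert len(df) == 0
        assert "modelled" in df.columns

    def test_unmodelled_family_flagged(self, two_family_seeds, small_forge):
        genomes, _ = small_forge
        hsps = search(two_family_seeds, genomes, SearchConfig())
        models = bati_iterate(two_family_seeds, genomes, BatiConfig())
        only_fama = [m for m in models if m.family == "FAMA"]
        df = bgmix_report(hsps, only_fama)
        famb = df[df["query"] == "FAMB_seed"]
        assert len(famb) and not famb["modelled"].any()
        fama = df[df["query"] == "FAMA_seed"]
        assert fama["modelled"].all()


def test_models_gff3_round_trip(two_family_seeds, small_forge, tmp_path):
    genomes, _ = small_forge
    models = bati_iterate(two_family_seeds, genomes, BatiConfig())
    write_models_gff3(models, tmp_path / "m.gff3")
    write_proteins_fasta(models, tmp_path / "m.fasta")
    back = read_models_gff3(tmp_path / "m.gff3", tmp_path / "m.fasta")
    assert {m.locus_id for m in back} == {m.locus_id for m in models}
    by_id = {m.locus_id: m for m in back}
    for m in models:
        assert by_id[m.locus_id].exons == m.exons
        assert by_id[m.locus_id].protein == m.protein
        assert by_id[m.locus_id].status == m.status
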