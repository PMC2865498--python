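"""Annotate-Tune-Iterate: from HSPs to gene models.

HSPs are clustered into loci by single-linkage on genomic gaps, chained
into exon structures by a maximum-score colinear dynamic program, exon
boundaries are nudged onto GT...AG splice signals, and intact predictions
re-enter the query set until no new locus appears.  A composite
position-sorted hit table (the review surface for missed genes) is also
produced.

All genomic spans are 0-based half-open forward-strand; a model's exon
list is kept in coding (5'->3') order, so minus-strand exons descend in
forward coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

from ._scoring import GAP_CHAR, score_alignment
from .seqforge import SeedProtein, splice_and_translate
from .transearch import HSP, GenomeSequence, Query, SearchConfig, search



@dataclass
class Locus:
    contig_id: str
    contig_length: int
    strand: str
    extent: tuple[int, int]
    members: list[HSP]


@dataclass
class GeneModel:
    locus_id: str
    contig_id: str
    contig_length: int
    strand: str
    exons: list[tuple[int, int]]  # coding order, forward-strand coords
    protein: str
    family: str
    supporting: list[str]  # HSP uids
    chain_score: int
    status: str  # intact | non_peptidase_homolog | pseudogene_fragment
    iteration_found: int = 1
    query_id: str = ""
    # kept query span per exon (chain bookkeeping used by the tuner)
    exon_query_spans: list[tuple[int, int]] | None = None

    @property
    def extent(self) -> tuple[int, int]:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))


@dataclass
class BatiConfig:
    search: SearchConfig = field(default_factory=SearchConfig)
    max_intron: int = 5000
    tune_window: int = 30
    max_iterations: int = 10
    dedup_overlap: float = 0.5


# ---------------------------------------------------------------------------
# clustering


def cluster_hsps(hsps: Sequence[HSP], max_intron: int = 5000) -> list[Locus]:
    """Single-linkage clusters of same-contig, same-strand HSPs.

    Two HSPs join a locus when the genomic gap between them is at most
    ``max_intron`` (overlapping HSPs always join).  Every input HSP is
    assigned to exactly one locus; loci come back ordered by (contig,
    start).
    """
    groups: dict[tuple[str, str], list[HSP]] = {}
    for h in hsps:
        groups.setdefault((h.contig_id, h.strand), []).append(h)
    loci: list[Locus] = []
    for (contig, strand), members in groups.items():
        members.sort(key=lambda h: (h.genome_span, h.query_id))
        current: list[HSP] = []
        reach = None
        for h in members:
            s, e = h.genome_span
            if current and s - reach > max_intron:
                loci.append(_make_locus(contig, strand, current))
                current = []
                reach = None
            current.append(h)
            reach = e if reach is None else max(reach, e)
        if current:
            loci.append(_make_locus(contig, strand, current))
    loci.sort(key=lambda l: (l.contig_id, l.extent, l.strand))
    return loci


def _make_locus(contig: str, strand: str, members: list[HSP]) -> Locus:
    return Locus(
        contig_id=contig,
        contig_length=members[0].contig_length,
        strand=strand,
        extent=(
            min(h.genome_span[0] for h in members),
            max(h.genome_span[1] for h in members),
        ),
        members=list(members),
    )


# ---------------------------------------------------------------------------
# chaining


def _coding_span(h: HSP) -> tuple[int, int]:
    s, e = h.genome_span
    if h.strand == "+":
        return s, e
    return h.contig_length - e, h.contig_length - s


def _trim_alignment(h: HSP, left_q: int, right_q: int):
    """Drop columns consuming ``left_q``/``right_q`` query residues per end.

    Boundary gap columns are stripped too, so the remainder re-scores
    cleanly.  Returns (qaln, saln, s_left, s_right, score) where s_left /
    s_right count subject residues removed at each end.
    """
    qa, sa = h.query_aln, h.subject_aln
    lo, hi = 0, len(qa)
    s_left = s_right = 0
    need = left_q
    while lo < hi and (need > 0 or qa[lo] == GAP_CHAR or sa[lo] == GAP_CHAR):
        if qa[lo] != GAP_CHAR:
            if need == 0:
                break
            need -= 1
        if sa[lo] != GAP_CHAR:
            s_left += 1
        lo += 1
    need = right_q
    while hi > lo and (need > 0 or qa[hi - 1] == GAP_CHAR or sa[hi - 1] == GAP_CHAR):
        if qa[hi - 1] != GAP_CHAR:
            if need == 0:
                break
            need -= 1
        if sa[hi - 1] != GAP_CHAR:
            s_right += 1
        hi -= 1
    if lo >= hi:
        return "", "", s_left, s_right, 0
    q_out, s_out = qa[lo:hi], sa[lo:hi]
    return q_out, s_out, s_left, s_right, score_alignment(q_out, s_out)


def chain_hsps(
    locus: Locus,
    family_of: Mapping[str, str] | None = None,
) -> GeneModel:
    """Best colinear chain of HSPs in a locus, as a gene model.

    The chain must be strictly increasing in both query and (coding-strand)
    genome coordinates, with genome overlaps forbidden.  Where consecutive
    HSPs overlap on the query — extensions routinely overshoot exon
    boundaries into intron sequence — the overlap is resolved by the
    optimal split: trim the upstream HSP's right and the downstream HSP's
    left so that together they cover the overlap, maximizing retained
    score.  The trimmed columns' score is the chain penalty, so the chain
    score equals the sum of member scores minus penalties.  Chains are
    built per query and the best-scoring one wins (ties break
    lexicographically on query id).
    """
    if not locus.members:
        raise ValueError("empty locus")
    best = None
    for qid in sorted({h.query_id for h in locus.members}):
        cand = _chain_for_query([h for h in locus.members if h.query_id == qid])
        if cand is None:
            continue
        score, chain, cuts = cand
        if best is None or score > best[0]:
            best = (score, chain, cuts, qid)
    assert best is not None
    _, chain, cuts, qid = best
    exons: list[tuple[int, int]] = []
    exon_qspans: list[tuple[int, int]] = []
    protein_parts: list[str] = []
    supporting = []
    chain_score = 0
    L = locus.contig_length
    for h, (left_q, right_q) in zip(chain, cuts):
        qaln, saln, s_left, s_right, sc = _trim_alignment(h, left_q, right_q)
        if not qaln:
            continue
        cs, ce = _coding_span(h)
        cs += 3 * s_left
        ce -= 3 * s_right
        if locus.strand == "+":
            exons.append((cs, ce))
        else:
            exons.append((L - ce, L - cs))
        exon_qspans.append((h.query_span[0] + left_q, h.query_span[1] - right_q))
        protein_parts.append(saln.replace(GAP_CHAR, ""))
        supporting.append(h.uid)
        chain_score += sc
    protein = "".join(protein_parts)
    status = "pseudogene_fragment" if "*" in protein else "intact"
    family = family_of.get(qid, qid) if family_of else qid
    g0 = min(s for s, _ in exons)
    g1 = max(e for _, e in exons)
    return GeneModel(
        locus_id=f"{locus.contig_id}:{g0}-{g1}({locus.strand})",
        contig_id=locus.contig_id,
        contig_length=L,
        strand=locus.strand,
        exons=exons,
        protein=protein,
        family=family,
        supporting=supporting,
        chain_score=chain_score,
        status=status,
        query_id=qid,
        exon_query_spans=exon_qspans,
    )


def _chain_for_query(members: list[HSP]):
    """Max-score colinear chain DP over one query's HSPs.

    DP state is (member, left-trim applied by the incoming edge), so a
    middle member can never be trimmed past its length by its two
    neighbouring junction splits.  Returns (score, chain, cuts) with
    per-member (left_trim, right_trim) query-residue counts.
    """
    hs = sorted(members, key=lambda h: (_coding_span(h), h.query_span))
    n = len(hs)
    qlen = [h.query_span[1] - h.query_span[0] for h in hs]
    prefix: list[dict[int, int]] = [dict() for _ in range(n)]
    suffix_cost: list[dict[int, int]] = [dict() for _ in range(n)]

    def prefix_score(j: int, o: int) -> int:
        # member j's score after trimming o query residues from its left
        if o not in prefix[j]:
            prefix[j][o] = _trim_alignment(hs[j], o, 0)[4]
        return prefix[j][o]

    def sfx(i: int, o: int) -> int:
        # cost of trimming o query residues off member i's right
        if o not in suffix_cost[i]:
            suffix_cost[i][o] = hs[i].score - _trim_alignment(hs[i], 0, o)[4]
        return suffix_cost[i][o]

    # dp[j][l]: best chain score ending at j with left-trim l, j's right intact
    dp: list[dict[int, int]] = [{0: h.score} for h in hs]
    back: list[dict[int, tuple[int, int, int] | None]] = [{0: None} for _ in hs]
    for j in range(n):
        qj0, qj1 = hs[j].query_span
        cj0, _ = _coding_span(hs[j])
        for i in range(j):
            qi0, qi1 = hs[i].query_span
            _, ci1 = _coding_span(hs[i])
            if qj0 <= qi0 or qj1 <= qi1 or cj0 < ci1:
                continue
            o = max(0, qi1 - qj0)
            for l_i, val_i in list(dp[i].items()):
                avail = qlen[i] - 1 - l_i  # right trim must leave >= 1 residue
                lo = max(0, o - (qlen[j] - 1))
                if lo > min(o, avail):
                    continue
                for o1 in range(lo, min(o, avail) + 1):
                    o2 = o - o1
                    val = val_i - sfx(i, o1) + prefix_score(j, o2)
                    if val > dp[j].get(o2, _NEG_SCORE):
                        dp[j][o2] = val
                        back[j][o2] = (i, l_i, o1)
    best_j, best_l = max(
        ((j, l) for j in range(n) for l in dp[j]),
        key=lambda jl: (dp[jl[0]][jl[1]], -jl[0], -jl[1]),
    )
    score = dp[best_j][best_l]
    # walk back collecting members and their (left, right) trims
    rev: list[tuple[int, int, int]] = []  # (index, left_trim, right_trim)
    j, l, right = best_j, best_l, 0
    while True:
        rev.append((j, l, right))
        prev = back[j][l]
        if prev is None:
            break
        j, l, right = prev
    rev.reverse()
    chain = [hs[idx] for idx, _, _ in rev]
    cuts = [(left, right) for _, left, right in rev]
    return score, chain, cuts


_NEG_SCORE = -(10**9)


# ---------------------------------------------------------------------------
# boundary tuning


def _seam_score(cseq, spans, q_first, idx, d1, d2, query):
    """Evaluate one candidate junction shift.

    Translates the codons around the shifted seam; when the chain's query
    protein is available, the seam translation is scored residue-by-residue
    against the query positions it should encode.  Chain trims keep query
    coverage contiguous, so the seam's query offset follows from the
    cumulative coding length.  Returns (has_stop, score-or-None).
    """
    from ._scoring import pair_score
    from .transearch import translate_nt

    s_i, e_i = spans[idx]
    s_j, e_j = spans[idx + 1]
    before = sum(e - s for s, e in spans[: idx + 1]) + d1  # coding nt upstream
    w_up = min((e_i + d1) - s_i, 18)
    w_up -= (w_up - before) % 3  # start the window on a codon boundary
    w_dn = min(e_j - (s_j + d2), 18)
    local = cseq[e_i + d1 - w_up : e_i + d1] + cseq[s_j + d2 : s_j + d2 + w_dn]
    aa = translate_nt(local)
    has_stop = "*" in aa
    score = None
    if query is not None and q_first is not None:
        q0 = q_first + (before - w_up) // 3
        qseg = query[max(0, q0) : max(0, q0) + len(aa)]
        score = sum(pair_score(a, b) for a, b in zip(aa, qseg))
    return has_stop, score


def tune_boundaries(
    model: GeneModel,
    genome: GenomeSequence,
    window: int = 30,
    query: str | None = None,
) -> GeneModel:
    """Nudge internal exon boundaries onto GT...AG splice signals.

    Each junction's donor/acceptor pair may shift by at most ``window`` nt
    and the two shifts must agree mod 3 (reading frame preserved).  When
    the chain's query protein is supplied the candidate whose seam
    translation best matches the query wins (curation against the protein
    evidence); otherwise stop-free candidates are preferred and the
    nearest valid pair (by total displacement) wins.  Junctions already on
    GT...AG are fixed points; junctions with no valid pair are unchanged.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if len(model.exons) < 2 or window == 0:
        return model
    L = model.contig_length
    cseq = (
        genome.residues
        if model.strand == "+"
        else reverse_complement(genome.residues)
    )
    # coding-space spans, ascending
    if model.strand == "+":
        spans = list(model.exons)
    else:
        spans = [(L - e, L - s) for s, e in model.exons]
    q_first = (
        model.exon_query_spans[0][0] if model.exon_query_spans else None
    )
    for idx in range(len(spans) - 1):
        s_i, e_i = spans[idx]
        s_j, e_j = spans[idx + 1]
        best = None
        for d1 in range(-window, window + 1):
            don = e_i + d1
            if don <= s_i or cseq[don : don + 2] != "GT":
                continue
            for d2 in range(-window, window + 1):
                if (d1 - d2) % 3 != 0:
                    continue
                acc = s_j + d2
                if acc >= e_j or acc - don < 4 or cseq[acc - 2 : acc] != "AG":
                    continue
                stop, score = _seam_score(
                    cseq, spans, q_first, idx, d1, d2, query
                )
                if score is not None:
                    key = (-score, abs(d1) + abs(d2), abs(d1), d1, d2)
                else:
                    key = (stop, abs(d1) + abs(d2), abs(d1), d1, d2)
                if best is None or key < best[0]:
                    best = (key, d1, d2)
        if best is not None:
            _, d1, d2 = best
            spans[idx] = (s_i, e_i + d1)
            spans[idx + 1] = (s_j + d2, e_j)
    if model.strand == "+":
        new_exons = spans
    else:
        new_exons = [(L - e, L - s) for s, e in spans]
    protein = splice_and_translate(genome.residues, new_exons, model.strand)
    status = "pseudogene_fragment" if "*" in protein else "intact"
    return GeneModel(
        locus_id=model.locus_id,
        contig_id=model.contig_id,
        contig_length=model.contig_length,
        strand=model.strand,
        exons=new_exons,
        protein=protein,
        family=model.family,
        supporting=model.supporting,
        chain_score=model.chain_score,
        status=status,
        iteration_found=model.iteration_found,
        query_id=model.query_id,
        exon_query_spans=model.exon_query_spans,
    )


# ---------------------------------------------------------------------------
# iteration


def _reciprocal_overlap(a: GeneModel, b: GeneModel) -> float:
    if a.contig_id != b.contig_id:
        return 0.0
    (a0, a1), (b0, b1) = a.extent, b.extent
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    return min(inter / (a1 - a0), inter / (b1 - b0))


def _dedup_models(models: list[GeneModel], threshold: float) -> list[GeneModel]:
    kept: list[GeneModel] = []
    for m in sorted(
        models, key=lambda m: (-m.chain_score, m.contig_id, m.extent, m.locus_id)
    ):
        if all(_reciprocal_overlap(m, k) < threshold for k in kept):
            kept.append(m)
    kept.sort(key=lambda m: (m.contig_id, m.extent, m.strand))
    return kept


def bati_iterate(
    seeds: Sequence[SeedProtein],
    genomes: Sequence[GenomeSequence],
    config: BatiConfig | None = None,
    *,
    return_hsps: bool = False,
):
    """The full Blast-Annotate-Tune-Iterate loop.

    Round 1 searches with the seed set; each later round adds the previous
    round's intact predictions (labelled with the family of their
    best-scoring supporting query) to the query set, and the loop stops as
    soon as a round contributes no new locus, or at ``max_iterations``.
    """
    cfg = config or BatiConfig()
    if cfg.max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    if not seeds:
        raise ValueError("empty seed set")
    genome_by_id = {g.id: g for g in genomes}
    family_of = {s.id: s.family for s in seeds}
    query_seq = {s.id: s.sequence for s in seeds}
    new_queries: list = list(seeds)
    seen_query_seqs = {s.sequence for s in seeds}
    all_hsps: dict[str, HSP] = {}
    models: list[GeneModel] = []
    for iteration in range(1, cfg.max_iterations + 1):
        for h in search(new_queries, genomes, cfg.search):
            all_hsps.setdefault(h.uid, h)
        loci = cluster_hsps(list(all_hsps.values()), cfg.max_intron)
        candidates = []
        for locus in loci:
            m = chain_hsps(locus, family_of)
            m = tune_boundaries(
                m,
                genome_by_id[m.contig_id],
                cfg.tune_window,
                query=query_seq.get(m.query_id),
            )
            candidates.append(m)
        merged = _dedup_models(candidates, cfg.dedup_overlap)
        for m in merged:
            prev = [
                p for p in models if _reciprocal_overlap(m, p) >= cfg.dedup_overlap
            ]
            m.iteration_found = (
                min(p.iteration_found for p in prev) if prev else iteration
            )
        new_found = any(m.iteration_found == iteration for m in merged)
        models = merged
        if not new_found:
            break
        new_queries = []
        for m in models:
            if m.status == "intact" and m.protein not in seen_query_seqs:
                seen_query_seqs.add(m.protein)
                new_queries.append(Query(m.locus_id, m.family, m.protein))
                family_of[m.locus_id] = m.family
                query_seq[m.locus_id] = m.protein
        if not new_queries:
            break
    if return_hsps:
        hsps = sorted(
            all_hsps.values(), key=lambda h: (h.contig_id, h.genome_span, h.query_id)
        )
        return models, hsps
    return models


# ---------------------------------------------------------------------------
# composite hit report (the "missed gene" review surface)


def bgmix_report(
    hsps: Sequence[HSP], models: Sequence[GeneModel] = ()
) -> pd.DataFrame:
    """All HSPs merged and sorted by chromosomal location.

    ``modelled`` flags HSPs whose genomic span overlaps a final gene
    model's extent on the same contig; unflagged rows are candidate missed
    genes.
    """
    rows = []
    for h in hsps:
        covered = any(
            m.contig_id == h.contig_id
            and min(m.extent[1], h.genome_span[1])
            > max(m.extent[0], h.genome_span[0])
            for m in models
        )
        rows.append(
            {
                "contig": h.contig_id,
                "start": h.genome_span[0],
                "end": h.genome_span[1],
                "strand": h.strand,
                "frame": h.frame,
                "query": h.query_id,
                "score": h.score,
                "evalue": h.evalue,
                "modelled": covered,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "contig", "start", "end", "strand", "frame",
            "query", "score", "evalue", "modelled",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["contig", "start", "score"], ascending=[True, True, False]
        ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# model I/O


def write_models_gff3(models: Iterable[GeneModel], path) -> None:
    lines = ["##gff-version 3"]
    for m in models:
        lo, hi = m.extent
        attrs = (
            f"ID={m.locus_id};family={m.family};status={m.status};"
            f"iteration_found={m.iteration_found};chain_score={m.chain_score}"
        )
        lines.append(
            "\t".join(
                [m.contig_id, "bati", "gene", str(lo + 1), str(hi), ".",
                 m.strand, ".", attrs]
            )
        )
        lines.append(
            "\t".join(
                [m.contig_id, "bati", "mRNA", str(lo + 1), str(hi), ".",
                 m.strand, ".", f"ID={m.locus_id}.t1;Parent={m.locus_id}"]
            )
        )
        for s, e in m.exons:
            lines.append(
                "\t".join(
                    [m.contig_id, "bati", "CDS", str(s + 1), str(e), ".",
                     m.strand, "0", f"ID={m.locus_id}.cds;Parent={m.locus_id}.t1"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_proteins_fasta(models: Iterable[GeneModel], path) -> None:
    SeqIO.write(
        [
            SeqRecord(
                Seq(m.protein),
                id=m.locus_id,
                description=f"family={m.family} status={m.status}",
            )
            for m in models
        ],
        str(path),
        "fasta",
    )


def _parse_gff_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for item in attrs.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_models_gff3(gff_path, proteins_fasta=None) -> list[GeneModel]:
    """Read back models written by :func:`write_models_gff3`."""
    proteins = {}
    if proteins_fasta is not None:
        proteins = {r.id: str(r.seq) for r in SeqIO.parse(str(proteins_fasta), "fasta")}
    genes: dict[str, GeneModel] = {}
    for line in Path(gff_path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        contig, _, ftype, start, end, _, strand, _, attrs = line.split("\t")
        a = _parse_gff_attrs(attrs)
        if ftype == "gene":
            mid = a["ID"]
            genes[mid] = GeneModel(
                locus_id=mid, contig_id=contig, contig_length=0, strand=strand,
                exons=[], protein=proteins.get(mid, ""), family=a.get("family", ""),
                supporting=[], chain_score=int(a.get("chain_score", 0)),
                status=a.get("status", "intact"),
                iteration_found=int(a.get("iteration_found", 1)),
            )
        elif ftype == "CDS":
            mid = a["Parent"].rsplit(".t1", 1)[0]
            genes[mid].exons.append((int(start) - 1, int(end)))
    for m in genes.values():
        if m.strand == "-":
            m.exons.sort(key=lambda se: -se[0])
        else:
            m.exons.sort()
    return list(genes.values())
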