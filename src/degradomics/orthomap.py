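"""Cross-species comparison: RBH orthology, duplications, family status.

Orthology is called by reciprocal best hit (RBH) over global pairwise
alignment scores; anything short of a mutual, strictly-unique best match
falls into the conservative "no clear orthologue" bucket.  Same-family
gene models close together on one contig are tandem duplication groups;
family copy counts map onto the presence/absence/duplicated/expanded
vocabulary of a degradome comparison matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

from ._scoring import GAP_EXTEND, GAP_OPEN, biopython_matrix
from .bati import GeneModel
from .seqforge import SeedProtein

STATUS_ORDER = [
    "absent", "not_found", "pseudogene_only", "present",
    "duplicated", "triplicated", "expanded",
]


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = biopython_matrix()
    # affine 11/1: a gap of length L costs 11 + L
    a.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    a.extend_gap_score = -GAP_EXTEND
    return a


def pairwise_protein_score(a: str, b: str) -> int:
    """Global affine-gap alignment score (BLOSUM62, gaps 11/1); symmetric."""
    if not a or not b:
        raise ValueError("empty sequence")
    return int(_aligner().score(a, b))


def align_pair(a: str, b: str):
    """One optimal global alignment (deterministic choice among co-optima)."""
    if not a or not b:
        raise ValueError("empty sequence")
    return _aligner().align(a, b)[0]


@dataclass
class OrthologyCall:
    gene_a: str
    gene_b: str | None
    call: str  # rbh_orthologue | no_clear_orthologue
    score_ab: int
    score_ba: int


def rbh(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    margin: int = 0,
) -> list[OrthologyCall]:
    """Reciprocal-best-hit calls for every gene in proteome A.

    (x, y) is an orthologue pair iff y is x's unique best scorer in B by
    strictly more than ``margin`` over the runner-up, and vice versa.
    Exact ties therefore yield no_clear_orthologue — the conservative
    treatment for large complex families where orthology is ambiguous.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("proteomes must be non-empty")
    ids_a = sorted(proteome_a)
    ids_b = sorted(proteome_b)
    scores = {
        (x, y): pairwise_protein_score(proteome_a[x], proteome_b[y])
        for x in ids_a
        for y in ids_b
    }
    return rbh_from_scores(scores, ids_a, ids_b, margin)


def rbh_from_scores(
    scores: Mapping[tuple[str, str], int],
    ids_a: Sequence[str],
    ids_b: Sequence[str],
    margin: int = 0,
) -> list[OrthologyCall]:
    """The mutual-unique-best rule applied to a precomputed score matrix."""
    ids_a = sorted(ids_a)
    ids_b = sorted(ids_b)

    def unique_best(cands, key):
        ranked = sorted(cands, key=lambda c: (-key(c), c))
        if len(ranked) == 1:
            return ranked[0]
        if key(ranked[0]) - key(ranked[1]) > margin:
            return ranked[0]
        return None

    best_in_b = {x: unique_best(ids_b, lambda y, x=x: scores[(x, y)]) for x in ids_a}
    best_in_a = {y: unique_best(ids_a, lambda x, y=y: scores[(x, y)]) for y in ids_b}
    calls = []
    for x in ids_a:
        y = best_in_b[x]
        if y is not None and best_in_a.get(y) == x:
            calls.append(
                OrthologyCall(x, y, "rbh_orthologue", scores[(x, y)], scores[(x, y)])
            )
        else:
            top = max(scores[(x, y2)] for y2 in ids_b)
            calls.append(OrthologyCall(x, None, "no_clear_orthologue", top, 0))
    return calls


# ---------------------------------------------------------------------------
# duplication structure


@dataclass
class TandemGroup:
    family: str
    contig: str
    model_ids: list[str]


@dataclass
class DuplicationCalls:
    tandem_groups: list[TandemGroup]
    dispersed_copies: dict[str, int]  # family -> copies outside tandem groups


def detect_tandem_duplication(
    models: Sequence[GeneModel], max_separation: int = 1_000_000
) -> DuplicationCalls:
    """Group same-family models by proximity on a contig.

    Models of one family on one contig with pairwise gaps at most
    ``max_separation`` form a group; groups of two or more are tandem
    duplications.  Remaining copies of families with at least two total
    copies are counted as dispersed.
    """
    by_family: dict[str, list[GeneModel]] = {}
    for m in models:
        by_family.setdefault(m.family, []).append(m)
    tandem: list[TandemGroup] = []
    dispersed: dict[str, int] = {}
    for family in sorted(by_family):
        fam_models = by_family[family]
        in_tandem: set[str] = set()
        by_contig: dict[str, list[GeneModel]] = {}
        for m in fam_models:
            by_contig.setdefault(m.contig_id, []).append(m)
        for contig in sorted(by_contig):
            ms = sorted(by_contig[contig], key=lambda m: m.extent)
            group: list[GeneModel] = []
            prev_end = None
            for m in ms + [None]:
                if m is not None and (
                    prev_end is None or m.extent[0] - prev_end <= max_separation
                ):
                    group.append(m)
                    prev_end = max(prev_end or 0, m.extent[1])
                    continue
                if len(group) >= 2:
                    tandem.append(
                        TandemGroup(family, contig, [g.locus_id for g in group])
                    )
                    in_tandem.update(g.locus_id for g in group)
                if m is not None:
                    group = [m]
                    prev_end = m.extent[1]
        if len(fam_models) >= 2:
            n_out = sum(1 for m in fam_models if m.locus_id not in in_tandem)
            if n_out:
                dispersed[family] = n_out
    return DuplicationCalls(tandem, dispersed)


# ---------------------------------------------------------------------------
# family status matrix (per family x species)


@dataclass
class FamilyStatus:
    family: str
    species: str
    copy_count: int
    intact_count: int  # models that are not pseudogene fragments
    status: str


def status_from_counts(
    copy_count: int, intact_count: int, gap_fraction: float = 0.0
) -> str:
    """The copy-count -> status mapping of the comparison matrix.

    A family with no copies is ``absent``, or ``not_found`` when more than
    20% of its expected region is assembly gap (N) — a lack of genomic
    data rather than a loss.  Copies with no intact open reading frame are
    ``pseudogene_only``; otherwise 1/2/3/4+ copies map to present /
    duplicated / triplicated / expanded.
    """
    if copy_count == 0:
        return "not_found" if gap_fraction > 0.20 else "absent"
    if intact_count == 0:
        return "pseudogene_only"
    if copy_count == 1:
        return "present"
    if copy_count == 2:
        return "duplicated"
    if copy_count == 3:
        return "triplicated"
    return "expanded"


def detect_family_status(
    models: Sequence[GeneModel],
    seeds: Sequence[SeedProtein],
    species: str,
    gap_fractions: Mapping[str, float] | None = None,
) -> list[FamilyStatus]:
    """Per-family status for one species' model set."""
    gap_fractions = gap_fractions or {}
    families = sorted({s.family for s in seeds})
    by_family: dict[str, list[GeneModel]] = {f: [] for f in families}
    for m in models:
        by_family.setdefault(m.family, []).append(m)
    out = []
    for family in families:
        ms = by_family[family]
        copy_count = len(ms)
        intact_count = sum(1 for m in ms if m.status != "pseudogene_fragment")
        out.append(
            FamilyStatus(
                family=family,
                species=species,
                copy_count=copy_count,
                intact_count=intact_count,
                status=status_from_counts(
                    copy_count, intact_count, gap_fractions.get(family, 0.0)
                ),
            )
        )
    return out


def status_matrix(statuses: Iterable[FamilyStatus]) -> pd.DataFrame:
    """Families x species matrix of status strings."""
    rows: dict[str, dict[str, str]] = {}
    species: list[str] = []
    for st in statuses:
        rows.setdefault(st.family, {})[st.species] = st.status
        if st.species not in species:
            species.append(st.species)
    df = pd.DataFrame(
        [[rows[f].get(sp, "absent") for sp in species] for f in sorted(rows)],
        index=sorted(rows),
        columns=species,
    )
    df.index.name = "family"
    return df


def write_orthology_tsv(calls: Iterable[OrthologyCall], path) -> None:
    pd.DataFrame(
        [
            {
                "gene_a": c.gene_a,
                "gene_b": c.gene_b if c.gene_b is not None else ".",
                "call": c.call,
                "score_ab": c.score_ab,
                "score_ba": c.score_ba,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)
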