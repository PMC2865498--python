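"""Catalytic-residue inspection and non-peptidase-homolog calling.

A predicted protein is aligned globally to its family's curated seed; the
seed's catalytic positions (triad for serine proteases, dyad for cysteine
and aspartyl, zinc-binding residues for metallo) are read through the
alignment.  Any substituted or deleted catalytic residue predicts loss of
proteolytic activity, so a single hit already demotes the gene to
non-peptidase homolog; conservative-substitution exceptions are not
granted (configurable off by callers that want them).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .bati import GeneModel
from .orthomap import align_pair, pairwise_protein_score
from .seqforge import SeedProtein


@dataclass
class CatalyticSite:
    seed_pos: int
    seed_residue: str
    candidate_pos: int | None  # None: aligned to a gap (deleted)
    candidate_residue: str | None

    @property
    def substituted(self) -> bool:
        return self.candidate_residue != self.seed_residue


def map_catalytic_positions(
    seed: SeedProtein, candidate: str
) -> list[CatalyticSite]:
    """Locate the seed's catalytic residues in a candidate protein.

    The candidate is aligned globally to the seed (same scheme as the RBH
    scores); each catalytic seed position reports the aligned candidate
    column, or None when it falls in a deletion.
    """
    if not candidate:
        raise ValueError("empty candidate protein")
    alignment = align_pair(seed.sequence, candidate)
    # aligned blocks: list of ((seed_start, seed_end), (cand_start, cand_end))
    blocks = list(zip(alignment.aligned[0], alignment.aligned[1]))
    sites = []
    for pos in seed.catalytic_positions:
        cand_pos = None
        for (ts, te), (qs, _) in blocks:
            if ts <= pos < te:
                cand_pos = qs + (pos - ts)
                break
        sites.append(
            CatalyticSite(
                seed_pos=pos,
                seed_residue=seed.sequence[pos],
                candidate_pos=cand_pos,
                candidate_residue=candidate[cand_pos] if cand_pos is not None else None,
            )
        )
    return sites


@dataclass
class PeptidaseCall:
    call: str  # peptidase | non_peptidase_homolog
    n_substituted: int
    sites: list[CatalyticSite]


def call_peptidase_status(mapping: Sequence[CatalyticSite]) -> PeptidaseCall:
    """Non-peptidase homolog iff any catalytic residue is substituted or deleted."""
    n = sum(1 for site in mapping if site.substituted)
    return PeptidaseCall(
        call="non_peptidase_homolog" if n >= 1 else "peptidase",
        n_substituted=n,
        sites=list(mapping),
    )


def classify_models(
    models: Sequence[GeneModel], seeds: Sequence[SeedProtein]
) -> pd.DataFrame:
    """Classify every intact model against its family seed.

    Models flagged non-peptidase homolog get their status field updated in
    place (pseudogene fragments are left as-is).  Returns the per-gene
    classification table.
    """
    by_family: dict[str, list[SeedProtein]] = {}
    for s in seeds:
        by_family.setdefault(s.family, []).append(s)
    rows = []
    for m in models:
        fam_seeds = by_family.get(m.family, [])
        if not fam_seeds or m.status == "pseudogene_fragment" or not m.protein:
            rows.append(
                {
                    "gene": m.locus_id, "family": m.family, "class": ".",
                    "substituted_positions": ".", "n_substituted": 0,
                    "call": "." if m.status == "pseudogene_fragment" else "peptidase",
                }
            )
            continue
        # best-scoring family seed anchors the positions; ties break on id
        seed = max(
            sorted(fam_seeds, key=lambda s: s.id),
            key=lambda s: pairwise_protein_score(s.sequence, m.protein),
        )
        result = call_peptidase_status(map_catalytic_positions(seed, m.protein))
        if result.call == "non_peptidase_homolog":
            m.status = "non_peptidase_homolog"
        subs = [
            f"{site.seed_residue}{site.seed_pos}"
            f"{site.candidate_residue or '-'}"
            for site in result.sites
            if site.substituted
        ]
        rows.append(
            {
                "gene": m.locus_id,
                "family": m.family,
                "class": seed.catalytic_class,
                "substituted_positions": ",".join(subs) if subs else ".",
                "n_substituted": result.n_substituted,
                "call": result.call,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "family", "class", "substituted_positions",
            "n_substituted", "call",
        ],
    )
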