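"""Synthetic genomes with implanted protease genes and an exact truth table.

The forge emulates the evolutionary events a degradome comparison must
detect — tandem and dispersed duplication, family expansion, gene loss,
and pseudogenization by catalytic-residue substitution or in-frame stops —
by implanting multi-exon protein-coding genes into i.i.d. random
intergenic background at a controlled protein divergence.

Divergence model: for each species x family, a shared "ancestor" protein
is drawn at half the configured divergence from the seed, and each copy
diverges a further half from that ancestor.  Copies within a species
therefore share lineage substitutions, as post-speciation duplicates do;
without that, duplicate pairs would carry no phylogenetic signal.

Substitution-only (no indels), standard genetic code, uniform random codon
choice, phase-0 introns with GT...AG termini.  Coordinates are 0-based
half-open on the forward strand; minus-strand genes store their exon spans
in coding (5'->3') order, i.e. descending forward coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

from ._scoring import AA20
from .transearch import CODONS, GenomeSequence, translate_nt

CATALYTIC_CLASSES = ("serine", "cysteine", "aspartyl", "metallo")

#: residues expected at each catalytic position, and their required count
CLASS_RESIDUES = {
    "serine": "HDS",  # the classic His-Asp-Ser triad
    "cysteine": "HC",  # His-Cys dyad
    "aspartyl": "DD",  # paired catalytic aspartates
    "metallo": "HEH",  # zinc-binding HExxH-style residues
}

_CODON_CHOICES: dict[str, list[str]] = {}
for codon, aa in CODONS.items():
    _CODON_CHOICES.setdefault(aa, []).append(codon)
for aa in _CODON_CHOICES:
    _CODON_CHOICES[aa].sort()


@dataclass
class SeedProtein:
    """A curated protease used as a homology-search query."""

    id: str
    family: str
    catalytic_class: str
    catalytic_positions: list[int]
    sequence: str

    def __post_init__(self) -> None:
        if self.catalytic_class not in CATALYTIC_CLASSES:
            raise ValueError(f"unknown catalytic class {self.catalytic_class!r}")
        expected = len(CLASS_RESIDUES[self.catalytic_class])
        if len(self.catalytic_positions) != expected:
            raise ValueError(
                f"{self.id}: class {self.catalytic_class} requires {expected} "
                f"catalytic positions, got {len(self.catalytic_positions)}"
            )
        if any(p < 0 or p >= len(self.sequence) for p in self.catalytic_positions):
            raise ValueError(f"{self.id}: catalytic position outside sequence")
        if set(self.sequence) - set(AA20):
            raise ValueError(f"{self.id}: sequence has non-standard residues")


@dataclass
class CopyPlan:
    """How many copies of one family a species carries, and where."""

    family: str
    copies: int = 1
    placement: str = "tandem"  # 'tandem' (main contig, adjacent) | 'dispersed'

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError("copies must be >= 0")
        if self.placement not in ("tandem", "dispersed"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass
class Knockout:
    species: str
    family: str
    copy_index: int
    mode: str  # 'catalytic_substitution' | 'inframe_stop'

    def __post_init__(self) -> None:
        if self.mode not in ("catalytic_substitution", "inframe_stop"):
            raise ValueError(f"unknown knockout mode {self.mode!r}")


@dataclass
class ForgeConfig:
    species: list[str]
    plan: dict[str, list[CopyPlan]]  # species -> plans
    knockouts: list[Knockout] = field(default_factory=list)
    divergence: float = 0.15
    n_exons: int = 3
    intron_length: tuple[int, int] = (60, 400)
    intergenic_length: tuple[int, int] = (6000, 12000)
    rng_seed: int = 0

    def validate(self, seeds: Sequence[SeedProtein]) -> None:
        if not (0 <= self.divergence < 0.5):
            raise ValueError("divergence must be in [0, 0.5)")
        if self.intron_length[0] < 20:
            raise ValueError("intron lengths must be >= 20 nt")
        if self.n_exons < 1:
            raise ValueError("need at least one exon")
        families = {s.family for s in seeds}
        for sp in self.species:
            for plan in self.plan.get(sp, []):
                if plan.family not in families:
                    raise ValueError(
                        f"family {plan.family!r} planned for {sp} is missing "
                        f"from the seed set"
                    )
        for ko in self.knockouts:
            plans = {p.family: p for p in self.plan.get(ko.species, [])}
            if ko.family not in plans or ko.copy_index >= plans[ko.family].copies:
                raise ValueError(f"knockout {ko} targets a copy that is not planned")


@dataclass
class TruthRecord:
    species: str
    family: str
    locus_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]  # coding order, forward-strand coords
    protein: str  # as implanted ('*' marks an in-frame stop knockout)
    status: str  # intact | non_peptidase_homolog | pseudogene_fragment
    event: str  # single | tandem_dup | dispersed_dup | knockout


# ---------------------------------------------------------------------------
# protein-level events


def mutate_protein(
    protein: str, rate: float, rng: np.random.Generator, protected: Iterable[int] = ()
) -> str:
    """Substitute each residue with probability ``rate`` (never at protected positions)."""
    protected = set(protected)
    out = list(protein)
    hits = np.nonzero(rng.random(len(protein)) < rate)[0]
    for i in hits:
        if int(i) in protected:
            continue
        choices = [a for a in AA20 if a != out[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def knockout_protein(
    protein: str,
    positions: Sequence[int],
    mode: str,
    rng: np.random.Generator,
) -> str:
    """Apply a pseudogenizing edit at the protein level.

    ``catalytic_substitution`` replaces each listed catalytic residue with a
    different residue drawn from the rng; ``inframe_stop`` marks the first
    listed position with '*', which back-translation renders as a stop
    codon.  An empty position list leaves the protein unchanged.
    """
    if not protein:
        raise ValueError("empty protein")
    if not positions:
        return protein
    out = list(protein)
    if mode == "catalytic_substitution":
        for p in positions:
            choices = [a for a in AA20 if a != out[p]]
            out[p] = choices[int(rng.integers(len(choices)))]
    elif mode == "inframe_stop":
        out[positions[0]] = "*"
    else:
        raise ValueError(f"unknown knockout mode {mode!r}")
    return "".join(out)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform random codon choice per residue under the standard code."""
    return "".join(
        _CODON_CHOICES[aa][int(rng.integers(len(_CODON_CHOICES[aa])))]
        for aa in protein
    )


def _random_nt(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# ---------------------------------------------------------------------------
# gene and genome assembly


def _split_exons(n_codons: int, n_exons: int, rng: np.random.Generator) -> list[int]:
    """Codon counts per exon (each >= 30 codons — 90 nt — where possible).

    Very short exons score below any sensible E-value cutoff in a
    translated search, so the forge does not emit them.
    """
    min_len = 30
    while n_exons > 1 and n_codons < n_exons * min_len:
        n_exons -= 1
    if n_exons == 1:
        return [n_codons]
    for _ in range(200):
        cuts = sorted(rng.choice(np.arange(min_len, n_codons - min_len + 1),
                                 size=n_exons - 1, replace=False).tolist())
        sizes = np.diff([0] + cuts + [n_codons])
        if (sizes >= min_len).all():
            return [int(s) for s in sizes]
    # fall back to an even split
    base = n_codons // n_exons
    sizes = [base] * n_exons
    sizes[-1] += n_codons - base * n_exons
    return sizes


def _build_gene(
    protein: str, cfg: ForgeConfig, rng: np.random.Generator
) -> tuple[str, list[tuple[int, int]]]:
    """Gene in coding orientation: (nucleotides, exon spans within the gene)."""
    cds = back_translate(protein, rng)
    sizes = _split_exons(len(protein), cfg.n_exons, rng)
    parts: list[str] = []
    spans: list[tuple[int, int]] = []
    pos = 0
    codon_at = 0
    for i, ncod in enumerate(sizes):
        exon = cds[3 * codon_at : 3 * (codon_at + ncod)]
        spans.append((pos, pos + len(exon)))
        parts.append(exon)
        pos += len(exon)
        codon_at += ncod
        if i < len(sizes) - 1:
            ilen = int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
            intron = "GT" + _random_nt(ilen - 4, rng) + "AG"
            parts.append(intron)
            pos += ilen
    return "".join(parts), spans


def splice_and_translate(
    contig: str, exons: Sequence[tuple[int, int]], strand: str
) -> str:
    """Translate a gene given its coding-order exon spans (forward coords)."""
    if strand == "+":
        cds = "".join(contig[s:e] for s, e in exons)
    else:
        cds = "".join(reverse_complement(contig[s:e]) for s, e in exons)
    return translate_nt(cds)


def forge_genome(
    seeds: Sequence[SeedProtein], config: ForgeConfig
) -> tuple[list[GenomeSequence], list[TruthRecord]]:
    """Emit genomes and the matching truth table for a forge plan."""
    config.validate(seeds)
    rng = np.random.default_rng(config.rng_seed)
    seed_by_family = {}
    for s in seeds:
        seed_by_family.setdefault(s.family, s)
    genomes: list[GenomeSequence] = []
    truth: list[TruthRecord] = []
    half = config.divergence / 2.0
    for sp in config.species:
        main_parts: list[str] = []
        main_pos = 0
        main_genes: list[dict] = []
        dispersed: list[dict] = []

        def _gap(lo=None, hi=None):
            lo = config.intergenic_length[0] if lo is None else lo
            hi = config.intergenic_length[1] if hi is None else hi
            return _random_nt(int(rng.integers(lo, hi + 1)), rng)

        for plan in config.plan.get(sp, []):
            if plan.copies == 0:
                continue
            seed = seed_by_family[plan.family]
            kos = {
                ko.copy_index: ko
                for ko in config.knockouts
                if ko.species == sp and ko.family == plan.family
            }
            ancestor = mutate_protein(
                seed.sequence, half, rng, protected=seed.catalytic_positions
            )
            for ci in range(plan.copies):
                prot = mutate_protein(
                    ancestor, half, rng, protected=seed.catalytic_positions
                )
                status, event = "intact", "single"
                if plan.copies > 1:
                    event = "tandem_dup" if plan.placement == "tandem" else "dispersed_dup"
                if ci in kos:
                    ko = kos[ci]
                    event = "knockout"
                    if ko.mode == "catalytic_substitution":
                        prot = knockout_protein(
                            prot, seed.catalytic_positions, ko.mode, rng
                        )
                        status = "non_peptidase_homolog"
                    else:
                        stop_at = len(prot) // 2
                        prot = knockout_protein(prot, [stop_at], ko.mode, rng)
                        status = "pseudogene_fragment"
                strand = "+" if rng.random() < 0.5 else "-"
                gene_nt, gene_spans = _build_gene(prot, config, rng)
                entry = {
                    "family": plan.family,
                    "copy": ci,
                    "protein": prot,
                    "strand": strand,
                    "status": status,
                    "event": event,
                    "gene_nt": gene_nt,
                    "gene_spans": gene_spans,
                }
                if plan.placement == "dispersed" and plan.copies > 1:
                    dispersed.append(entry)
                else:
                    main_genes.append(entry)
        # assemble the main contig
        contig_id = f"{sp}_chr1"
        for entry in main_genes:
            main_parts.append(_gap())
            main_pos = sum(len(p) for p in main_parts)
            truth.append(_place(entry, sp, contig_id, main_pos))
            main_parts.append(_oriented(entry))
        main_parts.append(_gap())
        genomes.append(GenomeSequence(contig_id, sp, "".join(main_parts)))
        # each dispersed copy sits on its own contig
        for i, entry in enumerate(dispersed):
            cid = f"{sp}_scaf{i + 2}"
            left = _gap()
            rec = _place(entry, sp, cid, len(left))
            seqs = left + _oriented(entry) + _gap()
            genomes.append(GenomeSequence(cid, sp, seqs))
            truth.append(rec)
    _verify(genomes, truth)
    return genomes, truth


def _oriented(entry: dict) -> str:
    g = entry["gene_nt"]
    return g if entry["strand"] == "+" else reverse_complement(g)


def _place(entry: dict, sp: str, contig: str, offset: int) -> TruthRecord:
    G = len(entry["gene_nt"])
    spans = []
    for s, e in entry["gene_spans"]:
        if entry["strand"] == "+":
            spans.append((offset + s, offset + e))
        else:
            spans.append((offset + G - e, offset + G - s))
    return TruthRecord(
        species=sp,
        family=entry["family"],
        locus_id=f"{sp}.{entry['family']}.c{entry['copy']}",
        contig=contig,
        strand=entry["strand"],
        exons=spans,
        protein=entry["protein"],
        status=entry["status"],
        event=entry["event"],
    )


def _verify(genomes: list[GenomeSequence], truth: list[TruthRecord]) -> None:
    by_id = {g.id: g.residues for g in genomes}
    for rec in truth:
        got = splice_and_translate(by_id[rec.contig], rec.exons, rec.strand)
        if got != rec.protein:
            raise AssertionError(f"forge self-check failed at {rec.locus_id}")


# ---------------------------------------------------------------------------
# I/O: genomes as FASTA, truth as GFF3 + TSV, seed sets as FASTA + TSV sidecar


def write_genomes_fasta(genomes: Iterable[GenomeSequence], path) -> None:
    records = [
        SeqRecord(Seq(g.residues), id=g.id, description=f"species={g.species}")
        for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genomes_fasta(path, species: str) -> list[GenomeSequence]:
    return [
        GenomeSequence(r.id, species, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")
    ]


def write_truth_gff3(truth: Iterable[TruthRecord], path) -> None:
    """Truth loci as GFF3 gene/mRNA/CDS features (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for rec in truth:
        lo = min(s for s, _ in rec.exons) + 1
        hi = max(e for _, e in rec.exons)
        attrs = (
            f"ID={rec.locus_id};family={rec.family};status={rec.status};"
            f"event={rec.event}"
        )
        lines.append(
            "\t".join(
                [rec.contig, "seqforge", "gene", str(lo), str(hi), ".",
                 rec.strand, ".", attrs]
            )
        )
        lines.append(
            "\t".join(
                [rec.contig, "seqforge", "mRNA", str(lo), str(hi), ".",
                 rec.strand, ".", f"ID={rec.locus_id}.t1;Parent={rec.locus_id}"]
            )
        )
        phase = 0
        for s, e in rec.exons:
            lines.append(
                "\t".join(
                    [rec.contig, "seqforge", "CDS", str(s + 1), str(e), ".",
                     rec.strand, str(phase),
                     f"ID={rec.locus_id}.cds;Parent={rec.locus_id}.t1"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def truth_table(truth: Iterable[TruthRecord]) -> pd.DataFrame:
    rows = [
        {
            "species": r.species,
            "family": r.family,
            "locus_id": r.locus_id,
            "contig": r.contig,
            "strand": r.strand,
            "exons": ";".join(f"{s}-{e}" for s, e in r.exons),
            "status": r.status,
            "event": r.event,
            "protein": r.protein,
        }
        for r in truth
    ]
    return pd.DataFrame(rows)


def write_truth_tsv(truth: Iterable[TruthRecord], path) -> None:
    truth_table(truth).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        exons = [
            (int(a), int(b))
            for a, b in (span.split("-") for span in str(r["exons"]).split(";"))
        ]
        out.append(
            TruthRecord(
                species=r["species"], family=r["family"], locus_id=r["locus_id"],
                contig=r["contig"], strand=r["strand"], exons=exons,
                protein=r["protein"], status=r["status"], event=r["event"],
            )
        )
    return out


def write_seed_set(seeds: Iterable[SeedProtein], fasta_path, tsv_path) -> None:
    seeds = list(seeds)
    SeqIO.write(
        [SeqRecord(Seq(s.sequence), id=s.id, description="") for s in seeds],
        str(fasta_path),
        "fasta",
    )
    pd.DataFrame(
        [
            {
                "id": s.id,
                "family": s.family,
                "class": s.catalytic_class,
                "catalytic_positions": ",".join(map(str, s.catalytic_positions)),
            }
            for s in seeds
        ]
    ).to_csv(tsv_path, sep="\t", index=False)


def load_seed_set(fasta_path, tsv_path) -> list[SeedProtein]:
    """Read a seed set (FASTA + TSV sidecar); invariants are checked on load."""
    seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
    meta = pd.read_csv(tsv_path, sep="\t")
    out = []
    for _, row in meta.iterrows():
        if row["id"] not in seqs:
            raise ValueError(f"seed {row['id']!r} missing from FASTA")
        out.append(
            SeedProtein(
                id=row["id"],
                family=row["family"],
                catalytic_class=row["class"],
                catalytic_positions=[
                    int(p) for p in str(row["catalytic_positions"]).split(",")
                ],
                sequence=seqs[row["id"]],
            )
        )
    return out


def forge_seed_set(
    families: Sequence[tuple[str, str]],
    rng_seed: int = 0,
    length_range: tuple[int, int] = (240, 340),
) -> list[SeedProtein]:
    """Random curated-seed stand-ins: one protein per (family, class) pair.

    Catalytic positions carry the canonical residues for the class (e.g.
    His-Asp-Ser for serine proteases) at well-separated interior sites.
    """
    rng = np.random.default_rng(rng_seed)
    out = []
    for fam, cls in families:
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = list("".join(AA20[i] for i in rng.integers(0, 20, L)))
        residues = CLASS_RESIDUES[cls]
        lo, hi = int(0.15 * L), int(0.85 * L)
        step = (hi - lo) // max(1, len(residues))
        positions = []
        for i, aa in enumerate(residues):
            p = lo + i * step + int(rng.integers(0, max(1, step // 2)))
            positions.append(min(p, L - 1))
            seq[positions[-1]] = aa
        out.append(
            SeedProtein(
                id=f"{fam}_seed",
                family=fam,
                catalytic_class=cls,
                catalytic_positions=sorted(set(positions)),
                sequence="".join(seq),
            )
        )
    return out
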