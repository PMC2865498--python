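"""End-to-end orchestration and the degradome comparison report.

A single plain-text (YAML) config drives the whole run: forge synthetic
genomes (or load real ones), search and annotate each species with the
iterative homology loop, classify catalytic residues, call orthology and
family status across species, and build bootstrap consensus trees for
families where orthology is ambiguous or copy number varies.  All
randomness flows from one master seed; identical config + seed gives
byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .bati import (
    BatiConfig,
    GeneModel,
    bati_iterate,
    bgmix_report,
    read_models_gff3,
    write_models_gff3,
    write_proteins_fasta,
)
from .orthomap import (
    detect_family_status,
    detect_tandem_duplication,
    rbh,
    status_matrix,
    write_orthology_tsv,
)
from .phylo import (
    Tree,
    bootstrap_resample,
    majority_consensus,
    parsimony_search,
    progressive_align,
    root_with_outgroup,
    write_newick,
)
from .protclass import classify_models
from .seqforge import (
    CopyPlan,
    ForgeConfig,
    Knockout,
    SeedProtein,
    forge_genome,
    forge_seed_set,
    load_seed_set,
    read_genomes_fasta,
    read_truth_tsv,
    truth_table,
    write_genomes_fasta,
    write_seed_set,
    write_truth_gff3,
    write_truth_tsv,
)
from .transearch import SearchConfig, write_hsp_table

log = logging.getLogger("degradomics")


def demo_config() -> dict:
    """The built-in three-species demonstration plan.

    Twelve shared families exercising every event the comparison must
    detect: a tandem duplication private to species A, a seven-copy
    dispersed expansion in species A with one catalytic knockout, a
    family triplicated in A and B but single-copy in C, two families lost
    from A and B, and seven stable single-copy families.
    """
    families = [
        {"name": "CASP3L", "class": "cysteine"},
        {"name": "ACRL", "class": "serine"},
        {"name": "MALTL", "class": "cysteine"},
        {"name": "GZMKL", "class": "serine"},
        {"name": "ELA2L", "class": "serine"},
        {"name": "BACEL", "class": "aspartyl"},
        {"name": "MMP1L", "class": "metallo"},
        {"name": "ADAM1L", "class": "metallo"},
        {"name": "CTSDL", "class": "aspartyl"},
        {"name": "GZMAL", "class": "serine"},
        {"name": "CASP9L", "class": "cysteine"},
        {"name": "PGAL", "class": "aspartyl"},
    ]
    def plan(**overrides):
        base = {f["name"]: {"family": f["name"], "copies": 1, "placement": "tandem"}
                for f in families}
        for fam, override in overrides.items():
            base[fam] = {"family": fam, **override}
        return [base[f["name"]] for f in families if base[f["name"]]["copies"] > 0]

    return {
        "seed": 0,
        "forge": {
            "species": ["spA", "spB", "spC"],
            "divergence": 0.15,
            "n_exons": 3,
            "intron_length": [60, 400],
            "intergenic_length": [6000, 12000],
            "families": families,
            "plan": {
                "spA": plan(
                    CASP3L={"copies": 2, "placement": "tandem"},
                    ACRL={"copies": 7, "placement": "dispersed"},
                    MALTL={"copies": 3, "placement": "tandem"},
                    GZMKL={"copies": 0},
                    ELA2L={"copies": 0},
                ),
                "spB": plan(
                    MALTL={"copies": 3, "placement": "tandem"},
                    GZMKL={"copies": 0},
                    ELA2L={"copies": 0},
                ),
                "spC": plan(),
            },
            "knockouts": [
                {"species": "spA", "family": "ACRL", "copy_index": 3,
                 "mode": "catalytic_substitution"},
            ],
        },
        "search": {},
        "bati": {},
        "orthology": {"margin": 0, "max_separation": 1_000_000},
        "phylo": {"replicates": 100, "threshold": 50},
    }


def load_config(source) -> dict:
    if isinstance(source, Mapping):
        return dict(source)
    return yaml.safe_load(Path(source).read_text())


def _forge_config_from_dict(cfg: dict, seed: int) -> tuple[list[SeedProtein], ForgeConfig]:
    f = cfg["forge"]
    seeds = forge_seed_set(
        [(fam["name"], fam["class"]) for fam in f["families"]],
        rng_seed=seed,
    )
    plan = {
        sp: [CopyPlan(**p) for p in plans] for sp, plans in f["plan"].items()
    }
    forge_cfg = ForgeConfig(
        species=list(f["species"]),
        plan=plan,
        knockouts=[Knockout(**k) for k in f.get("knockouts", [])],
        divergence=float(f.get("divergence", 0.15)),
        n_exons=int(f.get("n_exons", 3)),
        intron_length=tuple(f.get("intron_length", (60, 400))),
        intergenic_length=tuple(f.get("intergenic_length", (6000, 12000))),
        rng_seed=seed + 1,
    )
    return seeds, forge_cfg


def _rename_models(models: list[GeneModel], species: str) -> None:
    counters: dict[str, int] = {}
    for m in sorted(models, key=lambda m: (m.contig_id, m.extent)):
        n = counters.get(m.family, 0) + 1
        counters[m.family] = n
        m.locus_id = f"{species}.{m.family}.g{n}"


def phylo_family_tree(
    proteins: Mapping[str, str],
    replicates: int,
    threshold: float,
    rng_seed: int,
    outgroup: Sequence[str] | None = None,
) -> Tree:
    """Align a family, bootstrap, search, and take the strict consensus."""
    alignment = progressive_align(proteins)
    reps = bootstrap_resample(alignment, replicates, rng_seed)
    per_replicate = [parsimony_search(rep) for rep in reps]
    tree = majority_consensus(per_replicate, threshold)
    if outgroup:
        tree = root_with_outgroup(tree, outgroup)
    return tree


def run_pipeline(config, outdir, seed: int | None = None) -> dict:
    """Run every stage and write the artifact directory.

    Returns the in-memory artifacts (models per species, status matrix,
    orthology calls, trees, truth) alongside the paths written.
    """
    t0 = time.time()
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    master = int(cfg.get("seed", 0))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    if "forge" not in cfg and "inputs" not in cfg:
        raise ValueError("config must name either a forge plan or input files")

    # --- stage: forge (or load) ------------------------------------------
    truth = None
    if "forge" in cfg:
        seeds, forge_cfg = _forge_config_from_dict(cfg, master)
        genomes, truth = forge_genome(seeds, forge_cfg)
        species_list = forge_cfg.species
        write_seed_set(seeds, out / "seed_set.fasta", out / "seed_set.tsv")
        for sp in species_list:
            write_genomes_fasta(
                [g for g in genomes if g.species == sp], out / f"{sp}.genome.fasta"
            )
        write_truth_gff3(truth, out / "truth.gff3")
        write_truth_tsv(truth, out / "truth.tsv")
        log.info("stage=forge species=%d loci=%d", len(species_list), len(truth))
    else:
        inputs = cfg["inputs"]
        seeds = load_seed_set(inputs["seeds"]["fasta"], inputs["seeds"]["tsv"])
        genomes = []
        for sp, path in sorted(inputs["genomes"].items()):
            genomes.extend(read_genomes_fasta(path, sp))
        species_list = sorted(inputs["genomes"])
        if "truth" in inputs:
            truth = read_truth_tsv(inputs["truth"])

    search_cfg = SearchConfig(**cfg.get("search", {}))
    bati_cfg = BatiConfig(search=search_cfg, **cfg.get("bati", {}))

    # --- stage: search + annotate per species ----------------------------
    models_by_sp: dict[str, list[GeneModel]] = {}
    for sp in species_list:
        t = time.time()
        sp_genomes = [g for g in genomes if g.species == sp]
        models, hsps = bati_iterate(seeds, sp_genomes, bati_cfg, return_hsps=True)
        _rename_models(models, sp)
        models.sort(key=lambda m: (m.contig_id, m.extent))
        models_by_sp[sp] = models
        write_hsp_table(hsps, out / f"{sp}.hsps.tsv")
        bgmix_report(hsps, models).to_csv(
            out / f"{sp}.bgmix.tsv", sep="\t", index=False, float_format="%.3g"
        )
        log.info(
            "stage=annotate species=%s hsps=%d models=%d wall=%.1fs",
            sp, len(hsps), len(models), time.time() - t,
        )

    # --- stage: classify --------------------------------------------------
    class_tables = {}
    for sp in species_list:
        table = classify_models(models_by_sp[sp], seeds)
        table.to_csv(out / f"{sp}.classification.tsv", sep="\t", index=False)
        class_tables[sp] = table
        write_models_gff3(models_by_sp[sp], out / f"{sp}.models.gff3")
        write_proteins_fasta(models_by_sp[sp], out / f"{sp}.proteins.fasta")

    # --- stage: orthology + family status ---------------------------------
    ortho_cfg = cfg.get("orthology", {})
    margin = int(ortho_cfg.get("margin", 0))
    max_sep = int(ortho_cfg.get("max_separation", 1_000_000))
    proteomes = {
        sp: {
            m.locus_id: m.protein
            for m in models_by_sp[sp]
            if m.protein and m.status != "pseudogene_fragment"
        }
        for sp in species_list
    }
    ortho_calls = {}
    ambiguous_families: set[str] = set()
    for i, a in enumerate(species_list):
        for b in species_list[i + 1 :]:
            if not proteomes[a] or not proteomes[b]:
                continue
            calls = rbh(proteomes[a], proteomes[b], margin)
            ortho_calls[(a, b)] = calls
            write_orthology_tsv(calls, out / f"orthology.{a}-{b}.tsv")
            fam_of = {m.locus_id: m.family for m in models_by_sp[a]}
            ambiguous_families.update(
                fam_of[c.gene_a] for c in calls if c.call == "no_clear_orthologue"
            )
    statuses = []
    for sp in species_list:
        statuses.extend(detect_family_status(models_by_sp[sp], seeds, sp))
    matrix = status_matrix(statuses)
    matrix.to_csv(out / "family_status.tsv", sep="\t")
    tandem_rows = []
    for sp in species_list:
        calls = detect_tandem_duplication(models_by_sp[sp], max_sep)
        for g in calls.tandem_groups:
            tandem_rows.append(
                {"species": sp, "family": g.family, "contig": g.contig,
                 "n_copies": len(g.model_ids), "members": ",".join(g.model_ids)}
            )
    pd.DataFrame(
        tandem_rows, columns=["species", "family", "contig", "n_copies", "members"]
    ).to_csv(out / "tandem_duplications.tsv", sep="\t", index=False)
    log.info("stage=orthology pairs=%d families=%d", len(ortho_calls), len(matrix))

    # --- stage: phylogenetics ---------------------------------------------
    phylo_cfg = cfg.get("phylo", {})
    replicates = int(phylo_cfg.get("replicates", 100))
    threshold = float(phylo_cfg.get("threshold", 50))
    multi = {
        st.family
        for st in statuses
        if st.copy_count >= 2
    }
    trees: dict[str, Tree] = {}
    for fi, family in enumerate(sorted(multi | ambiguous_families)):
        members = {
            m.locus_id: m.protein
            for sp in species_list
            for m in models_by_sp[sp]
            if m.family == family and m.protein and m.status != "pseudogene_fragment"
        }
        if len(members) < 3:
            continue
        t = time.time()
        tree = phylo_family_tree(
            members, replicates, threshold,
            rng_seed=(master * 1000 + 7 * fi + 11) % (2**31),
            outgroup=phylo_cfg.get("outgroup", {}).get(family)
            if isinstance(phylo_cfg.get("outgroup"), dict)
            else None,
        )
        trees[family] = tree
        write_newick(tree, out / f"{family}.tree.nwk")
        log.info(
            "stage=phylo family=%s taxa=%d wall=%.1fs",
            family, len(members), time.time() - t,
        )

    # --- manifest ----------------------------------------------------------
    canon = json.dumps(
        {k: v for k, v in cfg.items() if not k.startswith("_")},
        sort_keys=True, default=str,
    )
    manifest = {
        "config_sha256": hashlib.sha256(canon.encode()).hexdigest(),
        "seed": master,
        "version": __version__,
        "species": list(species_list),
        "n_models": {sp: len(models_by_sp[sp]) for sp in species_list},
        "n_trees": len(trees),
        "model_ids": {
            sp: [m.locus_id for m in models_by_sp[sp]] for sp in species_list
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("stage=done wall=%.1fs", time.time() - t0)
    return {
        "outdir": out,
        "seeds": seeds,
        "genomes": genomes,
        "truth": truth,
        "models": models_by_sp,
        "statuses": statuses,
        "matrix": matrix,
        "orthology": ortho_calls,
        "classification": class_tables,
        "trees": trees,
    }


# ---------------------------------------------------------------------------
# evaluation against forge truth


def evaluate_run(
    models_by_sp: Mapping[str, Sequence[GeneModel]],
    matrix: pd.DataFrame,
    truth,
    seeds: Sequence[SeedProtein],
) -> pd.DataFrame:
    """Precision/recall of locus discovery, status-matrix agreement, and
    the peptidase-call confusion matrix, all against the forge truth."""
    from .orthomap import detect_family_status as _dfs, status_matrix as _sm

    rows = []
    truth_by_sp: dict[str, list] = {}
    for rec in truth:
        truth_by_sp.setdefault(rec.species, []).append(rec)
    confusion: dict[tuple[str, str], int] = {}
    for sp in sorted(models_by_sp):
        models = list(models_by_sp[sp])
        recs = truth_by_sp.get(sp, [])
        matched_truth = set()
        matched_models = set()
        for rec in recs:
            lo = min(s for s, _ in rec.exons)
            hi = max(e for _, e in rec.exons)
            for m in models:
                if (
                    m.contig_id == rec.contig
                    and m.strand == rec.strand
                    and m.family == rec.family
                ):
                    inter = min(hi, m.extent[1]) - max(lo, m.extent[0])
                    if inter > 0.5 * (hi - lo):
                        matched_truth.add(rec.locus_id)
                        matched_models.add(m.locus_id)
                        confusion[(rec.status, m.status)] = (
                            confusion.get((rec.status, m.status), 0) + 1
                        )
                        break
        recall = len(matched_truth) / len(recs) if recs else 1.0
        precision = (
            len(matched_models) / len(models) if models else 1.0
        )
        rows.append(
            {"species": sp, "metric": "locus_recall", "value": round(recall, 4)}
        )
        rows.append(
            {"species": sp, "metric": "locus_precision", "value": round(precision, 4)}
        )
    # status-matrix agreement
    truth_statuses = []
    for sp in sorted(models_by_sp):
        fake_models = [
            GeneModel(
                locus_id=r.locus_id, contig_id=r.contig, contig_length=0,
                strand=r.strand, exons=r.exons, protein=r.protein,
                family=r.family, supporting=[], chain_score=0,
                status=r.status,
            )
            for r in truth_by_sp.get(sp, [])
        ]
        truth_statuses.extend(_dfs(fake_models, seeds, sp))
    truth_matrix = _sm(truth_statuses)
    truth_matrix = truth_matrix.reindex(index=matrix.index, columns=matrix.columns)
    agree = (truth_matrix.values == matrix.values).mean()
    rows.append(
        {"species": "all", "metric": "status_matrix_agreement",
         "value": round(float(agree), 4)}
    )
    for (t_status, m_status), n in sorted(confusion.items()):
        rows.append(
            {"species": "all", "metric": f"confusion:{t_status}->{m_status}",
             "value": n}
        )
    return pd.DataFrame(rows, columns=["species", "metric", "value"])


def compare_to_truth(artifact_dir, truth_path=None) -> pd.DataFrame:
    """File-based wrapper around :func:`evaluate_run`."""
    art = Path(artifact_dir)
    truth_path = truth_path or art / "truth.tsv"
    if not Path(truth_path).exists():
        raise FileNotFoundError(f"truth table {truth_path} not found")
    truth = read_truth_tsv(truth_path)
    matrix = pd.read_csv(art / "family_status.tsv", sep="\t", index_col=0)
    from .seqforge import load_seed_set

    seeds = load_seed_set(art / "seed_set.fasta", art / "seed_set.tsv")
    models_by_sp = {}
    for gff in sorted(art.glob("*.models.gff3")):
        sp = gff.name.split(".models.gff3")[0]
        models_by_sp[sp] = read_models_gff3(gff, art / f"{sp}.proteins.fasta")
    df = evaluate_run(models_by_sp, matrix, truth, seeds)
    df.to_csv(art / "evaluation.tsv", sep="\t", index=False)
    return df
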