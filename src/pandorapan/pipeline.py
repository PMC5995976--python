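"""End-to-end orchestration: simulate (or load) -> annotate -> cluster ->
pan-genome -> synteny -> duplication/dN-dS -> gene-origin battery ->
proteomics -> cladistics, with a single JSON summary.

Every stage receives an explicit seed derived from the master seed, so a
rerun with the same configuration is reproducible end to end.
"""

from __future__ import annotations

import json
import os
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd

from . import io as pio
from .annotate import AnnotationParams, CodonUsageTable, annotate_genome
from .cladistics import build_matrix, content_tree, superalignment_similarity, tree_newick
from .cluster import all_vs_all, build_clusters, membership_table, orthologs
from .denovo import (
    compare_disorder,
    gene_feature_rows,
    gradient_test,
    intergenic_feature_rows,
    intergenic_scan,
    positional_filter,
    subject_regions_from_annotation,
)
from .dnds import (
    clade_omega,
    closest_paralog_distances,
    copy_number_stats,
    distance_divergence_correlation,
)
from .models import GeneModel
from .pangenome import categorize, fit_heaps, fluidity, rarefaction, sharing_spectrum
from .proteomics import abundance_correlation, core_proteome, rank_and_cut
from .simulate import SimParams, SimulatedClade, simulate_clade
from .synteny import blocks_table, core_density_profile, pairwise_collinearity

ALL_STAGES = ("simulate", "annotate", "cluster", "pangenome", "synteny",
              "dnds", "denovo", "proteome", "cladistics")


def _stage_seed(master: int, stage: str) -> int:
    return (master * 1000003 + sum(ord(c) for c in stage)) % (2**31 - 1)


def match_to_truth(
    annotated: Mapping[str, list[GeneModel]],
    truth_genes: pd.DataFrame,
    min_overlap: float = 0.5,
) -> dict[str, str]:
    """Map annotated CDS ids to simulator truth gene ids by same-strand
    coordinate overlap of at least ``min_overlap`` of the truth span."""
    mapping: dict[str, str] = {}
    for genome_id, genes in annotated.items():
        truths = truth_genes[truth_genes.genome_id == genome_id]
        spans = [(r.start, r.end, r.strand, r.gene_id) for r in truths.itertuples()]
        for g in genes:
            if g.kind != "CDS":
                continue
            best, best_ov = None, 0.0
            for s, e, strand, gid in spans:
                if strand != g.strand:
                    continue
                ov = min(e, g.end) - max(s, g.start)
                if ov > best_ov and ov >= min_overlap * (e - s):
                    best, best_ov = gid, ov
            if best is not None:
                mapping[g.id] = best
    return mapping


def run_pipeline(config: Mapping[str, Any], outdir: str) -> dict[str, Any]:
    """Run the configured stages; returns (and writes) the summary dict."""
    os.makedirs(outdir, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", ALL_STAGES))
    summary: dict[str, Any] = {"seed": seed, "stages": stages}

    # ------------------------------------------------------------ inputs
    clade: Optional[SimulatedClade] = None
    if "simulate" in stages:
        sim_cfg = dict(config.get("simulate", {}))
        preset = sim_cfg.pop("preset", "small")
        sim_cfg.setdefault("seed", _stage_seed(seed, "simulate"))
        params = (SimParams.small(**sim_cfg) if preset == "small"
                  else SimParams(**sim_cfg))
        clade = simulate_clade(params)
        clade.write(os.path.join(outdir, "sim"))
        genomes = clade.genomes
        evidence = clade.evidence
        clade_map = clade.clade_map
        usage = CodonUsageTable.from_counts(clade.reference_usage,
                                            reference="simulated host usage")
        summary["simulate"] = {
            "n_strains": params.n_strains,
            "genome_lengths": {s: len(g) for s, g in genomes.items()},
            "genome_gc": {s: round(g.gc, 4) for s, g in genomes.items()},
            "n_truth_genes": int(len(clade.truth.genes)),
        }
    else:
        inputs = config["inputs"]
        genome_list = pio.read_fasta(inputs["genomes"])
        genomes = {g.id: g for g in genome_list}
        evidence = {
            s: pio.read_evidence_bundle(
                genomes[s], paths["coverage_plus"], paths["coverage_minus"],
                paths.get("junctions"), paths.get("peptides"),
            )
            for s, paths in inputs["evidence"].items()
        }
        clade_map = dict(
            pd.read_csv(inputs["clades"], sep="\t").set_index("genome_id")["clade"]
        )
        usage = CodonUsageTable.from_table(
            pio.read_table(inputs["codon_usage"]), reference=inputs["codon_usage"]
        )

    # ---------------------------------------------------------- annotate
    annotated: dict[str, list[GeneModel]] = {}
    if "annotate" in stages:
        ann_params = AnnotationParams(**config.get("annotation", {}))
        reports = {}
        for s in sorted(genomes):
            genes, report = annotate_genome(genomes[s], evidence[s],
                                            params=ann_params)
            annotated[s] = genes
            reports[s] = report
        pio.write_gff3(
            [g for s in sorted(annotated) for g in annotated[s]],
            os.path.join(outdir, "annotation.gff3"),
        )
        summary["annotate"] = {
            s: {
                "n_cds": r.n_cds, "n_lncrna": r.n_lncrna,
                "n_ab_initio": r.n_ab_initio,
                "fraction_transcribed": round(r.fraction_transcribed, 4),
                "fraction_translated": round(r.fraction_translated, 4),
                "intron_fraction": round(r.intron_fraction, 4),
            } for s, r in reports.items()
        }

    proteins: dict[str, str] = {}
    genome_of: dict[str, str] = {}
    for s in sorted(annotated):
        for g in annotated[s]:
            if g.kind == "CDS":
                proteins[g.id] = g.protein(genomes[s])
                genome_of[g.id] = s
    cds_orders = {
        s: [g.id for g in sorted(annotated[s], key=lambda x: x.start)
            if g.kind == "CDS"]
        for s in sorted(annotated)
    }

    # ----------------------------------------------------------- cluster
    membership = edges = clusters = groups = None
    if "cluster" in stages:
        cl_cfg = dict(config.get("clustering", {}))
        edges = all_vs_all(proteins, e_max=cl_cfg.get("e_max", 1e-5))
        clusters = build_clusters(
            edges, proteins, genome_of,
            min_identity=cl_cfg.get("min_identity", 0.35),
            min_coverage=cl_cfg.get("min_coverage", 0.7),
        )
        membership = membership_table(clusters, genome_of)
        pio.write_table(membership, os.path.join(outdir, "clusters.tsv"))
        _, groups = orthologs(edges, genome_of)
        summary["cluster"] = {
            "n_proteins": len(proteins),
            "n_clusters": len(clusters),
            "n_ortholog_groups": len(groups),
        }

    # --------------------------------------------------------- pangenome
    categorized = None
    if "pangenome" in stages and membership is not None:
        pg_cfg = config.get("pangenome", {})
        curve = rarefaction(membership, n_perm=pg_cfg.get("n_perm", 200),
                            seed=_stage_seed(seed, "pangenome"))
        pio.write_table(curve.summary(), os.path.join(outdir, "pangenome_curve.tsv"))
        heaps = fit_heaps(curve)
        fl = fluidity(membership)
        categorized = categorize(membership, clade_map)
        pio.write_table(categorized, os.path.join(outdir, "gene_categories.tsv"))
        pio.write_table(sharing_spectrum(membership),
                        os.path.join(outdir, "sharing_spectrum.tsv"))
        core_clusters = int(
            (categorized.groupby("cluster_id")["category"].first() == "core").sum()
        )
        summary["pangenome"] = {
            "heaps_alpha": round(heaps.alpha, 4),
            "heaps_kappa": round(heaps.kappa, 2),
            "open_pangenome": bool(heaps.open_pangenome),
            "fluidity": round(fl.phi, 4),
            "fluidity_jackknife_var": round(fl.jackknife_variance, 6),
            "n_core_clusters": core_clusters,
            "core_cluster_fraction": round(
                core_clusters / membership["cluster_id"].nunique(), 4
            ),
        }

    # ----------------------------------------------------------- synteny
    block_members: set[str] = set()
    if "synteny" in stages and groups is not None:
        sy_cfg = config.get("synteny", {})
        coll, all_blocks = pairwise_collinearity(
            groups, cds_orders,
            max_gap=sy_cfg.get("max_gap", 5), min_block=sy_cfg.get("min_block", 3),
        )
        pio.write_table(coll, os.path.join(outdir, "collinearity.tsv"))
        pio.write_table(blocks_table(all_blocks), os.path.join(outdir, "blocks.tsv"))
        for blocks in all_blocks.values():
            for blk in blocks:
                for a, b in blk.pairs:
                    block_members.add(a)
                    block_members.add(b)
        profiles = {}
        if categorized is not None:
            cat_of = dict(zip(categorized.gene_id, categorized.category))
            for s, order in cds_orders.items():
                _, split, delta = core_density_profile(
                    [cat_of.get(g, "unassigned") for g in order]
                )
                profiles[s] = {"split_index": split, "delta": round(delta, 4)}
        summary["synteny"] = {
            "mean_collinearity": round(float(coll["collinear_fraction"].mean()), 4),
            "per_pair": {
                f"{r.genome_a}-{r.genome_b}": round(r.collinear_fraction, 4)
                for r in coll.itertuples()
            },
            "core_density_changepoint": profiles,
        }

    # -------------------------------------------------------------- dnds
    if "dnds" in stages and membership is not None:
        per_genome, hist = copy_number_stats(membership)
        pio.write_table(per_genome, os.path.join(outdir, "copy_number.tsv"))
        pio.write_table(hist, os.path.join(outdir, "family_sizes.tsv"))
        dists = closest_paralog_distances(cds_orders, membership)
        pio.write_table(dists, os.path.join(outdir, "paralog_distances.tsv"))
        summary["dnds"] = {
            "multi_copy_fraction": {
                r.genome_id: round(r.multi_copy_fraction, 4)
                for r in per_genome.itertuples()
            },
            "closest_paralog_mode_distance": (
                int(dists["min_rank_distance"].mode().iloc[0]) if len(dists) else None
            ),
        }
        # divergence vs distance on closest paralog pairs, using edge identities
        if edges is not None and len(dists) >= 10:
            ident = {}
            for e in edges:
                ident[(e.query_id, e.subject_id)] = e.identity
                ident[(e.subject_id, e.query_id)] = e.identity
            div_rows = []
            for r in dists.itertuples():
                fam = membership[(membership.cluster_id == r.cluster_id)
                                 & (membership.genome_id == r.genome_id)]
                rank = {g: i for i, g in enumerate(cds_orders[r.genome_id])}
                members = sorted(fam["gene_id"], key=lambda g: rank.get(g, 0))
                best = None
                for i, a in enumerate(members):
                    for b in members[i + 1:]:
                        d = abs(rank[a] - rank[b])
                        if d == r.min_rank_distance and (a, b) in ident:
                            best = 1.0 - ident[(a, b)]
                            break
                    if best is not None:
                        break
                if best is not None:
                    div_rows.append((r.min_rank_distance, best))
            if len(div_rows) >= 10:
                pairs_df = pd.DataFrame(div_rows,
                                        columns=["min_rank_distance", "divergence"])
                rho, pval = distance_divergence_correlation(
                    pairs_df, seed=_stage_seed(seed, "dnds")
                )
                summary["dnds"]["distance_divergence_rho"] = round(rho, 4)
                summary["dnds"]["distance_divergence_p"] = round(pval, 4)
        # clade omega on a sample of ortholog groups
        if groups:
            n_grp = int(config.get("dnds", {}).get("n_omega_groups", 15))
            cds_of = {}
            for s in sorted(annotated):
                for g in annotated[s]:
                    if g.kind == "CDS":
                        cds_of[g.id] = g.coding_sequence(genomes[s])
            grp_cds = [
                {genome_of[gid]: cds_of[gid] for gid in grp.values()}
                for grp in groups[:n_grp]
                if len(grp) >= 4
            ]
            try:
                om_table, u_stat, p = clade_omega(
                    grp_cds, clade_map, seed=_stage_seed(seed, "omega")
                )
                pio.write_table(om_table, os.path.join(outdir, "clade_omega.tsv"))
                med = om_table.groupby("clade")["omega"].median()
                summary["dnds"]["clade_omega_medians"] = {
                    k: round(v, 4) for k, v in med.items()
                }
                summary["dnds"]["clade_omega_p"] = round(p, 4)
            except ValueError as exc:
                summary["dnds"]["clade_omega"] = f"skipped: {exc}"

    # ------------------------------------------------------------ denovo
    if "denovo" in stages and categorized is not None:
        cat_of = dict(zip(categorized.gene_id, categorized.category))
        feat_frames, ig_frames = [], []
        for s in sorted(annotated):
            cds_genes = [g for g in annotated[s] if g.kind == "CDS"]
            feat_frames.append(gene_feature_rows(cds_genes, genomes[s], cat_of, usage))
            ig_frames.append(intergenic_feature_rows(
                genomes[s], annotated[s], usage,
                seed=_stage_seed(seed, f"ig_{s}"),
            ))
        features = pd.concat([f for f in feat_frames if len(f)],
                             ignore_index=True)
        ig = pd.concat([f for f in ig_frames if len(f)], ignore_index=True)
        pio.write_table(features, os.path.join(outdir, "gene_features.tsv"))
        grad = gradient_test(features, ig)
        pio.write_table(grad, os.path.join(outdir, "gradient_test.tsv"))
        summary["denovo"] = {
            "gradient_verdicts": dict(zip(grad.feature, grad.verdict)),
        }
        pos_frames = []
        for s in sorted(annotated):
            ordered = sorted(
                (g for g in annotated[s] if g.kind == "CDS"), key=lambda g: g.start
            )
            pos_frames.append(positional_filter(ordered, cat_of, block_members))
        pos = pd.concat(pos_frames, ignore_index=True)
        pio.write_table(pos, os.path.join(outdir, "positional_filter.tsv"))
        summary["denovo"]["n_strain_specific"] = int(len(pos))
        summary["denovo"]["n_positional_ok"] = int(pos.positional_context_ok.sum())
        # disorder: strain-specific (young) vs core (old) proteins
        ss_prot = [proteins[g] for g, c in cat_of.items()
                   if c == "strain_specific" and g in proteins]
        core_prot = [proteins[g] for g, c in cat_of.items()
                     if c == "core" and g in proteins]
        if len(ss_prot) >= 5 and len(core_prot) >= 5:
            m_ss, m_core, p = compare_disorder(ss_prot, core_prot)
            summary["denovo"]["disorder_median_strain_specific"] = round(m_ss, 4)
            summary["denovo"]["disorder_median_core"] = round(m_core, 4)
            summary["denovo"]["disorder_p"] = round(p, 4)
        # intergenic homology scan for positionally anchored young genes
        dn_cfg = config.get("denovo", {})
        max_queries = int(dn_cfg.get("max_scan_queries", 30))
        ok_ids = set(pos.loc[pos.positional_context_ok, "gene_id"])
        queries = {}
        for s in sorted(annotated):
            for g in annotated[s]:
                if g.id in ok_ids and len(queries) < max_queries:
                    queries[g.id] = g.coding_sequence(genomes[s])
        regions = []
        for s in sorted(annotated):
            regions.extend(subject_regions_from_annotation(genomes[s], annotated[s]))
        hits = intergenic_scan(queries, regions,
                               e_max=dn_cfg.get("e_max", 1e-3),
                               query_genome_of=genome_of)
        pio.write_table(hits, os.path.join(outdir, "intergenic_scan.tsv"))
        summary["denovo"]["n_scan_queries"] = len(queries)
        summary["denovo"]["n_scan_hits"] = int(len(hits))

    # ---------------------------------------------------------- proteome
    if "proteome" in stages and clade is not None and membership is not None:
        pr_cfg = config.get("proteome", {})
        k = int(pr_cfg.get("k", 200))
        truth_map = match_to_truth(annotated, clade.truth.genes)
        cluster_by_truth = {}
        for r in membership.itertuples():
            t = truth_map.get(r.gene_id)
            if t is not None:
                cluster_by_truth[t] = r.cluster_id
        retained = {}
        rep_rs = {}
        for s in sorted(genomes):
            tab = clade.proteome[clade.proteome.strain == s].reset_index(drop=True)
            rp = rank_and_cut(tab, method=pr_cfg.get("method", "fixed"), k=k)
            retained[s] = rp.retained
            r1 = tab[["protein_id", "source", "ibaq_r1"]].rename(
                columns={"ibaq_r1": "ibaq"})
            r2 = tab[["protein_id", "source", "ibaq_r2"]].rename(
                columns={"ibaq_r2": "ibaq"})
            r, _, _ = abundance_correlation(r1, r2)
            rep_rs[s] = round(r, 4)
        partition, core_frac = core_proteome(retained, cluster_by_truth)
        pio.write_table(partition, os.path.join(outdir, "proteome_partition.tsv"))
        summary["proteome"] = {
            "replicate_pearson_r": rep_rs,
            "n_proteome_clusters": int(len(partition)),
            "n_shared_by_all": int(partition.shared_by_all.sum()),
            "core_proteome_fraction": round(core_frac, 4),
        }

    # -------------------------------------------------------- cladistics
    if "cladistics" in stages and membership is not None:
        cl_cfg = config.get("cladistics", {})
        matrix = build_matrix(membership)
        pio.write_table(matrix.reset_index(), os.path.join(outdir, "pa_matrix.tsv"))
        if len(matrix) >= 4:
            tree, support = content_tree(
                matrix, n_bootstrap=cl_cfg.get("n_bootstrap", 100),
                seed=_stage_seed(seed, "cladistics"),
            )
            with open(os.path.join(outdir, "content_tree.nwk"), "w") as fh:
                fh.write(tree_newick(tree) + "\n")
            summary["cladistics"] = {
                "tree": tree_newick(tree),
                "min_support": (round(min(support.values()), 3) if support else None),
            }
        if groups:
            n_grp = int(cl_cfg.get("n_superalignment_groups", 40))
            grp_prot = [
                {genome_of[gid]: proteins[gid] for gid in grp.values()}
                for grp in groups[:n_grp] if len(grp) >= 2
            ]
            ident, simil = superalignment_similarity(grp_prot)
            pio.write_table(ident.reset_index(names="genome"),
                            os.path.join(outdir, "superalignment_identity.tsv"))
            pio.write_table(simil.reset_index(names="genome"),
                            os.path.join(outdir, "superalignment_similarity.tsv"))
            off = ~np.eye(len(ident), dtype=bool)
            summary.setdefault("cladistics", {})["superalignment_similarity_range"] = [
                round(float(np.nanmin(simil.to_numpy()[off])), 2),
                round(float(np.nanmax(simil.to_numpy()[off])), 2),
            ]

    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
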