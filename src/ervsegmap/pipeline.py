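"""End-to-end orchestration: simulate -> cluster -> test -> landscape ->
associate -> report, with a reproducible run manifest."""
from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

import ervsegmap
from ervsegmap import io as eio
from ervsegmap import junctions, landscape, phylo_assoc, report, synthetic_data
from ervsegmap.config import LINES, RunConfig
from ervsegmap.difftest import LocusCountTable, run_differential_tests


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def loci_to_simple(loci):
    return [
        landscape.SimpleLocus(
            locus_id=l.locus_id,
            chromosome=l.chromosome,
            start=l.start,
            end=l.end,
            orientation=l.orientation,
        )
        for l in loci
    ]


def build_count_tables(loci, line_totals, relaxed: bool = True):
    """Per-locus contingency inputs from clustered loci and line totals."""
    totals = tuple(int(line_totals[f"total_pairs_{l}"]) for l in LINES)
    tables = []
    for loc in loci:
        counts = loc.per_line_counts_relaxed if relaxed else loc.per_line_counts
        tables.append(
            LocusCountTable(
                locus_id=loc.locus_id,
                counts=tuple(int(c) for c in counts),
                line_totals=totals,
            )
        )
    return tables


def match_loci_to_truth(loci, truth, tolerance: int = 3_500):
    """Greedy one-to-one matching of called loci to simulated insertions.

    A call matches a truth record when its junction estimates — the
    junction-facing edges of the two clusters (upstream cluster end,
    downstream cluster start) — both lie within ``tolerance`` bases of
    the truth junctions. Anchors sit up to a mate-pair insert away from
    the junction on the outer side, so the inner cluster edges are the
    span endpoints that localize the insertion. Returns {insertion_id:
    locus_id} for the matched subset.
    """
    matched = {}
    used = set()
    for t in truth:
        ts, te = t.reference_span
        best = None
        for loc in loci:
            if loc.locus_id in used or loc.chromosome != t.chromosome:
                continue
            up_edge = loc.upstream_cluster.end
            down_edge = loc.downstream_cluster.start
            if abs(up_edge - ts) <= tolerance and abs(down_edge - te) <= tolerance:
                d = abs(up_edge - ts) + abs(down_edge - te)
                if best is None or d < best[0]:
                    best = (d, loc.locus_id)
        if best is not None:
            matched[t.insertion_id] = best[1]
            used.add(best[1])
    return matched


def run_all(config: RunConfig, outdir) -> dict:
    """Execute every stage on a fresh simulated dataset; write a manifest.

    The manifest records package version, seed, all parameter values,
    input checksums, and per-stage record counts. Returns the manifest
    dict (also written to ``manifest.json`` in ``outdir``).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation

    manifest: dict = {
        "package": "ervsegmap",
        "version": ervsegmap.__version__,
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": sim.seed,
        "parameters": config.to_dict(),
        "stages": {},
    }
    manifest_path = outdir / "manifest.json"

    def _halt(stage, err):
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
        raise

    # -- simulate ----------------------------------------------------------
    try:
        truth, genome, library = synthetic_data.simulate_truth(sim)
        records = synthetic_data.simulate_mate_pairs(truth, sim, library, genome)
        paths = synthetic_data.write_fixtures(
            truth, records, sim, outdir / "fixtures", genome=genome, library=library
        )
        manifest["inputs"] = {k: _sha256(p) for k, p in sorted(paths.items())}
        manifest["stages"]["simulate"] = {
            "insertions": len(truth),
            "read_pairs": int(len(records)),
        }
    except Exception as err:  # pragma: no cover - defensive
        _halt("simulate", err)

    erv_lengths = {k: len(v) for k, v in library.items()}

    # -- cluster -----------------------------------------------------------
    try:
        pairs = junctions.select_strict_pairs(records, score_min=config.score_min)
        clusters = junctions.cluster_junctions(
            pairs,
            max_window=config.window,
            min_footprint_frac=config.footprint_frac,
            read_len=sim.read_length,
        )
        loci, half = junctions.pair_junctions(
            clusters,
            max_separation=config.max_sep,
            erv_lengths=erv_lengths if config.require_flank_evidence else None,
            ltr_length=sim.ltr_length,
            read_len=sim.read_length,
        )
        loci = junctions.append_relaxed_reads(
            loci, records, relaxed_min=config.relaxed_min, score_min=config.score_min
        )
        eio.write_loci(loci, outdir / "loci.bed")
        manifest["stages"]["cluster"] = {
            "strict_pairs": len(pairs),
            "junction_clusters": len(clusters),
            "candidate_loci": len(loci),
            "half_supported": len(half),
        }
    except Exception as err:  # pragma: no cover
        _halt("cluster", err)

    # -- test --------------------------------------------------------------
    try:
        line_totals = eio.read_stats(paths["stats"])
        tables = build_count_tables(loci, line_totals)
        matched = match_loci_to_truth(loci, truth, tolerance=sim.insert_mean)
        in_ref = {
            matched[t.insertion_id]: t.in_reference
            for t in truth
            if t.insertion_id in matched
        }
        results, threshold = run_differential_tests(
            tables,
            alpha=config.alpha,
            fisher_cutoff=config.fisher_cutoff,
            in_reference=in_ref,
        )
        res_df = pd.DataFrame(
            [
                {
                    "locus_id": r.locus_id,
                    "count_H": r.counts[0],
                    "count_L": r.counts[1],
                    "count_W": r.counts[2],
                    "test": r.test_used,
                    "p_value": r.p_value,
                    "significant": r.significant,
                    "pattern": r.pattern,
                    "in_reference": r.in_reference,
                    "polarity": (
                        f"{r.polarity.kind}@{r.polarity.branch}"
                        if r.polarity and r.polarity.branch
                        else (r.polarity.kind if r.polarity else "")
                    ),
                }
                for r in results
            ]
        )
        res_df.to_csv(outdir / "results.tsv", sep="\t", index=False)
        n_sig = sum(r.significant and r.pattern != "HLW" for r in results)
        manifest["stages"]["test"] = {
            "loci_tested": len(results),
            "bonferroni_threshold": threshold,
            "nominal_differences": sum(
                r.pattern not in (None, "HLW") for r in results
            ),
            "corrected_significant": n_sig,
        }
    except Exception as err:  # pragma: no cover
        _halt("test", err)

    # -- landscape ---------------------------------------------------------
    try:
        genes = eio.read_genes_bed12(paths["genes"])
        simple = loci_to_simple(loci)
        relations = landscape.intersect_genes(
            simple, genes, flank=config.flank, bin_size=config.bin_size
        )
        profile = landscape.orientation_profile(relations)
        sweeps = eio.read_bed3(paths["sweeps"])
        genome_size = sim.n_chromosomes * sim.chromosome_length
        sig_loci = {r.locus_id for r in results if r.significant and r.pattern != "HLW"}
        sweep_res = landscape.sweep_overlap_test(
            [s for s in simple if s.locus_id in sig_loci], sweeps, genome_size
        )
        landscape.export_gene_lists(relations, results, outdir / "gene_lists")
        manifest["stages"]["landscape"] = {
            "gene_relations": len(relations),
            "intragenic": sum(r.relation == "intragenic" for r in relations),
            "sweep_overlap": sweep_res,
            "intragenic_antisense_fraction": profile[
                "intragenic_antisense_fraction"
            ],
        }
    except Exception as err:  # pragma: no cover
        _halt("landscape", err)

    # -- associate ---------------------------------------------------------
    try:
        assignments = [
            phylo_assoc.assign_best_erv(loc, records) for loc in loci
        ]
        newick = Path(paths["tree"]).read_text()
        annotated, tip_table, warns = phylo_assoc.annotate_tree(
            newick, assignments, results
        )
        (outdir / "erv_tree_annotated.nwk").write_text(annotated)
        pd.DataFrame(tip_table).to_csv(
            outdir / "tree_tips.tsv", sep="\t", index=False
        )
        manifest["stages"]["associate"] = {
            "assigned_loci": len(assignments),
            "annotated_tips": len(tip_table),
            "warnings": len(warns),
        }
    except Exception as err:  # pragma: no cover
        _halt("associate", err)

    # -- report ------------------------------------------------------------
    try:
        gene_adj = {}
        for rel in relations:
            gene_adj.setdefault(rel.locus_id, set()).add(rel.gene_id)
        summary = report.summarize(results, gene_adjacency=gene_adj)
        summary.to_frame().to_csv(outdir / "summary.tsv", sep="\t", index=False)
        eio.write_json(summary.venn_counts(), outdir / "venn.json")
        recall_denom = sum(
            1 for t in truth if max(t.per_line_pool_dosage) > 0
        )
        manifest["stages"]["report"] = {
            "candidate_loci": summary.total_candidate_loci,
            "nominal_differences": summary.total_differential_loci,
            "corrected_significant": summary.total_corrected_loci,
            "gene_adjacent_loci": summary.total_ervs_adjacent_to_genes,
            "truth_recovered": len(matched),
            "truth_detectable": recall_denom,
        }
    except Exception as err:  # pragma: no cover
        _halt("report", err)

    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
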