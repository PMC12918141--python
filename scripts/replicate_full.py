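#!/usr/bin/env python
"""Full-data replication driver (requires externally downloaded inputs).

This script reproduces the published full-scale comparison numbers — the
per-dataset ubiquitous counts, cross-dataset Spearman correlations, sector
proportions, weight-sensitivity overlaps, housekeeping-list overlap metrics,
the per-gene report for common reference genes, and the ubiquity-persistence
percentages in an external validation dataset — once the user has obtained
the source data (none of which is bundled here):

* GTEx v8 raw read counts (GCT) + gene lengths (Ensembl)  -> "GTEx (all)"
* GTEx v8 median-TPM-per-tissue matrix (GCT or TSV)       -> "GTEx (tissues)"
* Human Protein Atlas consensus tissue expression (TSV)   -> "HPA (tissues)"
* curated CMap drug-response summary table (TSV)          -> "CMap"
* TCGA glioma expression counts (TSV) + gene lengths      -> "Glioma (TCGA)"
* published housekeeping-gene lists (one Ensembl ID per line)

Not part of the test suite: it requires multi-GB downloads and hours of CPU.

Example:
    python scripts/replicate_full.py \
        --gtex-counts GTEx_counts.gct --gene-lengths lengths.tsv \
        --gtex-tissues GTEx_median_tpm.gct --hpa hpa_consensus.tsv \
        --cmap-matrix cmap_expression.tsv --cmap-stats cmap_stats.tsv \
        --glioma-counts tcga_glioma_counts.tsv \
        --hk-lists warrington.txt zhu.txt eisenberg.txt chang.txt joshi.txt \
        --out-dir replication/
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from ubigen.formats_io import (
    read_drug_stats,
    read_expression_tsv,
    read_gct,
    read_gene_lengths,
    read_gene_list,
    write_scores,
)
from ubigen.normalization import getmm_normalize
from ubigen.ranking_classification import (
    classify_sectors,
    gene_report,
    list_sector_profile,
    multi_list_intersections,
    spearman_rho,
    ubiquitous_set,
)
from ubigen.scoring_core import ScoringConfig, compose_scores
from ubigen.sensitivity import top_set_overlap, weight_grid


def load_matrix(path: str):
    return read_gct(path) if path.endswith(".gct") else read_expression_tsv(path)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__,
                                     formatter_class=argparse.RawDescriptionHelpFormatter)
    parser.add_argument("--gtex-counts", required=True)
    parser.add_argument("--gene-lengths", required=True)
    parser.add_argument("--gtex-tissues")
    parser.add_argument("--hpa")
    parser.add_argument("--cmap-matrix", required=True)
    parser.add_argument("--cmap-stats", required=True)
    parser.add_argument("--glioma-counts")
    parser.add_argument("--hk-lists", nargs="*", default=[])
    parser.add_argument("--out-dir", type=Path, required=True)
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}
    config = ScoringConfig()

    lengths = read_gene_lengths(args.gene_lengths)
    datasets = {}
    datasets["gtex_all"] = getmm_normalize(load_matrix(args.gtex_counts), lengths)
    datasets["cmap"] = load_matrix(args.cmap_matrix)
    if args.gtex_tissues:
        datasets["gtex_tissues"] = load_matrix(args.gtex_tissues)
    if args.hpa:
        datasets["hpa_tissues"] = load_matrix(args.hpa)
    if args.glioma_counts:
        datasets["glioma"] = getmm_normalize(load_matrix(args.glioma_counts), lengths)

    tables = {}
    for name, matrix in datasets.items():
        tables[name] = compose_scores(matrix, config)
        write_scores(tables[name], args.out_dir / f"scores_{name}.tsv")
        results[f"ubiquitous_count_{name}"] = len(ubiquitous_set(tables[name]))
        results[f"n_genes_{name}"] = len(tables[name])

    for name in datasets:
        if name != "gtex_all":
            results[f"spearman_gtex_all_vs_{name}"] = spearman_rho(
                tables["gtex_all"], tables[name]
            )

    sec = classify_sectors(tables["gtex_all"], tables["cmap"])
    counts = sec.counts()
    n_shared = len(sec.shared_genes)
    results["n_shared_gtex_cmap"] = n_shared
    results["sector_pct"] = {s: 100 * c / n_shared for s, c in counts.items()}
    sec.data.to_csv(args.out_dir / "sectors_gtex_cmap.tsv", sep="\t")

    grid = weight_grid(config.weights, rel_range=0.20, points_per_axis=11)
    results["sensitivity_overlap_pct"] = 100 * top_set_overlap(
        datasets["gtex_all"], config, grid
    )
    results["sensitivity_overlap_sector11_pct"] = 100 * top_set_overlap(
        datasets["gtex_all"], config, grid, restrict_to=sec.genes_in("11")
    )

    if args.hk_lists:
        lists = [read_gene_list(p) for p in args.hk_lists]
        results["hk_intersections"] = multi_list_intersections(lists)
        for gl in lists:
            profile = list_sector_profile(gl, sec)
            results[f"hk_{gl.name}_pct_in_11"] = 100 * profile.loc["11", "fraction_of_list"]
        common = frozenset.intersection(*(gl.gene_ids for gl in lists))
        report = gene_report(sorted(common), tables, sectors=sec)
        report.to_csv(args.out_dir / "common_reference_gene_report.tsv",
                      sep="\t", index=False)

    if "glioma" in tables:
        eleven = sec.genes_in("11")
        ten_eleven = eleven | sec.genes_in("10")
        glioma_ubiq = ubiquitous_set(tables["glioma"])
        results["glioma_pct_sector11_still_ubiquitous"] = (
            100 * len(eleven & glioma_ubiq) / len(eleven)
        )
        results["glioma_pct_sector10_11_still_ubiquitous"] = (
            100 * len(ten_eleven & glioma_ubiq) / len(ten_eleven)
        )

    (args.out_dir / "replication.json").write_text(
        json.dumps(results, indent=2, default=str) + "\n"
    )
    print(json.dumps(results, indent=2, default=str))


if __name__ == "__main__":
    main()
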