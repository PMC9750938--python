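#!/usr/bin/env python
"""Genotype QC and collapsing of qualifying variants to gene carriers.

Reads the cohort written by 01_simulate_cohort.py, applies the genotype
filters (SNV DP<7 & GQ<20, indel DP<10 & GQ<20, het-SNV allele-balance
binomial p <= 1e-3, variant missingness > 50%), prioritizes one
annotation per variant, assigns variants to the ten collapsing masks
(5 functional classes x {MAF<0.1%, singleton}) and writes the per-mask
carrier table.
"""

import sys
from pathlib import Path

from burdenmr import annotate
from burdenmr import io as bio

IN = Path("results/cohort")
OUT = Path("results/qc")


def main() -> None:
    variants, gtab = bio.read_vcf(IN / "genotypes.vcf")
    annotations = bio.read_table(IN / "annotations.tsv", bio.ANNOTATION_SCHEMA)
    gene_map = annotate.prioritize_annotations(annotations)
    variants = variants.merge(gene_map[["variant_id", "gene"]],
                              on="variant_id", how="left")

    kept, kept_gtab, report = bio.qc_genotypes(variants, gtab)
    OUT.mkdir(parents=True, exist_ok=True)
    bio.write_table(report, OUT / "qc_report.tsv")
    print(f"QC: {len(variants)} variants in, {len(kept)} kept "
          f"({len(variants) - len(kept)} dropped for missingness > 50%)")
    print(f"  genotypes set missing by DP/GQ: {kept_gtab.n_dpgq_missing}")
    print(f"  het SNVs set missing by allele balance: {kept_gtab.n_ab_missing}")

    matrices, cmafs, diag = bio.collapse_all_masks(kept, kept_gtab, annotations)
    bio.write_carriers(OUT / "carriers.tsv", matrices)
    bio.write_table(kept, OUT / "variants.qc.tsv")
    for mask, cm in matrices.items():
        print(f"  mask {mask}: {len(cm.genes)} genes with qualifying variants, "
              f"{int(cm.matrix.sum())} carrier flags")
    if diag.total():
        print(f"  variants skipped for missing scores: {diag.total()}")
    print(f"wrote {OUT}/carriers.tsv, qc_report.tsv")


if __name__ == "__main__":
    sys.exit(main())
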