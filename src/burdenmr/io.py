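"""File formats, configuration and the end-to-end pipeline.

Formats (all plain text, UTF-8, tab-delimited, ``.`` for missing values;
coordinates 1-based inclusive, VCF convention):

* minimal VCF v4.2 subset: CHROM/POS/ID/REF/ALT/QUAL/FILTER/INFO(AC,AN),
  FORMAT ``GT:DP:GQ:AD`` (read back through cyvcf2);
* annotation TSV (one row per variant x transcript);
* phenotype/covariate TSV;
* GWAS summary-statistic TSV (snp, ea, oa, eaf, beta, se, n);
* carrier TSV (long form: mask, gene, sample for carriers only).

``run_pipeline`` ties the stages together in QC -> annotate -> collapse ->
test -> diagnostics order, emits result tables plus a run manifest with
the seed, thresholds and conserved per-stage variant counts.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from . import __version__, annotate, burden, coloc, genoqc, mr, simcohort
from .errors import ConfigError, DataError


# ---------------------------------------------------------------------------
# table schemas


@dataclass(frozen=True)
class TableSchema:
    name: str
    required: tuple[str, ...]
    numeric: tuple[str, ...] = ()
    allele_cols: tuple[str, ...] = ()


ANNOTATION_SCHEMA = TableSchema(
    "annotation",
    required=("variant_id", "gene", "transcript", "protein_coding",
              "mane_select", "canonical", "consequence"),
    numeric=("revel", "cadd", "protein_pos"),
)
PHENOTYPE_SCHEMA = TableSchema(
    "phenotype",
    required=("sample",),
    numeric=("t2d", "quant", "age", "sex") + tuple(f"pc{i+1}" for i in range(10)),
)
SUMMARY_STAT_SCHEMA = TableSchema(
    "summary-stat",
    required=("snp", "ea", "oa", "eaf", "beta", "se", "n"),
    numeric=("eaf", "beta", "se", "n"),
    allele_cols=("ea", "oa"),
)
VARIANT_SCHEMA = TableSchema(
    "variant",
    required=("variant_id", "chrom", "pos", "ref", "alt", "gene", "ac", "an"),
    numeric=("pos", "ac", "an", "maf"),
    allele_cols=("ref", "alt"),
)
CARRIER_SCHEMA = TableSchema("carrier", required=("mask", "gene", "sample"))
TRACK_SCHEMA = TableSchema(
    "coloc-track", required=("snp", "beta", "se"), numeric=("beta", "se")
)


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read a TSV against a schema; schema violations name line and column."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"{schema.name} table not found: {path}")
    df = pd.read_csv(path, sep="\t", na_values=".", keep_default_na=True,
                     dtype={c: str for c in schema.allele_cols})
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    for col in schema.allele_cols:
        bad = ~df[col].fillna("").str.fullmatch(r"[ACGTacgt]+")
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header is line 1
            raise DataError(f"{path}: line {line}: malformed allele in column {col!r}")
    for col in schema.numeric:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise DataError(f"{path}: line {line}: non-numeric value in column {col!r}")
        df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=".")


# ---------------------------------------------------------------------------
# VCF subset


_GT_STR = {genoqc.HOM_REF: "0/0", genoqc.HET: "0/1",
           genoqc.HOM_ALT: "1/1", genoqc.MISSING: "./."}


def write_vcf(path: str | Path, variants: pd.DataFrame,
              gtab: simcohort.GenotypeTable) -> None:
    """Write the minimal VCF subset (GT:DP:GQ:AD, INFO AC/AN)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    order = np.lexsort((variants["pos"].to_numpy(),
                        variants["chrom"].to_numpy()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=burdenmr-{__version__}\n")
        for chrom in pd.unique(variants["chrom"].to_numpy()[order]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Alt allele count">\n')
        fh.write('##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gtab.samples) + "\n")
        vid_to_row = {v: i for i, v in enumerate(gtab.variant_ids)}
        for oi in order:
            row = variants.iloc[oi]
            ri = vid_to_row[row["variant_id"]]
            gt, dp, gq = gtab.gt[ri], gtab.dp[ri], gtab.gq[ri]
            adr, ada = gtab.ad_ref[ri], gtab.ad_alt[ri]
            fields = [
                f"{_GT_STR[g]}:{d}:{q}:{r},{a}"
                for g, d, q, r, a in zip(gt, dp, gq, adr, ada)
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t"
                f"{row['ref']}\t{row['alt']}\t.\tPASS\t"
                f"AC={row['ac']};AN={row['an']}\tGT:DP:GQ:AD\t" + "\t".join(fields) + "\n"
            )


def read_vcf(path: str | Path) -> tuple[pd.DataFrame, simcohort.GenotypeTable]:
    """Read the VCF subset back into (variant table, genotype table)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"VCF not found: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, gts, dps, gqs, adrs, adas = [], [], [], [], [], []
    gt_map = {0: genoqc.HOM_REF, 1: genoqc.HET, 3: genoqc.HOM_ALT, 2: genoqc.MISSING}
    for v in vcf:
        if len(v.ALT) != 1:
            raise DataError(f"{path}: {v.CHROM}:{v.POS} is not biallelic")
        vid = v.ID or f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
        rows.append(
            dict(variant_id=vid, chrom=v.CHROM, pos=v.POS, ref=v.REF,
                 alt=v.ALT[0], ac=int(v.INFO.get("AC", 0)),
                 an=int(v.INFO.get("AN", 0)))
        )
        gts.append([gt_map[t] for t in v.gt_types])
        dps.append(np.maximum(v.format("DP")[:, 0], 0))
        gqs.append(np.maximum(v.format("GQ")[:, 0], 0))
        ad = v.format("AD")
        adrs.append(np.maximum(ad[:, 0], 0))
        adas.append(np.maximum(ad[:, 1], 0))
    variants = pd.DataFrame(rows)
    gtab = simcohort.GenotypeTable(
        samples,
        list(variants["variant_id"]) if len(variants) else [],
        np.asarray(gts, dtype=np.int8).reshape(len(rows), len(samples)),
        np.asarray(dps, dtype=np.int16).reshape(len(rows), len(samples)),
        np.asarray(gqs, dtype=np.int16).reshape(len(rows), len(samples)),
        np.asarray(adrs, dtype=np.int16).reshape(len(rows), len(samples)),
        np.asarray(adas, dtype=np.int16).reshape(len(rows), len(samples)),
    )
    return variants, gtab


def write_carriers(path: str | Path,
                   matrices: Mapping[str, burden.CarrierMatrix]) -> None:
    rows = []
    for mask_name, cm in matrices.items():
        gidx, sidx = np.nonzero(cm.matrix)
        for g, s in zip(gidx, sidx):
            rows.append((mask_name, cm.genes[g], cm.samples[s]))
    write_table(pd.DataFrame(rows, columns=["mask", "gene", "sample"]), path)


def read_carriers(path: str | Path,
                  samples: Sequence[str]) -> dict[str, burden.CarrierMatrix]:
    df = read_table(path, CARRIER_SCHEMA)
    sample_idx = {s: i for i, s in enumerate(samples)}
    out: dict[str, burden.CarrierMatrix] = {}
    for mask_name, sub in df.groupby("mask", sort=True):
        genes = sorted(sub["gene"].unique())
        gene_idx = {g: i for i, g in enumerate(genes)}
        matrix = np.zeros((len(genes), len(samples)), dtype=bool)
        for g, s in zip(sub["gene"], sub["sample"]):
            if s not in sample_idx:
                raise DataError(f"{path}: unknown sample {s}")
            matrix[gene_idx[g], sample_idx[s]] = True
        out[str(mask_name)] = burden.CarrierMatrix(
            str(mask_name), genes, list(samples), matrix
        )
    return out


# ---------------------------------------------------------------------------
# pipeline configuration


_TOP_KEYS = {"seed", "out_dir", "log_level", "simulate", "inputs", "qc",
             "screen", "mr", "coloc"}
_SIM_KEYS = {"n_samples", "n_genes", "mean_variants_per_gene", "singleton_fraction",
             "baseline_prevalence", "causal_genes", "maf_max"}
_INPUT_KEYS = {"genotype_vcf", "annotation_tsv", "phenotype_tsv",
               "mr_exposure_tsv", "mr_outcome_tsv", "coloc_track1_tsv",
               "coloc_track2_tsv"}
_QC_KEYS = {"gate"}
_SCREEN_KEYS = {"significance", "carrier_floor", "gate", "sample_exclusions"}
_MR_KEYS = {"n_instruments", "theta", "pleiotropy_mean", "pleiotropy_sd",
            "reverse_causal_fraction", "seed"}
_COLOC_KEYS = {"n_snps", "shared", "p1", "p2", "p12"}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results/pipeline"
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)
    mr: dict = field(default_factory=dict)
    coloc: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key, allowed in (("simulate", _SIM_KEYS), ("inputs", _INPUT_KEYS),
                             ("qc", _QC_KEYS), ("screen", _SCREEN_KEYS),
                             ("mr", _MR_KEYS), ("coloc", _COLOC_KEYS)):
            section = raw.get(key) or {}
            bad = set(section) - allowed
            if bad:
                raise ConfigError(f"unknown keys in {key!r}: {sorted(bad)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.qc.get("gate", "and") not in ("and", "or"):
            raise ConfigError("qc.gate must be 'and' or 'or'")
        if not self.simulate:
            for key in ("genotype_vcf", "annotation_tsv", "phenotype_tsv"):
                if key not in self.inputs:
                    raise ConfigError(f"inputs.{key} is required when not simulating")
                if not Path(self.inputs[key]).exists():
                    raise ConfigError(f"inputs.{key}: no such file {self.inputs[key]}")

    def cohort_config(self) -> simcohort.CohortConfig:
        sim = dict(self.simulate)
        causal = tuple(
            simcohort.CausalGene(**c) for c in sim.pop("causal_genes", [])
        )
        return simcohort.CohortConfig(seed=self.seed, causal_genes=causal, **sim)

    def screen_config(self) -> burden.ScreenConfig:
        s = dict(self.screen)
        excl = tuple(s.pop("sample_exclusions", ()))
        return burden.ScreenConfig(sample_exclusions=excl, **s)


# ---------------------------------------------------------------------------
# stages


def qc_genotypes(
    variants: pd.DataFrame,
    gtab: simcohort.GenotypeTable,
    gate: str = "and",
) -> tuple[pd.DataFrame, simcohort.GenotypeTable, pd.DataFrame]:
    """Genotype-level QC: DP/GQ filter, allele-balance test, missingness.

    Returns (kept variant table with recomputed AC/AN/MAF, filtered
    genotype table, per-variant QC report).
    """
    is_indel = (
        variants["ref"].str.len() != variants["alt"].str.len()
    ).to_numpy() | (variants["ref"].str.len() > 1).to_numpy()
    gt1 = genoqc.filter_genotypes(gtab.gt, gtab.dp, gtab.gq, is_indel, gate=gate)
    n_dpgq = int(((gt1 == genoqc.MISSING) & (gtab.gt != genoqc.MISSING)).sum())
    gt2 = genoqc.apply_allele_balance(gt1, gtab.ad_ref, gtab.ad_alt, is_indel)
    n_ab = int(((gt2 == genoqc.MISSING) & (gt1 != genoqc.MISSING)).sum())
    keep, miss = genoqc.apply_variant_missingness(gt2)
    ac, an = genoqc.allele_counts(gt2)
    report = pd.DataFrame(
        {
            "variant_id": gtab.variant_ids,
            "n_dpgq_missing": ((gt1 == genoqc.MISSING) & (gtab.gt != genoqc.MISSING)).sum(axis=1),
            "n_ab_missing": ((gt2 == genoqc.MISSING) & (gt1 != genoqc.MISSING)).sum(axis=1),
            "missingness": miss,
            "kept": keep,
        }
    )
    out_variants = variants.copy()
    out_variants["ac"] = ac
    out_variants["an"] = an
    out_variants["maf"] = genoqc.minor_allele_frequency(ac, an)
    out_variants["missingness"] = miss
    out_variants = out_variants[keep].reset_index(drop=True)
    kept_gtab = simcohort.GenotypeTable(
        gtab.samples,
        [v for v, k in zip(gtab.variant_ids, keep) if k],
        gt2[keep], gtab.dp[keep], gtab.gq[keep],
        gtab.ad_ref[keep], gtab.ad_alt[keep],
    )
    kept_gtab.n_dpgq_missing = n_dpgq  # type: ignore[attr-defined]
    kept_gtab.n_ab_missing = n_ab  # type: ignore[attr-defined]
    return out_variants, kept_gtab, report


def collapse_all_masks(
    variants: pd.DataFrame,
    gtab: simcohort.GenotypeTable,
    annotations: pd.DataFrame,
    masks: Sequence[annotate.MaskSpec] | None = None,
) -> tuple[dict[str, burden.CarrierMatrix], dict[tuple[str, str], float], annotate.MaskDiagnostics]:
    """Prioritize annotations, resolve mask membership and collapse carriers.

    Returns (mask -> CarrierMatrix, (mask, gene) -> cMAF, diagnostics).
    """
    masks = list(masks) if masks is not None else annotate.default_masks()
    pri = annotate.prioritize_annotations(annotations)
    pri = pri[pri["variant_id"].isin(variants["variant_id"])]
    merged = variants.merge(
        pri.drop(columns=["gene"]), on="variant_id", how="left"
    )
    merged["var_class"] = merged["var_class"].fillna("other")
    member, diag = annotate.mask_variant_table(
        merged.rename(columns={"var_class": "var_class"}),
        ac=pd.Series(variants["ac"].to_numpy(), index=variants["variant_id"]),
        an=pd.Series(variants["an"].to_numpy(), index=variants["variant_id"]),
        masks=masks,
    )
    matrices: dict[str, burden.CarrierMatrix] = {}
    cmafs: dict[tuple[str, str], float] = {}
    maf = variants.set_index("variant_id")["maf"]
    genes_arr = variants["gene"].to_numpy()
    for mask in masks:
        qualifying = member[mask.name].to_numpy()
        cm = burden.collapse_gene_carriers(
            gtab.gt, genes_arr, qualifying, gtab.samples, mask.name
        )
        matrices[mask.name] = cm
        qual_vids = variants.loc[qualifying, ["variant_id", "gene"]]
        for gene, sub in qual_vids.groupby("gene"):
            cmafs[(mask.name, str(gene))] = float(maf[sub["variant_id"]].sum())
    return matrices, cmafs, diag


def export_diagnostics(
    results: pd.DataFrame,
    lambdas: Mapping[str, float],
    out_dir: str | Path,
) -> None:
    """Write QQ, Manhattan-style and lambda TSVs behind the screen plots."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lam = pd.DataFrame(
        {"mask": list(lambdas), "lambda": [lambdas[m] for m in lambdas]}
    )
    write_table(lam, out / "lambda.tsv")
    qq_rows = []
    if len(results):
        for mask_name, sub in results.groupby("mask"):
            p = np.sort(sub["p"].dropna().to_numpy())
            n = len(p)
            exp = (np.arange(1, n + 1) - 0.5) / n
            for o, e in zip(p, exp):
                qq_rows.append((mask_name, -np.log10(e), -np.log10(max(o, 1e-300))))
    write_table(
        pd.DataFrame(qq_rows, columns=["mask", "expected_nlog10p", "observed_nlog10p"]),
        out / "qq.tsv",
    )
    man_cols = ["gene", "mask", "p", "beta", "carriers", "significant"]
    man = results[man_cols] if len(results) else pd.DataFrame(columns=man_cols)
    write_table(man, out / "manhattan.tsv")


def run_pipeline(config: PipelineConfig) -> dict:
    """Full pipeline: simulate/read -> QC -> collapse -> screen -> MR/coloc.

    Deterministic given ``config.seed``. Returns the run manifest (also
    written to ``<out_dir>/manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    if config.simulate:
        cc = config.cohort_config()
        variants, gtab, annotations, covariates = simcohort.simulate_cohort(cc)
        write_vcf(out / "genotypes.vcf", variants, gtab)
        write_table(annotations, out / "annotations.tsv")
        carriers_true = {}
        # carriers of the injected qualifying variants drive the phenotype
        for causal in cc.causal_genes:
            idx = np.flatnonzero(
                (variants["gene"] == causal.gene) & variants["injected"]
            )
            carriers_true[causal.gene] = (gtab.gt[idx] > 0).any(axis=0)
        phenotype = simcohort.simulate_phenotypes(carriers_true, covariates, cc)
        pheno_table = covariates.merge(phenotype, on="sample")
        write_table(pheno_table, out / "phenotypes.tsv")
        variants_in, gtab_in = read_vcf(out / "genotypes.vcf")
        variants_in = variants_in.merge(
            variants[["variant_id", "gene"]], on="variant_id"
        )
        annotations_in = read_table(out / "annotations.tsv", ANNOTATION_SCHEMA)
        pheno_in = read_table(out / "phenotypes.tsv", PHENOTYPE_SCHEMA)
    else:
        variants_in, gtab_in = read_vcf(config.inputs["genotype_vcf"])
        annotations_in = read_table(config.inputs["annotation_tsv"], ANNOTATION_SCHEMA)
        pheno_in = read_table(config.inputs["phenotype_tsv"], PHENOTYPE_SCHEMA)
        gene_map = annotate.prioritize_annotations(annotations_in)
        variants_in = variants_in.merge(
            gene_map[["variant_id", "gene"]], on="variant_id", how="left"
        )
    if list(pheno_in["sample"]) != list(gtab_in.samples):
        raise DataError("phenotype samples do not match VCF samples")

    n_in = len(variants_in)
    kept_variants, kept_gtab, qc_report = qc_genotypes(
        variants_in, gtab_in, gate=config.qc.get("gate", "and")
    )
    write_table(qc_report, out / "qc_report.tsv")
    manifest["stages"]["qc"] = {
        "variants_in": n_in,
        "variants_kept": len(kept_variants),
        "variants_dropped": n_in - len(kept_variants),
        "genotypes_set_missing_dpgq": getattr(kept_gtab, "n_dpgq_missing", None),
        "genotypes_set_missing_allele_balance": getattr(kept_gtab, "n_ab_missing", None),
    }

    matrices, cmafs, diag = collapse_all_masks(
        kept_variants, kept_gtab, annotations_in
    )
    write_carriers(out / "carriers.tsv", matrices)
    manifest["stages"]["collapse"] = {
        "masks": {m: len(cm.genes) for m, cm in matrices.items()},
        "score_missing_tally": diag.total(),
    }

    cov_design, _ = simcohort.covariate_design(pheno_in)
    screen_cfg = config.screen_config()
    results, lambdas = burden.run_exome_screen(
        matrices, pheno_in, cov_design, screen_cfg, gene_cmaf=cmafs
    )
    write_table(results, out / "burden_results.tsv")
    export_diagnostics(results, lambdas, out / "diagnostics")
    manifest["stages"]["burden"] = {
        "tests": len(results),
        "significant": int(results["significant"].sum()) if len(results) else 0,
        "lambda": {k: (None if not np.isfinite(v) else round(v, 4))
                   for k, v in lambdas.items()},
        "thresholds": {"significance": screen_cfg.significance,
                       "carrier_floor": screen_cfg.carrier_floor,
                       "gate": screen_cfg.gate},
    }

    # MR arm
    if config.mr or {"mr_exposure_tsv", "mr_outcome_tsv"} <= set(config.inputs):
        if "mr_exposure_tsv" in config.inputs:
            exp = read_table(config.inputs["mr_exposure_tsv"], SUMMARY_STAT_SCHEMA)
            outc = read_table(config.inputs["mr_outcome_tsv"], SUMMARY_STAT_SCHEMA)
        else:
            mr_cfg = simcohort.MRSimConfig(
                seed=config.mr.get("seed", config.seed + 1),
                **{k: v for k, v in config.mr.items() if k != "seed"},
            )
            instruments = simcohort.simulate_mr_instruments(mr_cfg)
            exp, outc = simcohort.as_two_tables(instruments, seed=config.seed + 2)
            write_table(exp, out / "mr_exposure.tsv")
            write_table(outc, out / "mr_outcome.tsv")
        harmonized, dropped = mr.harmonize(exp, outc)
        # IVW on the harmonized set is the primary model; Steiger exclusions
        # are reported as a sensitivity count, not applied before the suite
        _, reverse_excluded, _ = mr.steiger_filter(harmonized)
        mr_results = mr.mr_suite(harmonized, seed=config.seed + 3)
        write_table(mr_results, out / "mr_results.tsv")
        manifest["stages"]["mr"] = {
            "instruments_harmonized": len(harmonized),
            "dropped_harmonization": len(dropped),
            "flagged_steiger": len(reverse_excluded),
        }

    # coloc arm
    if config.coloc or {"coloc_track1_tsv", "coloc_track2_tsv"} <= set(config.inputs):
        if "coloc_track1_tsv" in config.inputs:
            t1 = read_table(config.inputs["coloc_track1_tsv"], TRACK_SCHEMA)
            t2 = read_table(config.inputs["coloc_track2_tsv"], TRACK_SCHEMA)
        else:
            t1, t2, _ = simcohort.simulate_coloc_locus(
                n_snps=config.coloc.get("n_snps", 200),
                shared=config.coloc.get("shared", True),
                seed=config.seed + 4,
            )
        res = coloc.coloc_posteriors(
            t1, t2,
            p1=config.coloc.get("p1", 1e-4),
            p2=config.coloc.get("p2", 1e-4),
            p12=config.coloc.get("p12", 1e-5),
        )
        write_table(
            pd.DataFrame([res.as_dict()]), out / "coloc_posteriors.tsv"
        )
        manifest["stages"]["coloc"] = {"n_snps": res.n_snps, **res.as_dict()}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
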