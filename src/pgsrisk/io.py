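"""Readers and writers for the formats the pipeline touches.

Dialects
--------
* Dosage TSV: columns ``chrom pos effect_allele other_allele info eaf``
  followed by one column per sample; tab-delimited, 1-based positions.
  Round-trips bit-exactly (floats written with ``repr`` precision).
* VCF v4.2 with a ``DS`` FORMAT field (effect allele = ALT); ``EAF`` and
  ``IQS`` (imputation quality) INFO fields.  Hard ``GT`` records can be
  converted to dosages on request.
* Summary statistics: tab-delimited ``CHR POS EA OA BETA SE P EAF``
  (case-insensitive header); an ``OR`` column is accepted and
  log-transformed with a logged notice.
* Phenotypes: CSV with the cohort-table columns.

All readers reject malformed input rather than silently coercing it.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from ._exceptions import FormatError, ValidationError
from .containers import (GenotypeMatrix, HarmonizationReport, PolygenicScore,
                         validate_cohort_table, validate_summary_stats)

log = logging.getLogger(__name__)

_DOSAGE_META = ["chrom", "pos", "effect_allele", "other_allele",
                "info", "eaf"]


# ---------------------------------------------------------------------------
# dosage matrices


def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    meta = geno.variants.copy()
    meta["info"] = geno.info_scores
    meta["eaf"] = geno.eaf
    meta = meta[_DOSAGE_META]
    body = pd.DataFrame(geno.dosages.T, columns=geno.sample_ids)
    pd.concat([meta, body], axis=1).to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[:6] != _DOSAGE_META:
        raise FormatError(
            f"malformed dosage TSV header (line 1): expected columns "
            f"{_DOSAGE_META}, found {header[:6]}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     float_precision="round_trip")
    sample_ids = list(df.columns[6:])
    if not sample_ids:
        raise FormatError("dosage TSV contains no sample columns")
    return GenotypeMatrix(
        sample_ids=sample_ids,
        variants=df[["chrom", "pos", "effect_allele",
                     "other_allele"]].reset_index(drop=True),
        dosages=df[sample_ids].to_numpy(float).T,
        info_scores=df["info"].to_numpy(float),
        eaf=df["eaf"].to_numpy(float),
    )


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write dosages as VCF v4.2 (ALT = effect allele, FORMAT ``DS``)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=EAF,Number=1,Type=Float,'
                 'Description="Effect (ALT) allele frequency">\n')
        fh.write('##INFO=<ID=IQS,Number=1,Type=Float,'
                 'Description="Imputation quality score">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Effect (ALT) allele dosage">\n')
        for c in sorted({str(c) for c in geno.variants["chrom"]},
                        key=lambda s: (len(s), s)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in geno.sample_ids) + "\n")
        v = geno.variants
        for j in range(geno.n_variants):
            ds = geno.dosages[:, j]
            fields = [str(v["chrom"].iat[j]), str(int(v["pos"].iat[j])),
                      ".", v["other_allele"].iat[j],
                      v["effect_allele"].iat[j], ".", "PASS",
                      f"EAF={float(geno.eaf[j])!r};"
                      f"IQS={float(geno.info_scores[j])!r}",
                      "DS"]
            fields += ["." if np.isnan(d) else repr(float(d)) for d in ds]
            fh.write("\t".join(fields) + "\n")


def read_vcf(path, convert_gt: bool = False,
             multiallelic: str = "error") -> GenotypeMatrix:
    """Read dosages from VCF (``DS`` FORMAT, or hard ``GT`` if requested).

    Multi-allelic records raise by default (``multiallelic="skip"`` drops
    them with a logged notice).
    """
    from cyvcf2 import VCF

    if multiallelic not in ("error", "skip"):
        raise FormatError("multiallelic must be 'error' or 'skip'")
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise FormatError("VCF contains no samples")
    chroms, pos, ea, oa, info_s, eaf, rows = [], [], [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            if multiallelic == "skip":
                log.info("skipping multi-allelic record %s:%s",
                         rec.CHROM, rec.POS)
                continue
            raise FormatError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}")
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
        elif convert_gt:
            gt = np.asarray(rec.genotype.array())[:, :2]
            d = np.where((gt < 0).any(axis=1), np.nan,
                         (gt > 0).sum(axis=1)).astype(float)
        else:
            raise FormatError(
                f"record at {rec.CHROM}:{rec.POS} has no DS field "
                "(pass convert_gt=True to derive dosage from GT)")
        chroms.append(str(rec.CHROM))
        pos.append(int(rec.POS))
        oa.append(rec.REF)
        ea.append(rec.ALT[0])
        e = rec.INFO.get("EAF")
        eaf.append(float(e) if e is not None
                   else float(np.nanmean(d)) / 2.0)
        q = rec.INFO.get("IQS")
        info_s.append(float(q) if q is not None else 1.0)
        rows.append(d)
    if not rows:
        raise FormatError("VCF contains no usable variant records")
    return GenotypeMatrix(
        sample_ids=sample_ids,
        variants=pd.DataFrame({"chrom": chroms, "pos": pos,
                               "effect_allele": ea, "other_allele": oa}),
        dosages=np.vstack(rows).T,
        info_scores=np.array(info_s),
        eaf=np.array(eaf),
    )


def read_dosages(path, format: str = "tsv", **kwargs) -> GenotypeMatrix:
    if format == "tsv":
        return read_dosage_tsv(path)
    if format == "vcf":
        return read_vcf(path, **kwargs)
    raise FormatError(f"unknown dosage format {format!r}")


# ---------------------------------------------------------------------------
# summary statistics

_SUMSTAT_ALIASES = {"chr": "chrom", "pos": "pos", "ea": "effect_allele",
                    "oa": "other_allele", "beta": "beta", "se": "se",
                    "p": "p", "eaf": "eaf", "or": "or"}


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df.columns = [c.strip().lower() for c in df.columns]
    df = df.rename(columns=_SUMSTAT_ALIASES)
    if "beta" not in df.columns and "or" in df.columns:
        if (df["or"].to_numpy(float) <= 0).any():
            raise FormatError("OR column must be strictly positive")
        df["beta"] = np.log(df["or"].to_numpy(float))
        log.info("OR column log-transformed to beta")
    required = ["chrom", "pos", "effect_allele", "other_allele",
                "beta", "se", "p", "eaf"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"summary statistics missing columns: {missing}")
    df["chrom"] = df["chrom"].astype(str)
    p = df["p"].to_numpy(float)
    if (p == 0).any():
        tiny = np.finfo(float).tiny
        log.warning("%d zero p-values clamped to %.3g", int((p == 0).sum()),
                    tiny)
        df["p"] = np.where(p == 0, tiny, p)
    df = df[required]
    return validate_summary_stats(df)


def write_summary_stats(stats: pd.DataFrame, path) -> None:
    out = stats.rename(columns={"chrom": "CHR", "pos": "POS",
                                "effect_allele": "EA", "other_allele": "OA",
                                "beta": "BETA", "se": "SE", "p": "P",
                                "eaf": "EAF"})
    out[["CHR", "POS", "EA", "OA", "BETA", "SE", "P", "EAF"]].to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotypes, scores, reports


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_cohort_table(df)


def write_phenotypes(cohort: pd.DataFrame, path) -> None:
    validate_cohort_table(cohort).to_csv(path, index=False)


def write_ps_csv(ps: PolygenicScore, path, manifest_hash: str = "") -> None:
    with open(path, "w") as fh:
        if manifest_hash:
            fh.write(f"# run_manifest_hash={manifest_hash}\n")
        ps.to_frame().to_csv(fh, index=False)


def read_ps_csv(path) -> PolygenicScore:
    df = pd.read_csv(path, comment="#")
    std = df["standardized"].to_numpy(float)
    return PolygenicScore(sample_ids=list(df["id"]),
                          raw=df["raw"].to_numpy(float),
                          standardized=None if np.isnan(std).all() else std)


def write_harmonization_report(report: HarmonizationReport, path,
                               manifest_hash: str = "") -> None:
    payload = report.to_dict()
    if manifest_hash:
        payload["run_manifest_hash"] = manifest_hash
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def write_table(df: pd.DataFrame, path, manifest_hash: str = "") -> None:
    """CSV writer used for all tidy result tables."""
    with open(path, "w") as fh:
        if manifest_hash:
            fh.write(f"# run_manifest_hash={manifest_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
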