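"""Core in-memory containers shared across the pipeline.

Tabular data (summary statistics, cohort tables) live in plain pandas
DataFrames with documented column contracts; the containers here wrap the
objects that need extra structure — a dosage matrix with variant metadata,
a polygenic score with its standardization state, and the harmonization
audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import ValidationError

#: Columns every summary-statistics DataFrame must carry.  ``beta`` is the
#: log odds ratio for ``effect_allele``; ``eaf`` its frequency.
SUMSTATS_COLUMNS = ("chrom", "pos", "effect_allele", "other_allele",
                    "beta", "se", "p", "eaf")

#: Columns every cohort table must carry.  Clinical covariates beyond these
#: are cohort-specific (see :mod:`pgsrisk.cox` model specs).
COHORT_CORE_COLUMNS = ("id", "cohort", "baseline_age", "followup_time",
                       "event", "sex")

PARENTAL_CATEGORIES = frozenset({"yes", "no", "unknown"})

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_palindromic(a1: str, a2: str) -> bool:
    """True for strand-ambiguous (A/T or C/G) single-base allele pairs."""
    return (len(a1) == 1 and len(a2) == 1
            and _COMPLEMENT.get(a1.upper()) == a2.upper())


def variant_key(chrom, pos, a1: str, a2: str) -> tuple:
    """Canonical variant identity: position plus the *unordered* allele pair.

    Using the sorted allele pair makes matching robust to which allele a
    file happens to count; strand/build mismatches simply fail to match and
    surface in the harmonization report.
    """
    return (str(chrom), int(pos)) + tuple(sorted((a1.upper(), a2.upper())))


def validate_summary_stats(stats: pd.DataFrame) -> pd.DataFrame:
    """Validate a summary-statistics table, returning it unchanged.

    Raises :class:`ValidationError` on missing columns, duplicate variant
    keys, equal alleles, or p-values outside (0, 1].
    """
    missing = [c for c in SUMSTATS_COLUMNS if c not in stats.columns]
    if missing:
        raise ValidationError(f"summary statistics missing columns: {missing}")
    if (stats["effect_allele"].str.upper()
            == stats["other_allele"].str.upper()).any():
        raise ValidationError("effect and other allele identical in some rows")
    p = stats["p"].to_numpy(float)
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must lie in (0, 1]")
    keys = [variant_key(c, q, a, b) for c, q, a, b in zip(
        stats["chrom"], stats["pos"],
        stats["effect_allele"], stats["other_allele"])]
    if len(set(keys)) != len(keys):
        raise ValidationError("duplicate variant keys in summary statistics")
    return stats


def validate_cohort_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Validate the core cohort-table contract (id/time/event/sex columns)."""
    missing = [c for c in COHORT_CORE_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns: {missing}")
    if (cohort["followup_time"].to_numpy(float) <= 0).any():
        raise ValidationError("followup_time must be strictly positive")
    ev = set(pd.unique(cohort["event"]))
    if not ev <= {0, 1}:
        raise ValidationError(f"event must be 0/1, found {sorted(ev)}")
    if not set(pd.unique(cohort["sex"])) <= {"F", "M"}:
        raise ValidationError("sex must be coded F/M")
    for col in ("mother_diab", "father_diab"):
        if col in cohort.columns:
            bad = set(pd.unique(cohort[col].dropna())) - PARENTAL_CATEGORIES
            if bad:
                raise ValidationError(
                    f"{col} must be one of yes/no/unknown, found {sorted(bad)}")
    return cohort


@dataclass
class GenotypeMatrix:
    """Per-individual, per-variant effect-allele dosages with metadata.

    Attributes
    ----------
    sample_ids : list of str
    variants : DataFrame with columns chrom, pos, effect_allele,
        other_allele — one row per dosage column.
    dosages : (n_samples, n_variants) float array with values in [0, 2];
        NaN marks a missing dosage.
    info_scores : per-variant imputation quality in [0, 1].
    eaf : per-variant effect-allele frequency in (0, 1).
    """

    sample_ids: list
    variants: pd.DataFrame
    dosages: np.ndarray
    info_scores: np.ndarray
    eaf: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.info_scores = np.asarray(self.info_scores, dtype=float)
        self.eaf = np.asarray(self.eaf, dtype=float)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValidationError("sample_ids length != dosage rows")
        if len(self.variants) != m:
            raise ValidationError("variant table length != dosage columns")
        if len(self.info_scores) != m or len(self.eaf) != m:
            raise ValidationError("per-variant arrays must match column count")
        d = self.dosages
        finite = d[np.isfinite(d)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValidationError("dosages must lie in [0, 2]")
        keys = self.variant_keys()
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate variant keys in genotype matrix")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_keys(self) -> list:
        v = self.variants
        return [variant_key(c, p, a, b) for c, p, a, b in zip(
            v["chrom"], v["pos"], v["effect_allele"], v["other_allele"])]

    @property
    def maf(self) -> np.ndarray:
        """Minor allele frequency: min(eaf, 1 - eaf)."""
        return np.minimum(self.eaf, 1.0 - self.eaf)

    def subset_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            variants=self.variants.iloc[index].reset_index(drop=True),
            dosages=self.dosages[:, index],
            info_scores=self.info_scores[index],
            eaf=self.eaf[index],
        )

    def subset_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            variants=self.variants,
            dosages=self.dosages[index, :],
            info_scores=self.info_scores,
            eaf=self.eaf,
        )


@dataclass
class PolygenicScore:
    """A per-sample weighted allele score, optionally standardized.

    ``standardized`` is in SD units over the reference population used by
    :func:`pgsrisk.pgs.standardize_ps` (mean 0, SD 1 there, not necessarily
    in any sub-cohort).
    """

    sample_ids: list
    raw: np.ndarray
    standardized: np.ndarray | None = None
    n_variants_used: int = 0
    weight_source: str = ""

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        if len(self.sample_ids) != len(self.raw):
            raise ValidationError("sample_ids and raw score lengths differ")
        if self.standardized is not None:
            self.standardized = np.asarray(self.standardized, dtype=float)
            if len(self.standardized) != len(self.raw):
                raise ValidationError("raw and standardized lengths differ")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.sample_ids,
            "raw": self.raw,
            "standardized": (self.standardized if self.standardized is not None
                             else np.full(len(self.raw), np.nan)),
        })

    def reindex(self, ids) -> np.ndarray:
        """Standardized score values for ``ids`` (raises on unknown id)."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = [lookup[i] for i in ids]
        except KeyError as exc:
            raise ValidationError(f"id not covered by score: {exc}") from exc
        src = self.standardized if self.standardized is not None else self.raw
        return src[idx]


@dataclass
class HarmonizationReport:
    """Audit trail of aligning external weights to a genotype file."""

    n_matched: int = 0
    n_allele_flipped: int = 0
    n_strand_ambiguous_dropped: int = 0
    n_unmatched: int = 0
    actions: list = field(default_factory=list)  # (chrom, pos, action)

    def to_dict(self) -> dict:
        return {
            "n_matched": self.n_matched,
            "n_allele_flipped": self.n_allele_flipped,
            "n_strand_ambiguous_dropped": self.n_strand_ambiguous_dropped,
            "n_unmatched": self.n_unmatched,
            "actions": [list(a) for a in self.actions],
        }


@dataclass
class MembershipMap:
    """person id -> set of cohort labels the person appears in."""

    membership: dict

    def __post_init__(self):
        for pid, labels in self.membership.items():
            if not labels:
                raise ValidationError(f"empty membership set for {pid!r}")

    def cohorts_of(self, pid) -> set:
        return self.membership[pid]

    @property
    def person_ids(self) -> list:
        return list(self.membership)

    def validate_against(self, cohort_tables: dict) -> None:
        """Check every cohort row's id is mapped with the right label."""
        for label, table in cohort_tables.items():
            for pid in table["id"]:
                if pid not in self.membership:
                    raise ValidationError(f"id {pid!r} missing from membership")
                if label not in self.membership[pid]:
                    raise ValidationError(
                        f"id {pid!r} in table {label!r} but not in its map entry")
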