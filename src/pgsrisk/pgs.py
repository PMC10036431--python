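"""Polygenic score construction.

A PS is the per-individual sum of effect-allele dosages weighted by the
discovery log odds ratio, over a set of variants selected by pruning and
thresholding (independent genome-wide significant variants).  Scores are
standardized over the study population so hazard ratios are expressed per
SD.  Population-specific variants/weights are derived with cross-validation
so each person is scored with weights estimated on folds that exclude them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._exceptions import (CollinearityError, DegenerateScoreError,
                          EmptyIntersectionError, FoldDegeneracyError,
                          InvalidConfigError, ValidationError)
from .containers import (GenotypeMatrix, HarmonizationReport, PolygenicScore,
                         is_palindromic, validate_summary_stats, variant_key)

PALINDROMIC_EAF_WINDOW = 0.08  # |EAF - 0.5| below this: ambiguous, drop

GENOME_WIDE_P = 5e-8
DEFAULT_PT_WINDOW_BP = 500_000
DEFAULT_PT_R2_MAX = 0.1


def harmonize(stats: pd.DataFrame, geno: GenotypeMatrix,
              palindromic_window: float = PALINDROMIC_EAF_WINDOW
              ) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Align external summary statistics to a genotype file's counted alleles.

    Matching is by (chrom, pos, unordered allele pair).  Where the summary
    effect allele is the genotype's *other* allele, beta is negated and eaf
    complemented so the weight refers to the counted allele.  Palindromic
    (A/T, C/G) variants with |eaf - 0.5| < ``palindromic_window`` are
    dropped as strand-ambiguous.  Unmatched records are logged.

    Returns the aligned subset (in genotype column order context: carries a
    ``geno_index`` column pointing at the dosage column) and a report.
    """
    validate_summary_stats(stats)
    if len(stats) == 0 or geno.n_variants == 0:
        raise ValidationError("harmonize requires non-empty inputs")

    geno_lookup = {}
    gv = geno.variants
    for j, (c, p, a, b) in enumerate(zip(gv["chrom"], gv["pos"],
                                         gv["effect_allele"],
                                         gv["other_allele"])):
        geno_lookup[variant_key(c, p, a, b)] = j

    report = HarmonizationReport()
    rows = []
    for rec in stats.itertuples(index=False):
        ea, oa = rec.effect_allele.upper(), rec.other_allele.upper()
        key = variant_key(rec.chrom, rec.pos, ea, oa)
        j = geno_lookup.get(key)
        if j is None:
            report.n_unmatched += 1
            report.actions.append((rec.chrom, rec.pos, "unmatched"))
            continue
        if is_palindromic(ea, oa) and abs(rec.eaf - 0.5) < palindromic_window:
            report.n_strand_ambiguous_dropped += 1
            report.actions.append((rec.chrom, rec.pos, "ambiguous_dropped"))
            continue
        g_ea = gv["effect_allele"].iat[j].upper()
        g_oa = gv["other_allele"].iat[j].upper()
        if ea == g_ea and oa == g_oa:
            beta, eaf, action = rec.beta, rec.eaf, "matched"
        elif ea == g_oa and oa == g_ea:
            beta, eaf, action = -rec.beta, 1.0 - rec.eaf, "flipped"
            report.n_allele_flipped += 1
        else:
            report.n_unmatched += 1
            report.actions.append((rec.chrom, rec.pos, "allele_mismatch"))
            continue
        report.n_matched += 1
        report.actions.append((rec.chrom, rec.pos, action))
        rows.append({
            "chrom": rec.chrom, "pos": rec.pos,
            "effect_allele": g_ea, "other_allele": g_oa,
            "beta": beta, "se": rec.se, "p": rec.p, "eaf": eaf,
            "geno_index": j,
        })

    if report.n_matched == 0:
        raise EmptyIntersectionError(
            "no summary-statistic variant matched the genotype file")
    aligned = pd.DataFrame(rows)
    return aligned, report


def qc_filter(geno: GenotypeMatrix, maf_min: float = 0.01,
              info_min: float = 0.5) -> GenotypeMatrix:
    """Drop variants with MAF < maf_min or imputation info < info_min."""
    if not 0.0 <= maf_min <= 0.5:
        raise InvalidConfigError("maf_min must lie in [0, 0.5]")
    if not 0.0 <= info_min <= 1.0:
        raise InvalidConfigError("info_min must lie in [0, 1]")
    keep = np.flatnonzero((geno.maf >= maf_min)
                          & (geno.info_scores >= info_min))
    return geno.subset_variants(keep)


def select_variants_pt(stats: pd.DataFrame, geno: GenotypeMatrix,
                       p_threshold: float = GENOME_WIDE_P,
                       window_bp: int = DEFAULT_PT_WINDOW_BP,
                       r2_max: float = DEFAULT_PT_R2_MAX) -> pd.DataFrame:
    """Pruning-and-thresholding variant selection.

    Greedy in ascending p among variants with p < p_threshold: a candidate
    is rejected if it lies within ``window_bp`` of an already-selected
    variant on the same chromosome *and* its squared dosage correlation
    with that variant exceeds ``r2_max``.  Ties in p break on genomic
    position, then allele order, so the result is order-invariant.

    ``stats`` must carry a ``geno_index`` column (from :func:`harmonize`)
    or match the genotype variants by key.
    """
    if not 0.0 < p_threshold <= 1.0:
        raise InvalidConfigError("p_threshold must lie in (0, 1]")
    stats = _ensure_geno_index(stats, geno)
    cand = stats[stats["p"] < p_threshold].copy()
    if len(cand) == 0:
        return cand
    cand = cand.sort_values(
        ["p", "chrom", "pos", "effect_allele", "other_allele"],
        kind="mergesort").reset_index(drop=True)

    selected = []
    sel_chrom: list = []
    sel_pos: list = []
    sel_dos: list = []
    d_all = geno.dosages
    for rec in cand.itertuples(index=False):
        j = int(rec.geno_index)
        d = d_all[:, j]
        ok = True
        for c, p, ds in zip(sel_chrom, sel_pos, sel_dos):
            if str(c) == str(rec.chrom) and abs(int(p) - int(rec.pos)) <= window_bp:
                r2 = _dosage_r2(d, ds)
                if r2 > r2_max:
                    ok = False
                    break
        if ok:
            selected.append(rec)
            sel_chrom.append(rec.chrom)
            sel_pos.append(rec.pos)
            sel_dos.append(d)
    return pd.DataFrame(selected).reset_index(drop=True)


def _dosage_r2(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _ensure_geno_index(stats: pd.DataFrame, geno: GenotypeMatrix
                       ) -> pd.DataFrame:
    if "geno_index" in stats.columns:
        return stats
    lookup = {k: j for j, k in enumerate(geno.variant_keys())}
    idx = []
    for rec in stats.itertuples(index=False):
        key = variant_key(rec.chrom, rec.pos,
                          rec.effect_allele, rec.other_allele)
        if key not in lookup:
            raise ValidationError(
                f"variant {key} not present in genotypes; harmonize first")
        idx.append(lookup[key])
    out = stats.copy()
    out["geno_index"] = idx
    return out


def compute_ps(geno: GenotypeMatrix, weights: pd.DataFrame,
               weight_source: str = "") -> PolygenicScore:
    """Raw PS: per-individual sum of dosage times beta over the weight set.

    ``weights`` must be harmonized to the genotype file (same counted
    alleles); missing dosages are imputed as 2*eaf and logged via the
    returned score's ``weight_source`` suffix.
    """
    weights = _ensure_geno_index(weights, geno)
    gv = geno.variants
    for rec in weights.itertuples(index=False):
        j = int(rec.geno_index)
        if (rec.effect_allele.upper() != gv["effect_allele"].iat[j].upper()
                or rec.other_allele.upper() != gv["other_allele"].iat[j].upper()):
            raise ValidationError(
                f"weight at {rec.chrom}:{rec.pos} not harmonized to "
                "genotype counted allele")
    cols = weights["geno_index"].to_numpy(int)
    beta = weights["beta"].to_numpy(float)
    d = geno.dosages[:, cols]
    n_missing = int(np.isnan(d).sum())
    if n_missing:
        fill = 2.0 * weights["eaf"].to_numpy(float)
        d = np.where(np.isnan(d), fill[None, :], d)
    raw = d @ beta
    label = weight_source or "external"
    if n_missing:
        label += f" ({n_missing} missing dosages mean-imputed)"
    return PolygenicScore(sample_ids=list(geno.sample_ids), raw=raw,
                          n_variants_used=len(weights), weight_source=label)


def standardize_ps(ps: PolygenicScore,
                   reference_ids=None) -> PolygenicScore:
    """Standardize to mean 0, SD 1 over the reference population.

    By default the reference is the whole scored sample; pass
    ``reference_ids`` to standardize against a subset (scores outside the
    reference then generally have SD != 1, but hazard ratios remain per SD
    of the reference-scaled score).
    """
    if reference_ids is None:
        mask = np.ones(len(ps.raw), dtype=bool)
    else:
        ref = set(reference_ids)
        mask = np.fromiter((s in ref for s in ps.sample_ids),
                           dtype=bool, count=len(ps.sample_ids))
    if mask.sum() < 2:
        raise DegenerateScoreError("reference set must contain >= 2 samples")
    mu = ps.raw[mask].mean()
    sd = ps.raw[mask].std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateScoreError("score has zero variance over reference")
    return PolygenicScore(sample_ids=ps.sample_ids, raw=ps.raw,
                          standardized=(ps.raw - mu) / sd,
                          n_variants_used=ps.n_variants_used,
                          weight_source=ps.weight_source)


# ---------------------------------------------------------------------------
# cross-validated population-specific scores


def _status_by_horizon(phenotype: pd.DataFrame, horizon: float) -> np.ndarray:
    """1=event by horizon, 0=survived past horizon, -1=censored early."""
    t = phenotype["followup_time"].to_numpy(float)
    e = phenotype["event"].to_numpy(int)
    out = np.full(len(t), -1, dtype=int)
    out[(e == 1) & (t <= horizon)] = 1
    out[t > horizon] = 0
    return out


def _logistic_per_variant(y: np.ndarray, dosages: np.ndarray,
                          n_iter: int = 25, tol: float = 1e-10) -> np.ndarray:
    """Vectorized univariate logistic fits (intercept + dosage slope).

    Newton–Raphson on the 2-parameter model per variant, run for all
    variants simultaneously.  Returns (2, m): intercepts and slopes.
    """
    n, m = dosages.shape
    a = np.zeros(m)
    b = np.zeros(m)
    y = y.astype(float)[:, None]
    for _ in range(n_iter):
        eta = a[None, :] + b[None, :] * dosages
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = p * (1.0 - p)
        r = y - p
        g_a = r.sum(axis=0)
        g_b = (r * dosages).sum(axis=0)
        h_aa = w.sum(axis=0)
        h_ab = (w * dosages).sum(axis=0)
        h_bb = (w * dosages * dosages).sum(axis=0)
        det = h_aa * h_bb - h_ab * h_ab
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        da = (h_bb * g_a - h_ab * g_b) / det
        db = (h_aa * g_b - h_ab * g_a) / det
        a += np.clip(da, -5, 5)
        b += np.clip(db, -5, 5)
        if max(np.abs(g_a).max(), np.abs(g_b).max()) < tol:
            break
    # guard monomorphic or separated variants
    b = np.where(np.isfinite(b), b, 0.0)
    return np.vstack([a, b])


def _per_variant_assoc(y: np.ndarray, dosages: np.ndarray,
                       model: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant effect estimates and Wald p-values on training data."""
    from scipy import stats as sps

    if model == "logistic":
        ab = _logistic_per_variant(y, dosages)
        beta = ab[1]
        # Wald SE from the observed information at the optimum
        eta = ab[0][None, :] + beta[None, :] * dosages
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = p * (1.0 - p)
        h_aa = w.sum(axis=0)
        h_ab = (w * dosages).sum(axis=0)
        h_bb = (w * dosages * dosages).sum(axis=0)
        det = np.maximum(h_aa * h_bb - h_ab * h_ab, 1e-12)
        se = np.sqrt(h_aa / det)
        z = np.where(se > 0, beta / se, 0.0)
        pval = 2.0 * sps.norm.sf(np.abs(z))
        return beta, pval
    elif model == "cox":
        from .cox import CoxPH
        m = dosages.shape[1]
        beta = np.zeros(m)
        pval = np.ones(m)
        time = y[:, 0]
        event = y[:, 1]
        for j in range(m):
            x = dosages[:, j:j + 1]
            if x.std() == 0:
                continue
            res = CoxPH(time, event, x, ["dosage"]).fit()
            beta[j] = res.params[0]
            pval[j] = res.pvalues[0]
        return beta, pval
    raise InvalidConfigError(f"unknown per-variant model {model!r}")


def _fold_assignment(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    folds = np.repeat(np.arange(k), -(-n // k))[:n]
    rng.shuffle(folds)
    return folds


def cv_weight_ps(geno: GenotypeMatrix, phenotype: pd.DataFrame,
                 variants: pd.DataFrame | None = None, k: int = 10,
                 seed: int = 0, horizon: float = 10.0,
                 model: str = "logistic") -> PolygenicScore:
    """Population-specific *weights* via k-fold cross-validation.

    Samples are partitioned into k folds; per-variant weights are estimated
    on the other k-1 folds (univariate logistic regression of
    event-by-horizon on dosage by default, per-variant Cox via
    ``model="cox"``) and applied only to the held-out fold, so no person's
    own outcome informs their weights.
    """
    if k < 2:
        raise InvalidConfigError("k must be >= 2")
    pheno = phenotype.set_index("id").loc[geno.sample_ids]
    if variants is not None:
        variants = _ensure_geno_index(variants, geno)
        cols = variants["geno_index"].to_numpy(int)
    else:
        cols = np.arange(geno.n_variants)
    dos = geno.dosages[:, cols]
    dos = np.where(np.isnan(dos), 2.0 * geno.eaf[cols][None, :], dos)
    n = len(pheno)
    rng = np.random.default_rng(seed)
    folds = _fold_assignment(n, k, rng)

    status = _status_by_horizon(pheno, horizon)
    raw = np.zeros(n)
    for f in range(k):
        train = folds != f
        test = ~train
        if model == "logistic":
            y_tr = status[train]
            keep = y_tr >= 0  # censored-before-horizon excluded from fitting
            if keep.sum() == 0 or y_tr[keep].sum() == 0:
                raise FoldDegeneracyError(
                    f"fold {f} has no events by horizon; reduce k")
            beta, _ = _per_variant_assoc(y_tr[keep].astype(float),
                                         dos[train][keep], model)
        else:
            tr = pheno[train]
            y_tr = np.column_stack([tr["followup_time"].to_numpy(float),
                                    tr["event"].to_numpy(float)])
            if tr["event"].sum() == 0:
                raise FoldDegeneracyError(
                    f"fold {f} has no events; reduce k")
            beta, _ = _per_variant_assoc(y_tr, dos[train], model)
        raw[test] = dos[test] @ beta
    return PolygenicScore(sample_ids=list(geno.sample_ids), raw=raw,
                          n_variants_used=dos.shape[1],
                          weight_source=f"CV-weights (k={k}, {model})")


def cv_variant_ps(geno: GenotypeMatrix, phenotype: pd.DataFrame,
                  n_select: int = 287, k: int = 2, seed: int = 0,
                  horizon: float = 10.0,
                  model: str = "logistic") -> PolygenicScore:
    """Population-specific *variants* via k-fold (default twofold) CV.

    In each fold's training half, variants are ranked by univariate
    association p-value; the top ``n_select`` are selected and weighted
    from that half, then scored on the held-out fold.
    """
    if n_select > geno.n_variants:
        raise InvalidConfigError("n_select exceeds the number of variants")
    if k < 2:
        raise InvalidConfigError("k must be >= 2")
    pheno = phenotype.set_index("id").loc[geno.sample_ids]
    dos = geno.dosages
    dos = np.where(np.isnan(dos), 2.0 * geno.eaf[None, :], dos)
    n = len(pheno)
    rng = np.random.default_rng(seed)
    folds = _fold_assignment(n, k, rng)
    status = _status_by_horizon(pheno, horizon)

    raw = np.zeros(n)
    for f in range(k):
        train = folds != f
        test = ~train
        y_tr = status[train]
        keep = y_tr >= 0
        if keep.sum() == 0 or y_tr[keep].sum() == 0:
            raise FoldDegeneracyError(f"fold {f} has no events; reduce k")
        beta, pval = _per_variant_assoc(y_tr[keep].astype(float),
                                        dos[train][keep], model)
        # rank by p, ties broken by position then alleles for determinism
        order = np.lexsort((
            geno.variants["other_allele"].to_numpy(),
            geno.variants["effect_allele"].to_numpy(),
            geno.variants["pos"].to_numpy(int),
            geno.variants["chrom"].to_numpy(),
            pval))
        top = order[:n_select]
        raw[test] = dos[test][:, top] @ beta[top]
    return PolygenicScore(sample_ids=list(geno.sample_ids), raw=raw,
                          n_variants_used=n_select,
                          weight_source=f"CV-variants (k={k}, top {n_select})")


def residualize_ps(ps: PolygenicScore,
                   covariates: np.ndarray) -> PolygenicScore:
    """Residualize the standardized PS on covariates (e.g. genetic PCs).

    Least-squares residual on [1, covariates], re-standardized.  Raises on
    rank deficiency or when the PS is exactly linear in the covariates.
    """
    if ps.standardized is None:
        raise ValidationError("standardize the score before residualizing")
    x = np.column_stack([np.ones(len(ps.raw)), np.asarray(covariates, float)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise CollinearityError("covariate matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(x, ps.standardized, rcond=None)
    resid = ps.standardized - x @ coef
    sd = resid.std()
    if sd < 1e-12:
        raise DegenerateScoreError(
            "score is exactly linear in the covariates")
    out = PolygenicScore(sample_ids=ps.sample_ids, raw=resid,
                         n_variants_used=ps.n_variants_used,
                         weight_source=ps.weight_source + " (PC-residualized)")
    return standardize_ps(out)
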