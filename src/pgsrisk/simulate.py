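"""Synthetic cohorts with the structure the downstream analysis assumes.

The generator emulates a longitudinal diabetes study with three overlapping
age cohorts (adult, youth, birth), imputed genotype dosages, discovery GWAS
summary statistics, clinical covariates, and censored proportional-hazards
event times.  It exists so every downstream stage — polygenic score
construction, Cox/Breslow fitting, discrimination/reclassification/decision
metrics, and the cross-cohort bootstrap — can be exercised and validated
without any real data.

Design notes
------------
* The baseline hazard is Weibull (shape 1, i.e. exponential, by default) so
  closed-form checks exist; the real analysis is semi-parametric and never
  sees these choices.
* Censoring is an exponential dropout time truncated at an administrative
  horizon.
* Genotypes are hard Hardy–Weinberg allele counts by default; an optional
  perturbation produces continuous dosages to exercise the imputation-info
  filter.
* Covariate marginals and effect sizes are package defaults of the rough
  magnitude seen in incident type 2 diabetes cohorts; only the
  hazard-model *structure* matters for validating the methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._exceptions import InvalidConfigError
from .containers import (GenotypeMatrix, MembershipMap, validate_cohort_table,
                         validate_summary_stats)

_BASES = ("A", "C", "G", "T")
_ALLELE_PAIRS = [(a, b) for a in _BASES for b in _BASES if a != b]

#: Per-design covariate generators and log-hazard coefficients.  Continuous
#: covariates enter the linear predictor centred at ``mean`` so the Weibull
#: scale refers to a covariate-average individual.  Coefficients are log
#: hazard ratios per unit (age per decade, PS per SD).
COHORT_PRESETS: dict = {
    "adult": {
        "n_individuals": 2333,
        "baseline_hazard_scale": 35.0,
        "censoring_rate": 0.08,
        "admin_horizon": 25.0,
        "age": {"low": 20.0, "high": 60.0, "beta_per_decade": np.log(1.05)},
        "sex_beta_female": np.log(1.35),
        "parental": {
            "mother": {"p": (0.25, 0.55, 0.20),
                       "beta": (np.log(1.5), 0.0, np.log(1.3))},
            "father": {"p": (0.20, 0.55, 0.25),
                       "beta": (np.log(1.45), 0.0, np.log(1.2))},
        },
        "bmi": {"mean": 31.0, "sd": 6.5, "beta": np.log(1.02)},
        "fpg": {"mean_log": np.log(5.2), "sd_log": 0.10, "beta": np.log(1.9)},
        "hba1c": {"intercept": 20.0, "slope_fpg": 3.0, "resid_sd": 3.0,
                  "beta": np.log(1.06)},
        "twohpg": {"intercept": 0.5, "slope_fpg": 1.2, "resid_sd": 1.5,
                   "beta": np.log(1.15)},
    },
    "youth": {
        "n_individuals": 2229,
        "baseline_hazard_scale": 130.0,
        "censoring_rate": 0.05,
        "admin_horizon": 25.0,
        "age": {"low": 5.0, "high": 19.0, "beta_per_decade": np.log(2.1)},
        "sex_beta_female": np.log(1.40),
        "parental": {
            "mother": {"p": (0.30, 0.50, 0.20),
                       "beta": (np.log(2.4), 0.0, np.log(1.8))},
            "father": {"p": (0.20, 0.50, 0.30),
                       "beta": (np.log(1.9), 0.0, 0.0)},
        },
        "bmi_z": {"mean": 0.8, "sd": 1.1, "beta": np.log(1.5)},
        "fpg": {"mean_log": np.log(4.8), "sd_log": 0.07, "beta": np.log(2.0)},
        "hba1c": {"intercept": 18.0, "slope_fpg": 3.0, "resid_sd": 2.5,
                  "beta": np.log(1.06)},
        "twohpg": {"intercept": 0.5, "slope_fpg": 1.1, "resid_sd": 1.3,
                   "beta": np.log(1.20)},
    },
    "birth": {
        "n_individuals": 2894,
        "baseline_hazard_scale": 280.0,
        "censoring_rate": 0.03,
        "admin_horizon": 50.0,
        "sex_beta_female": np.log(1.18),
        "parental": {
            "mother": {"p": (0.20, 0.55, 0.25),
                       "beta": (np.log(4.0), 0.0, 0.0)},
            "father": {"p": (0.15, 0.55, 0.30),
                       "beta": (np.log(3.0), 0.0, 0.0)},
        },
        # U-shaped birthweight risk: elevated hazard below 3000 g and
        # above 4000 g relative to the 3000-4000 g reference band.
        "birthweight": {"mean": 3400.0, "sd": 550.0,
                        "beta_low": np.log(1.5), "beta_high": np.log(1.5)},
    },
}


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one synthetic cohort.

    Defaults for ``n_individuals``, hazard scale, censoring and horizon are
    filled per ``cohort_design`` from :data:`COHORT_PRESETS` when left None.
    """

    cohort_design: str = "adult"
    n_individuals: int | None = None
    n_variants: int = 300
    maf_range: tuple = (0.05, 0.5)
    frac_causal: float = 0.3
    true_ps_hr_per_sd: float = 1.3
    baseline_hazard_shape: float = 1.0
    baseline_hazard_scale: float | None = None
    censoring_rate: float | None = None
    admin_horizon: float | None = None
    dosage_noise: float = 0.0   # >0: beta-perturb hard genotypes
    seed: int = 0

    def resolved(self) -> "SimulationConfig":
        """Fill design-specific defaults and validate invariants."""
        if self.cohort_design not in COHORT_PRESETS:
            raise InvalidConfigError(
                f"unknown cohort_design {self.cohort_design!r}; "
                f"expected one of {sorted(COHORT_PRESETS)}")
        preset = COHORT_PRESETS[self.cohort_design]
        cfg = replace(
            self,
            n_individuals=(self.n_individuals if self.n_individuals is not None
                           else preset["n_individuals"]),
            baseline_hazard_scale=(
                self.baseline_hazard_scale
                if self.baseline_hazard_scale is not None
                else preset["baseline_hazard_scale"]),
            censoring_rate=(self.censoring_rate
                            if self.censoring_rate is not None
                            else preset["censoring_rate"]),
            admin_horizon=(self.admin_horizon
                           if self.admin_horizon is not None
                           else preset["admin_horizon"]),
        )
        if cfg.n_individuals <= 0 or cfg.n_variants <= 0:
            raise InvalidConfigError("n_individuals and n_variants must be > 0")
        lo, hi = cfg.maf_range
        if not (0.01 <= lo < hi <= 0.5):
            raise InvalidConfigError("maf_range must be ordered within (0.01, 0.5]")
        if not 0.0 <= cfg.frac_causal <= 1.0:
            raise InvalidConfigError("frac_causal must lie in [0, 1]")
        if cfg.true_ps_hr_per_sd <= 0:
            raise InvalidConfigError("true_ps_hr_per_sd must be > 0")
        if cfg.baseline_hazard_shape <= 0 or cfg.baseline_hazard_scale <= 0:
            raise InvalidConfigError("Weibull shape and scale must be > 0")
        if cfg.censoring_rate < 0:
            raise InvalidConfigError("censoring_rate must be >= 0")
        if not cfg.admin_horizon > 0:
            raise InvalidConfigError("admin_horizon must be > 0")
        return cfg

    def to_dict(self) -> dict:
        cfg = self.resolved()
        return {
            "cohort_design": cfg.cohort_design,
            "n_individuals": int(cfg.n_individuals),
            "n_variants": int(cfg.n_variants),
            "maf_range": [float(cfg.maf_range[0]), float(cfg.maf_range[1])],
            "frac_causal": float(cfg.frac_causal),
            "true_ps_hr_per_sd": float(cfg.true_ps_hr_per_sd),
            "baseline_hazard_shape": float(cfg.baseline_hazard_shape),
            "baseline_hazard_scale": float(cfg.baseline_hazard_scale),
            "censoring_rate": float(cfg.censoring_rate),
            "admin_horizon": float(cfg.admin_horizon),
            "dosage_noise": float(cfg.dosage_noise),
            "seed": int(cfg.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generator stage
    return np.random.default_rng([int(config.seed), stream])


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw Hardy–Weinberg effect-allele dosages with variant metadata.

    Variants are laid out on chromosomes 1–22 at 1 Mb spacing; allele pairs
    are uniform over ordered distinct bases (so ~1/6 are strand-ambiguous
    A/T or C/G pairs, exercising harmonization).  Imputation info scores are
    Beta(5, 1) — mostly near 1 with a small tail below 0.5.  With
    ``dosage_noise`` > 0, hard genotypes are perturbed toward continuous
    dosages within [0, 2] to mimic imputation uncertainty.
    """
    cfg = config.resolved()
    rng = _rng(cfg, 0)
    n, m = cfg.n_individuals, cfg.n_variants

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    dosages = rng.binomial(2, maf, size=(n, m)).astype(float)
    if cfg.dosage_noise > 0:
        jitter = rng.beta(2, 2, size=(n, m)) - 0.5
        dosages = np.clip(dosages + cfg.dosage_noise * jitter, 0.0, 2.0)
    info = rng.beta(5, 1, size=m)

    per_chrom = -(-m // 22)  # ceil
    chroms = [str(1 + i // per_chrom) for i in range(m)]
    pos = [1_000_000 * (1 + i % per_chrom) for i in range(m)]
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oa = [_ALLELE_PAIRS[i][1] for i in pair_idx]

    variants = pd.DataFrame({
        "chrom": chroms, "pos": pos,
        "effect_allele": ea, "other_allele": oa,
    })
    sample_ids = [f"P{i:06d}" for i in range(n)]
    return GenotypeMatrix(sample_ids=sample_ids, variants=variants,
                          dosages=dosages, info_scores=info, eaf=maf)


def draw_true_effects(genotypes: GenotypeMatrix,
                      config: SimulationConfig) -> pd.DataFrame:
    """True per-variant log hazard-scale effects underlying the simulation.

    A ``frac_causal`` subset gets N(0, 0.1^2) effects; the rest are exactly
    zero.  Returned in summary-statistics layout (se=0, p=1) so it can be
    fed anywhere a weight table is accepted.  Deterministic given the
    config seed and shared with :func:`simulate_summary_stats`.
    """
    cfg = config.resolved()
    rng = _rng(cfg, 1)
    m = genotypes.n_variants
    n_causal = int(round(cfg.frac_causal * m))
    causal = np.zeros(m, dtype=bool)
    if n_causal:
        causal[rng.choice(m, size=n_causal, replace=False)] = True
    beta = np.where(causal, rng.normal(0.0, 0.1, size=m), 0.0)
    out = genotypes.variants.copy()
    out["beta"] = beta
    out["se"] = 0.0
    out["p"] = 1.0
    out["eaf"] = genotypes.eaf
    return validate_summary_stats(out)


def simulate_summary_stats(genotypes: GenotypeMatrix,
                           config: SimulationConfig,
                           discovery_n: int) -> pd.DataFrame:
    """Noisy discovery GWAS summary statistics for the simulated variants.

    Reported log-ORs are the true effects plus Gaussian noise with
    SE = 1/sqrt(2 * discovery_n * maf * (1 - maf)); p-values are two-sided
    Wald.  Alleles and frequencies match the genotype metadata.
    """
    from scipy import stats as sps

    cfg = config.resolved()
    if discovery_n <= 0:
        raise InvalidConfigError("discovery_n must be > 0")
    truth = draw_true_effects(genotypes, cfg)
    rng = _rng(cfg, 2)
    maf = genotypes.maf
    se = 1.0 / np.sqrt(2.0 * discovery_n * maf * (1.0 - maf))
    beta_hat = truth["beta"].to_numpy() + rng.normal(0.0, se)
    z = beta_hat / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    out = genotypes.variants.copy()
    out["beta"] = beta_hat
    out["se"] = se
    out["p"] = np.clip(p, np.finfo(float).tiny, 1.0)
    out["eaf"] = genotypes.eaf
    return validate_summary_stats(out)


def true_standardized_ps(genotypes: GenotypeMatrix,
                         true_effects: pd.DataFrame) -> np.ndarray:
    """Standardized (mean 0, SD 1) true polygenic score of the sample."""
    raw = genotypes.dosages @ true_effects["beta"].to_numpy()
    sd = raw.std()
    if sd == 0:
        return np.zeros_like(raw)
    return (raw - raw.mean()) / sd


def _simulate_covariates(cfg: SimulationConfig, n: int,
                         rng: np.random.Generator) -> tuple:
    """Draw clinical covariates and their centred linear-predictor part."""
    preset = COHORT_PRESETS[cfg.cohort_design]
    cols: dict = {}
    lp = np.zeros(n)

    sex = np.where(rng.random(n) < 0.5, "F", "M")
    cols["sex"] = sex
    lp += preset["sex_beta_female"] * ((sex == "F") - 0.5)

    for parent, spec in preset["parental"].items():
        cats = rng.choice(["yes", "no", "unknown"], size=n, p=spec["p"])
        cols[f"{parent}_diab"] = cats
        b_yes, _, b_unk = spec["beta"]
        contrib = np.where(cats == "yes", b_yes,
                           np.where(cats == "unknown", b_unk, 0.0))
        lp += contrib - contrib.mean()

    if cfg.cohort_design in ("adult", "youth"):
        a = preset["age"]
        age = rng.uniform(a["low"], a["high"], size=n)
        cols["baseline_age"] = age
        lp += a["beta_per_decade"] * (age - age.mean()) / 10.0

        if cfg.cohort_design == "adult":
            b = preset["bmi"]
            bmi = rng.normal(b["mean"], b["sd"], size=n)
            cols["bmi"] = bmi
            lp += b["beta"] * (bmi - b["mean"])
        else:
            b = preset["bmi_z"]
            bmi_z = rng.normal(b["mean"], b["sd"], size=n)
            cols["bmi_z"] = bmi_z
            lp += b["beta"] * (bmi_z - b["mean"])

        f = preset["fpg"]
        fpg = rng.lognormal(f["mean_log"], f["sd_log"], size=n)
        cols["fpg"] = fpg
        lp += f["beta"] * (fpg - fpg.mean())

        h = preset["hba1c"]
        hba1c = h["intercept"] + h["slope_fpg"] * fpg \
            + rng.normal(0.0, h["resid_sd"], size=n)
        cols["hba1c"] = hba1c
        lp += h["beta"] * (hba1c - hba1c.mean())

        t = preset["twohpg"]
        twohpg = t["intercept"] + t["slope_fpg"] * fpg \
            + rng.normal(0.0, t["resid_sd"], size=n)
        twohpg = np.maximum(twohpg, 1.0)
        cols["twohpg"] = twohpg
        lp += t["beta"] * (twohpg - twohpg.mean())
    else:  # birth
        cols["baseline_age"] = np.zeros(n)
        bw = preset["birthweight"]
        birthweight = rng.normal(bw["mean"], bw["sd"], size=n)
        cols["birthweight_g"] = birthweight
        low = (birthweight < 3000.0).astype(float)
        high = (birthweight > 4000.0).astype(float)
        lp += bw["beta_low"] * (low - low.mean())
        lp += bw["beta_high"] * (high - high.mean())

    return cols, lp


def simulate_cohort(genotypes: GenotypeMatrix,
                    true_effects: pd.DataFrame,
                    config: SimulationConfig,
                    covariate_effects: str = "preset") -> pd.DataFrame:
    """Censored proportional-hazards event times plus clinical covariates.

    The linear predictor is log(true_ps_hr_per_sd) times the standardized
    true PS plus the preset covariate terms (``covariate_effects="none"``
    switches all covariate coefficients off while still emitting the
    columns).  Event times follow a Weibull proportional-hazards law; the
    observed time is min(event, exponential dropout, admin horizon).
    """
    cfg = config.resolved()
    if covariate_effects not in ("preset", "none"):
        raise InvalidConfigError(
            "covariate_effects must be 'preset' or 'none'")
    n = genotypes.n_samples
    rng = _rng(cfg, 3)

    cols, cov_lp = _simulate_covariates(cfg, n, rng)
    if covariate_effects == "none":
        cov_lp = np.zeros(n)
    ps = true_standardized_ps(genotypes, true_effects)
    lp = np.log(cfg.true_ps_hr_per_sd) * ps + cov_lp

    # Weibull PH: S(t|lp) = exp(-(t/scale)^shape * e^lp)
    u = rng.uniform(size=n)
    shape, scale = cfg.baseline_hazard_shape, cfg.baseline_hazard_scale
    t_event = scale * (-np.log(u) / np.exp(lp)) ** (1.0 / shape)
    if cfg.censoring_rate > 0:
        t_drop = rng.exponential(1.0 / cfg.censoring_rate, size=n)
    else:
        t_drop = np.full(n, np.inf)
    t_cens = np.minimum(t_drop, cfg.admin_horizon)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-8)  # followup_time must be > 0

    table = pd.DataFrame({
        "id": genotypes.sample_ids,
        "cohort": cfg.cohort_design,
        "followup_time": time,
        "event": event,
        **cols,
    })
    core = ["id", "cohort", "baseline_age", "followup_time", "event", "sex"]
    table = table[core + [c for c in table.columns if c not in core]]
    return validate_cohort_table(table)


def simulate_overlapping_cohorts(configs: dict,
                                 overlap_fraction: float = 0.5,
                                 seed: int | None = None):
    """Simulate several cohorts sharing a person registry.

    A fraction ``overlap_fraction`` of each cohort after the first is drawn
    from persons already in the registry; the rest are new.  Genotypes (and
    hence the true PS) are simulated once for the union, so a person keeps
    their genotype across cohorts while covariates and event times are
    cohort-specific.

    Returns ``(cohort_tables, membership, genotypes, true_effects)``.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise InvalidConfigError("overlap_fraction must lie in [0, 1]")
    if not configs:
        raise InvalidConfigError("need at least one cohort config")
    labels = list(configs)
    cfgs = {lab: configs[lab].resolved() for lab in labels}
    first = cfgs[labels[0]]
    for lab in labels[1:]:
        c = cfgs[lab]
        if (c.n_variants != first.n_variants
                or c.maf_range != first.maf_range
                or c.frac_causal != first.frac_causal):
            raise InvalidConfigError(
                "overlapping cohorts must share variant settings")
    seed = first.seed if seed is None else seed
    rng = np.random.default_rng([int(seed), 10])

    # person registry: lists of registry indices per cohort
    members: dict = {}
    registry_size = 0
    for k, lab in enumerate(labels):
        n = cfgs[lab].n_individuals
        if k == 0 or registry_size == 0:
            idx = np.arange(registry_size, registry_size + n)
            registry_size += n
        else:
            n_old = min(int(round(overlap_fraction * n)), registry_size)
            old = rng.choice(registry_size, size=n_old, replace=False)
            new = np.arange(registry_size, registry_size + (n - n_old))
            registry_size += n - n_old
            idx = np.concatenate([np.sort(old), new])
        members[lab] = idx

    geno_cfg = replace(first, n_individuals=registry_size, seed=seed)
    genotypes = simulate_genotypes(geno_cfg)
    truth = draw_true_effects(genotypes, geno_cfg)

    tables = {}
    for lab in labels:
        sub = genotypes.subset_samples(members[lab])
        tables[lab] = simulate_cohort(sub, truth, cfgs[lab])

    mapping: dict = {}
    for lab in labels:
        for i in members[lab]:
            mapping.setdefault(genotypes.sample_ids[i], set()).add(lab)
    membership = MembershipMap(mapping)
    membership.validate_against(tables)
    return tables, membership, genotypes, truth
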