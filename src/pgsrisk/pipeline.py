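"""End-to-end orchestration: simulate/score -> fit -> evaluate -> compare.

A :class:`RunConfig` holds either input paths (genotypes, summary
statistics, phenotypes) or a simulation block — exactly one of the two —
plus per-cohort model specs and horizons and the metric settings.  The
pipeline writes tidy CSV/JSON outputs and a machine-readable manifest
(seed, config hash, output list); rerunning an identical config reproduces
every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from ._exceptions import InvalidConfigError, PgsRiskError
from .compare import bootstrap_hr_difference
from .containers import MembershipMap
from .cox import (DEFAULT_HORIZONS, DEFAULT_SPECS, ModelSpec, fit_cox,
                  group_cumulative_incidence, predicted_cumulative_incidence)
from .metrics import (compare_auc, concordance, continuous_nri,
                      decision_curve, nri_bootstrap_ci, status_from_cohort)
from .pgs import (compute_ps, harmonize, qc_filter, select_variants_pt,
                  standardize_ps)
from .simulate import SimulationConfig, simulate_overlapping_cohorts, \
    simulate_summary_stats

log = logging.getLogger(__name__)


class PipelineError(PgsRiskError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (exactly one input mode)."""

    output_dir: str = "pgsrisk_out"
    seed: int = 0
    # input-paths mode
    genotypes_path: str | None = None
    genotypes_format: str = "tsv"
    summary_stats_path: str | None = None
    phenotypes_path: str | None = None
    # simulation mode
    simulation: dict | None = None  # label -> SimulationConfig dict,
    # plus optional keys overlap_fraction, discovery_n
    # analysis settings
    horizons: dict = field(default_factory=lambda: dict(DEFAULT_HORIZONS))
    specs: dict | None = None  # label -> list of covariate tokens
    p_threshold: float = 5e-8
    maf_min: float = 0.01
    info_min: float = 0.5
    n_boot_nri: int = 500
    n_boot_auc: int = 500
    n_boot_compare: int = 2000
    pt_grid: list | None = None

    def __post_init__(self):
        has_paths = any(p is not None for p in (
            self.genotypes_path, self.summary_stats_path,
            self.phenotypes_path))
        if has_paths and self.simulation is not None:
            raise InvalidConfigError(
                "config must have input paths OR a simulation block, not both")
        if not has_paths and self.simulation is None:
            raise InvalidConfigError(
                "config needs input paths or a simulation block")
        if has_paths and None in (self.genotypes_path,
                                  self.summary_stats_path,
                                  self.phenotypes_path):
            raise InvalidConfigError(
                "input-paths mode requires genotypes, summary stats and "
                "phenotypes paths")
        for h in self.horizons.values():
            if h <= 0:
                raise InvalidConfigError("horizons must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        return d

    def analysis_dict(self) -> dict:
        """The config minus the output location (what the results depend on)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.analysis_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _resolve_specs(config: RunConfig, labels) -> dict:
    specs = {}
    for lab in labels:
        if config.specs and lab in config.specs:
            specs[lab] = ModelSpec(lab, config.specs[lab])
        elif lab in DEFAULT_SPECS:
            specs[lab] = DEFAULT_SPECS[lab]
        else:
            raise InvalidConfigError(f"no model spec for cohort {lab!r}")
    return specs


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


@_stage("inputs")
def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        sim = dict(config.simulation)
        overlap = float(sim.pop("overlap_fraction", 0.5))
        discovery_n = int(sim.pop("discovery_n", 200_000))
        cfgs = {lab: SimulationConfig.from_dict(d) for lab, d in sim.items()}
        tables, membership, genotypes, _ = simulate_overlapping_cohorts(
            cfgs, overlap_fraction=overlap, seed=config.seed)
        first = next(iter(cfgs.values())).resolved()
        geno_cfg = SimulationConfig(
            cohort_design=first.cohort_design,
            n_individuals=genotypes.n_samples,
            n_variants=first.n_variants, maf_range=first.maf_range,
            frac_causal=first.frac_causal, seed=config.seed)
        stats = simulate_summary_stats(genotypes, geno_cfg, discovery_n)
        return genotypes, stats, tables, membership
    genotypes = pio.read_dosages(config.genotypes_path,
                                 config.genotypes_format)
    stats = pio.read_summary_stats(config.summary_stats_path)
    pheno = pio.read_phenotypes(config.phenotypes_path)
    tables = {lab: df.reset_index(drop=True)
              for lab, df in pheno.groupby("cohort")}
    membership = MembershipMap({
        pid: {lab for lab, df in tables.items()
              if pid in set(df["id"])}
        for pid in pheno["id"].unique()})
    return genotypes, stats, tables, membership


@_stage("score")
def _build_score(config, genotypes, stats):
    geno_qc = qc_filter(genotypes, config.maf_min, config.info_min)
    aligned, report = harmonize(stats, geno_qc)
    selected = select_variants_pt(aligned, geno_qc, config.p_threshold)
    if len(selected) == 0:
        raise InvalidConfigError(
            "pruning and thresholding selected zero variants")
    ps = compute_ps(geno_qc, selected, weight_source="P&T external weights")
    return standardize_ps(ps), report, selected


@_stage("evaluate")
def _evaluate_cohort(config, label, cohort, spec, ps):
    horizon = config.horizons.get(label, 10.0)
    ps_values = ps.reindex(cohort["id"])
    res_clin = fit_cox(cohort, spec)
    res_full = fit_cox(cohort, spec.with_ps(), ps)
    pred_clin = predicted_cumulative_incidence(
        res_clin, cohort, horizon, extrapolate=True, label="clinical")
    pred_full = predicted_cumulative_incidence(
        res_full, cohort, horizon, ps, extrapolate=True,
        label="clinical+PS")
    auc_cmp = compare_auc(pred_clin.probability, pred_full.probability,
                          cohort["followup_time"], cohort["event"],
                          n_boot=config.n_boot_auc, seed=config.seed)
    st = status_from_cohort(cohort, horizon)
    nri = continuous_nri(pred_clin.probability, pred_full.probability, st)
    nri_ci, _ = nri_bootstrap_ci(pred_clin.probability, pred_full.probability,
                                 cohort["followup_time"], cohort["event"],
                                 horizon, n_boot=max(config.n_boot_nri, 100),
                                 seed=config.seed)
    dca = decision_curve(
        {"clinical": pred_clin.probability,
         "clinical+PS": pred_full.probability},
        cohort["followup_time"], cohort["event"], horizon,
        pt_grid=(np.asarray(config.pt_grid, float)
                 if config.pt_grid is not None else None))
    deciles = group_cumulative_incidence(cohort, ps_values, horizon,
                                         predictions=pred_full)
    return {
        "label": label, "horizon": horizon,
        "results_clinical": res_clin, "results_full": res_full,
        "auc": auc_cmp, "nri": nri, "nri_ci": nri_ci, "dca": dca,
        "deciles": deciles,
        "hr_table_clinical": res_clin.hr_table(),
        "hr_table_full": res_full.hr_table(),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run; returns the result bundle.

    Writes per-cohort HR tables, a tidy metric table, decision curves,
    PS-decile incidence tables, the cross-cohort comparison and a JSON
    manifest into ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    mh = config.config_hash()

    genotypes, stats, tables, membership = _load_inputs(config)
    ps, report, selected = _build_score(config, genotypes, stats)

    labels = list(tables)
    specs = _resolve_specs(config, labels)
    bundle = {"config_hash": mh, "cohorts": {}, "ps": ps,
              "harmonization": report}
    outputs = []

    pio.write_ps_csv(ps, out / "polygenic_score.csv", mh)
    outputs.append("polygenic_score.csv")
    pio.write_harmonization_report(report, out / "harmonization.json", mh)
    outputs.append("harmonization.json")

    metric_rows = []
    for lab in labels:
        ev = _evaluate_cohort(config, lab, tables[lab], specs[lab], ps)
        bundle["cohorts"][lab] = ev
        pio.write_table(ev["hr_table_clinical"],
                        out / f"hr_table_{lab}_clinical.csv", mh)
        pio.write_table(ev["hr_table_full"],
                        out / f"hr_table_{lab}_full.csv", mh)
        pio.write_table(ev["dca"].table, out / f"decision_curve_{lab}.csv",
                        mh)
        pio.write_table(ev["deciles"], out / f"ps_decile_incidence_{lab}.csv",
                        mh)
        outputs += [f"hr_table_{lab}_clinical.csv", f"hr_table_{lab}_full.csv",
                    f"decision_curve_{lab}.csv",
                    f"ps_decile_incidence_{lab}.csv"]
        a = ev["auc"]
        ps_row = ev["hr_table_full"].set_index("covariate").loc["ps_sd"]
        metric_rows += [
            {"cohort": lab, "metric": "auc_clinical", "model": "clinical",
             "estimate": a.c_base, "lo95": np.nan, "hi95": np.nan},
            {"cohort": lab, "metric": "auc_full", "model": "clinical+PS",
             "estimate": a.c_full, "lo95": np.nan, "hi95": np.nan},
            {"cohort": lab, "metric": "delta_auc", "model": "clinical+PS",
             "estimate": a.delta, "lo95": a.ci95[0], "hi95": a.ci95[1]},
            {"cohort": lab, "metric": "ps_hr_per_sd", "model": "clinical+PS",
             "estimate": ps_row["hr"], "lo95": ps_row["ci_low"],
             "hi95": ps_row["ci_high"]},
            {"cohort": lab, "metric": "nri_total", "model": "clinical+PS",
             "estimate": ev["nri"].total, "lo95": ev["nri_ci"][0],
             "hi95": ev["nri_ci"][1]},
            {"cohort": lab, "metric": "nri_events", "model": "clinical+PS",
             "estimate": ev["nri"].event_component,
             "lo95": np.nan, "hi95": np.nan},
            {"cohort": lab, "metric": "nri_nonevents", "model": "clinical+PS",
             "estimate": ev["nri"].nonevent_component,
             "lo95": np.nan, "hi95": np.nan},
        ]
    metrics_df = pd.DataFrame(metric_rows)
    pio.write_table(metrics_df, out / "metrics.csv", mh)
    outputs.append("metrics.csv")
    bundle["metrics"] = metrics_df

    if len(labels) >= 2:
        try:
            comparison = bootstrap_hr_difference(
                tables, membership, ps, n_boot=config.n_boot_compare,
                seed=config.seed)
            bundle["comparison"] = comparison
            pio.write_table(comparison.table, out / "hr_comparison.csv", mh)
            outputs.append("hr_comparison.csv")
        except PgsRiskError as exc:
            raise PipelineError("compare", exc) from exc

    manifest = {
        "config_hash": mh,
        "seed": config.seed,
        "package": "pgsrisk",
        "n_variants_selected": int(len(selected)),
        "cohorts": {lab: {"n": int(len(tables[lab])),
                          "events": int(tables[lab]["event"].sum()),
                          "horizon": config.horizons.get(lab, 10.0)}
                    for lab in labels},
        "outputs": sorted(outputs),
        "config": config.analysis_dict(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    bundle["manifest"] = manifest
    return bundle
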