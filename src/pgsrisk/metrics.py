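"""Discrimination, reclassification and decision-analytic metrics.

All metrics operate on censored follow-up: Harrell's C over usable pairs
(equivalent to the ROC AUC for fixed-horizon classification), continuous
net reclassification improvement (NRI) at a fixed horizon with bootstrap
confidence intervals, and net benefit across threshold probabilities with
the Kaplan-Meier extension for survival outcomes.

Horizon-status convention: a person is an *event* if their event occurred
by the horizon, a *nonevent* if they were followed beyond the horizon
without the event, and *excluded* if censored before the horizon (their
status at the horizon is unknown).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._exceptions import (AlignmentError, DegenerateGroupingError,
                          InvalidConfigError, ValidationError)

log = logging.getLogger(__name__)

EVENT, NONEVENT, EXCLUDED = 1, 0, -1

#: Default threshold-probability grid for decision curves.
DEFAULT_PT_GRID = np.round(np.arange(0.01, 0.601, 0.01), 2)


def status_at_horizon(time, event, horizon: float) -> np.ndarray:
    """Classify each person at a fixed horizon.

    Returns an int array with 1 (event by horizon), 0 (followed beyond the
    horizon without the event) or -1 (censored before the horizon:
    excluded, status unknown).
    """
    if horizon <= 0:
        raise ValidationError("horizon must be > 0")
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    out = np.full(len(t), EXCLUDED, dtype=int)
    out[(e == 1) & (t <= horizon)] = EVENT
    out[t > horizon] = NONEVENT
    return out


def status_from_cohort(cohort: pd.DataFrame, horizon: float) -> np.ndarray:
    return status_at_horizon(cohort["followup_time"], cohort["event"],
                             horizon)


# ---------------------------------------------------------------------------
# Harrell's C


@dataclass
class ConcordanceResult:
    c_statistic: float
    n_concordant: int
    n_discordant: int
    n_tied: int
    n_usable_pairs: int
    ci95: tuple | None = None

    def __post_init__(self):
        if (self.n_concordant + self.n_discordant + self.n_tied
                != self.n_usable_pairs):
            raise ValidationError("pair counts do not sum to usable pairs")


def _pair_matrices(time, event, score):
    """Ordered-pair matrices for Harrell's C.

    ``U[i, j]`` is 1 when the pair is usable with i as the case (i had the
    event, and j's time exceeds i's — or equals it with j censored);
    ``W[i, j]`` is the concordance credit (1 if the case's score is higher,
    0.5 on a score tie, 0 otherwise).  Each usable unordered pair appears
    in exactly one ordered slot, so sums over both matrices count pairs
    once; with a bootstrap multiplicity vector c, the resampled C is
    (c' W c) / (c' U c).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    s = np.asarray(score, dtype=float)
    case = (e == 1)[:, None]
    later = t[None, :] > t[:, None]
    same_t_cens = (t[None, :] == t[:, None]) & (e[None, :] == 0)
    U = (case & (later | same_t_cens))
    gt = s[:, None] > s[None, :]
    eq = s[:, None] == s[None, :]
    W = U * (gt + 0.5 * eq)
    return U.astype(np.float32), W.astype(np.float32)


def concordance(time, event, score, n_boot: int = 200,
                seed: int | None = 0) -> ConcordanceResult:
    """Harrell's C over usable pairs, with a bootstrap 95% CI.

    A pair is usable if the ordering of the event times is determinable
    under censoring; ties in the score contribute 0.5.  The CI resamples
    individuals (``n_boot=0`` skips it).
    """
    e = np.asarray(event, dtype=int)
    if e.sum() < 1:
        raise ValidationError("need at least one event")
    U, W = _pair_matrices(time, event, score)
    usable = int(round(float(U.sum())))
    if usable == 0:
        raise DegenerateGroupingError("no usable pairs under censoring")
    conc = int(round(float((W == 1.0).sum())))
    tied = int(round(float((W == 0.5).sum())))
    disc = usable - conc - tied
    c = (conc + 0.5 * tied) / usable

    ci = None
    if n_boot:
        rng = np.random.default_rng(seed)
        n = len(e)
        cs = np.empty(n_boot)
        counts = np.zeros((n, n_boot), dtype=np.float32)
        idx = rng.integers(0, n, size=(n_boot, n))
        for b in range(n_boot):
            counts[:, b] = np.bincount(idx[b], minlength=n)
        num = np.einsum("ib,ib->b", counts, W @ counts)
        den = np.einsum("ib,ib->b", counts, U @ counts)
        ok = den > 0
        cs = num[ok] / den[ok]
        ci = (float(np.percentile(cs, 2.5)), float(np.percentile(cs, 97.5)))
    return ConcordanceResult(c_statistic=float(c), n_concordant=conc,
                             n_discordant=disc, n_tied=tied,
                             n_usable_pairs=usable, ci95=ci)


def delta_auc(auc_base: float, auc_full: float) -> float:
    """Difference in AUC (Harrell's C) between nested models."""
    return auc_full - auc_base


@dataclass
class AucComparison:
    c_base: float
    c_full: float
    delta: float
    p: float
    ci95: tuple
    n_boot: int


def compare_auc(score_base, score_full, time, event, n_boot: int = 500,
                seed: int = 0, method: str = "bootstrap") -> AucComparison:
    """Paired comparison of two models' C statistics on shared data.

    Both risk scores must be evaluated on the same individuals.  The
    default resamples individuals once per replicate and re-evaluates both
    C statistics on the shared resample; the p-value is a normal test on
    the bootstrap SE of the difference (``method="jackknife"`` uses
    leave-one-out influence values instead).
    """
    score_base = np.asarray(score_base, float)
    score_full = np.asarray(score_full, float)
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    if not (len(score_base) == len(score_full) == len(t) == len(e)):
        raise AlignmentError("scores and follow-up must share the sample set")
    U, Wa = _pair_matrices(t, e, score_base)
    _, Wb = _pair_matrices(t, e, score_full)
    usable = float(U.sum())
    c_a = float(Wa.sum() / usable)
    c_b = float(Wb.sum() / usable)
    delta = c_b - c_a

    n = len(t)
    rng = np.random.default_rng(seed)
    if method == "bootstrap":
        counts = np.zeros((n, n_boot), dtype=np.float32)
        idx = rng.integers(0, n, size=(n_boot, n))
        for b in range(n_boot):
            counts[:, b] = np.bincount(idx[b], minlength=n)
        den = np.einsum("ib,ib->b", counts, U @ counts)
        num_a = np.einsum("ib,ib->b", counts, Wa @ counts)
        num_b = np.einsum("ib,ib->b", counts, Wb @ counts)
        ok = den > 0
        deltas = num_b[ok] / den[ok] - num_a[ok] / den[ok]
        se = float(deltas.std(ddof=1))
        ci = (float(np.percentile(deltas, 2.5)),
              float(np.percentile(deltas, 97.5)))
    elif method == "jackknife":
        # leave-one-out influence of each subject on the difference
        ones = np.ones(n, dtype=np.float32)
        Ud, Wad, Wbd = U @ ones, Wa @ ones, Wb @ ones
        Uc, Wac, Wbc = U.T @ ones, Wa.T @ ones, Wb.T @ ones
        d_i = np.empty(n)
        tot_u, tot_a, tot_b = float(U.sum()), float(Wa.sum()), float(Wb.sum())
        for i in range(n):
            u_i = tot_u - Ud[i] - Uc[i]
            a_i = tot_a - Wad[i] - Wac[i]
            b_i = tot_b - Wbd[i] - Wbc[i]
            d_i[i] = (b_i - a_i) / u_i if u_i > 0 else 0.0
        se = float(np.sqrt((n - 1) / n * ((d_i - d_i.mean()) ** 2).sum()))
        z = sps.norm.ppf(0.975)
        ci = (delta - z * se, delta + z * se)
    else:
        raise InvalidConfigError("method must be 'bootstrap' or 'jackknife'")

    if se == 0.0:
        p = 1.0
    else:
        p = float(2.0 * sps.norm.sf(abs(delta) / se))
    return AucComparison(c_base=c_a, c_full=c_b, delta=delta, p=p,
                         ci95=ci, n_boot=n_boot)


# ---------------------------------------------------------------------------
# continuous NRI


@dataclass
class NRIResult:
    event_component: float
    nonevent_component: float
    n_events: int
    n_nonevents: int
    n_excluded: int = 0
    horizon: float | None = None
    ci95: tuple | None = None

    @property
    def total(self) -> float:
        """Net proportion of events reclassified up plus nonevents down."""
        return self.event_component + self.nonevent_component


def continuous_nri(pred_base, pred_full, status) -> NRIResult:
    """Continuous (category-free) NRI at a fixed horizon.

    event component = P(up | event) - P(down | event);
    nonevent component = P(down | nonevent) - P(up | nonevent);
    'up' means the full model assigns a strictly higher probability.  Exact
    ties count as neither direction; excluded persons are omitted.
    """
    pb = np.asarray(pred_base, dtype=float)
    pf = np.asarray(pred_full, dtype=float)
    st = np.asarray(status, dtype=int)
    if not (len(pb) == len(pf) == len(st)):
        raise AlignmentError("predictions and status must be aligned")
    ev = st == EVENT
    ne = st == NONEVENT
    n_ev, n_ne = int(ev.sum()), int(ne.sum())
    if n_ev == 0 or n_ne == 0:
        raise ValidationError("need >= 1 event and >= 1 nonevent")
    up = pf > pb
    down = pf < pb
    if not up.any() and not down.any():
        warnings.warn("all predictions tied: NRI carries no information")
        return NRIResult(0.0, 0.0, n_ev, n_ne, int((st == EXCLUDED).sum()))
    ec = (up[ev].mean() - down[ev].mean())
    nc = (down[ne].mean() - up[ne].mean())
    return NRIResult(float(ec), float(nc), n_ev, n_ne,
                     int((st == EXCLUDED).sum()))


def ipcw_nri(pred_base, pred_full, time, event, horizon: float) -> NRIResult:
    """Continuous NRI with inverse-probability-of-censoring weights.

    Persons censored before the horizon still cannot be classified, but
    events and nonevents are reweighted by the inverse probability of
    remaining uncensored (1/G(T-) for events, 1/G(horizon) for nonevents,
    with G the Kaplan-Meier censoring-survival curve), correcting the
    components for censoring that thins the two groups differentially.
    """
    from lifelines import KaplanMeierFitter

    pb = np.asarray(pred_base, float)
    pf = np.asarray(pred_full, float)
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    st = status_at_horizon(t, e, horizon)
    ev = st == EVENT
    ne = st == NONEVENT
    if ev.sum() == 0 or ne.sum() == 0:
        raise ValidationError("need >= 1 event and >= 1 nonevent")
    kmg = KaplanMeierFitter()
    kmg.fit(t, 1 - e)  # censoring distribution
    g_at = kmg.survival_function_at_times
    w = np.zeros(len(t))
    w[ev] = 1.0 / np.maximum(g_at(t[ev] - 1e-9).to_numpy(), 1e-10)
    w[ne] = 1.0 / max(float(g_at(horizon).iloc[0]), 1e-10)
    up = pf > pb
    down = pf < pb
    ec = (w[ev & up].sum() - w[ev & down].sum()) / w[ev].sum()
    nc = (w[ne & down].sum() - w[ne & up].sum()) / w[ne].sum()
    return NRIResult(float(ec), float(nc), int(ev.sum()), int(ne.sum()),
                     int((st == EXCLUDED).sum()), horizon=horizon)


def nri_bootstrap_ci(pred_base, pred_full, time, event, horizon: float,
                     n_boot: int = 1000, seed: int = 0,
                     stratify_by_event: bool = False
                     ) -> tuple[tuple, np.ndarray]:
    """Percentile 95% CI for the total NRI over individual-level resamples.

    Horizon status is re-derived within each replicate.  Replicates with no
    events or no nonevents are dropped (warned about above 10%).  Returns
    ``(ci, replicate_totals)``.
    """
    if n_boot < 100:
        raise InvalidConfigError("n_boot must be >= 100")
    pb = np.asarray(pred_base, float)
    pf = np.asarray(pred_full, float)
    st = status_at_horizon(time, event, horizon)
    up = (pf > pb).astype(float)
    down = (pf < pb).astype(float)
    n = len(pb)
    rng = np.random.default_rng(seed)
    if stratify_by_event:
        # resample separately within the event=1 and event=0 strata,
        # holding each stratum's size fixed
        e_arr = np.asarray(event, int)
        strata = [np.flatnonzero(e_arr == 1), np.flatnonzero(e_arr == 0)]
        parts = [s[rng.integers(0, len(s), size=(n_boot, len(s)))]
                 for s in strata if len(s)]
        idx = np.concatenate(parts, axis=1)
    else:
        idx = rng.integers(0, n, size=(n_boot, n))
    st_b = st[idx]
    ev = st_b == EVENT
    ne = st_b == NONEVENT
    n_ev = ev.sum(axis=1)
    n_ne = ne.sum(axis=1)
    ok = (n_ev > 0) & (n_ne > 0)
    n_dropped = int((~ok).sum())
    if n_dropped > 0.1 * n_boot:
        warnings.warn(f"{n_dropped}/{n_boot} bootstrap replicates dropped "
                      "(no events or no nonevents)")
    up_b, down_b = up[idx], down[idx]
    with np.errstate(invalid="ignore"):
        ec = ((up_b * ev).sum(axis=1) - (down_b * ev).sum(axis=1)) / n_ev
        nc = ((down_b * ne).sum(axis=1) - (up_b * ne).sum(axis=1)) / n_ne
    totals = (ec + nc)[ok]
    ci = (float(np.percentile(totals, 2.5)),
          float(np.percentile(totals, 97.5)))
    return ci, totals


def per_predictor_nri(cohort: pd.DataFrame, spec, horizon: float,
                      extra_scores=None, n_boot: int = 0, seed: int = 0,
                      extrapolate: bool = False) -> pd.DataFrame:
    """NRI of each predictor: full model vs the model without that block.

    Multi-level predictors (parental diabetes, birthweight bins) are
    dropped as a block.  Predictors whose reduced model fails to converge
    are flagged and omitted.  With ``n_boot`` > 0 a bootstrap CI on fixed
    predictions is added.
    """
    from ._exceptions import ConvergenceError
    from .cox import fit_cox, predicted_cumulative_incidence

    full = fit_cox(cohort, spec, extra_scores)
    pred_full = predicted_cumulative_incidence(
        full, cohort, horizon, extra_scores, extrapolate=extrapolate)
    st = status_from_cohort(cohort, horizon)
    rows = []
    for token in spec.covariates:
        reduced_spec = spec.without(token)
        try:
            reduced = fit_cox(cohort, reduced_spec,
                              extra_scores if "ps" in reduced_spec.covariates
                              else None)
        except ConvergenceError as exc:
            log.warning("reduced model without %r failed: %s", token, exc)
            continue
        pred_red = predicted_cumulative_incidence(
            reduced, cohort, horizon,
            extra_scores if "ps" in reduced_spec.covariates else None,
            extrapolate=extrapolate)
        res = continuous_nri(pred_red.probability, pred_full.probability, st)
        row = {"predictor": token, "nri": res.total,
               "event_component": res.event_component,
               "nonevent_component": res.nonevent_component}
        if n_boot:
            ci, _ = nri_bootstrap_ci(pred_red.probability,
                                     pred_full.probability,
                                     cohort["followup_time"],
                                     cohort["event"], horizon,
                                     n_boot=n_boot, seed=seed)
            row["lo95"], row["hi95"] = ci
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# decision curves


def _km_event_prob(time, event, horizon: float) -> float:
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(np.asarray(time, float), np.asarray(event, int))
    return float(1.0 - km.predict(horizon))


def net_benefit(prob, time, event, horizon: float, pt: float) -> float:
    """Net benefit of treating those with predicted risk >= pt.

    With x the proportion selected and F the Kaplan-Meier event probability
    by the horizon among the selected:
    ``net benefit = x*F - x*(1-F) * pt/(1-pt)`` (survival extension of
    decision-curve analysis).  Selecting nobody returns 0 by convention.
    """
    if not 0.0 < pt < 1.0:
        raise InvalidConfigError("pt must lie in (0, 1)")
    prob = np.asarray(prob, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    sel = prob >= pt
    x = float(sel.mean())
    if x == 0.0:
        log.debug("net_benefit: nobody selected at pt=%.3f", pt)
        return 0.0
    f = _km_event_prob(t[sel], e[sel], horizon)
    return x * f - x * (1.0 - f) * pt / (1.0 - pt)


@dataclass
class DecisionCurve:
    """Net benefit per model across a threshold-probability grid."""

    table: pd.DataFrame  # pt, model, net_benefit, proportion_selected
    horizon: float

    def curve(self, model: str) -> pd.DataFrame:
        return self.table[self.table["model"] == model].reset_index(drop=True)

    def marginal_benefit(self, model_a: str, model_b: str) -> pd.DataFrame:
        """Absolute and relative gain of B over A where A's benefit > 0."""
        a = self.curve(model_a).set_index("pt")["net_benefit"]
        b = self.curve(model_b).set_index("pt")["net_benefit"]
        out = pd.DataFrame({"pt": a.index,
                            "absolute": (b - a).to_numpy()})
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(a.to_numpy() > 0,
                           (b - a).to_numpy() / a.to_numpy() * 100.0, np.nan)
        out["relative_pct"] = rel
        return out


def decision_curve(predictions: dict, time, event, horizon: float,
                   pt_grid=None) -> DecisionCurve:
    """Decision-curve analysis for one or more risk models.

    ``predictions`` maps a model label to its per-person predicted
    probabilities by ``horizon``.  Reference strategies ``treat_all``
    (everyone selected; whole-cohort KM incidence) and ``treat_none``
    (identically zero) are always included.
    """
    pt_grid = DEFAULT_PT_GRID if pt_grid is None else np.asarray(pt_grid,
                                                                 float)
    if np.any(np.diff(pt_grid) <= 0) or pt_grid[0] <= 0 or pt_grid[-1] >= 1:
        raise InvalidConfigError("pt_grid must be strictly increasing in (0,1)")
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    f_all = _km_event_prob(t, e, horizon)
    rows = []
    for pt in pt_grid:
        rows.append({"pt": pt, "model": "treat_all",
                     "net_benefit": f_all - (1 - f_all) * pt / (1 - pt),
                     "proportion_selected": 1.0})
        rows.append({"pt": pt, "model": "treat_none",
                     "net_benefit": 0.0, "proportion_selected": 0.0})
    for label, prob in predictions.items():
        prob = np.asarray(prob, dtype=float)
        if len(prob) != len(t):
            raise AlignmentError(f"model {label!r} predictions misaligned")
        for pt in pt_grid:
            rows.append({"pt": pt, "model": label,
                         "net_benefit": net_benefit(prob, t, e, horizon, pt),
                         "proportion_selected": float((prob >= pt).mean())})
    return DecisionCurve(table=pd.DataFrame(rows), horizon=horizon)
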