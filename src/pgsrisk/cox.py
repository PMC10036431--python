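"""Cox proportional-hazards modelling with a Breslow baseline.

The model object follows the statsmodels convention: build a :class:`CoxPH`
from arrays or from a cohort table plus a :class:`ModelSpec`, call
``fit()``, and work with the returned :class:`CoxPHResults` (hazard-ratio
table, ``summary()``, Breslow baseline cumulative hazard, predicted
cumulative incidence at a fixed horizon).

The partial likelihood uses the Breslow approximation for tied event times
(matching the Breslow baseline; Efron is available via ``ties="efron"``)
and is maximized by Newton–Raphson with step-halving.  Predicted cumulative
incidence at horizon ``t`` is ``1 - exp(-H0(t) * exp(lp))`` with the linear
predictor centred at the covariate means used during fitting (predictions
are invariant to the centring).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._exceptions import (ConvergenceError, DegenerateGroupingError,
                          ExtrapolationError, InvalidConfigError,
                          SeparationError, ValidationError)
from .containers import PolygenicScore

# ---------------------------------------------------------------------------
# model specification / covariate encoding


@dataclass(frozen=True)
class ModelSpec:
    """Ordered covariate list for one cohort's Cox model.

    Tokens expand deterministically to design columns:

    ==============  ==================================================
    token           columns
    ==============  ==================================================
    ``age``         baseline age in decades
    ``sex``         female indicator (reference: male)
    ``parental``    mother_diabetic, mother_unknown, father_diabetic,
                    father_unknown (reference: non-diabetic parent)
    ``bmi``         BMI as-is (adult)
    ``bmi_z``       modified BMI z score (youth)
    ``fpg``         fasting plasma glucose, mmol/l
    ``hba1c``       HbA1c, mmol/mol
    ``twohpg``      2 h plasma glucose, mmol/l
    ``birthweight`` two indicators, <3000 g and >4000 g
                    (reference: 3000-4000 g)
    ``ps``          standardized polygenic score (per SD)
    ==============  ==================================================
    """

    cohort: str
    covariates: tuple

    def __init__(self, cohort: str, covariates):
        object.__setattr__(self, "cohort", cohort)
        object.__setattr__(self, "covariates", tuple(covariates))

    def with_ps(self) -> "ModelSpec":
        if "ps" in self.covariates:
            return self
        return ModelSpec(self.cohort, self.covariates + ("ps",))

    def without(self, token: str) -> "ModelSpec":
        return ModelSpec(self.cohort,
                         tuple(c for c in self.covariates if c != token))


#: Cohort-default clinical models: age, sex, parental diabetes, adiposity,
#: FPG and HbA1c for adult/youth; sex, parental diabetes and dichotomised
#: birthweight for the birth cohort.  Horizons: 10 y (adult, youth), 30 y
#: (birth).
DEFAULT_SPECS = {
    "adult": ModelSpec("adult", ("age", "sex", "parental", "bmi",
                                 "fpg", "hba1c")),
    "youth": ModelSpec("youth", ("age", "sex", "parental", "bmi_z",
                                 "fpg", "hba1c")),
    "birth": ModelSpec("birth", ("sex", "parental", "birthweight")),
}

DEFAULT_HORIZONS = {"adult": 10.0, "youth": 10.0, "birth": 30.0}


def build_design(cohort: pd.DataFrame, spec: ModelSpec,
                 extra_scores: PolygenicScore | np.ndarray | None = None
                 ) -> tuple[np.ndarray, list, dict]:
    """Expand a cohort table into a design matrix.

    Returns (X, column_names, blocks) where ``blocks`` maps each covariate
    token to the indices of its columns (multi-level predictors form one
    block, dropped together in leave-one-out comparisons).
    """
    cols: list = []
    names: list = []
    blocks: dict = {}

    def add(token, arrays, colnames):
        blocks[token] = list(range(len(names), len(names) + len(colnames)))
        cols.extend(arrays)
        names.extend(colnames)

    for token in spec.covariates:
        if token == "age":
            add(token, [cohort["baseline_age"].to_numpy(float) / 10.0],
                ["age_decades"])
        elif token == "sex":
            add(token, [(cohort["sex"] == "F").to_numpy(float)], ["sex_F"])
        elif token == "parental":
            arrays, colnames = [], []
            for parent in ("mother", "father"):
                cat = cohort[f"{parent}_diab"]
                arrays.append((cat == "yes").to_numpy(float))
                colnames.append(f"{parent}_diabetic")
                arrays.append((cat == "unknown").to_numpy(float))
                colnames.append(f"{parent}_unknown")
            add(token, arrays, colnames)
        elif token == "birthweight":
            bw = cohort["birthweight_g"].to_numpy(float)
            add(token, [(bw < 3000.0).astype(float),
                        (bw > 4000.0).astype(float)],
                ["bw_lt3000g", "bw_gt4000g"])
        elif token == "ps":
            if extra_scores is None:
                raise InvalidConfigError(
                    "spec includes 'ps' but no score was supplied")
            if isinstance(extra_scores, PolygenicScore):
                ps = extra_scores.reindex(cohort["id"])
            else:
                ps = np.asarray(extra_scores, float)
                if len(ps) != len(cohort):
                    raise ValidationError("score length != cohort rows")
            add(token, [ps], ["ps_sd"])
        elif token in ("bmi", "bmi_z", "fpg", "hba1c", "twohpg"):
            if token not in cohort.columns:
                raise InvalidConfigError(
                    f"cohort table lacks column {token!r} required by spec")
            add(token, [cohort[token].to_numpy(float)], [token])
        else:
            raise InvalidConfigError(f"unknown covariate token {token!r}")
    X = np.column_stack(cols) if cols else np.empty((len(cohort), 0))
    if np.isnan(X).any():
        raise ValidationError("design matrix contains missing values")
    return X, names, blocks


# ---------------------------------------------------------------------------
# Breslow baseline


@dataclass
class BreslowBaseline:
    """Step-function estimate of the baseline cumulative hazard H0(t)."""

    times: np.ndarray      # unique event times, ascending
    cum_hazard: np.ndarray  # H0 at those times

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        out = np.where(idx > 0, self.cum_hazard[np.maximum(idx - 1, 0)], 0.0)
        return out if out.ndim else float(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times,
                             "cum_hazard": self.cum_hazard})


# ---------------------------------------------------------------------------
# partial likelihood internals (data pre-sorted ascending by time)


def _breslow_quantities(beta, Xs, events_idx, first_idx):
    """Loglik, gradient, Hessian under the Breslow tie approximation."""
    n, p = Xs.shape
    lp = Xs @ beta
    lp_shift = lp - lp.max()  # numerical guard, cancels in all ratios
    w = np.exp(lp_shift)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    wxx = np.einsum("i,ij,ik->ijk", w, Xs, Xs)
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    fi = first_idx[events_idx]
    s0e = s0[fi]
    xbar = s1[fi] / s0e[:, None]
    loglik = float(np.sum(lp_shift[events_idx] - np.log(s0e)))
    grad = (Xs[events_idx] - xbar).sum(axis=0)
    hess = -(s2[fi] / s0e[:, None, None]
             - np.einsum("ij,ik->ijk", xbar, xbar)).sum(axis=0)
    return loglik, grad, hess


def _efron_quantities(beta, Xs, time_s, event_s):
    """Loglik/grad/Hessian with the Efron correction for tied events."""
    n, p = Xs.shape
    lp = Xs @ beta
    lp_shift = lp - lp.max()
    w = np.exp(lp_shift)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    wxx = np.einsum("i,ij,ik->ijk", w, Xs, Xs)
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    ev_times = time_s[event_s == 1]
    for t in np.unique(ev_times):
        at = np.flatnonzero((time_s == t) & (event_s == 1))
        first = np.searchsorted(time_s, t, side="left")
        d = len(at)
        sw = w[at].sum()
        swx = (w[at, None] * Xs[at]).sum(axis=0)
        swxx = wxx[at].sum(axis=0)
        for ell in range(d):
            f = ell / d
            a0 = s0[first] - f * sw
            a1 = s1[first] - f * swx
            a2 = s2[first] - f * swxx
            loglik -= np.log(a0)
            xb = a1 / a0
            grad -= xb
            hess -= a2 / a0 - np.outer(xb, xb)
        loglik += lp_shift[at].sum()
        grad += Xs[at].sum(axis=0)
    return float(loglik), grad, hess


# ---------------------------------------------------------------------------
# model / results


class CoxPH:
    """Cox proportional-hazards model (right-censored, Breslow ties).

    Parameters
    ----------
    time, event : arrays of follow-up time (>0) and 0/1 event indicators.
    exog : (n, p) covariate matrix.
    exog_names : optional column names.
    ties : "breslow" (default, consistent with the Breslow baseline) or
        "efron".
    """

    def __init__(self, time, event, exog, exog_names=None,
                 ties: str = "breslow"):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if exog.shape[0] != len(time):
            exog = exog.T
        if exog.shape[0] != len(time) or len(event) != len(time):
            raise ValidationError("time/event/exog lengths differ")
        if (time <= 0).any():
            raise ValidationError("follow-up times must be > 0")
        if event.sum() < 2:
            raise ValidationError("need at least 2 events to fit")
        if ties not in ("breslow", "efron"):
            raise InvalidConfigError("ties must be 'breslow' or 'efron'")
        self.ties = ties
        self.exog_names = (list(exog_names) if exog_names is not None
                           else [f"x{j}" for j in range(exog.shape[1])])
        if len(self.exog_names) != exog.shape[1]:
            raise ValidationError("exog_names length != covariate count")

        self._means = exog.mean(axis=0)
        Xc = exog - self._means
        if exog.shape[1] and np.linalg.matrix_rank(Xc) < exog.shape[1]:
            raise ValidationError(
                "design matrix rank deficient after centring")
        order = np.argsort(time, kind="mergesort")
        self._order = order
        self._time_s = time[order]
        self._event_s = event[order]
        self._X_s = Xc[order]
        self._events_idx = np.flatnonzero(self._event_s == 1)
        self._first_idx = np.searchsorted(self._time_s, self._time_s,
                                          side="left")
        self.n = len(time)
        self.n_events = int(event.sum())

    @classmethod
    def from_spec(cls, cohort: pd.DataFrame, spec: ModelSpec,
                  extra_scores=None, ties: str = "breslow") -> "CoxPH":
        """Build the model from a cohort table and a covariate spec."""
        X, names, blocks = build_design(cohort, spec, extra_scores)
        model = cls(cohort["followup_time"].to_numpy(float),
                    cohort["event"].to_numpy(int), X, names, ties=ties)
        model.spec = spec
        model.blocks = blocks
        model.sample_ids = list(cohort["id"])
        return model

    # -- likelihood interface (public for brute-force cross-checks) --------
    def loglik(self, beta) -> float:
        beta = np.atleast_1d(np.asarray(beta, dtype=float))
        if self.ties == "breslow":
            ll, _, _ = _breslow_quantities(beta, self._X_s, self._events_idx,
                                           self._first_idx)
        else:
            ll, _, _ = _efron_quantities(beta, self._X_s, self._time_s,
                                         self._event_s)
        return ll

    def _quantities(self, beta):
        if self.ties == "breslow":
            return _breslow_quantities(beta, self._X_s, self._events_idx,
                                       self._first_idx)
        return _efron_quantities(beta, self._X_s, self._time_s,
                                 self._event_s)

    def fit(self, max_iter: int = 50, tol_grad: float = 1e-8,
            tol_loglik: float = 1e-10) -> "CoxPHResults":
        p = self._X_s.shape[1]
        beta = np.zeros(p)
        ll, g, H = self._quantities(beta)
        converged = False
        for _ in range(max_iter):
            if np.max(np.abs(beta)) > 40.0:
                raise SeparationError(
                    "diverging coefficients: monotone partial likelihood "
                    "(perfect separation)", gradient_norm=float(
                        np.max(np.abs(g))))
            try:
                step = np.linalg.solve(-H, g)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(
                    f"singular information matrix: {exc}",
                    gradient_norm=float(np.max(np.abs(g)))) from exc
            scale = 1.0
            for _ in range(30):
                beta_new = beta + scale * step
                ll_new, g_new, H_new = self._quantities(beta_new)
                if ll_new >= ll - 1e-14:
                    break
                scale *= 0.5
            rel_change = abs(ll_new - ll) / max(abs(ll), 1.0)
            beta, ll, g, H = beta_new, ll_new, g_new, H_new
            if np.max(np.abs(g), initial=0.0) < tol_grad \
                    or rel_change < tol_loglik:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"Newton-Raphson did not converge in {max_iter} iterations",
                gradient_norm=float(np.max(np.abs(g), initial=0.0)))
        # monotone likelihoods flatten out (gradient -> 0) at extreme
        # coefficients, so separation can look like convergence
        if np.max(np.abs(beta), initial=0.0) > 15.0:
            raise SeparationError(
                "diverging coefficients: monotone partial likelihood "
                "(perfect separation)",
                gradient_norm=float(np.max(np.abs(g), initial=0.0)))

        cov = np.linalg.inv(-H) if p else np.empty((0, 0))
        baseline = self._breslow_baseline(beta)
        return CoxPHResults(model=self, params=beta, cov_params=cov,
                            loglik=ll, baseline=baseline, converged=True)

    def _breslow_baseline(self, beta) -> BreslowBaseline:
        """Breslow H0 increments d_k / sum_{risk set} exp(lp) at event times."""
        lp = self._X_s @ beta  # centred by construction
        w = np.exp(lp)
        s0 = np.cumsum(w[::-1])[::-1]
        ev_times = self._time_s[self._event_s == 1]
        uniq, counts = np.unique(ev_times, return_counts=True)
        first = np.searchsorted(self._time_s, uniq, side="left")
        increments = counts / s0[first]
        return BreslowBaseline(times=uniq,
                               cum_hazard=np.cumsum(increments))


@dataclass
class RiskPrediction:
    """Predicted probability of the event by a fixed horizon, per person."""

    sample_ids: list
    horizon: float
    probability: np.ndarray
    model_label: str = ""

    def __post_init__(self):
        self.probability = np.asarray(self.probability, dtype=float)
        if self.horizon <= 0:
            raise ValidationError("horizon must be > 0")
        pr = self.probability
        if ((pr < 0) | (pr > 1)).any():
            raise ValidationError("probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.sample_ids,
                             "horizon": self.horizon,
                             "probability": self.probability,
                             "model": self.model_label})


class CoxPHResults:
    """Fitted Cox model: estimates, covariance, baseline, predictions."""

    def __init__(self, model: CoxPH, params, cov_params, loglik,
                 baseline: BreslowBaseline, converged: bool):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.cov_params = np.asarray(cov_params, dtype=float)
        self.loglik = float(loglik)
        self.baseline = baseline
        self.converged = bool(converged)
        self.exog_names = model.exog_names
        self.n = model.n
        self.n_events = model.n_events

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * sps.norm.sf(np.abs(self.zvalues))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = sps.norm.ppf(1.0 - alpha / 2.0)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return np.column_stack([lo, hi])

    def hr_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per-covariate HR, 95% CI and two-sided Wald p."""
        ci = np.exp(self.conf_int(alpha))
        return pd.DataFrame({
            "covariate": self.exog_names,
            "hr": self.hazard_ratios,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p": self.pvalues,
        })

    def summary(self) -> str:
        head = (f"Cox proportional hazards ({self.model.ties} ties)\n"
                f"n = {self.n}, events = {self.n_events}, "
                f"log partial likelihood = {self.loglik:.4f}\n")
        tbl = self.hr_table()
        lines = [head,
                 f"{'covariate':<18}{'HR':>8}{'95% CI':>20}{'p':>12}"]
        for rec in tbl.itertuples(index=False):
            lines.append(f"{rec.covariate:<18}{rec.hr:>8.3f}"
                         f"{f'({rec.ci_low:.3f}, {rec.ci_high:.3f})':>20}"
                         f"{rec.p:>12.3g}")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        """JSON-ready payload: estimates, covariance, Breslow baseline."""
        return {
            "covariate_names": list(self.exog_names),
            "params": self.params.tolist(),
            "cov_params": self.cov_params.tolist(),
            "covariate_means": self.model._means.tolist(),
            "loglik": self.loglik,
            "n": self.n,
            "n_events": self.n_events,
            "ties": self.model.ties,
            "baseline_times": self.baseline.times.tolist(),
            "baseline_cum_hazard": self.baseline.cum_hazard.tolist(),
        }

    def save_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    # -- prediction ---------------------------------------------------------
    def linear_predictor(self, exog=None) -> np.ndarray:
        """Centred linear predictor for new covariates (default: training)."""
        if exog is None:
            Xc = self.model._X_s[np.argsort(self.model._order)]
        else:
            exog = np.atleast_2d(np.asarray(exog, dtype=float))
            Xc = exog - self.model._means
        return Xc @ self.params

    def predict_cumulative_incidence(self, horizon: float, exog=None,
                                     sample_ids=None,
                                     extrapolate: bool = False,
                                     label: str = "") -> RiskPrediction:
        """P(event by ``horizon``) = 1 - exp(-H0(horizon) * exp(lp))."""
        if horizon <= 0:
            raise ValidationError("horizon must be > 0")
        last = self.baseline.times[-1] if len(self.baseline.times) else 0.0
        if horizon > self.model._time_s[-1] and not extrapolate:
            raise ExtrapolationError(
                f"horizon {horizon} beyond last observed time "
                f"{self.model._time_s[-1]:.3f}; pass extrapolate=True")
        del last
        lp = self.linear_predictor(exog)
        h0 = self.baseline(horizon)
        prob = 1.0 - np.exp(-h0 * np.exp(lp))
        ids = sample_ids
        if ids is None:
            ids = getattr(self.model, "sample_ids", None) if exog is None \
                else list(range(len(lp)))
            if ids is None:
                ids = list(range(len(lp)))
        return RiskPrediction(sample_ids=list(ids), horizon=horizon,
                              probability=prob, model_label=label)


# ---------------------------------------------------------------------------
# functional wrappers mirroring the pipeline vocabulary


def fit_cox(cohort: pd.DataFrame, spec: ModelSpec, extra_scores=None,
            ties: str = "breslow") -> CoxPHResults:
    """Fit a cohort's Cox model from its table and covariate spec."""
    return CoxPH.from_spec(cohort, spec, extra_scores, ties=ties).fit()


def hr_table(results: CoxPHResults) -> pd.DataFrame:
    return results.hr_table()


def predicted_cumulative_incidence(results: CoxPHResults,
                                   cohort: pd.DataFrame, horizon: float,
                                   extra_scores=None,
                                   extrapolate: bool = False,
                                   label: str = "") -> RiskPrediction:
    """Predicted incidence by ``horizon`` for the rows of ``cohort``."""
    spec = getattr(results.model, "spec", None)
    if spec is None:
        raise InvalidConfigError(
            "results were not fit from a spec; use "
            "results.predict_cumulative_incidence with an exog matrix")
    X, _, _ = build_design(cohort, spec, extra_scores)
    return results.predict_cumulative_incidence(
        horizon, exog=X, sample_ids=list(cohort["id"]),
        extrapolate=extrapolate, label=label)


def km_incidence_at(time, event, horizon: float) -> float:
    """Kaplan-Meier complement (cumulative incidence) at ``horizon``."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(np.asarray(time, float), np.asarray(event, int))
    return float(1.0 - km.predict(horizon))


def group_cumulative_incidence(cohort: pd.DataFrame, values,
                               horizon: float, n_groups: int = 10,
                               predictions: RiskPrediction | None = None
                               ) -> pd.DataFrame:
    """Observed (KM) and optionally predicted incidence by quantile group.

    ``values`` is the grouping score (PS, or a clinical linear predictor);
    groups are formed by its quantiles (deciles by default, as in
    PS-decile incidence curves).
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(cohort):
        raise ValidationError("grouping values length != cohort rows")
    qs = np.quantile(values, np.linspace(0, 1, n_groups + 1))
    group = np.clip(np.searchsorted(qs, values, side="right") - 1,
                    0, n_groups - 1)
    rows = []
    t = cohort["followup_time"].to_numpy(float)
    e = cohort["event"].to_numpy(int)
    for g in range(n_groups):
        mask = group == g
        if mask.sum() == 0:
            raise DegenerateGroupingError(f"group {g} is empty")
        row = {"group": g + 1, "n": int(mask.sum()),
               "n_events": int(e[mask].sum()),
               "observed_incidence": km_incidence_at(t[mask], e[mask],
                                                     horizon)}
        if predictions is not None:
            row["predicted_incidence"] = float(
                predictions.probability[mask].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def risk_surface(results: CoxPHResults, ps_values, horizon: float,
                 ps_quantiles=(0.1, 0.3, 0.5, 0.7, 0.9),
                 lp_percentiles=(10, 25, 50, 75, 90)) -> pd.DataFrame:
    """Predicted incidence on a PS x clinical-risk grid.

    ``results`` must be a full model whose last-listed block is the PS; the
    clinical linear predictor is the fitted lp minus the PS term, and the
    surface evaluates 1 - exp(-H0(h) * exp(lp_clin + beta_ps * ps)) at
    combinations of clinical-lp percentiles and PS quantiles.
    """
    names = results.exog_names
    if "ps_sd" not in names:
        raise InvalidConfigError("risk_surface needs a model containing 'ps'")
    j = names.index("ps_sd")
    ps_values = np.asarray(ps_values, dtype=float)
    lp_full = results.linear_predictor()
    ps_centred = ps_values - results.model._means[j]
    lp_clin = lp_full - results.params[j] * ps_centred
    h0 = results.baseline(horizon)
    rows = []
    for pct in lp_percentiles:
        lc = np.percentile(lp_clin, pct)
        for q in ps_quantiles:
            psq = np.quantile(ps_values, q) - results.model._means[j]
            lp = lc + results.params[j] * psq
            rows.append({"clinical_lp_percentile": pct, "ps_quantile": q,
                         "predicted_incidence": 1.0 - np.exp(-h0 * np.exp(lp))})
    return pd.DataFrame(rows)


def calibration_bins(pred: RiskPrediction, cohort: pd.DataFrame,
                     n_bins: int = 10) -> pd.DataFrame:
    """Mean predicted vs observed KM incidence by predicted-risk decile."""
    if n_bins < 2:
        raise InvalidConfigError("n_bins must be >= 2")
    from lifelines import KaplanMeierFitter

    prob = pred.probability
    if np.ptp(prob) < 1e-12:
        warnings.warn("constant predictions: calibration collapses to one bin")
        edges = np.array([prob.min() - 1e-9, prob.max() + 1e-9])
    else:
        edges = np.quantile(prob, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
    binid = np.clip(np.searchsorted(edges, prob, side="right") - 1,
                    0, len(edges) - 2)
    t = cohort["followup_time"].to_numpy(float)
    e = cohort["event"].to_numpy(int)
    rows = []
    for b in range(len(edges) - 1):
        mask = binid == b
        if mask.sum() == 0:
            continue
        km = KaplanMeierFitter()
        km.fit(t[mask], e[mask])
        obs = float(1.0 - km.predict(pred.horizon))
        try:
            ci = km.confidence_interval_survival_function_
            idx = ci.index.searchsorted(pred.horizon, side="right") - 1
            lo = float(1.0 - ci.iloc[max(idx, 0), 1])
            hi = float(1.0 - ci.iloc[max(idx, 0), 0])
        except Exception:
            lo = hi = np.nan
        rows.append({"bin": b + 1, "n": int(mask.sum()),
                     "mean_predicted": float(prob[mask].mean()),
                     "observed_incidence": obs,
                     "observed_lo95": lo, "observed_hi95": hi})
    return pd.DataFrame(rows)
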