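"""Bootstrap comparison of PS hazard ratios across overlapping cohorts.

Cohorts drawn from one longitudinal study overlap in membership, so their
HR estimates are dependent; the comparison resamples *persons* (a sampled
person contributes all of their cohort rows, preserving the cross-cohort
dependence), refits the unadjusted per-SD Cox HR in each cohort per
replicate, and tests the observed log-HR difference against its bootstrap
standard error with a two-sided normal (Wald) test.  A percentile p-value
is available behind ``method="percentile"``.

The PS keeps its original (full-sample) standardization in every
replicate, so HRs remain per SD of the same score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._exceptions import InvalidConfigError, SeparationError, ValidationError
from .containers import MembershipMap, PolygenicScore

log = logging.getLogger(__name__)


def _fast_cox_1d(time, event, x, max_iter: int = 40,
                 tol: float = 1e-9) -> float:
    """Newton-Raphson for a single-covariate Cox model (Breslow ties)."""
    order = np.argsort(time, kind="mergesort")
    t = time[order]
    e = event[order]
    xs = x[order] - x.mean()
    ev = np.flatnonzero(e == 1)
    if len(ev) < 2:
        raise ValidationError("need at least 2 events")
    fi = np.searchsorted(t, t[ev], side="left")
    xe_sum = xs[ev].sum()
    beta = 0.0
    for _ in range(max_iter):
        w = np.exp(np.clip(beta * xs, -300.0, 300.0))
        wx = w * xs
        s0 = np.cumsum(w[::-1])[::-1][fi]
        s1 = np.cumsum(wx[::-1])[::-1][fi]
        s2 = np.cumsum((wx * xs)[::-1])[::-1][fi]
        xbar = s1 / s0
        g = xe_sum - xbar.sum()
        h = -(s2 / s0 - xbar * xbar).sum()
        if h >= 0.0:  # flat likelihood (constant covariate)
            return 0.0
        step = np.clip(-g / h, -2.0, 2.0)
        beta += step
        if abs(beta) > 40.0:
            raise SeparationError("diverging coefficient in 1-d Cox fit")
        if abs(g) < tol or abs(step) < 1e-12:
            break
    return float(beta)


@dataclass
class CohortComparison:
    """Pairwise bootstrap comparison of per-SD log hazard ratios."""

    table: pd.DataFrame  # cohort_a, cohort_b, log_hr_a, log_hr_b,
                         # delta_log_hr, se, p, n_boot, n_dropped
    log_hr: dict
    n_boot: int
    n_dropped: int
    seed: int
    replicates: pd.DataFrame | None = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def bootstrap_hr_difference(cohorts: dict, membership: MembershipMap,
                            ps: PolygenicScore, n_boot: int = 2000,
                            seed: int = 0, method: str = "wald",
                            keep_replicates: bool = False
                            ) -> CohortComparison:
    """Compare unadjusted PS hazard ratios across overlapping cohorts.

    Parameters
    ----------
    cohorts : dict mapping label -> cohort table (one row per person).
    membership : person -> cohort labels map covering every row.
    ps : standardized PS covering every person (fixed standardization).
    n_boot : person-level bootstrap replicates.
    method : "wald" (normal test on bootstrap SE, default) or
        "percentile" (sign-flip percentile p from centred replicates).
    """
    if method not in ("wald", "percentile"):
        raise InvalidConfigError("method must be 'wald' or 'percentile'")
    labels = list(cohorts)
    if len(labels) < 2:
        raise InvalidConfigError("need at least two cohorts to compare")
    membership.validate_against(cohorts)
    persons = membership.person_ids
    person_idx = {p: i for i, p in enumerate(persons)}
    n_persons = len(persons)

    data = {}
    for lab in labels:
        tab = cohorts[lab]
        if tab["id"].duplicated().any():
            raise ValidationError(
                f"cohort {lab!r} has duplicate person rows")
        t = tab["followup_time"].to_numpy(float)
        e = tab["event"].to_numpy(int)
        if e.sum() < 2:
            raise ValidationError(f"cohort {lab!r} has fewer than 2 events")
        x = ps.reindex(tab["id"])
        row_of = np.full(n_persons, -1, dtype=np.int64)
        for r, pid in enumerate(tab["id"]):
            row_of[person_idx[pid]] = r
        data[lab] = (t, e, x, row_of)

    observed = {lab: _fast_cox_1d(*data[lab][:3]) for lab in labels}

    rng = np.random.default_rng(seed)
    reps = {lab: np.full(n_boot, np.nan) for lab in labels}
    n_dropped = 0
    for b in range(n_boot):
        sampled = rng.integers(0, n_persons, size=n_persons)
        ok = True
        vals = {}
        for lab in labels:
            t, e, x, row_of = data[lab]
            rows = row_of[sampled]
            rows = rows[rows >= 0]
            if e[rows].sum() < 2:
                ok = False
                break
            try:
                vals[lab] = _fast_cox_1d(t[rows], e[rows], x[rows])
            except SeparationError:
                ok = False
                break
        if not ok:
            n_dropped += 1
            continue
        for lab in labels:
            reps[lab][b] = vals[lab]
    if n_dropped > 0.05 * n_boot:
        warnings.warn(f"{n_dropped}/{n_boot} bootstrap replicates dropped")

    rows = []
    for a, bl in combinations(labels, 2):
        diff = reps[a] - reps[bl]
        diff = diff[np.isfinite(diff)]
        if len(diff) < 2:
            raise ValidationError("too few usable bootstrap replicates")
        delta = observed[a] - observed[bl]
        se = float(diff.std(ddof=1))
        if method == "wald":
            p = float(2.0 * sps.norm.sf(abs(delta) / se)) if se > 0 else 1.0
        else:
            centred = diff - diff.mean()
            p = float(min(1.0, 2.0 * min(
                (centred >= abs(delta)).mean() + 0.5 / len(diff),
                (centred <= -abs(delta)).mean() + 0.5 / len(diff))))
        rows.append({"cohort_a": a, "cohort_b": bl,
                     "log_hr_a": observed[a], "log_hr_b": observed[bl],
                     "delta_log_hr": delta, "se": se, "p": min(p, 1.0),
                     "n_boot": n_boot, "n_dropped": n_dropped})
    table = pd.DataFrame(rows)
    rep_df = pd.DataFrame(reps) if keep_replicates else None
    return CohortComparison(table=table, log_hr=observed, n_boot=n_boot,
                            n_dropped=n_dropped, seed=seed,
                            replicates=rep_df)
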