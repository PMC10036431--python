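"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration) and shares no code with the package implementations it
cross-checks.
"""

import numpy as np


def harrell_c_enumeration(time, event, score):
    """O(n^2) pair enumeration of Harrell's C under right censoring.

    A pair is usable when the event-time ordering is determinable: the
    earlier subject had the event, or times are equal and exactly one had
    the event.  Returns (c, concordant, discordant, tied, usable).
    """
    n = len(time)
    conc = disc = tied = usable = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # i is the case of the ordered pair
            if event[i] != 1:
                continue
            if not (time[j] > time[i]
                    or (time[j] == time[i] and event[j] == 0)):
                continue
            usable += 1
            if score[i] > score[j]:
                conc += 1
            elif score[i] < score[j]:
                disc += 1
            else:
                tied += 1
    c = (conc + 0.5 * tied) / usable if usable else np.nan
    return c, conc, disc, tied, usable


def cox_loglik_1cov(beta, time, event, x):
    """Hand-written Breslow partial log likelihood, one covariate."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] != 1:
            continue
        risk = [j for j in range(len(time)) if time[j] >= time[i]]
        ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


def golden_section_max(f, lo=-10.0, hi=10.0, tol=1e-8):
    """Golden-section maximizer of a unimodal scalar function."""
    g = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - g * (b - a), a + g * (b - a)
    fc, fd = f(c), f(d)
    while abs(b - a) > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - g * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + g * (b - a)
            fd = f(d)
    return (a + b) / 2


def km_survival_at(time, event, horizon):
    """Hand Kaplan-Meier survival probability at a horizon."""
    order = np.argsort(time)
    t = np.asarray(time, float)[order]
    e = np.asarray(event, int)[order]
    s = 1.0
    for tt in sorted(set(t[e == 1])):
        if tt > horizon:
            break
        d = int(((t == tt) & (e == 1)).sum())
        at_risk = int((t >= tt).sum())
        s *= 1.0 - d / at_risk
    return s


def greedy_pt_selection(records, r2, p_threshold, window_bp, r2_max):
    """Exhaustive greedy pruning-and-thresholding reference.

    ``records`` is a list of dicts with chrom, pos, effect_allele,
    other_allele, p; ``r2`` maps frozenset pairs of record indices to
    squared correlation.  Returns selected record indices in selection
    order.
    """
    order = sorted(
        range(len(records)),
        key=lambda i: (records[i]["p"], records[i]["chrom"],
                       records[i]["pos"], records[i]["effect_allele"],
                       records[i]["other_allele"]))
    selected = []
    for i in order:
        if not records[i]["p"] < p_threshold:
            continue
        ok = True
        for j in selected:
            if records[i]["chrom"] != records[j]["chrom"]:
                continue
            if abs(records[i]["pos"] - records[j]["pos"]) > window_bp:
                continue
            if r2.get(frozenset((i, j)), 0.0) > r2_max:
                ok = False
                break
        if ok:
            selected.append(i)
    return selected


def nri_by_hand(pred_base, pred_full, is_event, is_nonevent):
    """Continuous NRI by explicit counting."""
    up_e = down_e = up_n = down_n = 0
    n_e = n_n = 0
    for pb, pf, ev, ne in zip(pred_base, pred_full, is_event, is_nonevent):
        if ev:
            n_e += 1
            if pf > pb:
                up_e += 1
            elif pf < pb:
                down_e += 1
        elif ne:
            n_n += 1
            if pf > pb:
                up_n += 1
            elif pf < pb:
                down_n += 1
    return (up_e - down_e) / n_e + (down_n - up_n) / n_n
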