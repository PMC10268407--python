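"""Independent brute-force oracles used by the test suite.

These deliberately re-state the rules literally and inefficiently, sharing no
code with the package implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# ---------------------------------------------------------------------------
# CA125 rules, literal form.  Series are [(day, value)] with day relative to
# treatment start (day 0); the pre-treatment sample is the latest sample with
# -window <= day <= 0.
# ---------------------------------------------------------------------------


def oracle_pretreatment(series, window_days=14):
    pre = [(d, v) for d, v in series if -window_days <= d <= 0]
    if not pre:
        return None
    return max(pre, key=lambda s: s[0])


def oracle_eligible(series, uln, window_days=14):
    pre = oracle_pretreatment(series, window_days)
    return pre is not None and pre[1] >= 2 * uln


def oracle_response(series, uln, window_days=14):
    """50% fall from pre-treatment, still seen >= 28 days later, never
    breached in between.  Returns (responded, day of first qualifying s1)."""
    if not oracle_eligible(series, uln, window_days):
        return False, None
    pre = oracle_pretreatment(series, window_days)[1]
    post = sorted((d, v) for d, v in series if d > 0)
    half = 0.5 * pre
    for i, (d1, v1) in enumerate(post):
        if v1 > half:
            continue
        for j in range(i + 1, len(post)):
            d2, v2 = post[j]
            if d2 - d1 < 28 or v2 > half:
                continue
            between = post[i + 1 : j]
            if all(v <= half for _, v in between):
                return True, d1
    return False, None


def oracle_progression(series, uln, window_days=14):
    """Rise to >= 2 x (nadir, or ULN when the marker normalised), on two
    occasions >= 7 days apart; date = first of the pair; threshold frozen at
    the first qualifying sample."""
    pre = oracle_pretreatment(series, window_days)
    post = sorted((d, v) for d, v in series if d > 0)
    if len(post) < 2:
        return False, None
    for i, (d1, v1) in enumerate(post):
        vals_so_far = [v for _, v in post[: i + 1]]
        if pre is not None:
            vals_so_far.append(pre[1])
        nadir = min(vals_so_far)
        threshold = 2 * (uln if nadir <= uln else nadir)
        if v1 < threshold:
            continue
        for d2, v2 in post[i + 1 :]:
            if d2 - d1 >= 7 and v2 >= threshold:
                return True, d1
    return False, None


# ---------------------------------------------------------------------------
# Log-rank: risk-table statistic written from the textbook formula, plus an
# exhaustive/Monte-Carlo permutation p-value based on that statistic.
# ---------------------------------------------------------------------------


def oracle_logrank_chi2(times_a, events_a, times_b, events_b):
    times = list(times_a) + list(times_b)
    events = list(events_a) + list(events_b)
    in_a = [True] * len(times_a) + [False] * len(times_b)
    event_times = sorted({t for t, e in zip(times, events) if e})
    O = E = V = 0.0
    for t in event_times:
        at_risk = [i for i, ti in enumerate(times) if ti >= t]
        deaths = [i for i, (ti, ei) in enumerate(zip(times, events)) if ti == t and ei]
        n = len(at_risk)
        d = len(deaths)
        n1 = sum(in_a[i] for i in at_risk)
        d1 = sum(in_a[i] for i in deaths)
        O += d1
        E += n1 * d / n
        if n > 1:
            V += (n1 / n) * (1 - n1 / n) * d * (n - d) / (n - 1)
    if V == 0:
        return 0.0
    return (O - E) ** 2 / V


def oracle_permutation_p(times, events, n_a, max_perms=10000, seed=0):
    """Permutation p-value of the log-rank chi-square under random relabelling
    of which ``n_a`` subjects form group A.  Exhaustive when feasible."""
    n = len(times)
    idx = list(range(n))

    def chi2_for(a_set):
        ta = [times[i] for i in a_set]
        ea = [events[i] for i in a_set]
        tb = [times[i] for i in idx if i not in a_set]
        eb = [events[i] for i in idx if i not in a_set]
        return oracle_logrank_chi2(ta, ea, tb, eb)

    observed = chi2_for(set(range(n_a)))
    n_comb = math.comb(n, n_a)
    if n_comb <= max_perms:
        assignments = [set(c) for c in itertools.combinations(idx, n_a)]
    else:
        rng = np.random.default_rng(seed)
        assignments = [
            set(rng.choice(n, size=n_a, replace=False)) for _ in range(max_perms)
        ]
    hits = sum(chi2_for(a) >= observed - 1e-12 for a in assignments)
    return observed, hits / len(assignments)
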