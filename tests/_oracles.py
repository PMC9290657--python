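"""Independent brute-force oracles used only by the tests.

Every function here evaluates its quantity by direct enumeration of the
defining sets, with no shared code with the package internals.
"""

from __future__ import annotations

import numpy as np


def enumerate_risk_sets(y, v, e, adjust):
    """[(event_time, d, indices)] by literal application of the definition."""
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    e = np.asarray(e, dtype=int)
    out = []
    for t in sorted(set(y[e == 1])):
        members = [
            j for j in range(len(y))
            if y[j] >= t and (not adjust or v[j] < t)
        ]
        d = int(sum((y == t) & (e == 1)))
        out.append((t, d, members))
    return out


def brute_partial_loglik(y, v, e, X, beta, adjust):
    """Breslow partial log-likelihood by explicit risk-set summation."""
    eta = np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)
    ll = 0.0
    for t, d, members in enumerate_risk_sets(y, v, e, adjust):
        if not members:
            raise ZeroDivisionError("empty risk set")
        failing = [j for j in range(len(y)) if y[j] == t and e[j] == 1]
        ll += sum(eta[j] for j in failing)
        ll -= d * np.log(sum(np.exp(eta[j]) for j in members))
    return ll


def brute_breslow_cumhaz(y, v, e, X, beta, adjust):
    """(times, cumhaz) of the Breslow baseline by explicit enumeration."""
    eta = np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)
    times, cumhaz = [], []
    total = 0.0
    for t, d, members in enumerate_risk_sets(y, v, e, adjust):
        if not members:
            raise ZeroDivisionError("empty risk set")
        total += d / sum(np.exp(eta[j]) for j in members)
        times.append(t)
        cumhaz.append(total)
    return np.array(times), np.array(cumhaz)


def brute_km(times, events, entries=None):
    """(event_times, survival) product-limit by explicit at-risk counting."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    entries = np.zeros_like(times) if entries is None else np.asarray(entries, dtype=float)
    ts, surv = [], []
    s = 1.0
    for t in sorted(set(times[events == 1])):
        at_risk = sum(1 for j in range(len(times)) if entries[j] < t <= times[j])
        d = int(sum((times == t) & (events == 1)))
        s *= 1.0 - d / at_risk
        ts.append(t)
        surv.append(s)
    return np.array(ts), np.array(surv)


def brute_concordance(times, events, scores):
    """Harrell's C by exhaustive pair enumeration (score ties count 1/2)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    scores = np.asarray(scores, dtype=float)
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(i + 1, n):
            if times[i] == times[j]:
                continue
            short, lng = (i, j) if times[i] < times[j] else (j, i)
            if not events[short]:
                continue
            den += 1.0
            if scores[short] > scores[lng]:
                num += 1.0
            elif scores[short] == scores[lng]:
                num += 0.5
    if den == 0:
        raise ZeroDivisionError("no comparable pairs")
    return num / den


def random_ltrc_case(rng, n_max=8, p_max=2, tie_prob=0.5):
    """Small random LTRC dataset on a coarse grid (ties are likely).

    Returns (y, v, e, X) with at least one event and every row y > v.
    """
    n = int(rng.integers(2, n_max + 1))
    p = int(rng.integers(1, p_max + 1))
    if rng.random() < tie_prob:
        y = rng.integers(1, 5, size=n).astype(float)
    else:
        y = np.round(rng.uniform(0.5, 5.0, size=n), 3)
    v = np.where(rng.random(n) < 0.5, 0.0, np.round(rng.uniform(0.0, 3.0, size=n), 3))
    v = np.minimum(v, y - 0.25)
    v = np.maximum(v, 0.0)
    e = rng.integers(0, 2, size=n)
    if e.sum() == 0:
        e[int(rng.integers(0, n))] = 1
    X = np.round(rng.standard_normal((n, p)), 3)
    return y, v, e.astype(int), X
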