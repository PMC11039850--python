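"""Independent naive oracles for the GV metrics and the regression algebra.

Everything here is deliberately written as plain loops / closed-form algebra,
sharing no code path with the package implementations it checks.
"""

import math

import numpy as np

K = 18.016


def naive_mean_sd(values):
    n = len(values)
    m = sum(values) / n
    var = sum((v - m) ** 2 for v in values) / (n - 1)
    return m, math.sqrt(var)


def _nearest_index(seconds, target, tol):
    best, best_d = None, None
    for j, s in enumerate(seconds):
        d = abs(s - target)
        if d <= tol and (best_d is None or d < best_d):
            best, best_d = j, d
    return best


def naive_conga(seconds, values, lag_minutes=60.0, cadence_minutes=15.0):
    tol = cadence_minutes * 60 / 2
    diffs = []
    for i, t in enumerate(seconds):
        j = _nearest_index(seconds, t - lag_minutes * 60, tol)
        if j is not None:
            diffs.append(values[i] - values[j])
    if len(diffs) < 2:
        return None
    _, sd = naive_mean_sd(diffs)
    return sd / K


def naive_li(seconds, values, interval_minutes=60.0, cadence_minutes=15.0):
    tol = cadence_minutes * 60 / 2
    picked = []
    t = 0.0
    while t <= seconds[-1] + tol:
        j = _nearest_index(seconds, t, tol)
        if j is not None and (not picked or j != picked[-1]):
            picked.append(j)
        t += interval_minutes * 60
    if len(picked) < 2:
        return None
    total = 0.0
    for a, b in zip(picked, picked[1:]):
        dg = (values[b] - values[a]) / K
        dt_h = (seconds[b] - seconds[a]) / 3600
        total += dg * dg / dt_h
    days = max((seconds[-1] - seconds[0]) / 86400, 1.0)
    return total / days


def naive_j_index(values):
    m, sd = naive_mean_sd(values)
    return 0.001 * (m + sd) ** 2


def risk_f(g):
    return 1.509 * (math.log(g) ** 1.084 - 5.381)


def naive_bgi(values):
    rl, rh = [], []
    for g in values:
        f = risk_f(g)
        r = 10 * f * f
        rl.append(r if f < 0 else 0.0)
        rh.append(r if f > 0 else 0.0)
    return sum(rl) / len(rl), sum(rh) / len(rh)


def naive_adrr(dates, values, min_readings=12):
    by_day = {}
    for d, v in zip(dates, values):
        by_day.setdefault(d, []).append(v)
    daily = []
    for d in sorted(by_day):
        vs = by_day[d]
        if len(vs) < min_readings:
            continue
        lr = max((10 * risk_f(v) ** 2 if risk_f(v) < 0 else 0.0) for v in vs)
        hr = max((10 * risk_f(v) ** 2 if risk_f(v) > 0 else 0.0) for v in vs)
        daily.append(lr + hr)
    if not daily:
        return None
    return sum(daily) / len(daily)


def naive_grade(values, cap=50.0):
    hs = []
    for g in values:
        g_mmol = g / K
        if g_mmol <= 1.0:
            continue
        h = 425 * (math.log10(math.log10(g_mmol)) + 0.16) ** 2
        hs.append(min(h, cap))
    return sum(hs) / len(hs) if hs else None


def naive_mage(values):
    n = len(values)
    if n < 4:
        return None
    _, sd = naive_mean_sd(values)
    collapsed = [values[0]]
    for v in values[1:]:
        if v != collapsed[-1]:
            collapsed.append(v)
    if len(collapsed) < 3 or sd == 0:
        return 0.0
    turning = []
    for i in range(1, len(collapsed) - 1):
        a, b, c = collapsed[i - 1], collapsed[i], collapsed[i + 1]
        if (b > a and b > c) or (b < a and b < c):
            turning.append(b)
    amps = [abs(y - x) for x, y in zip(turning, turning[1:]) if abs(y - x) > sd]
    return (sum(amps) / len(amps) / K) if amps else 0.0


def naive_modd(seconds, values, cadence_minutes=15.0):
    tol = cadence_minutes * 60 / 2
    diffs = []
    for i, t in enumerate(seconds):
        j = _nearest_index(seconds, t - 86400, tol)
        if j is not None:
            diffs.append(abs(values[i] - values[j]))
    if not diffs:
        return None
    return sum(diffs) / len(diffs) / K


def naive_m_value(values, reference=120.0):
    return sum(abs(10 * math.log10(g / reference)) ** 3 for g in values) / len(values)


def naive_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def normal_equations_ols(y, *columns):
    """Closed-form OLS with intercept: returns (coefs incl. intercept, adj R^2)."""
    X = np.column_stack([np.ones(len(y))] + [np.asarray(c, float) for c in columns])
    y = np.asarray(y, float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    n, p = X.shape
    r2 = 1 - ss_res / ss_tot
    adj = 1 - (1 - r2) * (n - 1) / (n - p)
    return beta, adj
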