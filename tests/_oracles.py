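"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by direct enumeration or the closed
form, sharing no code with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import binom


def mdrd_oracle(scr: float, age: float, female: bool, black: bool) -> float:
    """Direct evaluation of the re-expressed 4-variable MDRD formula."""
    val = 175.0 * math.exp(-1.154 * math.log(scr)) * math.exp(-0.203 * math.log(age))
    if female:
        val *= 0.742
    if black:
        val *= 1.212
    return val


def brute_force_uo_stages(rate_per_kg: np.ndarray, rate_ml: np.ndarray) -> np.ndarray:
    """Enumerate every trailing window explicitly at every hour.

    Returns one value per hour: -1 where the hour is not evaluable (the
    trailing 6 h window is incomplete), else the maximum satisfied AKIN
    urine-output stage using window means (0.5 over 6 h and 12 h, 0.3 over
    24 h) and the 12 h all-hours anuria rule (< 1 mL/h).
    """
    n = len(rate_per_kg)
    out = np.full(n, -1, dtype=int)
    for h in range(n):
        w6 = rate_per_kg[h - 5 : h + 1]
        if h < 5 or np.isnan(w6).any():
            continue
        stage = 0
        if np.mean(w6) < 0.5:
            stage = 1
        if h >= 11:
            w12 = rate_per_kg[h - 11 : h + 1]
            if not np.isnan(w12).any() and np.mean(w12) < 0.5:
                stage = max(stage, 2)
            a12 = rate_ml[h - 11 : h + 1]
            if not np.isnan(a12).any() and np.all(a12 < 1.0):
                stage = 3
        if h >= 23:
            w24 = rate_per_kg[h - 23 : h + 1]
            if not np.isnan(w24).any() and np.mean(w24) < 0.3:
                stage = 3
        out[h] = stage
    return out


def exact_pooled_prop_p(x1: int, n1: int, x2: int, n2: int) -> float:
    """Exact two-sided mid-p for equal proportions by full enumeration.

    Under H0 both arms are Binomial with the pooled rate; outcomes are
    ordered by the absolute difference in sample proportions, with the
    boundary (exactly-as-extreme) mass counted at half weight — the
    discrete analogue a continuous approximation targets.
    """
    p0 = (x1 + x2) / (n1 + n2)
    obs = abs(x1 / n1 - x2 / n2)
    pk1 = binom.pmf(np.arange(n1 + 1), n1, p0)
    pk2 = binom.pmf(np.arange(n2 + 1), n2, p0)
    d = np.abs(np.arange(n1 + 1)[:, None] / n1 - np.arange(n2 + 1)[None, :] / n2)
    joint = pk1[:, None] * pk2[None, :]
    beyond = joint[d > obs + 1e-12].sum()
    boundary = joint[np.abs(d - obs) <= 1e-12].sum()
    return float(beyond + 0.5 * boundary)


def product_limit_oracle(event_day, censor_day, max_day: int) -> np.ndarray:
    """Daily product-limit survival by direct counting.

    event_day None means censored at censor_day; a censored encounter is
    still at risk on its censoring day.
    """
    surv = []
    s = 1.0
    for k in range(1, max_day + 1):
        at_risk = sum(
            1
            for e, c in zip(event_day, censor_day)
            if (e is not None and e >= k) or (e is None and c >= k)
        )
        events = sum(1 for e in event_day if e == k)
        if at_risk > 0:
            s *= 1.0 - events / at_risk
        surv.append(s)
    return np.asarray(surv)
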