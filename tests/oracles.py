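"""Independent oracle implementations used by the test suite.

Everything here is deliberately written with naive loops / generic
linear-algebra so that it shares no code path with the package: the
brute-force event scan re-derives the full event definition frame by
frame, and the ANOVA oracle obtains sums of squares as sequential
residual-sum-of-squares drops of nested regression fits rather than from
cell-mean formulas.
"""

from __future__ import annotations

import math
import statistics

import numpy as np


# ---------------------------------------------------------------------------
# event detection


def _smooth3(v):
    n = len(v)
    s = np.empty(n)
    for i in range(n):
        lo = v[i - 1] if i > 0 else v[0]
        hi = v[i + 1] if i < n - 1 else v[n - 1]
        s[i] = (lo + v[i] + hi) / 3.0
    return s


def _diff_mad_noise_sd(v):
    d = [v[i + 1] - v[i] for i in range(len(v) - 1)]
    if not d:
        return 0.0
    med = statistics.median(d)
    mad = statistics.median([abs(x - med) for x in d])
    return 1.4826 * mad / math.sqrt(2.0)


def _first_strict_max(x, start, stop):
    """First index p in (start, stop] that is a strict local max of ``x``
    (plateaus take their first frame and must eventually fall)."""
    n = len(x)
    for p in range(start + 1, min(stop, n - 1) + 1):
        if p >= n - 1:
            break
        if not x[p] > x[p - 1]:
            continue
        q = p + 1
        while q < n and x[q] == x[p]:
            q += 1
        if q < n and x[q] < x[p]:
            return p
    return None


def brute_force_events(
    v,
    sd_pct,
    frame_rate_hz=20.0,
    min_amp_pct=0.02,
    sd_factor=0.3,
    min_rise_frames=2,
    peak_window_s=2.0,
    prominence_factor=5.0,
    min_persist_frames=4,
    baseline_window_frames=21,
):
    """Exhaustive per-frame scan applying the complete event definition."""
    v = np.asarray(v, dtype=float)
    n = v.size
    s = _smooth3(v)
    sig = _diff_mad_noise_sd(v)
    window = int(round(peak_window_s * frame_rate_hz))
    threshold = max(min_amp_pct, sd_factor * float(sd_pct))
    events = []
    claimed = set()
    for o in range(n - 1):
        # onset = foot of a smoothed rise: next step up, last non-flat step down
        if not s[o + 1] > s[o]:
            continue
        prev_sign = 0
        for j in range(o - 1, -1, -1):
            if s[j + 1] != s[j]:
                prev_sign = 1 if s[j + 1] > s[j] else -1
                break
        if prev_sign > 0:
            continue
        # smoothed peak for the shape gates
        m = _first_strict_max(s, o, n)
        if m is None:
            continue
        rise = s[m] - s[o]
        if rise <= 0:
            continue
        lo = max(0, o - baseline_window_frames + 1)
        base = max(statistics.median(list(s[lo : o + 1])), s[o])
        if s[m] - base < prominence_factor * sig:
            continue
        half = s[o] + 0.5 * rise
        q = m
        while q < n and s[q] >= half:
            q += 1
        if q - m < min_persist_frames:
            continue
        # numeric criteria, on the raw trace, after snapping the onset to
        # the raw foot (lowest raw value within one frame, ties -> later)
        lo2 = max(o - 1, 0)
        hi2 = min(o + 1, n - 1)
        best = lo2
        for idx in range(lo2, hi2 + 1):
            if v[idx] <= v[best]:
                best = idx
        o_raw = best
        if o_raw + window >= n:
            continue
        p = _first_strict_max(v, o_raw, o_raw + window)
        if p is None or p in claimed:
            continue
        amplitude = v[p] - v[o_raw]
        if p - o_raw >= min_rise_frames and amplitude >= threshold:
            claimed.add(p)
            events.append((o_raw, p, amplitude))
    return events


# ---------------------------------------------------------------------------
# mixed ANOVA sums of squares via nested regression fits


def _rss(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def anova_ss_oracle(table):
    """Sequential SS for the 2-level mixed design from nested linear models.

    ``table`` is a long-format DataFrame (animal, group, period, value).
    Returns the five components plus the total.
    """
    animals = sorted(table["animal"].unique())
    groups = sorted(table["group"].unique())
    periods = sorted(table["period"].unique())
    assert len(periods) == 2
    y = []
    cols_group, cols_subj, col_period = [], [], []
    for _, row in table.iterrows():
        y.append(row["value"])
        cols_group.append(groups.index(row["group"]))
        cols_subj.append(animals.index(row["animal"]))
        col_period.append(periods.index(row["period"]))
    y = np.asarray(y, dtype=float)
    n_obs = y.size
    ones = np.ones((n_obs, 1))
    G = np.zeros((n_obs, len(groups)))
    G[np.arange(n_obs), cols_group] = 1.0
    S = np.zeros((n_obs, len(animals)))
    S[np.arange(n_obs), cols_subj] = 1.0
    P = np.asarray(col_period, dtype=float).reshape(-1, 1)
    GP = G * P  # group-by-period interaction columns
    X0 = ones
    X1 = np.hstack([ones, G])
    X2 = np.hstack([ones, G, S])
    X3 = np.hstack([ones, G, S, P])
    X4 = np.hstack([ones, G, S, P, GP])
    rss0, rss1, rss2, rss3, rss4 = (_rss(X, y) for X in (X0, X1, X2, X3, X4))
    return {
        "group": rss0 - rss1,
        "subjects_within_group": rss1 - rss2,
        "period": rss2 - rss3,
        "interaction": rss3 - rss4,
        "period_by_subjects": rss4,
        "total": rss0,
    }
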