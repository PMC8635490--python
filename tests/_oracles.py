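"""Independent brute-force oracles used only by the test suite.

Everything here is written from the definitions, deliberately avoiding the
vectorized code paths in :mod:`facemimic`, so that agreement between the
two is informative.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy import stats as sps


# ---------------------------------------------------------------------------
# recurrence oracles
# ---------------------------------------------------------------------------

def brute_crp(a, b, eps=2.0, strict=True):
    """Double-loop cross-recurrence matrix with Manhattan distance."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n, m = a.shape[0], b.shape[0]
    out = np.zeros((n, m), dtype=int)
    for i in range(n):
        for j in range(m):
            d = sum(abs(a[i, c] - b[j, c]) for c in range(a.shape[1]))
            if (d < eps) if strict else (d <= eps):
                out[i, j] = 1
    return out


def brute_diagonal_histogram(crp):
    """Scan every diagonal cell by cell, counting maximal runs of 1s."""
    crp = np.asarray(crp)
    n, m = crp.shape
    hist = Counter()
    for k in range(-(n - 1), m):
        cells = [(i, i + k) for i in range(n) if 0 <= i + k < m]
        run = 0
        for (i, j) in cells:
            if crp[i, j]:
                run += 1
            else:
                if run:
                    hist[run] += 1
                run = 0
        if run:
            hist[run] += 1
    return dict(hist)


def brute_crqa(crp, l_min=8):
    """All line-based measures straight from the definitions."""
    crp = np.asarray(crp)
    n, m = crp.shape
    hist = brute_diagonal_histogram(crp)
    n_rec = int(crp.sum())
    if n_rec == 0:
        return {"crr": 0.0, "l_avg": 0.0, "l_max": 0, "det_normalized": 0.0,
                "det_as_printed": 0.0, "hist": {}, "empty": True}
    crr = 100.0 * n_rec / (n * m)
    long_points = sum(l * c for l, c in hist.items() if l >= l_min)
    long_lines = sum(c for l, c in hist.items() if l >= l_min)
    all_points = sum(l * c for l, c in hist.items())
    all_lines = sum(c for l, c in hist.items())
    return {
        "crr": crr,
        "l_avg": long_points / long_lines if long_lines else 0.0,
        "l_max": max(hist),
        "det_normalized": long_points / all_points,
        "det_as_printed": long_points / all_lines,
        "hist": hist,
        "empty": False,
    }


def brute_has_run(active, min_run):
    """Check every (start, length) pair for a run of >= min_run True."""
    active = list(active)
    for start in range(len(active)):
        for length in range(min_run, len(active) - start + 1):
            if all(active[start:start + length]):
                return True
    return False


# ---------------------------------------------------------------------------
# general-linear-model oracle for the balanced mixed design
# ---------------------------------------------------------------------------

def mixed_anova_oracle(y, groups):
    """Classic sums-of-squares decomposition of a balanced mixed design.

    Parameters
    ----------
    y : (subjects, within_levels) array of observations.
    groups : length-subjects sequence of group labels; every group must
        have the same number of subjects.

    Returns
    -------
    dict with, per effect (``between``, ``within``, ``interaction``):
    F, df1, df2, p and partial eta squared.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    a = len(levels)
    n_per = [int((groups == g).sum()) for g in levels]
    if len(set(n_per)) != 1:
        raise ValueError("oracle requires equal group sizes")
    n = n_per[0]
    N, b = y.shape
    grand = y.mean()

    subj_means = y.mean(axis=1)
    group_means = {g: y[groups == g].mean() for g in levels}
    within_means = y.mean(axis=0)
    cell_means = {g: y[groups == g].mean(axis=0) for g in levels}

    ss_total = ((y - grand) ** 2).sum()
    ss_subj = b * ((subj_means - grand) ** 2).sum()
    ss_between = b * n * sum((group_means[g] - grand) ** 2 for g in levels)
    ss_subj_within = ss_subj - ss_between
    ss_within = N * ((within_means - grand) ** 2).sum()
    ss_inter = n * sum(
        (cell_means[g][w] - group_means[g] - within_means[w] + grand) ** 2
        for g in levels for w in range(b))
    ss_err = ss_total - ss_subj - ss_within - ss_inter

    df_between, df_sw = a - 1, N - a
    df_within, df_err = b - 1, (N - a) * (b - 1)
    df_inter = (a - 1) * (b - 1)

    def eff(ss, df1, ss_e, df2):
        F = (ss / df1) / (ss_e / df2)
        return {"F": F, "df1": df1, "df2": df2,
                "p": float(sps.f.sf(F, df1, df2)),
                "np2": ss / (ss + ss_e)}

    return {
        "between": eff(ss_between, df_between, ss_subj_within, df_sw),
        "within": eff(ss_within, df_within, ss_err, df_err),
        "interaction": eff(ss_inter, df_inter, ss_err, df_err),
    }


def regression_oracle(x, y):
    """Closed-form least squares on z-scored variables."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    zx = (x - x.mean()) / x.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    beta = float((zx * zy).sum() / (zx * zx).sum())
    df = n - 2
    se = np.sqrt((1 - beta ** 2) / df) if abs(beta) < 1 else 0.0
    t = beta / se if se else np.inf * np.sign(beta)
    p = 2 * sps.t.sf(abs(t), df) if np.isfinite(t) else 0.0
    return {"beta": beta, "t": float(t), "df": df, "p": float(p),
            "r_sq": beta ** 2}
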