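"""Between-cluster comparisons on selected edges and on NSSI severity.

Welch's unequal-variance t-test and the classic pooled-SD Cohen's d, both
computable from summary statistics alone so published tables can be
recomputed; percentile summaries of severity per cluster.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

Z_95 = 1.959963984540054  # normal 97.5% quantile; group sizes are large


def welch_t(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int):
    """Welch's t from group means, SDs and sizes.

    Returns (t, df, two-sided p).  t = (m1 - m2)/sqrt(s1^2/n1 + s2^2/n2),
    df by Welch-Satterthwaite.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 members")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    v1, v2 = s1**2 / n1, s2**2 / n2
    if v1 + v2 == 0:
        raise ValueError("both group variances are zero; t undefined")
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def cohens_d_pooled(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int) -> float:
    """Classic Cohen's d: (m1 - m2) / pooled SD, no small-sample correction.

    s_p^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2).
    """
    if n1 + n2 < 3:
        raise ValueError("need n1 + n2 >= 3")
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("pooled SD is zero; d undefined")
    return float((m1 - m2) / np.sqrt(sp2))


def compare_groups(z_table: pd.DataFrame, assignments: pd.Series | np.ndarray) -> pd.DataFrame:
    """Per-edge two-group comparison of raw (unstandardized) z-scores.

    One row per selected edge with group means, SDs, sizes, Welch t/df/p,
    pooled Cohen's d and normal-approximation 95% CIs of each group mean.
    """
    y = np.asarray(assignments)
    groups = np.unique(y)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 clusters, got {len(groups)}")
    g1, g2 = groups
    if (y == g1).sum() < 2 or (y == g2).sum() < 2:
        raise ValueError("each cluster needs at least 2 members")
    cols = [c for c in z_table.columns if c != "patient_id"]
    rows = []
    for c in cols:
        x = z_table[c].to_numpy(dtype=float)
        a, b = x[y == g1], x[y == g2]
        m1, s1, n1 = a.mean(), a.std(ddof=1), len(a)
        m2, s2, n2 = b.mean(), b.std(ddof=1), len(b)
        t, df, p = welch_t(m1, s1, n1, m2, s2, n2)
        d = cohens_d_pooled(m1, s1, n1, m2, s2, n2)
        rows.append(
            {
                "edge": c,
                "mean_1": m1, "sd_1": s1, "n_1": n1,
                "mean_2": m2, "sd_2": s2, "n_2": n2,
                "t": t, "df": df, "p": p, "cohens_d": d,
                "ci95_lo_1": m1 - Z_95 * s1 / np.sqrt(n1),
                "ci95_hi_1": m1 + Z_95 * s1 / np.sqrt(n1),
                "ci95_lo_2": m2 - Z_95 * s2 / np.sqrt(n2),
                "ci95_hi_2": m2 + Z_95 * s2 / np.sqrt(n2),
            }
        )
    return pd.DataFrame(rows)


def severity_summary(
    severities: pd.Series | np.ndarray, assignments: pd.Series | np.ndarray
) -> dict:
    """Percentile summaries of NSSI severity per cluster plus a Welch t-test.

    Quantiles use linear interpolation between order statistics.
    """
    sev = np.asarray(severities, dtype=float)
    y = np.asarray(assignments)
    groups = np.unique(y)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 clusters, got {len(groups)}")
    per_cluster = []
    samples = []
    for g in groups:
        x = sev[y == g]
        if len(x) == 0:
            raise ValueError(f"cluster {g} is empty")
        samples.append(x)
        qs = np.percentile(x, [10, 25, 50, 75, 90], method="linear")
        per_cluster.append(
            {
                "cluster": g,
                "n": len(x),
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
                "min": float(x.min()),
                "p10": float(qs[0]),
                "q1": float(qs[1]),
                "median": float(qs[2]),
                "q3": float(qs[3]),
                "p90": float(qs[4]),
                "max": float(x.max()),
            }
        )
    a, b = samples
    t, df, p = welch_t(a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b))
    return {"clusters": pd.DataFrame(per_cluster), "t": t, "df": df, "p": p}
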