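"""Strain-level and population-level summary statistics.

Mirrors the descriptive layer of a longitudinal allergen-challenge
study: per-strain means and standard errors of baseline, final and delta
PC150 with paired baseline-vs-final t-tests, a one-way ANOVA across
strains, a Spearman correlation table of the phenotypes against
inflammation biomarkers, and a two-group (Welch) contrast of
lung-resistance PC150 values.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats as sps


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    x = x[~np.isnan(x)]
    if x.size == 0:
        return np.nan, np.nan
    se = float(x.std(ddof=1) / math.sqrt(x.size)) if x.size > 1 else np.nan
    return float(x.mean()), se


def strain_summaries(
    phenotypes: pd.DataFrame, strains: pd.Series | dict
) -> pd.DataFrame:
    """Per-strain PC150 summary with paired baseline-vs-final t-tests.

    ``phenotypes`` is a PC150 phenotype table (columns mouse_id,
    pc150_baseline, pc150_final, delta). ``strains`` maps mouse_id ->
    strain label. Missing members of a pair are dropped pairwise and the
    paired t uses df = n_pairs - 1. A final "population" row pools all
    mice. Strains with a single mouse are flagged and get no test.
    """
    df = phenotypes.copy()
    strains = pd.Series(strains)
    df["strain"] = df["mouse_id"].map(strains)
    rows = []
    groups = list(df.groupby("strain", sort=False)) + [("population", df)]
    for strain, grp in groups:
        b = grp["pc150_baseline"].to_numpy(dtype=float)
        f = grp["pc150_final"].to_numpy(dtype=float)
        d = grp["delta"].to_numpy(dtype=float)
        row = {"strain": strain, "n": len(grp)}
        for name, vec in (("baseline", b), ("final", f), ("delta", d)):
            m, se = _mean_se(vec)
            row[f"mean_{name}"], row[f"se_{name}"] = m, se
        pairs = ~np.isnan(b) & ~np.isnan(f)
        n_pairs = int(pairs.sum())
        row["n_pairs"] = n_pairs
        if n_pairs >= 2 and np.ptp(b[pairs] - f[pairs]) > 0:
            t, p = sps.ttest_rel(b[pairs], f[pairs])
            row.update(t_statistic=float(t), df=n_pairs - 1, p_value=float(p),
                       flag="")
        elif n_pairs >= 2:
            row.update(t_statistic=0.0, df=n_pairs - 1, p_value=1.0,
                       flag="zero_variance")
        else:
            row.update(t_statistic=np.nan, df=np.nan, p_value=np.nan,
                       flag="too_few_pairs")
        rows.append(row)
    return pd.DataFrame(rows)


def strain_anova(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA across strains.

    Returns (F, p). Computed from the between/within sums of squares so
    degenerate inputs behave sensibly: identical group means give F = 0
    (p = 1) even when the within-group variance is zero.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    arrays = [a[~np.isnan(a)] for a in arrays]
    arrays = [a for a in arrays if a.size > 0]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups with data")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    df_b = len(arrays) - 1
    df_w = all_vals.size - len(arrays)
    if df_w <= 0:
        raise ValueError("ANOVA needs at least 2 observations in some group")
    if ss_between == 0.0:
        return 0.0, 1.0
    if ss_within == 0.0:
        return float("inf"), 0.0
    F = (ss_between / df_b) / (ss_within / df_w)
    return float(F), float(sps.f.sf(F, df_b, df_w))


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided permutation p-value by full enumeration (tiny n only)."""
    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = abs(rho)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = sps.spearmanr(rx, ry[list(perm)]).statistic
        if abs(r) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman(x, y) -> tuple[float, float, int]:
    """Spearman rho with average-rank ties; (rho, p, n complete pairs).

    p-values use the t approximation for n >= 10 and exact permutation
    enumeration below that (n <= 7; between 8 and 9 the t approximation
    is used with a note that pre-conditions ask for >= 10 pairs).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        return np.nan, np.nan, n
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan, n
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    if n >= 8:
        p = float(res.pvalue)
    else:
        p = _spearman_exact_p(x, y, rho)
    return rho, p, n


def correlation_matrix(
    phenotypes: pd.DataFrame,
    biomarkers: pd.DataFrame,
    phenotype_columns: tuple[str, ...] = ("pc150_final", "delta"),
) -> pd.DataFrame:
    """Spearman correlations of phenotypes against a biomarker panel.

    Pairwise-complete observations; one row per (phenotype, biomarker)
    pair with rho, p and the n used. Constant variables yield NaN rho
    with a flag rather than an error.
    """
    merged = phenotypes.merge(biomarkers, on="mouse_id", how="inner")
    marker_cols = [c for c in biomarkers.columns if c != "mouse_id"]
    rows = []
    for pcol in phenotype_columns:
        for mcol in marker_cols:
            rho, p, n = spearman(merged[pcol], merged[mcol])
            rows.append(
                {
                    "phenotype": pcol,
                    "biomarker": mcol,
                    "rho": rho,
                    "p_value": p,
                    "n": n,
                    "flag": "" if not np.isnan(rho) else "undefined",
                }
            )
    return pd.DataFrame(rows)


def resistance_contrast(
    group_a: np.ndarray, group_b: np.ndarray, labels: tuple[str, str] = ("A", "B")
) -> dict:
    """Two-strain lung-resistance PC150 contrast (Welch two-sample t).

    Inputs are per-mouse PC150 values computed from collapsed resistance
    series; NaN (undefined) mice are excluded with a logged count.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n_excluded = int(np.isnan(a).sum() + np.isnan(b).sum())
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 defined PC150 values")
    mean_a, se_a = _mean_se(a)
    mean_b, se_b = _mean_se(b)
    if np.ptp(np.concatenate([a, b])) == 0:
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=False)
    return {
        "groups": {
            labels[0]: {"n": len(a), "mean": mean_a, "se": se_a},
            labels[1]: {"n": len(b), "mean": mean_b, "se": se_b},
        },
        "t_statistic": float(t),
        "p_value": float(p),
        "n_excluded": n_excluded,
    }
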