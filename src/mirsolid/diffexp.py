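"""Abundance filtering and empirical-Bayes moderated-t differential expression.

The model follows the standard small-sample empirical-Bayes treatment of
log-expression data: each feature's log2(normalized count + pseudocount) is
fit by a one-way linear model on condition, giving a residual variance s^2
with d degrees of freedom.  The per-feature variances are assumed to follow
a scaled inverse-chi-square prior with d0 degrees of freedom and location
s0^2, estimated by matching the first two moments of log(s^2) to the
resulting log-F distribution (digamma/trigamma inversion).  The posterior
("squeezed") variance

    s~^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

replaces s^2 in the two-sample t statistic, which then has d0 + d degrees
of freedom.  Benjamini-Hochberg adjusted P values are reported alongside
raw ones; selection follows the raw-P criterion with BH shown for honesty
about multiplicity.

Only miRNAs whose condition-mean normalized abundance reaches ``min_cpm``
(default 300 per million, i.e. a relative abundance of 0.03%) in at least
one condition enter the test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .quantify import CountMatrix

DEFAULT_MIN_CPM = 300.0
DEFAULT_PSEUDOCOUNT = 0.5


class PriorEstimationError(RuntimeError):
    """Raised when every feature has zero residual variance."""


def abundance_filter(
    counts: CountMatrix, min_cpm: float = DEFAULT_MIN_CPM
) -> pd.Series:
    """Flag features whose condition-mean cpm reaches ``min_cpm`` somewhere.

    300 cpm under per-10^6 normalization is the same cut as a 0.03%
    relative abundance.
    """
    norm = counts.normalized
    cond = pd.Series({s: counts.conditions.get(s, "?") for s in norm.columns})
    cond_means = norm.T.groupby(cond).mean().T
    return (cond_means >= min_cpm).any(axis=1)


def log_expression(
    counts: CountMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """log2(normalized counts + pseudocount), features x samples."""
    return np.log2(counts.normalized + pseudocount)


def merge_technical_replicates(
    log_expr: pd.DataFrame, groups: "dict[str, str]"
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Average technical replicates (log scale) into biological units.

    ``groups`` maps sample -> biological unit id; the returned condition
    mapping must be rebuilt by the caller from any one member sample.
    """
    unit = pd.Series({s: groups.get(s, s) for s in log_expr.columns})
    merged = log_expr.T.groupby(unit).mean().T
    return merged, dict(unit)


def log2fc(
    counts: CountMatrix,
    contrast: tuple[str, str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Mean per-replicate-pair log2 fold change (cond_a over cond_b) +- SE.

    Samples of the two conditions are paired by order (replicate pairing);
    the per-pair log2 ratios are averaged and their standard error over
    pairs reported (0 for a single pair).
    """
    cond_a, cond_b = contrast
    sa = counts.condition_samples(cond_a)
    sb = counts.condition_samples(cond_b)
    if not sa or not sb:
        missing = cond_a if not sa else cond_b
        raise ValueError(f"contrast condition {missing!r} has no samples")
    npairs = min(len(sa), len(sb))
    ratios = [
        np.log2(
            (counts.normalized[sa[i]] + pseudocount)
            / (counts.normalized[sb[i]] + pseudocount)
        )
        for i in range(npairs)
    ]
    mat = pd.concat(ratios, axis=1)
    mean = mat.mean(axis=1)
    se = (
        mat.std(axis=1, ddof=1) / np.sqrt(npairs)
        if npairs > 1
        else pd.Series(0.0, index=mean.index)
    )
    return pd.DataFrame({"log2fc": mean, "se": se})


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        raise ValueError("trigamma is positive; target must be > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match the scaled inverse-chi-square prior (d0, s0^2).

    Works on z = log(s^2): under the model z - log(s0^2) follows a log-F
    whose mean and variance involve digamma/trigamma of d/2 and d0/2.
    Features with non-positive s^2 are ignored for the moments; if the
    observed spread of z is no larger than expected from chi-square noise
    alone, d0 = +inf (complete pooling) is returned.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if not ok.any():
        raise PriorEstimationError(
            "all features have zero residual variance; cannot estimate prior"
        )
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
    evar -= float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    return d0, s0_2


def squeeze_variances(
    s2: np.ndarray, df: float, d0: float, s0_2: float
) -> np.ndarray:
    """Posterior variances: convex combination of s^2 and the prior s0^2."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(d0):
        return np.full_like(s2, s0_2)
    return (d0 * s0_2 + df * s2) / (d0 + df)


def fit_moderated_t(
    log_expr: pd.DataFrame,
    design: "dict[str, str] | pd.Series",
    contrast: tuple[str, str],
) -> pd.DataFrame:
    """Empirical-Bayes moderated t for one contrast of a one-way design.

    ``log_expr`` is features x samples of log2(normalized + pseudocount);
    ``design`` maps sample -> condition.  Returns a per-feature table with
    group-mean difference, residual and moderated variances, the prior
    (d0, s0^2), moderated t, raw and BH-adjusted two-sided P.
    """
    design = pd.Series(dict(design)) if not isinstance(design, pd.Series) else design
    design = design.reindex(log_expr.columns)
    if design.isna().any():
        missing = list(log_expr.columns[design.isna()])
        raise ValueError(f"samples without condition label: {missing}")
    conditions = list(dict.fromkeys(design))
    cond_a, cond_b = contrast
    for c in (cond_a, cond_b):
        if c not in conditions:
            raise ValueError(f"contrast condition {c!r} not in design")
    n_total = log_expr.shape[1]
    df_resid = n_total - len(conditions)
    if df_resid < 1:
        raise ValueError(
            f"no residual degrees of freedom ({n_total} samples, "
            f"{len(conditions)} conditions)"
        )
    X = log_expr.to_numpy(dtype=float)
    group_means = {}
    rss = np.zeros(X.shape[0])
    for c in conditions:
        cols = np.asarray(design == c)
        sub = X[:, cols]
        mu = sub.mean(axis=1)
        group_means[c] = mu
        rss += ((sub - mu[:, None]) ** 2).sum(axis=1)
    s2 = rss / df_resid
    d0, s0_2 = estimate_variance_prior(s2, df_resid)
    s2_post = squeeze_variances(s2, df_resid, d0, s0_2)
    n_a = int((design == cond_a).sum())
    n_b = int((design == cond_b).sum())
    diff = group_means[cond_a] - group_means[cond_b]
    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, diff / se, 0.0)
    df_total = d0 + df_resid if np.isfinite(d0) else np.inf
    if np.isinf(df_total):
        from scipy.stats import norm as norm_dist

        pvals = 2.0 * norm_dist.sf(np.abs(tstat))
    else:
        pvals = 2.0 * t_dist.sf(np.abs(tstat), df_total)
    adj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": diff,
            "s2": s2,
            "s2_post": s2_post,
            "d0": d0,
            "s0_2": s0_2,
            "df_total": df_total,
            "t": tstat,
            "pvalue": pvals,
            "adj_pvalue": adj,
        },
        index=log_expr.index,
    )


@dataclass
class DiffExpResult:
    """Per-contrast fold changes and the moderated-t table for the main
    contrast, with the abundance-filter flag."""

    table: pd.DataFrame
    contrast: tuple[str, str]


def differential_expression(
    counts: CountMatrix,
    contrast: tuple[str, str],
    extra_contrasts: "list[tuple[str, str]] | None" = None,
    min_cpm: float = DEFAULT_MIN_CPM,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    technical_groups: "dict[str, str] | None" = None,
) -> DiffExpResult:
    """End-to-end differential expression for a count matrix.

    Technical replicates (``technical_groups``: sample -> biological unit)
    are averaged on the log scale before fitting; the moderated t is
    computed on abundance-passing features only, with fold changes +- SE
    reported for the main and any extra contrasts.
    """
    passes = abundance_filter(counts, min_cpm)
    le = log_expression(counts, pseudocount)
    design = {s: counts.conditions.get(s, "?") for s in le.columns}
    if technical_groups:
        le, unit_of = merge_technical_replicates(le, technical_groups)
        design = {}
        for sample, unit in unit_of.items():
            design[unit] = counts.conditions.get(sample, "?")
    tested = le.loc[passes[passes].index]
    fit = fit_moderated_t(tested, design, contrast)
    fc = log2fc(counts, contrast, pseudocount)
    table = pd.DataFrame(index=counts.features)
    a, b = contrast
    table[f"log2fc_{a}_vs_{b}"] = fc["log2fc"]
    table[f"se_{a}_vs_{b}"] = fc["se"]
    for extra in extra_contrasts or []:
        efc = log2fc(counts, extra, pseudocount)
        ea, eb = extra
        table[f"log2fc_{ea}_vs_{eb}"] = efc["log2fc"]
        table[f"se_{ea}_vs_{eb}"] = efc["se"]
    for col in ["s2", "s2_post", "d0", "s0_2", "t", "pvalue", "adj_pvalue"]:
        table[col] = fit[col]
    table["model_log2fc"] = fit["log2fc"]
    table["passes_filter"] = passes
    table["max_cpm"] = counts.normalized.max(axis=1)
    return DiffExpResult(table=table, contrast=contrast)


def top_table(
    diff: DiffExpResult, alpha: float = 0.05, rank_by: str = "pvalue"
) -> tuple[pd.DataFrame, int, int]:
    """Regulated features at raw P < alpha, ordered by increasing P.

    Returns (selected table, n_up, n_down) where direction comes from the
    model fold change for the result's main contrast.
    """
    t = diff.table
    sel = t[t["passes_filter"] & (t["pvalue"] < alpha)].sort_values(rank_by)
    lfc = sel["model_log2fc"]
    return sel, int((lfc > 0).sum()), int((lfc < 0).sum())
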