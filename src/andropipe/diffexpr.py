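"""Empirical-Bayes moderated differential-expression testing.

The multi-class test is a moderated one-way F across the five treatment groups
(control + four androgen supplementations).  Per-clone residual variances
s_g^2 (df d = N - G) are shrunk toward a prior s0^2 with prior df d0,

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d),

where (d0, s0^2) are estimated by matching the empirical mean and variance of
log s_g^2 to the moments of a scaled-F log-variance (digamma/trigamma moment
matching with Newton root-finding).  Moderated t/F statistics gain d0 extra
denominator degrees of freedom.

Pairwise contrasts use a Bonferroni-partitioned threshold (global alpha
divided by the number of comparisons) and feed the T/11KT specificity call.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidConfigError, InvalidDesignError, InvalidInputError
from .normalize import ExpressionMatrix

logger = logging.getLogger(__name__)

#: the study's three day-7 pairwise comparisons
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("control", "T2d7"),
    ("control", "KTd7"),
    ("KTd7", "T2d7"),
)

SPECIFICITY_LABELS = ("T only", "11KT only", "T >11KT", "shared-equal", "none")


@dataclass
class ModeratedFit:
    """Group means plus shrunken variance machinery for one expression matrix."""

    group_means: pd.DataFrame  # clone x group
    group_n: pd.Series  # samples per group
    s2: pd.Series  # per-clone residual variance
    df_resid: float  # d = N - G
    d0: float  # prior df (may be +inf)
    s0_2: float  # prior variance
    s2_post: pd.Series  # shrunken variance

    @property
    def n_groups(self) -> int:
        return len(self.group_n)

    @property
    def df_total(self) -> float:
        return self.d0 + self.df_resid


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Newton steps are taken on 1/trigamma, which is nearly linear; this is the
    standard scheme for inverting the trigamma function.
    """
    if y <= 0:
        raise InvalidInputError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) / x < tol:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match s2 ~ s0^2 * F(df, d0); returns (d0, s0^2).

    If the empirical variance of log s2 does not exceed the theoretical floor
    trigamma(df/2), the prior df is infinite and all posterior variances
    collapse onto s0^2.
    """
    z = np.log(np.maximum(s2, np.finfo(float).tiny))
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_2 = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_2 = math.exp(e_mean)
    return d0, s0_2


def fit_moderated_model(expr: ExpressionMatrix | pd.DataFrame, groups: Mapping | pd.Series) -> ModeratedFit:
    """Fit per-clone group means and the shrunken-variance model."""
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    groups = groups.loc[values.columns]
    counts = groups.value_counts()
    if len(counts) < 2:
        raise InvalidDesignError("need at least 2 groups")
    small = counts[counts < 2]
    if not small.empty:
        raise InvalidDesignError(f"groups with <2 samples: {sorted(small.index)}")

    means = values.T.groupby(groups).mean().T  # clone x group
    n_total, n_groups = len(groups), len(counts)
    df_resid = float(n_total - n_groups)
    fitted = means.loc[:, groups.to_numpy()].to_numpy()
    resid = values.to_numpy() - fitted
    s2 = pd.Series((resid**2).sum(axis=1) / df_resid, index=values.index, name="s2")

    d0, s0_2 = _fit_f_dist(s2.to_numpy(), df_resid)
    if math.isinf(d0):
        s2_post = pd.Series(np.full(len(s2), s0_2), index=s2.index, name="s2_post")
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        s2_post.name = "s2_post"
    group_n = counts.loc[means.columns].astype(int)
    return ModeratedFit(means, group_n, s2, df_resid, d0, s0_2, s2_post)


def moderated_F_test(fit: ModeratedFit) -> pd.DataFrame:
    """Per-clone moderated F statistic and p-value.

    F = between-group mean square / s~^2, with (G-1, d0+d) df; an infinite d0
    turns the reference distribution into chi^2_{G-1}/(G-1).
    """
    n = fit.group_n.to_numpy(dtype=float)
    means = fit.group_means.to_numpy()
    grand = (means * n).sum(axis=1) / n.sum()
    ss_between = (n * (means - grand[:, None]) ** 2).sum(axis=1)
    df1 = fit.n_groups - 1
    F = ss_between / df1 / fit.s2_post.to_numpy()
    if math.isinf(fit.d0):
        p = stats.chi2.sf(F * df1, df1)
    else:
        p = stats.f.sf(F, df1, fit.df_total)
    return pd.DataFrame({"F": F, "p": p}, index=fit.group_means.index)


def moderated_t(fit: ModeratedFit, group_a: str, group_b: str) -> pd.DataFrame:
    """Moderated t for the contrast group_b - group_a, with two-sided p."""
    for g in (group_a, group_b):
        if g not in fit.group_means.columns:
            raise InvalidInputError(f"unknown group {g!r}")
    diff = fit.group_means[group_b] - fit.group_means[group_a]
    se = np.sqrt(fit.s2_post * (1.0 / fit.group_n[group_a] + 1.0 / fit.group_n[group_b]))
    t = diff / se
    if math.isinf(fit.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), fit.df_total)
    return pd.DataFrame({"effect": diff, "t": t, "p": p}, index=fit.group_means.index)


def bh_fdr(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidInputError("pvals must be a non-empty 1-D sequence")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InvalidInputError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def pairwise_contrasts(
    expr: ExpressionMatrix | pd.DataFrame,
    groups: Mapping | pd.Series,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    alpha_global: float = 0.01,
    fit: ModeratedFit | None = None,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Moderated t per pair with a Bonferroni-partitioned significance flag.

    The per-comparison threshold is alpha_global / len(pairs); a contrast is
    significant iff p < threshold (strictly).
    """
    pairs = [tuple(p) for p in pairs]
    if not pairs:
        raise InvalidConfigError("pairs must be non-empty")
    if fit is None:
        fit = fit_moderated_model(expr, groups)
    threshold = alpha_global / len(pairs)
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for a, b in pairs:
        tab = moderated_t(fit, a, b)
        tab["significant"] = tab["p"] < threshold
        tab.attrs["threshold"] = threshold
        out[(a, b)] = tab
    return out


def bonferroni_threshold(alpha_global: float = 0.01, n_pairs: int = 3) -> float:
    """Per-comparison p-value threshold for a partitioned global type-I risk."""
    if n_pairs < 1:
        raise InvalidConfigError("n_pairs must be >= 1")
    return alpha_global / n_pairs


def classify_specificity(
    pair_flags: Mapping[tuple[str, str], bool],
    effect_sizes: Mapping[str, float],
) -> str:
    """T/11KT specificity label for one clone.

    ``pair_flags`` must hold the three comparisons control-vs-T2d7,
    control-vs-KTd7 and KTd7-vs-T2d7; ``effect_sizes`` the log2 effects of the
    two control contrasts under keys "T" and "KT".
    """
    try:
        c_t = pair_flags[("control", "T2d7")]
        c_kt = pair_flags[("control", "KTd7")]
        kt_t = pair_flags[("KTd7", "T2d7")]
    except KeyError as exc:
        raise InvalidInputError(f"missing pairwise comparison: {exc}") from exc
    if c_t and not c_kt:
        return "T only"
    if c_kt and not c_t:
        return "11KT only"
    if c_t and c_kt:
        if kt_t and abs(effect_sizes["T"]) > abs(effect_sizes["KT"]):
            return "T >11KT"
        return "shared-equal"
    return "none"


def de_analysis(
    expr: ExpressionMatrix | pd.DataFrame,
    groups: Mapping | pd.Series,
    fdr: float = 0.01,
    alpha_global: float = 0.01,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    control: str = "control",
) -> pd.DataFrame:
    """Full DE stage: moderated F + BH-FDR call, pairwise flags, specificity.

    Returns a per-clone table with columns F, p, q, de (q < fdr, strict),
    direction (sign of treated-minus-control at the smallest-p control
    contrast), one t/p/significant triple per pair, and the specificity label.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    fit = fit_moderated_model(values, groups)
    res = moderated_F_test(fit)
    res["q"] = bh_fdr(res["p"].to_numpy())
    res["de"] = res["q"] < fdr

    group_series = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    treated = [g for g in fit.group_means.columns if g != control]
    contrast_p = pd.DataFrame(index=values.index, columns=treated, dtype=float)
    contrast_eff = pd.DataFrame(index=values.index, columns=treated, dtype=float)
    for g in treated:
        tab = moderated_t(fit, control, g)
        contrast_p[g] = tab["p"]
        contrast_eff[g] = tab["effect"]
    best = contrast_p.to_numpy().argmin(axis=1)
    best_eff = contrast_eff.to_numpy()[np.arange(len(values)), best]
    res["direction"] = np.sign(best_eff).astype(int)

    pw = pairwise_contrasts(values, group_series, pairs=pairs, alpha_global=alpha_global, fit=fit)
    for (a, b), tab in pw.items():
        tag = f"{a}_vs_{b}"
        res[f"t_{tag}"] = tab["t"]
        res[f"p_{tag}"] = tab["p"]
        res[f"sig_{tag}"] = tab["significant"]

    if set(DEFAULT_PAIRS) <= set(pw):
        eff_t = pw[("control", "T2d7")]["effect"]
        eff_kt = pw[("control", "KTd7")]["effect"]
        labels = []
        for clone in values.index:
            flags = {pair: bool(pw[pair].loc[clone, "significant"]) for pair in DEFAULT_PAIRS}
            labels.append(
                classify_specificity(
                    flags, {"T": float(eff_t.loc[clone]), "KT": float(eff_kt.loc[clone])}
                )
            )
        res["specificity"] = labels
    res.attrs["d0"] = fit.d0
    res.attrs["s0_2"] = fit.s0_2
    logger.info(
        "de_analysis: %d/%d clones significant at FDR %g (d0=%.3g, s0^2=%.3g)",
        int(res["de"].sum()), len(res), fdr, fit.d0, fit.s0_2,
    )
    return res
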