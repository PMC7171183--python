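"""Empirical-Bayes moderated two-group differential analysis.

Per-feature weighted least squares on a two-group design gives a group-mean
difference (log2 fold change for genes), residual variance s_g^2 with
d_g = n - 2 degrees of freedom, and the unscaled variance of the contrast
v = 1/sum(w_1) + 1/sum(w_2).  A scaled inverse chi-square prior
(d_0, s_0^2) for the gene variances is estimated by matching the mean and
variance of log s_g^2 to the digamma/trigamma moments of a scaled-F
distribution; the moderated t divides the difference by the posterior
variance s~^2 = (d_0 s_0^2 + d_g s_g^2) / (d_0 + d_g) and is referred to a
Student t with d_0 + d_g degrees of freedom (normal when d_0 is infinite).

The same machinery applies unchanged to gene-set score matrices.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import special, stats

from mhc_escape.normalization import ExpressionMatrix


@dataclasses.dataclass
class GroupFit:
    feature_ids: list[str]
    difference: np.ndarray     # group2 - group1 mean difference per feature
    s2: np.ndarray             # residual variance per feature
    df_resid: float            # residual degrees of freedom (n - 2)
    v: np.ndarray              # unscaled variance of the difference

    def __post_init__(self) -> None:
        if np.any(self.s2 < 0):
            raise ValueError("residual variances must be nonnegative")
        if self.df_resid < 1:
            raise ValueError("at least 1 residual degree of freedom required")
        if np.any(self.v <= 0):
            raise ValueError("contrast variance must be positive")


@dataclasses.dataclass
class VariancePrior:
    d0: float       # prior degrees of freedom, may be inf; 0 = no moderation
    s0_sq: float    # prior variance

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError(f"prior df must be >= 0, got {self.d0}")
        if not (self.s0_sq > 0):
            raise ValueError(f"prior variance must be > 0, got {self.s0_sq}")


def fit_two_group(
    expr: ExpressionMatrix,
    groups: np.ndarray,
    use_weights: bool = True,
) -> GroupFit:
    """Weighted least-squares two-group fit per feature.

    ``groups`` is a length-n vector with exactly two levels; the reported
    difference is (second level - first level), levels in order of first
    appearance.  Precision weights attached to ``expr`` are used unless
    ``use_weights`` is False.
    """
    groups = np.asarray(groups)
    levels = list(dict.fromkeys(groups.tolist()))
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    m1 = groups == levels[0]
    m2 = groups == levels[1]
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    y = expr.values
    n = y.shape[1]
    if expr.weights is not None and use_weights:
        w = expr.weights
    else:
        w = np.ones_like(y)

    sw1 = w[:, m1].sum(axis=1)
    sw2 = w[:, m2].sum(axis=1)
    mu1 = (w[:, m1] * y[:, m1]).sum(axis=1) / sw1
    mu2 = (w[:, m2] * y[:, m2]).sum(axis=1) / sw2
    fitted = np.where(m1[None, :], mu1[:, None], mu2[:, None])
    rss = (w * (y - fitted) ** 2).sum(axis=1)
    df_resid = n - 2
    s2 = rss / df_resid
    v = 1.0 / sw1 + 1.0 / sw2
    return GroupFit(list(expr.gene_ids), mu2 - mu1, s2, float(df_resid), v)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df_resid: float) -> VariancePrior:
    """Moment estimator for the variance prior on the log scale.

    Matches mean and variance of log s_g^2 to the theoretical moments of a
    scaled-F distribution.  The empirical excess spread beyond the
    chi-square contribution trigamma(df/2) determines d0 (infinite when no
    excess remains); s0^2 follows from the mean.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    if not positive.any():
        raise ValueError("all residual variances are zero")
    if positive.sum() < 50:
        raise ValueError("need at least 50 features with positive variance")
    z = np.log(s2[positive])
    e = z - special.digamma(df_resid / 2) + np.log(df_resid / 2)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, df_resid / 2))
    if excess > 0:
        d0 = 2 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    else:
        # no excess spread beyond the chi-square contribution: the prior
        # is degenerate and the plain average of the variances estimates it
        d0 = np.inf
        s0_sq = float(np.mean(s2[positive]))
    return VariancePrior(d0, s0_sq)


def moderated_t(fit: GroupFit, prior: VariancePrior) -> pd.DataFrame:
    """Moderated t-statistics and two-sided p-values (pre-FDR).

    Returns columns ``feature``, ``log2FC``, ``t``, ``p``.
    d0 = 0 reduces to the ordinary two-sample t; d0 = inf uses the prior
    variance exactly with a normal reference.
    """
    d0, s0 = prior.d0, prior.s0_sq
    dg = fit.df_resid
    if np.isinf(d0):
        s2_post = np.full_like(fit.s2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + dg * fit.s2) / (d0 + dg)
        df_total = d0 + dg
    t = fit.difference / np.sqrt(s2_post * fit.v)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {"feature": fit.feature_ids, "log2FC": fit.difference, "t": t, "p": p}
    )


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with enforced monotonicity."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0, 1)
    return q


def differential_table(
    expr: ExpressionMatrix,
    groups: np.ndarray,
    use_weights: bool = True,
    prior: VariancePrior | None = None,
) -> pd.DataFrame:
    """Fit, estimate the prior (unless given), moderate and BH-adjust.

    Returns columns ``feature``, ``log2FC``, ``t``, ``p``, ``q`` sorted by p.
    """
    fit = fit_two_group(expr, groups, use_weights=use_weights)
    if prior is None:
        prior = estimate_variance_prior(fit.s2, fit.df_resid)
    table = moderated_t(fit, prior)
    table["q"] = bh_fdr(table["p"].to_numpy())
    return table.sort_values("p", kind="stable").reset_index(drop=True)


def score_differential(scores, groups: np.ndarray) -> pd.DataFrame:
    """Moderated-t differential analysis over a gene-set score matrix.

    Accepts a :class:`~mhc_escape.enrichment.ScoreMatrix`; weights are not
    used for set-level scores.
    """
    expr = ExpressionMatrix(
        list(scores.set_names), list(scores.sample_ids), scores.values
    )
    fit = fit_two_group(expr, groups, use_weights=False)
    n_sets = len(scores.set_names)
    if n_sets >= 50:
        prior = estimate_variance_prior(fit.s2, fit.df_resid)
    else:
        # too few sets for a stable moment fit: fall back to no moderation
        s0 = float(np.median(fit.s2[fit.s2 > 0])) if (fit.s2 > 0).any() else 1.0
        prior = VariancePrior(d0=0.0, s0_sq=s0)
    table = moderated_t(fit, prior)
    table["q"] = bh_fdr(table["p"].to_numpy())
    return table.sort_values("p", kind="stable").reset_index(drop=True)
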