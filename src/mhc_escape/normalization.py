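"""Between-sample normalization of RNA-seq counts.

Implements trimmed mean of M-values (TMM) scale factors, the exact
log2-counts-per-million transform, mean-variance precision weights in the
style of voom, FPKM length correction and per-gene centering.

TMM follows the original formulation: a reference sample is chosen as the
column whose upper quartile of nonzero CPM is closest to the mean upper
quartile; for every other sample the log-ratio (M) and average-abundance
(A) values over genes expressed in both are trimmed two-sided (30% on M,
5% on A by default) and the surviving M-values are averaged with inverse
asymptotic-variance weights.  Factors are rescaled to geometric mean 1.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import statsmodels.api as sm

from mhc_escape.core_io import CountMatrix


@dataclasses.dataclass
class NormalizationParams:
    """Tuning knobs for normalization.

    trim_m, trim_a : two-sided trim fractions for the M and A values.
    prior_count, prior_lib : pseudocounts of the log-CPM transform
        (0.5 added to counts, 1 added to the scaled library size).
    lowess_span : span of the lowess mean-variance trend used for
        precision weights.
    """

    trim_m: float = 0.30
    trim_a: float = 0.05
    prior_count: float = 0.5
    prior_lib: float = 1.0
    lowess_span: float = 0.5

    def __post_init__(self) -> None:
        for name, val in (("trim_m", self.trim_m), ("trim_a", self.trim_a)):
            if not 0 <= val < 0.5:
                raise ValueError(f"{name} must be in [0, 0.5), got {val}")
        if not 0 < self.lowess_span <= 1:
            raise ValueError(f"lowess_span must be in (0, 1], got {self.lowess_span}")


@dataclasses.dataclass
class ExpressionMatrix:
    """Normalized log2-CPM values with optional precision weights."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale_factors: np.ndarray | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("expression matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.scale_factors is not None:
            f = np.asarray(self.scale_factors, dtype=float)
            if np.any(f <= 0):
                raise ValueError("scale factors must be positive")
            gm = np.exp(np.mean(np.log(f)))
            if abs(gm - 1.0) > 1e-8:
                raise ValueError(f"scale factors must have geometric mean 1, got {gm}")
            self.scale_factors = f
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != self.values.shape:
                raise ValueError("weights shape mismatch")
            if np.any(w <= 0) or not np.all(np.isfinite(w)):
                raise ValueError("weights must be strictly positive and finite")
            self.weights = w

    def gene_values(self, gene: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present in expression matrix")
        return self.values[i]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def _upper_quartile_nonzero_cpm(values: np.ndarray, lib: np.ndarray) -> np.ndarray:
    uq = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        col = values[:, j]
        nz = col[col > 0]
        if nz.size == 0:
            raise ValueError(f"sample column {j} has no nonzero counts")
        uq[j] = np.quantile(nz / lib[j], 0.75)
    return uq


def tmm_factors(
    counts: CountMatrix, params: NormalizationParams | None = None
) -> np.ndarray:
    """Per-sample TMM scale factors, rescaled to geometric mean 1."""
    params = params or NormalizationParams()
    values = counts.values.astype(float)
    lib = counts.library_sizes.astype(float)
    if np.any(lib == 0):
        j = int(np.flatnonzero(lib == 0)[0])
        raise ValueError(f"sample {counts.sample_ids[j]!r} has zero library size")

    uq = _upper_quartile_nonzero_cpm(values, lib)
    ref = int(np.argmin(np.abs(uq - uq.mean())))  # ties -> lowest index

    log_factors = np.zeros(counts.n_samples)
    for j in range(counts.n_samples):
        if j == ref:
            continue
        log_factors[j] = _pairwise_tmm_log2(
            values[:, j], values[:, ref], lib[j], lib[ref],
            counts.sample_ids[j], params,
        )
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _pairwise_tmm_log2(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    sample_name: str,
    params: NormalizationParams,
) -> float:
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise ValueError(
            f"sample {sample_name!r} shares no co-expressed genes with the reference"
        )
    y, r = obs[both], ref[both]
    p_obs, p_ref = y / n_obs, r / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic variance of M (delta method on two binomials)
    v = (n_obs - y) / (n_obs * y) + (n_ref - r) / (n_ref * r)

    n = m.size
    lo_m = np.floor(n * params.trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * params.trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = _rank(m)
    rank_a = _rank(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    w = 1.0 / v[keep]
    f = np.sum(m[keep] * w) / np.sum(w)
    return 0.0 if not np.isfinite(f) else f


def _rank(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(x, method="average")


def log_cpm(
    counts: CountMatrix,
    factors: np.ndarray,
    params: NormalizationParams | None = None,
) -> ExpressionMatrix:
    """log2( (count + 0.5) / (library x factor + 1) x 1e6 ), exactly."""
    params = params or NormalizationParams()
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (counts.n_samples,):
        raise ValueError(
            f"factor vector of length {factors.size} does not align with "
            f"{counts.n_samples} samples"
        )
    eff_lib = counts.library_sizes * factors
    values = np.log2(
        (counts.values + params.prior_count)
        / (eff_lib + params.prior_lib)[None, :]
        * 1e6
    )
    return ExpressionMatrix(
        list(counts.gene_ids), list(counts.sample_ids), values, scale_factors=factors
    )


def _design_matrix(groups: np.ndarray | None, n: int) -> np.ndarray:
    if groups is None:
        return np.ones((n, 1))
    groups = np.asarray(groups)
    levels = list(dict.fromkeys(groups.tolist()))
    design = np.zeros((n, len(levels)))
    for k, lev in enumerate(levels):
        design[groups == lev, k] = 1.0
    return design


def voom_weights(
    counts: CountMatrix,
    factors: np.ndarray,
    groups: np.ndarray | None = None,
    params: NormalizationParams | None = None,
) -> np.ndarray:
    """Per-observation precision weights from the mean-variance trend.

    Per-gene residual standard deviations on the log-CPM scale (after a
    group-means fit) are square-rooted and regressed by lowess on average
    log2 count; the trend evaluated at each observation's fitted count is
    raised to the -4 power to give an inverse-variance weight.
    """
    params = params or NormalizationParams()
    expr = log_cpm(counts, factors, params)
    y = expr.values
    n = counts.n_samples
    design = _design_matrix(groups, n)
    df_resid = n - np.linalg.matrix_rank(design)
    if df_resid < 1:
        raise ValueError("fewer than 1 residual degree of freedom")
    # per-sample group sizes for the cell-means fit
    for k in range(design.shape[1]):
        if design[:, k].sum() < 2:
            raise ValueError("each design cell needs >= 2 samples")

    pinv = np.linalg.pinv(design)
    coef = y @ pinv.T            # genes x cells
    fitted = coef @ design.T
    resid = y - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / df_resid)

    eff_lib = counts.library_sizes * np.asarray(factors, dtype=float)
    # average log2 count per gene: mean log-CPM shifted back to count scale
    sx = y.mean(axis=1) + np.mean(np.log2(eff_lib + params.prior_lib)) - np.log2(1e6)
    sy = np.sqrt(sigma)

    order = np.argsort(sx, kind="stable")
    trend = sm.nonparametric.lowess(
        sy[order], sx[order], frac=params.lowess_span, it=3, return_sorted=True
    )
    tx, ty = trend[:, 0], trend[:, 1]

    # fitted log2 count for every observation, flat extrapolation at the ends
    fitted_count = fitted + (np.log2(eff_lib + params.prior_lib) - np.log2(1e6))[None, :]
    pred_sqrt_sd = np.interp(fitted_count, tx, ty)
    pred_sqrt_sd = np.clip(pred_sqrt_sd, 1e-6, None)
    weights = pred_sqrt_sd**-4
    if np.any(~np.isfinite(weights)) or np.any(weights <= 0):
        raise RuntimeError("non-finite or nonpositive precision weight produced")
    return weights


def fpkm(counts: CountMatrix, gene_lengths: dict[str, float]) -> ExpressionMatrix:
    """Fragments per kilobase per million: count / (kb length x library/1e6)."""
    lengths = np.empty(counts.n_genes)
    for i, g in enumerate(counts.gene_ids):
        if g not in gene_lengths:
            raise ValueError(f"gene {g!r} has no length")
        ln = gene_lengths[g]
        if not ln > 0:
            raise ValueError(f"gene {g!r} has nonpositive length {ln}")
        lengths[i] = ln
    lib = counts.library_sizes.astype(float)
    values = counts.values / ((lengths[:, None] / 1e3) * (lib[None, :] / 1e6))
    return ExpressionMatrix(list(counts.gene_ids), list(counts.sample_ids), values)


def center_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's mean across samples (row-center)."""
    centered = expr.values - expr.values.mean(axis=1, keepdims=True)
    return ExpressionMatrix(
        list(expr.gene_ids),
        list(expr.sample_ids),
        centered,
        scale_factors=expr.scale_factors,
        weights=expr.weights,
    )
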