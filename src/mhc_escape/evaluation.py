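"""ROC evaluation of predictive scores, correlation reports and
cell-fraction aggregation.

AUC is the Mann-Whitney U statistic scaled by n1*n0 (ties count one half),
i.e. the probability that a random responder outscores a random
non-responder.  The 95% CI uses the Hanley-McNeil standard error with a
normal interval clipped to [0, 1]; a Wilson interval on the rank-based
proportion is available as an alternative.  The two-sided p-value against
AUC = 0.5 uses the normal approximation to U with tie-corrected variance.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mhc_escape.dge import bh_fdr
from mhc_escape.signatures import SIGNATURE_ORIENTATION


@dataclasses.dataclass
class ROCResult:
    signature: str
    auc: float
    ci_lo: float
    ci_hi: float
    p: float
    n_pos: int
    n_neg: int
    orientation: int
    ci_method: str = "hanley-mcneil"

    def __post_init__(self) -> None:
        if not 0 <= self.auc <= 1:
            raise ValueError(f"AUC out of range: {self.auc}")
        if not (self.ci_lo <= self.auc <= self.ci_hi):
            raise ValueError("CI must bracket the AUC")


def _split_classes(scores: np.ndarray, labels: np.ndarray):
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be nonempty")
    return pos, neg


def auc_mann_whitney(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC = U / (n1*n0), ties contributing one half."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _split_classes(scores, np.asarray(labels))
    ranks = stats.rankdata(scores)
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = pos.size, neg.size
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def auc_confidence_interval(
    auc: float, n_pos: int, n_neg: int, level: float = 0.95,
    method: str = "hanley-mcneil",
) -> tuple[float, float]:
    """CI for the AUC, clipped to [0, 1].

    ``hanley-mcneil``: normal interval with the Hanley-McNeil SE.
    ``wilson``: Wilson score interval treating the AUC as a proportion of
    the n_pos*n_neg pairwise comparisons won (conservative surrogate for
    the commercial hybrid method).
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class sizes must be positive")
    z = stats.norm.ppf(0.5 + level / 2)
    if method == "hanley-mcneil":
        q1 = auc / (2 - auc)
        q2 = 2 * auc**2 / (1 + auc)
        var = (
            auc * (1 - auc)
            + (n_pos - 1) * (q1 - auc**2)
            + (n_neg - 1) * (q2 - auc**2)
        ) / (n_pos * n_neg)
        se = np.sqrt(max(var, 0.0))
        lo, hi = auc - z * se, auc + z * se
    elif method == "wilson":
        n_eff = min(n_pos, n_neg)  # effective comparisons are limited by the smaller class
        denom = 1 + z**2 / n_eff
        center = (auc + z**2 / (2 * n_eff)) / denom
        half = z * np.sqrt(auc * (1 - auc) / n_eff + z**2 / (4 * n_eff**2)) / denom
        lo, hi = center - half, center + half
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))


def auc_p_value(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Two-sided p versus AUC = 0.5, normal approximation with tie correction."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = _split_classes(scores, labels)
    n1, n0 = pos.size, neg.size
    n = n1 + n0
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2
    _, tie_counts = np.unique(scores, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var_u = n1 * n0 / 12 * ((n + 1) - tie_term)
    if var_u <= 0:
        return 1.0
    z = (u - n1 * n0 / 2) / np.sqrt(var_u)
    return float(min(1.0, 2 * stats.norm.sf(abs(z))))


def evaluate_signatures(
    battery: pd.DataFrame,
    labels: pd.Series,
    orientation: Mapping[str, int] | None = None,
    ci_method: str = "hanley-mcneil",
) -> pd.DataFrame:
    """One ROCResult row per signature column of the battery.

    ``labels`` maps sample ids to 'responder'/'non-responder' (or booleans);
    unlabeled samples are dropped with a warning.  Orientation is fixed a
    priori per signature (never flipped post hoc): a score whose
    orientation is -1 is negated before the AUC.
    """
    orientation = dict(SIGNATURE_ORIENTATION) | dict(orientation or {})
    lab = labels.reindex(battery.index)
    if lab.dtype == object:
        lab = lab.map({"responder": True, "non-responder": False})
    keep = lab.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} unlabeled samples from ROC")
    lab = lab[keep].astype(bool)

    rows = []
    for col in battery.columns:
        if col == "inflamed" or battery[col].dtype == bool:
            continue
        scores = battery.loc[keep, col].to_numpy(dtype=float)
        sign = orientation.get(col, +1)
        oriented = sign * scores
        auc = auc_mann_whitney(oriented, lab.to_numpy())
        lo, hi = auc_confidence_interval(
            auc, int(lab.sum()), int((~lab).sum()), method=ci_method
        )
        p = auc_p_value(oriented, lab.to_numpy())
        res = ROCResult(
            col, auc, lo, hi, p, int(lab.sum()), int((~lab).sum()), sign, ci_method
        )
        rows.append(dataclasses.asdict(res))
    return pd.DataFrame(rows)


def roc_curve_points(scores: Sequence[float], labels: Sequence[bool]) -> pd.DataFrame:
    """FPR/TPR step coordinates for plotting, highest threshold first."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _split_classes(scores, labels)
    order = np.argsort(-scores, kind="stable")
    tp = np.concatenate([[0], np.cumsum(labels[order])])
    fp = np.concatenate([[0], np.cumsum(~labels[order])])
    return pd.DataFrame({"fpr": fp / fp[-1], "tpr": tp / tp[-1]})


def groupwise_correlation(
    x: pd.Series,
    y: pd.Series,
    groups: pd.Series,
    method: str = "pearson",
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Per-group correlation between two aligned sample-indexed variables."""
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    rows = []
    for g, idx in groups.groupby(groups).groups.items():
        xs, ys = x.reindex(idx), y.reindex(idx)
        ok = xs.notna() & ys.notna()
        if ok.sum() < min_group_size:
            warnings.warn(f"group {g!r} below minimum size; omitted")
            continue
        fn = stats.pearsonr if method == "pearson" else stats.spearmanr
        r, p = fn(xs[ok], ys[ok])
        rows.append({"group": g, "n": int(ok.sum()), "r": float(r), "p": float(p)})
    return pd.DataFrame(rows, columns=["group", "n", "r", "p"])


def correlation_matrix(
    rows_df: pd.DataFrame, method: str = "spearman"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise correlations between the rows of ``rows_df``
    (features x samples), with BH-FDR over the off-diagonal p-values.

    Returns (coefficient matrix, q-value matrix).  Constant rows yield NaN
    coefficients (reported as missing, not an error).
    """
    if rows_df.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    names = list(rows_df.index)
    k = len(names)
    coef = np.eye(k)
    pmat = np.zeros((k, k))
    fn = stats.spearmanr if method == "spearman" else stats.pearsonr
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            xi = rows_df.iloc[i].to_numpy(dtype=float)
            yj = rows_df.iloc[j].to_numpy(dtype=float)
            if np.std(xi) == 0 or np.std(yj) == 0:
                coef[i, j] = coef[j, i] = np.nan
                pmat[i, j] = pmat[j, i] = np.nan
                continue
            r, p = fn(xi, yj)
            coef[i, j] = coef[j, i] = r
            pmat[i, j] = pmat[j, i] = p
            pairs.append((i, j, p))
    qmat = np.full((k, k), np.nan)
    np.fill_diagonal(qmat, 0.0)
    if pairs:
        qs = bh_fdr(np.array([p for _, _, p in pairs]))
        for (i, j, _), q in zip(pairs, qs):
            qmat[i, j] = qmat[j, i] = q
    return (
        pd.DataFrame(coef, index=names, columns=names),
        pd.DataFrame(qmat, index=names, columns=names),
    )


def aggregate_cell_fractions(
    fractions: pd.DataFrame, mapping: Mapping[str, str], atol: float = 0.01
) -> pd.DataFrame:
    """Sum fine-grained leukocyte-subset fractions into major types.

    ``fractions`` is samples x subsets (e.g. the 22 deconvolved subsets);
    ``mapping`` sends every subset column to a major type (e.g. 11 types).
    Row sums are conserved exactly.
    """
    unmapped = [c for c in fractions.columns if c not in mapping]
    if unmapped:
        raise ValueError(f"unmapped cell subset: {unmapped[0]!r}")
    sums = fractions.sum(axis=1)
    if np.any(np.abs(sums - 1) > atol):
        bad = sums.index[np.abs(sums - 1) > atol][0]
        raise ValueError(f"fractions for sample {bad!r} do not sum to 1")
    grouped = fractions.T.groupby(
        fractions.columns.map(mapping), sort=False
    ).sum().T
    return grouped
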