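"""Single-sample GSEA and preranked GSEA.

ssGSEA: for one sample, genes are ordered by decreasing expression (ties
broken by gene-id order) and the enrichment score is the sum over all rank
positions of the difference between the weighted in-set empirical CDF and
the unweighted out-of-set ECDF.  In-set steps are weighted by rank^alpha
(the top-ranked gene has rank N), normalized so in-set weights sum to 1;
alpha defaults to 0.25.

Preranked GSEA: the classic weighted Kolmogorov-Smirnov running sum over a
user-supplied gene-level statistic (in-set increments proportional to
|stat|), with a null built by resampling random gene sets of matching size,
normalized enrichment scores, permutation p-values and BH-FDR q-values.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from mhc_escape.core_io import GeneSetCollection
from mhc_escape.normalization import ExpressionMatrix


@dataclasses.dataclass
class EnrichmentParams:
    """alpha: rank weight exponent; n_permutations: preranked null size."""

    alpha: float = 0.25
    n_permutations: int = 1000
    seed: int = 0
    min_max_rescale: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.n_permutations < 100:
            raise ValueError("at least 100 permutations required")


@dataclasses.dataclass
class ScoreMatrix:
    """Gene-set x sample enrichment scores."""

    set_names: list[str]
    sample_ids: list[str]
    values: np.ndarray
    params: EnrichmentParams | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.set_names), len(self.sample_ids)):
            raise ValueError("score matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("enrichment scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.set_names, columns=self.sample_ids)


def _descending_order(values: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    """Indices ordering genes by decreasing value; ties by gene-id order."""
    order = sorted(range(len(gene_ids)), key=lambda i: (-values[i], gene_ids[i]))
    return np.asarray(order)


def ssgsea_sample(
    values: np.ndarray,
    gene_ids: list[str],
    gene_set: set[str] | list[str],
    params: EnrichmentParams | None = None,
) -> float:
    """ssGSEA enrichment score for one sample.

    ES = sum over positions of (weighted in-set ECDF - out-of-set ECDF).
    """
    params = params or EnrichmentParams()
    members = set(gene_set) & set(gene_ids)
    if not members:
        raise ValueError("gene set has empty intersection with the universe")
    if len(members) == len(gene_ids):
        raise ValueError("gene set equals the whole universe; complement undefined")
    order = _descending_order(np.asarray(values, dtype=float), gene_ids)
    in_set = np.asarray([gene_ids[i] in members for i in order])
    return _ssgsea_es(in_set, params.alpha)


def _ssgsea_es(in_set: np.ndarray, alpha: float) -> float:
    n = in_set.size
    ranks = np.arange(n, 0, -1, dtype=float)  # top gene has rank N
    w = np.where(in_set, ranks**alpha, 0.0)
    cum_in = np.cumsum(w) / w.sum()
    n_out = n - in_set.sum()
    cum_out = np.cumsum(~in_set) / n_out
    return float(np.sum(cum_in - cum_out))


def ssgsea_matrix(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    params: EnrichmentParams | None = None,
) -> ScoreMatrix:
    """ssGSEA scores for every (set, sample) pair.

    Sets with no overlap with the gene universe are dropped with a warning;
    dropping every set is an error.
    """
    import warnings

    params = params or EnrichmentParams()
    universe = set(expr.gene_ids)
    kept = []
    for s in collection:
        if set(s.genes) & universe:
            kept.append(s)
        else:
            warnings.warn(f"gene set {s.name!r} has no overlap with universe; dropped")
    if not kept:
        raise ValueError("every gene set was dropped: no overlap with universe")

    n_genes, n_samples = expr.values.shape
    ranks_desc = np.arange(n_genes, 0, -1, dtype=float) ** params.alpha
    scores = np.empty((len(kept), n_samples))
    # tie-break by gene id: pre-sort gene index by id so stable argsort on
    # negated values resolves ties lexicographically
    id_order = sorted(range(n_genes), key=lambda i: expr.gene_ids[i])
    id_order = np.asarray(id_order)
    member_masks = [
        np.asarray([g in set(s.genes) for g in expr.gene_ids]) for s in kept
    ]
    for j in range(n_samples):
        col = expr.values[id_order, j]
        order = id_order[np.argsort(-col, kind="stable")]
        for k, mask in enumerate(member_masks):
            in_set = mask[order]
            n_in = in_set.sum()
            if n_in == n_genes:
                raise ValueError(
                    f"gene set {kept[k].name!r} equals the whole universe"
                )
            w = np.where(in_set, ranks_desc, 0.0)
            cum_in = np.cumsum(w) / w.sum()
            cum_out = np.cumsum(~in_set) / (n_genes - n_in)
            scores[k, j] = np.sum(cum_in - cum_out)
    if params.min_max_rescale:
        rng = scores.max() - scores.min()
        if rng > 0:
            scores = (scores - scores.min()) / rng
    return ScoreMatrix([s.name for s in kept], list(expr.sample_ids), scores, params)


def zscore_by_set(scores: ScoreMatrix) -> ScoreMatrix:
    """Standardize each set's scores across samples (mean 0, sd 1, ddof=1)."""
    if len(scores.sample_ids) < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    mu = scores.values.mean(axis=1, keepdims=True)
    sd = scores.values.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ValueError(
            f"gene set {scores.set_names[flat[0]]!r} has zero variance across samples"
        )
    return ScoreMatrix(
        list(scores.set_names),
        list(scores.sample_ids),
        (scores.values - mu) / sd,
        scores.params,
    )


def _gsea_es(stats_sorted: np.ndarray, in_set_sorted: np.ndarray) -> float:
    """Classic weighted KS running-sum extreme for one set.

    ``stats_sorted`` are the gene statistics in descending order;
    ``in_set_sorted`` flags set membership in the same order.
    """
    n = stats_sorted.size
    n_in = int(in_set_sorted.sum())
    if n_in == 0 or n_in == n:
        raise ValueError("set must be a nonempty proper subset of the universe")
    w = np.abs(stats_sorted) * in_set_sorted
    total = w.sum()
    if total == 0:
        # all in-set stats are zero: fall back to equal increments
        w = in_set_sorted.astype(float)
        total = w.sum()
    hit = np.cumsum(w) / total
    miss = np.cumsum(~in_set_sorted) / (n - n_in)
    running = hit - miss
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    return float(running[i_max] if running[i_max] >= -running[i_min] else running[i_min])


def preranked_gsea(
    stats: pd.Series,
    collection: GeneSetCollection,
    params: EnrichmentParams | None = None,
) -> pd.DataFrame:
    """Preranked GSEA over a gene-level statistic.

    Returns a DataFrame with columns ``set``, ``size``, ``ES``, ``NES``,
    ``p``, ``q``.  The null is built per set size by resampling random gene
    sets from the universe (seeded); NES divides ES by the mean |null ES|
    of matching sign, p is the same-sign tail fraction, q is BH-FDR.
    """
    from mhc_escape.dge import bh_fdr

    params = params or EnrichmentParams()
    if stats.index.has_duplicates:
        dup = stats.index[stats.index.duplicated()][0]
        raise ValueError(f"duplicate gene in ranked statistic: {dup!r}")
    if not np.all(np.isfinite(stats.to_numpy(dtype=float))):
        raise ValueError("ranked statistics must be finite")

    gene_ids = list(stats.index)
    values = stats.to_numpy(dtype=float)
    order = sorted(range(len(gene_ids)), key=lambda i: (-values[i], gene_ids[i]))
    order = np.asarray(order)
    stats_sorted = values[order]
    genes_sorted = [gene_ids[i] for i in order]
    pos_of_gene = {g: i for i, g in enumerate(genes_sorted)}
    n = len(genes_sorted)

    rng = np.random.default_rng(params.seed)
    null_cache: dict[int, np.ndarray] = {}

    def null_es(size: int) -> np.ndarray:
        if size not in null_cache:
            es = np.empty(params.n_permutations)
            mask = np.zeros(n, dtype=bool)
            for b in range(params.n_permutations):
                idx = rng.choice(n, size=size, replace=False)
                mask[:] = False
                mask[idx] = True
                es[b] = _gsea_es(stats_sorted, mask)
            null_cache[size] = es
        return null_cache[size]

    rows = []
    for s in collection:
        members = set(s.genes) & set(genes_sorted)
        if len(set(s.genes)) > n:
            raise ValueError(f"gene set {s.name!r} is larger than the universe")
        if not members or len(members) == n:
            raise ValueError(
                f"gene set {s.name!r} must be a nonempty proper subset of the universe"
            )
        mask = np.zeros(n, dtype=bool)
        mask[[pos_of_gene[g] for g in members]] = True
        es = _gsea_es(stats_sorted, mask)
        null = null_es(len(members))
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if same_sign.size:
            denom = np.abs(same_sign).mean()
            nes = es / denom if denom > 0 else 0.0
            p = float(np.mean(np.abs(same_sign) >= abs(es)))
        else:
            nes, p = 0.0, 1.0 / params.n_permutations
        rows.append(
            {"set": s.name, "size": len(members), "ES": es, "NES": nes, "p": p}
        )
    out = pd.DataFrame(rows)
    out["p"] = out["p"].clip(lower=np.finfo(float).tiny)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
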