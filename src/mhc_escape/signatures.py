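"""The seven published PD-1 predictive scores and the inflamed classifier.

CYT score: mean of normalized GZMA and PRF1 log2-CPM.
CD8A-CSF1R: numeric difference of the two genes' normalized expression.
18-immune gene signature: ssGSEA score of a user-supplied 18-gene set.
IPRES: mean of per-set Z-scores of ssGSEA scores over a user-supplied
    collection of resistance gene sets.
IMPRES: count of checkpoint gene pairs whose configured inequality holds.
TIDE and CIBERSORT CD8 T-cell fractions are externally computed and merged
    as optional columns (only TIDE's documented input centering is provided
    here, via :func:`mhc_escape.normalization.center_genes`).

A tumor is called inflamed when its CYT score is at or above the lowest
CYT score observed among responding (RES) on-treatment lesions.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mhc_escape.core_io import GeneSetCollection
from mhc_escape.enrichment import (
    EnrichmentParams,
    ScoreMatrix,
    ssgsea_matrix,
    zscore_by_set,
)
from mhc_escape.normalization import ExpressionMatrix


@dataclasses.dataclass
class ImpresPair:
    """One checkpoint-gene comparison: satisfied when the inequality holds.

    direction ``'gt'`` means gene_a > gene_b scores a point; ``'lt'`` the
    reverse.  Ties never score (configurable at the scoring call).
    """

    gene_a: str
    gene_b: str
    direction: str = "gt"

    def __post_init__(self) -> None:
        if self.direction not in ("gt", "lt"):
            raise ValueError(f"direction must be 'gt' or 'lt', got {self.direction!r}")
        if self.gene_a == self.gene_b:
            raise ValueError(f"degenerate pair ({self.gene_a!r}, {self.gene_b!r})")


@dataclasses.dataclass
class SignatureConfig:
    cyt_genes: tuple[str, str] = ("GZMA", "PRF1")
    ratio_genes: tuple[str, str] = ("CD8A", "CSF1R")
    immune18_genes: tuple[str, ...] = ()
    ipres_sets: GeneSetCollection | None = None
    impres_pairs: tuple[ImpresPair, ...] = ()
    hla_genes: tuple[str, ...] = ("HLA-A", "HLA-B", "HLA-C", "B2M")

    def all_genes(self) -> set[str]:
        genes = set(self.cyt_genes) | set(self.ratio_genes) | set(self.hla_genes)
        genes |= set(self.immune18_genes)
        for p in self.impres_pairs:
            genes |= {p.gene_a, p.gene_b}
        if self.ipres_sets is not None:
            for s in self.ipres_sets:
                genes |= set(s.genes)
        return genes


def read_impres_pairs(path: str | Path) -> tuple[ImpresPair, ...]:
    """Read a 3-column TSV (gene_a, gene_b, direction) of checkpoint pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ("gene_a", "gene_b", "direction")
    if tuple(df.columns[:3]) != required:
        raise ValueError(f"pair table must have columns {required}")
    return tuple(
        ImpresPair(r.gene_a, r.gene_b, r.direction) for r in df.itertuples()
    )


def _require_genes(expr: ExpressionMatrix, genes: Sequence[str]) -> None:
    present = set(expr.gene_ids)
    for g in genes:
        if g not in present:
            raise KeyError(f"required gene {g!r} missing from expression matrix")


def cyt_score(expr: ExpressionMatrix, config: SignatureConfig | None = None) -> pd.Series:
    """Cytolytic activity: per-sample mean of GZMA and PRF1 log2-CPM."""
    config = config or SignatureConfig()
    _require_genes(expr, config.cyt_genes)
    vals = np.vstack([expr.gene_values(g) for g in config.cyt_genes])
    return pd.Series(vals.mean(axis=0), index=expr.sample_ids, name="cyt")


def cd8a_csf1r_score(
    expr: ExpressionMatrix, config: SignatureConfig | None = None
) -> pd.Series:
    """Per-sample CD8A minus CSF1R normalized expression."""
    config = config or SignatureConfig()
    a, b = config.ratio_genes
    _require_genes(expr, (a, b))
    return pd.Series(
        expr.gene_values(a) - expr.gene_values(b),
        index=expr.sample_ids,
        name="cd8a_csf1r",
    )


def immune18_score(
    abundance: ExpressionMatrix,
    config: SignatureConfig,
    params: EnrichmentParams | None = None,
) -> pd.Series:
    """ssGSEA score of the 18-gene immune signature per sample.

    Consumes the length-corrected abundance matrix when available (the
    convention for ssGSEA), else log-CPM.  Partial gene coverage warns;
    zero overlap is an error.
    """
    import warnings

    if not config.immune18_genes:
        raise ValueError("immune18 gene list is empty; supply it in SignatureConfig")
    overlap = set(config.immune18_genes) & set(abundance.gene_ids)
    if not overlap:
        raise ValueError("no immune-signature gene present in the matrix")
    if len(overlap) < len(set(config.immune18_genes)):
        warnings.warn(
            f"immune signature covers {len(overlap)}/{len(set(config.immune18_genes))} genes"
        )
    from mhc_escape.core_io import GeneSet

    coll = GeneSetCollection(
        [GeneSet("immune18", "", sorted(set(config.immune18_genes)))]
    )
    sm = ssgsea_matrix(abundance, coll, params)
    return pd.Series(sm.values[0], index=sm.sample_ids, name="immune18")


def ipres_score(
    abundance: ExpressionMatrix,
    config: SignatureConfig,
    params: EnrichmentParams | None = None,
) -> pd.Series:
    """IPRES: per-sample mean of per-set Z-scored ssGSEA scores."""
    if config.ipres_sets is None or len(config.ipres_sets) == 0:
        raise ValueError("IPRES gene sets not configured")
    sm = ssgsea_matrix(abundance, config.ipres_sets, params)
    z = zscore_by_set(sm)
    return pd.Series(z.values.mean(axis=0), index=z.sample_ids, name="ipres")


def impres_score(
    expr: ExpressionMatrix,
    config: SignatureConfig,
    ties_satisfy: bool = False,
) -> pd.Series:
    """IMPRES: number of checkpoint-pair inequalities satisfied per sample."""
    if not config.impres_pairs:
        raise ValueError("IMPRES pair list is empty; supply it in SignatureConfig")
    score = np.zeros(len(expr.sample_ids), dtype=int)
    for pair in config.impres_pairs:
        _require_genes(expr, (pair.gene_a, pair.gene_b))
        a = expr.gene_values(pair.gene_a)
        b = expr.gene_values(pair.gene_b)
        diff = a - b if pair.direction == "gt" else b - a
        hit = diff > 0
        if ties_satisfy:
            hit |= diff == 0
        score += hit.astype(int)
    return pd.Series(score, index=expr.sample_ids, name="impres")


def classify_inflamed(
    cyt: pd.Series, res_reference: Sequence[float], two_sided: bool = False
) -> pd.Series:
    """Inflamed iff CYT >= min of the responding-lesion reference range.

    ``two_sided=True`` additionally requires CYT <= max(reference).
    """
    ref = np.asarray(list(res_reference), dtype=float)
    if ref.size == 0:
        raise ValueError("empty RES reference range")
    flag = cyt >= ref.min()
    if two_sided:
        flag &= cyt <= ref.max()
    return flag.rename("inflamed")


def signature_battery(
    expr: ExpressionMatrix,
    config: SignatureConfig,
    abundance: ExpressionMatrix | None = None,
    params: EnrichmentParams | None = None,
    external_scores: Mapping[str, pd.Series] | None = None,
    res_reference: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Assemble the per-sample signature score table.

    Always computes ``cyt`` and ``cd8a_csf1r``; computes ``immune18``,
    ``ipres`` and ``impres`` when configured; merges external columns
    (``tide``, ``cd8_fraction``) when supplied; adds ``inflamed`` when a
    RES CYT reference is given.  ssGSEA-based scores use ``abundance``
    (FPKM) when provided, else ``expr``.
    """
    rank_matrix = abundance if abundance is not None else expr
    if abundance is not None and list(abundance.sample_ids) != list(expr.sample_ids):
        mismatch = set(abundance.sample_ids) ^ set(expr.sample_ids)
        raise ValueError(f"sample mismatch between matrices: {sorted(mismatch)}")

    table = pd.DataFrame(index=pd.Index(expr.sample_ids, name="sample_id"))
    table["cyt"] = cyt_score(expr, config)
    table["cd8a_csf1r"] = cd8a_csf1r_score(expr, config)
    if config.immune18_genes:
        table["immune18"] = immune18_score(rank_matrix, config, params)
    if config.ipres_sets is not None and len(config.ipres_sets):
        table["ipres"] = ipres_score(rank_matrix, config, params)
    if config.impres_pairs:
        table["impres"] = impres_score(expr, config)
    if external_scores:
        for name, series in external_scores.items():
            missing = set(table.index) - set(series.index)
            if missing:
                raise ValueError(
                    f"external score {name!r} lacks samples: {sorted(missing)}"
                )
            table[name] = series.reindex(table.index)
    if res_reference is not None:
        table["inflamed"] = classify_inflamed(table["cyt"], res_reference)
    return table


#: a priori ROC orientation per signature: +1 when a higher score predicts
#: response (more immune activity), -1 when a higher score predicts
#: resistance (IPRES, TIDE are resistance signatures).
SIGNATURE_ORIENTATION: dict[str, int] = {
    "cyt": +1,
    "cd8a_csf1r": +1,
    "immune18": +1,
    "impres": +1,
    "cd8_fraction": +1,
    "ipres": -1,
    "tide": -1,
}
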