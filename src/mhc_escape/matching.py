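"""CYT-score-matched tumor pairing with divergent HLA-A expression.

All unordered pairs of eligible (PRE or PROG) tumors are screened: a pair
is a candidate when the two CYT scores are similar (min/max ratio >= 0.9,
the symmetric reading of the 0.9-1.1 window) and the HLA-A transcript
difference exceeds two-fold (|delta log2| > 1, strict).  Candidates are
ranked by descending HLA-A difference and selected greedily so that no
tumor enters two pairs; within a pair the lower-HLA-A member is labeled
``low``, the other ``high``.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd


@dataclasses.dataclass
class MatchCriteria:
    cyt_ratio_min: float = 0.9          # min/max CYT ratio lower bound
    hla_fold_threshold: float = 2.0     # linear fold; |delta log2| must exceed log2 of this
    eligible_timepoints: tuple[str, ...] = ("PRE", "PROG")
    pre_prog_only: bool = False         # restrict pairs to one PRE x one PROG

    def __post_init__(self) -> None:
        if not 0 < self.cyt_ratio_min <= 1:
            raise ValueError("cyt_ratio_min must be in (0, 1]")
        if self.hla_fold_threshold <= 1:
            raise ValueError("hla_fold_threshold must exceed 1")


@dataclasses.dataclass
class CandidatePair:
    sample_a: str
    sample_b: str
    cyt_a: float
    cyt_b: float
    cyt_ratio: float
    hla_a: float
    hla_b: float
    delta_log2: float

    @property
    def members(self) -> tuple[str, str]:
        return (self.sample_a, self.sample_b)


@dataclasses.dataclass
class MatchedPairSet:
    pairs: list[CandidatePair]
    group_labels: pd.Series     # sample_id -> 'low' | 'high'
    criteria: MatchCriteria

    def __len__(self) -> int:
        return len(self.pairs)


def enumerate_candidate_pairs(
    samples: pd.DataFrame,
    criteria: MatchCriteria | None = None,
    cyt_shift: float = 0.0,
) -> list[CandidatePair]:
    """Screen all unordered eligible pairs against both criteria.

    ``samples`` needs columns ``sample_id``, ``cyt``, ``hla_a_log2``,
    ``timepoint``.  CYT ratios are taken on the CYT values as-is (log-CPM
    average scale); nonpositive CYT values are an error unless a positive
    ``cyt_shift`` is supplied, which is added before ratioing.  Output is
    sorted by descending |delta log2 HLA-A|, ties broken by the
    lexicographic (sample_a, sample_b) pair.
    """
    criteria = criteria or MatchCriteria()
    df = samples[samples["timepoint"].isin(criteria.eligible_timepoints)]
    if len(df) < 2:
        raise ValueError("need at least 2 eligible samples")
    cyt = df["cyt"].to_numpy(dtype=float) + cyt_shift
    if np.any(cyt <= 0):
        sid = df["sample_id"].iloc[int(np.flatnonzero(cyt <= 0)[0])]
        raise ValueError(
            f"nonpositive CYT score for sample {sid!r}; CYT ratios are undefined "
            "there — pass a positive cyt_shift to translate scores first"
        )
    hla = df["hla_a_log2"].to_numpy(dtype=float)
    ids = df["sample_id"].tolist()
    tps = df["timepoint"].tolist()
    log_thresh = np.log2(criteria.hla_fold_threshold)

    out: list[CandidatePair] = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if criteria.pre_prog_only and tps[i] == tps[j]:
                continue
            ratio = min(cyt[i], cyt[j]) / max(cyt[i], cyt[j])
            delta = abs(hla[i] - hla[j])
            if ratio >= criteria.cyt_ratio_min and delta > log_thresh:
                a, b = sorted((i, j), key=lambda k: ids[k])
                out.append(
                    CandidatePair(
                        ids[a], ids[b], float(cyt[a] - cyt_shift),
                        float(cyt[b] - cyt_shift), float(ratio),
                        float(hla[a]), float(hla[b]), float(delta),
                    )
                )
    out.sort(key=lambda p: (-p.delta_log2, p.sample_a, p.sample_b))
    return out


def select_matched_pairs(
    candidates: Sequence[CandidatePair],
    criteria: MatchCriteria | None = None,
) -> MatchedPairSet:
    """Greedy disjoint selection over the ranked candidate list.

    Sweeps candidates in their sorted order, accepting a pair iff neither
    member is already used.  An empty candidate list yields an empty set.
    """
    criteria = criteria or MatchCriteria()
    used: set[str] = set()
    selected: list[CandidatePair] = []
    for pair in candidates:
        if pair.sample_a in used or pair.sample_b in used:
            continue
        selected.append(pair)
        used.update(pair.members)
    labels = assign_expression_groups(selected)
    return MatchedPairSet(selected, labels, criteria)


def assign_expression_groups(pairs: Sequence[CandidatePair]) -> pd.Series:
    """Within each pair, the lower-HLA-A member is 'low', the other 'high'."""
    labels: dict[str, str] = {}
    for p in pairs:
        if p.hla_a < p.hla_b:
            labels[p.sample_a], labels[p.sample_b] = "low", "high"
        else:
            labels[p.sample_a], labels[p.sample_b] = "high", "low"
    return pd.Series(labels, name="hla_group", dtype=object)


def pair_table(pairs: MatchedPairSet) -> pd.DataFrame:
    """Flat TSV-ready view of the selected pairs."""
    rows = [
        {
            "sample_a": p.sample_a,
            "sample_b": p.sample_b,
            "cyt_a": p.cyt_a,
            "cyt_b": p.cyt_b,
            "ratio": p.cyt_ratio,
            "hla_a_a": p.hla_a,
            "hla_a_b": p.hla_b,
            "delta_log2": p.delta_log2,
        }
        for p in pairs.pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample_a", "sample_b", "cyt_a", "cyt_b", "ratio",
            "hla_a_a", "hla_a_b", "delta_log2",
        ],
    )


def validate_pair_set(pairs: MatchedPairSet) -> None:
    """Re-check every invariant on a selected pair set; never fires on
    output of :func:`select_matched_pairs`."""
    seen: set[str] = set()
    log_thresh = np.log2(pairs.criteria.hla_fold_threshold)
    for p in pairs.pairs:
        if p.sample_a in seen or p.sample_b in seen:
            raise AssertionError(f"sample reused across pairs: {p.members}")
        seen.update(p.members)
        if not (pairs.criteria.cyt_ratio_min <= p.cyt_ratio <= 1):
            raise AssertionError(f"pair {p.members} violates CYT ratio window")
        if not p.delta_log2 > log_thresh:
            raise AssertionError(f"pair {p.members} violates HLA-A fold threshold")
    n_low = (pairs.group_labels == "low").sum()
    n_high = (pairs.group_labels == "high").sum()
    if n_low != n_high or n_low != len(pairs.pairs):
        raise AssertionError("group sizes must both equal the pair count")
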