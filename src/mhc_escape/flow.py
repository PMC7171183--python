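"""Flow-cytometry HLA-ABC quantities.

Melanoma MHC class I surface expression is summarized relative to the
tumor-infiltrating lymphocytes (TILs) of the same dissociate: the
geometric-mean MFI ratio melanoma/TIL, with ratios below 0.65 called
downregulated (the TILs act as an internal staining control).  Relative
marker expression against an unstained control uses the median-MFI
statistic instead, and in-vitro cytokine induction is the treated/vehicle
fold change.  Gating happens upstream; inputs are gated-population summary
tables.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_DOWNREGULATION_THRESHOLD = 0.65

FLOW_COLUMNS = (
    "sample_id",
    "population",
    "marker",
    "statistic",
    "stained_mfi",
    "unstained_mfi",
)


@dataclasses.dataclass
class HlaStatus:
    sample_id: str
    ratio: float
    threshold: float = DEFAULT_DOWNREGULATION_THRESHOLD

    @property
    def status(self) -> str:
        return "downregulated" if self.ratio < self.threshold else "normal"


def read_flow_table(path: str | Path) -> pd.DataFrame:
    """Read the gated-population summary CSV and validate its columns."""
    df = pd.read_csv(path)
    missing = [c for c in FLOW_COLUMNS if c not in df.columns and c != "unstained_mfi"]
    if missing:
        raise ValueError(f"flow table missing columns: {missing}")
    bad = df["stained_mfi"] <= 0
    if bad.any():
        sid = df.loc[bad, "sample_id"].iloc[0]
        raise ValueError(f"nonpositive MFI for sample {sid!r}")
    return df


def relative_marker_expression(stained_mfi: float, unstained_mfi: float) -> float:
    """Stained / unstained median-MFI ratio."""
    if stained_mfi <= 0 or unstained_mfi <= 0:
        raise ValueError("MFI values must be positive")
    return stained_mfi / unstained_mfi


def hla_abc_relative(melanoma_mfi: float, til_mfi: float) -> float:
    """Melanoma / TIL geometric-mean MFI ratio for one dissociate."""
    if melanoma_mfi <= 0 or til_mfi <= 0:
        raise ValueError("MFI values must be positive")
    return melanoma_mfi / til_mfi


def classify_hla_status(
    ratio: float,
    sample_id: str = "",
    threshold: float = DEFAULT_DOWNREGULATION_THRESHOLD,
) -> HlaStatus:
    """Downregulated iff ratio < threshold (strict); 0.65 by default."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return HlaStatus(sample_id, float(ratio), float(threshold))


def induction_ratio(treated_mfi: float, vehicle_mfi: float) -> float:
    """Fold induction: treated / vehicle MFI."""
    if treated_mfi <= 0 or vehicle_mfi <= 0:
        raise ValueError("MFI values must be positive")
    return treated_mfi / vehicle_mfi


def hla_status_table(
    flow: pd.DataFrame,
    marker: str = "HLA-ABC",
    threshold: float = DEFAULT_DOWNREGULATION_THRESHOLD,
) -> pd.DataFrame:
    """Per-sample melanoma/TIL ratio and downregulation call.

    Requires, per sample, one ``melanoma`` and one ``TIL`` row for the
    marker with the geometric-mean statistic; a sample missing either
    population is an error.
    """
    sub = flow[(flow["marker"] == marker)]
    rows = []
    for sid, grp in sub.groupby("sample_id", sort=False):
        pops = grp.set_index("population")["stained_mfi"]
        for pop in ("melanoma", "TIL"):
            if pop not in pops.index:
                raise ValueError(f"sample {sid!r} lacks a {pop} population row")
        ratio = hla_abc_relative(float(pops["melanoma"]), float(pops["TIL"]))
        status = classify_hla_status(ratio, sid, threshold)
        rows.append(
            {
                "sample_id": sid,
                "ratio": status.ratio,
                "status": status.status,
                "threshold": threshold,
            }
        )
    if not rows:
        raise ValueError(f"no rows for marker {marker!r}")
    return pd.DataFrame(rows)


def flow_transcript_concordance(
    ratios: pd.Series, hla_a_log2: pd.Series
) -> tuple[float, float]:
    """Spearman correlation (rho, two-sided p) between the flow
    melanoma/TIL HLA-ABC ratio and HLA-A transcript level on the samples
    present in both series."""
    common = ratios.index.intersection(hla_a_log2.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired samples")
    rho, p = stats.spearmanr(ratios.reindex(common), hla_a_log2.reindex(common))
    return float(rho), float(p)
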