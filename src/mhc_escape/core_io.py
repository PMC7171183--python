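"""Readers, writers and sample-metadata semantics for the pipeline's formats.

Count matrices travel as either a TSV (header row of sample ids, first
column header ``gene``) or a MatrixMarket coordinate-integer file with
``.rows``/``.cols`` label sidecars.  Gene identifiers are case-sensitive
HGNC symbols; no alias resolution is attempted.  Sample metadata is a TSV
with columns ``sample_id``, ``patient_id``, ``timepoint``, ``irrc_response``,
``resistance_class`` (and optionally ``biopsy_site``); empty strings encode
missing values and are surfaced as ``None``/NaN, never silently coerced.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

TIMEPOINTS = ("PRE", "RES", "PROG")
RESPONSES = ("CR", "PR", "SD", "PD")
RESPONDER_CLASSES = ("CR", "PR")
NONRESPONDER_CLASSES = ("SD", "PD")
LESION_STATUSES = ("CR", "PR", "SD", "PD", "NEW")
RESISTANCE_CLASSES = ("innate", "acquired")


class FormatError(ValueError):
    """Raised when an input file violates the documented dialect."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


@dataclasses.dataclass
class CountMatrix:
    """Raw gene x sample integer counts, the pipeline's entry point.

    Parameters
    ----------
    gene_ids : ordered unique gene symbols (rows).
    sample_ids : ordered unique sample identifiers (columns).
    values : nonnegative integer counts, shape ``(len(gene_ids), len(sample_ids))``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        vals = np.asarray(self.values)
        if vals.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {vals.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.sample_ids) < 2:
            raise FormatError("count matrix requires at least 2 samples")
        if not np.issubdtype(vals.dtype, np.integer):
            frac, _ = np.modf(vals.astype(float))
            bad = np.argwhere(frac != 0)
            if bad.size:
                i, j = bad[0]
                raise FormatError(
                    f"non-integer count {vals[i, j]!r} at gene "
                    f"{self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
                )
            vals = vals.astype(np.int64)
        neg = np.argwhere(vals < 0)
        if neg.size:
            i, j = neg[0]
            raise FormatError(
                f"negative count {vals[i, j]} at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        self.values = vals.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample column sums."""
        return self.values.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids), self.values[:, idx])


def read_counts(path: str | Path) -> CountMatrix:
    """Read a count matrix from TSV or MatrixMarket-plus-sidecar form.

    The dialect is chosen by extension: ``.mtx`` implies MatrixMarket with
    ``<stem>.rows`` and ``<stem>.cols`` label files; anything else is read
    as TSV with first column header ``gene``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".mtx":
        return _read_counts_mtx(path)
    return _read_counts_tsv(path)


def _read_counts_tsv(path: Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene":
        raise FormatError(
            f"{path}: first column header must be 'gene', got {df.columns[0]!r}"
        )
    genes = df.iloc[:, 0].tolist()
    samples = list(df.columns[1:])
    body = df.iloc[:, 1:]
    values = body.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        # locate the offending cell for the error message
        for j, col in enumerate(body.columns):
            coerced = pd.to_numeric(body[col], errors="coerce")
            bad = coerced.isna() & body[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise FormatError(
                    f"{path}: non-numeric count {body[col].iloc[i]!r} at gene "
                    f"{genes[i]!r}, sample {col!r}"
                )
        values = body.apply(pd.to_numeric).to_numpy()
    return CountMatrix(genes, samples, values)


def _read_counts_mtx(path: Path) -> CountMatrix:
    rows_path = path.with_suffix(".rows")
    cols_path = path.with_suffix(".cols")
    for side in (rows_path, cols_path):
        if not side.exists():
            raise FileNotFoundError(f"missing label sidecar {side}")
    genes = rows_path.read_text().splitlines()
    samples = cols_path.read_text().splitlines()
    mat = scipy.io.mmread(path)
    values = np.asarray(
        mat.todense() if scipy.sparse.issparse(mat) else mat
    )
    return CountMatrix(genes, samples, values)


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    """Write a count matrix in the dialect implied by the extension."""
    path = Path(path)
    if path.suffix == ".mtx":
        sparse = scipy.sparse.coo_matrix(counts.values)
        scipy.io.mmwrite(path, sparse, field="integer")
        path.with_suffix(".rows").write_text("\n".join(counts.gene_ids) + "\n")
        path.with_suffix(".cols").write_text("\n".join(counts.sample_ids) + "\n")
    else:
        df = counts.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")


@dataclasses.dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")
        _check_unique(self.genes, f"member (set {self.name!r})")


class GeneSetCollection:
    """Ordered, uniquely named gene sets (GMT semantics)."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.name in self._sets:
                raise FormatError(f"duplicate gene set name: {s.name!r}")
            self._sets[s.name] = s

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection(self._sets[n] for n in names)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a tab-delimited GMT file: name, description, member genes."""
    path = Path(path)
    sets = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
        sets.append(GeneSet(name, desc, genes))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([s.name, s.description, *s.genes]) for s in collection
    ]
    Path(path).write_text("\n".join(lines) + "\n")


METADATA_COLUMNS = (
    "sample_id",
    "patient_id",
    "timepoint",
    "irrc_response",
    "resistance_class",
)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample metadata TSV.

    Returns a DataFrame with one row per sample.  Empty strings become
    missing values.  Enforces: unique sample ids, known timepoints and
    response classes, and ``resistance_class`` present iff
    ``timepoint == 'PROG'``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"metadata missing required columns: {missing_cols}")
    df = df.replace("", None)
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    _check_unique(df["sample_id"].tolist(), "sample")
    bad_tp = df.loc[~df["timepoint"].isin(TIMEPOINTS), "timepoint"]
    if len(bad_tp):
        raise FormatError(f"unknown timepoint {bad_tp.iloc[0]!r}")
    resp = df["irrc_response"]
    bad_resp = df.loc[resp.notna() & ~resp.isin(RESPONSES), "irrc_response"]
    if len(bad_resp):
        raise FormatError(f"unknown irRC response {bad_resp.iloc[0]!r}")
    rc = df["resistance_class"]
    prog = df["timepoint"] == "PROG"
    if (rc.notna() & ~prog).any():
        sid = df.loc[rc.notna() & ~prog, "sample_id"].iloc[0]
        raise FormatError(
            f"sample {sid!r}: resistance_class set on non-PROG timepoint"
        )
    if (prog & rc.isna()).any():
        sid = df.loc[prog & rc.isna(), "sample_id"].iloc[0]
        raise FormatError(f"PROG sample {sid!r} lacks resistance_class")
    bad_rc = df.loc[rc.notna() & ~rc.isin(RESISTANCE_CLASSES), "resistance_class"]
    if len(bad_rc):
        raise FormatError(f"unknown resistance class {bad_rc.iloc[0]!r}")
    return df.reset_index(drop=True)


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for c in out.columns:
        out[c] = out[c].fillna("")
    out.to_csv(path, sep="\t", index=False)


def classify_response_groups(metadata: pd.DataFrame) -> pd.Series:
    """Per-patient responder label from the best irRC response.

    CR/PR -> ``'responder'``; SD/PD -> ``'non-responder'``; missing ->
    ``None`` (unlabeled, excluded from downstream ROC).  Conflicting
    responses recorded for one patient raise an error.
    """
    labels: dict[str, str | None] = {}
    for patient, grp in metadata.groupby("patient_id", sort=False):
        responses = set(grp["irrc_response"].dropna())
        if len(responses) > 1:
            raise ValueError(
                f"patient {patient!r} has conflicting irRC responses: "
                f"{sorted(responses)}"
            )
        if not responses:
            labels[patient] = None
            continue
        (resp,) = responses
        labels[patient] = (
            "responder" if resp in RESPONDER_CLASSES else "non-responder"
        )
    return pd.Series(labels, name="responder_label")


def classify_patient_heterogeneity(lesion_responses: Sequence[str]) -> bool:
    """Flag a heterogeneous (mixed) radiologic response for one patient.

    True iff at least one lesion progressed or appeared new (PD or NEW)
    *and* at least one lesion responded (CR or PR).
    """
    if not lesion_responses:
        raise ValueError("no lesion records supplied")
    statuses = set(lesion_responses)
    unknown = statuses - set(LESION_STATUSES)
    if unknown:
        raise ValueError(f"unknown lesion status: {sorted(unknown)}")
    progressing = bool(statuses & {"PD", "NEW"})
    responding = bool(statuses & {"CR", "PR"})
    return progressing and responding
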