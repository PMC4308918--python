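"""Expression containers, normalization and presence filtering.

Abundance matrices are features x samples. Small-RNA abundance is expressed
in reads per million aligned reads (RPM); mRNA isoform abundance in FPKM.
Presence filters reproduce the study thresholds: a miRNA is "expressed" when
it exceeds 10 RPM in strictly more than 10% of samples (strict inequalities),
an mRNA isoform when it reaches 1 FPKM in at least 10% of samples (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_UNITS = ("counts", "RPM", "FPKM", "quantile-normalized")


@dataclass
class ExpressionMatrix:
    """A features x samples abundance table with a unit tag.

    ``values`` is a pandas DataFrame indexed by feature id with sample ids as
    columns.  Units change only through the declared operations
    (:func:`rpm_normalize`, :func:`quantile_normalize`).
    """

    values: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[list(feature_ids)])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return replace(self, values=self.values[list(sample_ids)])

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path, unit: str) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = "feature_id"
        return cls(values=df, unit=unit)


@dataclass
class SampleAnnotation:
    """Per-sample metadata: group (tumor/normal), molecular subtype by cell of
    origin (ABC/GCB/unclassified), cohort, and cancer-type label."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("group", "subtype", "cohort", "cancer_type")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"sample annotation missing column {col!r}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in annotation")

    def samples_in(self, **criteria) -> list[str]:
        """Sample ids matching all ``column=value`` (or ``column=list``) criteria."""
        mask = pd.Series(True, index=self.table.index)
        for col, val in criteria.items():
            vals = val if isinstance(val, (list, tuple, set)) else [val]
            mask &= self.table[col].isin(list(vals))
        return list(self.table.index[mask])

    def check_covers(self, m: ExpressionMatrix) -> None:
        missing = set(m.sample_ids) - set(self.table.index)
        if missing:
            raise ValueError(f"samples without annotation: {sorted(missing)[:5]}")

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path) -> "SampleAnnotation":
        return cls(table=pd.read_csv(path, sep="\t", index_col=0))


def rpm_normalize(counts: ExpressionMatrix, aligned_totals: pd.Series | dict) -> ExpressionMatrix:
    """Scale raw counts to reads per million aligned reads.

    ``aligned_totals`` gives, per sample, the total number of aligned
    small-RNA reads (not just those assigned to miRNAs).  RPM[f, s] =
    counts[f, s] / totals[s] * 1e6.
    """
    if counts.unit != "counts":
        raise ValueError(f"rpm_normalize expects counts, got {counts.unit}")
    totals = pd.Series(aligned_totals)
    missing = set(counts.sample_ids) - set(totals.index)
    if missing:
        raise ValueError(f"missing aligned totals for samples: {sorted(missing)[:5]}")
    totals = totals.loc[counts.sample_ids]
    bad = totals.index[totals <= 0].tolist()
    if bad:
        raise ValueError(f"non-positive aligned totals for samples: {bad[:5]}")
    rpm = counts.values.div(totals, axis=1) * 1e6
    return ExpressionMatrix(values=rpm, unit="RPM")


def filter_expressed_mirna(
    m: ExpressionMatrix,
    min_rpm: float = 10.0,
    min_fraction: float = 0.10,
    strict: bool = True,
) -> list[str]:
    """Feature ids of miRNAs passing the presence threshold.

    Default (strict): retained iff value > min_rpm in strictly more than
    ``min_fraction`` of samples.  With ``strict=False`` both comparisons are
    inclusive.  Input feature order is preserved.
    """
    if m.unit != "RPM":
        raise ValueError(f"filter_expressed_mirna expects RPM, got {m.unit}")
    return _presence_filter(m, min_rpm, min_fraction, strict=strict)


def filter_expressed_mrna(
    m: ExpressionMatrix,
    min_fpkm: float = 1.0,
    min_fraction: float = 0.10,
    strict: bool = False,
) -> list[str]:
    """Feature ids of mRNA isoforms at >= min_fpkm in >= min_fraction of samples
    (inclusive by default)."""
    if m.unit != "FPKM":
        raise ValueError(f"filter_expressed_mrna expects FPKM, got {m.unit}")
    return _presence_filter(m, min_fpkm, min_fraction, strict=strict)


def _presence_filter(m: ExpressionMatrix, threshold: float, min_fraction: float, strict: bool) -> list[str]:
    if m.values.empty:
        raise ValueError("empty expression matrix")
    n = m.values.shape[1]
    vals = m.values.to_numpy()
    if strict:
        frac = (vals > threshold).sum(axis=1) / n
        keep = frac > min_fraction
    else:
        frac = (vals >= threshold).sum(axis=1) / n
        keep = frac >= min_fraction
    return [fid for fid, k in zip(m.feature_ids, keep) if k]


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto a common (mean-quantile) distribution.

    The reference distribution is the row-wise mean of the column-sorted
    matrix; each column's values are replaced by the reference value at their
    rank, with ties receiving the mean of the reference values over their tied
    ranks (the conventional mean-rank dialect).
    """
    if m.values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    vals = m.values.to_numpy(dtype=float)
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = reference.copy()
        # average reference values over runs of tied input values
        sorted_col = col[order]
        i = 0
        nrow = len(col)
        while i < nrow:
            k = i
            while k + 1 < nrow and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            if k > i:
                ranked[i : k + 1] = reference[i : k + 1].mean()
            i = k + 1
        out[order, j] = ranked
    df = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values=df, unit="quantile-normalized")
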