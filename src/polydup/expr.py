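"""Expression summarisation from mapped-read counts.

Only the arithmetic layer: RPKM (reads per kilobase of transcript per
million mapped reads) from a count table, CDS lengths and per-sample
mapped totals, plus log2 fold tables against a baseline sample. Read
alignment is out of scope; counts are an input. A negative-binomial
count generator is provided so "no drastic change" null scenarios can
be emulated in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


def rpkm(count: float, length_bp: float, total_mapped: float) -> float:
    """count / (length_bp/1000) / (total_mapped/1e6)."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / (length_bp / 1e3) / (total_mapped / 1e6)


@dataclass
class ExpressionTable:
    """Counts (genes x samples) with CDS lengths (bp) and mapped totals."""

    counts: pd.DataFrame
    lengths: pd.Series  # indexed like counts rows, bp
    totals: pd.Series  # indexed like counts columns, mapped reads per sample

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("missing CDS length for some genes")
        if (self.lengths <= 0).any():
            raise ValueError("CDS lengths must be positive")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.totals = self.totals.reindex(self.counts.columns)
        if self.totals.isna().any():
            raise ValueError("missing mapped total for some samples")
        colsums = self.counts.sum(axis=0)
        if (self.totals < colsums - 1e-9).any():
            raise ValueError("mapped totals smaller than column count sums")

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        lengths: pd.Series,
        totals: pd.Series | None = None,
    ) -> "ExpressionTable":
        if totals is None:
            totals = counts.sum(axis=0)
        return cls(counts=counts, lengths=lengths, totals=totals)

    def rpkm(self) -> pd.DataFrame:
        per_kb = self.lengths.values[:, None] / 1e3
        per_million = self.totals.values[None, :] / 1e6
        return pd.DataFrame(
            self.counts.values / per_kb / per_million,
            index=self.counts.index,
            columns=self.counts.columns,
        )


def fold_table(
    rpkm_df: pd.DataFrame, baseline: str, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2((rpkm+pc)/(rpkm_baseline+pc)) per gene per sample.

    The baseline column is identically zero in the result.
    """
    if baseline not in rpkm_df.columns:
        raise ValueError(f"baseline sample {baseline!r} not in table")
    base = rpkm_df[baseline].values[:, None] + pseudocount
    return pd.DataFrame(
        np.log2((rpkm_df.values + pseudocount) / base),
        index=rpkm_df.index,
        columns=rpkm_df.columns,
    )


def simulate_counts(
    lengths: pd.Series,
    samples: list[str],
    rng: np.random.Generator,
    mean_rpkm: float = 50.0,
    dispersion: float = 0.3,
    depth: float = 1e6,
) -> ExpressionTable:
    """Negative-binomial counts with a flat expression profile.

    Gene baselines are log-normal around ``mean_rpkm``; per-sample counts
    are NB with var = mu + dispersion*mu^2 around the same per-gene mean
    (the "no drastic change across samples" null). ``depth`` is the
    per-sample mapped total before the family's own reads are added.
    """
    base_rpkm = mean_rpkm * rng.lognormal(0.0, 0.5, size=len(lengths))
    mu = base_rpkm * (lengths.values / 1e3) * (depth / 1e6)
    counts = np.empty((len(lengths), len(samples)), dtype=np.int64)
    r = 1.0 / dispersion
    for j in range(len(samples)):
        p = r / (r + mu)
        counts[:, j] = rng.negative_binomial(r, p)
    df = pd.DataFrame(counts, index=lengths.index, columns=samples)
    totals = pd.Series(depth, index=samples) + df.sum(axis=0)
    return ExpressionTable(counts=df, lengths=lengths.copy(), totals=totals)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6f", index_label="id")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
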