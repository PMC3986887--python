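"""Expression and methylation profiles at the cell-type-class level.

A *profile* is a vector over cell-type classes: for a TSS cluster the
RLE-normalized CAGE expression averaged within each class, for a cytosine
the percent methylation averaged within each class (with per-class summed
read coverage).  This module reads the per-sample tables, averages by
class, normalizes expression, applies the coverage/completeness and
expression filters, derives promoter windows from TSS clusters and
assigns cytosines to the promoters that contain them.

Coordinates are 0-based half-open throughout; methylation positions refer
to the C of the CpG dyad on the forward strand (minus-strand records are
collapsed onto it with a coverage-weighted average).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import InsufficientDataError, MappingError, NormalizationError

#: promoter window relative to the TSS cluster, in the direction of transcription
PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500

MIN_COVERAGE = 10          # reads per class below which a value is missing
MIN_CLASS_FRACTION = 0.5   # fraction of classes that must carry data
MIN_EXPRESSION = 1.0       # at least one class value >= 1 retains a TSS
MIN_AMPLITUDE = 50.0       # strict >: percentage points for "differential"


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_sample_map(path: str | Path) -> pd.DataFrame:
    """Sample table with columns sample_id, class_id, normal (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "class_id": str})
    df["normal"] = df["normal"].astype(bool)
    return df.set_index("sample_id")


def read_methylation_table(
    path: str | Path, collapse_strands: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long per-sample methylation table -> (percent, coverage) wide tables.

    Input columns: chrom, pos0, strand, sample, coverage, percent_meth.
    With ``collapse_strands`` the two strands of a CpG dyad are merged
    onto the forward C position using a coverage-weighted percent.
    Returns wide frames indexed by (chrom, pos0) with sample columns;
    absent records are missing values.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    if collapse_strands:
        df = df.assign(pos0=df["pos0"] - (df["strand"] == "-").astype(int))
        weighted = df["percent_meth"] * df["coverage"]
        grouped = df.assign(_w=weighted).groupby(["chrom", "pos0", "sample"])
        agg = grouped.agg(coverage=("coverage", "sum"), _w=("_w", "sum"))
        agg["percent_meth"] = np.where(
            agg["coverage"] > 0, agg["_w"] / agg["coverage"].replace(0, np.nan), np.nan
        )
        df = agg.reset_index()
    percent = df.pivot_table(
        index=["chrom", "pos0"], columns="sample", values="percent_meth", aggfunc="mean"
    )
    coverage = df.pivot_table(
        index=["chrom", "pos0"], columns="sample", values="coverage", aggfunc="sum"
    )
    return percent, coverage


def read_expression_table(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TSS-cluster table -> (clusters, counts) with clusters indexed by id."""
    df = pd.read_csv(path, sep="\t", dtype={"cluster_id": str, "chrom": str})
    meta_cols = ["cluster_id", "chrom", "start", "end", "strand"]
    clusters = df[meta_cols].set_index("cluster_id")
    counts = df.drop(columns=meta_cols[1:]).set_index("cluster_id").astype(float)
    return clusters, counts


# ---------------------------------------------------------------------------
# class averaging and normalization
# ---------------------------------------------------------------------------

def _classes_of(columns: pd.Index, sample_map: pd.DataFrame) -> pd.Series:
    unmapped = [c for c in columns if c not in sample_map.index]
    if unmapped:
        raise MappingError(f"samples not in sample map: {unmapped[:5]}")
    return sample_map.loc[columns, "class_id"]


def average_by_class(values: pd.DataFrame, sample_map: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean over each class's non-missing sample values.

    A class value is missing iff every sample of the class is missing.
    """
    classes = _classes_of(values.columns, sample_map)
    return values.T.groupby(classes.values).mean().T


def sum_by_class(values: pd.DataFrame, sample_map: pd.DataFrame) -> pd.DataFrame:
    """Per-class sum (used for read coverage); missing iff all missing."""
    classes = _classes_of(values.columns, sample_map)
    return values.T.groupby(classes.values).sum(min_count=1).T


def rle_normalize(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Relative log expression (median-of-ratios) normalization.

    The size factor of a sample is the median, over clusters with positive
    counts in every sample, of the count divided by the cluster's
    geometric mean across samples.  Values are the counts divided by the
    sample's size factor.
    """
    if (counts.values < 0).any():
        raise NormalizationError("negative counts")
    reference = (counts > 0).all(axis=1)
    if not reference.any():
        raise NormalizationError("no cluster with positive counts in all samples")
    logs = np.log(counts.loc[reference])
    log_ratios = logs.sub(logs.mean(axis=1), axis=0)
    size_factors = np.exp(log_ratios.median(axis=0))
    return counts.div(size_factors, axis=1), size_factors


def filter_tss(expression: pd.DataFrame, min_value: float = MIN_EXPRESSION) -> pd.DataFrame:
    """Keep TSS clusters with at least one class value >= ``min_value``."""
    keep = (expression >= min_value).any(axis=1)
    return expression.loc[keep]


def filter_cytosines(
    percent: pd.DataFrame,
    coverage: pd.DataFrame,
    min_coverage: int = MIN_COVERAGE,
    min_class_fraction: float = MIN_CLASS_FRACTION,
    n_classes: int | None = None,
) -> pd.DataFrame:
    """Mask low-coverage class values, then drop incomplete cytosines.

    A class value with summed coverage below ``min_coverage`` is treated
    as missing; a cytosine is retained when the number of non-missing
    classes reaches ``ceil(min_class_fraction * n_classes)`` (25 of 50,
    18 of 36).
    """
    coverage = coverage.reindex(columns=percent.columns).fillna(0.0)
    masked = percent.where(coverage >= min_coverage)
    total = percent.shape[1] if n_classes is None else n_classes
    required = math.ceil(min_class_fraction * total)
    return masked.loc[masked.notna().sum(axis=1) >= required]


# ---------------------------------------------------------------------------
# amplitude
# ---------------------------------------------------------------------------

def amplitude(values) -> float:
    """Max minus min over the non-missing class values (>= 2 required)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise InsufficientDataError("amplitude requires >= 2 class values")
    return float(arr.max() - arr.min())


def is_differential(values, min_amplitude: float = MIN_AMPLITUDE) -> bool:
    """Strictly greater than ``min_amplitude`` percentage points."""
    return amplitude(values) > min_amplitude


def differential_flags(percent: pd.DataFrame, min_amplitude: float = MIN_AMPLITUDE) -> pd.Series:
    """Vectorized differential flag per cytosine (False when < 2 values)."""
    amp = percent.max(axis=1) - percent.min(axis=1)
    enough = percent.notna().sum(axis=1) >= 2
    return (amp > min_amplitude) & enough


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def define_promoters(clusters: pd.DataFrame) -> pd.DataFrame:
    """Promoter windows around TSS clusters, strand-aware, clipped at 0.

    Plus strand: ``[start - 1500, end + 500)``; minus strand:
    ``[start - 500, end + 1500)``.  Overlapping promoters are kept
    independently (no merging); unclipped windows span the cluster plus
    exactly 2000 bp.
    """
    plus = clusters["strand"] == "+"
    start = np.where(
        plus, clusters["start"] - PROMOTER_UPSTREAM, clusters["start"] - PROMOTER_DOWNSTREAM
    )
    end = np.where(
        plus, clusters["end"] + PROMOTER_DOWNSTREAM, clusters["end"] + PROMOTER_UPSTREAM
    )
    return pd.DataFrame(
        {
            "chrom": clusters["chrom"],
            "start": np.maximum(start, 0).astype(int),
            "end": end.astype(int),
            "strand": clusters["strand"],
            "cluster_id": clusters.index,
        },
        index=clusters.index,
    )


def assign_cytosines_to_promoters(
    cytosines: pd.DataFrame, promoters: pd.DataFrame
) -> pd.DataFrame:
    """All (cytosine, promoter) containment pairs.

    ``cytosines`` needs chrom/pos columns (index = cytosine id); a
    cytosine inside several overlapping promoters yields several pairs.
    """
    trees: dict[str, IntervalTree] = {}
    for cluster_id, row in promoters.iterrows():
        if row["end"] <= row["start"]:
            continue
        trees.setdefault(row["chrom"], IntervalTree()).addi(
            row["start"], row["end"], cluster_id
        )
    pairs: list[tuple] = []
    for cyt_id, row in cytosines.iterrows():
        tree = trees.get(row["chrom"])
        if tree is None:
            continue
        for iv in tree.at(row["pos"]):
            pairs.append((cyt_id, iv.data))
    return pd.DataFrame(pairs, columns=["cytosine_id", "cluster_id"])
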