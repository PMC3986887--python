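"""Methylation-expression correlation and CpG traffic-light calling.

For every (cytosine, promoter) pair the Spearman correlation SCC between
the cytosine's per-class methylation profile and the TSS cluster's
per-class expression profile is computed on pairwise-complete classes.
Significance uses the transformation to Student's t with n - 2 degrees of
freedom:

    ``t = SCC * sqrt(n - 2) / sqrt(1 - SCC**2)``

with a two-sided P-value; the sign of the effect is read from SCC.  A
differentially methylated cytosine (profile amplitude > 50 points) with
at least one significantly negative SCC (P <= 0.01) is a CpG "traffic
light"; positives are called analogously when no negative call applies.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

MIN_PAIRS = 5            # minimum pairwise-complete classes for an SCC
DEFAULT_ALPHA = 0.01
SUMMARY_ALPHAS = (0.05, 0.01, 0.001)

LABEL_NEGATIVE = "negative_significant"
LABEL_POSITIVE = "positive_significant"
LABEL_NONE = "insignificant"


def spearman(x, y, min_pairs: int = MIN_PAIRS) -> tuple[float, int]:
    """Spearman correlation on pairwise-complete classes.

    Average ranks handle ties.  Returns ``(nan, n)`` when fewer than
    ``min_pairs`` complete pairs remain or when either vector is constant
    (undefined correlation; excluded downstream).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < min_pairs:
        return float("nan"), n
    xr = stats.rankdata(x[mask])
    yr = stats.rankdata(y[mask])
    xr -= xr.mean()
    yr -= yr.mean()
    denom = np.sqrt((xr * xr).sum() * (yr * yr).sum())
    if denom == 0.0:  # constant vector: undefined correlation
        return float("nan"), n
    return float((xr * yr).sum() / denom), n


def scc_significance(scc: float, n: int) -> tuple[float, float]:
    """Student-t statistic and two-sided P-value for an SCC.

    ``|SCC| = 1`` maps to an infinite statistic and P = 0 (flagged by the
    caller via the t value); otherwise P is the two-sided tail of
    Student's t with ``n - 2`` degrees of freedom.
    """
    if abs(scc) >= 1.0:
        return float(np.sign(scc)) * float("inf"), 0.0
    t = scc * np.sqrt(n - 2) / np.sqrt(1.0 - scc * scc)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(t), float(min(p, 1.0))


def correlate_pairs(
    methylation: pd.DataFrame,
    expression: pd.DataFrame,
    pairs: pd.DataFrame,
    min_pairs: int = MIN_PAIRS,
) -> pd.DataFrame:
    """SCC, n, t and P for every (cytosine, promoter) pair.

    ``methylation``/``expression`` are class-level wide tables;
    ``pairs`` has columns cytosine_id and cluster_id.  Pairs with too few
    complete classes or an undefined correlation are omitted.
    """
    classes = methylation.columns.intersection(expression.columns)
    meth = methylation[classes].to_numpy()
    expr = expression[classes].to_numpy()
    meth_row = {k: i for i, k in enumerate(methylation.index)}
    expr_row = {k: i for i, k in enumerate(expression.index)}

    records = []
    for cyt_id, cluster_id in pairs.itertuples(index=False):
        i = meth_row.get(cyt_id)
        j = expr_row.get(cluster_id)
        if i is None or j is None:
            continue
        scc, n = spearman(meth[i], expr[j], min_pairs)
        if not np.isfinite(scc):
            continue
        t, p = scc_significance(scc, n)
        records.append((cyt_id, cluster_id, scc, n, t, p))
    return pd.DataFrame(
        records, columns=["cytosine_id", "cluster_id", "scc", "n", "t", "p"]
    )


def call_traffic_lights(
    results: pd.DataFrame,
    differential: pd.Series,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-cytosine call using the at-least-one rule over its promoters.

    negative_significant: differential and >= 1 result with SCC < 0 and
    P <= alpha; positive_significant: differential, not negative, and
    >= 1 result with SCC > 0 and P <= alpha.  Cytosines significant in
    both directions keep the negative label and are flagged ambiguous.
    """
    res = results.copy()
    res["neg_sig"] = (res["scc"] < 0) & (res["p"] <= alpha)
    res["pos_sig"] = (res["scc"] > 0) & (res["p"] <= alpha)
    res["neg_p"] = res["p"].where(res["scc"] < 0)
    res["pos_p"] = res["p"].where(res["scc"] > 0)
    grouped = res.groupby("cytosine_id").agg(
        any_negative=("neg_sig", "any"),
        any_positive=("pos_sig", "any"),
        best_negative_p=("neg_p", "min"),
        best_positive_p=("pos_p", "min"),
        best_p=("p", "min"),
        n_results=("p", "size"),
    )
    diff = differential.reindex(grouped.index).fillna(False).astype(bool)
    label = np.where(
        diff & grouped["any_negative"],
        LABEL_NEGATIVE,
        np.where(diff & grouped["any_positive"], LABEL_POSITIVE, LABEL_NONE),
    )
    calls = grouped.assign(
        differential=diff,
        label=label,
        ambiguous=grouped["any_negative"] & grouped["any_positive"],
    )
    return calls


def summarize_calls(
    results: pd.DataFrame,
    differential: pd.Series,
    total: int | None = None,
    alphas: Iterable[float] = SUMMARY_ALPHAS,
) -> pd.DataFrame:
    """Count table by sign and significance level with fractions of total.

    ``n_significant`` counts cytosines with at least one significant SCC
    of the given sign; ``n_traffic_light`` additionally requires the
    differential-methylation flag.  ``total`` defaults to the number of
    analyzed cytosines (those with >= 1 SCC result).
    """
    total = int(results["cytosine_id"].nunique()) if total is None else total
    rows = []
    for alpha in alphas:
        calls = call_traffic_lights(results, differential, alpha)
        for sign, any_col, lab in (
            ("negative", "any_negative", LABEL_NEGATIVE),
            ("positive", "any_positive", LABEL_POSITIVE),
        ):
            n_sig = int(calls[any_col].sum())
            n_tl = int((calls["label"] == lab).sum())
            rows.append((sign, alpha, n_sig, n_tl, n_sig / total))
    return pd.DataFrame(
        rows, columns=["sign", "alpha", "n_significant", "n_traffic_light", "fraction"]
    )


def fractions_from_counts(
    counts: Mapping[str, Mapping[float, int]], total: int
) -> dict[str, dict[float, float]]:
    """Significant counts -> fractions of the analyzed total (Table-1 style)."""
    return {
        sign: {alpha: c / total for alpha, c in by_alpha.items()}
        for sign, by_alpha in counts.items()
    }
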