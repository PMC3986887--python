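"""Over/underrepresentation of CpG traffic lights within TFBSs.

For every TF (and model kind) the number of analyzed CpGs overlapping its
predicted binding sites is compared with the number of traffic lights
among them.  The expected count is the genome-wide traffic-light fraction
times the CpGs in the TF's sites; the test is a one-sample chi-square
with one degree of freedom (no continuity correction), Bonferroni
corrected over the TFs entering the test.  An exact binomial tail
(distance ordering, which is equivalent to ordering by the chi-square
statistic) is reported alongside, since the chi-square approximation
degrades at small expected counts.  TF-function classes
(activator/repressor/both) are compared with Welch's t-test on the
per-TF observed/expected ratios, and CpG positions inside hits are
stratified by the motif's core/medium/low column-pair classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError
from .motif_models import CpGColumnPair

BONFERRONI_ALPHA = 0.05


# ---------------------------------------------------------------------------
# overlap counting
# ---------------------------------------------------------------------------

def overlap_membership(
    cpgs: pd.DataFrame, hits: pd.DataFrame
) -> dict[tuple[str, str], np.ndarray]:
    """Boolean membership of each CpG in each (kind, tf) hit set.

    ``cpgs`` needs chrom/pos columns (index = cytosine id).  A CpG counts
    once per TF per model kind regardless of hit multiplicity.
    """
    membership: dict[tuple[str, str], np.ndarray] = {}
    if hits.empty:
        return membership
    chroms = cpgs["chrom"].to_numpy()
    positions = cpgs["pos"].to_numpy()
    for (kind, tf), sub in hits.groupby(["kind", "tf"]):
        trees: dict[str, IntervalTree] = {}
        for row in sub.itertuples(index=False):
            trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
        inside = np.zeros(len(cpgs), dtype=bool)
        for i in range(len(cpgs)):
            tree = trees.get(chroms[i])
            if tree is not None and tree.overlaps_point(int(positions[i])):
                inside[i] = True
        membership[(kind, tf)] = inside
    return membership


def count_overlaps(cpgs: pd.DataFrame, hits: pd.DataFrame) -> pd.DataFrame:
    """Per-(kind, tf) counts of analyzed CpGs and significant CpGs inside hits.

    ``cpgs`` carries boolean columns ``negative`` and ``positive`` (the
    traffic-light and positive-SCC calls); only CpGs present in the frame
    (i.e. with at least one SCC result) are counted.
    """
    membership = overlap_membership(cpgs, hits)
    neg = cpgs["negative"].to_numpy()
    pos = cpgs["positive"].to_numpy()
    rows = []
    for (kind, tf), inside in sorted(membership.items()):
        rows.append(
            (tf, kind, int(inside.sum()), int(neg[inside].sum()), int(pos[inside].sum()))
        )
    return pd.DataFrame(
        rows, columns=["tf", "kind", "n_cpg_in_tfbs", "observed_negative", "observed_positive"]
    )


# ---------------------------------------------------------------------------
# the test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    observed: int
    n_cpg_in_tfbs: int
    expected: float
    ratio: float
    chi2: float
    p: float
    p_bonferroni: float
    p_binomial: float
    direction: str  # under | over | none


def exact_binomial_p(observed: int, n: int, fraction: float) -> float:
    """P(|X - e| >= |observed - e|) for X ~ Binomial(n, fraction).

    Distance-from-expectation ordering; identical to ordering outcomes by
    the one-sample chi-square statistic.
    """
    e = n * fraction
    k = np.arange(n + 1)
    pmf = stats.binom.pmf(k, n, fraction)
    return float(pmf[np.abs(k - e) >= abs(observed - e) - 1e-9].sum())


def enrichment_test(
    observed: int,
    n_in_tfbs: int,
    global_fraction: float,
    m_tests: int = 1,
    alpha: float = BONFERRONI_ALPHA,
) -> EnrichmentResult:
    """One-sample chi-square of observed vs expected traffic-light counts."""
    if n_in_tfbs <= 0:
        raise ConfigurationError("n_in_tfbs must be positive")
    if not 0.0 < global_fraction < 1.0:
        raise ConfigurationError("global_fraction must be in (0, 1)")
    expected = global_fraction * n_in_tfbs
    chi2 = (observed - expected) ** 2 / expected + (
        (n_in_tfbs - observed) - (n_in_tfbs - expected)
    ) ** 2 / (n_in_tfbs - expected)
    p = float(stats.chi2.sf(chi2, df=1))
    p_bonf = min(1.0, p * m_tests)
    if p_bonf < alpha and observed < expected:
        direction = "under"
    elif p_bonf < alpha and observed > expected:
        direction = "over"
    else:
        direction = "none"
    return EnrichmentResult(
        observed=observed,
        n_cpg_in_tfbs=n_in_tfbs,
        expected=expected,
        ratio=observed / expected,
        chi2=float(chi2),
        p=p,
        p_bonferroni=p_bonf,
        p_binomial=exact_binomial_p(observed, n_in_tfbs, global_fraction),
        direction=direction,
    )


def enrichment_table(
    cpgs: pd.DataFrame,
    hits: pd.DataFrame,
    sign: str = "negative",
    alpha: float = BONFERRONI_ALPHA,
    require_observed: bool = True,
) -> pd.DataFrame:
    """Per-TF enrichment of significant CpGs within hits, per model kind.

    The global fraction is the fraction of significant CpGs of the given
    sign among all analyzed CpGs.  Bonferroni's m counts, per model kind,
    the TFs entering the test (by default those with at least one
    observed significant CpG in their sites, mirroring the inclusion rule
    of the per-TF tables).
    """
    if sign not in ("negative", "positive"):
        raise ConfigurationError("sign must be 'negative' or 'positive'")
    counts = count_overlaps(cpgs, hits)
    global_fraction = float(cpgs[sign].mean())
    obs_col = f"observed_{sign}"
    rows = []
    for kind, sub in counts.groupby("kind"):
        sub = sub[sub["n_cpg_in_tfbs"] > 0]
        entering = sub[sub[obs_col] > 0] if require_observed else sub
        m = len(entering)
        for row in entering.itertuples(index=False):
            res = enrichment_test(
                getattr(row, obs_col), row.n_cpg_in_tfbs, global_fraction, m, alpha
            )
            rows.append(
                (
                    row.tf,
                    kind,
                    row.n_cpg_in_tfbs,
                    res.observed,
                    res.expected,
                    res.ratio,
                    res.chi2,
                    res.p,
                    res.p_bonferroni,
                    res.p_binomial,
                    res.direction,
                    m,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "tf",
            "kind",
            "n_cpg_in_tfbs",
            "observed",
            "expected",
            "ratio",
            "chi2",
            "p",
            "p_bonferroni",
            "p_binomial",
            "direction",
            "m_tests",
        ],
    )


# ---------------------------------------------------------------------------
# TF function classes
# ---------------------------------------------------------------------------

def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch's t with explicit handling of degenerate (zero-variance) inputs."""
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean())) * float("inf"), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def compare_function_classes(
    table: pd.DataFrame, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Mean observed/expected ratio per TF-function class, repressors vs rest.

    ``labels`` maps TF id to activator/repressor/both.  Classes with
    fewer than two members are skipped.  Returns one row per comparison
    (repressor vs activator, repressor vs both) and per model kind, with
    the class means and the Welch two-sided test.
    """
    df = table.assign(function=table["tf"].map(labels))
    rows = []
    for kind, sub in df.groupby("kind"):
        groups = {
            fn: g["ratio"].to_numpy()
            for fn, g in sub.groupby("function")
            if len(g) >= 2
        }
        if "repressor" not in groups:
            continue
        for other in ("activator", "both"):
            if other not in groups:
                continue
            t, p = _welch(groups["repressor"], groups[other])
            rows.append(
                (
                    kind,
                    other,
                    float(groups["repressor"].mean()),
                    float(groups[other].mean()),
                    len(groups["repressor"]),
                    len(groups[other]),
                    t,
                    p,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "kind",
            "versus",
            "mean_ratio_repressor",
            "mean_ratio_other",
            "n_repressor",
            "n_other",
            "t",
            "p",
        ],
    )


# ---------------------------------------------------------------------------
# positional (core/flanking) stratification
# ---------------------------------------------------------------------------

def _motif_column(pos: int, start: int, end: int, strand: str) -> int:
    """Motif column of the C of a forward-strand CpG inside a hit.

    On the minus strand the CpG dyad maps onto itself (CG is its own
    reverse complement); the motif-strand C corresponds to the forward G.
    """
    if strand == "+":
        return pos - start
    return end - pos - 2


def positional_enrichment(
    cpgs: pd.DataFrame,
    hits: pd.DataFrame,
    pair_classes: Mapping[tuple[str, str], Sequence[CpGColumnPair]],
    global_fraction: float | None = None,
    sign: str = "negative",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratify CpG-in-hit counts by the motif column pair they occupy.

    Each (CpG, hit) overlap is attributed to the motif column pair the
    CpG occupies; pairs classified by DIC route the CpG to the core,
    medium, low or mixed stratum of that TF (counted once per stratum).
    CpGs not aligned to a classified C-G column pair are tallied as
    ``non_cpg_column``.  Returns the per-(kind, tf, stratum) enrichment
    table and a cross-TF paired comparison of core vs flanking
    (medium + low) ratios.
    """
    if global_fraction is None:
        global_fraction = float(cpgs[sign].mean())
    sig = cpgs[sign]
    class_of: dict[tuple[str, str, int], str] = {}
    for (kind, tf), pairs in pair_classes.items():
        for pair in pairs:
            class_of[(kind, tf, pair.position)] = pair.category

    # sorted position index per chromosome for O(log n) hit -> CpG lookup
    order = np.lexsort((cpgs["pos"].to_numpy(), cpgs["chrom"].to_numpy()))
    sorted_pos: dict[str, np.ndarray] = {}
    sorted_ids: dict[str, np.ndarray] = {}
    chroms_sorted = cpgs["chrom"].to_numpy()[order]
    pos_sorted = cpgs["pos"].to_numpy()[order]
    ids_sorted = cpgs.index.to_numpy()[order]
    for chrom in np.unique(chroms_sorted):
        sel = chroms_sorted == chrom
        sorted_pos[chrom] = pos_sorted[sel]
        sorted_ids[chrom] = ids_sorted[sel]

    tallies: dict[tuple[str, str, str], set] = {}
    for row in hits.itertuples(index=False):
        pos_arr = sorted_pos.get(row.chrom)
        if pos_arr is None:
            continue
        lo = np.searchsorted(pos_arr, row.start, side="left")
        hi = np.searchsorted(pos_arr, row.end - 2, side="right")
        for k in range(lo, hi):
            pos = int(pos_arr[k])
            column = _motif_column(pos, row.start, row.end, row.strand)
            stratum = class_of.get((row.kind, row.tf, column), "non_cpg_column")
            tallies.setdefault((row.kind, row.tf, stratum), set()).add(sorted_ids[row.chrom][k])

    sig_by_id = sig.to_dict()
    rows = []
    for (kind, tf, stratum), members in sorted(tallies.items()):
        n = len(members)
        observed = sum(bool(sig_by_id[m]) for m in members)
        if stratum != "non_cpg_column" and n > 0 and 0 < global_fraction < 1:
            res = enrichment_test(observed, n, global_fraction)
            ratio, chi2, p = res.ratio, res.chi2, res.p
        else:
            expected = n * global_fraction
            ratio = observed / expected if expected > 0 else np.nan
            chi2 = p = np.nan
        rows.append((kind, tf, stratum, n, observed, n * global_fraction, ratio, chi2, p))
    strata = pd.DataFrame(
        rows,
        columns=["kind", "tf", "stratum", "n_cpg", "observed", "expected", "ratio", "chi2", "p"],
    )

    comparisons = []
    for kind, sub in strata.groupby("kind"):
        wide = sub.pivot_table(index="tf", columns="stratum", values="ratio")
        flanking_cols = [c for c in ("medium", "low") if c in wide.columns]
        if "core" not in wide.columns or not flanking_cols:
            continue
        flank = wide[flanking_cols].mean(axis=1)
        both = pd.DataFrame({"core": wide["core"], "flanking": flank}).dropna()
        if len(both) < 2:
            continue
        res = stats.ttest_rel(both["core"], both["flanking"])
        comparisons.append(
            (
                kind,
                len(both),
                float(both["core"].mean()),
                float(both["flanking"].mean()),
                float(res.statistic),
                float(res.pvalue),
            )
        )
    paired = pd.DataFrame(
        comparisons,
        columns=["kind", "n_tf", "mean_core_ratio", "mean_flanking_ratio", "t", "p"],
    )
    return strata, paired


# ---------------------------------------------------------------------------
# permutation calibration
# ---------------------------------------------------------------------------

def permutation_calibration(
    membership: Mapping[tuple[str, str], np.ndarray],
    labels: np.ndarray,
    n_permutations: int = 200,
    rng: np.random.Generator | None = None,
    alpha: float = BONFERRONI_ALPHA,
) -> dict[str, float]:
    """Null calibration by permuting traffic-light labels across CpGs.

    Under random label assignment the per-TF observed/expected ratio has
    mean 1 and the Bonferroni-significant count stays near 0.  Returns
    the mean ratio over TFs and permutations, the mean significant count
    per permutation, and the family size m.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    labels = np.asarray(labels, dtype=bool)
    g = labels.mean()
    if not 0 < g < 1:
        raise InsufficientDataError("labels must contain both classes")
    matrix = np.column_stack([m for _, m in sorted(membership.items())]).astype(float)
    n_vec = matrix.sum(axis=0)
    keep = n_vec > 0
    matrix, n_vec = matrix[:, keep], n_vec[keep]
    m = matrix.shape[1]
    expected = g * n_vec
    ratios = np.empty((n_permutations, m))
    significant = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(labels).astype(float)
        observed = perm @ matrix
        ratios[b] = observed / expected
        chi2 = (observed - expected) ** 2 / expected + (
            (n_vec - observed) - (n_vec - expected)
        ) ** 2 / (n_vec - expected)
        p = stats.chi2.sf(chi2, df=1)
        significant[b] = (np.minimum(1.0, p * m) < alpha).sum()
    return {
        "mean_ratio": float(ratios.mean()),
        "mean_significant": float(significant.mean()),
        "m": float(m),
    }
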