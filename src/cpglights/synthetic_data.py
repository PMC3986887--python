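"""Synthetic methylome/transcriptome generator with planted structure.

The generator emulates every input of the analysis on a synthetic
chromosome ``chrS1``: a CAGE-like TSS-cluster count table across samples
grouped into cell-type classes, an RRBS-like per-cytosine methylation
table, promoter sequences carrying planted motif occurrences, and the
feature tracks and TF-function labels the downstream stages consume.

Planted structure:

* a fraction of cytosines is *negatively* (or positively) correlated with
  its promoter's expression: the class-level methylation is a monotone
  function of the class expression rank spanning > 50 percentage points,
  plus truncated Gaussian noise clipped to [0, 100];
* null cytosines draw class values from a bimodal low/high mixture
  independent of expression;
* motif occurrences are drawn from each TF's position count matrix and
  placed without overlap inside promoters; a subset of the measured
  cytosines sits on a CpG column pair of an occurrence, and the
  probability that such an inside cytosine is planted-negative equals
  ``depletion_factor`` times the outside probability (optionally
  stratified by the column pair's core/medium/low class);
* per-class read coverage is drawn with stated fractions of low-coverage
  and missing classes so the downstream filters have work to do.

All randomness flows from ``config.seed`` through per-stage
``numpy.random.Generator`` instances, so identical configurations
reproduce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import profiles
from .errors import ConfigurationError, InsufficientDataError
from .motif_models import (
    ALPHABET,
    CpGColumnPair,
    MotifAlignment,
    PositionCountMatrix,
    find_cpg_positions,
)

CHROM = "chrS1"

# stage tags mixed into the seed so stages draw independent streams
_STAGE_EXPRESSION = 1
_STAGE_METHYLATION = 2
_STAGE_PROMOTERS = 3
_STAGE_ALIGNMENT = 4
_STAGE_TRACKS = 5


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stage])


# ---------------------------------------------------------------------------
# motif set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifSpec:
    """A TF's position count matrix plus its regulatory function label."""

    tf_id: str
    pcm: PositionCountMatrix
    function: str  # activator | repressor | both

    @property
    def cpg_pairs(self) -> list[CpGColumnPair]:
        return find_cpg_positions(self.pcm)


def _column(p: Sequence[float], n: float) -> np.ndarray:
    counts = np.asarray(p, dtype=float) * n
    return counts


def _pcm_from_columns(tf_id: str, columns: list[Sequence[float]], n: float) -> PositionCountMatrix:
    counts = np.column_stack([_column(c, n) for c in columns])
    return PositionCountMatrix(tf_id, counts, n)


def _strong(base: int) -> list[float]:
    p = [0.05, 0.05, 0.05, 0.05]
    p[base] = 0.85
    return p


def _core(base: int) -> list[float]:
    p = [0.9 / 27, 0.9 / 27, 0.9 / 27, 0.9 / 27]
    p = [0.1 / 3] * 4
    p[base] = 0.9
    return p


# medium/low CpG columns keep C (resp. G) maximal but with DIC between the
# reference thresholds (medium) or below the lower one (low)
_MEDIUM_C = [0.15, 0.45, 0.25, 0.15]
_MEDIUM_G = [0.15, 0.25, 0.45, 0.15]
_LOW_C = [0.24, 0.28, 0.24, 0.24]
_LOW_G = [0.24, 0.24, 0.28, 0.24]

_A, _C, _G, _T = range(4)


def default_motif_set(n: float = 400.0) -> list[MotifSpec]:
    """Five synthetic TF models with CpG-containing column pairs.

    TFA/TFB/TFE carry a high-information (core) CpG pair, TFC a medium
    one, and TFD both a core and a medium pair, so positional
    stratification has material in every stratum.
    """
    specs = [
        (
            "TFA",
            "activator",
            [_strong(_T), _strong(_G), _strong(_A), _core(_C), _core(_G), _strong(_T), _strong(_C), _strong(_A)],
        ),
        (
            "TFB",
            "repressor",
            [_strong(_A), _strong(_C), _strong(_T), _strong(_G), _core(_C), _core(_G), _strong(_A), _strong(_T), _strong(_G)],
        ),
        (
            "TFC",
            "activator",
            [_strong(_G), _strong(_A), _MEDIUM_C, _MEDIUM_G, _strong(_T), _strong(_C), _strong(_A)],
        ),
        (
            "TFD",
            "repressor",
            [_strong(_T), _strong(_A), _core(_C), _core(_G), _strong(_T), _strong(_G), _MEDIUM_C, _MEDIUM_G, _strong(_A), _strong(_C)],
        ),
        (
            "TFE",
            "both",
            [_strong(_C), _strong(_T), _strong(_G), _core(_C), _core(_G), _strong(_A), _strong(_G), _strong(_T)],
        ),
    ]
    return [MotifSpec(tf, _pcm_from_columns(tf, cols, n), fn) for tf, fn, cols in specs]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions of the synthetic experiment.

    Defaults mirror the real study's shape: 50 cell-type classes of which
    36 are normal, a planted negative (traffic-light) rate of 0.166 and a
    positive rate of 0.008 among background cytosines, amplitude > 50
    points for planted profiles, and a two-fold depletion of planted
    negatives on motif CpG positions.
    """

    n_classes: int = 50
    n_normal: int = 36
    n_tss: int = 200
    #: mean count of background (outside-TFBS) measured cytosines per promoter
    n_cpg_per_promoter: float = 10.0
    frac_negative: float = 0.166
    frac_positive: float = 0.008
    #: class-level methylation noise, percentage points (truncated Gaussian)
    noise_sd: float = 5.0
    #: additional per-sample replica jitter, percentage points
    replica_sd: float = 2.0
    depletion_factor: float = 0.5
    #: optional per-stratum depletion (keys core/medium/low/mixed);
    #: overrides depletion_factor when set
    depletion_by_stratum: dict | None = None
    motif_set: list[MotifSpec] = field(default_factory=default_motif_set)
    seed: int = 0

    # sampling design
    samples_per_class: int | None = None   # fixed; None draws 1..4 per class
    mean_coverage: float = 30.0
    low_coverage_mean: float = 5.0
    frac_low_coverage: float = 0.05
    frac_missing: float = 0.15

    # planted profile shape
    meth_low: float = 5.0
    meth_high: float = 95.0
    null_high_prob: float = 0.5
    null_low_range: tuple[float, float] = (5.0, 20.0)
    null_high_range: tuple[float, float] = (80.0, 95.0)

    # geometry
    cluster_length: int = 20
    promoter_gap: int = 100
    n_occurrences_per_tf: int = 1
    #: probability that a motif CpG column pair hosts a measured cytosine
    occupancy: float = 0.5
    peak_flank: int = 50
    background_gc: float = 0.45

    # expression model
    expr_log_mean: float = 3.0
    expr_log_sd: float = 1.0
    class_log_sd: float = 1.0
    housekeeping_fraction: float = 0.05
    housekeeping_log_mean: float = 5.0
    housekeeping_class_log_sd: float = 0.2
    libsize_range: tuple[float, float] = (0.5, 2.0)

    # synthetic CGI track
    cgi_prob_negative: float = 0.8
    cgi_prob_other: float = 0.5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.frac_negative + self.frac_positive > 1:
            raise ConfigurationError("frac_negative + frac_positive must be <= 1")
        if not 0 < self.depletion_factor <= 1:
            raise ConfigurationError("depletion_factor must be in (0, 1]")
        if self.depletion_by_stratum is not None:
            for v in self.depletion_by_stratum.values():
                if not 0 < v <= 1:
                    raise ConfigurationError("stratum depletion factors must be in (0, 1]")
        if self.n_normal > self.n_classes:
            raise ConfigurationError("n_normal must not exceed n_classes")
        if self.n_tss < 1:
            raise ConfigurationError("n_tss must be >= 1")
        if self.n_classes < 3:
            raise ConfigurationError("n_classes must be >= 3")
        if self.noise_sd < 0 or self.replica_sd < 0:
            raise ConfigurationError("noise levels must be non-negative")
        if not self.motif_set:
            raise ConfigurationError("motif_set must be non-empty")
        for spec in self.motif_set:
            if spec.pcm.length < 4:
                raise ConfigurationError(f"{spec.tf_id}: PCM length must be >= 4")
        if self.meth_high - self.meth_low <= 50:
            raise ConfigurationError("planted amplitude must exceed 50 points")

    @property
    def promoter_span(self) -> int:
        return self.cluster_length + profiles.PROMOTER_UPSTREAM + profiles.PROMOTER_DOWNSTREAM

    def promoter_start(self, i: int) -> int:
        return i * (self.promoter_span + self.promoter_gap)

    def cluster_id(self, i: int) -> str:
        return f"tss{i:05d}"


@dataclass
class SyntheticTruth:
    """Planted labels and geometry of one simulated experiment."""

    cytosines: pd.DataFrame   # cytosine_id, promoter, tf, occurrence, pair_position, category, inside, label [, chrom, pos]
    occurrences: pd.DataFrame | None = None
    config: SimulationConfig | None = None


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """CAGE-like raw count table, TSS cluster coordinates and sample map.

    Per-cluster class means are log-normal (a housekeeping subset has
    high mean and low class variance so RLE normalization always has
    reference clusters); per-sample counts are Poisson with sample
    library-size factors drawn from ``libsize_range``.
    """
    rng = _rng(config.seed, _STAGE_EXPRESSION)
    K = config.n_classes

    if config.samples_per_class is not None:
        sizes = np.full(K, config.samples_per_class)
    else:
        sizes = rng.integers(1, 5, size=K)
    class_ids = [f"class{k:02d}" for k in range(K)]
    samples, sample_class, normal = [], [], []
    for k, size in enumerate(sizes):
        for r in range(size):
            samples.append(f"s{len(samples):03d}")
            sample_class.append(class_ids[k])
            normal.append(k < config.n_normal)
    sample_map = pd.DataFrame(
        {"class_id": sample_class, "normal": normal}, index=pd.Index(samples, name="sample_id")
    )

    n = config.n_tss
    housekeeping = rng.random(n) < config.housekeeping_fraction
    base = np.where(
        housekeeping,
        rng.lognormal(config.housekeeping_log_mean, 0.2, size=n),
        rng.lognormal(config.expr_log_mean, config.expr_log_sd, size=n),
    )
    class_sd = np.where(housekeeping, config.housekeeping_class_log_sd, config.class_log_sd)
    class_factors = rng.lognormal(0.0, 1.0, size=(n, K)) ** (class_sd[:, None] / 1.0)
    rates = base[:, None] * class_factors

    libsizes = rng.uniform(*config.libsize_range, size=len(samples))
    counts = np.empty((n, len(samples)), dtype=np.int64)
    for s, sample in enumerate(samples):
        k = class_ids.index(sample_class[s])
        counts[:, s] = rng.poisson(rates[:, k] * libsizes[s])

    strand = np.where(np.arange(n) % 2 == 0, "+", "-")
    prom_start = np.array([config.promoter_start(i) for i in range(n)])
    start = np.where(
        strand == "+",
        prom_start + profiles.PROMOTER_UPSTREAM,
        prom_start + profiles.PROMOTER_DOWNSTREAM,
    )
    clusters = pd.DataFrame(
        {
            "chrom": CHROM,
            "start": start,
            "end": start + config.cluster_length,
            "strand": strand,
        },
        index=pd.Index([config.cluster_id(i) for i in range(n)], name="cluster_id"),
    )
    count_table = pd.DataFrame(counts, index=clusters.index, columns=samples)
    return clusters, count_table, sample_map


# ---------------------------------------------------------------------------
# site assignment and labels
# ---------------------------------------------------------------------------

def _stratum_factor(config: SimulationConfig, inside: bool, category: str) -> float:
    if not inside:
        return 1.0
    if config.depletion_by_stratum is not None:
        return config.depletion_by_stratum.get(category, 1.0)
    return config.depletion_factor


def assign_sites_and_labels(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign each measured cytosine a site (motif CpG slot or background)
    and a planted label with the site's depletion factor applied."""
    pair_cache = {spec.tf_id: spec.cpg_pairs for spec in config.motif_set}
    rows: list[tuple] = []
    for i in range(config.n_tss):
        for spec in config.motif_set:
            for occ in range(config.n_occurrences_per_tf):
                for pair in pair_cache[spec.tf_id]:
                    if rng.random() < config.occupancy:
                        rows.append((i, spec.tf_id, occ, pair.position, pair.category, True))
        n_out = rng.poisson(config.n_cpg_per_promoter)
        for _ in range(n_out):
            rows.append((i, "", -1, -1, "outside", False))
    df = pd.DataFrame(
        rows, columns=["promoter", "tf", "occurrence", "pair_position", "category", "inside"]
    )
    df.index = pd.Index([f"c{j:07d}" for j in range(len(df))], name="cytosine_id")

    u = rng.random(len(df))
    factors = np.array(
        [_stratum_factor(config, ins, cat) for ins, cat in zip(df["inside"], df["category"])]
    )
    p_neg = config.frac_negative * factors
    p_pos = config.frac_positive
    label = np.where(u < p_neg, "negative", np.where(u < p_neg + p_pos, "positive", "null"))
    return df.assign(label=label)


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def simulate_methylation(
    class_expression: pd.DataFrame,
    sample_map: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """RRBS-like per-sample methylation table plus the planted truth.

    ``class_expression`` is the class-level expression table whose rows
    correspond, in order, to the simulated promoters.  Planted profiles
    are monotone in the class expression rank; coverage and missingness
    are drawn per class and distributed over the class's samples.
    Positions are assigned later by :func:`simulate_promoters`.
    """
    if class_expression.shape[1] < 3:
        raise InsufficientDataError("need >= 3 classes")
    if len(class_expression) != config.n_tss:
        raise ConfigurationError("class_expression rows must match n_tss")
    rng = _rng(config.seed, _STAGE_METHYLATION)
    cytosines = assign_sites_and_labels(config, rng)

    K = class_expression.shape[1]
    expr = class_expression.to_numpy()
    ranks = np.apply_along_axis(rankdata, 1, expr)  # average ranks, 1..K
    span = config.meth_high - config.meth_low

    n_cyt = len(cytosines)
    values = np.empty((n_cyt, K))
    prom = cytosines["promoter"].to_numpy()
    labels = cytosines["label"].to_numpy()
    frac = (ranks - 1) / (K - 1)
    is_neg = labels == "negative"
    is_pos = labels == "positive"
    is_null = ~is_neg & ~is_pos
    values[is_neg] = config.meth_high - span * frac[prom[is_neg]]
    values[is_pos] = config.meth_low + span * frac[prom[is_pos]]
    n_null = int(is_null.sum())
    high = rng.random((n_null, K)) < config.null_high_prob
    lo = rng.uniform(*config.null_low_range, size=(n_null, K))
    hi = rng.uniform(*config.null_high_range, size=(n_null, K))
    values[is_null] = np.where(high, hi, lo)
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    values = np.clip(values, 0.0, 100.0)

    # per-class coverage regime: missing, low, or normal
    u = rng.random((n_cyt, K))
    missing = u < config.frac_missing
    low = (u >= config.frac_missing) & (u < config.frac_missing + config.frac_low_coverage)
    class_cov_mean = np.where(missing, 0.0, np.where(low, config.low_coverage_mean, config.mean_coverage))

    class_ids = list(class_expression.columns)
    samples_of = {
        cls: list(sample_map.index[sample_map["class_id"] == cls]) for cls in class_ids
    }
    frames = []
    for k, cls in enumerate(class_ids):
        members = samples_of[cls]
        if not members:
            continue
        per_sample_mean = class_cov_mean[:, k] / len(members)
        for sample in members:
            cov = rng.poisson(per_sample_mean)
            present = cov > 0
            if not present.any():
                continue
            vals = values[present, k]
            if config.replica_sd > 0:
                vals = np.clip(vals + rng.normal(0.0, config.replica_sd, size=vals.shape), 0.0, 100.0)
            frames.append(
                pd.DataFrame(
                    {
                        "cytosine_id": cytosines.index[present],
                        "sample": sample,
                        "coverage": cov[present],
                        "percent_meth": vals,
                    }
                )
            )
    meth = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["cytosine_id", "sample", "coverage", "percent_meth"]
    )
    return meth, SyntheticTruth(cytosines=cytosines, config=config)


# ---------------------------------------------------------------------------
# promoters, occurrences and coordinates
# ---------------------------------------------------------------------------

def _draw_occurrence(
    spec: MotifSpec, rng: np.random.Generator, forced: dict[int, int] | None = None
) -> str:
    """Column-independent draw from the PCM, with optional forced columns."""
    probs = spec.pcm.counts / spec.pcm.n
    letters = []
    for j in range(spec.pcm.length):
        if forced and j in forced:
            letters.append(ALPHABET[forced[j]])
        else:
            letters.append(ALPHABET[rng.choice(4, p=probs[:, j])])
    return "".join(letters)


def place_geometry(
    cytosines: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    with_sequences: bool = True,
) -> tuple[dict[str, str] | None, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Place occurrences and cytosines inside promoters; realize sequences.

    Returns (sequences, occurrences, cytosines-with-coordinates, peaks).
    With ``with_sequences=False`` only coordinates are produced, which is
    the fast path for counting-level replicate studies.
    """
    spec_of = {spec.tf_id: spec for spec in config.motif_set}
    span = config.promoter_span
    gc = config.background_gc
    comp = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    sequences: dict[str, str] | None = {} if with_sequences else None
    occ_rows, peak_rows = [], []
    positions = np.full(len(cytosines), -1, dtype=np.int64)
    cyt_by_prom = cytosines.groupby("promoter", sort=True)

    row_index = {cid: i for i, cid in enumerate(cytosines.index)}
    for i in range(config.n_tss):
        prom_start = config.promoter_start(i)
        name = config.cluster_id(i)
        occupied = np.zeros(span, dtype=bool)
        seq = rng.choice(4, size=span, p=comp).astype(np.int8) if with_sequences else None

        try:
            group = cyt_by_prom.get_group(i)
        except KeyError:
            group = cytosines.iloc[0:0]
        hosted: dict[tuple[str, int], list[tuple[str, int]]] = {}
        for row in group.itertuples():
            if row.inside:
                hosted.setdefault((row.tf, row.occurrence), []).append(
                    (row.Index, row.pair_position)
                )

        occ_start: dict[tuple[str, int], int] = {}
        for spec in config.motif_set:
            L = spec.pcm.length
            for occ in range(config.n_occurrences_per_tf):
                for _ in range(200):
                    s = int(rng.integers(0, span - L + 1))
                    if not occupied[s : s + L].any():
                        break
                else:
                    raise ConfigurationError("could not place motif occurrence; promoter too crowded")
                occupied[s : s + L] = True
                occ_start[(spec.tf_id, occ)] = s
                forced: dict[int, int] = {}
                for _cid, p in hosted.get((spec.tf_id, occ), []):
                    forced[p] = 1      # C of the hosting pair
                    forced[p + 1] = 2  # G
                if with_sequences:
                    word = _draw_occurrence(spec, rng, forced)
                    seq[s : s + L] = [ALPHABET.index(b) for b in word]
                occ_rows.append((CHROM, prom_start + s, prom_start + s + L, spec.tf_id, occ, name))
                peak_rows.append(
                    (
                        CHROM,
                        prom_start + max(0, s - config.peak_flank),
                        prom_start + min(span, s + L + config.peak_flank),
                        spec.tf_id,
                    )
                )

        for row in group.itertuples():
            cid = row.Index
            if row.inside:
                s = occ_start[(row.tf, row.occurrence)]
                positions[row_index[cid]] = prom_start + s + row.pair_position
            else:
                for _ in range(500):
                    p = int(rng.integers(0, span - 1))
                    if not occupied[p : p + 2].any():
                        break
                else:
                    raise ConfigurationError("no free position for background cytosine")
                occupied[p : p + 2] = True
                if with_sequences:
                    seq[p], seq[p + 1] = 1, 2  # plant the CpG dyad
                positions[row_index[cid]] = prom_start + p

        if with_sequences:
            sequences[name] = "".join(ALPHABET[c] for c in seq)

    placed = cytosines.assign(chrom=CHROM, pos=positions)
    occurrences = pd.DataFrame(
        occ_rows, columns=["chrom", "start", "end", "tf", "occurrence", "promoter"]
    )
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "tf"])
    return sequences, occurrences, placed, peaks


def simulate_promoters(
    truth: SyntheticTruth, config: SimulationConfig
) -> tuple[dict[str, str], SyntheticTruth]:
    """Realize promoter sequences, plant occurrences, assign coordinates.

    Every planted occurrence lies within its promoter; a hosting CpG
    column pair is forced to C·G (the conditional draw given the pair is
    occupied), and background cytosines are planted CpG dyads outside all
    occurrences.
    """
    rng = _rng(config.seed, _STAGE_PROMOTERS)
    sequences, occurrences, placed, peaks = place_geometry(truth.cytosines, config, rng, True)
    for spec in config.motif_set:
        if spec.pcm.length > config.promoter_span:
            raise ConfigurationError(f"{spec.tf_id}: motif longer than promoter")
    new_truth = SyntheticTruth(cytosines=placed, occurrences=occurrences, config=config)
    new_truth.peaks = peaks  # type: ignore[attr-defined]
    return sequences, new_truth


def simulate_truth_only(config: SimulationConfig) -> SyntheticTruth:
    """Labels plus geometry without sequences or methylation values.

    Fast path for replicate studies that operate at the counting level.
    """
    rng = _rng(config.seed, _STAGE_METHYLATION)
    cytosines = assign_sites_and_labels(config, rng)
    rng2 = _rng(config.seed, _STAGE_PROMOTERS)
    _, occurrences, placed, peaks = place_geometry(cytosines, config, rng2, False)
    truth = SyntheticTruth(cytosines=placed, occurrences=occurrences, config=config)
    truth.peaks = peaks  # type: ignore[attr-defined]
    return truth


def simulate_alignment(
    pcm: PositionCountMatrix, n_seqs: int, seed: int | np.random.Generator
) -> MotifAlignment:
    """Sample ``n_seqs`` sequences column-independently from PCM frequencies."""
    if n_seqs < 1:
        raise ConfigurationError("n_seqs must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, _STAGE_ALIGNMENT)
    probs = pcm.counts / pcm.n
    draws = np.stack(
        [rng.choice(4, size=n_seqs, p=probs[:, j]) for j in range(pcm.length)], axis=1
    )
    seqs = tuple("".join(ALPHABET[c] for c in row) for row in draws)
    return MotifAlignment(pcm.tf_id, seqs)


def simulate_cgi_track(truth: SyntheticTruth, config: SimulationConfig) -> pd.DataFrame:
    """Synthetic CpG-island-like track covering planted negatives with
    higher probability than other cytosines."""
    rng = _rng(config.seed, _STAGE_TRACKS)
    cyt = truth.cytosines
    prob = np.where(cyt["label"] == "negative", config.cgi_prob_negative, config.cgi_prob_other)
    covered = rng.random(len(cyt)) < prob
    df = pd.DataFrame(
        {
            "chrom": cyt["chrom"][covered],
            "start": cyt["pos"][covered],
            "end": cyt["pos"][covered] + 2,
        }
    ).sort_values(["chrom", "start"], ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# orchestration and writers
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig, outdir: str | Path | None = None) -> dict:
    """Run the full generator and optionally write all input files.

    Expression is normalized (RLE) and class-averaged before driving the
    planted methylation profiles, so the monotone relation is planted
    against exactly the expression table the pipeline will correlate
    against.
    """
    clusters, counts, sample_map = simulate_expression(config)
    normalized, _ = profiles.rle_normalize(counts)
    class_expr = profiles.average_by_class(normalized, sample_map)
    meth, truth = simulate_methylation(class_expr, sample_map, config)
    sequences, truth = simulate_promoters(truth, config)
    cgi = simulate_cgi_track(truth, config)
    functions = pd.DataFrame(
        {"tf": [s.tf_id for s in config.motif_set], "function": [s.function for s in config.motif_set]}
    )

    pos_of = truth.cytosines["pos"]
    meth_out = meth.assign(
        chrom=CHROM, pos0=meth["cytosine_id"].map(pos_of), strand="+"
    )[["chrom", "pos0", "strand", "sample", "coverage", "percent_meth"]]

    result = {
        "clusters": clusters,
        "counts": counts,
        "sample_map": sample_map,
        "class_expression": class_expr,
        "methylation": meth_out,
        "methylation_by_id": meth,
        "sequences": sequences,
        "truth": truth,
        "cgi": cgi,
        "functions": functions,
    }
    if outdir is not None:
        write_inputs(result, config, Path(outdir))
    return result


def write_fasta(sequences: Mapping[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_inputs(result: dict, config: SimulationConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result["sample_map"].reset_index().assign(
        normal=lambda d: d["normal"].astype(int)
    ).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    expr = result["clusters"].join(result["counts"]).reset_index()
    expr.to_csv(outdir / "expression_counts.tsv", sep="\t", index=False)
    result["methylation"].to_csv(
        outdir / "methylation.tsv", sep="\t", index=False, float_format="%.4f"
    )
    write_fasta(result["sequences"], outdir / "promoters.fa")
    promoters = profiles.define_promoters(result["clusters"])
    promoters.assign(score=0)[["chrom", "start", "end", "cluster_id", "score", "strand"]].to_csv(
        outdir / "promoters.bed", sep="\t", index=False, header=False
    )
    truth = result["truth"]
    truth.occurrences.assign(score=0, strand="+")[
        ["chrom", "start", "end", "tf", "score", "strand"]
    ].to_csv(outdir / "occurrences.bed", sep="\t", index=False, header=False)
    truth.peaks.to_csv(outdir / "peaks.bed", sep="\t", index=False, header=False)
    truth.cytosines.reset_index()[
        ["cytosine_id", "chrom", "pos", "label", "tf", "category", "inside"]
    ].to_csv(outdir / "truth.tsv", sep="\t", index=False)
    result["functions"].to_csv(outdir / "tf_functions.tsv", sep="\t", index=False)
    tracks = outdir / "tracks"
    tracks.mkdir(exist_ok=True)
    result["cgi"].to_csv(tracks / "cgi.bed", sep="\t", index=False, header=False)
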