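"""Motif models for TFBS prediction.

This module builds the three model layers used by the binding-site
analysis:

* :class:`PositionCountMatrix` (PCM) — raw nucleotide counts per column of
  a gap-free binding-site alignment.
* :class:`PWM` — additive log-odds position weight matrix with a score
  threshold calibrated to an exact tail probability of the score of a
  random background word (dynamic programming over the discretized score
  distribution; full enumeration is used as an independent oracle in the
  test suite).
* :class:`RDM` — remote dependency model: a weight for every ordered
  nucleotide pair ``a`` at every position pair ``i < j``, built from the
  alignment dinucleotide frequencies ``f[a, i, j]`` and normalized by the
  sum over position pairs of the per-pair maximal frequency, so that the
  per-pair maxima sum to exactly one.  A word is scored by summing the
  weights of all of its ordered position pairs; the consensus of a
  degenerate alignment therefore scores exactly 1.

The module also computes the discrete information content (DIC) of motif
columns from raw counts,

    ``DIC = (1/N) * (sum_a ln(x_a!) - ln(N!))``,

which is 0 for a single-nucleotide column and decreases towards the
uniform column.  Two reference thresholds classify CpG-containing column
pairs: ``Th`` is the DIC of a column with three equally frequent
nucleotides, ``th`` the DIC of a column with frequencies (f, f, 2f, 2f).
A column pair with C then G as (tie-permissive) major nucleotides is
"core" when both DICs exceed ``Th``, "medium" when both lie in
``[th, Th]``, "low" when both fall below ``th``, and "mixed" otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .errors import ConfigurationError, DegenerateModelError, InputError

ALPHABET = "ACGT"
A, C, G, T = range(4)
#: ordered dinucleotides are indexed as 4 * first + second
N_DINUCLEOTIDES = 16

UNIFORM_BACKGROUND = np.full(4, 0.25)
#: target tail probability for threshold calibration: 5 of 10,000 random words
DEFAULT_TARGET_P = 0.0005
#: minimal number of sequences retained after PWM filtering of an alignment
MIN_ALIGNMENT_SEQS = 15
#: score discretization step of the dynamic-programming tail computation
SCORE_RESOLUTION = 1e-4
#: longest motif for which the RDM null distribution is fully enumerated
MAX_ENUMERATION_LENGTH = 10
#: Monte-Carlo sample size for longer RDMs
MONTE_CARLO_WORDS = 2_000_000


def encode_word(word: str) -> np.ndarray:
    """Map an ACGT string to integer codes; any other character is an error."""
    codes = np.frombuffer(word.upper().encode("ascii"), dtype=np.uint8)
    out = _CODE_TABLE[codes]
    if (out > 3).any():
        raise InputError(f"non-ACGT character in word {word!r}")
    return out.astype(np.int64)


_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _CODE_TABLE[ord(_b)] = _i
    _CODE_TABLE[ord(_b.lower())] = _i


# ---------------------------------------------------------------------------
# alignments and count matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifAlignment:
    """Equal-length binding-site sequences for one TF."""

    tf_id: str
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ConfigurationError(f"{self.tf_id}: empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ConfigurationError(f"{self.tf_id}: unequal sequence lengths")
        for s in self.sequences:
            encode_word(s)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class PositionCountMatrix:
    """Nucleotide counts ``counts[a, j]`` with column sums equal to ``n``."""

    tf_id: str
    counts: np.ndarray  # shape (4, L)
    n: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ConfigurationError("PCM must have shape (4, L)")
        if (counts < 0).any():
            raise InputError("negative counts in PCM")
        if not np.allclose(counts.sum(axis=0), self.n):
            raise ConfigurationError("PCM column sums must equal n")

    @property
    def length(self) -> int:
        return self.counts.shape[1]


def build_pcm(alignment: MotifAlignment) -> PositionCountMatrix:
    """Count nucleotides per column of the alignment."""
    L = alignment.length
    counts = np.zeros((4, L))
    for seq in alignment.sequences:
        codes = encode_word(seq)
        for j in range(L):
            counts[codes[j], j] += 1
    return PositionCountMatrix(alignment.tf_id, counts, alignment.n)


def simulate_consensus(pcm: PositionCountMatrix) -> str:
    """Majority word of a PCM (ties broken by alphabet order)."""
    return "".join(ALPHABET[a] for a in pcm.counts.argmax(axis=0))


# ---------------------------------------------------------------------------
# PWM
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """Log-odds matrix ``matrix[a, j]`` with an optional calibrated threshold.

    The log-odds use a background-proportional pseudocount:
    ``w[a,j] = ln((x[a,j] + pc * q_a) / ((N + pc) * q_a))``.
    """

    tf_id: str
    matrix: np.ndarray  # shape (4, L)
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    threshold: float | None = None
    threshold_pvalue: float | None = None

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def score(self, word: str) -> float:
        codes = encode_word(word)
        if codes.size != self.length:
            raise InputError(f"word length {codes.size} != motif length {self.length}")
        return float(self.matrix[codes, np.arange(self.length)].sum())

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=0).sum())


def build_pwm(
    pcm: PositionCountMatrix,
    background: np.ndarray | Sequence[float] = UNIFORM_BACKGROUND,
    pseudocount: float | None = None,
) -> PWM:
    """Log-odds PWM from a PCM.

    The default pseudocount is ``ln(N)``, which keeps rare-letter scores
    stable as the alignment grows.
    """
    q = np.asarray(background, dtype=float)
    if q.shape != (4,) or not np.isclose(q.sum(), 1.0) or (q <= 0).any():
        raise ConfigurationError("background must be 4 positive probabilities summing to 1")
    if pcm.length == 0:
        raise ConfigurationError("zero-length PCM")
    pc = float(np.log(max(pcm.n, 2.0))) if pseudocount is None else float(pseudocount)
    w = np.log((pcm.counts + pc * q[:, None]) / ((pcm.n + pc) * q[:, None]))
    return PWM(pcm.tf_id, w, q)


def filter_alignment(
    alignment: MotifAlignment,
    pwm: PWM,
    threshold: float | None = None,
    min_n: int = MIN_ALIGNMENT_SEQS,
) -> MotifAlignment | None:
    """Drop alignment sequences scoring below the PWM threshold.

    Returns ``None`` (discard) when fewer than ``min_n`` sequences remain.
    """
    thr = pwm.threshold if threshold is None else threshold
    if thr is None:
        raise ConfigurationError("PWM has no calibrated threshold")
    kept = tuple(s for s in alignment.sequences if pwm.score(s) >= thr)
    if len(kept) < min_n:
        return None
    return MotifAlignment(alignment.tf_id, kept)


# ---------------------------------------------------------------------------
# RDM
# ---------------------------------------------------------------------------

@dataclass
class RDM:
    """Remote dependency model.

    ``weights[d, k]`` is the normalized weight of ordered dinucleotide
    ``d = 4 * first + second`` at the k-th position pair ``pairs[k]``;
    ``frequencies`` holds the raw per-pair dinucleotide frequencies.
    """

    tf_id: str
    weights: np.ndarray       # shape (16, n_pairs)
    frequencies: np.ndarray   # shape (16, n_pairs)
    pairs: tuple[tuple[int, int], ...]
    length: int
    threshold: float | None = None
    threshold_pvalue: float | None = None

    def score(self, word: str) -> float:
        codes = encode_word(word)
        if codes.size != self.length:
            raise InputError(f"word length {codes.size} != motif length {self.length}")
        return score_word_rdm(word, self)


def position_pairs(length: int) -> tuple[tuple[int, int], ...]:
    """All ordered position pairs ``i < j`` of a motif of this length."""
    return tuple((i, j) for i in range(length - 1) for j in range(i + 1, length))


def build_rdm(alignment: MotifAlignment) -> RDM:
    """Build the remote dependency model from an alignment.

    ``f[a, i, j]`` is the fraction of sequences carrying ordered
    dinucleotide ``a`` at positions ``(i, j)``; the weights divide the
    frequencies by the sum over pairs of the per-pair maximum, so
    ``sum_{i<j} max_a weights[a, i, j] == 1`` exactly.
    """
    L = alignment.length
    pairs = position_pairs(L)
    codes = np.stack([encode_word(s) for s in alignment.sequences])  # (N, L)
    freqs = np.zeros((N_DINUCLEOTIDES, len(pairs)))
    for k, (i, j) in enumerate(pairs):
        dinuc = 4 * codes[:, i] + codes[:, j]
        freqs[:, k] = np.bincount(dinuc, minlength=N_DINUCLEOTIDES) / alignment.n
    denom = freqs.max(axis=0).sum()
    return RDM(alignment.tf_id, freqs / denom, freqs, pairs, L)


def score_word_rdm(word: str, rdm: RDM) -> float:
    """Sum of the pairwise weights of the word's ordered dinucleotides."""
    codes = encode_word(word)
    if codes.size != rdm.length:
        raise InputError(f"word length {codes.size} != motif length {rdm.length}")
    idx = np.array([4 * codes[i] + codes[j] for (i, j) in rdm.pairs])
    return float(rdm.weights[idx, np.arange(len(rdm.pairs))].sum())


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------

def pwm_score_distribution(
    pwm: PWM, resolution: float = SCORE_RESOLUTION
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the PWM score of a random background word.

    Column scores are rounded to a grid of step ``resolution`` and the
    column distributions convolved, so the result is exact on the grid
    (maximal rounding error ``L * resolution / 2`` on the score axis).
    Returns ``(scores, probs)`` with scores ascending.
    """
    iw = np.rint(pwm.matrix / resolution).astype(np.int64)
    probs = np.array([1.0])
    offset = 0
    for j in range(pwm.length):
        col = iw[:, j]
        lo, hi = int(col.min()), int(col.max())
        new = np.zeros(probs.size + hi - lo)
        for a in range(4):
            s = int(col[a]) - lo
            new[s : s + probs.size] += pwm.background[a] * probs
        probs = new
        offset += lo
    support = np.nonzero(probs > 0.0)[0]
    return (offset + support) * resolution, probs[support]


def threshold_from_distribution(
    scores: np.ndarray, probs: np.ndarray, target_p: float
) -> tuple[float, float]:
    """Smallest attainable score ``s`` with ``P(score >= s) <= target_p``.

    Returns ``(threshold, achieved_tail_probability)``; raises
    :class:`DegenerateModelError` when even the maximal score is attained
    with probability above the target (e.g. all words tie).
    """
    order = np.argsort(scores)[::-1]
    tail = np.cumsum(probs[order])
    ok = tail <= target_p * (1 + 1e-12)
    if not ok[0]:
        raise DegenerateModelError(
            f"no score attains tail probability <= {target_p}"
        )
    k = int(ok.sum()) - 1  # ok is a True-prefix because tail is monotone
    return float(scores[order[k]]), float(tail[k])


def calibrate_pwm_threshold(
    pwm: PWM,
    target_p: float = DEFAULT_TARGET_P,
    resolution: float = SCORE_RESOLUTION,
) -> tuple[float, float]:
    """Calibrate and store the PWM threshold at the target tail probability."""
    scores, probs = pwm_score_distribution(pwm, resolution)
    thr, achieved = threshold_from_distribution(scores, probs, target_p)
    pwm.threshold, pwm.threshold_pvalue = thr, achieved
    return thr, achieved


def enumerate_rdm_scores(
    rdm: RDM, background: np.ndarray = UNIFORM_BACKGROUND
) -> tuple[np.ndarray, np.ndarray]:
    """Scores and probabilities of all ``4**L`` words (vectorized)."""
    L = rdm.length
    n = 4**L
    codes = np.arange(n, dtype=np.int64)
    digits = np.empty((L, n), dtype=np.int16)
    for k in range(L):
        digits[k] = (codes // 4 ** (L - 1 - k)) % 4
    scores = np.zeros(n)
    for k, (i, j) in enumerate(rdm.pairs):
        scores += rdm.weights[4 * digits[i] + digits[j], k]
    wprob = np.ones(n)
    q = np.asarray(background, dtype=float)
    for k in range(L):
        wprob *= q[digits[k]]
    uniq, inverse = np.unique(scores, return_inverse=True)
    return uniq, np.bincount(inverse, weights=wprob)


def calibrate_rdm_threshold(
    rdm: RDM,
    target_p: float = DEFAULT_TARGET_P,
    background: np.ndarray = UNIFORM_BACKGROUND,
    rng: np.random.Generator | None = None,
    max_enumeration_length: int = MAX_ENUMERATION_LENGTH,
    n_monte_carlo: int = MONTE_CARLO_WORDS,
) -> tuple[float, float, float]:
    """Calibrate the RDM threshold at the target tail probability.

    Motifs up to ``max_enumeration_length`` are enumerated exactly; longer
    motifs use a Monte-Carlo sample of ``n_monte_carlo`` background words,
    in which case the returned standard error of the achieved tail is
    positive (it is 0.0 for the exact path).
    """
    if rdm.length <= max_enumeration_length:
        scores, probs = enumerate_rdm_scores(rdm, background)
        thr, achieved = threshold_from_distribution(scores, probs, target_p)
        stderr = 0.0
    else:
        rng = np.random.default_rng(0) if rng is None else rng
        q = np.asarray(background, dtype=float)
        digits = rng.choice(4, size=(rdm.length, n_monte_carlo), p=q).astype(np.int16)
        scores = np.zeros(n_monte_carlo)
        for k, (i, j) in enumerate(rdm.pairs):
            scores += rdm.weights[4 * digits[i] + digits[j], k]
        uniq, inverse = np.unique(scores, return_inverse=True)
        probs = np.bincount(inverse) / n_monte_carlo
        thr, achieved = threshold_from_distribution(uniq, probs, target_p)
        stderr = float(np.sqrt(achieved * (1 - achieved) / n_monte_carlo))
    rdm.threshold, rdm.threshold_pvalue = thr, achieved
    return thr, achieved, stderr


# ---------------------------------------------------------------------------
# discrete information content
# ---------------------------------------------------------------------------

def dic(counts: Sequence[float] | np.ndarray) -> float:
    """Discrete information content of one motif column (natural log).

    ``DIC = (1/N) * (sum_a ln(x_a!) - ln(N!))`` with real-valued counts
    handled through the log-gamma function.  Maximal (0) for a
    single-nucleotide column, most negative for the uniform column.
    """
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise InputError("negative counts")
    n = x.sum()
    if n <= 0:
        raise InputError("empty column")
    return float((gammaln(x + 1).sum() - gammaln(n + 1)) / n)


def dic_thresholds(n: float) -> tuple[float, float]:
    """Reference DIC thresholds ``(Th, th)`` for column classification.

    ``Th`` is the DIC of a column with three equally frequent nucleotides
    (N/3, N/3, N/3, 0); ``th`` that of a column with two nucleotides at
    frequency f and two at 2f, i.e. (N/6, N/6, N/3, N/3).  Fractional
    counts go through log-gamma.  ``Th > th`` for every ``n >= 3``.
    """
    if n < 3:
        raise ConfigurationError("dic_thresholds requires n >= 3")
    th_high = dic([n / 3, n / 3, n / 3, 0.0])
    th_low = dic([n / 6, n / 6, n / 3, n / 3])
    assert th_high > th_low
    return th_high, th_low


@dataclass(frozen=True)
class CpGColumnPair:
    """A C·G column pair ``(position, position + 1)`` of a motif."""

    tf_id: str
    position: int  # column index of the C; the G sits at position + 1
    dic_c: float
    dic_g: float
    category: str  # core | medium | low | mixed


def classify_pair(dic_c: float, dic_g: float, th_high: float, th_low: float) -> str:
    if dic_c > th_high and dic_g > th_high:
        return "core"
    if th_low <= dic_c <= th_high and th_low <= dic_g <= th_high:
        return "medium"
    if dic_c < th_low and dic_g < th_low:
        return "low"
    return "mixed"


def find_cpg_positions(pcm: PositionCountMatrix) -> list[CpGColumnPair]:
    """CpG column pairs of a PCM with their DIC-based category.

    A pair is emitted when C attains the column maximum at ``j`` and G at
    ``j + 1`` (ties count as major).
    """
    th_high, th_low = dic_thresholds(pcm.n)
    pairs: list[CpGColumnPair] = []
    counts = pcm.counts
    for j in range(pcm.length - 1):
        if counts[C, j] < counts[:, j].max() or counts[G, j + 1] < counts[:, j + 1].max():
            continue
        dic_c = dic(counts[:, j])
        dic_g = dic(counts[:, j + 1])
        pairs.append(
            CpGColumnPair(pcm.tf_id, j, dic_c, dic_g, classify_pair(dic_c, dic_g, th_high, th_low))
        )
    return pairs


# ---------------------------------------------------------------------------
# model bundle and plain-text archive
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """Everything the scanner and the positional analysis need for one TF."""

    tf_id: str
    pcm: PositionCountMatrix
    pwm: PWM
    rdm: RDM
    cpg_pairs: list[CpGColumnPair]
    n_filtered: int


def build_motif_models(
    alignment: MotifAlignment,
    background: np.ndarray = UNIFORM_BACKGROUND,
    target_p: float = DEFAULT_TARGET_P,
    min_n: int = MIN_ALIGNMENT_SEQS,
    rng: np.random.Generator | None = None,
) -> ModelBundle | None:
    """Full model-building path for one alignment.

    Builds and calibrates the PWM, filters the alignment at the PWM
    threshold (discarding the TF when fewer than ``min_n`` sequences
    remain), then builds and calibrates the RDM from the filtered
    alignment and classifies the CpG column pairs of the filtered PCM.
    """
    pcm0 = build_pcm(alignment)
    pwm = build_pwm(pcm0, background)
    calibrate_pwm_threshold(pwm, target_p)
    filtered = filter_alignment(alignment, pwm, min_n=min_n)
    if filtered is None:
        return None
    pcm = build_pcm(filtered)
    rdm = build_rdm(filtered)
    calibrate_rdm_threshold(rdm, target_p, background, rng=rng)
    return ModelBundle(alignment.tf_id, pcm, pwm, rdm, find_cpg_positions(pcm), filtered.n)


def read_alignment(path: str | Path, tf_id: str | None = None) -> MotifAlignment:
    """One sequence per line; an optional ``>name`` header names the TF."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        tf_id = tf_id or lines[0][1:].strip()
        lines = lines[1:]
    return MotifAlignment(tf_id or Path(path).stem, tuple(lines))


def read_pcm(path: str | Path) -> PositionCountMatrix:
    """PCM file: ``>TF`` header then one row of 4 counts per column."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise InputError(f"{path}: missing >TF header")
    tf_id = lines[0][1:].strip()
    rows = np.array([[float(v) for v in ln.split()] for ln in lines[1:]])
    if rows.ndim != 2 or rows.shape[1] != 4:
        raise InputError(f"{path}: expected L rows of 4 counts")
    return PositionCountMatrix(tf_id, rows.T, rows.sum(axis=1)[0])


def write_model_archive(bundle: ModelBundle, path: str | Path) -> None:
    """Plain-text archive of PCM, PWM and RDM with thresholds and DIC."""
    lines = [f">{bundle.tf_id} length={bundle.pcm.length} n={bundle.pcm.n:g}"]
    lines.append("# PCM (columns A C G T)")
    for j in range(bundle.pcm.length):
        lines.append("\t".join(f"{v:g}" for v in bundle.pcm.counts[:, j]))
    lines.append(
        f"# PWM threshold={bundle.pwm.threshold:.6f} pvalue={bundle.pwm.threshold_pvalue:.3e}"
    )
    for j in range(bundle.pwm.length):
        lines.append("\t".join(f"{v:.6f}" for v in bundle.pwm.matrix[:, j]))
    lines.append(
        f"# RDM threshold={bundle.rdm.threshold:.6f} pvalue={bundle.rdm.threshold_pvalue:.3e}"
    )
    for k, (i, j) in enumerate(bundle.rdm.pairs):
        lines.append(
            f"{i}\t{j}\t" + "\t".join(f"{v:.6f}" for v in bundle.rdm.weights[:, k])
        )
    lines.append("# CpG column pairs: position dic_c dic_g category")
    for pair in bundle.cpg_pairs:
        lines.append(f"{pair.position}\t{pair.dic_c:.6f}\t{pair.dic_g:.6f}\t{pair.category}")
    Path(path).write_text("\n".join(lines) + "\n")
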