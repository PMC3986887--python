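"""Promoter scanning with calibrated PWM and RDM models.

Every length-L window of every promoter is scored on both strands;
windows reaching the model's calibrated threshold become hits reported in
forward genomic coordinates.  Windows containing a non-ACGT base are
skipped.  Hits can optionally be restricted to ChIP-seq-style peak
intervals (full containment).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

from .motif_models import ALPHABET, PWM, RDM, MotifAlignment, _CODE_TABLE

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

HIT_COLUMNS = ["tf", "kind", "chrom", "start", "end", "strand", "score", "promoter"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Promoter FASTA -> {record id: upper-case sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def encode_sequence(seq: str) -> np.ndarray:
    """Integer codes; non-ACGT characters map to 4."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE_TABLE[raw]
    return np.where(codes > 3, 4, codes).astype(np.int8)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _windows(codes: np.ndarray, length: int) -> tuple[np.ndarray, np.ndarray]:
    win = np.lib.stride_tricks.sliding_window_view(codes, length)
    valid = (win < 4).all(axis=1)
    return np.where(win < 4, win, 0), valid


def pwm_window_scores(codes: np.ndarray, pwm: PWM) -> np.ndarray:
    """Score of every window; -inf where the window has a non-ACGT base."""
    if codes.size < pwm.length:
        return np.empty(0)
    win, valid = _windows(codes, pwm.length)
    scores = pwm.matrix[win, np.arange(pwm.length)].sum(axis=1)
    scores[~valid] = -np.inf
    return scores


def rdm_window_scores(codes: np.ndarray, rdm: RDM) -> np.ndarray:
    if codes.size < rdm.length:
        return np.empty(0)
    win, valid = _windows(codes, rdm.length)
    scores = np.zeros(win.shape[0])
    for k, (i, j) in enumerate(rdm.pairs):
        scores += rdm.weights[4 * win[:, i].astype(np.int16) + win[:, j], k]
    scores[~valid] = -np.inf
    return scores


def _model_scores(codes: np.ndarray, model: PWM | RDM) -> np.ndarray:
    if isinstance(model, PWM):
        return pwm_window_scores(codes, model)
    return rdm_window_scores(codes, model)


def scan(
    promoters: pd.DataFrame,
    sequences: Mapping[str, str],
    models: Iterable[PWM | RDM],
    thresholds: Mapping[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Scan promoter sequences with calibrated models on both strands.

    ``promoters`` needs chrom/start columns indexed by promoter name;
    ``sequences`` maps promoter names to their forward-strand sequence.
    Reverse-strand hits are scored on the reverse complement and reported
    in forward coordinates.  ``thresholds`` overrides the models'
    calibrated thresholds (keyed by (tf, kind)).
    """
    models = list(models)
    rows: list[tuple] = []
    for name, prom in promoters.iterrows():
        seq = sequences[name]
        fwd = encode_sequence(seq)
        rev = encode_sequence(reverse_complement(seq))
        for model in models:
            kind = "pwm" if isinstance(model, PWM) else "rdm"
            thr = model.threshold
            if thresholds is not None:
                thr = thresholds.get((model.tf_id, kind), thr)
            if thr is None:
                raise ValueError(f"{model.tf_id} ({kind}): no threshold")
            L = model.length
            for strand, codes in (("+", fwd), ("-", rev)):
                scores = _model_scores(codes, model)
                for w in np.nonzero(scores >= thr)[0]:
                    if strand == "+":
                        start = int(prom["start"]) + int(w)
                    else:
                        start = int(prom["start"]) + len(seq) - int(w) - L
                    rows.append(
                        (
                            model.tf_id,
                            kind,
                            prom["chrom"],
                            start,
                            start + L,
                            strand,
                            float(scores[w]),
                            name,
                        )
                    )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def restrict_to_peaks(hits: pd.DataFrame, peaks: pd.DataFrame) -> pd.DataFrame:
    """Keep hits fully contained in at least one peak interval.

    When ``peaks`` carries a ``tf`` column the containment is checked
    against that TF's peaks only (per-factor ChIP-seq restriction).
    """
    if hits.empty or peaks.empty:
        return hits.iloc[0:0]
    per_tf = "tf" in peaks.columns
    trees: dict[tuple, IntervalTree] = {}
    for row in peaks.itertuples(index=False):
        key = (row.tf, row.chrom) if per_tf else (row.chrom,)
        trees.setdefault(key, IntervalTree()).addi(int(row.start), int(row.end))
    keep = []
    for idx, row in hits.iterrows():
        key = (row["tf"], row["chrom"]) if per_tf else (row["chrom"],)
        tree = trees.get(key)
        if tree is None:
            continue
        if any(iv.begin <= row["start"] and iv.end >= row["end"] for iv in tree.overlap(row["start"], row["end"])):
            keep.append(idx)
    return hits.loc[keep]


def hit_sequences(
    hits: pd.DataFrame, promoters: pd.DataFrame, sequences: Mapping[str, str]
) -> list[str]:
    """Forward-strand sequence under each hit."""
    out = []
    for row in hits.itertuples(index=False):
        offset = int(promoters.loc[row.promoter, "start"])
        out.append(sequences[row.promoter][row.start - offset : row.end - offset])
    return out


def gc_content(seqs: Iterable[str]) -> float:
    total = gc = 0
    for s in seqs:
        s = s.upper()
        total += len(s)
        gc += s.count("G") + s.count("C")
    if total == 0:
        raise ValueError("no sequence")
    return gc / total


def compare_gc(
    hits: pd.DataFrame,
    promoters: pd.DataFrame,
    sequences: Mapping[str, str],
    alignment: MotifAlignment,
) -> tuple[float, float, float]:
    """Mean G+C of hit sequences vs the alignment, and their difference."""
    gc_hits = gc_content(hit_sequences(hits, promoters, sequences))
    gc_align = gc_content(alignment.sequences)
    return gc_hits, gc_align, gc_hits - gc_align
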