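"""Co-localization of CpG classes with genomic feature tracks.

Produces the fraction matrix "class of CpG x feature track" (CpG
islands, promoters, gene bodies, repeats, conserved elements, SNPs,
DNase clusters): the cell is the fraction of that class's CpGs contained
in at least one interval of the track.  A CpG position is treated as the
1-bp interval [p, p+1).  Promoter and gene-body tracks can be derived
from stranded gene models (promoter = [TSS-1500, TSS+500), gene body =
[TSS+500, gene end), strand-adjusted).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .profiles import PROMOTER_DOWNSTREAM, PROMOTER_UPSTREAM


def read_bed(path: str | Path) -> pd.DataFrame:
    """First columns of a BED file (chrom, start, end [, name, score, strand])."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : min(6, df.shape[1])]
    df.columns = names[: df.shape[1]]
    return df


def _track_trees(track: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in track.itertuples(index=False):
        if row.end > row.start:
            trees.setdefault(row.chrom, IntervalTree()).addi(int(row.start), int(row.end))
    return trees


def colocalize(
    cpg_sets: Mapping[str, pd.DataFrame], tracks: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Fraction matrix of CpG classes (rows) against feature tracks (columns).

    ``cpg_sets`` maps a class name to a frame with chrom/pos columns.
    Fractions across tracks need not sum to 1 (tracks overlap); an empty
    class yields missing cells.
    """
    trees_by_track = {name: _track_trees(track) for name, track in tracks.items()}
    out = {}
    for cls, cpgs in cpg_sets.items():
        row = {}
        for name, trees in trees_by_track.items():
            if len(cpgs) == 0:
                row[name] = np.nan
                continue
            inside = 0
            for chrom, pos in zip(cpgs["chrom"], cpgs["pos"]):
                tree = trees.get(chrom)
                if tree is not None and tree.overlaps_point(int(pos)):
                    inside += 1
            row[name] = inside / len(cpgs)
        out[cls] = row
    return pd.DataFrame(out).T


def derive_gene_tracks(genes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Promoter and gene-body tracks from stranded gene models.

    ``genes`` needs chrom/start/end/strand (BED-like, half-open).
    Promoter: [TSS-1500, TSS+500); gene body: [TSS+500, gene end), both
    strand-adjusted and clipped at 0.  Genes shorter than 500 bp yield an
    empty body; unstranded records are skipped with a warning.
    """
    promoters, bodies = [], []
    for row in genes.itertuples(index=False):
        if row.strand not in ("+", "-"):
            warnings.warn(f"skipping unstranded gene record at {row.chrom}:{row.start}")
            continue
        if row.strand == "+":
            p_start, p_end = row.start - PROMOTER_UPSTREAM, row.start + PROMOTER_DOWNSTREAM
            b_start, b_end = row.start + PROMOTER_DOWNSTREAM, row.end
        else:
            p_start, p_end = row.end - PROMOTER_DOWNSTREAM, row.end + PROMOTER_UPSTREAM
            b_start, b_end = row.start, row.end - PROMOTER_DOWNSTREAM
        promoters.append((row.chrom, max(0, p_start), max(0, p_end)))
        if b_end > b_start:
            bodies.append((row.chrom, max(0, b_start), b_end))
    cols = ["chrom", "start", "end"]
    return pd.DataFrame(promoters, columns=cols), pd.DataFrame(bodies, columns=cols)
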