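"""Expression summaries feeding the chromatin analyses.

RPKM computation from a replicate count table, quintile assignment with a
separate zero-expression group, per-gene chromatin-state overlap
percentages, thresholding of a precomputed differential-expression table,
and exact gene-list overlap tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ChromatinStateAnnotation, GenomicInterval

QUINTILE_LABELS = ("Q5", "Q4", "Q3", "Q2", "Q1")  # highest to lowest expression


def rpkm(counts, gene_length, library_size):
    """Reads per kilobase of gene model per million mapped reads."""
    gene_length = np.asarray(gene_length, dtype=float)
    library_size = float(library_size)
    if np.any(gene_length <= 0):
        raise ValueError("gene_length must be > 0")
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return np.asarray(counts, dtype=float) / (gene_length / 1e3) / (library_size / 1e6)


def add_rpkm(df: pd.DataFrame, count_cols: Sequence[str],
             length_col: str = "length") -> pd.DataFrame:
    """Append per-replicate RPKM columns and their mean.

    The library size of each replicate is the column total of the provided
    table, making the computation self-contained.
    """
    out = df.copy()
    for col in count_cols:
        out[f"rpkm_{col}"] = rpkm(df[col], df[length_col], df[col].sum())
    out["mean_rpkm"] = out[[f"rpkm_{c}" for c in count_cols]].mean(axis=1)
    return out


def assign_quintiles(df: pd.DataFrame, count_cols: Sequence[str],
                     length_col: str = "length",
                     gene_col: str = "gene_id") -> pd.Series:
    """Assign each gene to ``zero`` or an expression quintile ``Q1``..``Q5``.

    Genes with zero counts in *all* replicates form the ``zero`` group.
    The remaining genes are ranked by mean RPKM (descending; ties broken by
    gene identifier) and split into five groups of as-equal-as-possible
    size, ``Q5`` holding the highest-expressed genes. Call once per
    genotype: quintiles are genotype-specific.
    """
    work = add_rpkm(df, count_cols, length_col=length_col)
    zero = (df[count_cols] == 0).all(axis=1)
    labels = pd.Series("zero", index=df.index, dtype=object)
    nz = work.loc[~zero].sort_values(
        by=["mean_rpkm", gene_col], ascending=[False, True], kind="stable"
    )
    if len(nz) < 5:
        raise ValueError(f"only {len(nz)} nonzero genes; cannot form quintiles")
    for lbl, chunk in zip(QUINTILE_LABELS, np.array_split(nz.index.to_numpy(), 5)):
        labels.loc[chunk] = lbl
    return labels


def state_overlap(
    genes: Sequence[GenomicInterval],
    states: Sequence[ChromatinStateAnnotation],
) -> pd.DataFrame:
    """Percentage of each gene's length overlapped by each chromatin state.

    Rows are genes (indexed by name or coordinate string), columns the state
    labels present plus ``unannotated``; every row sums to 100.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    state_labels: list[str] = []
    for ann in states:
        if ann.state not in state_labels:
            state_labels.append(ann.state)
        by_chrom.setdefault(ann.interval.chrom, []).append(
            (ann.interval.start, ann.interval.end, ann.state)
        )
    for ivs in by_chrom.values():
        ivs.sort()

    rows = []
    index = []
    for g in genes:
        pct = {s: 0.0 for s in state_labels}
        covered = 0
        for s0, e0, lab in by_chrom.get(g.chrom, ()):
            if s0 >= g.end:
                break
            ov = min(e0, g.end) - max(s0, g.start)
            if ov > 0:
                pct[lab] += 100.0 * ov / g.length
                covered += ov
        pct["unannotated"] = 100.0 * (g.length - covered) / g.length
        rows.append(pct)
        index.append(g.name if g.name else f"{g.chrom}:{g.start}-{g.end}")
    return pd.DataFrame(rows, index=index).fillna(0.0)


def _detect_fc_scale(fc: pd.Series) -> str:
    # linear fold changes are strictly positive; log2 values straddle zero
    return "log2" if (fc < 0).any() else "linear"


def de_filter(
    table: pd.DataFrame,
    p_col: str = "p",
    fc_col: str = "fc",
    p_max: float = 0.05,
    fc_min: float = 2.0,
    fc_scale: str = "auto",
) -> pd.DataFrame:
    """Partition a differential-expression table into up / down / ns.

    ``up`` requires ``p < p_max`` and linear fold change ``> fc_min``;
    ``down`` requires ``p < p_max`` and fold change ``< 1/fc_min``. The fold
    change column may be linear or log2; ``auto`` detects log2 by the
    presence of negative values.
    """
    for col in (p_col, fc_col):
        if col not in table.columns:
            raise KeyError(f"missing column {col!r}")
    fc = table[fc_col].astype(float)
    if fc_scale == "auto":
        fc_scale = _detect_fc_scale(fc)
    if fc_scale == "log2":
        fc = np.exp2(fc)
    elif fc_scale != "linear":
        raise ValueError(f"unknown fc_scale {fc_scale!r}")
    sig = table[p_col].astype(float) < p_max
    out = table.copy()
    out["direction"] = np.where(
        sig & (fc > fc_min), "up", np.where(sig & (fc < 1.0 / fc_min), "down", "ns")
    )
    return out


@dataclass
class ListOverlap:
    overlap: int
    table: tuple[int, int, int, int]  # (both, a_only, b_only, neither)
    fisher_p: float
    hypergeom_p: float  # one-sided enrichment


def list_overlap(list_a, list_b, universe_size: int) -> ListOverlap:
    """Fisher exact test (two-sided) for the overlap of two gene lists.

    The 2x2 table is built from memberships within a universe of
    ``universe_size`` genes; the one-sided hypergeometric enrichment
    p-value is reported alongside.
    """
    a, b = set(list_a), set(list_b)
    both = len(a & b)
    a_only = len(a) - both
    b_only = len(b) - both
    neither = universe_size - len(a | b)
    if neither < 0:
        raise ValueError("universe smaller than the union of the lists")
    _, fisher_p = stats.fisher_exact(
        [[both, a_only], [b_only, neither]], alternative="two-sided"
    )
    hyper_p = float(stats.hypergeom.sf(both - 1, universe_size, len(a), len(b)))
    return ListOverlap(
        overlap=both,
        table=(both, a_only, b_only, neither),
        fisher_p=float(fisher_p),
        hypergeom_p=hyper_p,
    )
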