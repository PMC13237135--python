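"""Interval algebra and peak-set statistics for chromatin profiling workflows.

All coordinates are BED-style: 0-based, half-open ``[start, end)``.  The
operations mirror the bedtools semantics used in CUT&RUN/ATAC analyses:

* ``merge`` unions intervals whose gap is at most ``distance`` (a gap of
  exactly ``distance`` merges, matching ``bedtools merge -d``);
* ``reproducible`` keeps intervals of one replicate overlapping (>= 1 bp)
  any interval of the other (``bedtools intersect -u``), then merges;
* ``partition_consensus`` labels every consensus peak gained, lost or
  persistent against differential-accessibility region sets, with
  gained-before-lost priority so the labels partition the set.

Also here: the exogenous-genome spike-in scale factor used to normalise
CUT&RUN coverage, and the accessibility-versus-expression quadrant
concordance with its two-sided Fisher exact test.
"""

from __future__ import annotations

import logging
import math
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GAINED = "gained"
LOST = "lost"
PERSISTENT = "persistent"

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def intervals_frame(records) -> pd.DataFrame:
    """Build a validated interval table from (chrom, start, end[, ...]) tuples."""
    df = pd.DataFrame(records, columns=BED_COLUMNS[: len(records[0])] if records else
                      BED_COLUMNS[:3])
    return validate_intervals(df)


def validate_intervals(df: pd.DataFrame) -> pd.DataFrame:
    required = {"chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"interval table missing columns: {sorted(missing)}")
    if len(df) and ((df["start"] < 0).any() or (df["start"] >= df["end"]).any()):
        raise ValueError("intervals must satisfy 0 <= start < end")
    return df


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(
        drop=True
    )


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 (or narrowPeak; first six columns used), no header."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = min(df.shape[1], 6)
    df = df.iloc[:, :ncol]
    df.columns = BED_COLUMNS[:ncol]
    return validate_intervals(df)


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def merge(peaks: pd.DataFrame, distance: int = 0) -> pd.DataFrame:
    """Union intervals whose same-chromosome gap is <= ``distance`` bp.

    The output is sorted and disjoint.  ``merge`` is idempotent.
    """
    validate_intervals(peaks)
    if peaks.empty:
        return peaks[["chrom", "start", "end"]].copy()
    df = sort_intervals(peaks)
    out_chrom, out_start, out_end = [], [], []
    for chrom, group in df.groupby("chrom", sort=True):
        starts = group["start"].to_numpy()
        ends = group["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= distance:  # gap == distance still merges
                cur_e = max(cur_e, int(e))
            else:
                out_chrom.append(chrom); out_start.append(cur_s); out_end.append(cur_e)
                cur_s, cur_e = int(s), int(e)
        out_chrom.append(chrom); out_start.append(cur_s); out_end.append(cur_e)
    return pd.DataFrame({"chrom": out_chrom, "start": out_start, "end": out_end})


def _overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does it overlap (>=1 bp) any subject interval?"""
    hits = np.zeros(len(query), dtype=bool)
    if subject.empty or query.empty:
        return hits
    merged = merge(subject, distance=0)
    by_chrom = {c: g for c, g in merged.groupby("chrom")}
    for chrom, group in query.groupby("chrom"):
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        qs = group["start"].to_numpy()
        qe = group["end"].to_numpy()
        # disjoint sorted subject: overlap iff the first interval with
        # end > query.start begins before query.end
        idx = np.searchsorted(ends, qs, side="right")
        ok = idx < len(starts)
        res = np.zeros(len(group), dtype=bool)
        res[ok] = starts[idx[ok]] < qe[ok]
        hits[query.index.get_indexer(group.index)] = res
    return hits


def reproducible(rep_a: pd.DataFrame, rep_b: pd.DataFrame) -> pd.DataFrame:
    """Replicate-reproducible peaks: A intervals overlapping any B, merged."""
    validate_intervals(rep_a)
    validate_intervals(rep_b)
    a = rep_a.reset_index(drop=True)
    kept = a[_overlaps_any(a, rep_b)]
    if kept.empty:
        return kept[["chrom", "start", "end"]].copy()
    return merge(kept, distance=0)


def partition_consensus(
    consensus: pd.DataFrame, gained: pd.DataFrame, lost: pd.DataFrame
) -> pd.DataFrame:
    """Label each consensus peak gained, lost or persistent.

    A peak overlapping a gained region is ``gained``; otherwise one
    overlapping a lost region is ``lost``; all remaining peaks are
    ``persistent``.  The gained-before-lost priority makes the labels
    mutually exclusive and exhaustive; peaks overlapping both sets are
    logged.
    """
    validate_intervals(consensus)
    cons = consensus.reset_index(drop=True).copy()
    in_gain = _overlaps_any(cons, validate_intervals(gained))
    in_lost = _overlaps_any(cons, validate_intervals(lost))
    both = in_gain & in_lost
    if both.any():
        logger.warning(
            "%d consensus peaks overlap both gained and lost regions; "
            "labelled gained by priority", int(both.sum()),
        )
    labels = np.where(in_gain, GAINED, np.where(in_lost, LOST, PERSISTENT))
    cons["label"] = labels
    return cons


def spikein_factor(ecoli_reads: int, human_reads: int) -> float:
    """Spike-in normalisation factor: ``1 / ((ecoli / human) * 100)``.

    Coverage values are multiplied by this factor, so samples with more
    exogenous (E. coli) reads per endogenous read are scaled down.
    """
    if ecoli_reads <= 0 or human_reads <= 0:
        raise ValueError("read counts must be positive")
    return 1.0 / ((ecoli_reads / human_reads) * 100.0)


class QuadrantResult(NamedTuple):
    table: np.ndarray          # rows: peak L2FC sign (+, -); cols: gene sign (+, -)
    concordance: float         # (n++ + n--) / n
    odds_ratio: float          # inf when a discordant cell is empty
    p_value: float             # two-sided Fisher exact
    n_excluded: int            # pairs with a zero L2FC, dropped
    degenerate: bool           # a table margin is empty (testing uninformative)


def quadrant_concordance(
    pairs: pd.DataFrame, mode: str = "signed"
) -> QuadrantResult:
    """Concordance of paired peak/gene log2 fold-changes.

    Each row pairs a differentially accessible peak's L2FC with the L2FC of
    its annotated gene.  Pairs are assigned to quadrants by sign (zero
    L2FCs are excluded and counted); concordant quadrants are (+,+) and
    (-,-).  ``mode="signed"`` (default) runs the two-sided Fisher exact
    test on the signed 2x2 table; ``mode="observed_expected"`` tests the
    concordant/discordant split against the uniform-null expectation of an
    even split.  The odds ratio of the signed table is reported as ``inf``
    under complete concordance (where formal testing is uninformative and
    ``degenerate`` is set).
    """
    if mode not in ("signed", "observed_expected"):
        raise ValueError(f"unknown mode {mode!r}")
    if pairs.empty:
        raise ValueError("no pairs supplied")
    x = pairs["l2fc_peak"].to_numpy(dtype=float)
    y = pairs["l2fc_gene"].to_numpy(dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("L2FC values must be finite")
    nonzero = (x != 0) & (y != 0)
    n_excluded = int((~nonzero).sum())
    if n_excluded:
        logger.info("excluded %d pairs with a zero L2FC", n_excluded)
    x, y = x[nonzero], y[nonzero]
    if len(x) == 0:
        raise ValueError("all pairs lie on an axis (zero L2FC)")
    n_pp = int(((x > 0) & (y > 0)).sum())
    n_pm = int(((x > 0) & (y < 0)).sum())
    n_mp = int(((x < 0) & (y > 0)).sum())
    n_mm = int(((x < 0) & (y < 0)).sum())
    table = np.array([[n_pp, n_pm], [n_mp, n_mm]])
    n = table.sum()
    concordance = (n_pp + n_mm) / n
    if n_pm == 0 or n_mp == 0:
        odds_ratio = math.inf if n_pp * n_mm > 0 else math.nan
    else:
        odds_ratio = (n_pp * n_mm) / (n_pm * n_mp)
    # complete (dis)concordance or an empty margin: the exact test carries
    # no information ("precluding formal statistical testing")
    degenerate = bool(
        (n_pm == 0 and n_mp == 0)
        or (n_pp == 0 and n_mm == 0)
        or min(table.sum(axis=0).min(), table.sum(axis=1).min()) == 0
    )
    if mode == "signed":
        _, p = stats.fisher_exact(table, alternative="two-sided")
    else:
        n_conc = n_pp + n_mm
        expected = n / 2.0
        obs_exp = np.array(
            [[n_conc, n - n_conc], [round(expected), n - round(expected)]]
        )
        _, p = stats.fisher_exact(obs_exp, alternative="two-sided")
    return QuadrantResult(table, concordance, odds_ratio, float(p), n_excluded,
                          bool(degenerate))
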