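"""Small genomic-interval helpers.

All intervals handled here are 0-based half-open ``[start, end)`` on named
chromosomes, the BED convention; conversion from 1-based inclusive coordinates
happens at the I/O boundary. SNPs are point features at 1-based positions, so a
SNP at position ``pos`` occupies the 0-based point ``pos - 1``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end"]


def as_interval_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.loc[:, INTERVAL_COLUMNS].copy()
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    bad = df["start"] > df["end"]
    if bad.any():
        first = df[bad].iloc[0]
        raise ValueError(
            f"interval with start > end: {first['chrom']}:{first['start']}-{first['end']}"
        )
    return df


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: sorted, with overlapping/adjacent runs coalesced."""
    df = as_interval_frame(df)
    if df.empty:
        return df
    out = []
    for chrom, grp in df.sort_values(["chrom", "start", "end"]).groupby(
        "chrom", sort=True
    ):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # overlap or adjacency merges
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=INTERVAL_COLUMNS)


def _per_chrom_arrays(merged: pd.DataFrame) -> dict:
    tables = {}
    for chrom, grp in merged.groupby("chrom", sort=False):
        tables[chrom] = (grp["start"].to_numpy(), grp["end"].to_numpy())
    return tables


def points_in_intervals(
    chroms, positions_1based, intervals: pd.DataFrame
) -> np.ndarray:
    """Boolean mask: does each 1-based point fall inside any interval?"""
    merged = merge_intervals(intervals)
    tables = _per_chrom_arrays(merged)
    chroms = np.asarray(chroms)
    pts = np.asarray(positions_1based, dtype=np.int64) - 1
    out = np.zeros(len(pts), dtype=bool)
    for chrom in np.unique(chroms):
        if chrom not in tables:
            continue
        starts, ends = tables[chrom]
        sel = chroms == chrom
        idx = np.searchsorted(starts, pts[sel], side="right") - 1
        hit = (idx >= 0) & (pts[sel] < ends[np.clip(idx, 0, len(ends) - 1)])
        out[sel] = hit
    return out


def intervals_overlap_any(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Boolean mask per query row: does it overlap any target interval?"""
    query = as_interval_frame(query)
    merged = merge_intervals(targets)
    tables = _per_chrom_arrays(merged)
    out = np.zeros(len(query), dtype=bool)
    qc = query["chrom"].to_numpy()
    qs = query["start"].to_numpy()
    qe = query["end"].to_numpy()
    for chrom in np.unique(qc):
        if chrom not in tables:
            continue
        starts, ends = tables[chrom]
        sel = np.flatnonzero(qc == chrom)
        for i in sel:
            j = np.searchsorted(starts, qs[i], side="right") - 1
            if j >= 0 and ends[j] > qs[i]:
                out[i] = True
                continue
            j += 1
            if j < len(starts) and starts[j] < qe[i]:
                out[i] = True
    return out
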