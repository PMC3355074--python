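"""Genomic coordinate frame shared by every pipeline stage.

All coordinates are 0-based, half-open ``[start, end)`` and serialize as BED.
The central object is the :class:`WindowGrid`: a fixed-width tiling of each
chromosome (100 kb by default) that serves as the universal frame for
methylation levels, methylation-index values, desert calls, and window-level
association statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end"]


def _as_interval_frame(elements) -> pd.DataFrame:
    """Coerce an interval collection into a (chrom, start, end) DataFrame."""
    if isinstance(elements, pd.DataFrame):
        df = elements
    else:
        df = pd.DataFrame(list(elements), columns=BED_COLUMNS)
    missing = [c for c in BED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interval frame missing columns: {missing}")
    return df


def validate_intervals(df: pd.DataFrame, chrom_sizes: Mapping[str, int]) -> None:
    """Reject intervals that fall off the declared genome."""
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {chrom!r}")
        size = chrom_sizes[chrom]
        if (sub["start"] < 0).any() or (sub["end"] > size).any():
            raise ValueError(f"interval outside bounds of chromosome {chrom!r}")
        if (sub["start"] >= sub["end"]).any():
            raise ValueError(f"empty or inverted interval on chromosome {chrom!r}")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class WindowGrid:
    """Fixed-width windows tiling each chromosome, minus gap-dominated tiles.

    ``excluded[i]`` flags windows whose gap content is at or above the
    exclusion fraction; they remain in the frame (so indices are stable) but
    are never valid for methylation or association statistics.
    """

    window_size: int
    chrom_sizes: dict[str, int]
    chrom: np.ndarray        # str array, one entry per window
    start: np.ndarray        # int64
    excluded: np.ndarray     # bool
    gap_fraction: np.ndarray = field(default=None)

    _chrom_offsets: dict[str, tuple[int, int]] = field(default=None, repr=False)

    def __post_init__(self):
        if self._chrom_offsets is None:
            offsets = {}
            i = 0
            while i < self.n_windows:
                c = self.chrom[i]
                j = i
                while j < self.n_windows and self.chrom[j] == c:
                    j += 1
                offsets[c] = (i, j)
                i = j
            self._chrom_offsets = offsets

    @property
    def n_windows(self) -> int:
        return len(self.start)

    @property
    def end(self) -> np.ndarray:
        return self.start + self.window_size

    def n_tiles(self, chrom: str) -> int:
        lo, hi = self._chrom_offsets[chrom]
        return hi - lo

    def window_range(self, chrom: str) -> tuple[int, int]:
        """[lo, hi) global window-index range for a chromosome."""
        return self._chrom_offsets[chrom]

    def overlapping_windows(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of windows with >=1 bp overlap with [start, end)."""
        if chrom not in self._chrom_offsets:
            raise ValueError(f"unknown chromosome {chrom!r}")
        lo, hi = self._chrom_offsets[chrom]
        first = max(0, start // self.window_size)
        last = min(hi - lo, -(-end // self.window_size))  # ceil division
        if first >= last:
            return np.empty(0, dtype=np.int64)
        return np.arange(lo + first, lo + last, dtype=np.int64)

    def window_of_positions(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Global window index per position; -1 for positions beyond the tiling."""
        lo, hi = self._chrom_offsets[chrom]
        idx = np.asarray(pos, dtype=np.int64) // self.window_size
        out = lo + idx
        out[(idx < 0) | (idx >= hi - lo)] = -1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "excluded": self.excluded,
            }
        )


def partition_genome(
    chrom_sizes: Mapping[str, int],
    gaps=None,
    window_size: int = 100_000,
    gap_exclude_fraction: float = 0.5,
) -> WindowGrid:
    """Tile each chromosome with fixed windows from position 0.

    Trailing partial windows are dropped (unequal denominators would make
    window methylation levels incomparable).  Windows whose bases are gap at
    >= ``gap_exclude_fraction`` are flagged excluded; windows with minor gap
    overlap stay, since the downstream minimum-event filter removes windows
    that cannot actually be sampled.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    gap_df = _as_interval_frame(gaps) if gaps is not None else pd.DataFrame(columns=BED_COLUMNS)
    if len(gap_df):
        validate_intervals(gap_df, chrom_sizes)
        gap_df = merge_intervals(gap_df)  # overlapping gaps must not double-count

    chroms, starts, gapfracs = [], [], []
    for chrom, size in chrom_sizes.items():
        n = size // window_size
        if n == 0:
            continue
        w_start = np.arange(n, dtype=np.int64) * window_size
        gap_bases = np.zeros(n, dtype=np.int64)
        sub = gap_df[gap_df["chrom"] == chrom]
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            first = s // window_size
            last = min(n, -(-e // window_size))
            for w in range(first, last):
                ws = w * window_size
                gap_bases[w] += min(e, ws + window_size) - max(s, ws)
        chroms.append(np.full(n, chrom, dtype=object))
        starts.append(w_start)
        gapfracs.append(gap_bases / window_size)

    chrom_arr = np.concatenate(chroms) if chroms else np.empty(0, dtype=object)
    start_arr = np.concatenate(starts) if starts else np.empty(0, dtype=np.int64)
    frac_arr = np.concatenate(gapfracs) if gapfracs else np.empty(0)
    return WindowGrid(
        window_size=window_size,
        chrom_sizes=dict(chrom_sizes),
        chrom=chrom_arr,
        start=start_arr,
        excluded=frac_arr >= gap_exclude_fraction,
        gap_fraction=frac_arr,
    )


def windows_containing(elements, grid: WindowGrid) -> np.ndarray:
    """Boolean label per window: True iff >=1 bp of any element overlaps it."""
    df = _as_interval_frame(elements)
    validate_intervals(df, grid.chrom_sizes)
    labels = np.zeros(grid.n_windows, dtype=bool)
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in grid._chrom_offsets:
            continue
        lo, hi = grid.window_range(chrom)
        n = hi - lo
        ws = grid.window_size
        first = np.maximum(0, sub["start"].to_numpy() // ws)
        last = np.minimum(n, -(-sub["end"].to_numpy() // ws))
        for f, l in zip(first, last):
            if f < l:
                labels[lo + f : lo + l] = True
    return labels


def sample_matched_segments(
    elements,
    chrom_sizes: Mapping[str, int],
    n_per_element: int = 100,
    rng=None,
    gaps=None,
    retry_cap: int = 100,
) -> pd.DataFrame:
    """Length- and chromosome-matched random segments (the permutation null).

    For each element, ``n_per_element`` segments of identical length are drawn
    with a uniform start on the same chromosome.  Draws overlapping an
    assembly gap are redrawn up to ``retry_cap`` times; a segment that cannot
    escape the gaps is emitted with ``gap_overlap=True``.
    """
    rng = np.random.default_rng(rng)
    df = _as_interval_frame(elements)
    validate_intervals(df, chrom_sizes)
    gap_df = _as_interval_frame(gaps) if gaps is not None else None
    gap_by_chrom = {}
    if gap_df is not None and len(gap_df):
        for chrom, sub in gap_df.groupby("chrom", sort=False):
            s = sub.sort_values("start")
            gap_by_chrom[chrom] = (s["start"].to_numpy(), s["end"].to_numpy())

    out_chrom, out_start, out_len, out_src, out_flag = [], [], [], [], []
    for i, (chrom, s, e) in enumerate(zip(df["chrom"], df["start"], df["end"])):
        length = e - s
        size = chrom_sizes[chrom]
        hi = size - length
        if hi < 0:
            raise ValueError(f"element longer than chromosome {chrom!r}")
        starts = rng.integers(0, hi + 1, size=n_per_element)
        flags = np.zeros(n_per_element, dtype=bool)
        if chrom in gap_by_chrom:
            gs, ge = gap_by_chrom[chrom]
            bad = _overlaps_sorted(starts, starts + length, gs, ge)
            tries = 0
            while bad.any() and tries < retry_cap:
                starts[bad] = rng.integers(0, hi + 1, size=int(bad.sum()))
                bad = _overlaps_sorted(starts, starts + length, gs, ge)
                tries += 1
            flags = bad
        out_chrom.append(np.full(n_per_element, chrom, dtype=object))
        out_start.append(starts)
        out_len.append(np.full(n_per_element, length, dtype=np.int64))
        out_src.append(np.full(n_per_element, i, dtype=np.int64))
        out_flag.append(flags)

    if not out_chrom:
        return pd.DataFrame(columns=BED_COLUMNS + ["source_index", "gap_overlap"])
    start = np.concatenate(out_start)
    return pd.DataFrame(
        {
            "chrom": np.concatenate(out_chrom),
            "start": start,
            "end": start + np.concatenate(out_len),
            "source_index": np.concatenate(out_src),
            "gap_overlap": np.concatenate(out_flag),
        }
    )


def _overlaps_sorted(starts, ends, gap_starts, gap_ends) -> np.ndarray:
    """Vectorized any-overlap test against a sorted, disjoint gap set."""
    # The nearest gap starting before each segment end is the only candidate
    # to its left; check it plus the next gap to the right.
    idx = np.searchsorted(gap_starts, ends, side="left") - 1
    hit = np.zeros(len(starts), dtype=bool)
    ok = idx >= 0
    hit[ok] = gap_ends[idx[ok]] > starts[ok]
    return hit


def flank_at_distance(elements, distance: int, flank_size: int, chrom_sizes) -> pd.DataFrame:
    """Two flanks per element, placed ``distance`` bases outward of each edge.

    Flanks are clipped at chromosome bounds; flanks empty after clipping are
    dropped.
    """
    if distance < 0 or flank_size <= 0:
        raise ValueError("distance must be >= 0 and flank_size > 0")
    df = _as_interval_frame(elements)
    validate_intervals(df, chrom_sizes)
    rows = []
    for i, (chrom, s, e) in enumerate(zip(df["chrom"], df["start"], df["end"])):
        size = chrom_sizes[chrom]
        left = (max(0, s - distance - flank_size), max(0, s - distance))
        right = (min(size, e + distance), min(size, e + distance + flank_size))
        for fs, fe in (left, right):
            if fe > fs:
                rows.append((chrom, fs, fe, i))
    return pd.DataFrame(rows, columns=BED_COLUMNS + ["source_index"])


def merge_intervals(df: pd.DataFrame, merge_gap: int = 0) -> pd.DataFrame:
    """Union of intervals, merging pairs separated by <= merge_gap bases."""
    df = _as_interval_frame(df)
    if df.empty:
        return df[BED_COLUMNS].copy()
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"])
        cur_s, cur_e = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + merge_gap:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=BED_COLUMNS)
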