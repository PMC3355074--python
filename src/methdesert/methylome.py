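"""Window methylomes from per-CpG bisulfite observations.

A window's methylation level is the ratio of methylated CpG sampling events
to total CpG sampling events in reads mapping within the window.  Windows
with fewer than ``min_events`` sampling events (20 by default; a
deep-coverage variant additionally requires a minimum mapped-read count) are
invalid: low-coverage estimates there are dominated by mappability noise.

Methylation deserts are the valid windows in the lowest percentile (1% or
5%) of levels; they are where germline hypomethylation concentrates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import WindowGrid


@dataclass
class WindowMethylome:
    grid: WindowGrid
    events: np.ndarray        # total CpG sampling events per window
    meth_events: np.ndarray   # methylated events per window
    valid: np.ndarray         # bool
    reads: np.ndarray = None  # mapped-read count, optional
    n_outside: int = 0        # observations falling outside the tiling
    fixed_level: np.ndarray = None  # set when levels are not count-derived

    @property
    def level(self) -> np.ndarray:
        """Methylation level per window; NaN where invalid."""
        if self.fixed_level is not None:
            return self.fixed_level
        with np.errstate(invalid="ignore", divide="ignore"):
            lvl = self.meth_events / self.events.astype(float)
        lvl[~self.valid] = np.nan
        return lvl


@dataclass
class DesertCallSet:
    percentile: float
    desert_windows: np.ndarray  # global window indices
    level_cutoff: float
    degenerate: bool = False    # all valid levels tied

    def mask(self, n_windows: int) -> np.ndarray:
        m = np.zeros(n_windows, dtype=bool)
        m[self.desert_windows] = True
        return m


def build_window_methylome(
    obs: pd.DataFrame,
    grid: WindowGrid,
    min_events: int = 20,
    min_reads: int = 0,
    reads: np.ndarray = None,
) -> WindowMethylome:
    """Accumulate per-CpG observations (chrom, pos, n_meth, n_total) into windows.

    Observations outside the window tiling are counted (``n_outside``), not
    fatal.  ``reads`` is an optional per-window mapped-read vector for the
    deep-coverage validity rule.
    """
    if min_events < 1:
        raise ValueError("min_events must be >= 1")
    events = np.zeros(grid.n_windows, dtype=np.int64)
    meth = np.zeros(grid.n_windows, dtype=np.int64)
    n_outside = 0
    for chrom, sub in obs.groupby("chrom", sort=False):
        if chrom not in grid.chrom_sizes:
            raise ValueError(f"observation on unknown chromosome {chrom!r}")
        widx = grid.window_of_positions(chrom, sub["pos"].to_numpy())
        inside = widx >= 0
        n_outside += int((~inside).sum())
        np.add.at(events, widx[inside], sub["n_total"].to_numpy()[inside])
        np.add.at(meth, widx[inside], sub["n_meth"].to_numpy()[inside])
    if (meth > events).any():
        raise ValueError("n_meth exceeds n_total in accumulated window counts")
    valid = (~grid.excluded) & (events >= min_events)
    if reads is not None:
        reads = np.asarray(reads)
        valid &= reads >= min_reads
    return WindowMethylome(grid, events, meth, valid, reads=reads, n_outside=n_outside)


def average_methylomes(a: WindowMethylome, b: WindowMethylome) -> WindowMethylome:
    """Unweighted mean of two replicate methylomes in level space.

    A window is valid only where both replicates are valid; event counts are
    summed for bookkeeping (the averaged level is not re-derivable from them).
    """
    if a.grid is not b.grid and not (
        a.grid.window_size == b.grid.window_size
        and np.array_equal(a.grid.start, b.grid.start)
        and np.array_equal(a.grid.chrom, b.grid.chrom)
    ):
        raise ValueError("methylomes built on different grids")
    valid = a.valid & b.valid
    mean_level = np.full(a.grid.n_windows, np.nan)
    mean_level[valid] = (a.level[valid] + b.level[valid]) / 2.0
    events = a.events + b.events
    return WindowMethylome(
        a.grid, events, np.zeros_like(events), valid, fixed_level=mean_level
    )


def call_deserts(m: WindowMethylome, percentile: float = 0.01) -> DesertCallSet:
    """Valid windows at or below the empirical percentile cutoff of levels.

    The cutoff is the k-th smallest valid level with k = max(1,
    floor(percentile * n_valid)); ties at the cutoff are all included, so the
    desert fraction can exceed the percentile by the tied mass.
    """
    if not (0 < percentile < 1):
        raise ValueError("percentile must be in (0, 1)")
    valid_idx = np.flatnonzero(m.valid)
    if len(valid_idx) == 0:
        raise ValueError("no valid windows")
    levels = m.level[valid_idx]
    k = max(1, int(np.floor(percentile * len(valid_idx))))
    cutoff = np.sort(levels)[k - 1]
    sel = levels <= cutoff
    return DesertCallSet(
        percentile=percentile,
        desert_windows=valid_idx[sel],
        level_cutoff=float(cutoff),
        degenerate=bool(sel.all()),
    )


def clopper_pearson(k: np.ndarray, n: np.ndarray, confidence: float = 0.95):
    """Exact (Clopper-Pearson) two-sided binomial confidence interval."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    alpha = 1.0 - confidence
    lo = np.where(k > 0, stats.beta.ppf(alpha / 2, k, n - k + 1), 0.0)
    hi = np.where(k < n, stats.beta.ppf(1 - alpha / 2, k + 1, n - k), 1.0)
    return lo, hi


def accuracy_profile(
    m: WindowMethylome, error_bound: float = 0.10, confidence: float = 0.95
):
    """Per-window estimation-accuracy flags from exact binomial intervals.

    A valid window passes when the half-width of its Clopper-Pearson interval,
    relative to the point estimate, is <= ``error_bound``; at level 0 the
    absolute half-width is used instead (relative error is undefined there).
    Returns ``(pass_flags, fraction_passing)`` over valid windows.
    """
    valid_idx = np.flatnonzero(m.valid)
    k = m.meth_events[valid_idx]
    n = m.events[valid_idx]
    lo, hi = clopper_pearson(k, n, confidence)
    half = (hi - lo) / 2.0
    level = k / n.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = half / level
    passing = np.where(level > 0, rel <= error_bound, half <= error_bound)
    flags = np.zeros(m.grid.n_windows, dtype=bool)
    flags[valid_idx] = passing
    frac = float(passing.mean()) if len(passing) else float("nan")
    return flags, frac
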