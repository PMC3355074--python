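"""Association statistics linking methylation to structural elements.

The statistical layer of the pipeline: two-sample Kolmogorov-Smirnov tests
of window methylation against element-bearing windows, size-matched
permutation nulls (each element compared to random same-length segments on
its own chromosome), distance-decay profiles of flanking hypomethylation,
chi-square enrichment folds for window strata such as methylation deserts,
and statistical relative / attributable risk over window groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    WindowGrid,
    _as_interval_frame,
    flank_at_distance,
    sample_matched_segments,
    windows_containing,
)
from .methylome import WindowMethylome

EXACT_KS_MAX_N = 50  # combined sample size below which the exact KS law is used


@dataclass
class AssociationResult:
    kind: str                  # KS | chisq | fold | RR | AR | permutation
    value: float               # the headline statistic (D, fold, RR, ...)
    p_value: float
    n_case: int = 0
    n_control: int = 0
    direction: str = None      # which group is lower (KS-style tests)
    n_replicates: int = None
    seed: object = None
    extras: dict = field(default_factory=dict)


def _ks(x: np.ndarray, y: np.ndarray):
    method = "exact" if len(x) + len(y) < EXACT_KS_MAX_N else "asymp"
    res = stats.ks_2samp(x, y, method=method)
    direction = "case_lower" if np.median(x) < np.median(y) else "control_lower"
    return float(res.statistic), float(res.pvalue), direction


def ks_methylation_association(
    m: WindowMethylome, element_windows: np.ndarray
) -> AssociationResult:
    """Two-sample KS of methylation levels: element windows vs the rest."""
    valid = m.valid
    lv = m.level
    case = lv[valid & element_windows]
    control = lv[valid & ~element_windows]
    if len(case) == 0 or len(control) == 0:
        return AssociationResult(
            "KS", float("nan"), float("nan"), len(case), len(control),
            extras={"empty_group": True},
        )
    d, p, direction = _ks(case, control)
    return AssociationResult("KS", d, p, len(case), len(control), direction)


def score_elements(elements, m: WindowMethylome) -> np.ndarray:
    """Methylation level per element: event-weighted mean of the valid
    windows it overlaps; NaN when it overlaps no valid window."""
    df = _as_interval_frame(elements).reset_index(drop=True)
    grid = m.grid
    lv = m.level
    ev = m.events.astype(float)
    weights = np.where(m.valid, ev, 0.0)
    wsum = np.zeros(len(df))
    lsum = np.zeros(len(df))
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in grid._chrom_offsets:
            continue
        lo, hi = grid.window_range(chrom)
        n = hi - lo
        ws = grid.window_size
        first = np.maximum(0, sub["start"].to_numpy() // ws)
        last = np.minimum(n, -(-sub["end"].to_numpy() // ws))
        rows = sub.index.to_numpy()
        span = last - first
        for k in range(int(span.max()) if len(span) else 0):
            sel = span > k
            widx = lo + first[sel] + k
            wsum[rows[sel]] += weights[widx]
            lsum[rows[sel]] += weights[widx] * np.nan_to_num(lv[widx])
    with np.errstate(invalid="ignore", divide="ignore"):
        out = lsum / wsum
    out[wsum == 0] = np.nan
    return out


def permutation_association(
    elements,
    m: WindowMethylome,
    n_per_element: int = 100,
    rng_seed=None,
    gaps=None,
) -> AssociationResult:
    """Size-matched permutation test of element methylation.

    Each element's methylation level is compared (two-sample KS) to the
    levels of ``n_per_element`` random segments of the same length on the
    same chromosome.  D_max is reported as the fraction of elements in
    excess at low methylation (its sign/direction recorded).
    """
    obs = score_elements(elements, m)
    nulls_df = sample_matched_segments(
        elements, m.grid.chrom_sizes, n_per_element, rng=rng_seed, gaps=gaps
    )
    null = score_elements(nulls_df, m)
    obs_ok = obs[~np.isnan(obs)]
    null_ok = null[~np.isnan(null)]
    n_excluded = int(np.isnan(obs).sum())
    if len(obs_ok) == 0 or len(null_ok) == 0:
        return AssociationResult(
            "permutation", float("nan"), float("nan"),
            extras={"empty_group": True},
        )
    d, p, direction = _ks(obs_ok, null_ok)
    return AssociationResult(
        "permutation", d, p, len(obs_ok), len(null_ok), direction,
        n_replicates=n_per_element, seed=rng_seed,
        extras={"n_elements_excluded": n_excluded},
    )


def distance_decay(
    elements,
    m: WindowMethylome,
    distances=tuple(range(10_000, 100_001, 10_000)),
    flank_size: int = 10_000,
    n_per_element: int = 100,
    rng_seed=None,
) -> list:
    """Flanking-hypomethylation profile at increasing distances.

    For each distance, the methylation of ``flank_size`` regions placed that
    far outward of each element is KS-compared with flanks at the same
    distance from size-matched random segments (drawn once per call).
    """
    chrom_sizes = m.grid.chrom_sizes
    nulls_df = sample_matched_segments(
        elements, chrom_sizes, n_per_element, rng=rng_seed
    )
    out = []
    for dist in distances:
        case_fl = flank_at_distance(elements, dist, flank_size, chrom_sizes)
        null_fl = flank_at_distance(nulls_df, dist, flank_size, chrom_sizes)
        case = score_elements(case_fl, m)
        null = score_elements(null_fl, m)
        case = case[~np.isnan(case)]
        null = null[~np.isnan(null)]
        if len(case) == 0 or len(null) == 0:
            out.append(
                AssociationResult(
                    "KS", float("nan"), float("nan"),
                    extras={"distance": dist, "empty_group": True},
                )
            )
            continue
        d, p, direction = _ks(case, null)
        out.append(
            AssociationResult(
                "KS", d, p, len(case), len(null), direction,
                n_replicates=n_per_element, seed=rng_seed,
                extras={"distance": dist},
            )
        )
    return out


def enrichment_fold(
    elements, stratum_windows: np.ndarray, grid: WindowGrid,
    valid: np.ndarray = None,
) -> AssociationResult:
    """Element enrichment in a window stratum with a chi-square p-value.

    fold = (fraction of elements in stratum windows) / (fraction of valid
    windows in the stratum); chi-square contrasts element in/out counts with
    window in/out counts.  A zero expected cell falls back to an exact
    binomial test.
    """
    if valid is None:
        valid = ~grid.excluded
    stratum = stratum_windows & valid
    n_stratum = int(stratum.sum())
    n_valid = int(valid.sum())
    if n_stratum == 0:
        raise ValueError("empty stratum")
    labels = windows_containing(elements, grid)
    df = _as_interval_frame(elements)
    in_stratum = np.zeros(len(df), dtype=bool)
    for i, (chrom, s, e) in enumerate(zip(df["chrom"], df["start"], df["end"])):
        widx = grid.overlapping_windows(chrom, s, e)
        in_stratum[i] = bool(stratum[widx].any()) if len(widx) else False
    k = int(in_stratum.sum())
    n = len(df)
    frac_windows = n_stratum / n_valid
    fold = (k / n) / frac_windows if n else float("nan")
    table = np.array([[k, n - k], [n_stratum, n_valid - n_stratum]], dtype=float)
    expected = stats.contingency.expected_freq(table)
    if (expected == 0).any():
        p = stats.binomtest(k, n, frac_windows).pvalue
        return AssociationResult(
            "fold", fold, float(p), k, n - k, extras={"fallback": "binomial"}
        )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return AssociationResult(
        "fold", fold, float(p), k, n - k, extras={"chi2": float(chi2)}
    )


def case_control_enrichment(
    case_elements, control_elements, stratum_windows: np.ndarray, grid: WindowGrid
) -> AssociationResult:
    """Case vs control element concentration in a stratum (2x2 chi-square)."""

    def in_stratum_count(elements):
        df = _as_interval_frame(elements)
        k = 0
        for chrom, s, e in zip(df["chrom"], df["start"], df["end"]):
            widx = grid.overlapping_windows(chrom, s, e)
            k += bool(stratum_windows[widx].any()) if len(widx) else False
        return k, len(df)

    k1, n1 = in_stratum_count(case_elements)
    k2, n2 = in_stratum_count(control_elements)
    if n1 == 0 or n2 == 0:
        raise ValueError("both element sets must be non-empty")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    fold = (k1 / n1) / (k2 / n2) if k2 > 0 else float("inf")
    if (table.sum(axis=0) == 0).any() or (stats.contingency.expected_freq(table) == 0).any():
        res = stats.fisher_exact(table.astype(int))
        return AssociationResult(
            "chisq", fold, float(res.pvalue), n1, n2, extras={"fallback": "fisher"}
        )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return AssociationResult(
        "chisq", fold, float(p), n1, n2, extras={"chi2": float(chi2)}
    )


def relative_attributable_risk(
    element_windows: np.ndarray,
    exposure_windows: np.ndarray,
    valid: np.ndarray = None,
) -> tuple:
    """Statistical relative risk and attributable risk of element-bearing
    windows under an exposure (desert or DP-LCR window status).

    RR = P(a|e) / P(a|not e); AR = [P(a) - P(a|not e)] / P(a) (the
    population attributable fraction).  The excess-risk difference
    P(a|e) - P(a|not e) is reported in extras.
    """
    if valid is not None:
        a = element_windows[valid]
        e = exposure_windows[valid]
    else:
        a, e = element_windows, exposure_windows
    n = len(a)
    ne = int(e.sum())
    if ne == 0 or ne == n:
        raise ValueError("exposure group empty or universal")
    p_a = a.mean()
    p_a_e = a[e].mean()
    p_a_ne = a[~e].mean()
    table = np.array(
        [
            [int((a & e).sum()), int((~a & e).sum())],
            [int((a & ~e).sum()), int((~a & ~e).sum())],
        ],
        dtype=float,
    )
    if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
        _, p_chi, _, _ = stats.chi2_contingency(table, correction=False)
    else:
        p_chi = float("nan")
    if p_a_ne == 0:
        rr = float("inf")
        flagged = True
    else:
        rr = p_a_e / p_a_ne
        flagged = False
    ar = (p_a - p_a_ne) / p_a if p_a > 0 else float("nan")
    extras = {
        "excess_risk": float(p_a_e - p_a_ne),
        "p_a": float(p_a),
        "p_a_given_e": float(p_a_e),
        "p_a_given_not_e": float(p_a_ne),
        "counts": table.astype(int).tolist(),
        "rr_infinite": flagged,
    }
    rr_res = AssociationResult("RR", float(rr), float(p_chi), ne, n - ne, extras=extras)
    ar_res = AssociationResult("AR", float(ar), float(p_chi), ne, n - ne, extras=extras)
    return rr_res, ar_res


def feature_enrichment_permutation(
    features,
    target_windows: np.ndarray,
    grid: WindowGrid,
    n_perm: int = 1000,
    rng_seed=None,
) -> AssociationResult:
    """Permutation enrichment of interval features in target windows.

    Observed = number of features overlapping any target window; the null
    re-places length-matched features uniformly on their chromosomes
    ``n_perm`` times.  p uses the add-one estimator and is never 0.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    df = _as_interval_frame(features)

    def count_overlap(frame):
        k = 0
        for chrom, s, e in zip(frame["chrom"], frame["start"], frame["end"]):
            widx = grid.overlapping_windows(chrom, s, e)
            k += bool(target_windows[widx].any()) if len(widx) else False
        return k

    observed = count_overlap(df)
    rng = np.random.default_rng(rng_seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = sample_matched_segments(df, grid.chrom_sizes, 1, rng=rng)
        null[i] = count_overlap(perm)
    null_mean = null.mean()
    fold = observed / null_mean if null_mean > 0 else float("inf")
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return AssociationResult(
        "permutation", float(fold), float(p), observed, int(null_mean),
        n_replicates=n_perm, seed=rng_seed,
        extras={"observed": observed, "null_mean": float(null_mean)},
    )
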