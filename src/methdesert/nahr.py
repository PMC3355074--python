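"""NAHR-signature classification of CNVs against LCR architecture.

Non-allelic homologous recombination between directly-oriented paralogous
repeats deletes or duplicates the whole intervening region.  A CNV cohort
therefore carries an NAHR signature when CNVs lying between *paralogous*
LCRs preferentially span the inter-LCR distance ("whole-region", >=40% of
the distance by the operational cutoff) compared with CNVs between
non-paralogous LCRs — a 2x2 contingency whose odds ratio quantifies the
enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = (
    "whole_paralogous",
    "scattered_paralogous",
    "whole_nonparalogous",
    "scattered_nonparalogous",
    "complex",
    "lcr_overlapping",
    "unassociated",
)


@dataclass
class LcrArchitecture:
    """Flattened cluster members, sorted per chromosome, with cluster ids."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    cluster_id: np.ndarray

    @classmethod
    def from_clusters(cls, clusters) -> "LcrArchitecture":
        rows = []
        for ci, cluster in enumerate(clusters):
            for seg in cluster.members:
                rows.append((seg.chrom, seg.start, seg.end, ci))
        if not rows:
            e = np.empty(0)
            return cls(e.astype(object), e.astype(int), e.astype(int), e.astype(int))
        df = (
            pd.DataFrame(rows, columns=["chrom", "start", "end", "cluster_id"])
            .drop_duplicates(subset=["chrom", "start", "end"])
            .sort_values(["chrom", "start", "end"], ignore_index=True)
        )
        return cls(
            df["chrom"].to_numpy(),
            df["start"].to_numpy(),
            df["end"].to_numpy(),
            df["cluster_id"].to_numpy(),
        )

    def on_chrom(self, chrom: str):
        m = self.chrom == chrom
        return self.start[m], self.end[m], self.cluster_id[m]


def classify_cnv(
    chrom: str,
    start: int,
    end: int,
    arch: LcrArchitecture,
    whole_fraction: float = 0.40,
) -> str:
    """Assign one CNV to its LCR-architecture category.

    Precedence: (1) overlapping LCRs of two or more different clusters →
    complex; (2)/(3) lying inside the gap between two flanking LCRs → whole
    vs scattered (>= ``whole_fraction`` of the inter-LCR distance) and
    paralogous vs non-paralogous (flanks same vs different cluster); (4)
    overlapping an LCR otherwise → lcr_overlapping; (5) unassociated.
    """
    ls, le, lc = arch.on_chrom(chrom)
    if len(ls) == 0:
        return "unassociated"
    overlap = (ls < end) & (start < le)
    touched = np.unique(lc[overlap])
    if len(touched) >= 2:
        return "complex"
    if len(touched) == 1:
        return "lcr_overlapping"
    # no LCR overlap: find the flanking LCRs around the CNV
    left_mask = le <= start
    right_mask = ls >= end
    if not left_mask.any() or not right_mask.any():
        return "unassociated"
    li = np.flatnonzero(left_mask)[np.argmax(le[left_mask])]
    ri = np.flatnonzero(right_mask)[np.argmin(ls[right_mask])]
    gap = ls[ri] - le[li]
    if gap <= 0:
        return "unassociated"
    coverage = (end - start) / gap
    paralogous = lc[li] == lc[ri]
    if coverage >= whole_fraction:
        return "whole_paralogous" if paralogous else "whole_nonparalogous"
    return "scattered_paralogous" if paralogous else "scattered_nonparalogous"


def classify_cnvs(
    cnvs: pd.DataFrame, clusters, whole_fraction: float = 0.40
) -> pd.DataFrame:
    """Classify a CNV table (chrom, start, end[, sample, state]) per call."""
    arch = (
        clusters
        if isinstance(clusters, LcrArchitecture)
        else LcrArchitecture.from_clusters(clusters)
    )
    cats = [
        classify_cnv(c, s, e, arch, whole_fraction)
        for c, s, e in zip(cnvs["chrom"], cnvs["start"], cnvs["end"])
    ]
    out = cnvs.copy()
    out["category"] = cats
    return out


@dataclass
class NahrContingency:
    table: np.ndarray          # [[whole_par, scat_par], [whole_nonpar, scat_nonpar]]
    chi2: float
    p_value: float
    odds_ratio: float
    nahr_fraction_all: float          # whole_paralogous / all CNVs
    nahr_fraction_lcr: float          # whole_paralogous / LCR-associated CNVs
    zero_margin: bool = False


def nahr_contingency(categories: Iterable[str]) -> NahrContingency:
    """2x2 test of whole vs scattered CNVs between paralogous vs
    non-paralogous LCR flanks (Pearson chi-square, no continuity
    correction)."""
    cats = pd.Series(list(categories))
    n = len(cats)
    wp = int((cats == "whole_paralogous").sum())
    sp = int((cats == "scattered_paralogous").sum())
    wn = int((cats == "whole_nonparalogous").sum())
    sn = int((cats == "scattered_nonparalogous").sum())
    table = np.array([[wp, sp], [wn, sn]], dtype=float)
    lcr_assoc = n - int((cats == "unassociated").sum())
    frac_all = wp / n if n else float("nan")
    frac_lcr = wp / lcr_assoc if lcr_assoc else float("nan")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return NahrContingency(
            table, float("nan"), float("nan"), float("nan"),
            frac_all, frac_lcr, zero_margin=True,
        )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (wp * sn) / (sp * wn) if sp * wn > 0 else float("inf")
    return NahrContingency(table, float(chi2), float(p), float(odds), frac_all, frac_lcr)
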