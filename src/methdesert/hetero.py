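"""Structural heterozygosity (2pq) as a mutability proxy.

Under the infinite-allele model at drift-mutation equilibrium, the ratio of
heterozygosity rates between two neutral loci equals the ratio of their
mutation rates, so per-locus structural heterozygosity ranks loci by
structural mutability.  The normal copy state is the homozygous major
allele; any aberrant signal (gain or loss) marks presence of a minor
structural allele.  Related samples (trios / parent-child pairs) sharing a
variant are collapsed to a single count so transmission is not mistaken for
recurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import WindowGrid
from .methylome import DesertCallSet


@dataclass
class Pedigree:
    """sample -> (family, role); samples absent from the table are unrelated."""

    family: dict = field(default_factory=dict)
    role: dict = field(default_factory=dict)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        fam = dict(zip(df["sample"], df["family"]))
        role = dict(zip(df["sample"], df["role"]))
        counts = df[df["role"] == "child"].groupby("family").size()
        if (counts > 1).any():
            raise ValueError("a trio family lists more than one child")
        return cls(fam, role)

    def family_of(self, sample: str):
        # unrelated samples form singleton families keyed by their own id
        return self.family.get(sample, f"__singleton__{sample}")

    def n_collapsed(self) -> int:
        """Cohort members in excess of one vote per family."""
        sizes = {}
        for fam in self.family.values():
            sizes[fam] = sizes.get(fam, 0) + 1
        return sum(c - 1 for c in sizes.values())


@dataclass
class CnvLocus:
    chrom: str
    start: int
    end: int
    carriers: frozenset            # sample ids with aberrant state
    states: dict = None            # sample -> gain/loss (bookkeeping)
    het: float = float("nan")
    q: float = float("nan")


def define_loci(calls: pd.DataFrame, merge_gap: int = 0) -> list:
    """Merge overlapping calls (within ``merge_gap``) across samples into loci."""
    loci = []
    for chrom, sub in calls.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"])
        cur = None
        for row in sub.itertuples(index=False):
            if cur is None:
                cur = [chrom, row.start, row.end, {(row.sample, row.state)}]
            elif row.start <= cur[2] + merge_gap:
                cur[2] = max(cur[2], row.end)
                cur[3].add((row.sample, row.state))
            else:
                loci.append(cur)
                cur = [chrom, row.start, row.end, {(row.sample, row.state)}]
        if cur is not None:
            loci.append(cur)
    out = []
    for chrom, s, e, carriers in loci:
        states = {}
        for sample, state in carriers:
            states[sample] = state
        out.append(
            CnvLocus(chrom, int(s), int(e), frozenset(states), states=states)
        )
    return out


def heterozygosity(
    locus: CnvLocus,
    n_samples_total: int,
    pedigree: Pedigree = None,
    verbose: bool = False,
):
    """2pq at one locus with family-collapsed allele counting.

    Each family carries one vote: carriers within one family count once in
    the numerator, and the denominator is the family-collapsed cohort size
    (total samples minus within-family duplicates), the same at every locus
    so that transmitted variants neither inflate q nor shift the baseline.
    With ``verbose`` the numerator-only variant (full per-sample
    denominator) is returned alongside.
    """
    if n_samples_total < 1:
        raise ValueError("no samples observed at locus")
    pedigree = pedigree or Pedigree()
    carrier_families = {pedigree.family_of(s) for s in locus.carriers}
    n_variant = len(carrier_families)  # one count per carrying family
    n_eff = n_samples_total - pedigree.n_collapsed()
    if n_eff <= 0:
        raise ValueError("no effective samples at locus")
    q = n_variant / n_eff
    het = 2 * q * (1 - q)
    if verbose:
        q_raw = n_variant / n_samples_total
        return het, q, {"het_full_denominator": 2 * q_raw * (1 - q_raw), "n_eff": n_eff}
    return het, q


def annotate_heterozygosity(
    loci: list, n_samples_total: int, pedigree: Pedigree = None
) -> list:
    for locus in loci:
        locus.het, locus.q = heterozygosity(locus, n_samples_total, pedigree)
    return loci


@dataclass
class StratumComparison:
    mean_in: float
    sd_in: float
    n_in: int
    mean_out: float
    sd_out: float
    n_out: int
    ks_d: float
    p_value: float
    skipped: bool = False


def het_by_stratum(
    loci: list, deserts: DesertCallSet, grid: WindowGrid
) -> StratumComparison:
    """Compare heterozygosity of loci inside vs outside methylation deserts.

    A locus is in the desert stratum when any window it overlaps is a
    desert.  Reports group means/SDs and a two-sample KS test.
    """
    desert_mask = deserts.mask(grid.n_windows)
    het_in, het_out = [], []
    for locus in loci:
        widx = grid.overlapping_windows(locus.chrom, locus.start, locus.end)
        in_desert = bool(desert_mask[widx].any()) if len(widx) else False
        (het_in if in_desert else het_out).append(locus.het)
    if not het_in or not het_out:
        import warnings

        warnings.warn("empty heterozygosity stratum: comparison skipped")
        return StratumComparison(
            float("nan"), float("nan"), len(het_in),
            float("nan"), float("nan"), len(het_out),
            float("nan"), float("nan"), skipped=True,
        )
    het_in = np.asarray(het_in)
    het_out = np.asarray(het_out)
    ks = stats.ks_2samp(het_in, het_out)
    return StratumComparison(
        float(het_in.mean()), float(het_in.std(ddof=1)) if len(het_in) > 1 else 0.0,
        len(het_in),
        float(het_out.mean()), float(het_out.std(ddof=1)) if len(het_out) > 1 else 0.0,
        len(het_out),
        float(ks.statistic), float(ks.pvalue),
    )
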