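"""Germline methylation index (MI) from CpG-transition SNPs.

Methylated cytosines deaminate to thymine at elevated rates, so CpG sites
that were methylated in the germline over evolutionary time accumulate C->T
(or, on the other strand, G->A) polymorphisms whose ancestral allele is the
CpG base.  Such SNPs are "mSNPs".  Per window, the observed mSNP count is
normalized by N_CpG * N_SNP — proportional to the expected mSNP count under
genome-uniform methylation — and rescaled so the genome-wide mean index is 1.
MI = 0 marks windows with no mSNP at all: candidate germline hypomethylation
independent of any sperm methylome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import WindowGrid

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class WindowMI:
    grid: WindowGrid
    n_snp: np.ndarray
    n_cpg: np.ndarray
    n_msnp: np.ndarray
    mi: np.ndarray       # normalized index, NaN where invalid
    valid: np.ndarray
    n_unclassifiable: int = 0  # SNPs lacking flanking context


def classify_msnp(ref: str, alt: str, ancestral: str, prev_base: str, next_base: str) -> bool:
    """True iff the SNP is a CpG-transition with the ancestral CpG allele.

    C/T within CpG (next base G) with ancestral C, or G/A within CpG on the
    reverse strand (previous base C) with ancestral G.  Unknown ancestral
    allele or missing context is never an mSNP.
    """
    alleles = {ref.upper(), alt.upper()}
    ancestral = ancestral.upper()
    if alleles == {"C", "T"} and ancestral == "C":
        return next_base.upper() == "G"
    if alleles == {"G", "A"} and ancestral == "G":
        return prev_base.upper() == "C"
    return False


def _seq_of(genome, chrom: str) -> str:
    seq = genome[chrom]
    return seq if isinstance(seq, str) else str(seq[:])


def count_cpg(seq: str) -> int:
    """CpG dinucleotides counted once (not per cytosine); gap bases never match."""
    return seq.upper().count("CG")


def compute_mi(grid: WindowGrid, snps: pd.DataFrame, genome) -> WindowMI:
    """Per-window MI from a SNP table (chrom, pos, ref, alt, ancestral).

    ``genome`` maps chromosome name to sequence (str or pyfaidx record).
    Windows with no SNP are invalid; N_CpG = 0 with N_SNP > 0 yields MI = 0
    when no mSNP is observed and an invalid flag otherwise (an mSNP without a
    reference CpG is an annotation inconsistency, not a signal).
    """
    n_snp = np.zeros(grid.n_windows, dtype=np.int64)
    n_msnp = np.zeros(grid.n_windows, dtype=np.int64)
    n_cpg = np.zeros(grid.n_windows, dtype=np.int64)
    n_unclassifiable = 0

    for chrom in grid.chrom_sizes:
        if chrom not in grid._chrom_offsets:
            continue
        seq = _seq_of(genome, chrom).upper()
        lo, hi = grid.window_range(chrom)
        ws = grid.window_size
        for w in range(lo, hi):
            s = (w - lo) * ws
            # a CpG straddling the window boundary belongs to the window of
            # its cytosine, hence the end bound of s + ws + 1
            n_cpg[w] = seq.count("CG", s, s + ws + 1)

    if len(snps) == 0:
        valid = np.zeros(grid.n_windows, dtype=bool)
        mi = np.full(grid.n_windows, np.nan)
        warnings.warn("empty SNP set: all windows invalid")
        return WindowMI(grid, n_snp, n_cpg, n_msnp, mi, valid)

    for chrom, sub in snps.groupby("chrom", sort=False):
        if chrom not in grid._chrom_offsets:
            continue
        seq = _seq_of(genome, chrom).upper()
        pos = sub["pos"].to_numpy()
        widx = grid.window_of_positions(chrom, pos)
        inside = widx >= 0
        np.add.at(n_snp, widx[inside], 1)
        for p, w, ref, alt, anc in zip(
            pos, widx, sub["ref"], sub["alt"], sub["ancestral"]
        ):
            if w < 0:
                continue
            if p - 1 < 0 or p + 1 >= len(seq):
                n_unclassifiable += 1
                continue
            if classify_msnp(ref, alt, anc, seq[p - 1], seq[p + 1]):
                n_msnp[w] += 1

    valid = n_snp > 0
    bad = valid & (n_cpg == 0) & (n_msnp > 0)
    valid &= ~bad
    raw = np.full(grid.n_windows, np.nan)
    ok = valid & (n_cpg > 0)
    raw[ok] = n_msnp[ok] / (n_cpg[ok] * n_snp[ok]).astype(float)
    raw[valid & (n_cpg == 0)] = 0.0  # no CpG, no mSNP: zero by definition
    mean_raw = np.nanmean(raw[valid])
    mi = np.full(grid.n_windows, np.nan)
    if mean_raw > 0:
        mi[valid] = raw[valid] / mean_raw
    else:
        mi[valid] = 0.0
    return WindowMI(grid, n_snp, n_cpg, n_msnp, mi, valid, n_unclassifiable)
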