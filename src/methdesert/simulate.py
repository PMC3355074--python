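"""Synthetic genomes, methylomes, SNP tables, and CNV cohorts with planted truth.

Every pipeline stage is exercised against data with known structure: genomes
carry planted segmental duplications of controlled size, identity,
separation, and orientation; window methylomes have a designated desert
fraction and binomial per-CpG bisulfite sampling; SNP tables implement the
methylation-index premise (CpG-transition probability proportional to local
methylation); element sets are placed with a controlled desert-enrichment
fold; CNV cohorts have known per-locus allele frequencies, trio structure,
and a planted fraction of NAHR-type whole-region events.

Background sequence is i.i.d. at the configured GC content — no realistic
repeat landscape.  All sampling flows from the mandatory seed, so any
(config, seed) pair regenerates identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hetero import Pedigree
from .intervals import WindowGrid, merge_intervals
from .lcr import reverse_complement

_BASES = np.array(list("ACGT"))
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(enc: np.ndarray) -> str:
    return _BASE_BYTES[enc].tobytes().decode("ascii")


@dataclass(frozen=True)
class DuplicationSpec:
    size: int
    identity: float             # 1 - substitution rate applied to the copy
    separation: int             # unique bases between source end and copy start
    orientation: str = "direct"


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline inputs.

    Coverage defaults to ~800 CpG sampling events per 100 kb window,
    matching low-coverage (2.5x) whole-genome bisulfite sperm data; the
    desert fraction (1%) and low desert methylation against a
    high-methylation beta background reflect the sperm methylome's bimodal
    character.
    """

    seed: int
    chrom_sizes: dict = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 1_000_000}
    )
    gc_content: float = 0.41
    duplications: tuple = ()
    window_size: int = 100_000
    desert_fraction: float = 0.01
    desert_level: float = 0.03
    background_beta: tuple = (6.0, 2.0)       # mean 0.75
    mean_events_per_window: float = 787.0
    cpg_density: float = 0.01                 # used when no genome is supplied
    snp_slope: float = 0.05                   # per-CpG mSNP probability per unit methylation
    background_snp_rate: float = 5e-4         # per non-CpG base
    n_elements: int = 500
    element_size: int = 10_000
    desert_fold: float = 1.0
    n_samples: int = 200
    n_trios: int = 0
    n_loci: int = 100
    locus_q_range: tuple = (0.05, 0.3)
    nahr_fraction: float = 0.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class TruthSet:
    duplication_pairs: list = field(default_factory=list)  # (spec, seg_a, seg_b)
    expected_dp_regions: pd.DataFrame = None
    desert_windows: np.ndarray = None
    true_methylation: np.ndarray = None
    elements: pd.DataFrame = None
    locus_q: np.ndarray = None
    loci: pd.DataFrame = None


def lcr_benchmark_config(seed: int) -> SimConfig:
    """Canonical 20 Mbp LCR-detection benchmark.

    Four chromosomes (8/6/4/2 Mb) carrying 12 direct duplication pairs that
    meet the DP-LCR criteria (10-50 kb, identity 0.95-0.99, separation
    0.1-8 Mb), 6 inverted pairs, and 6 sub-threshold pairs (identity < 0.90
    or size < 10 kb) that must yield no DP-LCR region.  Separations are
    log-uniform, clipped to what fits the hosting chromosome.
    """
    rng = np.random.default_rng(seed)
    chrom_sizes = {"chr1": 8_000_000, "chr2": 6_000_000, "chr3": 4_000_000, "chr4": 2_000_000}
    max_size = max(chrom_sizes.values())
    dups = []

    def sep_for(size, lo=1e5, hi=None):
        hi = hi or (max_size - 2 * size - 5_000)
        return int(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    for _ in range(12):  # qualifying direct pairs
        size = int(rng.integers(10_000, 50_001))
        dups.append(
            DuplicationSpec(size, float(rng.uniform(0.95, 0.99)), sep_for(size))
        )
    for _ in range(6):   # inverted pairs, otherwise qualifying
        size = int(rng.integers(10_000, 50_001))
        dups.append(
            DuplicationSpec(
                size, float(rng.uniform(0.95, 0.99)), sep_for(size, hi=1.5e6), "inverted"
            )
        )
    for i in range(6):   # sub-threshold: low identity or too small
        if i % 2 == 0:
            size = int(rng.integers(10_000, 30_001))
            ident = float(rng.uniform(0.80, 0.88))
        else:
            size = int(rng.integers(3_000, 9_000))
            ident = float(rng.uniform(0.95, 0.99))
        dups.append(DuplicationSpec(size, ident, sep_for(size, hi=1.5e6)))

    # place large spans first so the big separations find room
    dups.sort(key=lambda d: 2 * d.size + d.separation, reverse=True)
    return SimConfig(seed=seed, chrom_sizes=chrom_sizes, duplications=tuple(dups))


def _random_sequence(rng, length: int, gc: float) -> np.ndarray:
    return rng.choice(4, size=length, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _mutate(rng, enc: np.ndarray, rate: float) -> np.ndarray:
    out = enc.copy()
    hit = np.flatnonzero(rng.random(len(enc)) < rate)
    # substitute with a uniformly random *different* base
    out[hit] = (out[hit] + rng.integers(1, 4, size=len(hit))) % 4
    return out


def simulate_genome(cfg: SimConfig, rng=None):
    """i.i.d. background sequence with planted duplication pairs.

    Each duplication copies a source segment, applies uniform substitutions
    at rate ``1 - identity``, reverse-complements if inverted, and inserts
    the copy ``separation`` bases downstream.  Raises when a spec cannot be
    placed without overlapping previously planted segments.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    enc = {c: _random_sequence(rng, n, cfg.gc_content) for c, n in cfg.chrom_sizes.items()}
    occupied = {c: [] for c in cfg.chrom_sizes}
    margin = 1000
    truth = TruthSet()

    def conflict(chrom, s, e):
        return any(s < oe + margin and os - margin < e for os, oe in occupied[chrom])

    for spec in cfg.duplications:
        placed = False
        for _ in range(200):
            feasible = [
                c
                for c, n in cfg.chrom_sizes.items()
                if n > 2 * spec.size + spec.separation + 2 * margin
            ]
            if not feasible:
                break
            chrom = feasible[rng.integers(len(feasible))]
            span = 2 * spec.size + spec.separation
            start = int(rng.integers(margin, cfg.chrom_sizes[chrom] - span - margin))
            copy_start = start + spec.size + spec.separation
            if conflict(chrom, start, start + spec.size) or conflict(
                chrom, copy_start, copy_start + spec.size
            ):
                continue
            src = enc[chrom][start : start + spec.size]
            copy = _mutate(rng, src, 1.0 - spec.identity)
            if spec.orientation == "inverted":
                copy = (3 - copy)[::-1]
            enc[chrom][copy_start : copy_start + spec.size] = copy
            occupied[chrom].extend(
                [(start, start + spec.size), (copy_start, copy_start + spec.size)]
            )
            truth.duplication_pairs.append(
                (
                    spec,
                    (chrom, start, start + spec.size),
                    (chrom, copy_start, copy_start + spec.size),
                )
            )
            placed = True
            break
        if not placed:
            raise ValueError(f"cannot place duplication {spec} without overlap")

    regions = [
        (a[0], a[2], b[1])
        for spec, a, b in truth.duplication_pairs
        if spec.orientation == "direct"
        and spec.size >= 10_000
        and spec.identity >= 0.95
        and 0 < spec.separation < 10_000_000
    ]
    truth.expected_dp_regions = (
        merge_intervals(pd.DataFrame(regions, columns=["chrom", "start", "end"]))
        if regions
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    genome = {c: _decode(v) for c, v in enc.items()}
    return genome, truth


def simulate_methylome_truth(cfg: SimConfig, grid: WindowGrid, rng):
    """Planted per-window methylation with a designated desert fraction."""
    rng = np.random.default_rng(rng)
    level = rng.beta(*cfg.background_beta, size=grid.n_windows)
    eligible = np.flatnonzero(~grid.excluded)
    n_desert = max(1, int(round(cfg.desert_fraction * len(eligible))))
    desert = rng.choice(eligible, size=n_desert, replace=False)
    level[desert] = cfg.desert_level
    return level, np.sort(desert)


def plant_halos(
    true_level: np.ndarray,
    grid: WindowGrid,
    elements: pd.DataFrame,
    halo: int,
    level: float,
) -> np.ndarray:
    """Lower methylation in windows within ``halo`` bases of any element."""
    out = true_level.copy()
    for chrom, s, e in zip(elements["chrom"], elements["start"], elements["end"]):
        widx = grid.overlapping_windows(
            chrom, max(0, s - halo), min(grid.chrom_sizes[chrom], e + halo)
        )
        out[widx] = level
    return out


def _cpg_positions(cfg: SimConfig, grid: WindowGrid, genome, rng):
    """(chrom, pos) of CpG cytosines; synthetic uniform sites if no genome."""
    chroms, positions = [], []
    if genome is not None:
        for chrom, seq in genome.items():
            seq = seq if isinstance(seq, str) else str(seq[:])
            arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
            pos = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
            chroms.append(np.full(len(pos), chrom, dtype=object))
            positions.append(pos)
    else:
        for chrom, size in grid.chrom_sizes.items():
            n = int(cfg.cpg_density * size)
            pos = np.sort(rng.choice(size - 1, size=n, replace=False))
            chroms.append(np.full(n, chrom, dtype=object))
            positions.append(pos)
    return (
        np.concatenate(chroms) if chroms else np.empty(0, dtype=object),
        np.concatenate(positions) if positions else np.empty(0, dtype=np.int64),
    )


def simulate_methylome_and_obs(cfg: SimConfig, grid: WindowGrid, genome=None, rng=None):
    """Planted window methylation plus binomial per-CpG bisulfite sampling.

    Per CpG, sampling events are Poisson with mean chosen so a window
    averages ``mean_events_per_window`` events; methylated events are
    binomial at the window's true level.  Returns (true_level,
    desert_window_indices, observations).
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    true_level, desert = simulate_methylome_truth(cfg, grid, rng)
    chroms, positions = _cpg_positions(cfg, grid, genome, rng)

    widx = np.full(len(positions), -1, dtype=np.int64)
    for chrom in grid.chrom_sizes:
        m = chroms == chrom
        if m.any():
            widx[m] = grid.window_of_positions(chrom, positions[m])
    inside = widx >= 0
    chroms, positions, widx = chroms[inside], positions[inside], widx[inside]

    cpg_per_window = np.bincount(widx, minlength=grid.n_windows)
    lam = np.where(
        cpg_per_window[widx] > 0,
        cfg.mean_events_per_window / np.maximum(cpg_per_window[widx], 1),
        0.0,
    )
    n_total = rng.poisson(lam)
    keep = n_total > 0
    n_meth = rng.binomial(n_total[keep], true_level[widx[keep]])
    obs = pd.DataFrame(
        {
            "chrom": chroms[keep],
            "pos": positions[keep],
            "n_meth": n_meth,
            "n_total": n_total[keep],
        }
    )
    return true_level, desert, obs


def simulate_snps(cfg: SimConfig, grid: WindowGrid, genome, true_methylation, rng=None):
    """SNP table implementing the methylation-index premise.

    Each CpG becomes an mSNP (C/T ancestral C, or G/A ancestral G; strand
    uniform) with probability ``snp_slope * window methylation``; background
    SNPs land on non-CpG bases at ``background_snp_rate`` with ancestral =
    reference (never mSNPs).
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    rows = []
    for chrom, seq in genome.items():
        seq = (seq if isinstance(seq, str) else str(seq[:])).upper()
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        cpg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        widx = grid.window_of_positions(chrom, cpg)
        inside = widx >= 0
        cpg, widx = cpg[inside], widx[inside]
        meth = np.nan_to_num(true_methylation[widx])
        hit = rng.random(len(cpg)) < cfg.snp_slope * meth
        strand_g = rng.random(int(hit.sum())) < 0.5
        for p, on_g in zip(cpg[hit], strand_g):
            if on_g:
                rows.append((chrom, int(p) + 1, "G", "A", "G"))
            else:
                rows.append((chrom, int(p), "C", "T", "C"))
        # background SNPs outside CpG dinucleotides
        in_cpg = np.zeros(len(arr), dtype=bool)
        all_cpg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        in_cpg[all_cpg] = True
        in_cpg[all_cpg + 1] = True
        candidates = np.flatnonzero(~in_cpg)
        n_bg = rng.binomial(len(candidates), cfg.background_snp_rate)
        bg = rng.choice(candidates, size=n_bg, replace=False)
        for p in bg:
            ref = chr(arr[p])
            if ref not in "ACGT":
                continue
            alt = rng.choice([b for b in "ACGT" if b != ref])
            rows.append((chrom, int(p), ref, str(alt), ref))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "ancestral"])
    return df.sort_values(["chrom", "pos"], ignore_index=True)


def desert_placement_probability(fold: float, desert_fraction: float) -> float:
    """Placement probability giving a desert odds-enrichment of ``fold``."""
    f = desert_fraction
    return fold * f / (1 - f + fold * f)


def simulate_elements(cfg: SimConfig, grid: WindowGrid, desert_windows, rng=None):
    """Elements placed with a controlled desert enrichment.

    Each element lands inside a uniformly chosen desert window with
    probability pi = F*f / (1 - f + F*f) (F = ``desert_fold``, f = desert
    window fraction), else inside a uniformly chosen non-desert window.
    """
    if cfg.desert_fold < 1:
        raise ValueError("desert_fold must be >= 1")
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    eligible = np.flatnonzero(~grid.excluded)
    desert_windows = np.asarray(desert_windows)
    non_desert = np.setdiff1d(eligible, desert_windows)
    f = len(desert_windows) / len(eligible)
    pi = desert_placement_probability(cfg.desert_fold, f)
    size = min(cfg.element_size, grid.window_size)
    rows = []
    for _ in range(cfg.n_elements):
        in_desert = rng.random() < pi and len(desert_windows) > 0
        pool = desert_windows if in_desert else non_desert
        w = pool[rng.integers(len(pool))]
        start = int(grid.start[w] + rng.integers(grid.window_size - size + 1))
        rows.append((grid.chrom[w], start, start + size, bool(in_desert)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "in_desert"])


def simulate_cnv_cohort(cfg: SimConfig, dp_regions: pd.DataFrame, chrom_sizes, rng=None):
    """CNV cohort with planted allele frequencies, trios, and NAHR loci.

    A ``nahr_fraction`` of loci are whole-region events strictly inside a
    DP-LCR region (covering 60-95% of it); the rest are scattered intervals
    placed uniformly.  Each unrelated sample carries a locus variant with
    its planted q; trio parents likewise, children inherit each parental
    variant with probability 1/2.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    if cfg.n_samples < 2:
        raise ValueError("need at least two samples")

    samples, ped_rows = [], []
    for i in range(cfg.n_trios):
        for role in ("father", "mother", "child"):
            sid = f"T{i}_{role}"
            samples.append(sid)
            ped_rows.append((sid, f"fam{i}", role))
    n_unrelated = cfg.n_samples - 3 * cfg.n_trios
    for i in range(n_unrelated):
        samples.append(f"S{i}")
    pedigree = Pedigree.from_frame(
        pd.DataFrame(ped_rows, columns=["sample", "family", "role"])
        if ped_rows
        else pd.DataFrame(columns=["sample", "family", "role"])
    )

    n_nahr = int(round(cfg.nahr_fraction * cfg.n_loci))
    loci = []
    q = rng.uniform(*cfg.locus_q_range, size=cfg.n_loci)
    dp = dp_regions.reset_index(drop=True) if dp_regions is not None else pd.DataFrame()
    for i in range(cfg.n_loci):
        if i < n_nahr and len(dp):
            r = dp.iloc[int(rng.integers(len(dp)))]
            span = r["end"] - r["start"]
            frac = rng.uniform(0.6, 0.95)
            length = max(1, int(frac * span))
            lo = int(r["start"] + rng.integers(max(1, span - length)))
            loci.append((r["chrom"], lo, lo + length, True))
        else:
            chrom = list(chrom_sizes)[int(rng.integers(len(chrom_sizes)))]
            length = int(rng.integers(5_000, 50_000))
            lo = int(rng.integers(max(1, chrom_sizes[chrom] - length)))
            loci.append((chrom, lo, lo + length, False))
    loci_df = pd.DataFrame(loci, columns=["chrom", "start", "end", "nahr_type"])

    calls = []
    for i, row in loci_df.iterrows():
        state = "loss" if rng.random() < 0.5 else "gain"
        carriers = set()
        for t in range(cfg.n_trios):
            father = rng.random() < q[i]
            mother = rng.random() < q[i]
            child = (father and rng.random() < 0.5) or (mother and rng.random() < 0.5)
            if father:
                carriers.add(f"T{t}_father")
            if mother:
                carriers.add(f"T{t}_mother")
            if child:
                carriers.add(f"T{t}_child")
        for s in range(n_unrelated):
            if rng.random() < q[i]:
                carriers.add(f"S{s}")
        for sid in sorted(carriers):
            calls.append((row["chrom"], row["start"], row["end"], sid, state))
    calls_df = pd.DataFrame(calls, columns=["chrom", "start", "end", "sample", "state"])
    truth = TruthSet(locus_q=q, loci=loci_df)
    return calls_df, pedigree, truth
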