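"""Low-copy repeat (segmental duplication) detection by k-mer self-comparison.

The genome is cut into consecutive 500 bp fragments and every fragment is
compared against every other (both strands) through a gapped-pattern k-mer
index: a 21 bp sampling pattern reading 13 positions, tolerant of point
mismatches.  k-mers over-represented in high copy-number repeats (LINEs,
SINEs, microsatellites) are blacklisted first so the self-comparison sees
segmental duplications rather than the interspersed repeat background.

Fragment matches are reciprocally filtered (top-50, list cap 1000), chained
into pairwise LCR blocks along consistent diagonals, clustered into paralog
families by k-mer content and positional overlap, and finally reduced to the
NAHR-susceptible regions between directly-oriented paralogous LCRs
(DP-LCRs: >=10 kb members, >=95% identity, <10 Mb apart on one chromosome).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .intervals import merge_intervals

# Default gapped sampling pattern: 13 sampled offsets at the two ends of a
# 21 bp pattern, 8 unsampled in the middle.  A config constant so runs are
# reproducible; any 13-of-21 layout is accepted.
DEFAULT_OFFSETS = (0, 1, 2, 3, 4, 5, 6, 15, 16, 17, 18, 19, 20)

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i
    _BASE_CODE[ord(b.lower())] = i


@dataclass(frozen=True)
class KmerScheme:
    pattern_length: int = 21
    k: int = 13
    sampled_offsets: tuple = DEFAULT_OFFSETS
    fragment_length: int = 500

    def __post_init__(self):
        if len(self.sampled_offsets) != self.k:
            raise ValueError("sampled_offsets must list exactly k offsets")
        if max(self.sampled_offsets) >= self.pattern_length:
            raise ValueError("sampled offset beyond pattern length")


@dataclass
class KmerBlacklist:
    excluded: np.ndarray          # sorted uint64 codes
    fdr_threshold: float = 0.1
    hcr_min_freq: int = 10

    def contains(self, codes: np.ndarray) -> np.ndarray:
        if len(self.excluded) == 0:
            return np.zeros(len(codes), dtype=bool)
        idx = np.searchsorted(self.excluded, codes)
        idx = np.minimum(idx, len(self.excluded) - 1)
        return self.excluded[idx] == codes


@dataclass
class Segment:
    chrom: str
    start: int
    end: int

    def __len__(self):
        return self.end - self.start

    def overlaps(self, other: "Segment") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class PairwiseLCR:
    a: Segment
    b: Segment
    orientation: str            # "direct" | "inverted"
    score: float                # summed shared-kmer score
    density: float              # score / side-A block length
    identity: float = np.nan
    kmer_profile: frozenset = None  # k-mer codes over both member segments

    @property
    def size(self) -> int:
        return len(self.a) + len(self.b)


@dataclass
class LCRCluster:
    pairs: list                 # retained PairwiseLCR members
    members: list = field(default_factory=list)  # Segment list after filtering


@dataclass
class FragmentIndex:
    """Consecutive fixed-length fragments over a genome, globally numbered."""

    fragment_length: int
    chroms: list
    chrom_sizes: dict
    offsets: dict               # chrom -> (first global frag id, count)
    n_fragments: int

    @classmethod
    def build(cls, chrom_sizes: dict, fragment_length: int) -> "FragmentIndex":
        offsets, total = {}, 0
        chroms = list(chrom_sizes)
        for c in chroms:
            n = chrom_sizes[c] // fragment_length
            offsets[c] = (total, n)
            total += n
        return cls(fragment_length, chroms, dict(chrom_sizes), offsets, total)

    def locate(self, frag_ids: np.ndarray):
        """(chrom, start) per global fragment id."""
        chrom = np.empty(len(frag_ids), dtype=object)
        start = np.empty(len(frag_ids), dtype=np.int64)
        for c, (first, n) in self.offsets.items():
            m = (frag_ids >= first) & (frag_ids < first + n)
            chrom[m] = c
            start[m] = (frag_ids[m] - first) * self.fragment_length
        return chrom, start


def encode_sequence(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _genome_items(genome):
    for chrom, seq in genome.items():
        yield chrom, (seq if isinstance(seq, str) else str(seq[:]))


def pattern_kmer_codes(enc: np.ndarray, scheme: KmerScheme):
    """Forward and reverse-complement k-mer codes at every valid placement.

    Returns ``(positions, fwd_codes, rc_codes)``; placements whose sampled
    bases include an N are dropped (never hashed).  The reverse-complement
    code is the code the pattern would produce reading the minus strand of
    the same 21 bp placement.
    """
    L = len(enc)
    p = scheme.pattern_length
    if L < p:
        e = np.empty(0, dtype=np.int64)
        return e, np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.uint64)
    n = L - p + 1
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    ok = np.ones(n, dtype=bool)
    # mirror layout: sampling offset o forward corresponds to offset
    # p - 1 - o on the reverse strand; complement base = 3 - base
    for i, off in enumerate(scheme.sampled_offsets):
        bases = enc[off : off + n]
        ok &= bases < 4
        fwd |= bases.astype(np.uint64) << np.uint64(2 * i)
    for i, off in enumerate(scheme.sampled_offsets):
        mirror = enc[p - 1 - off : p - 1 - off + n]
        ok &= mirror < 4
        rc |= (3 - np.minimum(mirror, 3)).astype(np.uint64) << np.uint64(2 * i)
    pos = np.flatnonzero(ok)
    return pos, fwd[pos], rc[pos]


def _chi2_2x2(a, b, c, d):
    """Vectorized Pearson chi-square (no continuity correction) for [[a,b],[c,d]]."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(den > 0, num / den, 0.0)
    return chi2, stats.chi2.sf(chi2, df=1)


def build_blacklist(
    genome,
    repeats,
    scheme: KmerScheme = KmerScheme(),
    hcr_min_freq: int = 10,
    fdr_threshold: float = 0.1,
) -> KmerBlacklist:
    """Blacklist k-mers over-represented in high copy-number repeats (HCRs).

    Candidates are k-mers with frequency > ``hcr_min_freq`` inside the HCR
    annotation; each is tested by a 2x2 chi-square of its HCR vs non-HCR
    counts against HCR vs non-HCR base totals, Benjamini-Hochberg corrected
    at ``fdr_threshold``; significantly enriched k-mers are excluded.
    """
    if repeats is None or len(repeats) == 0:
        warnings.warn("empty repeat annotation: blacklist is empty")
        return KmerBlacklist(np.empty(0, dtype=np.uint64), fdr_threshold, hcr_min_freq)
    rep = repeats if isinstance(repeats, pd.DataFrame) else pd.DataFrame(
        list(repeats), columns=["chrom", "start", "end"]
    )
    hcr_codes, all_codes = [], []
    hcr_bases = 0
    total_bases = 0
    for chrom, seq in _genome_items(genome):
        enc = encode_sequence(seq)
        pos, fwd, _ = pattern_kmer_codes(enc, scheme)
        mask = np.zeros(len(enc), dtype=bool)
        sub = rep[rep["chrom"] == chrom]
        for s, e in zip(sub["start"], sub["end"]):
            mask[s:e] = True
        hcr_bases += int(mask.sum())
        total_bases += len(enc)
        in_hcr = mask[pos]  # placement assigned by its start base
        hcr_codes.append(fwd[in_hcr])
        all_codes.append(fwd)
    hcr_codes = np.concatenate(hcr_codes) if hcr_codes else np.empty(0, np.uint64)
    all_codes = np.concatenate(all_codes) if all_codes else np.empty(0, np.uint64)
    if len(hcr_codes) == 0:
        return KmerBlacklist(np.empty(0, dtype=np.uint64), fdr_threshold, hcr_min_freq)

    cand, cand_hcr = np.unique(hcr_codes, return_counts=True)
    keep = cand_hcr > hcr_min_freq
    cand, cand_hcr = cand[keep], cand_hcr[keep]
    if len(cand) == 0:
        return KmerBlacklist(np.empty(0, dtype=np.uint64), fdr_threshold, hcr_min_freq)
    all_sorted = np.sort(all_codes)
    total_count = (
        np.searchsorted(all_sorted, cand, side="right")
        - np.searchsorted(all_sorted, cand, side="left")
    )
    out_count = total_count - cand_hcr
    out_bases = total_bases - hcr_bases
    chi2, p = _chi2_2x2(cand_hcr, out_count, hcr_bases - cand_hcr, out_bases - out_count)
    q = stats.false_discovery_control(p)
    enriched = (cand_hcr / max(hcr_bases, 1)) > (out_count / max(out_bases, 1))
    excluded = cand[(q < fdr_threshold) & enriched]
    return KmerBlacklist(np.sort(excluded), fdr_threshold, hcr_min_freq)


def _pairs_from_runs(codes: np.ndarray, frags: np.ndarray, flags: np.ndarray,
                     max_occ: int):
    """Emit fragment pairs sharing a code.

    ``flags`` is 0 for forward-strand placements, 1 for reverse-complement
    reads.  A (0,0) pairing is a direct match; (0,1) is inverted.  Ordered
    inverted pairings arise twice per shared placement pair, hence their
    final counts are halved by the caller.
    """
    order = np.argsort(codes, kind="stable")
    codes, frags, flags = codes[order], frags[order], flags[order]
    boundary = np.flatnonzero(np.diff(codes) != 0) + 1
    starts = np.concatenate(([0], boundary))
    ends = np.concatenate((boundary, [len(codes)]))
    lens = ends - starts

    direct_a, direct_b, inv_a, inv_b = [], [], [], []

    # vectorize by run length: all runs of one length processed as a matrix
    for L in np.unique(lens):
        if L < 2 or L > max_occ:
            continue
        run_starts = starts[lens == L]
        idx = run_starts[:, None] + np.arange(L)[None, :]  # (R, L)
        f = frags[idx]
        g = flags[idx]
        ii, jj = np.triu_indices(L, k=1)
        fa, fb = f[:, ii].ravel(), f[:, jj].ravel()
        ga, gb = g[:, ii].ravel(), g[:, jj].ravel()
        diff_frag = fa != fb
        dmask = (ga == 0) & (gb == 0) & diff_frag
        direct_a.append(np.minimum(fa[dmask], fb[dmask]))
        direct_b.append(np.maximum(fa[dmask], fb[dmask]))
        imask = (ga != gb) & diff_frag
        inv_a.append(np.minimum(fa[imask], fb[imask]))
        inv_b.append(np.maximum(fa[imask], fb[imask]))

    def cat(parts):
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)

    return (cat(direct_a), cat(direct_b)), (cat(inv_a), cat(inv_b))


def self_compare(
    genome,
    scheme: KmerScheme = KmerScheme(),
    blacklist: KmerBlacklist = None,
    min_score: int = 10,
    max_kmer_occurrence: int = 100,
) -> tuple[pd.DataFrame, FragmentIndex]:
    """All-vs-all fragment comparison via the gapped-pattern k-mer index.

    Returns a match table (frag_a < frag_b, orientation, score = count of
    shared sampled k-mers) and the fragment index.  Self-pairs are
    suppressed; k-mers occurring more than ``max_kmer_occurrence`` times
    genome-wide are skipped (they carry no positional information and the
    blacklist should already cover them).
    """
    chrom_sizes = {c: len(s) for c, s in _genome_items(genome)}
    frag_index = FragmentIndex.build(chrom_sizes, scheme.fragment_length)

    code_parts, frag_parts, flag_parts = [], [], []
    for chrom, seq in _genome_items(genome):
        first, nfrag = frag_index.offsets[chrom]
        if nfrag == 0:
            continue
        enc = encode_sequence(seq)
        pos, fwd, rc = pattern_kmer_codes(enc, scheme)
        frag = pos // scheme.fragment_length
        within = (pos % scheme.fragment_length) <= (
            scheme.fragment_length - scheme.pattern_length
        )
        keep = within & (frag < nfrag)
        pos, fwd, rc, frag = pos[keep], fwd[keep], rc[keep], frag[keep]
        if blacklist is not None:
            bad = blacklist.contains(fwd) | blacklist.contains(rc)
            fwd, rc, frag = fwd[~bad], rc[~bad], frag[~bad]
        gfrag = (frag + first).astype(np.int64)
        code_parts.extend([fwd, rc])
        frag_parts.extend([gfrag, gfrag])
        flag_parts.extend(
            [np.zeros(len(gfrag), dtype=np.int8), np.ones(len(gfrag), dtype=np.int8)]
        )

    codes = np.concatenate(code_parts) if code_parts else np.empty(0, np.uint64)
    frags = np.concatenate(frag_parts) if frag_parts else np.empty(0, np.int64)
    flags = np.concatenate(flag_parts) if flag_parts else np.empty(0, np.int8)

    (da, db), (ia, ib) = _pairs_from_runs(codes, frags, flags, max_kmer_occurrence)

    nf = np.int64(frag_index.n_fragments)
    rows = []
    for (pa, pb), orient, divisor in (((da, db), "direct", 1), ((ia, ib), "inverted", 2)):
        if len(pa) == 0:
            continue
        key = pa * nf + pb
        uniq, counts = np.unique(key, return_counts=True)
        score = counts / divisor
        keep = score >= min_score
        uniq, score = uniq[keep], score[keep]
        rows.append(
            pd.DataFrame(
                {
                    "frag_a": (uniq // nf).astype(np.int64),
                    "frag_b": (uniq % nf).astype(np.int64),
                    "orientation": orient,
                    "score": score,
                }
            )
        )
    matches = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["frag_a", "frag_b", "orientation", "score"])
    )
    matches = matches.sort_values(
        ["frag_a", "frag_b", "orientation"], ignore_index=True
    )
    return matches, frag_index


def reciprocal_filter(
    matches: pd.DataFrame, top_n: int = 50, max_list: int = 1000
) -> pd.DataFrame:
    """Keep (a, b) iff each appears in the other's top-``top_n`` match list.

    A fragment's match list pools both orientations.  Fragments with more
    than ``max_list`` matches are dropped wholesale (tandem-repeat hubs).
    Ties at rank ``top_n`` break by (score desc, partner coordinate asc).
    """
    if matches.empty:
        return matches.copy()
    fwd = matches[["frag_a", "frag_b", "score"]].to_numpy()
    both = np.concatenate([fwd, fwd[:, [1, 0, 2]]])
    owner, partner, score = both[:, 0], both[:, 1], both[:, 2]
    order = np.lexsort((partner, -score, owner))
    owner, partner = owner[order], partner[order]
    first = np.concatenate(([True], owner[1:] != owner[:-1]))
    group_start = np.flatnonzero(first)
    sizes = np.diff(np.concatenate((group_start, [len(owner)])))
    rank = np.arange(len(owner)) - np.repeat(group_start, sizes)
    list_size = np.repeat(sizes, sizes)
    good = (rank < top_n) & (list_size <= max_list)
    ok_pairs = set(zip(owner[good].astype(int), partner[good].astype(int)))
    keep = [
        (int(a), int(b)) in ok_pairs and (int(b), int(a)) in ok_pairs
        for a, b in zip(matches["frag_a"], matches["frag_b"])
    ]
    return matches[np.asarray(keep, dtype=bool)].reset_index(drop=True)


def merge_fragments(
    matches: pd.DataFrame,
    frag_index: FragmentIndex,
    max_span: int = 1000,
    max_radius: int = 250,
    min_density: float = 0.05,
) -> list:
    """Chain co-oriented fragment matches into pairwise LCR blocks.

    Consecutive matches merge when the side-A step is < ``max_span`` and the
    partner step deviates from the diagonal (anti-diagonal when inverted) by
    <= ``max_radius``.  A block survives when total score / side-A block
    length exceeds ``min_density``.
    """
    if matches.empty:
        return []
    L = frag_index.fragment_length
    chrom_a, start_a = frag_index.locate(matches["frag_a"].to_numpy())
    chrom_b, start_b = frag_index.locate(matches["frag_b"].to_numpy())
    df = matches.assign(
        chrom_a=chrom_a, start_a=start_a, chrom_b=chrom_b, start_b=start_b
    )
    # fragment starts quantize true partner positions to the fragment grid,
    # so a single duplication populates up to two adjacent diagonals; the
    # radius tolerance is therefore widened by one fragment length
    diag_tol = max_radius + L
    out = []
    for (ca, cb, orient), sub in df.groupby(
        ["chrom_a", "chrom_b", "orientation"], sort=True
    ):
        sub = sub.sort_values(["start_a", "start_b"])
        sa = sub["start_a"].to_numpy()
        sb = sub["start_b"].to_numpy()
        sc = sub["score"].to_numpy()
        diag = sb - sa if orient == "direct" else sb + sa
        n = len(sub)
        parent = np.arange(n)

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        # connect matches close on side A and on the same diagonal band
        hi = np.searchsorted(sa, sa + max_span, side="right")
        for i in range(n):
            for j in range(i + 1, hi[i]):
                if abs(diag[j] - diag[i]) <= diag_tol:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        groups = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        for idxs in groups.values():
            idx = np.array(idxs)
            a_lo, a_hi = sa[idx].min(), sa[idx].max() + L
            b_lo, b_hi = sb[idx].min(), sb[idx].max() + L
            total = sc[idx].sum()
            density = total / (a_hi - a_lo)
            if density > min_density:
                out.append(
                    PairwiseLCR(
                        a=Segment(ca, int(a_lo), int(a_hi)),
                        b=Segment(cb, int(b_lo), int(b_hi)),
                        orientation=orient,
                        score=float(total),
                        density=float(density),
                    )
                )
    out.sort(key=lambda p: (p.a.chrom, p.a.start, p.b.chrom, p.b.start, p.orientation))
    return out


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def compute_identity(seq_a: str, seq_b: str, orientation: str = "direct") -> float:
    """Global-alignment identity (matches / alignment columns).

    The second sequence is reverse-complemented for inverted pairings.  A
    length ratio above 5 is a degenerate pairing and scores 0.
    """
    if min(len(seq_a), len(seq_b)) == 0:
        return 0.0
    if max(len(seq_a), len(seq_b)) / min(len(seq_a), len(seq_b)) > 5:
        return 0.0
    if orientation == "inverted":
        seq_b = reverse_complement(seq_b)
    res = edlib.align(seq_a.upper(), seq_b.upper(), task="path", mode="NW")
    cols = 0
    match = 0
    for n, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        n = int(n)
        cols += n
        if op == "=":
            match += n
    return match / cols if cols else 0.0


def _cigar_runs(cigar: str):
    return [(int(n), op) for n, op in re.findall(r"(\d+)([=XIDM])", cigar)]


def refine_pair(pair: PairwiseLCR, seq_a: str, seq_b: str) -> PairwiseLCR:
    """Snap block boundaries to the aligned paralogous core.

    Merged blocks are quantized to fragment boundaries and carry up to one
    fragment of flanking unique sequence at each end, which dilutes identity.
    The two blocks are globally aligned and the maximum-scoring sub-path
    (match +1, mismatch/gap -1; a Kadane pass over CIGAR runs) defines the
    refined member coordinates and the core identity.
    """
    sb = reverse_complement(seq_b) if pair.orientation == "inverted" else seq_b
    res = edlib.align(seq_a.upper(), sb.upper(), task="path", mode="NW")
    runs = _cigar_runs(res["cigar"])
    if not runs:
        return pair
    # prefix sums of query (a) / target (b) consumption and match counts
    q = t = 0
    best = cur = 0
    cur_start = 0
    best_span = (0, 0)
    bounds = [(0, 0)]
    for n, op in runs:
        if op in ("=", "X", "M"):
            q += n
            t += n
        elif op == "I":
            q += n
        else:  # D
            t += n
        bounds.append((q, t))
        # mismatches and gaps cost 2: unit-cost alignment of unrelated DNA
        # still matches ~55-60% of columns, so a -1 penalty would never trim
        # flanking unique sequence; -2 trims anything below ~67% identity
        val = n if op == "=" else -2 * n
        if cur <= 0:
            cur = val
            cur_start = len(bounds) - 2
        else:
            cur += val
        if cur > best:
            best = cur
            best_span = (cur_start, len(bounds) - 1)
    if best <= 0:
        return pair
    i, j = best_span
    (q0, t0), (q1, t1) = bounds[i], bounds[j]
    match = sum(n for n, op in runs[i:j] if op == "=")
    cols = sum(n for n, _ in runs[i:j])
    if cols < 50:  # too little aligned core to trust
        return pair
    new_a = Segment(pair.a.chrom, pair.a.start + q0, pair.a.start + q1)
    if pair.orientation == "inverted":
        new_b = Segment(pair.b.chrom, pair.b.end - t1, pair.b.end - t0)
    else:
        new_b = Segment(pair.b.chrom, pair.b.start + t0, pair.b.start + t1)
    pair.a, pair.b = new_a, new_b
    pair.identity = match / cols
    return pair


def segment_kmer_set(genome, seg: Segment, scheme: KmerScheme) -> set:
    seq = None
    for chrom, s in _genome_items(genome):
        if chrom == seg.chrom:
            seq = s[seg.start : seg.end]
            break
    if seq is None:
        raise ValueError(f"unknown chromosome {seg.chrom!r}")
    _, fwd, _ = pattern_kmer_codes(encode_sequence(seq), scheme)
    return set(fwd.tolist())


def annotate_pairs(
    pairs: list, genome, scheme: KmerScheme = KmerScheme(), refine: bool = True
) -> list:
    """Refine block boundaries and fill in identity and k-mer profiles."""
    seqs = dict(_genome_items(genome))
    for p in pairs:
        sa = seqs[p.a.chrom][p.a.start : p.a.end]
        sb = seqs[p.b.chrom][p.b.start : p.b.end]
        if refine:
            refine_pair(p, sa, sb)
            sa = seqs[p.a.chrom][p.a.start : p.a.end]
            sb = seqs[p.b.chrom][p.b.start : p.b.end]
            if np.isnan(p.identity):
                p.identity = compute_identity(sa, sb, p.orientation)
        else:
            p.identity = compute_identity(sa, sb, p.orientation)
        _, fa, _ = pattern_kmer_codes(encode_sequence(sa), scheme)
        _, fb, _ = pattern_kmer_codes(encode_sequence(sb), scheme)
        p.kmer_profile = frozenset(fa.tolist()) | frozenset(fb.tolist())
    return pairs


def kmer_similarity(pair_a: PairwiseLCR, pair_b: PairwiseLCR) -> float:
    """k-mer content similarity between two pairwise LCRs.

    score = 1 - (|symmetric difference| + ln(1 + size difference)) /
    |intersection|; an empty intersection can never cluster (-inf).
    """
    if not pair_a.kmer_profile or not pair_b.kmer_profile:
        return float("-inf")
    inter = len(pair_a.kmer_profile & pair_b.kmer_profile)
    if inter == 0:
        return float("-inf")
    diff = len(pair_a.kmer_profile ^ pair_b.kmer_profile)
    size_diff = abs(pair_a.size - pair_b.size)
    return 1.0 - (diff + np.log1p(size_diff)) / inter


def cluster_lcrs(
    pairs: list,
    min_similarity: float = 0.5,
    min_len: int = 1000,
    min_identity: float = 0.90,
) -> list:
    """Single-linkage clustering of pairwise LCRs into paralog families.

    Two pairs connect when their k-mer similarity reaches ``min_similarity``
    or any of their member segments positionally overlap.  After clustering,
    members shorter than ``min_len`` or whose best within-pair identity is
    below ``min_identity`` are removed; a pair losing a member is dropped and
    clusters emptied by the filter vanish.
    """
    n = len(pairs)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = pairs[i], pairs[j]
            if kmer_similarity(pi, pj) >= min_similarity or any(
                s.overlaps(t) for s in (pi.a, pi.b) for t in (pj.a, pj.b)
            ):
                union(i, j)

    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    clusters = []
    for idxs in groups.values():
        kept_pairs = []
        for i in idxs:
            p = pairs[i]
            # identity filter against the best paralog = the pair's own match
            if len(p.a) >= min_len and len(p.b) >= min_len and p.identity >= min_identity:
                kept_pairs.append(p)
        if not kept_pairs:
            continue
        members = []
        for p in kept_pairs:
            members.extend([p.a, p.b])
        clusters.append(LCRCluster(pairs=kept_pairs, members=members))
    clusters.sort(key=lambda c: (c.members[0].chrom, c.members[0].start))
    return clusters


def find_dp_lcr_regions(
    clusters: list,
    min_size: int = 10_000,
    min_identity: float = 0.95,
    max_distance: int = 10_000_000,
) -> pd.DataFrame:
    """Regions between directly-oriented paralogous LCRs (the NAHR substrate).

    Every same-cluster matched pair on one chromosome in direct orientation,
    with both members >= ``min_size`` and identity >= ``min_identity`` and an
    intervening gap in (0, ``max_distance``), contributes its intervening
    region; overlapping regions are merged.
    """
    rows = []
    for cluster in clusters:
        for p in cluster.pairs:
            if p.orientation != "direct":
                continue
            if p.a.chrom != p.b.chrom:
                continue
            if len(p.a) < min_size or len(p.b) < min_size:
                continue
            if p.identity < min_identity:
                continue
            left, right = (p.a, p.b) if p.a.start <= p.b.start else (p.b, p.a)
            gap_lo, gap_hi = left.end, right.start
            if 0 < gap_hi - gap_lo < max_distance:
                rows.append((p.a.chrom, gap_lo, gap_hi))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return merge_intervals(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


@dataclass
class LCRResult:
    matches: pd.DataFrame
    frag_index: FragmentIndex
    pairs: list
    clusters: list
    dp_regions: pd.DataFrame


def detect_lcrs(
    genome,
    repeats=None,
    scheme: KmerScheme = KmerScheme(),
    min_score: int = 10,
    top_n: int = 50,
    max_list: int = 1000,
    max_span: int = 1000,
    max_radius: int = 250,
    min_density: float = 0.05,
    min_similarity: float = 0.5,
    min_len: int = 1000,
    min_identity: float = 0.90,
    dp_min_size: int = 10_000,
    dp_min_identity: float = 0.95,
    dp_max_distance: int = 10_000_000,
) -> LCRResult:
    """Run the full LCR pipeline: blacklist, self-compare, filter, merge,
    cluster, and DP-LCR region extraction."""
    blacklist = build_blacklist(genome, repeats, scheme) if repeats is not None else None
    matches, frag_index = self_compare(genome, scheme, blacklist, min_score=min_score)
    filtered = reciprocal_filter(matches, top_n=top_n, max_list=max_list)
    pairs = merge_fragments(
        filtered, frag_index, max_span=max_span, max_radius=max_radius,
        min_density=min_density,
    )
    pairs = annotate_pairs(pairs, genome, scheme)
    clusters = cluster_lcrs(
        pairs, min_similarity=min_similarity, min_len=min_len, min_identity=min_identity
    )
    dp_regions = find_dp_lcr_regions(
        clusters, min_size=dp_min_size, min_identity=dp_min_identity,
        max_distance=dp_max_distance,
    )
    return LCRResult(matches, frag_index, pairs, clusters, dp_regions)
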