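"""k-mer self-comparison, reciprocal filtering, merging, clustering, DP-LCRs."""

import numpy as np
import pandas as pd
import pytest

from methdesert import simulate
from methdesert.lcr import (
    DEFAULT_OFFSETS,
    FragmentIndex,
    KmerBlacklist,
    KmerScheme,
    LCRCluster,
    PairwiseLCR,
    Segment,
    build_blacklist,
    cluster_lcrs,
    compute_identity,
    detect_lcrs,
    encode_sequence,
    find_dp_lcr_regions,
    kmer_similarity,
    merge_fragments,
    pattern_kmer_codes,
    reciprocal_filter,
    reverse_complement,
    self_compare,
)

BASES = np.array(list("ACGT"))


def random_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


def mutate(rng, seq, rate):
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
    return "".join(out)


class TestKmerScheme:
    def test_default_layout_is_13_of_21(self):
        s = KmerScheme()
        assert len(DEFAULT_OFFSETS) == 13
        assert s.pattern_length - len(set(DEFAULT_OFFSETS)) == 8
        assert max(DEFAULT_OFFSETS) == 20

    def test_rejects_inconsistent_layout(self):
        with pytest.raises(ValueError):
            KmerScheme(sampled_offsets=(0, 1, 2))

    def test_n_at_sampled_position_never_hashed(self):
        seq = "A" * 30 + "N" + "A" * 30
        scheme = KmerScheme()
        pos, fwd, rc = pattern_kmer_codes(encode_sequence(seq), scheme)
        sampled = set(scheme.sampled_offsets) | {
            scheme.pattern_length - 1 - o for o in scheme.sampled_offsets
        }
        bad_starts = {30 - o for o in sampled if 0 <= 30 - o}
        assert not (set(pos.tolist()) & bad_starts)


class TestSelfCompare:
    def test_identical_fragments_direct_full_score(self, rng):
        frag = random_seq(rng, 500)
        genome = {"c1": frag + random_seq(rng, 500), "c2": frag + random_seq(rng, 500)}
        matches, _ = self_compare(genome, min_score=10)
        direct = matches[matches["orientation"] == "direct"]
        assert len(direct) == 1
        # one shared k-mer per valid placement
        assert direct.iloc[0]["score"] == 500 - 21 + 1

    def test_reverse_complement_fragment_same_score_inverted(self, rng):
        frag = random_seq(rng, 500)
        genome = {
            "c1": frag + random_seq(rng, 500),
            "c2": reverse_complement(frag) + random_seq(rng, 500),
        }
        matches, _ = self_compare(genome, min_score=10)
        inv = matches[matches["orientation"] == "inverted"]
        assert len(inv) == 1
        assert inv.iloc[0]["score"] == 500 - 21 + 1

    def test_score_at_90pct_identity_matches_placement_oracle(self, rng):
        """Shared-kmer score vs brute-force expectation over placements."""
        scheme = KmerScheme()
        n_rep = 40
        scores = []
        for _ in range(n_rep):
            frag = random_seq(rng, 500)
            frag2 = mutate(rng, frag, 0.10)
            genome = {"c1": frag + random_seq(rng, 500), "c2": frag2 + random_seq(rng, 500)}
            matches, _ = self_compare(genome, min_score=1)
            direct = matches[
                (matches["orientation"] == "direct")
                & (matches["frag_a"] == 0)
                & (matches["frag_b"] == 2)
            ]
            scores.append(direct["score"].sum())
        # brute-force per-placement survival: a placement survives iff none
        # of its 13 sampled bases mutated
        expected = (500 - 21 + 1) * 0.9 ** 13
        sem = np.std(scores, ddof=1) / np.sqrt(n_rep)
        assert abs(np.mean(scores) - expected) < 3 * sem + 1e-9

    def test_blacklisted_kmers_skipped(self, rng):
        frag = random_seq(rng, 500)
        genome = {"c1": frag + random_seq(rng, 500), "c2": frag + random_seq(rng, 500)}
        _, fwd, rc = pattern_kmer_codes(encode_sequence(frag), KmerScheme())
        bl = KmerBlacklist(np.sort(np.unique(np.concatenate([fwd, rc]))))
        matches, _ = self_compare(genome, blacklist=bl, min_score=1)
        assert matches.empty


class TestBuildBlacklist:
    def test_high_copy_kmer_excluded_low_freq_not(self, rng):
        motif = random_seq(rng, 30)
        hcr = motif * 40
        genome = {"c": hcr + random_seq(rng, 120_000)}
        repeats = pd.DataFrame([("c", 0, len(hcr))], columns=["chrom", "start", "end"])
        bl = build_blacklist(genome, repeats)
        assert len(bl.excluded) > 0
        # a k-mer with HCR frequency <= 10 never excluded: rare motif
        rare = random_seq(rng, 25)
        genome2 = {"c": rare * 2 + random_seq(rng, 120_000)}
        repeats2 = pd.DataFrame([("c", 0, 50)], columns=["chrom", "start", "end"])
        bl2 = build_blacklist(genome2, repeats2)
        assert len(bl2.excluded) == 0

    def test_empty_annotation_warns_empty_blacklist(self, rng):
        genome = {"c": random_seq(rng, 5_000)}
        with pytest.warns(UserWarning):
            bl = build_blacklist(genome, pd.DataFrame(columns=["chrom", "start", "end"]))
        assert len(bl.excluded) == 0


class TestReciprocalFilter:
    def _matches(self, rows):
        return pd.DataFrame(rows, columns=["frag_a", "frag_b", "orientation", "score"])

    def test_mutual_best_pair_kept(self):
        m = self._matches([(0, 1, "direct", 50.0)])
        assert len(reciprocal_filter(m)) == 1

    def test_fragment_with_over_1000_matches_dropped(self):
        rows = [(0, b, "direct", 50.0) for b in range(1, 1002)]
        m = self._matches(rows)
        assert reciprocal_filter(m).empty

    def test_matches_brute_force_double_loop_oracle(self, rng):
        n_frag = 30
        rows = []
        for a in range(n_frag):
            for b in range(a + 1, n_frag):
                if rng.random() < 0.5:
                    rows.append((a, b, "direct", float(rng.integers(1, 100))))
        m = self._matches(rows)
        top_n, max_list = 5, 8
        got = reciprocal_filter(m, top_n=top_n, max_list=max_list)
        # oracle: explicit per-fragment sorted lists
        lists = {}
        for a, b, _, s in rows:
            lists.setdefault(a, []).append((b, s))
            lists.setdefault(b, []).append((a, s))
        for k in lists:
            lists[k].sort(key=lambda t: (-t[1], t[0]))
        expected = []
        for a, b, o, s in rows:
            la, lb = lists[a], lists[b]
            if len(la) > max_list or len(lb) > max_list:
                continue
            if b in [x for x, _ in la[:top_n]] and a in [x for x, _ in lb[:top_n]]:
                expected.append((a, b))
        assert list(zip(got["frag_a"], got["frag_b"])) == expected


class TestMergeFragments:
    def _index(self, n_frags=100):
        return FragmentIndex.build({"c": n_frags * 500}, 500)

    def test_planted_consecutive_matches_merge_to_one_block(self):
        idx = self._index()
        m = pd.DataFrame(
            [(10, 40, "direct", 200.0), (11, 41, "direct", 200.0), (12, 42, "direct", 200.0)],
            columns=["frag_a", "frag_b", "orientation", "score"],
        )
        pairs = merge_fragments(m, idx)
        assert len(pairs) == 1
        assert (pairs[0].a.start, pairs[0].a.end) == (5000, 6500)
        assert (pairs[0].b.start, pairs[0].b.end) == (20000, 21500)

    def test_distant_side_a_matches_not_merged(self):
        idx = self._index()
        m = pd.DataFrame(
            [(10, 40, "direct", 200.0), (20, 50, "direct", 200.0)],
            columns=["frag_a", "frag_b", "orientation", "score"],
        )
        pairs = merge_fragments(m, idx)
        assert len(pairs) == 2

    def test_low_density_block_dropped(self):
        idx = self._index()
        m = pd.DataFrame(
            [(10, 40, "direct", 10.0)],
            columns=["frag_a", "frag_b", "orientation", "score"],
        )
        assert merge_fragments(m, idx) == []  # 10/500 = 0.02 < 0.05

    def test_off_grid_duplication_offset_still_single_block(self):
        # partner split across two adjacent diagonals (quantization)
        idx = self._index()
        rows = []
        for i in range(5):
            rows.append((10 + i, 40 + i, "direct", 120.0))
            rows.append((10 + i, 41 + i, "direct", 120.0))
        m = pd.DataFrame(rows, columns=["frag_a", "frag_b", "orientation", "score"])
        pairs = merge_fragments(m, idx)
        assert len(pairs) == 1


class TestKmerSimilarity:
    def _pair(self, profile, size):
        p = PairwiseLCR(
            Segment("c", 0, size // 2), Segment("c", 1000, 1000 + size - size // 2),
            "direct", 1.0, 1.0,
        )
        p.kmer_profile = frozenset(profile)
        return p

    def test_identical_profiles_score_one(self):
        a = self._pair(range(100), 2000)
        b = self._pair(range(100), 2000)
        assert kmer_similarity(a, b) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        a = self._pair(set(range(10)) | {100, 101}, 500)
        b = self._pair(set(range(10)) | {200, 201, 202}, 500)
        # 1 - (5 + ln(1)) / 10
        assert kmer_similarity(a, b) == pytest.approx(0.5)

    def test_empty_intersection_is_sentinel(self):
        a = self._pair({1, 2}, 100)
        b = self._pair({3, 4}, 100)
        assert kmer_similarity(a, b) == float("-inf")

    def test_monotone_in_diff_and_size(self, rng):
        base = set(range(50))
        a = self._pair(base, 1000)
        prev = kmer_similarity(a, self._pair(base, 1000))
        for extra in (2, 5, 9):
            s = kmer_similarity(a, self._pair(base | set(range(1000, 1000 + extra)), 1000))
            assert s < prev
            prev = s
        assert kmer_similarity(a, self._pair(base, 1400)) < kmer_similarity(
            a, self._pair(base, 1100)
        )


class TestComputeIdentity:
    def test_identical_sequences(self, rng):
        s = random_seq(rng, 800)
        assert compute_identity(s, s) == 1.0

    def test_planted_substitutions(self, rng):
        s = random_seq(rng, 1000)
        mut = list(s)
        subs = rng.choice(1000, size=50, replace=False)
        for i in subs:
            mut[i] = str(rng.choice([b for b in "ACGT" if b != mut[i]]))
        ident = compute_identity(s, "".join(mut))
        assert ident == pytest.approx(0.95, abs=0.002)

    def test_inverted_orientation_equals_direct_after_rc(self, rng):
        s = random_seq(rng, 600)
        t = mutate(rng, s, 0.05)
        assert compute_identity(s, reverse_complement(t), "inverted") == pytest.approx(
            compute_identity(s, t, "direct")
        )

    def test_degenerate_length_ratio(self, rng):
        assert compute_identity(random_seq(rng, 1000), random_seq(rng, 100)) == 0.0


class TestClusterAndDpRegions:
    def _pair(self, a, b, orientation="direct", identity=0.97, profile=None):
        p = PairwiseLCR(Segment(*a), Segment(*b), orientation, 100.0, 0.5, identity)
        p.kmer_profile = frozenset(profile or [])
        return p

    def test_overlapping_pairs_cluster_together(self):
        p1 = self._pair(("c", 0, 12_000), ("c", 50_000, 62_000), profile=[1, 2])
        p2 = self._pair(("c", 55_000, 67_000), ("c", 200_000, 212_000), profile=[900])
        clusters = cluster_lcrs([p1, p2])
        assert len(clusters) == 1

    def test_dissimilar_disjoint_pairs_stay_singletons(self):
        p1 = self._pair(("c", 0, 12_000), ("c", 50_000, 62_000), profile=[1])
        p2 = self._pair(("c", 100_000, 112_000), ("c", 200_000, 212_000), profile=[2])
        assert len(cluster_lcrs([p1, p2])) == 2

    def test_matches_union_find_oracle(self, rng):
        pairs = []
        for i in range(12):
            s = int(rng.integers(0, 500_000))
            t = int(rng.integers(0, 500_000))
            pairs.append(
                self._pair(
                    ("c", s, s + 5_000), ("c", t, t + 5_000),
                    profile=rng.choice(50, size=10, replace=False).tolist(),
                )
            )
        clusters = cluster_lcrs(pairs, min_len=1000, min_identity=0.9)
        # oracle: explicit connectivity matrix + transitive closure
        n = len(pairs)
        adj = np.eye(n, dtype=bool)
        for i in range(n):
            for j in range(n):
                pi, pj = pairs[i], pairs[j]
                sim = kmer_similarity(pi, pj) >= 0.5
                ov = any(
                    s.overlaps(t) for s in (pi.a, pi.b) for t in (pj.a, pj.b)
                )
                adj[i, j] |= sim or ov
        for _ in range(n):
            adj = adj @ adj
        comp_ids = set()
        for i in range(n):
            comp_ids.add(tuple(np.flatnonzero(adj[i]).tolist()))
        assert len(clusters) == len(comp_ids)

    def test_member_filters_remove_short_and_divergent(self):
        short = self._pair(("c", 0, 800), ("c", 5_000, 5_800), profile=[1])
        divergent = self._pair(
            ("c", 50_000, 62_000), ("c", 100_000, 112_000), identity=0.85, profile=[2]
        )
        assert cluster_lcrs([short, divergent]) == []

    def test_dp_region_from_qualifying_pair(self):
        p = self._pair(("c", 0, 20_000), ("c", 2_020_000, 2_040_000), identity=0.97)
        regions = find_dp_lcr_regions([LCRCluster(pairs=[p], members=[p.a, p.b])])
        assert list(map(tuple, regions.to_numpy())) == [("c", 20_000, 2_020_000)]

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(orientation="inverted"),
            dict(identity=0.93),
            dict(b=("c", 12_020_000, 12_040_000)),   # 12 Mb apart
            dict(a=("c", 0, 8_000), b=("c", 2_020_000, 2_028_000)),  # <10 kb
        ],
    )
    def test_disqualified_pairs_emit_no_region(self, kwargs):
        a = kwargs.pop("a", ("c", 0, 20_000))
        b = kwargs.pop("b", ("c", 2_020_000, 2_040_000))
        p = self._pair(a, b, **kwargs)
        regions = find_dp_lcr_regions([LCRCluster(pairs=[p], members=[p.a, p.b])])
        assert regions.empty


@pytest.fixture(scope="module")
def planted():
    cfg = simulate.SimConfig(
        seed=41,
        chrom_sizes={"chr1": 2_500_000},
        duplications=(
            simulate.DuplicationSpec(15_000, 0.97, 400_000),
            simulate.DuplicationSpec(12_000, 0.96, 200_000, "inverted"),
            simulate.DuplicationSpec(11_000, 0.85, 300_000),
        ),
    )
    genome, truth = simulate.simulate_genome(cfg)
    return genome, truth


class TestPipelineOnPlantedGenomes:
    def test_planted_direct_pair_recovered(self, planted):
        genome, truth = planted
        res = detect_lcrs(genome)
        assert len(res.dp_regions) == 1
        exp = truth.expected_dp_regions.iloc[0]
        got = res.dp_regions.iloc[0]
        assert abs(got["start"] - exp["start"]) <= 500
        assert abs(got["end"] - exp["end"]) <= 500

    def test_inverted_and_subthreshold_pairs_emit_nothing(self, planted):
        genome, truth = planted
        res = detect_lcrs(genome)
        # the only emitted region comes from the single qualifying pair
        assert len(res.dp_regions) == 1
        inv = [p for p in res.pairs if p.orientation == "inverted"]
        assert inv and all(p.identity < 0.995 for p in inv)

    def test_identity_estimates_track_planted_rates(self, planted):
        genome, truth = planted
        res = detect_lcrs(genome)
        by_orientation = {}
        for p in res.pairs:
            if len(p.a) > 5_000:
                by_orientation.setdefault(p.orientation, []).append(p)
        planted_direct = sorted(
            spec.identity
            for spec, _, _ in truth.duplication_pairs
            if spec.orientation == "direct"
        )
        found_direct = sorted(p.identity for p in by_orientation["direct"])
        assert len(found_direct) == len(planted_direct)
        for est, true in zip(found_direct, planted_direct):
            assert abs(est - true) < 0.01

    def test_strand_symmetry(self):
        """The mirror genome yields the mirror-image LCR coordinates."""
        cfg = simulate.SimConfig(
            seed=17,
            chrom_sizes={"chr1": 1_200_000},
            duplications=(simulate.DuplicationSpec(12_000, 0.97, 150_000),),
        )
        genome, _ = simulate.simulate_genome(cfg)
        L = len(genome["chr1"])
        mirrored = {"chr1": reverse_complement(genome["chr1"])}
        res_f = detect_lcrs(genome)
        res_r = detect_lcrs(mirrored)
        assert len(res_f.pairs) == len(res_r.pairs) == 1
        pf, pr = res_f.pairs[0], res_r.pairs[0]
        # segments reflect: [s, e) -> [L - e, L - s)
        got = sorted([(pr.a.start, pr.a.end), (pr.b.start, pr.b.end)])
        exp = sorted([(L - pf.a.end, L - pf.a.start), (L - pf.b.end, L - pf.b.start)])
        for (gs, ge), (es, ee) in zip(got, exp):
            assert abs(gs - es) <= 50 and abs(ge - ee) <= 50
        assert pr.orientation == "direct"

    def test_determinism(self, planted):
        genome, _ = planted
        r1 = detect_lcrs(genome)
        r2 = detect_lcrs(genome)
        pd.testing.assert_frame_equal(r1.matches, r2.matches)
        pd.testing.assert_frame_equal(r1.dp_regions, r2.dp_regions)
        assert [(p.a, p.b, p.identity) for p in r1.pairs] == [
            (p.a, p.b, p.identity) for p in r2.pairs
        ]
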