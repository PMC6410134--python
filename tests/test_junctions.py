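"""Junction clustering and pairing: thresholds, footprints, pairing rules,
brute-force oracle equivalence, order invariance."""
import random
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ervsegmap import junctions
from ervsegmap.io import ALIGNMENT_COLUMNS
from ervsegmap.junctions import (
    AnchoredPair,
    cluster_junctions,
    pair_junctions,
    append_relaxed_reads,
    select_strict_pairs,
    tune_to_target,
)


def make_record(read_id, pos, score=450, strand="+", erv_orientation="antisense",
                line="H", erv="ERV_A", chrom="chr1", erv_pos=0, quality="top"):
    return dict(zip(ALIGNMENT_COLUMNS, [
        read_id, line, erv, score, erv_orientation, erv_pos, chrom, pos,
        strand, quality,
    ]))


def make_pair(read_id, pos, side="up", orientation="sense", line="H",
              erv="ERV_A", chrom="chr1", score=450, erv_pos=0):
    return AnchoredPair(
        read_id=read_id, line_id=line, erv_id=erv, erv_score=score,
        erv_pos=erv_pos, chromosome=chrom, pos=pos, side=side,
        orientation=orientation,
    )


class TestSelectStrictPairs:
    @pytest.mark.parametrize("score,kept", [(424, 0), (425, 1), (493, 1)])
    def test_score_threshold_boundary(self, score, kept):
        df = pd.DataFrame([make_record("r1", 100, score=score)])
        assert len(select_strict_pairs(df, score_min=425)) == kept

    def test_empty_input(self):
        df = pd.DataFrame(columns=ALIGNMENT_COLUMNS)
        assert select_strict_pairs(df) == []

    def test_filter_count_matches_brute_force(self, rng):
        scores = rng.integers(400, 494, size=120)
        df = pd.DataFrame(
            [make_record(f"r{i}", 100 * i, score=int(s)) for i, s in enumerate(scores)]
        )
        k_below = int((scores < 425).sum())
        assert len(select_strict_pairs(df, score_min=425)) == len(df) - k_below

    def test_secondary_anchor_excluded(self):
        df = pd.DataFrame([make_record("r1", 100, quality="secondary")])
        assert select_strict_pairs(df) == []

    def test_side_orientation_convention(self):
        # + anchor with antisense ERV read: upstream flank, sense insertion
        df = pd.DataFrame([make_record("r1", 100, strand="+", erv_orientation="antisense"),
                           make_record("r2", 200, strand="-", erv_orientation="antisense")])
        pairs = {p.read_id: p for p in select_strict_pairs(df)}
        assert (pairs["r1"].side, pairs["r1"].orientation) == ("up", "sense")
        assert (pairs["r2"].side, pairs["r2"].orientation) == ("down", "antisense")


class TestClusterJunctions:
    def test_two_overlapping_reads_reach_footprint_floor(self):
        # union footprint 70 = 0.02 * 3500: exactly at the retention floor
        pairs = [make_pair("a", 0), make_pair("b", 20)]
        clusters = cluster_junctions(pairs)
        assert len(clusters) == 1 and clusters[0].footprint == 70

    def test_single_read_below_footprint_floor_discarded(self):
        assert cluster_junctions([make_pair("a", 0)]) == []

    def test_distant_anchors_never_merge(self):
        pairs = [make_pair("a", 0), make_pair("b", 20), make_pair("c", 4000),
                 make_pair("d", 4020)]
        clusters = cluster_junctions(pairs)
        assert len(clusters) == 2

    def test_per_line_counts_sum_to_members(self):
        pairs = [make_pair(f"r{i}", 10 * i, line=l)
                 for i, l in enumerate(["H", "H", "L", "W", "W", "W"])]
        (cluster,) = cluster_junctions(pairs)
        assert cluster.per_line_counts == (2, 1, 3)
        assert sum(cluster.per_line_counts) == cluster.n_members


def _oracle_cluster(pairs, max_window=3500, min_frac=0.02, read_len=50):
    """Independent oracle: brute-force transitive closure of the pairwise
    gap rule, then the same left-to-right interval-cap split and footprint
    filter, all re-implemented from scratch."""
    parent = list(range(len(pairs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(pairs)):
        for j in range(len(pairs)):
            a, b = pairs[i], pairs[j]
            if (a.chromosome, a.side, a.orientation) != (b.chromosome, b.side, b.orientation):
                continue
            lo, hi = sorted([a.pos, b.pos])
            if hi - (lo + read_len) < max_window:
                parent[find(i)] = find(j)

    comps = {}
    for i in range(len(pairs)):
        comps.setdefault(find(i), []).append(pairs[i])
    out = []
    for comp in comps.values():
        comp.sort(key=lambda p: (p.pos, p.read_id))
        piece = []
        for p in comp:
            if piece and p.pos + read_len - piece[0].pos > max_window:
                out.append(piece)
                piece = []
            piece.append(p)
        if piece:
            out.append(piece)
    kept = []
    for piece in out:
        covered = set()
        for p in piece:
            covered.update(range(p.pos, p.pos + read_len))
        if len(covered) >= min_frac * max_window:
            kept.append(frozenset(p.read_id for p in piece))
    return set(kept)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 30_000), st.sampled_from(["up", "down"])),
        min_size=0,
        max_size=50,
    )
)
def test_clustering_equals_brute_force_closure(layout):
    pairs = [
        make_pair(f"r{i}", pos, side=side) for i, (pos, side) in enumerate(layout)
    ]
    ours = {
        frozenset(c.members) for c in cluster_junctions(pairs)
    }
    assert ours == _oracle_cluster(pairs)


def test_clustering_is_input_order_invariant(rng):
    pairs = [
        make_pair(f"r{i}", int(p), side=("up" if i % 2 else "down"))
        for i, p in enumerate(rng.integers(0, 50_000, size=80))
    ]
    ref = cluster_junctions(pairs)
    shuffled = pairs[:]
    random.Random(5).shuffle(shuffled)
    alt = cluster_junctions(shuffled)
    assert [(c.start, c.end, c.members) for c in ref] == [
        (c.start, c.end, c.members) for c in alt
    ]


def _mk_cluster(side, start, end, erv="ERV_A", orientation="sense", n=3,
                chrom="chr1", erv_positions=None):
    return junctions.JunctionCluster(
        chromosome=chrom, side=side, orientation=orientation, start=start,
        end=end, footprint=min(150, end - start),
        members=tuple(f"{side}{start}_{i}" for i in range(n)),
        erv_ids=Counter({erv: n}),
        erv_positions=erv_positions or {erv: [0] * n},
        per_line_counts=(n, 0, 0),
    )


class TestPairJunctions:
    def test_separation_beyond_limit_not_paired(self):
        up = _mk_cluster("up", 0, 200)
        down = _mk_cluster("down", 21_000, 21_200)
        loci, half = pair_junctions([up, down])
        assert loci == [] and len(half) == 2

    def test_disjoint_erv_sets_not_paired(self):
        up = _mk_cluster("up", 0, 200, erv="ERV_A")
        down = _mk_cluster("down", 1_000, 1_200, erv="ERV_B")
        loci, half = pair_junctions([up, down])
        assert loci == [] and len(half) == 2

    def test_nearest_first_matching(self):
        up = _mk_cluster("up", 10_000, 10_200)
        d1 = _mk_cluster("down", 15_000, 15_200)
        d2 = _mk_cluster("down", 18_000, 18_200)
        loci, half = pair_junctions([up, d1, d2])
        assert len(loci) == 1
        assert loci[0].downstream_cluster.start == 15_000
        assert half == [d2]

    def test_nearest_first_equals_exhaustive_minimum(self, rng):
        # on small inputs greedy nearest-first must reproduce the pairing
        # found by exhaustively trying every up->down assignment in greedy
        # distance order
        import itertools

        ups = [_mk_cluster("up", int(s), int(s) + 200) for s in
               sorted(rng.integers(0, 60_000, size=4))]
        downs = [_mk_cluster("down", int(s), int(s) + 200) for s in
                 sorted(rng.integers(0, 60_000, size=4))]
        loci, _ = pair_junctions(ups + downs)
        # oracle: enumerate all valid (up, down) pairs, sort by span, greedily take
        valid = []
        for u, d in itertools.product(ups, downs):
            if u.end > d.start or d.end - u.start >= 20_000:
                continue
            valid.append((d.end - u.start, u.start, u.start, d.start))
        valid.sort()
        taken_u, taken_d, expect = set(), set(), []
        for span, s, us, ds in valid:
            if us in taken_u or ds in taken_d:
                continue
            taken_u.add(us)
            taken_d.add(ds)
            expect.append((us, ds))
        got = sorted((l.upstream_cluster.start, l.downstream_cluster.start) for l in loci)
        assert got == sorted(expect)

    def test_flank_evidence_required_when_lengths_known(self):
        # both clusters hitting the consensus middle cannot represent a
        # 5'-plus-3' junction pair
        up = _mk_cluster("up", 0, 200, erv_positions={"ERV_A": [4000]})
        down = _mk_cluster("down", 1_000, 1_200, erv_positions={"ERV_A": [4000]})
        loci, _ = pair_junctions([up, down], erv_lengths={"ERV_A": 9_000})
        assert loci == []
        up2 = _mk_cluster("up", 0, 200, erv_positions={"ERV_A": [100]})
        down2 = _mk_cluster("down", 1_000, 1_200, erv_positions={"ERV_A": [8_800]})
        loci2, _ = pair_junctions([up2, down2], erv_lengths={"ERV_A": 9_000})
        assert len(loci2) == 1

    def test_each_cluster_joins_at_most_one_locus(self, mixed_run):
        cfg, outdir, manifest = mixed_run
        n_clusters = manifest["stages"]["cluster"]["junction_clusters"]
        n_loci = manifest["stages"]["cluster"]["candidate_loci"]
        n_half = manifest["stages"]["cluster"]["half_supported"]
        assert 2 * n_loci + n_half == n_clusters


class TestAppendRelaxedReads:
    def _locus(self):
        up = _mk_cluster("up", 1_000, 1_300)
        down = _mk_cluster("down", 4_000, 4_300)
        loci, _ = pair_junctions([up, down])
        assert len(loci) == 1
        return loci

    def test_no_relaxed_reads_leaves_counts_unchanged(self):
        loci = self._locus()
        df = pd.DataFrame(columns=ALIGNMENT_COLUMNS)
        out = append_relaxed_reads(loci, df)
        assert out[0].per_line_counts_relaxed == out[0].per_line_counts

    def test_relaxed_read_inside_interval_counts_once(self):
        loci = self._locus()
        df = pd.DataFrame([
            make_record("x1", 1_100, score=410, line="L"),  # inside up cluster
        ])
        out = append_relaxed_reads(loci, df)
        assert out[0].per_line_counts_relaxed == (
            out[0].per_line_counts[0],
            out[0].per_line_counts[1] + 1,
            out[0].per_line_counts[2],
        )

    def test_relaxed_read_one_base_outside_not_appended(self):
        loci = self._locus()
        df = pd.DataFrame([make_record("x1", 1_300, score=410)])  # end is exclusive
        out = append_relaxed_reads(loci, df)
        assert out[0].per_line_counts_relaxed == out[0].per_line_counts

    def test_strict_score_not_double_counted(self):
        loci = self._locus()
        df = pd.DataFrame([make_record("x1", 1_100, score=430)])
        out = append_relaxed_reads(loci, df)
        assert out[0].per_line_counts_relaxed == out[0].per_line_counts


class TestTuneToTarget:
    def _pairs(self, rng):
        pairs = []
        for k in range(40):
            base = 30_000 * k
            for i in range(6):
                score = int(rng.integers(400, 494))
                pairs.append(make_pair(f"u{k}_{i}", base + 10 * i, side="up",
                                       score=score))
                pairs.append(make_pair(f"d{k}_{i}", base + 2_000 + 10 * i,
                                       side="down", score=score))
        return pairs

    def test_locus_count_non_increasing_in_threshold(self, rng):
        pairs = self._pairs(rng)
        _, counts = tune_to_target(pairs, target_loci=10)
        thresholds = sorted(counts)
        for a, b in zip(thresholds, thresholds[1:]):
            assert counts[a] >= counts[b]

    def test_unreachable_target_returns_minimum_threshold(self, rng):
        pairs = self._pairs(rng)
        best, counts = tune_to_target(pairs, target_loci=10_000)
        assert best == min(counts)

    def test_empty_pair_set_rejected(self):
        with pytest.raises(ValueError):
            tune_to_target([], target_loci=10)

    def test_locus_target_from_library_size(self):
        assert junctions.derive_locus_target(532) == 10_640
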