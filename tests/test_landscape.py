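"""Gene landscape: boundary conventions, quadratic-scan oracle, orientation
profile, sweep overlap."""
import numpy as np
import pytest
from scipy import stats

from ervsegmap.landscape import (
    GeneModel,
    SimpleLocus,
    export_gene_lists,
    intersect_genes,
    merge_intervals,
    orientation_profile,
    sweep_overlap_test,
)


def gene(gid="g1", chrom="chr1", start=500_000, end=520_000, strand="+"):
    return GeneModel(gene_id=gid, chromosome=chrom, start=start, end=end, strand=strand)


def locus(lid="l1", chrom="chr1", start=0, end=200, orientation="sense"):
    return SimpleLocus(locus_id=lid, chromosome=chrom, start=start, end=end,
                       orientation=orientation)


class TestIntersectGenes:
    def test_locus_inside_transcript_is_intragenic(self):
        rels = intersect_genes([locus(start=505_000, end=506_000)], [gene()])
        assert len(rels) == 1
        assert rels[0].relation == "intragenic" and rels[0].distance == 0

    @pytest.mark.parametrize("gap,included", [(150_000, True), (150_001, False)])
    def test_flank_boundary_convention(self, gap, included):
        # locus ends exactly `gap` bases before the gene start
        l = locus(start=500_000 - gap - 200, end=500_000 - gap)
        rels = intersect_genes([l], [gene()])
        assert (len(rels) == 1) == included
        if included:
            assert rels[0].distance == 150_000 and rels[0].distance_bin == 15

    def test_up_downstream_follow_gene_strand(self):
        left = locus(lid="left", start=400_000, end=400_200)
        right = locus(lid="right", start=530_000, end=530_200)
        for strand, expected in [("+", ("upstream", "downstream")),
                                 ("-", ("downstream", "upstream"))]:
            rels = intersect_genes([left, right], [gene(strand=strand)])
            by_id = {r.locus_id: r.relation for r in rels}
            assert (by_id["left"], by_id["right"]) == expected

    def test_relative_orientation_against_gene_strand(self):
        l = locus(start=505_000, end=505_200, orientation="antisense")
        (rel,) = intersect_genes([l], [gene(strand="+")])
        assert rel.relative_orientation == "antisense"
        (rel,) = intersect_genes([l], [gene(strand="-")])
        assert rel.relative_orientation == "sense"

    def test_matches_quadratic_all_pairs_scan(self, rng):
        genes = [
            gene(gid=f"g{i}", start=int(s), end=int(s) + int(rng.integers(1_000, 30_000)),
                 strand="+" if rng.random() < 0.5 else "-")
            for i, s in enumerate(rng.integers(0, 2_000_000, size=50))
        ]
        loci = [
            locus(lid=f"l{i}", start=int(s), end=int(s) + 200,
                  orientation="sense" if rng.random() < 0.5 else "antisense")
            for i, s in enumerate(rng.integers(0, 2_000_000, size=60))
        ]
        fast = intersect_genes(loci, genes, flank=150_000)
        slow = []
        for l in loci:  # independent brute force over every pair
            for g in genes:
                if l.start < g.end and g.start < l.end:
                    slow.append((l.locus_id, g.gene_id, 0))
                else:
                    d = g.start - l.end if l.end <= g.start else l.start - g.end
                    if d <= 150_000:
                        slow.append((l.locus_id, g.gene_id, d))
        assert sorted((r.locus_id, r.gene_id, r.distance) for r in fast) == sorted(slow)

    def test_translation_invariance(self):
        genes = [gene(start=500_000, end=520_000)]
        loci = [locus(start=400_000, end=400_200)]
        base = intersect_genes(loci, genes)
        shift = 12_345
        moved = intersect_genes(
            [locus(start=400_000 + shift, end=400_200 + shift)],
            [gene(start=500_000 + shift, end=520_000 + shift)],
        )
        assert [(r.relation, r.distance) for r in base] == [
            (r.relation, r.distance) for r in moved
        ]

    def test_unknown_chromosome_skipped(self):
        rels = intersect_genes([locus(chrom="chrZ")], [gene()])
        assert rels == []


class TestOrientationProfile:
    def test_forced_antisense_intragenic_fraction_is_one(self):
        g = gene()
        loci = [locus(lid=f"l{i}", start=505_000 + 300 * i, end=505_200 + 300 * i,
                      orientation="antisense") for i in range(10)]
        profile = orientation_profile(intersect_genes(loci, [g]))
        assert profile["intragenic_antisense_fraction"] == 1.0

    def test_unbiased_orientations_stay_inside_binomial_ci(self, rng):
        genes = [gene(gid=f"g{i}", chrom=f"chr{i}", start=100_000, end=400_000)
                 for i in range(6)]
        loci = []
        for i in range(600):
            c = f"chr{i % 6}"
            s = 110_000 + (i // 6) * 2_000
            loci.append(locus(lid=f"l{i}", chrom=c, start=s, end=s + 200,
                              orientation="sense" if rng.random() < 0.5 else "antisense"))
        profile = orientation_profile(intersect_genes(loci, genes))
        n = sum(profile["intragenic"].values())
        assert n >= 500
        half_width = stats.norm.ppf(0.995) * np.sqrt(0.25 / n)
        assert abs(profile["intragenic_antisense_fraction"] - 0.5) < half_width

    def test_bin_counts_conserve_intergenic_relations(self, rng):
        genes = [gene()]
        loci = [locus(lid=f"l{i}", start=int(s), end=int(s) + 200)
                for i, s in enumerate(rng.integers(0, 1_000_000, size=200))]
        rels = intersect_genes(loci, genes)
        profile = orientation_profile(rels)
        binned = sum(
            v for side in ("upstream", "downstream")
            for slot in profile[side].values() for v in slot.values()
        )
        assert binned == sum(r.relation != "intragenic" for r in rels)

    def test_empty_relations_give_empty_profile(self):
        profile = orientation_profile([])
        assert profile["upstream"] == {} and profile["downstream"] == {}
        assert np.isnan(profile["intragenic_antisense_fraction"])


class TestSweepOverlap:
    def test_no_sweeps_means_no_overlap(self):
        res = sweep_overlap_test([locus()], [], genome_size=1_000_000)
        assert res["overlapping"] == 0 and res["p_value"] == 1.0

    def test_full_coverage_means_certain_overlap(self):
        res = sweep_overlap_test(
            [locus(start=100, end=300)], [("chr1", 0, 1_000_000)],
            genome_size=1_000_000,
        )
        assert res["overlapping"] == 1 and res["p_value"] == 1.0

    def test_overlap_count_matches_binomial_moments(self, rng):
        # 10% sweep fraction, uniformly placed loci: k within 3 SE of n*p0
        sweeps = [("chr1", i * 100_000, i * 100_000 + 10_000) for i in range(10)]
        n = 369
        starts = rng.integers(0, 999_800, size=n)
        loci = [locus(lid=f"l{i}", start=int(s), end=int(s) + 200)
                for i, s in enumerate(starts)]
        res = sweep_overlap_test(loci, sweeps, genome_size=1_000_000)
        se = np.sqrt(n * 0.1 * 0.9)
        assert abs(res["overlapping"] - 36.9) < 3 * se
        assert res["sweep_fraction"] == pytest.approx(0.1)

    def test_overlapping_sweeps_merged_before_fraction(self):
        merged = merge_intervals([("chr1", 0, 100), ("chr1", 50, 150)])
        assert merged == [("chr1", 0, 150)]

    def test_zero_genome_rejected(self):
        with pytest.raises(ValueError):
            sweep_overlap_test([], [], genome_size=0)


class TestExportGeneLists:
    def _results(self, pattern="H..", significant=True):
        from ervsegmap.difftest import DifferentialResult

        return [
            DifferentialResult(
                locus_id="l1", counts=(5, 0, 0), p_value=1e-8, test_used="fisher",
                significant=significant, pattern=pattern,
            )
        ]

    def test_empty_results_write_header_only_files(self, tmp_path):
        paths = export_gene_lists([], [], tmp_path)
        assert len(paths) == 6
        for p in paths.values():
            lines = open(p).read().splitlines()
            assert len(lines) == 1 and lines[0].startswith("#")

    def test_gene_listed_once_despite_two_adjacent_loci(self, tmp_path):
        g = gene()
        loci = [locus(lid="l1", start=400_000, end=400_200),
                locus(lid="l2", start=530_000, end=530_200)]
        rels = intersect_genes(loci, [g])
        from ervsegmap.difftest import DifferentialResult

        results = [
            DifferentialResult(locus_id=lid, counts=(5, 0, 0), p_value=1e-8,
                               test_used="fisher", significant=True, pattern="H..")
            for lid in ("l1", "l2")
        ]
        paths = export_gene_lists(rels, results, tmp_path)
        lines = [l for l in open(paths["H.."]).read().splitlines() if not l.startswith("#")]
        assert lines == ["g1"]

    def test_list_sizes_match_summary_gene_columns(self, tmp_path):
        from ervsegmap.difftest import DifferentialResult
        from ervsegmap.report import summarize

        g1, g2 = gene(gid="a"), gene(gid="b", start=700_000, end=720_000)
        loci = [locus(lid="l1", start=505_000, end=505_200),
                locus(lid="l2", start=705_000, end=705_200)]
        rels = intersect_genes(loci, [g1, g2])
        results = [
            DifferentialResult(locus_id=lid, counts=(5, 0, 0), p_value=1e-8,
                               test_used="fisher", significant=True, pattern=".L.")
            for lid in ("l1", "l2")
        ]
        paths = export_gene_lists(rels, results, tmp_path)
        listed = [l for l in open(paths[".L."]).read().splitlines() if not l.startswith("#")]
        gene_adj = {r.locus_id: {r.gene_id} for r in rels}
        summary = summarize(results, gene_adjacency=gene_adj)
        assert len(listed) == summary.rows[".L."].genes_adjacent_to_ervs
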