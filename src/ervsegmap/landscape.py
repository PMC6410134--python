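"""Genomic landscape of candidate insertion loci.

Relates loci to annotated genes within a flanking window (default 150 kb),
classifies each relation as intragenic / upstream / downstream with the
locus's orientation relative to the gene strand, bins intergenic distances
(default 10 kb bins), and tests whether loci fall into selective-sweep
intervals more often than their genomic footprint predicts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """A gene collapsed to transcript-level extremes, 0-based half-open."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class LocusGeneRelation:
    locus_id: str
    gene_id: str
    relation: str  # intragenic / upstream / downstream (vs gene orientation)
    distance: int  # nearest-edge gap; 0 if intragenic
    relative_orientation: str  # sense / antisense (locus vs gene strand)
    distance_bin: int  # floor(distance / bin_size)


@dataclass(frozen=True)
class SimpleLocus:
    """Minimal locus view used by the landscape operations."""

    locus_id: str
    chromosome: str
    start: int
    end: int
    orientation: str  # sense == host forward strand


def _relate(locus: SimpleLocus, gene: GeneModel, flank: int, bin_size: int,
            anchor: str) -> LocusGeneRelation | None:
    if locus.chromosome != gene.chromosome:
        return None
    overlap = locus.start < gene.end and gene.start < locus.end
    if overlap:
        relation, distance = "intragenic", 0
    else:
        if anchor == "tss":
            # distance from the locus's nearest edge to the TSS
            tss = gene.tss
            distance = min(abs(locus.start - tss), abs(locus.end - 1 - tss))
        else:
            distance = (
                gene.start - locus.end if locus.end <= gene.start
                else locus.start - gene.end
            )
        if distance > flank:
            return None
        locus_left_of_gene = locus.end <= gene.start
        if gene.strand == "+":
            relation = "upstream" if locus_left_of_gene else "downstream"
        else:
            relation = "downstream" if locus_left_of_gene else "upstream"
    locus_strand = "+" if locus.orientation == "sense" else "-"
    rel_orient = "sense" if locus_strand == gene.strand else "antisense"
    return LocusGeneRelation(
        locus_id=locus.locus_id,
        gene_id=gene.gene_id,
        relation=relation,
        distance=max(distance, 0),
        relative_orientation=rel_orient,
        distance_bin=max(distance, 0) // bin_size,
    )


def intersect_genes(
    loci: list[SimpleLocus],
    genes: list[GeneModel],
    flank: int = 150_000,
    bin_size: int = 10_000,
    anchor: str = "edge",
) -> list[LocusGeneRelation]:
    """Emit every (locus, gene) relation with a gap of at most ``flank``.

    A locus overlapping the transcript is intragenic (distance 0);
    otherwise the distance is between nearest interval edges (or to the
    TSS with ``anchor="tss"``) and up/downstream follows the gene strand.
    A locus may relate to many genes and vice versa. Loci on chromosomes
    absent from the annotation are skipped with a warning.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # one extra base so an exact flank-distance locus still hits the tree;
        # _relate applies the precise boundary rule
        trees.setdefault(g.chromosome, IntervalTree()).addi(
            g.start - flank - 1, g.end + flank + 1, g
        )
    relations: list[LocusGeneRelation] = []
    missing = set()
    for locus in loci:
        tree = trees.get(locus.chromosome)
        if tree is None:
            missing.add(locus.chromosome)
            continue
        for iv in tree.overlap(locus.start, max(locus.end, locus.start + 1)):
            rel = _relate(locus, iv.data, flank, bin_size, anchor)
            if rel is not None:
                relations.append(rel)
    if missing:
        logger.warning("loci on unannotated chromosomes skipped: %s", sorted(missing))
    relations.sort(key=lambda r: (r.locus_id, r.gene_id))
    return relations


def orientation_profile(relations: list[LocusGeneRelation]) -> dict:
    """Per-bin sense/antisense gene counts up/downstream plus intragenic bias.

    Returns ``{"upstream": {bin: {"sense": n, "antisense": n}}, "downstream":
    {...}, "intragenic": {"sense": n, "antisense": n}, "intragenic_antisense_
    fraction": f, "intragenic_binomial_p": p}``; the binomial test is
    two-sided against an even 0.5 split.
    """
    profile = {"upstream": {}, "downstream": {}}
    intragenic = {"sense": 0, "antisense": 0}
    for rel in relations:
        if rel.relation == "intragenic":
            intragenic[rel.relative_orientation] += 1
        else:
            bins = profile[rel.relation]
            slot = bins.setdefault(rel.distance_bin, {"sense": 0, "antisense": 0})
            slot[rel.relative_orientation] += 1
    n_intra = intragenic["sense"] + intragenic["antisense"]
    if n_intra:
        frac = intragenic["antisense"] / n_intra
        p = stats.binomtest(
            intragenic["antisense"], n_intra, 0.5, alternative="two-sided"
        ).pvalue
    else:
        frac, p = float("nan"), float("nan")
    return {
        "upstream": profile["upstream"],
        "downstream": profile["downstream"],
        "intragenic": intragenic,
        "intragenic_antisense_fraction": frac,
        "intragenic_binomial_p": float(p),
    }


def merge_intervals(intervals):
    """Merge possibly-overlapping (chrom, start, end) intervals."""
    by_chrom: dict[str, list] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    merged = []
    for chrom in sorted(by_chrom):
        cur_s = cur_e = None
        for s, e in sorted(by_chrom[chrom]):
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            merged.append((chrom, cur_s, cur_e))
    return merged


def sweep_overlap_test(
    loci: list[SimpleLocus],
    sweeps,
    genome_size: int,
) -> dict:
    """Binomial test of locus presence inside selective-sweep intervals.

    Under the null, each of the n loci falls in a sweep independently with
    probability p0 = merged sweep bases / genome bases; the observed count
    k (locus midpoints inside sweeps) is compared to Bin(n, p0) two-sided.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    merged = merge_intervals(sweeps)
    sweep_bases = sum(e - s for _, s, e in merged)
    p0 = sweep_bases / genome_size
    by_chrom: dict[str, list] = {}
    for chrom, s, e in merged:
        by_chrom.setdefault(chrom, []).append((s, e))
    k = 0
    for locus in loci:
        mid = (locus.start + locus.end) // 2
        for s, e in by_chrom.get(locus.chromosome, ()):
            if s <= mid < e:
                k += 1
                break
    n = len(loci)
    if n == 0 or p0 in (0.0, 1.0):
        p = 1.0
    else:
        p = stats.binomtest(k, n, p0, alternative="two-sided").pvalue
    return {
        "n_loci": n,
        "overlapping": k,
        "sweep_fraction": p0,
        "expected": n * p0,
        "p_value": float(p),
    }


def export_gene_lists(
    relations: list[LocusGeneRelation],
    results,
    outdir,
    significant_only: bool = True,
) -> dict:
    """Write one plain-text gene-ID list per presence pattern.

    Gene lists are intended for external ontology/annotation services;
    each gene appears once per list. Returns {pattern: path}.
    """
    from ervsegmap.difftest import PATTERNS

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes_by_locus: dict[str, set] = {}
    for rel in relations:
        genes_by_locus.setdefault(rel.locus_id, set()).add(rel.gene_id)

    lists: dict[str, set] = {pat: set() for pat in PATTERNS if pat != "HLW"}
    for res in results:
        if res.pattern in (None, "HLW"):
            continue
        if significant_only and not res.significant:
            continue
        lists[res.pattern] |= genes_by_locus.get(res.locus_id, set())

    paths = {}
    for pat, genes in lists.items():
        path = outdir / f"genes_{pat.replace('.', 'x')}.txt"
        with open(path, "w") as fh:
            fh.write(f"# genes adjacent to {pat} candidate loci\n")
            for g in sorted(genes):
                fh.write(g + "\n")
        paths[pat] = path
    return paths
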