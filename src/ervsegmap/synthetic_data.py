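"""Pooled mate-pair simulation of segregating ERV insertions.

The generator emulates the statistical structure the pipeline assumes:
three pooled line genomes (H, L, W) of ``pool_size_per_line`` diploid
individuals each, segregating ERV insertions with per-line allele
frequencies, mate pairs of two 50 nt reads flanking a ~3,500 nt insert,
and unequal fold coverage across the pools.

Each insertion is a full-length provirus, an internally deleted
(truncated) provirus retaining both LTRs, or a solo-LTR. Carrier
haplotypes emit junction-spanning pairs at both the 5' (upstream/left)
and 3' (downstream/right) host flanks: the ERV-side read gets a mapper
score from the configured score model, the host-side mate a unique
anchor. Reads are not emitted as sequence; the pipeline's contract is
alignment records.

Emission model
--------------
Per carrier haplotype, pair starts occur at rate c/(2L) per base, where c
is the per-haplotype fold coverage (line coverage / 2n) and L the read
length. A pair supports one junction side when the junction falls between
its two reads with the ERV-side read fully inside the element, giving an
effective start window of min(insert - 2L, element_length - L) bases.
The expected junction-pair count per side for a line is therefore

    lambda = dosage * coverage / (2 * pool_size) / (2 * L) * window,

evaluated at the mean insert size; the realized count is Poisson(lambda).
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ervsegmap import io as eio
from ervsegmap.config import LINES, ConfigError, SimulationConfig
from ervsegmap.junctions import PAIR_GEOMETRY

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class GroundTruthInsertion:
    """A simulated segregating ERV insertion with its pool dosages."""

    insertion_id: str
    chromosome: str
    position: int  # 0-based host base immediately 5' of the integration
    orientation: str  # sense/antisense vs host forward strand
    erv_family_id: str
    form: str  # full / truncated / solo_ltr
    element_length: int
    in_reference: bool
    per_line_allele_frequency: tuple[float, float, float]
    per_line_pool_dosage: tuple[int, int, int]

    @property
    def reference_span(self) -> tuple[int, int]:
        """Host interval the element occupies in reference coordinates.

        A non-reference insertion is a point in the reference assembly; an
        in-reference element occupies its full length.
        """
        if self.in_reference:
            return self.position, self.position + self.element_length
        return self.position, self.position


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def simulate_truth(config: SimulationConfig):
    """Simulate the ground truth: insertions, reference genome, ERV library.

    Returns ``(truth, genome, library)`` where ``genome`` maps chromosome
    name -> sequence and ``library`` maps ERV family id -> consensus
    sequence. Deterministic given ``config.seed``; insertion positions are
    non-overlapping (each reserves its reference span plus an insert-sized
    guard on both sides so junction anchors never interleave).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome = {c: _random_sequence(rng, config.chromosome_length) for c in chrom_names}

    lo, hi = config.erv_length_range
    family_lengths = rng.integers(lo, hi + 1, size=config.n_erv_families)
    library = {
        f"ERV_{i + 1:03d}": _random_sequence(rng, int(family_lengths[i]))
        for i in range(config.n_erv_families)
    }
    family_ids = sorted(library)

    n = config.n_insertions
    freqs = config.allele_freq_model.draw(rng, n) if n else np.zeros((0, 3))
    guard = config.insert_mean + 2 * config.read_length

    # place insertions without overlap: reserve [pos - guard, span_end + guard)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    truth: list[GroundTruthInsertion] = []
    max_attempts = 200 * max(n, 1)
    attempts = 0
    while len(truth) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ConfigError(
                f"could not place {n} non-overlapping insertions on "
                f"{config.n_chromosomes} x {config.chromosome_length} bases"
            )
        i = len(truth)
        fam = family_ids[int(rng.integers(len(family_ids)))]
        fam_len = len(library[fam])
        u = rng.random()
        if u < config.solo_ltr_fraction:
            form, elen = "solo_ltr", config.ltr_length
        elif u < config.solo_ltr_fraction + config.truncated_fraction * (
            1 - config.solo_ltr_fraction
        ):
            form = "truncated"
            elen = int(
                rng.integers(2 * config.ltr_length + config.read_length, fam_len)
            )
        else:
            form, elen = "full", fam_len
        in_ref = bool(rng.random() < config.in_reference_fraction)
        span_len = elen if in_ref else 0
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        limit = config.chromosome_length - span_len - guard
        if limit <= guard:
            raise ConfigError("chromosome too short for the configured geometry")
        pos = int(rng.integers(guard, limit))
        lo_r, hi_r = pos - guard, pos + span_len + guard
        if any(s < hi_r and lo_r < e for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((lo_r, hi_r))
        dosage = tuple(
            int(rng.binomial(config.haploids_per_pool, f)) for f in freqs[i]
        )
        truth.append(
            GroundTruthInsertion(
                insertion_id=f"ins_{i + 1:05d}",
                chromosome=chrom,
                position=pos,
                orientation="sense" if rng.random() < 0.5 else "antisense",
                erv_family_id=fam,
                form=form,
                element_length=elen,
                in_reference=in_ref,
                per_line_allele_frequency=tuple(float(f) for f in freqs[i]),
                per_line_pool_dosage=dosage,
            )
        )
    truth.sort(key=lambda t: (t.chromosome, t.position))
    return truth, genome, library


def expected_junction_pairs(
    config: SimulationConfig, dosage: int, line_index: int, element_length: int
) -> float:
    """Expected junction-spanning pair count for one side of one insertion."""
    window = min(
        config.insert_mean - 2 * config.read_length,
        element_length - config.read_length,
    )
    if window <= 0 or dosage <= 0:
        return 0.0
    per_hap = config.coverage_per_line[line_index] / config.haploids_per_pool
    return dosage * per_hap / (2 * config.read_length) * window


def _element_to_consensus(pos_elem: int, elen: int, fam_len: int, ltr: int) -> int:
    """Map an element coordinate to the family consensus.

    Truncated elements are modelled as internal deletions that retain both
    LTR-bearing ends, so positions in the element's left half map to the
    consensus prefix and the right half to the consensus suffix. Solo-LTRs
    (element == one LTR) map to the 5' LTR of the consensus.
    """
    if elen == fam_len:
        return pos_elem
    keep5 = max(ltr, elen // 2)
    if pos_elem < keep5:
        return pos_elem
    return fam_len - (elen - pos_elem)


def simulate_mate_pairs(
    truth: list[GroundTruthInsertion],
    config: SimulationConfig,
    library: dict[str, str],
    genome: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Emit per-line ERV-anchored alignment records for every insertion.

    For each carrier haplotype both junction sides are sampled at the rate
    given by :func:`expected_junction_pairs`. A configurable fraction of
    additional noise pairs carries a random ERV association and a random
    (mis-)anchor. Deterministic given the config seed.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    family_ids = sorted(library)
    chrom_names = sorted({t.chromosome for t in truth}) or [
        f"chr{i + 1}" for i in range(config.n_chromosomes)
    ]

    L = config.read_length
    rows: list[tuple] = []
    serial = 0
    for t in truth:
        fam_len = len(library[t.erv_family_id])
        left_edge, right_edge = t.reference_span
        for li, line in enumerate(LINES):
            dosage = t.per_line_pool_dosage[li]
            lam = expected_junction_pairs(config, dosage, li, t.element_length)
            if lam <= 0:
                continue
            for side in ("up", "down"):
                k = int(rng.poisson(lam))
                if k == 0:
                    continue
                strand, erv_orient = PAIR_GEOMETRY[(side, t.orientation)]
                inserts = np.clip(
                    rng.normal(config.insert_mean, config.insert_sd, size=k),
                    2 * L,
                    2 * config.insert_mean,
                ).astype(int)
                for ins in inserts:
                    window = min(ins - 2 * L, t.element_length - L)
                    if window <= 0:
                        continue
                    # distance of the ERV-side read start from the junction,
                    # measured into the element
                    erv_dist = int(rng.integers(0, window))
                    anchor_gap = ins - erv_dist - 2 * L  # flank gap to junction
                    if side == "up":
                        pos = left_edge - anchor_gap - L
                    else:
                        pos = right_edge + anchor_gap
                    pos = max(0, pos)
                    junction_end = (
                        ("5p" if side == "up" else "3p")
                        if t.orientation == "sense"
                        else ("3p" if side == "up" else "5p")
                    )
                    if junction_end == "5p":
                        pos_elem = erv_dist
                    else:
                        pos_elem = t.element_length - erv_dist - L
                    erv_pos = _element_to_consensus(
                        pos_elem, t.element_length, fam_len, config.ltr_length
                    )
                    serial += 1
                    rows.append(
                        (
                            f"rp_{serial:08d}",
                            line,
                            t.erv_family_id,
                            int(config.score_model.draw(rng, 1)[0]),
                            erv_orient,
                            int(np.clip(erv_pos, 0, fam_len - L)),
                            t.chromosome,
                            int(pos),
                            strand,
                            "top",
                        )
                    )

    # noise pairs: mis-scored or mis-anchored ERV associations scattered
    # uniformly over the genome
    n_noise = int(rng.binomial(len(rows), config.noise_rate)) if rows else 0
    cov = np.asarray(config.coverage_per_line, dtype=float)
    line_weights = cov / cov.sum() if cov.sum() > 0 else None
    for _ in range(n_noise if line_weights is not None else 0):
        fam = family_ids[int(rng.integers(len(family_ids)))]
        fam_len = len(library[fam])
        serial += 1
        rows.append(
            (
                f"rp_{serial:08d}",
                LINES[int(rng.choice(3, p=line_weights))],
                fam,
                int(config.score_model.draw(rng, 1)[0]),
                "sense" if rng.random() < 0.5 else "antisense",
                int(rng.integers(0, max(fam_len - L, 1))),
                chrom_names[int(rng.integers(len(chrom_names)))],
                int(rng.integers(0, config.chromosome_length - L)),
                "+" if rng.random() < 0.5 else "-",
                "top",
            )
        )

    return pd.DataFrame(rows, columns=eio.ALIGNMENT_COLUMNS)


def simulate_genes(
    config: SimulationConfig, rng: np.random.Generator, n_genes: int = 60
):
    """Random non-overlapping gene models over the simulated chromosomes."""
    from ervsegmap.landscape import GeneModel

    genes = []
    per_chrom = max(1, n_genes // config.n_chromosomes)
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        slot = config.chromosome_length // per_chrom
        for gi in range(per_chrom):
            glen = int(rng.integers(2_000, min(40_000, max(4_000, slot // 2))))
            start = int(gi * slot + rng.integers(0, max(slot - glen, 1)))
            genes.append(
                GeneModel(
                    gene_id=f"gene_{chrom}_{gi + 1:04d}",
                    chromosome=chrom,
                    start=start,
                    end=start + glen,
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
    return genes


def simulate_sweeps(
    config: SimulationConfig, rng: np.random.Generator, fraction: float = 0.05
) -> list[tuple[str, int, int]]:
    """Non-overlapping selective-sweep intervals covering ~``fraction`` of the genome."""
    sweeps = []
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        total = int(config.chromosome_length * fraction)
        n_iv = max(1, total // 50_000)
        iv_len = total // n_iv
        slot = config.chromosome_length // n_iv
        for i in range(n_iv):
            start = int(i * slot + rng.integers(0, max(slot - iv_len, 1)))
            sweeps.append((chrom, start, start + iv_len))
    return sweeps


def simulate_tree(library: dict[str, str], rng: np.random.Generator) -> str:
    """A random rooted binary newick tree over the ERV families."""
    nodes = [f"{name}" for name in sorted(library)]
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        bl_a, bl_b = rng.uniform(0.01, 0.5, size=2)
        nodes.append(f"({a}:{bl_a:.4f},{b}:{bl_b:.4f})")
    return nodes[0] + ";"


def write_fixtures(
    truth: list[GroundTruthInsertion],
    records: pd.DataFrame,
    config: SimulationConfig,
    outdir,
    genome: dict[str, str] | None = None,
    library: dict[str, str] | None = None,
) -> dict:
    """Write all fixture files for a simulated dataset; returns their paths.

    Files: reference FASTA, ERV library FASTA, per-line alignment TSVs,
    ground-truth BED, gene annotation (BED12), sweep intervals (BED3), a
    newick tree over ERV families, and per-line read-pair totals.
    Byte-identical across runs with the same seed.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    paths = {}
    if genome is not None:
        paths["reference"] = outdir / "reference.fa"
        eio.write_fasta(genome, paths["reference"])
    if library is not None:
        paths["library"] = outdir / "erv_library.fa"
        eio.write_fasta(library, paths["library"])

    for line in LINES:
        p = outdir / f"alignments_{line}.tsv"
        eio.write_alignments(records[records["line_id"] == line], p)
        paths[f"alignments_{line}"] = p

    paths["truth"] = outdir / "truth.bed"
    with open(paths["truth"], "w") as fh:
        for t in truth:
            s, e = t.reference_span
            fh.write(
                f"{t.chromosome}\t{s}\t{max(e, s + 1)}\t{t.insertion_id}\t0\t"
                f"{'+' if t.orientation == 'sense' else '-'}\t{t.form}\t"
                f"{t.erv_family_id}\t{int(t.in_reference)}\t"
                f"{','.join(str(d) for d in t.per_line_pool_dosage)}\n"
            )

    genes = simulate_genes(config, rng)
    paths["genes"] = outdir / "genes.bed12"
    eio.write_genes_bed12(genes, paths["genes"])

    sweeps = simulate_sweeps(config, rng)
    paths["sweeps"] = outdir / "sweeps.bed"
    eio.write_bed3(sweeps, paths["sweeps"])

    if library is not None:
        paths["tree"] = outdir / "erv_tree.nwk"
        Path(paths["tree"]).write_text(simulate_tree(library, rng) + "\n")

    totals = {
        f"total_pairs_{line}": int((records["line_id"] == line).sum())
        for line in LINES
    }
    paths["stats"] = outdir / "line_totals.txt"
    eio.write_stats(totals, paths["stats"])
    return paths


def checksum(path) -> str:
    return hashlib.sha256(open(path, "rb").read()).hexdigest()
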