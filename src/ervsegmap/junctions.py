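"""Junction detection: cluster ERV-anchored mate pairs into candidate loci.

One read of a mate pair aligns to the ERV reference library, its mate to a
unique chromosomal position in the flanking host DNA. Anchors on the same
chromosome and junction side are clustered (single linkage with a gap rule
bounded by the mate-pair insert size), clusters must be covered by enough
read footprint, and an upstream cluster is paired with a downstream cluster
sharing orientation and ERV association into a candidate insertion locus.

Side/orientation convention
---------------------------
With inward-pointing mate pairs the host anchor's strand determines which
flank it sits on, and the ERV-side read's orientation relative to the
consensus then fixes the insertion orientation:

    anchor strand   ERV read vs consensus   junction side   insertion
    +               antisense               upstream (5')   sense
    -               sense                   downstream (3') sense
    +               sense                   upstream (5')   antisense
    -               antisense               downstream (3') antisense

"upstream" always means the left (lower-coordinate) host flank.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ervsegmap.config import LINES

logger = logging.getLogger(__name__)

#: (anchor_strand, erv_read_orientation) -> (side, insertion_orientation)
SIDE_ORIENTATION = {
    ("+", "antisense"): ("up", "sense"),
    ("-", "sense"): ("down", "sense"),
    ("+", "sense"): ("up", "antisense"),
    ("-", "antisense"): ("down", "antisense"),
}

#: inverse map: (side, insertion_orientation) -> (anchor_strand, erv_read_orientation)
PAIR_GEOMETRY = {v: k for k, v in SIDE_ORIENTATION.items()}


@dataclass(frozen=True)
class AnchoredPair:
    """A strict-score ERV read joined with its unique chromosomal anchor."""

    read_id: str
    line_id: str
    erv_id: str
    erv_score: int
    erv_pos: int
    chromosome: str
    pos: int
    side: str
    orientation: str


@dataclass
class JunctionCluster:
    """Anchors supporting one side (5' or 3' host flank) of one junction."""

    chromosome: str
    side: str
    orientation: str
    start: int
    end: int
    footprint: int
    members: tuple[str, ...]
    erv_ids: Counter
    erv_positions: dict
    per_line_counts: tuple[int, int, int]

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class CandidateLocus:
    """A paired upstream/downstream junction: one putative ERV insertion."""

    locus_id: str
    chromosome: str
    start: int
    end: int
    orientation: str
    erv_ids: Counter
    per_line_counts: tuple[int, int, int]
    per_line_counts_relaxed: tuple[int, int, int]
    upstream_cluster: JunctionCluster
    downstream_cluster: JunctionCluster
    member_reads: tuple[str, ...] = field(default_factory=tuple)


def select_strict_pairs(
    alignments: pd.DataFrame,
    anchors: pd.DataFrame | None = None,
    score_min: int = 425,
) -> list[AnchoredPair]:
    """Join ERV-side reads with their mates' unique anchors at a strict score.

    ``alignments`` may carry the anchor columns itself (the combined TSV
    dialect) or be joined against a separate ``anchors`` frame on read_id.
    Pairs are kept when the ERV-side score is >= ``score_min`` and the mate
    has a top-quality unique placement. Reads whose mate has no anchor are
    skipped and counted in the log.
    """
    if anchors is not None:
        anchors = anchors.drop_duplicates(subset="read_id", keep="first")
        merged = alignments.merge(
            anchors, on="read_id", how="left", suffixes=("", "_anchor"), indicator=True
        )
        n_orphans = int((merged["_merge"] == "left_only").sum())
        if n_orphans:
            logger.warning("%d ERV reads had no anchored mate; skipped", n_orphans)
        merged = merged[merged["_merge"] == "both"].drop(columns="_merge")
    else:
        merged = alignments
        n_orphans = int(merged["chrom"].isna().sum())
        if n_orphans:
            logger.warning("%d ERV reads had no anchored mate; skipped", n_orphans)
        merged = merged.dropna(subset=["chrom", "pos"])

    merged = merged[
        (merged["erv_score"] >= score_min) & (merged["anchor_quality"] == "top")
    ]
    merged = merged.drop_duplicates(subset="read_id", keep="first")

    pairs = []
    for row in merged.itertuples(index=False):
        key = (row.strand, row.erv_orientation)
        if key not in SIDE_ORIENTATION:
            continue
        side, orientation = SIDE_ORIENTATION[key]
        pairs.append(
            AnchoredPair(
                read_id=row.read_id,
                line_id=row.line_id,
                erv_id=row.erv_id,
                erv_score=int(row.erv_score),
                erv_pos=int(row.erv_pos),
                chromosome=row.chrom,
                pos=int(row.pos),
                side=side,
                orientation=orientation,
            )
        )
    return pairs


def _interval_union(intervals: list[tuple[int, int]]) -> int:
    """Total bases covered by the union of sorted-or-not intervals."""
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def _split_chain(sorted_pairs: list, max_window: int, read_len: int) -> list[list]:
    """Split one linked chain left-to-right so each piece spans <= max_window."""
    pieces: list[list] = []
    cur: list = []
    for p in sorted_pairs:
        if cur and (p.pos + read_len - cur[0].pos) > max_window:
            pieces.append(cur)
            cur = []
        cur.append(p)
    if cur:
        pieces.append(cur)
    return pieces


def _link_chains(sorted_pairs: list, max_window: int, read_len: int) -> list[list]:
    """Single-linkage chains: successive anchors link while the gap between
    read intervals is below max_window. Equivalent to transitive closure of
    the pairwise gap rule on one chromosome/side/orientation group."""
    chains: list[list] = []
    cur: list = []
    for p in sorted_pairs:
        if cur and (p.pos - (cur[-1].pos + read_len)) >= max_window:
            chains.append(cur)
            cur = []
        cur.append(p)
    if cur:
        chains.append(cur)
    return chains


def cluster_junctions(
    pairs: list[AnchoredPair],
    max_window: int = 3_500,
    min_footprint_frac: float = 0.02,
    read_len: int = 50,
) -> list[JunctionCluster]:
    """Cluster anchored pairs into junction clusters per chromosome and side.

    Single-linkage under the gap rule (anchors link while the gap between
    their read intervals is < max_window), with oversize chains split
    left-to-right so every cluster interval spans <= max_window. Clusters
    whose union read footprint is below min_footprint_frac * max_window
    (default 70 bases) are discarded. Output is sorted by coordinate and
    independent of input order.
    """
    min_footprint = min_footprint_frac * max_window
    groups: dict[tuple, list[AnchoredPair]] = {}
    for p in pairs:
        groups.setdefault((p.chromosome, p.side, p.orientation), []).append(p)

    clusters: list[JunctionCluster] = []
    for (chrom, side, orientation), members in groups.items():
        members.sort(key=lambda p: (p.pos, p.read_id))
        for chain in _link_chains(members, max_window, read_len):
            for piece in _split_chain(chain, max_window, read_len):
                footprint = _interval_union(
                    [(p.pos, p.pos + read_len) for p in piece]
                )
                if footprint < min_footprint:
                    continue
                line_counts = Counter(p.line_id for p in piece)
                erv_pos: dict[str, list[int]] = {}
                for p in piece:
                    erv_pos.setdefault(p.erv_id, []).append(p.erv_pos)
                clusters.append(
                    JunctionCluster(
                        chromosome=chrom,
                        side=side,
                        orientation=orientation,
                        start=piece[0].pos,
                        end=max(p.pos for p in piece) + read_len,
                        footprint=footprint,
                        members=tuple(sorted(p.read_id for p in piece)),
                        erv_ids=Counter(p.erv_id for p in piece),
                        erv_positions=erv_pos,
                        per_line_counts=tuple(
                            line_counts.get(line, 0) for line in LINES
                        ),
                    )
                )
    clusters.sort(key=lambda c: (c.chromosome, c.start, c.side, c.orientation))
    return clusters


def _hits_terminal_region(
    positions: list[int], erv_len: int, ltr_len: int, read_len: int, end: str
) -> bool:
    """True if any read hits the given terminal third of the consensus or an LTR.

    Solo-LTR derived reads map inside an LTR; either LTR counts for either
    end since the two proviral LTRs are identical at integration.
    """
    third = erv_len / 3.0
    for pos in positions:
        mid = pos + read_len / 2.0
        if end == "5p" and mid <= third:
            return True
        if end == "3p" and mid >= erv_len - third:
            return True
        if mid <= ltr_len or mid >= erv_len - ltr_len:
            return True
    return False


def _flank_evidence_ok(
    up: JunctionCluster,
    down: JunctionCluster,
    shared_ervs: set,
    erv_lengths: dict | None,
    ltr_length: int,
    read_len: int,
) -> bool:
    """Check that the two clusters hit the two opposite ends of the element.

    For a sense insertion the upstream (left) flank abuts the consensus 5'
    end and the downstream flank its 3' end; antisense swaps the ends.
    Skipped when consensus lengths are unknown.
    """
    if erv_lengths is None:
        return True
    sense = up.orientation == "sense"
    up_end, down_end = ("5p", "3p") if sense else ("3p", "5p")
    for erv in shared_ervs:
        length = erv_lengths.get(erv)
        if length is None:
            continue
        ok_up = _hits_terminal_region(
            up.erv_positions.get(erv, []), length, ltr_length, read_len, up_end
        )
        ok_down = _hits_terminal_region(
            down.erv_positions.get(erv, []), length, ltr_length, read_len, down_end
        )
        if ok_up and ok_down:
            return True
    return False


def pair_junctions(
    clusters: list[JunctionCluster],
    max_separation: int = 20_000,
    erv_lengths: dict | None = None,
    ltr_length: int = 300,
    read_len: int = 50,
):
    """Pair upstream with downstream junction clusters into candidate loci.

    A valid pair shares chromosome, orientation and at least one target ERV,
    shows evidence for both element ends (when consensus lengths are given),
    and spans < max_separation from upstream start to downstream end.
    Greedy nearest-first matching; each cluster joins at most one locus.
    Ties break to the leftmost pair, then the smallest shared erv_id.
    Returns (loci, half_supported_clusters).
    """
    ups = [c for c in clusters if c.side == "up"]
    downs = [c for c in clusters if c.side == "down"]

    candidates = []
    for iu, u in enumerate(ups):
        for idv, d in enumerate(downs):
            if u.chromosome != d.chromosome or u.orientation != d.orientation:
                continue
            # the two flank clusters sit on opposite sides of the junction,
            # so a genuine upstream cluster lies entirely left of its
            # downstream partner; this also blocks cross-pairing between
            # neighbouring same-family insertions
            if u.end > d.start:
                continue
            span_start, span_end = u.start, d.end
            if span_end - span_start >= max_separation:
                continue
            shared = set(u.erv_ids) & set(d.erv_ids)
            if not shared:
                continue
            if not _flank_evidence_ok(u, d, shared, erv_lengths, ltr_length, read_len):
                continue
            separation = span_end - span_start
            candidates.append(
                (separation, span_start, min(shared), iu, idv, u, d)
            )

    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used_up: set[int] = set()
    used_down: set[int] = set()
    loci: list[CandidateLocus] = []
    for separation, span_start, _, iu, idv, u, d in candidates:
        if iu in used_up or idv in used_down:
            continue
        used_up.add(iu)
        used_down.add(idv)
        counts = tuple(
            a + b for a, b in zip(u.per_line_counts, d.per_line_counts)
        )
        span_end = span_start + separation
        loci.append(
            CandidateLocus(
                locus_id=f"locus_{u.chromosome}_{span_start}_{span_end}",
                chromosome=u.chromosome,
                start=span_start,
                end=span_end,
                orientation=u.orientation,
                erv_ids=u.erv_ids + d.erv_ids,
                per_line_counts=counts,
                per_line_counts_relaxed=counts,
                upstream_cluster=u,
                downstream_cluster=d,
                member_reads=tuple(sorted(u.members + d.members)),
            )
        )
    loci.sort(key=lambda l: (l.chromosome, l.start, l.end))
    half = [
        c
        for i, c in enumerate(ups)
        if i not in used_up
    ] + [c for i, c in enumerate(downs) if i not in used_down]
    return loci, half


def append_relaxed_reads(
    loci: list[CandidateLocus],
    alignments: pd.DataFrame,
    anchors: pd.DataFrame | None = None,
    relaxed_min: int = 400,
    score_min: int = 425,
) -> list[CandidateLocus]:
    """Append relaxed-score reads (relaxed_min <= score < score_min) to loci.

    A relaxed read increments a locus's relaxed per-line counts when its
    anchor falls inside one of the locus's junction-cluster intervals and it
    matches that cluster's ERV association, side and orientation. New loci
    are never created.
    """
    relaxed = select_strict_pairs(alignments, anchors, score_min=relaxed_min)
    relaxed = [p for p in relaxed if p.erv_score < score_min]

    out: list[CandidateLocus] = []
    for loc in loci:
        extra = [0, 0, 0]
        for p in relaxed:
            for cl in (loc.upstream_cluster, loc.downstream_cluster):
                if (
                    p.chromosome == cl.chromosome
                    and p.side == cl.side
                    and p.orientation == cl.orientation
                    and cl.start <= p.pos < cl.end
                    and p.erv_id in cl.erv_ids
                ):
                    extra[LINES.index(p.line_id)] += 1
                    break
        out.append(
            replace(
                loc,
                per_line_counts_relaxed=tuple(
                    c + e for c, e in zip(loc.per_line_counts, extra)
                ),
            )
        )
    return out


def tune_to_target(
    pairs_by_threshold,
    target_loci: int = 10_000,
    thresholds=None,
    **cluster_kwargs,
) -> tuple[int, dict[int, int]]:
    """Sweep the strict score threshold toward a target locus count.

    ``pairs_by_threshold`` is either a list of AnchoredPair (all at the
    relaxed floor) or a callable threshold -> pairs. The expected locus
    count is around 20x the number of full-length library elements (the
    solo-LTR : provirus ratio); clustering conditions are chosen so the
    recovered locus count lands near that target. Returns the threshold
    minimizing |count - target| (ties to the higher, more conservative
    threshold) plus the full sweep counts.
    """
    if target_loci <= 0:
        raise ValueError("target_loci must be positive")

    if callable(pairs_by_threshold):
        get_pairs = pairs_by_threshold
        if thresholds is None:
            raise ValueError("thresholds required with a callable pair source")
    else:
        all_pairs = list(pairs_by_threshold)
        if not all_pairs:
            raise ValueError("empty pair set")
        if thresholds is None:
            scores = sorted({p.erv_score for p in all_pairs})
            thresholds = scores

        def get_pairs(t, _pairs=all_pairs):
            return [p for p in _pairs if p.erv_score >= t]

    counts: dict[int, int] = {}
    for t in thresholds:
        clusters = cluster_junctions(get_pairs(t), **{
            k: v for k, v in cluster_kwargs.items()
            if k in ("max_window", "min_footprint_frac", "read_len")
        })
        loci, _ = pair_junctions(
            clusters,
            **{k: v for k, v in cluster_kwargs.items()
               if k in ("max_separation", "erv_lengths", "ltr_length", "read_len")},
        )
        counts[t] = len(loci)

    best_count = max(counts.values(), default=0)
    if best_count < target_loci:
        logger.warning(
            "target of %d loci not achievable; best is %d", target_loci, best_count
        )
        # everything undershoots: keep the most permissive threshold
        best = min(t for t in counts if counts[t] == best_count)
    else:
        best = min(counts, key=lambda t: (abs(counts[t] - target_loci), -t))
    return best, counts


def derive_locus_target(n_full_ervs: int, solo_ratio: float = 20.0) -> int:
    """Expected candidate locus count from the library's full-element count.

    Solo-LTRs — the product of recombination between a provirus's two LTRs —
    outnumber full-length elements about 20:1, so a library of N proviruses
    implies roughly 20N + N segregating loci.
    """
    return int(round(n_full_ervs * solo_ratio))
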