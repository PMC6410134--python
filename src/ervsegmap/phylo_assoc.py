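"""Associate candidate loci with reference-assembly ERVs on a phylogeny.

Mate-pair reads reach only a short way into each insertion, so a locus is
tied to the reference ERV its member reads support best (summed alignment
score), and a provided reference-ERV tree is annotated at the matching
tips with the locus's line-difference pattern. Tree inference itself is
consumed, not computed: the input newick (typically rooted on a distant
outgroup element) is taken as given and preserved byte-for-byte apart
from inserted tip comments.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import dendropy
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ErvAssignment:
    locus_id: str
    best_erv_id: str
    support: int  # summed member-read alignment score for the winner
    margin: int  # gap to the runner-up (== support if unopposed)
    ambiguous: bool


def per_erv_support(locus, alignments) -> dict[str, int]:
    """Summed member-read scores per target ERV for one locus."""
    members = set(locus.member_reads)
    support: dict[str, int] = {}
    sub = alignments[alignments["read_id"].isin(members)]
    for row in sub.itertuples(index=False):
        support[row.erv_id] = support.get(row.erv_id, 0) + int(row.erv_score)
    return support


def assign_best_erv(locus, alignments, min_margin: int = 0) -> ErvAssignment:
    """Pick the reference ERV with maximal summed read support for a locus.

    Ties break to the lexicographically smaller ERV id; the assignment is
    flagged ambiguous when the winner's margin over the runner-up is below
    ``min_margin`` (a tie always is).
    """
    support = per_erv_support(locus, alignments)
    if not support:
        raise ValueError(f"locus {locus.locus_id} has no ERV-library hits")
    ranked = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
    best_id, best_sup = ranked[0]
    margin = best_sup - ranked[1][1] if len(ranked) > 1 else best_sup
    tie = len(ranked) > 1 and ranked[1][1] == best_sup
    return ErvAssignment(
        locus_id=locus.locus_id,
        best_erv_id=best_id,
        support=best_sup,
        margin=margin,
        ambiguous=tie or margin < min_margin,
    )


def _tip_labels(newick_text: str) -> set[str]:
    tree = dendropy.Tree.get(
        data=newick_text, schema="newick", preserve_underscores=True
    )
    return {leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon}


def annotate_tree(
    newick_text: str,
    assignments: list[ErvAssignment],
    results=None,
) -> tuple[str, list[dict], list[str]]:
    """Attach per-tip difference symbols as newick comment blocks.

    Each tip named by an assignment gains a ``[&...]`` comment listing the
    presence patterns (from ``results``, keyed by locus_id) and locus count
    of the loci assigned to it. Topology, branch lengths and untouched tips
    are byte-preserved: annotation is textual insertion after the tip
    label. Returns (annotated newick, tip table rows, warnings for
    assignments naming unknown tips).
    """
    patterns_by_locus = {}
    if results is not None:
        patterns_by_locus = {
            r.locus_id: r.pattern for r in results if r.pattern is not None
        }

    known = _tip_labels(newick_text)
    per_tip: dict[str, list[ErvAssignment]] = {}
    warnings: list[str] = []
    for a in assignments:
        if a.best_erv_id not in known:
            warnings.append(
                f"assignment for {a.locus_id} names unknown tip {a.best_erv_id}"
            )
            continue
        per_tip.setdefault(a.best_erv_id, []).append(a)

    out = newick_text
    table = []
    for tip in sorted(per_tip):
        assigned = per_tip[tip]
        pats = sorted(
            patterns_by_locus.get(a.locus_id, "?") for a in assigned
        )
        comment = f"[&loci={len(assigned)},patterns={'|'.join(pats)}]"
        # insert the comment directly after the tip label (quoted or bare)
        pattern = re.compile(
            r"(?<![\w.|])(" + re.escape(tip) + r")(?=[\s:,)\[;])"
        )
        out, n = pattern.subn(r"\1" + comment.replace("\\", "\\\\"), out, count=1)
        if n == 0:
            warnings.append(f"tip {tip} present in taxa but not matched in text")
        table.append(
            {
                "erv_id": tip,
                "n_loci": len(assigned),
                "patterns": "|".join(pats),
                "locus_ids": ",".join(a.locus_id for a in assigned),
            }
        )
    for w in warnings:
        logger.warning(w)
    return out, table, warnings


def dispersion_summary(
    annotated_tips: dict[str, int],
    clade_map: dict[str, str],
) -> dict:
    """Spread of annotated tips across major clades of the reference tree.

    Tests whether annotations distribute across clades proportionally to
    clade sizes (chi-square goodness of fit). A concentrated signal — all
    differences inside one retroviral clade — would indicate lineage-
    specific retroviral expansion rather than standing variation.
    """
    clades = sorted(set(clade_map.values()))
    sizes = {c: 0 for c in clades}
    for tip, clade in clade_map.items():
        sizes[clade] += 1
    counts = {c: 0 for c in clades}
    unassigned = 0
    for tip, n in annotated_tips.items():
        clade = clade_map.get(tip)
        if clade is None:
            unassigned += n
        else:
            counts[clade] += n
    total = sum(counts.values())
    out = {
        "per_clade_counts": counts,
        "per_clade_sizes": sizes,
        "unassigned": unassigned,
        "n_clades_hit": sum(1 for c in clades if counts[c] > 0),
        "total_annotations": total,
    }
    if total > 0 and len(clades) > 1:
        expected = [total * sizes[c] / sum(sizes.values()) for c in clades]
        observed = [counts[c] for c in clades]
        chi, p = stats.chisquare(observed, expected)
        out["chi_square"] = float(chi)
        out["p_value"] = float(p)
    else:
        out["chi_square"] = float("nan")
        out["p_value"] = float("nan")
    return out
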