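"""Pattern-level summary tables and Venn counts for differential loci.

The reporting unit is the presence pattern: which of the three lines
(H, L, W) carry a candidate insertion. Seven non-empty patterns exist;
``HLW`` (present in all lines) carries no differential signal and is
excluded from corrected-significance accounting ("nd" in reports).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ervsegmap.difftest import PATTERNS, DifferentialResult


@dataclass
class PatternRow:
    """One presence pattern's counts in the summary table."""

    candidate_loci: int = 0
    corrected_loci: int = 0
    ervs_adjacent_to_genes: int = 0
    genes_adjacent_to_ervs: int = 0


@dataclass
class PatternSummary:
    """Per-pattern counts plus the headline totals derived from them."""

    rows: dict = field(default_factory=dict)

    @classmethod
    def from_rows(cls, rows: dict) -> "PatternSummary":
        clean = {}
        for pat in PATTERNS:
            row = rows.get(pat, PatternRow())
            if isinstance(row, (tuple, list)):
                row = PatternRow(*row)
            clean[pat] = row
        return cls(rows=clean)

    # -- headline totals (computed, never stored) --------------------------
    @property
    def total_candidate_loci(self) -> int:
        return sum(r.candidate_loci for r in self.rows.values())

    @property
    def total_differential_loci(self) -> int:
        """Candidate loci absent or near-absent in at least one line."""
        return sum(
            r.candidate_loci for p, r in self.rows.items() if p != "HLW"
        )

    @property
    def total_corrected_loci(self) -> int:
        return sum(
            r.corrected_loci for p, r in self.rows.items() if p != "HLW"
        )

    @property
    def total_ervs_adjacent_to_genes(self) -> int:
        return sum(
            r.ervs_adjacent_to_genes for p, r in self.rows.items() if p != "HLW"
        )

    @property
    def total_genes_adjacent_to_ervs(self) -> int:
        return sum(
            r.genes_adjacent_to_ervs for p, r in self.rows.items() if p != "HLW"
        )

    @property
    def differential_fraction(self) -> float:
        """Fraction of candidate loci showing a nominal line difference."""
        total = self.total_candidate_loci
        return self.total_differential_loci / total if total else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pat in PATTERNS:
            r = self.rows.get(pat, PatternRow())
            nd = pat == "HLW"
            rows.append(
                {
                    "pattern": pat,
                    "candidate_loci": r.candidate_loci,
                    "corrected_loci": "nd" if nd else r.corrected_loci,
                    "ervs_adjacent_to_genes": "nd" if nd else r.ervs_adjacent_to_genes,
                    "genes_adjacent_to_ervs": "nd" if nd else r.genes_adjacent_to_ervs,
                }
            )
        return pd.DataFrame(rows)

    def venn_counts(self) -> dict:
        """Venn-region locus counts over the three lines.

        Patterns map one-to-one onto Venn regions (the pattern's line set
        is the region's membership)."""
        return {
            pat: self.rows.get(pat, PatternRow()).candidate_loci
            for pat in PATTERNS
        }


def summarize(
    results: list[DifferentialResult],
    gene_adjacency: dict | None = None,
) -> PatternSummary:
    """Aggregate per-locus results into the pattern summary table.

    ``gene_adjacency`` optionally maps locus_id -> set of adjacent gene
    ids (for corrected-significant loci); it feeds the two gene columns.
    """
    rows = {pat: PatternRow() for pat in PATTERNS}
    gene_sets: dict[str, set] = {pat: set() for pat in PATTERNS}
    for res in results:
        pat = res.pattern
        if pat is None or pat not in rows:
            continue
        rows[pat].candidate_loci += 1
        if res.significant and pat != "HLW":
            rows[pat].corrected_loci += 1
            if gene_adjacency and res.locus_id in gene_adjacency:
                genes = set(gene_adjacency[res.locus_id])
                if genes:
                    rows[pat].ervs_adjacent_to_genes += 1
                    gene_sets[pat] |= genes
    for pat in PATTERNS:
        rows[pat].genes_adjacent_to_ervs = len(gene_sets[pat])
    return PatternSummary.from_rows(rows)


#: Pattern-level candidate-locus table for the three-line domestic chicken
#: survey (high-growth H, low-growth L, White Leghorn W pools) that this
#: pipeline models: candidate loci, Bonferroni-corrected differential loci,
#: and gene adjacency within 150 kb, per presence pattern. Used as the
#: worked example for the reporting path; the headline totals
#: (12,709 candidates, 8,340 with a line difference, 369 corrected,
#: 115 gene-adjacent insertions next to 229 genes) are arithmetic over
#: these rows and are always recomputed via PatternSummary.
CHICKEN_THREE_LINE_PATTERN_TABLE = {
    "H..": PatternRow(874, 38, 11, 29),
    ".L.": PatternRow(1109, 52, 19, 38),
    "..W": PatternRow(616, 117, 46, 95),
    "HL.": PatternRow(2966, 103, 19, 36),
    "H.W": PatternRow(1227, 30, 9, 11),
    ".LW": PatternRow(1548, 29, 11, 20),
    "HLW": PatternRow(4369, 0, 0, 0),
}

#: Per-line pooled-library characteristics of the same survey: pool size,
#: fold coverage, and ERV-host read-pair totals (the normalization
#: baseline for the contingency tables).
CHICKEN_THREE_LINE_LIBRARIES = {
    "H": {"n": 11, "coverage": 5.53, "erv_assoc_reads": 233_621, "erv_host_pairs": 82_719},
    "L": {"n": 11, "coverage": 5.19, "erv_assoc_reads": 239_189, "erv_host_pairs": 98_942},
    "W": {"n": 11, "coverage": 3.37, "erv_assoc_reads": 191_873, "erv_host_pairs": 90_759},
}
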