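"""Per-locus differential presence testing across the three pooled lines.

Each candidate locus yields a 2x3 contingency table: supporting read-pair
counts per line against the remaining line-wide ERV-host pair totals,
which absorbs the fold-coverage imbalance between pools. Loci with sparse
support (minimum count below a cutoff, default 15) are tested with the
Freeman-Halton exact test (the 2x3 generalization of Fisher's exact test,
computed by enumeration over tables with fixed margins); well-supported
loci use Pearson's chi-square with 2 degrees of freedom. Family-wise error
over all tested loci is controlled by Bonferroni correction.

Presence patterns name the subset of lines carrying the insertion, in the
fixed order (H, L, W) with absent lines dotted: ``H..`` is private to the
high-growth line, ``HL.`` is shared by the growth-selected lines, ``HLW``
is present everywhere (and carries no differential signal).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats
from scipy.special import gammaln

from ervsegmap.config import LINES

logger = logging.getLogger(__name__)

PATTERNS = ("H..", ".L.", "..W", "HL.", "H.W", ".LW", "HLW")

#: branches of the fixed line tree (((H,L),W),reference) and the tip set
#: gained/lost by a single event on each
BRANCH_CLADES = {
    "H": frozenset({"H"}),
    "L": frozenset({"L"}),
    "W": frozenset({"W"}),
    "HL": frozenset({"H", "L"}),
    "HLW": frozenset({"H", "L", "W"}),
}


@dataclass
class LocusCountTable:
    """Per-line supporting reads at one locus plus line-wide totals."""

    locus_id: str
    counts: tuple[int, int, int]
    line_totals: tuple[int, int, int]

    def validate(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if any(t <= 0 for t in self.line_totals):
            raise ValueError("line totals must be positive")
        if any(c > t for c, t in zip(self.counts, self.line_totals)):
            raise ValueError("counts cannot exceed line totals")


@dataclass
class Polarity:
    """Parsimony interpretation of a pattern on the fixed line tree."""

    kind: str  # gain / loss / ambiguous / none
    branch: str | None
    resolutions: tuple[str, ...] = ()


@dataclass
class DifferentialResult:
    locus_id: str
    counts: tuple[int, int, int]
    p_value: float
    test_used: str  # fisher / chi-square
    significant: bool
    pattern: str | None
    polarity: Polarity | None = None
    in_reference: bool = False
    chromosome: str | None = None
    start: int | None = None
    end: int | None = None


def freeman_halton_2x3(counts, rest) -> float:
    """Exact p for a 2x3 table by enumeration over tables with fixed margins.

    Probability weights are multivariate hypergeometric (the conditional
    null given margins); the p-value sums the probabilities of all tables
    no more probable than the observed one (two-sided by construction).
    """
    counts = [int(c) for c in counts]
    rest = [int(r) for r in rest]
    col = [c + r for c, r in zip(counts, rest)]
    s = sum(counts)  # first-row total
    n = sum(col)

    log_norm = (
        gammaln(s + 1)
        + gammaln(n - s + 1)
        - gammaln(n + 1)
        + sum(gammaln(cj + 1) for cj in col)
    )

    def log_p_grid(a, b, c):
        return log_norm - (
            gammaln(a + 1)
            + gammaln(b + 1)
            + gammaln(c + 1)
            + gammaln(col[0] - a + 1)
            + gammaln(col[1] - b + 1)
            + gammaln(col[2] - c + 1)
        )

    lp_obs = float(log_p_grid(counts[0], counts[1], counts[2]))
    a_lo, a_hi = max(0, s - col[1] - col[2]), min(s, col[0])
    a = np.arange(a_lo, a_hi + 1)[:, None]
    b = np.arange(0, min(s, col[1]) + 1)[None, :]
    c = s - a - b
    valid = (c >= 0) & (c <= col[2])
    lp = log_p_grid(
        np.broadcast_to(a, valid.shape)[valid], b[0][np.where(valid)[1]], c[valid]
    )
    total = float(np.exp(lp[lp <= lp_obs + 1e-9]).sum())
    return min(total, 1.0)


def test_locus(table: LocusCountTable, fisher_cutoff: int = 15) -> DifferentialResult:
    """Test one locus for read-support differences across the lines.

    The exact (Freeman-Halton) path is taken when the minimum locus count
    is below ``fisher_cutoff``; otherwise a Pearson chi-square against
    expectations proportional to the line totals, df = 2, upper tail.
    An all-zero locus carries no evidence and gets p = 1 by convention.
    """
    table.validate()
    counts = table.counts
    rest = tuple(t - c for c, t in zip(counts, table.line_totals))

    if sum(counts) == 0:
        logger.info("locus %s has no supporting reads; p = 1", table.locus_id)
        return DifferentialResult(
            locus_id=table.locus_id,
            counts=counts,
            p_value=1.0,
            test_used="fisher",
            significant=False,
            pattern=None,
        )

    if min(counts) < fisher_cutoff:
        p = freeman_halton_2x3(counts, rest)
        used = "fisher"
    else:
        obs = np.array([counts, rest], dtype=float)
        _, p, _, _ = stats.chi2_contingency(obs, correction=False)
        used = "chi-square"
    return DifferentialResult(
        locus_id=table.locus_id,
        counts=counts,
        p_value=float(p),
        test_used=used,
        significant=False,
        pattern=None,
    )


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Family-wise corrected per-test threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def round_one_sig_fig(x: float) -> float:
    """Round to one significant figure (reporting convention)."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp)


def classify_pattern(
    table: LocusCountTable, absence_frac: float = 0.02
) -> str | None:
    """Call per-line presence/absence and name the resulting pattern.

    A line is called absent when its count is at or below
    ``max(1, floor(absence_frac * expected))`` where the expected count is
    the locus total shared out proportionally to the line-wide totals
    (the coverage-scaled expectation under equal presence). Loci absent
    everywhere return None and are excluded.
    """
    total = sum(table.counts)
    if total == 0:
        return None
    shares = np.asarray(table.line_totals, dtype=float)
    shares = shares / shares.sum()
    present = []
    for c, share in zip(table.counts, shares):
        cutoff = max(1, math.floor(absence_frac * total * share))
        present.append(c > cutoff)
    if not any(present):
        return None
    return "".join(l if p else "." for l, p in zip(LINES, present))


def pattern_lines(pattern: str) -> frozenset:
    return frozenset(l for l in pattern if l != ".")


def polarize_on_tree(pattern: str, in_reference_assembly: bool) -> Polarity:
    """Polarize a presence pattern into gain/loss events on the line tree.

    The fixed tree is (((H, L), W), reference): the reference assembly
    genome is the outgroup. A locus present in the reference assembly is
    ancestrally present, so lines lacking it reflect losses; a
    non-reference locus is ancestrally absent, so presence reflects gains.
    When the pattern's line set is exactly one branch's clade a single
    event explains it; otherwise two events are needed and the minimal
    resolutions are reported as ambiguous.
    """
    lines = pattern_lines(pattern)
    if not lines:
        return Polarity(kind="none", branch=None)

    if not in_reference_assembly:
        target = lines  # single gain must create exactly these carriers
        event = "gain"
    else:
        target = frozenset(LINES) - lines  # single loss removes these
        event = "loss"
        if not target:
            return Polarity(kind="none", branch=None)  # present everywhere

    for branch, clade in BRANCH_CLADES.items():
        if clade == target:
            return Polarity(kind=event, branch=branch)

    resolutions = _minimal_two_event_resolutions(lines, in_reference_assembly)
    return Polarity(kind="ambiguous", branch=None, resolutions=tuple(resolutions))


def _minimal_two_event_resolutions(lines: frozenset, in_ref: bool) -> list[str]:
    """Enumerate minimal event sets explaining a pattern on the fixed tree.

    Brute force over per-branch events (none/gain/loss on each of the five
    branches), simulating tip states from the root state (present iff the
    locus is in the reference assembly), keeping scenarios of minimal size.
    """
    branches = list(BRANCH_CLADES)
    # order from root towards tips so nested branches apply after wider ones
    order = sorted(branches, key=lambda b: -len(BRANCH_CLADES[b]))
    best: list[tuple[int, str]] = []
    for events in product(("none", "gain", "loss"), repeat=len(order)):
        state = {l: in_ref for l in LINES}
        valid = True
        for branch, ev in zip(order, events):
            if ev == "none":
                continue
            clade = BRANCH_CLADES[branch]
            base = {state[l] for l in clade}
            if ev == "gain" and base == {True}:
                valid = False  # gain onto already-present clade
                break
            if ev == "loss" and base == {False}:
                valid = False
                break
            for l in clade:
                state[l] = ev == "gain"
        if not valid:
            continue
        if frozenset(l for l in LINES if state[l]) != lines:
            continue
        cost = sum(e != "none" for e in events)
        desc = "+".join(
            f"{e}@{b}" for b, e in zip(order, events) if e != "none"
        )
        best.append((cost, desc))
    if not best:
        return []
    min_cost = min(c for c, _ in best)
    return sorted({d for c, d in best if c == min_cost})


def run_differential_tests(
    tables: list[LocusCountTable],
    alpha: float = 0.05,
    fisher_cutoff: int = 15,
    absence_frac: float = 0.02,
    in_reference: dict | None = None,
) -> tuple[list[DifferentialResult], float]:
    """Test every locus, apply Bonferroni, classify and polarize patterns.

    Returns the per-locus results plus the corrected threshold alpha/m
    (m = number of loci tested).
    """
    m = len(tables)
    if m == 0:
        return [], float("nan")
    threshold = bonferroni_threshold(m, alpha)
    results = []
    for t in tables:
        res = test_locus(t, fisher_cutoff=fisher_cutoff)
        res.pattern = classify_pattern(t, absence_frac=absence_frac)
        in_ref = bool(in_reference.get(t.locus_id, False)) if in_reference else False
        res.in_reference = in_ref
        res.significant = res.p_value < threshold
        if res.pattern is not None:
            res.polarity = polarize_on_tree(res.pattern, in_ref)
        results.append(res)
    return results, threshold
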