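"""Quadparser-style G-quadruplex prediction and enrichment summaries.

A candidate intramolecular quadruplex is four runs of at least three G's
separated by loops of 1-7 nucleotides; runs of C's mark a quadruplex on the
opposite strand and are scanned in the same pass. Matching is greedy and
left-to-right: runs are taken maximal, the next run is the earliest one
reachable within the loop bounds, and matches never overlap (within a base
type). N never participates in a run or loop. Promoter-level presence is
summarised per gene group (Table-style n_genes / n_with_G4 / percentage)
and compared between a cyclic-gene set and the genome background with a
two-sided Fisher exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class G4Pattern:
    """Run/loop geometry of the quadruplex pattern."""

    min_run: int = 3
    n_runs: int = 4
    loop_min: int = 1
    loop_max: int = 7

    def __post_init__(self) -> None:
        if self.min_run < 2:
            raise ValueError("min_run must be >= 2")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if self.loop_min < 1 or self.loop_max < self.loop_min:
            raise ValueError("need 1 <= loop_min <= loop_max")


@dataclass
class G4Annotation:
    """Predicted quadruplex intervals for one promoter (0-based half-open)."""

    gene: str
    intervals: list  # (start, end, base) with base in {"G", "C"}

    @property
    def has_g4(self) -> bool:
        return bool(self.intervals)


def _runs_of(seq: str, base: str, min_run: int):
    """Maximal runs of ``base`` with length >= min_run, as (start, end)."""
    runs = []
    i = 0
    L = len(seq)
    while i < L:
        if seq[i] == base:
            j = i
            while j < L and seq[j] == base:
                j += 1
            if j - i >= min_run:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _scan_base(seq: str, base: str, pattern: G4Pattern):
    """Greedy left-to-right maximal-run matching for one base type."""
    runs = _runs_of(seq, base, pattern.min_run)
    matches = []
    idx = 0
    n = len(runs)
    while idx < n:
        start, end = runs[idx]
        chain_end = end
        k = idx
        ok = True
        for _ in range(pattern.n_runs - 1):
            nxt = None
            for m in range(k + 1, n):
                gap = runs[m][0] - chain_end
                if gap < pattern.loop_min:
                    continue  # runs are maximal so gap >= 1 always; keep general
                if gap > pattern.loop_max:
                    break
                loop = seq[chain_end : runs[m][0]]
                if "N" in loop or "n" in loop:
                    break
                nxt = m
                break
            if nxt is None:
                ok = False
                break
            k = nxt
            chain_end = runs[k][1]
        if ok:
            matches.append((start, chain_end, base))
            # non-overlapping: resume after the last consumed run
            idx = k + 1
        else:
            idx += 1
    return matches


def find_g4(seq: str, pattern: G4Pattern = G4Pattern()):
    """All predicted quadruplex intervals in ``seq`` (both G- and C-type),
    sorted by start. Coordinates are 0-based half-open."""
    if not seq:
        return []
    matches = _scan_base(seq, "G", pattern) + _scan_base(seq, "C", pattern)
    return sorted(matches)


def annotate_promoter(gene: str, seq: str, pattern: G4Pattern = G4Pattern()):
    return G4Annotation(gene, find_g4(seq, pattern))


def promoter_g4_table(groups: dict, pattern: G4Pattern = G4Pattern()):
    """Per-group presence counts: {group: {gene: promoter_seq}} ->
    {group: {n_genes, n_with_g4, percent}}. Percentages are rounded to the
    nearest integer; an empty group reports 0 with a flag."""
    out = {}
    for group, promoters in groups.items():
        n = len(promoters)
        if n == 0:
            logger.warning("promoter_g4_table: empty group %r", group)
            out[group] = {"n_genes": 0, "n_with_g4": 0, "percent": 0, "empty": True}
            continue
        with_g4 = sum(1 for seq in promoters.values() if find_g4(seq, pattern))
        out[group] = {
            "n_genes": n,
            "n_with_g4": with_g4,
            "percent": int(round(100.0 * with_g4 / n)),
            "empty": False,
        }
    return out


def group_percent(n_with: int, n_total: int) -> int:
    """Nearest-integer percentage as printed in presence tables."""
    if n_total == 0:
        return 0
    return int(round(100.0 * n_with / n_total))


def fisher_enrichment(k_in: int, n_in: int, k_bg: int, n_bg: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table
    (with G4 / without) x (gene set / background).

    Two-sidedness sums all tables with point probability <= the observed
    one. A zero-margin table returns p = 1."""
    for k, n in ((k_in, n_in), (k_bg, n_bg)):
        if k < 0 or n < 0 or k > n:
            raise ValueError("need 0 <= k <= n for both groups")
    table = np.array([[k_in, n_in - k_in], [k_bg, n_bg - k_bg]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
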