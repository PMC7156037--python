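"""Venn-style overlap of locus sets with a one-sided Fisher exact test.

The overlap of two sets drawn from a stated universe is summarised as a
2x2 table and tested for enrichment against the hypergeometric null: the
p-value is P(X >= observed overlap) with X ~ Hypergeometric(N, |A|, |B|).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Sequence

import math

from scipy import stats

P_FLOOR = 2.2e-16  # display floor for tiny p-values in text output


@dataclass(frozen=True)
class OverlapResult:
    """2x2 overlap table with odds ratio and Fisher p-value."""

    table: tuple[int, int, int, int]  # (in_both, a_only, b_only, neither)
    odds_ratio: float
    p: float
    alternative: str = "greater"


def overlap_table(set_a: Collection[str], set_b: Collection[str],
                  universe: Collection[str]) -> tuple[int, int, int, int]:
    """Counts (|A∩B|, |A\\B|, |B\\A|, |universe \\ (A∪B)|)."""
    a, b, u = set(set_a), set(set_b), set(universe)
    for label, s in (("A", a), ("B", b)):
        stray = s - u
        if stray:
            raise ValueError(
                f"set {label} member(s) outside the universe: {sorted(stray)[:5]}"
            )
    both = len(a & b)
    return both, len(a) - both, len(b) - both, len(u - (a | b))


def fisher_exact_upper(table: Sequence[int], alternative: str = "greater") -> OverlapResult:
    """Fisher's exact test on a 2x2 overlap table.

    One-sided (enrichment) by default: ``p = P(X >= a)`` for
    X ~ Hypergeometric(N = a+b+c+d, K = a+b, n = a+c). Odds ratio is
    ``(a*d)/(b*c)``, infinity when ``b*c == 0`` and ``a*d > 0``.
    """
    a, b, c, d = (int(x) for x in table)
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    n_universe = a + b + c + d
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    if alternative == "greater":
        p = float(stats.hypergeom.sf(a - 1, n_universe, a + b, a + c))
    elif alternative == "two-sided":
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = min(p, 1.0)
    return OverlapResult((a, b, c, d), odds, p, alternative)


def format_p(p: float) -> str:
    """Text rendering of a p-value with the conventional 2.2e-16 floor."""
    if p < P_FLOOR:
        return "< 2.2e-16"
    return f"{p:.4g}"


def fisher_overlap(set_a: Collection[str], set_b: Collection[str],
                 universe: Collection[str], alternative: str = "greater") -> OverlapResult:
    """Convenience composition of overlap_table and fisher_exact_upper."""
    return fisher_exact_upper(overlap_table(set_a, set_b, universe), alternative)


def pairwise_overlaps(named_sets: dict[str, Collection[str]],
                      universe: Collection[str]) -> list[tuple[str, str, OverlapResult]]:
    """All pairwise Fisher tests among the named sets (Venn counts only)."""
    names = list(named_sets)
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = fisher_overlap(named_sets[names[i]], named_sets[names[j]], universe)
            out.append((names[i], names[j], res))
    return out
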