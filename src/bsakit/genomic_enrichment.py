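"""Genomic-compartment enrichment tests.

Classifies loci into chromosome arms vs pericentromeres (midpoint rule),
tests compartment enrichment of a locus set against the genomic background
with a chi-square goodness-of-fit (df = 1, no continuity correction), and
reports the fraction of a set overlapping heterochromatic chromatin states
(states 8/9 of a nine-state segmentation, ≥50% length-overlap rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree
from scipy import stats

from .genome import GenomeModel, Locus, LocusSet

ARM = "arm"
PERICENTROMERIC = "pericentromeric"


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed compartment counts vs expected background proportions."""

    set_name: str
    observed: tuple[int, int]  # (n_arm, n_peri)
    expected_proportions: tuple[float, float]  # (p_arm, p_peri)
    chi2: float
    df: int
    p: float
    stars: str


def significance_stars(p: float) -> str:
    """'**' for p ≤ 0.01, '*' for p ≤ 0.05, else 'n.s'."""
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "n.s"


def classify_compartment(locus: Locus, genome: GenomeModel) -> str:
    """Arm vs pericentromeric by the locus midpoint (boundary inclusive)."""
    if locus.chrom not in genome.names:
        raise ValueError(f"locus {locus.id} on unknown chromosome {locus.chrom!r}")
    interval = dict(genome.pericentromere).get(locus.chrom)
    if interval is None:
        return ARM
    start, end = interval
    return PERICENTROMERIC if start <= locus.midpoint <= end else ARM


def compartment_counts(loci: Iterable[Locus], genome: GenomeModel) -> tuple[int, int]:
    n_arm = n_peri = 0
    for locus in loci:
        if classify_compartment(locus, genome) == ARM:
            n_arm += 1
        else:
            n_peri += 1
    return n_arm, n_peri


def background_proportions(all_loci: LocusSet, locus_class: str,
                           genome: GenomeModel) -> tuple[float, float]:
    """Compartment proportions of the class-filtered genomic background."""
    filtered = all_loci.filter_class(locus_class)
    if len(filtered) == 0:
        raise ValueError(
            f"background {all_loci.name!r} is empty after filtering for class "
            f"{locus_class!r}"
        )
    n_arm, n_peri = compartment_counts(filtered, genome)
    total = n_arm + n_peri
    return n_arm / total, n_peri / total


def chi2_goodness_of_fit(observed: Sequence[int],
                         proportions: Sequence[float]) -> tuple[float, float]:
    """Closed-form chi-square goodness-of-fit against expected proportions.

    ``chi2 = sum((O - E)^2 / E)`` with ``E = n * p`` and df = number of
    categories − 1 (no continuity correction); returns ``(chi2, p)`` with p
    the upper-tail chi-square probability.
    """
    if len(observed) != len(proportions) or len(observed) < 2:
        raise ValueError("observed and proportions must align, length >= 2")
    n = sum(observed)
    if n <= 0:
        raise ValueError("empty observation vector")
    expected = [n * p for p in proportions]
    if any(e <= 0 for e in expected):
        raise ValueError(
            "an expected count is zero; use a background with every "
            "category represented"
        )
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return chi2, float(stats.chi2.sf(chi2, df=len(observed) - 1))


def chi2_enrichment(locus_set: LocusSet, background: tuple[float, float],
                    genome: GenomeModel) -> EnrichmentResult:
    """Chi-square goodness-of-fit of compartment counts vs the background.

    Compartment membership is by locus midpoint; the background proportions
    come from :func:`background_proportions` (or the config).
    """
    if len(locus_set) == 0:
        raise ValueError(f"locus set {locus_set.name!r} is empty")
    p_arm, p_peri = background
    o_arm, o_peri = compartment_counts(locus_set, genome)
    chi2, p = chi2_goodness_of_fit((o_arm, o_peri), (p_arm, p_peri))
    return EnrichmentResult(
        set_name=locus_set.name,
        observed=(o_arm, o_peri),
        expected_proportions=(p_arm, p_peri),
        chi2=chi2,
        df=1,
        p=p,
        stars=significance_stars(p),
    )


# ---------------------------------------------------------------------------
# chromatin states

def read_state_bed(path: str) -> list[tuple[str, int, int, int]]:
    """BED of chromatin-state blocks; the name column is the state number.

    Returns 1-based inclusive ``(chrom, start, end, state)`` tuples.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]) + 1, int(parts[2]), int(parts[3])))
    return out


def chromatin_state_fraction(
    locus_set: LocusSet,
    state_intervals: Sequence[tuple[str, int, int, int]],
    states: frozenset[int] | set[int] = frozenset({8, 9}),
    min_overlap: float = 0.5,
) -> float:
    """Fraction of set members overlapping the given states.

    A member counts as targeted when at least ``min_overlap`` of its length
    is covered by (merged) blocks of the selected states. States 8 and 9 of
    the nine-state *A. thaliana* segmentation are the heterochromatic,
    H3K9me2/DNA-methylation-associated states.
    """
    if not state_intervals:
        raise ValueError("no chromatin-state annotation loaded")
    if len(locus_set) == 0:
        raise ValueError("empty locus set")
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, state in state_intervals:
        if state in states:
            # half-open on integers for the tree; merge below
            trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)
    for tree in trees.values():
        tree.merge_overlaps()
    n_hit = 0
    for m in locus_set:
        tree = trees.get(m.chrom)
        if tree is None:
            continue
        covered = 0
        for iv in tree.overlap(m.start, m.end + 1):
            covered += min(iv.end, m.end + 1) - max(iv.begin, m.start)
        if covered >= min_overlap * m.length:
            n_hit += 1
    return n_hit / len(locus_set)


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("set\tn_arm\tn_peri\tp_arm_expected\tp_peri_expected\tchi2\tdf\tp\tstars\n")
        for r in results:
            fh.write(
                f"{r.set_name}\t{r.observed[0]}\t{r.observed[1]}\t"
                f"{r.expected_proportions[0]:.6g}\t{r.expected_proportions[1]:.6g}\t"
                f"{r.chi2:.6g}\t{r.df}\t{r.p:.6g}\t{r.stars}\n"
            )
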