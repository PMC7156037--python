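"""Mapping-by-sequencing scan for a causal EMS mutation.

Pipeline: EMS-spectrum filtering of pooled-sequencing SNPs, zygosity
classification from the pooled variant frequency, a 500-kb windowed
homozygote/heterozygote ratio scan, and linkage-interval calling around
the genome-wide ratio peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .genome import GenomeModel

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

# (ref, alt) pairs produced by EMS alkylation of guanine: G→A on the strand
# carrying the G, observed as C→T on the opposite strand.
EMS_PAIRS = frozenset({("G", "A"), ("C", "T")})


class Zygosity(str, Enum):
    HOMOZYGOUS = "homozygous"
    HETEROZYGOUS = "heterozygous"
    DISCARDED = "discarded"


@dataclass(frozen=True)
class VariantRecord:
    """One pooled-sequencing SNP with read depths and derived frequency."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_depth: int
    total_depth: int
    allele_freq: float

    def __post_init__(self) -> None:
        if not 0 <= self.alt_depth <= self.total_depth:
            raise ValueError(
                f"{self.chrom}:{self.pos}: alt_depth {self.alt_depth} "
                f"outside [0, {self.total_depth}]"
            )
        if self.total_depth > 0:
            expected = self.alt_depth / self.total_depth
            if abs(self.allele_freq - expected) > 1e-6:
                raise ValueError(
                    f"{self.chrom}:{self.pos}: allele_freq {self.allele_freq} "
                    f"inconsistent with depths ({expected:.6f})"
                )

    @classmethod
    def from_depths(cls, chrom: str, pos: int, ref: str, alt: str,
                    alt_depth: int, total_depth: int) -> "VariantRecord":
        freq = alt_depth / total_depth if total_depth > 0 else 0.0
        return cls(chrom, pos, ref, alt, alt_depth, total_depth, freq)


@dataclass(frozen=True)
class ZygosityThresholds:
    """Variant-frequency bands for pooled zygosity calls.

    Defaults follow the standard bulk-segregant convention: a site is called
    homozygous in the pool at frequency ≥ 0.80 and heterozygous within
    [0.45, 0.55]; everything else is discarded as ambiguous.
    """

    hom_min: float = 0.80
    het_min: float = 0.45
    het_max: float = 0.55

    def __post_init__(self) -> None:
        if not (0 < self.het_min <= self.het_max < self.hom_min <= 1):
            raise ValueError(
                f"need 0 < het_min <= het_max < hom_min <= 1, got "
                f"({self.het_min}, {self.het_max}, {self.hom_min})"
            )


@dataclass(frozen=True)
class WindowStat:
    """Homozygote/heterozygote counts and ratio for one tiling window."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_hom: int
    n_het: int
    ratio: float


@dataclass(frozen=True)
class LinkageInterval:
    """The called mapping interval around the genome-wide ratio peak."""

    chrom: str
    start: int
    end: int
    peak_window: WindowStat
    peak_ratio: float


class NoSignalError(RuntimeError):
    """No homozygosity-enriched window exists in the scan."""


# ---------------------------------------------------------------------------
# stage 1: EMS-spectrum filter

def ems_filter(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Keep only variants matching the EMS mutation spectrum (G:C→A:T).

    A record passes iff (ref=G, alt=A) or (ref=C, alt=T). Records with
    indels or ambiguity codes are rejected with a logged warning, never an
    exception; input order is preserved.
    """
    kept = []
    for v in variants:
        if len(v.ref) != 1 or len(v.alt) != 1 or v.ref not in VALID_BASES or v.alt not in VALID_BASES:
            logger.warning(
                "rejecting non-SNP or ambiguous record %s:%d %s>%s",
                v.chrom, v.pos, v.ref, v.alt,
            )
            continue
        if (v.ref, v.alt) in EMS_PAIRS:
            kept.append(v)
    return kept


# ---------------------------------------------------------------------------
# stage 2: zygosity classification

def classify_zygosity(freq: float,
                      thresholds: ZygosityThresholds = ZygosityThresholds()) -> Zygosity:
    """Call pooled zygosity from a variant frequency.

    Homozygous iff ``freq >= hom_min``; heterozygous iff
    ``het_min <= freq <= het_max``; otherwise discarded. Boundaries are
    inclusive exactly as stated.
    """
    if not 0 <= freq <= 1:
        raise ValueError(f"variant frequency {freq} outside [0, 1]")
    if freq >= thresholds.hom_min:
        return Zygosity.HOMOZYGOUS
    if thresholds.het_min <= freq <= thresholds.het_max:
        return Zygosity.HETEROZYGOUS
    return Zygosity.DISCARDED


# ---------------------------------------------------------------------------
# stage 3: windowed ratio scan

def window_ratio_scan(
    classified: Sequence[tuple[VariantRecord, Zygosity]],
    genome: GenomeModel,
    window_size: int = 500_000,
) -> list[WindowStat]:
    """Tile each chromosome with non-overlapping windows and count calls.

    Each non-discarded variant falls in exactly one window. The window ratio
    is ``n_hom / max(n_het, 1)`` (heterozygote count floored at one so the
    ratio stays finite); an empty window scores 0. The terminal window may
    be shorter than *window_size* and ratios are plain counts, not
    length-normalised.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    counts: dict[str, list[list[int]]] = {}
    n_windows = {}
    for chrom, length in genome.chromosomes:
        n = -(-length // window_size)  # ceil
        n_windows[chrom] = n
        counts[chrom] = [[0, 0] for _ in range(n)]
    for v, z in classified:
        if z is Zygosity.DISCARDED:
            continue
        if v.chrom not in counts:
            raise ValueError(f"variant {v.chrom}:{v.pos} on unknown chromosome")
        if not 1 <= v.pos <= genome.length(v.chrom):
            raise ValueError(
                f"variant {v.chrom}:{v.pos} {v.ref}>{v.alt} beyond chromosome "
                f"length {genome.length(v.chrom)}"
            )
        idx = (v.pos - 1) // window_size
        if z is Zygosity.HOMOZYGOUS:
            counts[v.chrom][idx][0] += 1
        else:
            counts[v.chrom][idx][1] += 1
    stats = []
    for chrom, length in genome.chromosomes:
        for i in range(n_windows[chrom]):
            start = i * window_size + 1
            end = min((i + 1) * window_size, length)
            n_hom, n_het = counts[chrom][i]
            ratio = 0.0 if (n_hom == 0 and n_het == 0) else n_hom / max(n_het, 1)
            stats.append(WindowStat(chrom, start, end, n_hom, n_het, ratio))
    return stats


# ---------------------------------------------------------------------------
# stage 4: linkage-interval calling

def call_linkage_interval(scan: Sequence[WindowStat], tau: float = 0.5) -> LinkageInterval:
    """Delimit the mapping interval around the genome-wide ratio maximum.

    The peak is the global-maximum window (earliest window on the earliest
    chromosome on ties); the interval spans from the first to the last
    window on the peak's chromosome whose ratio is ≥ ``tau * peak_ratio``
    (the peak is necessarily inside). Windows below the cutoff strictly
    inside the span do not break it: at realistic EMS densities many
    windows hold no variant at all, and an evidence gap is not evidence
    against linkage.
    """
    if not scan:
        raise NoSignalError("empty scan")
    if not 0 < tau <= 1:
        raise ValueError("tau must be in (0, 1]")
    peak = max(scan, key=lambda w: w.ratio)  # max is stable: earliest wins ties
    if peak.ratio <= 0:
        raise NoSignalError(
            "all window ratios are zero — no homozygosity-enriched region; "
            "consider a larger pool or higher sequencing depth"
        )
    cutoff = tau * peak.ratio
    above = [w for w in scan if w.chrom == peak.chrom and w.ratio >= cutoff]
    return LinkageInterval(
        chrom=peak.chrom,
        start=min(w.start for w in above),
        end=max(w.end for w in above),
        peak_window=peak,
        peak_ratio=peak.ratio,
    )


# ---------------------------------------------------------------------------
# VCF input and the composed pipeline

def read_vcf(path: str) -> list[VariantRecord]:
    """Read pooled-pool SNPs from a VCF with INFO AD/DP (or AF fallback).

    Frequencies are recomputed from AD/DP when both are present; the AF
    field is used only when depths are absent.
    """
    from cyvcf2 import VCF

    records = []
    vcf = VCF(path)
    try:
        for var in vcf:
            ref = var.REF
            alt = var.ALT[0] if var.ALT else ""
            ad = var.INFO.get("AD")
            dp = var.INFO.get("DP")
            if ad is not None and dp is not None:
                rec = VariantRecord.from_depths(var.CHROM, var.POS, ref, alt,
                                                int(ad), int(dp))
            else:
                af = var.INFO.get("AF")
                if af is None:
                    raise ValueError(
                        f"{var.CHROM}:{var.POS}: neither AD/DP nor AF present"
                    )
                records.append(VariantRecord(var.CHROM, var.POS, ref, alt, 0, 0, float(af)))
                continue
            records.append(rec)
    finally:
        vcf.close()
    return records


@dataclass
class MappingResult:
    interval: LinkageInterval
    windows: list[WindowStat]
    classified: list[tuple[VariantRecord, Zygosity]] = field(repr=False, default_factory=list)
    n_input: int = 0
    n_ems: int = 0


def run_mapping(
    vcf_path: str,
    genome: GenomeModel,
    thresholds: ZygosityThresholds = ZygosityThresholds(),
    window_size: int = 500_000,
    tau: float = 0.5,
    exclude: set[tuple[str, int]] | None = None,
    outdir: str | None = None,
) -> MappingResult:
    """EMS filter → zygosity → window scan → interval call, from a VCF.

    *exclude* optionally removes known parental-background sites given as
    ``(chrom, pos)`` pairs before filtering. When *outdir* is given, writes
    ``windows.bed`` (score = ratio), ``interval.bed`` and ``scan.tsv``.
    """
    try:
        variants = read_vcf(vcf_path)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage name
        raise RuntimeError(f"[read_vcf] {exc}") from exc
    n_input = len(variants)
    if exclude:
        variants = [v for v in variants if (v.chrom, v.pos) not in exclude]
    ems = ems_filter(variants)
    classified = [(v, classify_zygosity(v.allele_freq, thresholds)) for v in ems]
    try:
        windows = window_ratio_scan(classified, genome, window_size)
        interval = call_linkage_interval(windows, tau)
    except NoSignalError as exc:
        raise NoSignalError(f"[call_linkage_interval] {exc}") from exc
    result = MappingResult(interval, windows, classified, n_input, len(ems))
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_window_bed(windows, out / "windows.bed")
        write_interval_bed(interval, out / "interval.bed")
        write_scan_tsv(windows, out / "scan.tsv")
    return result


def write_window_bed(windows: Sequence[WindowStat], path) -> None:
    """BED6 of window ratios (0-based half-open; score = ratio)."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start - 1}\t{w.end}\twindow\t{w.ratio:.4f}\t.\n")


def write_interval_bed(interval: LinkageInterval, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"{interval.chrom}\t{interval.start - 1}\t{interval.end}\t"
            f"linkage_interval\t{interval.peak_ratio:.4f}\t.\n"
        )


def write_scan_tsv(windows: Sequence[WindowStat], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tn_hom\tn_het\tratio\n")
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.n_hom}\t{w.n_het}\t{w.ratio:.6g}\n")
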