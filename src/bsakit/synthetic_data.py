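"""Synthetic inputs with known ground truth for every pipeline stage.

Emulates (i) an F2 bulk-segregant pool from a homozygous EMS line crossed
to wild type and phenotype-selected at the causal locus, sequenced at
finite depth; (ii) a five-chromosome genome with pericentromere intervals
and gene/TE placement; (iii) promoter sets carrying a motif at a background
vs an elevated rate; (iv) differential-expression and qPCR-style tables
with planted truth.

Randomness: each operation draws from ``numpy.random.default_rng(seed + k)``
where *k* is a fixed per-operation offset, so adding an operation never
shifts the streams of the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bsa_mapping import VariantRecord
from .genome import ConfigurationError, GenomeModel, Locus, LocusSet, RecombinationModel

# fixed per-operation seed offsets (see module docstring)
_OP_GENOME = 0
_OP_POOL = 1
_OP_PROMOTERS = 2
_OP_DE = 3

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# genome + annotation

@dataclass(frozen=True)
class GenomeConfig:
    """Synthetic genome layout.

    Defaults give five 30-Mb chromosomes with a centred pericentromere
    covering 30% of each — a scaled-down cartoon of the *A. thaliana*
    karyotype with its TE-dense pericentromeric compartment.
    """

    chrom_lengths: tuple[int, ...] = (30_000_000,) * 5
    peri_fraction: float = 0.3
    n_genes: int = 5000
    n_tes: int = 4000
    te_peri_fold: float = 4.0  # TE density inside peri relative to arms
    cm_per_mb: float = 4.0
    gene_length: tuple[int, int] = (500, 5000)
    te_length: tuple[int, int] = (200, 3000)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ConfigurationError("need at least one chromosome")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ConfigurationError("zero-length chromosome in config")
        if not 0 < self.peri_fraction < 1:
            raise ConfigurationError("peri_fraction must be in (0, 1)")
        if self.te_peri_fold <= 0:
            raise ConfigurationError("te_peri_fold must be positive")


def simulate_genome(config: GenomeConfig = GenomeConfig()) -> tuple[GenomeModel, LocusSet]:
    """Build a GenomeModel and place genes/TEs with known compartment truth.

    Pericentromeres are centred intervals of length ``peri_fraction * L``.
    Genes are placed uniformly over the genome; TEs are placed with density
    ``te_peri_fold`` times higher inside pericentromeres than on arms.
    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed + _OP_GENOME)
    chroms = tuple((f"Chr{i + 1}", int(l)) for i, l in enumerate(config.chrom_lengths))
    peri = {}
    for name, length in chroms:
        span = int(round(config.peri_fraction * length))
        start = (length - span) // 2 + 1
        peri[name] = (start, start + span - 1)
    genome = GenomeModel(chroms, peri, config.cm_per_mb)

    lengths = np.array([l for _, l in chroms], dtype=float)
    peri_len = np.array([peri[n][1] - peri[n][0] + 1 for n, _ in chroms], dtype=float)
    arm_len = lengths - peri_len

    members: list[Locus] = []

    def place(n: int, prefix: str, lclass: str, size_range: tuple[int, int],
              peri_fold: float) -> None:
        # chromosome weight proportional to effective (density-weighted) length
        eff = arm_len + peri_fold * peri_len
        chrom_idx = rng.choice(len(chroms), size=n, p=eff / eff.sum())
        for k in range(n):
            ci = int(chrom_idx[k])
            name, length = chroms[ci]
            p_lo, p_hi = peri[name]
            p_peri = peri_fold * peri_len[ci] / (arm_len[ci] + peri_fold * peri_len[ci])
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            if rng.random() < p_peri:
                mid = int(rng.integers(p_lo, p_hi + 1))
            else:
                # uniform over the two arms
                arm_total = int(arm_len[ci])
                u = int(rng.integers(1, arm_total + 1))
                mid = u if u < p_lo else p_hi + (u - p_lo + 1)
            start = max(1, mid - size // 2)
            end = min(length, start + size - 1)
            members.append(Locus(f"{prefix}{k + 1:05d}", name, start, end, lclass))

    place(config.n_genes, "GENE", "gene", config.gene_length, 1.0)
    place(config.n_tes, "TE", "TE", config.te_length, config.te_peri_fold)
    return genome, LocusSet("synthetic_annotation", members, genome)


# ---------------------------------------------------------------------------
# bulk-segregant pool

@dataclass(frozen=True)
class SimParams:
    """Design of the simulated phenotype-selected F2 pool.

    Pool size 60 and 50x mean depth are realistic defaults for an
    *Arabidopsis* mapping-by-sequencing experiment; ``error_rate`` adds
    symmetric base-miscall reads (off by default).
    """

    n_mutations: int = 400
    causal: tuple[str, int] = ("Chr1", 15_000_000)
    pool_size: int = 60
    mean_depth: float = 50.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mutations < 1:
            raise ConfigurationError("n_mutations must be >= 1")
        if self.pool_size < 1:
            raise ConfigurationError("pool_size must be >= 1")
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ConfigurationError("error_rate must be in [0, 0.5)")


def pooled_allele_frequency_expectation(d_morgans: float,
                                        recomb: RecombinationModel = RecombinationModel()) -> float:
    """Expected mutant-allele frequency in the selected pool at genetic
    distance *d* from the causal locus: ``1 - r(d)`` (0.5 for unlinked)."""
    return 1.0 - recomb.recombination_fraction(d_morgans)


def simulate_bsa_pool(
    genome: GenomeModel,
    params: SimParams = SimParams(),
    recomb: RecombinationModel = RecombinationModel(),
    sites: Sequence[tuple[str, int]] | None = None,
) -> list[VariantRecord]:
    """Simulate pooled-sequencing EMS variants from a selected F2 pool.

    EMS sites are uniform over the genome (or, for planned marker designs,
    the explicit *sites* list) and all obey the G→A / C→T spectrum.
    Selection fixes the mutant allele at the causal site in every pool
    member, so each of the ``2 * pool_size`` gametes carries the mutant
    allele at a linked marker with probability ``1 - r(d)`` (Haldane), and
    0.5 on other chromosomes. Read depth is Poisson(mean_depth); alternate
    reads are Binomial(depth, pooled frequency).
    """
    causal_chrom, causal_pos = params.causal
    if causal_chrom not in genome.names:
        raise ConfigurationError(f"causal chromosome {causal_chrom!r} not in genome")
    if not genome.contains(causal_chrom, causal_pos):
        raise ConfigurationError(f"causal position {causal_pos} outside {causal_chrom}")

    rng = np.random.default_rng(params.seed + _OP_POOL)
    if sites is None:
        lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
        chrom_idx = rng.choice(len(lengths), size=params.n_mutations,
                               p=lengths / lengths.sum())
        pos = np.array([int(rng.integers(1, lengths[c] + 1)) for c in chrom_idx])
        names = [genome.chromosomes[c][0] for c in chrom_idx]
        sites = list(zip(names, pos.tolist()))
    else:
        sites = [(c, int(p)) for c, p in sites]
        for chrom, p in sites:
            if not genome.contains(chrom, p):
                raise ConfigurationError(f"site {chrom}:{p} outside genome")

    # append the causal site unless it was already drawn
    if (causal_chrom, causal_pos) not in sites:
        sites = list(sites) + [(causal_chrom, causal_pos)]

    n_gametes = 2 * params.pool_size
    records = []
    for chrom, p in sites:
        if (chrom, p) == (causal_chrom, causal_pos):
            freq = 1.0
        elif chrom == causal_chrom:
            d = genome.genetic_distance(abs(p - causal_pos))
            carrier_p = 1.0 - recomb.recombination_fraction(d)
            freq = rng.binomial(n_gametes, carrier_p) / n_gametes
        else:
            freq = rng.binomial(n_gametes, 0.5) / n_gametes
        depth = int(rng.poisson(params.mean_depth))
        read_p = freq * (1 - params.error_rate) + (1 - freq) * params.error_rate
        alt = int(rng.binomial(depth, read_p)) if depth > 0 else 0
        ref_base = "G" if rng.random() < 0.5 else "C"
        alt_base = "A" if ref_base == "G" else "T"
        records.append(VariantRecord.from_depths(chrom, p, ref_base, alt_base, alt, depth))

    order = {n: i for i, n in enumerate(genome.names)}
    records.sort(key=lambda r: (order[r.chrom], r.pos))
    return records


def write_vcf(records: Sequence[VariantRecord], genome: GenomeModel, path) -> None:
    """Write VCF v4.2 with INFO fields AD (alt depth), DP, AF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in genome.chromosomes:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=AD,Number=1,Type=Integer,Description="Alternate allele read depth">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            info = f"AD={r.alt_depth};DP={r.total_depth};AF={r.allele_freq:.6f}"
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\n")


# ---------------------------------------------------------------------------
# promoter sets with embedded motif

def simulate_promoter_set(
    n_background: int,
    n_target: int,
    motif,
    background_rate: float,
    target_rate: float,
    promoter_length: int = 1000,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random promoters with the motif consensus embedded at known rates.

    Each promoter is an i.i.d. uniform ACGT sequence; with the per-set
    probability one exact copy of the motif consensus is embedded at a
    uniform position, on a uniformly chosen strand. Returns a dict of
    sequences keyed by promoter ID and a truth table with carrier status,
    embed position (1-based) and strand.
    """
    consensus = motif.consensus_sequence()
    m = len(consensus)
    if m > promoter_length:
        raise ConfigurationError(
            f"motif length {m} exceeds promoter length {promoter_length}"
        )
    for rate, label in ((background_rate, "background"), (target_rate, "target")):
        if not 0 <= rate <= 1:
            raise ConfigurationError(f"{label}_rate {rate} outside [0, 1]")
    rng = np.random.default_rng(seed + _OP_PROMOTERS)
    seqs: dict[str, str] = {}
    rows = []
    for group, n, rate, prefix in (("background", n_background, background_rate, "BG"),
                                   ("target", n_target, target_rate, "TG")):
        for k in range(n):
            pid = f"{prefix}{k + 1:05d}"
            seq = "".join(_BASES[rng.integers(0, 4, size=promoter_length)])
            carrier = bool(rng.random() < rate)
            pos0, strand = -1, "."
            if carrier:
                pos0 = int(rng.integers(0, promoter_length - m + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                insert = consensus if strand == "+" else _revcomp(consensus)
                seq = seq[:pos0] + insert + seq[pos0 + m:]
            seqs[pid] = seq
            rows.append({"id": pid, "set": group, "carrier": carrier,
                         "position": pos0 + 1 if carrier else 0, "strand": strand})
    truth = pd.DataFrame(rows, columns=["id", "set", "carrier", "position", "strand"])
    return seqs, truth


def write_fasta(seqs: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=i, description="") for i, s in seqs.items()]
    seqio_write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# differential-expression tables

def simulate_de_table(n_loci: int, n_up: int, n_down: int, seed: int = 0) -> pd.DataFrame:
    """TSV-shaped table of (locus, log2FC, padj) with planted up/down rows.

    Exactly *n_up* rows satisfy log2FC ≥ 2 with padj < 0.01, exactly
    *n_down* satisfy log2FC ≤ −2 with padj < 0.01, and every other row
    fails at least one threshold (padj ≥ 0.01).
    """
    if min(n_loci, n_up, n_down) < 0:
        raise ConfigurationError("counts must be non-negative")
    if n_up + n_down > n_loci:
        raise ConfigurationError("n_up + n_down exceeds n_loci")
    rng = np.random.default_rng(seed + _OP_DE)
    rows = []
    for i in range(n_loci):
        locus = f"AT{i // 10000 + 1}G{(i % 10000) * 10 + 10010:05d}"
        if i < n_up:
            lfc = float(rng.uniform(2.0, 8.0))
            padj = float(rng.uniform(1e-10, 0.0099))
        elif i < n_up + n_down:
            lfc = float(-rng.uniform(2.0, 8.0))
            padj = float(rng.uniform(1e-10, 0.0099))
        else:
            lfc = float(rng.uniform(-6.0, 6.0))
            padj = float(rng.uniform(0.011, 1.0))  # fails the padj threshold
        rows.append({"locus": locus, "log2FC": lfc, "padj": padj})
    df = pd.DataFrame(rows)
    return df.sample(frac=1.0, random_state=np.random.RandomState(seed % (2**31))).reset_index(drop=True)
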