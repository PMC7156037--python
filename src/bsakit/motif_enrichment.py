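"""Promoter-motif carrier analysis with a resampling null.

Scans 1-kb promoters (anchored at the translation start) for a supplied
motif — an IUPAC consensus or a position weight matrix — computes carrier
proportions per gene set, and tests enrichment by drawing random gene sets
of the same size from the promoter universe.

The motif itself is an input: motif discovery is out of scope, and the
bundled test motif is a synthetic stand-in, not a biological motif.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import re

logger = logging.getLogger(__name__)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifModel:
    """A promoter motif: IUPAC consensus or letter-probability matrix.

    Exactly one of *consensus* / *pwm* is set. In PWM mode a window is a
    hit when its log-odds score (base 2, vs a uniform background) reaches
    ``threshold`` times the maximal achievable score.
    """

    consensus: str | None = None
    pwm: np.ndarray | None = None  # shape (L, 4), columns A C G T
    threshold: float = 0.8
    name: str = "motif"

    def __post_init__(self) -> None:
        if (self.consensus is None) == (self.pwm is None):
            raise ValueError("provide exactly one of consensus or pwm")
        if self.consensus is not None:
            if not self.consensus:
                raise ValueError("empty motif")
            bad = set(self.consensus.upper()) - set(_IUPAC)
            if bad:
                raise ValueError(f"non-IUPAC symbols in consensus: {sorted(bad)}")
            object.__setattr__(self, "consensus", self.consensus.upper())
        else:
            pwm = np.asarray(self.pwm, dtype=float)
            if pwm.ndim != 2 or pwm.shape[1] != 4 or pwm.shape[0] == 0:
                raise ValueError("pwm must have shape (L, 4) with L >= 1")
            if np.any(pwm < 0) or np.any(np.abs(pwm.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError("pwm rows must be probabilities summing to 1")
            object.__setattr__(self, "pwm", pwm)
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")

    def __len__(self) -> int:
        return len(self.consensus) if self.consensus is not None else self.pwm.shape[0]

    def consensus_sequence(self) -> str:
        """A concrete ACGT realisation: argmax per PWM column, or the
        alphabetically first base compatible with each IUPAC code."""
        if self.pwm is not None:
            return "".join("ACGT"[i] for i in self.pwm.argmax(axis=1))
        return "".join(_IUPAC[c][0] for c in self.consensus)

    @classmethod
    def from_meme(cls, path: str, threshold: float = 0.8) -> "MotifModel":
        """Read the first motif from a MEME minimal-format file."""
        from Bio import motifs as bio_motifs

        with open(path) as fh:
            records = bio_motifs.parse(fh, "minimal")
        if not records:
            raise ValueError(f"no motifs in {path}")
        mot = records[0]
        pwm = np.column_stack([np.asarray(mot.pwm[b], dtype=float) for b in "ACGT"])
        pwm = pwm / pwm.sum(axis=1, keepdims=True)
        return cls(pwm=pwm, threshold=threshold, name=mot.name or "motif")


@dataclass(frozen=True)
class MotifHit:
    position: int  # 1-based start of the match on the forward strand
    strand: str  # "+" | "-"
    score: float


@dataclass(frozen=True)
class CarrierReport:
    """Carrier status of a gene set: who has ≥1 motif hit in its promoter."""

    set_name: str
    n_genes: int
    n_carriers: int
    proportion: float
    hits: Mapping[str, tuple[MotifHit, ...]] = field(default_factory=dict)


@dataclass(frozen=True)
class ResamplingResult:
    """Empirical enrichment test against random same-size gene sets."""

    observed_proportion: float
    n_draws: int
    null_mean: float
    null_sd: float
    p: float  # (1 + #{draws >= observed}) / (1 + n_draws)
    seed: int


# ---------------------------------------------------------------------------
# promoter extraction

def extract_promoters(genes: Iterable, chromosome_sequences: Mapping[str, str],
                      length: int = 1000) -> dict[str, str]:
    """Upstream promoter per gene, anchored at the translation start (ATG).

    *genes* are records with ``id``, ``chrom``, ``strand`` and coordinates;
    the ATG is taken as ``start`` on the plus strand and ``end`` on the
    minus strand, and the returned sequence is the *length*-bp window 5' of
    it on the coding strand (reverse-complemented for minus-strand genes).
    Promoters truncated at a chromosome edge are returned shorter, with a
    logged warning.
    """
    out: dict[str, str] = {}
    for g in genes:
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene {g.id}: missing or invalid strand {g.strand!r}")
        seq = chromosome_sequences[g.chrom].upper()
        if g.strand == "+":
            atg = g.start
            lo = max(1, atg - length)
            promoter = seq[lo - 1: atg - 1]
        else:
            atg = g.end
            hi = min(len(seq), atg + length)
            promoter = _revcomp(seq[atg: hi])
        if len(promoter) < length:
            logger.warning(
                "promoter of %s truncated to %d bp at the chromosome edge",
                g.id, len(promoter),
            )
        out[g.id] = promoter
    return out


# ---------------------------------------------------------------------------
# scanning

def _iupac_regex(consensus: str) -> re.Pattern:
    # N matches nothing in the subject: character classes list ACGT only,
    # so an N in the sequence can never satisfy a position.
    return re.compile("(?=(" + "".join(
        c if len(_IUPAC[c]) == 1 else "[" + _IUPAC[c] + "]" for c in consensus
    ) + "))")


def scan_motif(sequence: str, motif: MotifModel, both_strands: bool = True) -> list[MotifHit]:
    """All motif hits in a sequence, on the forward strand and (by default)
    the reverse complement; positions are 1-based on the forward strand."""
    seq = sequence.upper()
    m = len(motif)
    hits: list[MotifHit] = []
    if motif.consensus is not None:
        pattern = _iupac_regex(motif.consensus)
        for match in pattern.finditer(seq):
            hits.append(MotifHit(match.start() + 1, "+", float(m)))
        if both_strands:
            rc = _revcomp(seq)
            for match in pattern.finditer(rc):
                hits.append(MotifHit(len(seq) - match.start() - m + 1, "-", float(m)))
    else:
        log_odds = np.log2(np.maximum(motif.pwm, 1e-12) / 0.25)
        max_score = float(log_odds.max(axis=1).sum())
        cutoff = motif.threshold * max_score - 1e-9
        strands = [("+", seq)]
        if both_strands:
            strands.append(("-", _revcomp(seq)))
        idx = np.full(256, -1, dtype=int)
        for b, i in _BASE_INDEX.items():
            idx[ord(b)] = i
        for strand, s in strands:
            if len(s) < m:
                continue
            codes = idx[np.frombuffer(s.encode(), dtype=np.uint8)]
            windows = np.lib.stride_tricks.sliding_window_view(codes, m)
            valid = (windows >= 0).all(axis=1)  # N never matches
            scores = log_odds[np.arange(m), windows.clip(min=0)].sum(axis=1)
            for start in np.nonzero(valid & (scores >= cutoff))[0]:
                pos = int(start) + 1 if strand == "+" else len(s) - int(start) - m + 1
                hits.append(MotifHit(pos, strand, float(scores[start])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def carrier_proportion(gene_ids: Sequence[str], promoters: Mapping[str, str],
                       motif: MotifModel, set_name: str = "set",
                       both_strands: bool = True) -> CarrierReport:
    """Carrier report for a gene set: a gene is a carrier iff its promoter
    has at least one motif hit."""
    if not gene_ids:
        raise ValueError("empty gene set")
    missing = [g for g in gene_ids if g not in promoters]
    if missing:
        raise ValueError(f"no promoter record for gene(s): {missing[:5]}")
    hits = {}
    n_carriers = 0
    for g in gene_ids:
        h = tuple(scan_motif(promoters[g], motif, both_strands))
        if h:
            n_carriers += 1
            hits[g] = h
    n = len(gene_ids)
    return CarrierReport(set_name, n, n_carriers, n_carriers / n, hits)


# ---------------------------------------------------------------------------
# resampling null

def random_gene_test(observed: CarrierReport, universe_promoters: Mapping[str, str],
                     motif: MotifModel, n_draws: int = 10_000, seed: int = 0,
                     both_strands: bool = True) -> ResamplingResult:
    """Empirical p-value for the observed carrier proportion.

    Each draw samples, without replacement, a random gene set of the
    observed size from the promoter universe and records its carrier
    proportion. The p-value uses the add-one rule
    ``(1 + #{null >= observed}) / (1 + n_draws)`` so it is never zero.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    ids = list(universe_promoters)
    k = observed.n_genes
    if k > len(ids):
        raise ValueError("observed set larger than the promoter universe")
    # scan each universe promoter once; draws then only index the flags
    carrier_flags = np.array(
        [bool(scan_motif(universe_promoters[g], motif, both_strands)) for g in ids]
    )
    rng = np.random.default_rng(seed)
    n_universe = len(ids)
    null = np.empty(n_draws)
    for i in range(n_draws):
        pick = rng.choice(n_universe, size=k, replace=False)
        null[i] = carrier_flags[pick].mean()
    n_ge = int(np.sum(null >= observed.proportion - 1e-12))
    return ResamplingResult(
        observed_proportion=observed.proportion,
        n_draws=n_draws,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_draws > 1 else 0.0,
        p=(1 + n_ge) / (1 + n_draws),
        seed=seed,
    )
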