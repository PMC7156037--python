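"""Expression and proteomics scoring utilities.

Three small, exactly testable operations: differential-expression threshold
filtering (|log2FC| >= 2, padj < 0.01), relative qPCR quantification by the
2^-ddCt method, and normalised spectral abundance factors (NSAF) for
spectral-count proteomics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeThresholds:
    """Fold-change and adjusted-p cutoffs for calling misregulated loci.

    log2FC boundaries are inclusive (>= up, <= down); the padj cutoff is
    strict (< padj_max).
    """

    log2fc_up: float = 2.0
    log2fc_down: float = -2.0
    padj_max: float = 0.01

    def __post_init__(self) -> None:
        if not self.log2fc_up > 0 > self.log2fc_down:
            raise ValueError("need log2fc_up > 0 > log2fc_down")
        if not 0 < self.padj_max < 1:
            raise ValueError("padj_max must be in (0, 1)")


def de_filter(table: pd.DataFrame,
              thresholds: DeThresholds = DeThresholds()) -> tuple[set[str], set[str]]:
    """Split a (locus, log2FC, padj) table into up- and downregulated sets.

    Up iff ``log2FC >= log2fc_up`` and ``padj < padj_max``; down iff
    ``log2FC <= log2fc_down`` and ``padj < padj_max``. Rows with a missing
    padj are skipped with a warning.
    """
    up, down = set(), set()
    n_skipped = 0
    for row in table.itertuples(index=False):
        locus, lfc, padj = row.locus, row.log2FC, row.padj
        if padj is None or (isinstance(padj, float) and math.isnan(padj)):
            n_skipped += 1
            continue
        if padj < thresholds.padj_max:
            if lfc >= thresholds.log2fc_up:
                up.add(locus)
            elif lfc <= thresholds.log2fc_down:
                down.add(locus)
    if n_skipped:
        logger.warning("skipped %d rows with missing padj", n_skipped)
    return up, down


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR well: target and housekeeping-reference Ct for a sample."""

    sample: str
    target_ct: float
    reference_ct: float
    replicate: int = 1

    def __post_init__(self) -> None:
        for label, ct in (("target", self.target_ct), ("reference", self.reference_ct)):
            if not math.isfinite(ct) or ct <= 0:
                raise ValueError(f"{self.sample}: {label} Ct must be finite and positive")


def ddct_relative_expression(sample: Sequence[QpcrMeasurement],
                             calibrator: Sequence[QpcrMeasurement]) -> float:
    """Fold change of the sample vs the calibrator by 2^-ddCt.

    Replicate Ct values are averaged before differencing: dCt = mean target
    Ct - mean reference Ct per group; ddCt = dCt_sample - dCt_calibrator;
    fold = 2^-ddCt. The reference is a housekeeping gene measured in the
    same wells.
    """
    for label, group in (("sample", sample), ("calibrator", calibrator)):
        if not group:
            raise ValueError(f"no measurements for the {label}")
    def dct(group: Sequence[QpcrMeasurement]) -> float:
        t = sum(m.target_ct for m in group) / len(group)
        r = sum(m.reference_ct for m in group) / len(group)
        return t - r
    ddct = dct(sample) - dct(calibrator)
    return 2.0 ** (-ddct)


@dataclass(frozen=True)
class SpectralCount:
    """Spectral count and length for one protein in an IP-MS experiment."""

    protein_id: str
    count: int
    length: int  # residues

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"{self.protein_id}: negative spectral count")
        if self.length <= 0:
            raise ValueError(f"{self.protein_id}: protein length must be positive")


def nsaf(counts: Iterable[SpectralCount], scale: float = 1e5) -> dict[str, float]:
    """Normalised spectral abundance factors, scaled (NSAFe5 by default).

    ``SAF_i = count_i / length_i``; ``NSAF_i = SAF_i / sum_j SAF_j``; the
    reported value is ``NSAF_i * scale``, so values sum to *scale*.
    """
    counts = list(counts)
    saf = {c.protein_id: c.count / c.length for c in counts}
    total = sum(saf.values())
    if total == 0:
        raise ValueError("all spectral counts are zero")
    return {pid: s / total * scale for pid, s in saf.items()}
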