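"""Presence/absence calls from per-bin read counts.

A mark is called present in a bin when the upper-tail Poisson probability of
the observed count under a background rate is at or below ``p_threshold``.
Without a control track the background is the genome-wide mean count of the
mark; with a control it is the control count scaled to matched sequencing
depth (with a pseudocount), floored at the genome-wide mean so empty control
bins cannot produce spurious calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import BinnedGenome, BinaryTrackSet

logger = logging.getLogger(__name__)

__all__ = ["CountTrackSet", "BinarizeParams", "count_reads_per_bin", "binarize_counts"]


@dataclass
class CountTrackSet:
    """Per-chromosome bins × marks read counts, optionally with a matched control."""

    genome: BinnedGenome
    marks: list[str]
    counts: dict[str, np.ndarray]
    control_counts: Optional[dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        for store in (self.counts, self.control_counts):
            if store is None:
                continue
            for chrom in self.genome.chrom_names:
                mat = np.asarray(store[chrom])
                expected = (self.genome.n_bins(chrom), len(self.marks))
                if mat.shape != expected:
                    raise ValueError(f"counts for {chrom!r}: shape {mat.shape} != {expected}")
                if (mat < 0).any():
                    raise ValueError(f"negative counts on {chrom!r}")
                store[chrom] = mat.astype(np.int64)

    def stacked(self, control: bool = False) -> np.ndarray:
        store = self.control_counts if control else self.counts
        assert store is not None
        return np.concatenate([store[c] for c in self.genome.chrom_names], axis=0)

    @property
    def total_reads(self) -> np.ndarray:
        return self.stacked().sum(axis=0)


@dataclass
class BinarizeParams:
    """Tunables of the Poisson tail test (all overridable)."""

    p_threshold: float = 1e-4
    pseudocount: float = 1.0
    shift: int = 0  # bp added to each read 5' position before binning

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")


def count_reads_per_bin(
    reads: pd.DataFrame, genome: BinnedGenome, shift: int = 0
) -> dict[str, np.ndarray]:
    """Assign each read to the bin containing its (optionally shifted) 5' position.

    The 5' position is ``start`` on the + strand and ``end - 1`` on the −
    strand.  Reads on unknown chromosomes or shifted off the chromosome are
    skipped with a warning tally.  Returns one count column per chromosome.
    """
    out = {c: np.zeros(genome.n_bins(c), dtype=np.int64) for c in genome.chrom_names}
    skipped = 0
    strand = reads["strand"] if "strand" in reads else pd.Series("." , index=reads.index)
    five_prime = np.where(strand.to_numpy() == "-", reads["end"].to_numpy() - 1, reads["start"].to_numpy())
    five_prime = five_prime + shift
    for chrom, grp_idx in reads.groupby("chrom").groups.items():
        if chrom not in genome.lengths:
            skipped += len(grp_idx)
            continue
        pos = five_prime[reads.index.get_indexer(grp_idx)]
        ok = (pos >= 0) & (pos < genome.lengths[chrom])
        skipped += int((~ok).sum())
        bins = pos[ok] // genome.bin_size
        np.add.at(out[chrom], bins, 1)
    if skipped:
        logger.warning("count_reads_per_bin: skipped %d reads (unknown chrom or off-genome)", skipped)
    return out


def poisson_upper_tail(observed: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """P(X >= observed) for X ~ Poisson(lam)."""
    return stats.poisson.sf(np.asarray(observed) - 1, lam)


def binarize_counts(
    counts: CountTrackSet, params: BinarizeParams | None = None, condition: str = "sample"
) -> BinaryTrackSet:
    """Poisson upper-tail test per bin and mark; ties at the threshold call 1."""
    params = params or BinarizeParams()
    X = counts.stacked()
    n_bins, M = X.shape
    lam = np.empty_like(X, dtype=float)
    global_mean = X.mean(axis=0)

    for m, mark in enumerate(counts.marks):
        if X[:, m].sum() == 0:
            logger.warning("binarize_counts: mark %r has zero reads (degenerate track)", mark)
            lam[:, m] = 1.0  # arbitrary: observed is all zero, calls will be 0
            continue
        if counts.control_counts is None:
            lam[:, m] = global_mean[m]
        else:
            ctrl = counts.stacked(control=True)[:, m].astype(float)
            scale = X[:, m].sum() / max(ctrl.sum(), 1.0)
            lam[:, m] = np.maximum((ctrl + params.pseudocount) * scale, global_mean[m])

    tail = poisson_upper_tail(X, lam)
    calls_flat = (tail <= params.p_threshold).astype(np.uint8)
    calls_flat[X == 0] = 0  # tail prob is 1 but guard degenerate lam

    calls: dict[str, np.ndarray] = {}
    offset = 0
    for chrom in counts.genome.chrom_names:
        n = counts.genome.n_bins(chrom)
        calls[chrom] = calls_flat[offset : offset + n]
        offset += n
    return BinaryTrackSet(counts.genome, condition, list(counts.marks), calls)
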