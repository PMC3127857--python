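"""Stranded per-position base-count pileups.

The caller operates on a *mapped sequence matrix*: for every reference
coordinate, the number of A/C/G/T base calls observed, kept separately for
forward-read and reverse-read data so variants can be confirmed on both
strands independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import GenomicInterval

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
STRANDS = ("fwd", "rev")


@dataclass
class StrandedPileup:
    """Per-position, per-strand A/C/G/T counts over a target interval."""

    interval: GenomicInterval
    fwd: np.ndarray  # (L, 4) non-negative ints
    rev: np.ndarray  # (L, 4)

    def __post_init__(self) -> None:
        L = len(self.interval)
        self.fwd = np.asarray(self.fwd, dtype=np.int64)
        self.rev = np.asarray(self.rev, dtype=np.int64)
        for name, arr in (("fwd", self.fwd), ("rev", self.rev)):
            if arr.shape != (L, 4):
                raise ValueError(f"{name} counts must have shape ({L}, 4), got {arr.shape}")
            if (arr < 0).any():
                raise ValueError(f"{name} counts must be non-negative")

    def __len__(self) -> int:
        return len(self.interval)

    def strand(self, s: str) -> np.ndarray:
        if s == "fwd":
            return self.fwd
        if s == "rev":
            return self.rev
        raise KeyError(s)

    @property
    def total(self) -> np.ndarray:
        """Combined (L, 4) counts over both strands."""
        return self.fwd + self.rev

    @property
    def depth(self) -> np.ndarray:
        """Total fold-coverage per position (both strands)."""
        return self.total.sum(axis=1)

    def depth_strand(self, s: str) -> np.ndarray:
        return self.strand(s).sum(axis=1)

    def positions(self) -> np.ndarray:
        return np.arange(self.interval.start, self.interval.end)

    def subset(self, sub: GenomicInterval) -> "StrandedPileup":
        if not self.interval.contains(sub):
            raise ValueError("subset interval not contained in pileup interval")
        lo = sub.start - self.interval.start
        hi = sub.end - self.interval.start
        return StrandedPileup(sub, self.fwd[lo:hi], self.rev[lo:hi])

    @classmethod
    def empty(cls, interval: GenomicInterval) -> "StrandedPileup":
        L = len(interval)
        return cls(interval, np.zeros((L, 4), dtype=np.int64), np.zeros((L, 4), dtype=np.int64))


def write_pileup_tsv(pileup: StrandedPileup, path: str | Path) -> None:
    """Write the TSV dialect: chrom, pos0, strand, nA, nC, nG, nT."""
    rows = []
    pos = pileup.positions()
    for strand_name, counts in (("+", pileup.fwd), ("-", pileup.rev)):
        for i, p in enumerate(pos):
            rows.append(
                (pileup.interval.chrom, int(p), strand_name, *counts[i].tolist())
            )
    df = pd.DataFrame(rows, columns=["chrom", "pos0", "strand", "nA", "nC", "nG", "nT"])
    df.to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path: str | Path) -> StrandedPileup:
    """Read a pileup TSV back into a StrandedPileup (one chromosome)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos0", "strand", "nA", "nC", "nG", "nT"}
    if not required.issubset(df.columns):
        raise ValueError(f"pileup TSV missing columns {sorted(required - set(df.columns))}")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("pileup TSV must cover a single chromosome")
    lo, hi = int(df["pos0"].min()), int(df["pos0"].max()) + 1
    interval = GenomicInterval(str(chroms[0]), lo, hi)
    fwd = np.zeros((hi - lo, 4), dtype=np.int64)
    rev = np.zeros((hi - lo, 4), dtype=np.int64)
    for row in df.itertuples(index=False):
        target = fwd if row.strand == "+" else rev
        target[int(row.pos0) - lo] += np.array([row.nA, row.nC, row.nG, row.nT])
    return StrandedPileup(interval, fwd, rev)
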