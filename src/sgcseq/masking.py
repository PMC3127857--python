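"""Short-read-tailored repeat masking.

Two per-base scores are computed over a target interval and combined by
logical OR:

* a *repeat score* from 14-base tiles (1-base increments) perfectly matching
  any sequence in a repeat-consensus library, either strand; every matching
  tile adds 1 to each of the 14 coordinates it covers;
* a *genome score* from 36-base tiles that occur more than once in the
  genome (the target itself lies in the genome, so multiplicity >= 2 marks
  multi-mapping sequence).

Shorter tiles were found to eliminate true variants and longer tiles to
inflate false positives, hence the 14/36 defaults; both are parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .reference import GenomicInterval, revcomp
from ._kmer import kmer_multiplicity

logger = logging.getLogger(__name__)

REPEAT_TILE = 14
GENOME_TILE = 36


@dataclass
class MaskTrack:
    """Per-base repeat/genome scores and the combined boolean mask."""

    interval: GenomicInterval
    repeat_score: np.ndarray
    genome_score: np.ndarray
    masked: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.interval)
        for name in ("repeat_score", "genome_score", "masked"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} length {arr.shape} != interval length {n}")

    def to_frame(self) -> pd.DataFrame:
        pos = np.arange(self.interval.start, self.interval.end)
        return pd.DataFrame(
            {
                "chrom": self.interval.chrom,
                "pos0": pos,
                "repeat_score": self.repeat_score,
                "genome_score": self.genome_score,
                "masked": self.masked.astype(int),
            }
        )

    def masked_intervals(self) -> list[GenomicInterval]:
        """Maximal masked runs as intervals (BED-ready)."""
        out: list[GenomicInterval] = []
        run_start: int | None = None
        for i, flag in enumerate(self.masked):
            if flag and run_start is None:
                run_start = i
            elif not flag and run_start is not None:
                out.append(
                    GenomicInterval(
                        self.interval.chrom,
                        self.interval.start + run_start,
                        self.interval.start + i,
                    )
                )
                run_start = None
        if run_start is not None:
            out.append(
                GenomicInterval(
                    self.interval.chrom,
                    self.interval.start + run_start,
                    self.interval.end,
                )
            )
        return out


def _library_tiles(repeat_library: Mapping[str, str], k: int) -> set[str]:
    tiles: set[str] = set()
    for seq in repeat_library.values():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            tile = seq[i : i + k]
            tiles.add(tile)
            tiles.add(revcomp(tile))
    return tiles


def repeat_tile_score(
    target_seq: str,
    repeat_library: Mapping[str, str],
    k: int = REPEAT_TILE,
) -> np.ndarray:
    """Per-base repeat-library tile score over the target.

    Each length-k tile of the target with a perfect match (either strand)
    to any library sequence adds 1 to all k coordinates it covers;
    overlapping matches accumulate.
    """
    if len(target_seq) < k:
        raise ValueError(f"target length {len(target_seq)} < tile size {k}")
    scores = np.zeros(len(target_seq), dtype=np.int64)
    if not repeat_library:
        logger.warning("empty repeat library: repeat scores are all zero")
        return scores
    tiles = _library_tiles(repeat_library, k)
    target = target_seq.upper()
    for i in range(len(target) - k + 1):
        if target[i : i + k] in tiles:
            scores[i : i + k] += 1
    return scores


def genome_tile_score(
    target_seq: str,
    genome: Mapping[str, str],
    k: int = GENOME_TILE,
) -> np.ndarray:
    """Per-base genome multi-mapping tile score over the target.

    A length-k tile contributes 1 to its k coordinates when it occurs more
    than once in the genome (both strands, positions deduplicated).
    """
    if len(target_seq) < k:
        raise ValueError(f"target length {len(target_seq)} < tile size {k}")
    target = target_seq.upper()
    mult = kmer_multiplicity(target, genome, k)
    if (mult == 0).all():
        logger.warning("target sequence not found in genome")
    scores = np.zeros(len(target), dtype=np.int64)
    for i in np.flatnonzero(mult >= 2):
        scores[i : i + k] += 1
    return scores


def combine_mask(
    interval: GenomicInterval,
    repeat_score: np.ndarray,
    genome_score: np.ndarray,
) -> MaskTrack:
    """Logical-OR combination: a base is masked if either score is nonzero."""
    repeat_score = np.asarray(repeat_score)
    genome_score = np.asarray(genome_score)
    if repeat_score.shape != genome_score.shape:
        raise ValueError("score arrays must have equal length")
    masked = (repeat_score > 0) | (genome_score > 0)
    return MaskTrack(interval, repeat_score, genome_score, masked)


def mask_target(
    genome: Mapping[str, str],
    interval: GenomicInterval,
    repeat_library: Mapping[str, str],
    k_repeat: int = REPEAT_TILE,
    k_genome: int = GENOME_TILE,
) -> MaskTrack:
    """Convenience: both tile scores plus the OR-combined mask for a target."""
    seq = genome[interval.chrom][interval.start : interval.end]
    return combine_mask(
        interval,
        repeat_tile_score(seq, repeat_library, k=k_repeat),
        genome_tile_score(seq, genome, k=k_genome),
    )


def write_mask_bed(tracks: Iterable[MaskTrack], path) -> None:
    with open(path, "w") as fh:
        for track in tracks:
            for iv in track.masked_intervals():
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_mask_bed(path, interval: GenomicInterval) -> np.ndarray:
    """Boolean mask array over ``interval`` from a BED of masked regions."""
    masked = np.zeros(len(interval), dtype=bool)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return masked
    for row in df.itertuples(index=False):
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        if chrom != interval.chrom:
            continue
        lo = max(start, interval.start) - interval.start
        hi = min(end, interval.end) - interval.start
        if hi > lo:
            masked[lo:hi] = True
    return masked
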