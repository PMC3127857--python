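"""Exact and 1-mismatch k-mer occurrence counting over small genomes.

Counting is double-stranded but position-deduplicated: a window at position
``p`` of a chromosome is counted once if it equals the query k-mer or its
reverse complement, so palindromic queries are not double-counted.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .reference import revcomp

_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_TO_CODE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 codes; other characters map to 255."""
    return _BASE_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_view(codes: np.ndarray, k: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(codes, k)


def hamming_profile(seq: str, kmer: str) -> np.ndarray:
    """Hamming distance of ``kmer`` to every length-k window of ``seq``.

    Windows containing non-ACGT characters compare as mismatches there.
    Returns an int array of length ``len(seq) - k + 1`` (empty if shorter).
    """
    k = len(kmer)
    if len(seq) < k:
        return np.zeros(0, dtype=np.int64)
    windows = _window_view(encode(seq), k)
    return (windows != encode(kmer)).sum(axis=1)


def count_occurrences(
    kmer: str, genome: Mapping[str, str]
) -> tuple[int, int]:
    """(exact, one-mismatch) occurrence counts of ``kmer`` over both strands.

    A window counts as exact if it equals the k-mer or its reverse
    complement; as one-mismatch if its minimum Hamming distance to either
    orientation is exactly 1.
    """
    if set(kmer) - set("ACGT"):
        raise ValueError(f"k-mer must be ACGT only, got {kmer!r}")
    rc = revcomp(kmer)
    exact = 0
    mm1 = 0
    for seq in genome.values():
        d_fwd = hamming_profile(seq, kmer)
        if d_fwd.size == 0:
            continue
        if rc == kmer:
            dist = d_fwd
        else:
            dist = np.minimum(d_fwd, hamming_profile(seq, rc))
        exact += int((dist == 0).sum())
        mm1 += int((dist == 1).sum())
    return exact, mm1


def find_occurrences(
    kmer: str, genome: Mapping[str, str]
) -> list[tuple[str, int, str]]:
    """Exact occurrence loci of ``kmer`` as (chrom, start, strand) tuples.

    A forward-strand match is a window equal to the k-mer; a reverse-strand
    match is a window equal to its reverse complement. A palindromic match
    is reported once, on the forward strand.
    """
    rc = revcomp(kmer)
    hits: list[tuple[str, int, str]] = []
    for chrom, seq in genome.items():
        d_fwd = hamming_profile(seq, kmer)
        for pos in np.flatnonzero(d_fwd == 0):
            hits.append((chrom, int(pos), "+"))
        if rc != kmer:
            d_rev = hamming_profile(seq, rc)
            for pos in np.flatnonzero(d_rev == 0):
                hits.append((chrom, int(pos), "-"))
    return hits


def kmer_multiplicity(seq: str, genome: Mapping[str, str], k: int) -> np.ndarray:
    """Double-stranded genome occurrence count for every k-tile of ``seq``.

    Returns an int array over tile offsets 0..len(seq)-k. Used for
    multi-mapping detection: a tile drawn from inside the genome has
    multiplicity >= 1.
    """
    from collections import Counter

    if len(seq) < k:
        raise ValueError(f"sequence shorter than tile size k={k}")
    counts: Counter[str] = Counter()
    for chrom_seq in genome.values():
        for i in range(len(chrom_seq) - k + 1):
            counts[chrom_seq[i : i + k]] += 1
    out = np.zeros(len(seq) - k + 1, dtype=np.int64)
    for i in range(out.size):
        tile = seq[i : i + k]
        rc = revcomp(tile)
        n = counts[tile]
        if rc != tile:
            n += counts[rc]
        out[i] = n
    return out
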