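"""Indel filtering rules for gapped short-read alignments.

Gapped alignment itself is performed upstream (by the aligner whose output
we consume); this module applies three high-specificity filters that
remove the false-positive indels typical of short single reads:

1. *Breakpoint diversity* — at least two distinct read start positions
   (breakpoints) among supporting reads on the forward strand AND at least
   two on the reverse strand.
2. *Depth* — total fold-coverage at the indel's 5' position above 50.
3. *Uniqueness* — no supporting read's sequence can be placed elsewhere in
   the genome with fewer than 3 mismatches, which would mark the indel as
   an off-target capture artifact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._kmer import hamming_profile
from .pileup import StrandedPileup
from .reference import revcomp

MIN_BREAKPOINTS = 2
MIN_FC = 50
MIN_ALT_MISMATCHES = 3


@dataclass(frozen=True)
class GappedReadRecord:
    """One gapped-alignment record supporting a candidate indel."""

    read_id: str
    breakpoint: int          # first aligned reference position of the read
    strand: str              # "+" or "-"
    indel_pos: int           # 0-based reference position of the indel 5' end
    indel_seq: str           # inserted sequence, or deleted reference bases
    is_insertion: bool
    read_seq: str            # the read's base sequence as sequenced

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"record {self.read_id}: strand must be + or -")


@dataclass
class IndelCall:
    indel_pos: int
    indel_seq: str
    is_insertion: bool
    n_fwd_breakpoints: int
    n_rev_breakpoints: int
    depth_5prime: int
    min_alt_mismatches: int
    passes: bool
    reasons: tuple[str, ...]


def _best_alternative_placement(
    read_seq: str,
    genome: Mapping[str, str],
    exclude: tuple[str, int, int] | None,
) -> int:
    """Minimum mismatch count of the read over all other genome placements.

    ``exclude`` is a (chrom, start, end) window around the indel locus
    whose placements are ignored (the read's own origin). Both strands are
    scanned. Returns a large value when the read fits nowhere.
    """
    best = len(read_seq) + 1
    for chrom, seq in genome.items():
        for query in (read_seq, revcomp(read_seq)):
            dist = hamming_profile(seq, query)
            if dist.size == 0:
                continue
            if exclude is not None and chrom == exclude[0]:
                lo = max(0, exclude[1] - len(read_seq))
                hi = min(dist.size, exclude[2])
                dist = dist.copy()
                dist[lo:hi] = len(read_seq) + 1
            best = min(best, int(dist.min()))
    return best


def filter_indels(
    records: Sequence[GappedReadRecord],
    pileup: StrandedPileup,
    genome: Mapping[str, str],
    min_breakpoints: int = MIN_BREAKPOINTS,
    min_fc: int = MIN_FC,
    min_alt_mismatches: int = MIN_ALT_MISMATCHES,
    exclusion_radius: int = 100,
) -> list[IndelCall]:
    """Apply the three indel filters; one call per distinct indel.

    Records are grouped by (position, sequence, type). ``exclusion_radius``
    bounds the window around the indel locus ignored during the
    alternative-placement scan.
    """
    groups: dict[tuple[int, str, bool], list[GappedReadRecord]] = {}
    for rec in records:
        groups.setdefault((rec.indel_pos, rec.indel_seq, rec.is_insertion), []).append(rec)
    calls: list[IndelCall] = []
    chrom = pileup.interval.chrom
    for (pos, seq, is_ins), recs in sorted(groups.items()):
        fwd_bp = {r.breakpoint for r in recs if r.strand == "+"}
        rev_bp = {r.breakpoint for r in recs if r.strand == "-"}
        reasons: list[str] = []
        if len(fwd_bp) < min_breakpoints or len(rev_bp) < min_breakpoints:
            reasons.append("breakpoints")
        if pileup.interval.start <= pos < pileup.interval.end:
            depth5 = int(pileup.depth[pos - pileup.interval.start])
        else:
            depth5 = 0
        if depth5 <= min_fc:
            reasons.append("depth")
        exclude = (chrom, pos - exclusion_radius, pos + exclusion_radius)
        best_alt = min(
            (_best_alternative_placement(r.read_seq, genome, exclude) for r in recs),
            default=len(seq) + 1,
        )
        if best_alt < min_alt_mismatches:
            reasons.append("alternative_placement")
        calls.append(
            IndelCall(
                indel_pos=pos,
                indel_seq=seq,
                is_insertion=is_ins,
                n_fwd_breakpoints=len(fwd_bp),
                n_rev_breakpoints=len(rev_bp),
                depth_5prime=depth5,
                min_alt_mismatches=best_alt,
                passes=not reasons,
                reasons=tuple(reasons),
            )
        )
    return calls
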