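"""Quality-control annotation of capture arms.

Four flags mark oligos at risk of failure or off-target capture:

* ``W`` — whole-genome duplication: either 20-nt arm occurs more than once
  in the genome (exact matches, both strands).
* ``P`` — paralog: both arms are duplicated and a second locus reproduces
  copies of both arms within 1 kb of each other, in phase (same order and
  strand as the design locus). P implies W by construction.
* ``A`` — the outer 14 bases of either arm perfectly match an Alu consensus.
* ``R`` — the same outer 14-mer matches any other repeat consensus.

Flags use exact matches only; 1-mismatch genome occurrence counts are
reported as metadata. The module also provides the per-column restriction-
site prevalence analysis over a multiple alignment, used to explain why an
enzyme whose site is conserved inside Alu elements circularizes repeat
fragments off-target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kmer
from .design import CaptureOligo
from .reference import RestrictionEnzyme, get_enzyme, revcomp

PARALOG_WINDOW = 1000
OUTER_BASES = 14

FLAG_ORDER = ("W", "P", "A", "R")


@dataclass
class FlagAnnotation:
    oligo_id: str
    W: bool = False
    P: bool = False
    A: bool = False
    R: bool = False
    arm5_hits: tuple[int, int] = (0, 0)   # (exact, 1-mismatch)
    arm3_hits: tuple[int, int] = (0, 0)
    repeat_names: tuple[str, ...] = ()
    evaluated_repeats: bool = True

    @property
    def flags(self) -> frozenset[str]:
        return frozenset(f for f in FLAG_ORDER if getattr(self, f))

    @property
    def any_flag(self) -> bool:
        return bool(self.flags)


def count_genome_occurrences(kmer: str, genome: Mapping[str, str]) -> tuple[int, int]:
    """(exact, single-mismatch) occurrence counts of a k-mer over both strands."""
    return _kmer.count_occurrences(kmer, genome)


def _outer_14mers(oligo: CaptureOligo, n: int = OUTER_BASES) -> dict[str, str]:
    """Outer n bases of each arm (the end farthest from the linker)."""
    return {"arm5": oligo.arm5_seq[:n], "arm3": oligo.arm3_seq[-n:]}


def _matches_library(kmer: str, library: Mapping[str, str]) -> list[str]:
    rc = revcomp(kmer)
    hits = []
    for name, seq in library.items():
        seq = seq.upper()
        if kmer in seq or rc in seq:
            hits.append(name)
    return hits


def _in_phase_pair_exists(
    arm5_hits: Sequence[tuple[str, int, str]],
    arm3_hits: Sequence[tuple[str, int, str]],
    origin5: tuple[str, int, str],
    window: int = PARALOG_WINDOW,
) -> bool:
    """True if a second locus reproduces both arm copies in phase.

    In phase: same chromosome and strand, the arms in the same relative
    order as at the design locus (arm5 upstream of arm3 on +, downstream
    on -), within ``window`` bases.
    """
    for c5, p5, s5 in arm5_hits:
        if (c5, p5, s5) == origin5:
            continue
        for c3, p3, s3 in arm3_hits:
            if c5 != c3 or s5 != s3:
                continue
            offset = p3 - p5 if s5 == "+" else p5 - p3
            if 0 < offset <= window:
                return True
    return False


def assign_flags(
    oligo: CaptureOligo,
    genome: Mapping[str, str],
    alu_consensus: Mapping[str, str] | None = None,
    repeat_library: Mapping[str, str] | None = None,
) -> FlagAnnotation:
    """Annotate one oligo with W/P/A/R flags against a genome and libraries.

    When a consensus library is missing the corresponding flag is left
    unset and the annotation records that repeats were not evaluated.
    """
    ann = FlagAnnotation(oligo_id=oligo.oligo_id)
    ann.arm5_hits = count_genome_occurrences(oligo.arm5_seq, genome)
    ann.arm3_hits = count_genome_occurrences(oligo.arm3_seq, genome)
    ann.W = ann.arm5_hits[0] > 1 or ann.arm3_hits[0] > 1
    if ann.arm5_hits[0] > 1 and ann.arm3_hits[0] > 1:
        hits5 = _kmer.find_occurrences(oligo.arm5_seq, genome)
        hits3 = _kmer.find_occurrences(oligo.arm3_seq, genome)
        origin5 = (oligo.arm5.chrom, oligo.arm5.start, "+")
        ann.P = _in_phase_pair_exists(hits5, hits3, origin5)
    outer = _outer_14mers(oligo)
    names: list[str] = []
    if alu_consensus is None and repeat_library is None:
        ann.evaluated_repeats = False
    if alu_consensus is not None:
        for kmer in outer.values():
            hit = _matches_library(kmer, alu_consensus)
            if hit:
                ann.A = True
                names.extend(hit)
    if repeat_library is not None:
        for kmer in outer.values():
            hit = _matches_library(kmer, repeat_library)
            if hit:
                ann.R = True
                names.extend(hit)
    ann.repeat_names = tuple(sorted(set(names)))
    return ann


def annotate_panel(
    oligos: Sequence[CaptureOligo],
    genome: Mapping[str, str],
    alu_consensus: Mapping[str, str] | None = None,
    repeat_library: Mapping[str, str] | None = None,
) -> list[FlagAnnotation]:
    return [assign_flags(o, genome, alu_consensus, repeat_library) for o in oligos]


def flag_summary(
    annotations: Sequence[FlagAnnotation],
    enzymes: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-enzyme flag counts plus a Total column.

    ``enzymes`` maps oligo_id -> enzyme name; without it all oligos fall in
    one "all" column. Rows: designed, no_flag, W, P, A, R, flagged_union.
    The union row counts oligos carrying at least one flag and is at most
    the sum of the individual flag rows.
    """
    enz_of = enzymes or {}
    groups: dict[str, list[FlagAnnotation]] = {}
    for ann in annotations:
        groups.setdefault(enz_of.get(ann.oligo_id, "all"), []).append(ann)
    rows = ["designed", "no_flag", "W", "P", "A", "R", "flagged_union"]
    data = {}
    for enzyme in sorted(groups):
        anns = groups[enzyme]
        data[enzyme] = [
            len(anns),
            sum(not a.any_flag for a in anns),
            sum(a.W for a in anns),
            sum(a.P for a in anns),
            sum(a.A for a in anns),
            sum(a.R for a in anns),
            sum(a.any_flag for a in anns),
        ]
    df = pd.DataFrame(data, index=rows)
    df["Total"] = df.sum(axis=1)
    return df


def annotations_to_frame(annotations: Sequence[FlagAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "oligo_id": [a.oligo_id for a in annotations],
            "W": [int(a.W) for a in annotations],
            "P": [int(a.P) for a in annotations],
            "A": [int(a.A) for a in annotations],
            "R": [int(a.R) for a in annotations],
            "arm5_exact": [a.arm5_hits[0] for a in annotations],
            "arm5_mm1": [a.arm5_hits[1] for a in annotations],
            "arm3_exact": [a.arm3_hits[0] for a in annotations],
            "arm3_mm1": [a.arm3_hits[1] for a in annotations],
            "repeat_names": [",".join(a.repeat_names) or "." for a in annotations],
        }
    )


def alignment_site_prevalence(
    alignment: Mapping[str, str] | Sequence[str],
    enzymes: Sequence[RestrictionEnzyme | str],
) -> pd.DataFrame:
    """Fraction of aligned sequences with a recognition site starting per column.

    A site starts at column ``c`` of a sequence when the residue at ``c`` is
    not a gap and the next 4 residues of that sequence, skipping gap
    columns, match the enzyme's recognition sequence. Returns a long-format
    frame with columns (column, enzyme, fraction).
    """
    seqs = list(alignment.values()) if isinstance(alignment, Mapping) else list(alignment)
    if not seqs:
        raise ValueError("empty alignment")
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("ragged alignment: sequences differ in length")
    enzs = [get_enzyme(e) if isinstance(e, str) else e for e in enzymes]
    counts = {enz.name: np.zeros(width, dtype=np.int64) for enz in enzs}
    for seq in seqs:
        seq = seq.upper()
        residue_cols = [i for i, ch in enumerate(seq) if ch not in "-."]
        degapped = "".join(seq[i] for i in residue_cols)
        for enz in enzs:
            site = enz.recognition
            start = degapped.find(site)
            while start != -1:
                counts[enz.name][residue_cols[start]] += 1
                start = degapped.find(site, start + 1)
    n = len(seqs)
    records = [
        {"column": col, "enzyme": name, "fraction": counts[name][col] / n}
        for name in counts
        for col in range(width)
    ]
    return pd.DataFrame.from_records(records)
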