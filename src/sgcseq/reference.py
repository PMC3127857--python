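"""Reference sequences, regions of interest, SNP tracks and restriction digestion.

All coordinates are 0-based half-open internally (BED native); 1-based
coordinates appear only in VCF output. A restriction *cut position* is the
top-strand phosphodiester bond index: cutting a sequence at position ``p``
yields the pieces ``seq[:p]`` and ``seq[p:]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

IUPAC_CODES = set("ACGTRYSWKMBDHVN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT(N) sequence."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )


@dataclass(frozen=True)
class ROI:
    """Region of interest: an exon plus up to ``pad`` bases of flanking intron."""

    gene: str
    exon: GenomicInterval
    pad: int
    interval: GenomicInterval
    roi_id: str = ""

    def __post_init__(self) -> None:
        if not self.interval.contains(self.exon):
            raise ValueError(f"ROI interval must contain its exon ({self.roi_id})")


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A 4-base-cutter with a top-strand cut offset within the recognition site."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if len(self.recognition) != 4:
            raise ValueError(f"{self.name}: recognition site must be 4 bases")
        if set(self.recognition) - set("ACGT"):
            raise ValueError(f"{self.name}: recognition site must be ACGT only")
        if not 0 <= self.cut_offset <= 4:
            raise ValueError(f"{self.name}: cut offset must be in [0, 4]")


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment: the interval between two consecutive cuts."""

    enzyme: str
    interval: GenomicInterval

    def __len__(self) -> int:
        return len(self.interval)


# Four 4-base cutters with the highest design coverage; standard NEB cut
# chemistry. Sau3AI and its isoschizomer DpnII recognize the same site and
# are modelled as one entry with two names.
BUILTIN_ENZYMES: dict[str, RestrictionEnzyme] = {}


def _register(enz: RestrictionEnzyme, *aliases: str) -> None:
    BUILTIN_ENZYMES[enz.name] = enz
    for alias in aliases:
        BUILTIN_ENZYMES[alias] = enz


_register(RestrictionEnzyme("MseI", "TTAA", 1))
_register(RestrictionEnzyme("BfaI", "CTAG", 1))
_register(RestrictionEnzyme("Sau3AI", "GATC", 0), "DpnII")
_register(RestrictionEnzyme("CviQI", "GTAC", 1))


def get_enzyme(name: str) -> RestrictionEnzyme:
    try:
        return BUILTIN_ENZYMES[name]
    except KeyError:
        raise KeyError(
            f"unknown restriction enzyme {name!r}; known: "
            f"{sorted(set(e.name for e in BUILTIN_ENZYMES.values()))}"
        ) from None


def load_enzymes_yaml(path: str | Path) -> dict[str, RestrictionEnzyme]:
    """Load user enzyme definitions from a YAML mapping.

    Format: ``{name: {recognition: GATC, cut_offset: 0}}``. Returns the
    builtin table augmented by (or overridden with) the file's entries.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    table = dict(BUILTIN_ENZYMES)
    for name, entry in raw.items():
        table[name] = RestrictionEnzyme(
            name, entry["recognition"].upper(), int(entry["cut_offset"])
        )
    return table


class SNPTrack:
    """Set of known-polymorphism coordinates, queried per interval."""

    def __init__(self, positions: Iterable[tuple[str, int]] = ()) -> None:
        self._by_chrom: dict[str, set[int]] = {}
        for chrom, pos in positions:
            self._by_chrom.setdefault(chrom, set()).add(int(pos))

    def __contains__(self, item: tuple[str, int]) -> bool:
        chrom, pos = item
        return pos in self._by_chrom.get(chrom, ())

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def in_interval(self, iv: GenomicInterval) -> list[int]:
        """Sorted SNP positions falling inside ``iv``."""
        positions = self._by_chrom.get(iv.chrom, ())
        return sorted(p for p in positions if iv.start <= p < iv.end)

    def overlaps(self, iv: GenomicInterval) -> bool:
        return bool(self.in_interval(iv))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SNPTrack":
        """Read a SNP track TSV with columns chrom, pos0[, ref, alt]."""
        df = pd.read_csv(path, sep="\t", comment="#", header=None).iloc[:, :2]
        df.columns = ["chrom", "pos0"]
        return cls(zip(df["chrom"].astype(str), df["pos0"].astype(int)))


def load_reference(fasta_path: str | Path) -> dict[str, str]:
    """Load a FASTA reference into a name -> uppercase sequence mapping.

    Names are the first whitespace-delimited token of each header. Records
    containing non-IUPAC characters are rejected with the offending record
    named in the error.
    """
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - IUPAC_CODES
        if bad:
            raise ValueError(
                f"record {record.id!r}: non-IUPAC characters {sorted(bad)}"
            )
        if record.id in genome:
            raise ValueError(f"duplicate sequence name {record.id!r}")
        genome[record.id] = seq
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_exon_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ exon table: chrom, start, end[, gene]."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 3:
        raise ValueError("exon BED needs at least 3 columns")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.assign(gene="NA")
    df.columns = ["chrom", "start", "end", "gene"]
    return df


def build_rois(
    exon_table: pd.DataFrame,
    genome: Mapping[str, str],
    pad: int = 50,
) -> list[ROI]:
    """Expand each exon by ``pad`` intronic bases per side, clipped to the chromosome.

    ``exon_table`` columns: chrom, start, end, gene. One ROI per exon row;
    gene association and row order are preserved.
    """
    rois: list[ROI] = []
    counters: dict[str, int] = {}
    for row in exon_table.itertuples(index=False):
        chrom, start, end, gene = str(row.chrom), int(row.start), int(row.end), str(row.gene)
        if chrom not in genome:
            raise KeyError(f"exon chromosome {chrom!r} not in reference")
        chrom_len = len(genome[chrom])
        if not (0 <= start < end <= chrom_len):
            raise ValueError(
                f"exon {chrom}:{start}-{end} outside chromosome bounds (len {chrom_len})"
            )
        exon = GenomicInterval(chrom, start, end)
        padded = GenomicInterval(chrom, max(0, start - pad), min(chrom_len, end + pad))
        counters[gene] = counters.get(gene, 0) + 1
        rois.append(
            ROI(gene=gene, exon=exon, pad=pad, interval=padded,
                roi_id=f"{gene}.{counters[gene]}")
        )
    return rois


def scan_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """All top-strand cut positions of ``enzyme`` in ``seq``, sorted ascending.

    One cut per recognition-site occurrence at ``occurrence_start +
    cut_offset``; overlapping occurrences are all reported. The bundled
    recognition sites are palindromic, so a top-strand scan covers both
    strands.
    """
    if not seq:
        raise ValueError("empty sequence")
    site = enzyme.recognition
    cuts: list[int] = []
    start = seq.find(site)
    while start != -1:
        cuts.append(start + enzyme.cut_offset)
        start = seq.find(site, start + 1)
    return sorted(set(cuts))


def digest(
    genome: Mapping[str, str],
    seq_name: str,
    enzyme: RestrictionEnzyme | str,
) -> list[Fragment]:
    """In-silico digest of one chromosome into restriction fragments.

    Fragments are the intervals between consecutive top-strand cut positions
    plus the two terminal pieces; zero-length fragments (adjacent cuts or a
    cut at a sequence end) are dropped with a warning. Fragment lengths sum
    to the chromosome length.
    """
    if isinstance(enzyme, str):
        enzyme = get_enzyme(enzyme)
    if seq_name not in genome:
        raise KeyError(f"unknown sequence {seq_name!r}")
    seq = genome[seq_name]
    cuts = scan_sites(seq, enzyme) if seq else []
    bounds = [0] + [c for c in cuts if 0 < c < len(seq)] + [len(seq)]
    fragments: list[Fragment] = []
    for left, right in zip(bounds[:-1], bounds[1:]):
        if right == left:
            logger.warning(
                "dropping zero-length fragment at %s:%d (%s)", seq_name, left, enzyme.name
            )
            continue
        fragments.append(
            Fragment(enzyme.name, GenomicInterval(seq_name, left, right))
        )
    return fragments


def digest_all(
    genome: Mapping[str, str], enzyme: RestrictionEnzyme | str
) -> dict[str, list[Fragment]]:
    """Digest every chromosome; mapping chrom -> fragment list."""
    return {name: digest(genome, name, enzyme) for name in genome}
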