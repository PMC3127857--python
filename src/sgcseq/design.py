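"""Capture oligonucleotide design over restriction fragments.

Each capture oligo is an 80-mer: two 20-nt genome-complementary capture
arms joined by a 40-nt constant linker. The captured molecule is a
restriction fragment that circularizes when both arms anneal; efficient
capture requires the amplicon (the genomic span between the arms' outer
edges) to stay within ``max_amplicon`` bases. When an arm is placed
internally to the fragment, the genomic sequence protruding beyond it — the
*flap* — is cleaved enzymatically before ligation; flap lengths are
recorded because they depress capture yield.

Placement rules per region of interest (ROI) and fragment:

1. If the whole fragment fits within ``max_amplicon``, one oligo is placed
   with both arms flush inside the two cut ends (no flaps).
2. Otherwise an arm is anchored flush inside a cut end whenever the ROI
   portion is reachable within ``max_amplicon`` from that end, leaving a
   single flap beyond the other, internally-placed arm; failing that, both
   arms sit at the boundaries of the (tiled) target span, leaving two flaps.
3. ROIs spanning internal cut sites receive tiled oligos, one set per
   overlapped fragment, so amplicons jointly cover the coverable ROI bases.
4. Arms may not overlap known SNP positions; when no SNP-free placement
   exists the oligo is emitted with a design-failure annotation and excluded
   from coverage accounting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .reference import (
    Fragment,
    GenomicInterval,
    ROI,
    RestrictionEnzyme,
    SNPTrack,
    digest_all,
    get_enzyme,
    revcomp,
)

logger = logging.getLogger(__name__)

ARM_LENGTH = 20
LINKER_LENGTH = 40
OLIGO_LENGTH = 2 * ARM_LENGTH + LINKER_LENGTH

#: Bundled constant linker motif (configurable); any fixed 40-mer works for
#: design bookkeeping — the real vector sequence is assay-specific.
DEFAULT_LINKER = "CTTCAGCTTCCCGATTACGGATCGTCGTATGCAGTGAAAC"


@dataclass(frozen=True)
class DesignParams:
    max_amplicon: int = 800          # inclusive upper bound on amplicon length
    arm_length: int = ARM_LENGTH
    linker: str = DEFAULT_LINKER
    pad: int = 50                    # intronic padding used when building ROIs

    def __post_init__(self) -> None:
        if len(self.linker) != LINKER_LENGTH:
            raise ValueError(f"linker must be {LINKER_LENGTH} nt")
        if self.max_amplicon < 2 * self.arm_length:
            raise ValueError("max_amplicon must admit two arms")


@dataclass(frozen=True)
class CaptureOligo:
    """An 80-mer capture design: arms, linker, amplicon, flaps, QC flags."""

    oligo_id: str
    enzyme: str
    arm5_seq: str
    arm5: GenomicInterval
    arm3_seq: str
    arm3: GenomicInterval
    linker: str
    amplicon: GenomicInterval
    flap5: int
    flap3: int
    roi_ids: tuple[str, ...]
    flags: frozenset[str] = frozenset()
    design_failure: bool = False

    def __post_init__(self) -> None:
        if len(self.arm5_seq) != ARM_LENGTH or len(self.arm3_seq) != ARM_LENGTH:
            raise ValueError("capture arms must be exactly 20 nt")
        if len(self.full_sequence) != OLIGO_LENGTH:
            raise ValueError("oligo must be exactly 80 nt")
        if self.flap5 < 0 or self.flap3 < 0:
            raise ValueError("flap lengths must be non-negative")
        if not (self.amplicon.contains(self.arm5) and self.amplicon.contains(self.arm3)):
            raise ValueError("arms must lie within the amplicon")

    @property
    def full_sequence(self) -> str:
        return self.arm5_seq + self.linker + self.arm3_seq

    def arm_gc_percent(self) -> float:
        arms = self.arm5_seq + self.arm3_seq
        return 100.0 * sum(b in "GC" for b in arms) / len(arms)


@dataclass
class DesignReport:
    """Panel-level design bookkeeping (a design-summary table)."""

    n_genes: int
    n_rois: int
    n_oligos: int
    roi_bases: int
    covered_roi_bases: int
    rois_per_gene: float
    oligos_per_gene: int
    oligos_per_roi: int
    pct_roi_bases_covered: float
    per_enzyme_oligos: dict[str, int] = field(default_factory=dict)
    per_roi_covered: dict[str, int] = field(default_factory=dict)
    per_gene_oligos: dict[str, int] = field(default_factory=dict)


def summary_ratios(n_genes: int, n_rois: int, n_oligos: int) -> tuple[float, int, int]:
    """(ROIs/gene to 2 decimals, oligos/gene and oligos/ROI to nearest int)."""
    if n_genes <= 0:
        raise ValueError("summary requires at least one gene")
    if n_rois <= 0:
        raise ValueError("summary requires at least one ROI")
    return (
        round(n_rois / n_genes, 2),
        round(n_oligos / n_genes),
        round(n_oligos / n_rois),
    )


def capture_totals(
    roi_kb_covered: float, extra_intron_kb: float, roi_kb_total: float
) -> tuple[float, float]:
    """Assay capture-size arithmetic.

    Returns (total theoretical captured Kb, percent of ROI bases covered to
    one decimal). The total is the designed ROI coverage plus intronic
    sequence captured beyond the padded ROI because amplicons extend to
    restriction sites outside it.
    """
    if roi_kb_total <= 0:
        raise ValueError("total ROI size must be positive")
    total = round(roi_kb_covered + extra_intron_kb, 3)
    pct = round(100.0 * roi_kb_covered / roi_kb_total, 1)
    return total, pct


def _interval_union_length(intervals: Iterable[GenomicInterval]) -> int:
    spans = sorted((iv.chrom, iv.start, iv.end) for iv in intervals)
    total = 0
    cur_chrom, cur_start, cur_end = None, 0, 0
    for chrom, start, end in spans:
        if chrom != cur_chrom or start > cur_end:
            total += cur_end - cur_start
            cur_chrom, cur_start, cur_end = chrom, start, end
        else:
            cur_end = max(cur_end, end)
    total += cur_end - cur_start
    return total


def _arm_at(genome: Mapping[str, str], chrom: str, start: int, arm_length: int) -> tuple[str, GenomicInterval]:
    iv = GenomicInterval(chrom, start, start + arm_length)
    return genome[chrom][iv.start : iv.end], iv


def _arms_snp_free(snps: SNPTrack, *arms: GenomicInterval) -> bool:
    return not any(snps.overlaps(arm) for arm in arms)


def design_roi(
    roi: ROI,
    fragments: Sequence[Fragment],
    genome: Mapping[str, str],
    snp_track: SNPTrack | None = None,
    params: DesignParams | None = None,
) -> list[CaptureOligo]:
    """Design capture oligos for one ROI against one enzyme's fragments.

    Returns possibly-empty list; uncovered ROI intervals are logged. Oligos
    whose arms unavoidably overlap SNPs carry ``design_failure=True``.
    """
    params = params or DesignParams()
    snps = snp_track or SNPTrack()
    arm = params.arm_length
    max_amp = params.max_amplicon
    oligos: list[CaptureOligo] = []
    overlapping = [f for f in fragments if f.interval.overlaps(roi.interval)]
    if not overlapping:
        logger.info("ROI %s has no usable fragment; uncovered %s:%d-%d",
                    roi.roi_id, roi.interval.chrom, roi.interval.start, roi.interval.end)
        return []
    counter = 0
    for frag in overlapping:
        fiv = frag.interval
        target = fiv.intersect(roi.interval)
        assert target is not None
        for s, e, flap5, flap3 in _plan_amplicons(fiv, target, max_amp, arm):
            counter += 1
            arm5_seq, arm5_iv = _arm_at(genome, fiv.chrom, s, arm)
            arm3_seq, arm3_iv = _arm_at(genome, fiv.chrom, e - arm, arm)
            failure = not _arms_snp_free(snps, arm5_iv, arm3_iv)
            if failure:
                # reject-and-retile is not attempted beyond the alternative
                # anchorings already tried in planning; report the failure
                logger.info("ROI %s oligo %d: capture arm overlaps a known SNP",
                            roi.roi_id, counter)
            oligos.append(
                CaptureOligo(
                    oligo_id=f"{roi.roi_id}.{frag.enzyme}.{counter}",
                    enzyme=frag.enzyme,
                    arm5_seq=arm5_seq,
                    arm5=arm5_iv,
                    arm3_seq=arm3_seq,
                    arm3=arm3_iv,
                    linker=params.linker,
                    amplicon=GenomicInterval(fiv.chrom, s, e),
                    flap5=flap5,
                    flap3=flap3,
                    roi_ids=(roi.roi_id,),
                    design_failure=failure,
                )
            )
    return oligos


def _plan_amplicons(
    fragment: GenomicInterval,
    target: GenomicInterval,
    max_amp: int,
    arm: int,
) -> list[tuple[int, int, int, int]]:
    """Amplicon placements (start, end, flap5, flap3) covering ``target``.

    Every amplicon is anchored flush at a restriction cut end: the
    circularization junction is ligated at a fragment end, so only the
    other, internally-placed arm may leave a (cleavable) flap. The
    fragment-fits case emits the whole fragment. In an oversized fragment
    the coverable bases are those within ``max_amp`` of either cut end;
    they receive a 5'-anchored and/or a 3'-anchored amplicon whose inner
    arm sits at the target boundary (or at maximal reach). Bases beyond
    reach of both cut ends are uncoverable by this enzyme.
    """
    min_amp = 2 * arm
    if len(fragment) < min_amp:
        # two non-overlapping arms cannot fit; nothing designable here
        return []
    if len(fragment) <= max_amp:
        return [(fragment.start, fragment.end, 0, 0)]
    left_reach = fragment.start + max_amp   # rightmost coverable from 5' cut
    right_reach = fragment.end - max_amp    # leftmost coverable from 3' cut
    if target.end - fragment.start <= max_amp:
        e = max(target.end, fragment.start + min_amp)
        return [(fragment.start, e, 0, fragment.end - e)]
    if fragment.end - target.start <= max_amp:
        s = min(target.start, fragment.end - min_amp)
        return [(s, fragment.end, s - fragment.start, 0)]
    plans: list[tuple[int, int, int, int]] = []
    if target.start < left_reach:
        plans.append((fragment.start, left_reach, 0, fragment.end - left_reach))
    if target.end > right_reach:
        plans.append((right_reach, fragment.end, right_reach - fragment.start, 0))
    if left_reach < right_reach:
        logger.info(
            "target %s:%d-%d has %d bases beyond reach of either cut end",
            fragment.chrom, target.start, target.end,
            max(0, min(target.end, right_reach) - max(target.start, left_reach)),
        )
    return plans


def design_panel(
    rois: Sequence[ROI],
    genome: Mapping[str, str],
    enzymes: Sequence[RestrictionEnzyme | str],
    snp_track: SNPTrack | None = None,
    params: DesignParams | None = None,
) -> tuple[list[CaptureOligo], DesignReport]:
    """Design a capture panel: union over enzymes of per-ROI designs."""
    if not rois:
        raise ValueError("empty ROI list")
    if not enzymes:
        raise ValueError("at least one enzyme required")
    params = params or DesignParams()
    oligos: list[CaptureOligo] = []
    for enzyme in enzymes:
        enz = get_enzyme(enzyme) if isinstance(enzyme, str) else enzyme
        frags_by_chrom = digest_all(genome, enz)
        for roi in rois:
            frags = frags_by_chrom.get(roi.interval.chrom, [])
            oligos.extend(design_roi(roi, frags, genome, snp_track, params))
    report = design_summary(oligos, rois)
    return oligos, report


def design_summary(oligos: Sequence[CaptureOligo], rois: Sequence[ROI]) -> DesignReport:
    """Panel bookkeeping: totals, per-gene/ROI averages, base coverage.

    Coverage counts the union of amplicon∩ROI intervals of non-failed
    oligos; design-failure oligos are excluded from coverage accounting.
    """
    genes = sorted({roi.gene for roi in rois})
    if not genes:
        raise ValueError("summary requires at least one gene")
    roi_by_id = {roi.roi_id: roi for roi in rois}
    per_roi_covered: dict[str, int] = {}
    for roi in rois:
        pieces = [
            seg
            for o in oligos
            if not o.design_failure and roi.roi_id in o.roi_ids
            for seg in [o.amplicon.intersect(roi.interval)]
            if seg is not None
        ]
        per_roi_covered[roi.roi_id] = _interval_union_length(pieces)
    per_gene_oligos: dict[str, int] = {g: 0 for g in genes}
    per_enzyme: dict[str, int] = {}
    for o in oligos:
        per_enzyme[o.enzyme] = per_enzyme.get(o.enzyme, 0) + 1
        for rid in o.roi_ids:
            per_gene_oligos[roi_by_id[rid].gene] += 1
    roi_bases = sum(len(roi.interval) for roi in rois)
    covered = sum(per_roi_covered.values())
    rois_per_gene, oligos_per_gene, oligos_per_roi = summary_ratios(
        len(genes), len(rois), len(oligos)
    )
    return DesignReport(
        n_genes=len(genes),
        n_rois=len(rois),
        n_oligos=len(oligos),
        roi_bases=roi_bases,
        covered_roi_bases=covered,
        rois_per_gene=rois_per_gene,
        oligos_per_gene=oligos_per_gene,
        oligos_per_roi=oligos_per_roi,
        pct_roi_bases_covered=100.0 * covered / roi_bases if roi_bases else 0.0,
        per_enzyme_oligos=per_enzyme,
        per_roi_covered=per_roi_covered,
        per_gene_oligos=per_gene_oligos,
    )


def rank_enzymes(
    rois: Sequence[ROI],
    genome: Mapping[str, str],
    enzymes: Sequence[RestrictionEnzyme | str],
    snp_track: SNPTrack | None = None,
    params: DesignParams | None = None,
) -> pd.DataFrame:
    """Per-enzyme design effectiveness, best first.

    Columns: enzyme, pct_rois_fully_designable, pct_roi_bases_covered.
    Sorted by base coverage descending, ties broken by enzyme name.
    """
    rows = []
    for enzyme in enzymes:
        enz = get_enzyme(enzyme) if isinstance(enzyme, str) else enzyme
        frags_by_chrom = digest_all(genome, enz)
        full = 0
        covered = 0
        total = 0
        for roi in rois:
            frags = frags_by_chrom.get(roi.interval.chrom, [])
            oligos = design_roi(roi, frags, genome, snp_track, params)
            pieces = [
                seg
                for o in oligos
                if not o.design_failure
                for seg in [o.amplicon.intersect(roi.interval)]
                if seg is not None
            ]
            cov = _interval_union_length(pieces)
            covered += cov
            total += len(roi.interval)
            if cov == len(roi.interval):
                full += 1
        rows.append(
            {
                "enzyme": enz.name,
                "pct_rois_fully_designable": 100.0 * full / len(rois) if rois else 0.0,
                "pct_roi_bases_covered": 100.0 * covered / total if total else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["pct_roi_bases_covered", "enzyme"], ascending=[False, True]
    ).reset_index(drop=True)


OLIGO_TABLE_COLUMNS = [
    "id", "enzyme", "chrom", "arm5_start", "arm5_end", "arm3_start", "arm3_end",
    "amplicon_start", "amplicon_end", "flap5", "flap3",
    "arm5_seq", "arm3_seq", "full_80mer", "flags", "design_failure",
]


def oligos_to_frame(oligos: Sequence[CaptureOligo]) -> pd.DataFrame:
    rows = [
        {
            "id": o.oligo_id,
            "enzyme": o.enzyme,
            "chrom": o.amplicon.chrom,
            "arm5_start": o.arm5.start,
            "arm5_end": o.arm5.end,
            "arm3_start": o.arm3.start,
            "arm3_end": o.arm3.end,
            "amplicon_start": o.amplicon.start,
            "amplicon_end": o.amplicon.end,
            "flap5": o.flap5,
            "flap3": o.flap3,
            "arm5_seq": o.arm5_seq,
            "arm3_seq": o.arm3_seq,
            "full_80mer": o.full_sequence,
            "flags": "".join(sorted(o.flags)) or ".",
            "design_failure": int(o.design_failure),
        }
        for o in oligos
    ]
    return pd.DataFrame(rows, columns=OLIGO_TABLE_COLUMNS)


def write_oligo_table(oligos: Sequence[CaptureOligo], path) -> None:
    oligos_to_frame(oligos).to_csv(path, sep="\t", index=False)
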