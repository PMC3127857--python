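"""Synthetic references, pileups, matched pairs and barcoded reads.

Every generator is seeded and fully deterministic: one top-level seed fans
out to per-component substreams (numpy ``SeedSequence.spawn``) so each
dataset can be regenerated independently. Truth manifests accompany every
dataset so downstream callers can be scored without re-deriving ground
truth.

The default simulated error model is a uniform 1% miscall rate split
equally over the three alternative bases, matching the per-base error
range of short-read sequencing these assays were run on (0.5-1%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .demux import BarcodedRead
from .pileup import BASES, StrandedPileup
from .reference import GenomicInterval, SNPTrack, write_fasta
from .snv import ErrorMatrix

DEFAULT_ERROR_RATE = 0.01


@dataclass
class SimulationSpec:
    """Parameters of a synthetic study genome and its planted features."""

    seed: int = 0
    genome_length: int = 20_000
    gc: float = 0.41
    chrom: str = "chrS"
    site_spacing: dict[str, int] = field(default_factory=dict)  # enzyme recognition -> spacing
    n_snps: int = 20
    n_exons: int = 8
    exon_length: int = 150
    genes: int = 2
    pad: int = 50
    duplications: tuple[tuple[int, int], ...] = ()  # (block_length, n_extra_copies)
    n_repeats: int = 2
    repeat_length: int = 300
    repeat_copies: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")


@dataclass
class SyntheticReference:
    genome: dict[str, str]
    exons: pd.DataFrame                   # chrom, start, end, gene
    snps: SNPTrack
    snp_table: pd.DataFrame               # chrom, pos0, ref, alt
    repeats: dict[str, str]
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit genome FASTA, exon BED, SNP TSV, repeat FASTA and truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "exons": outdir / "exons.bed",
            "snps": outdir / "snps.tsv",
            "repeats": outdir / "repeats.fa",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.genome, paths["genome"])
        self.exons.to_csv(paths["exons"], sep="\t", header=False, index=False)
        self.snp_table.to_csv(paths["snps"], sep="\t", header=False, index=False)
        write_fasta(self.repeats, paths["repeats"])
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2, default=str)
        return paths


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=probs)


def _to_str(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def simulate_reference(spec: SimulationSpec) -> SyntheticReference:
    """Generate a genome with planted restriction sites, SNPs, duplications
    and repeat elements, plus exon/ROI definitions and a truth manifest."""
    streams = np.random.SeedSequence(spec.seed).spawn(6)
    rng_seq, rng_site, rng_snp, rng_dup, rng_rep, rng_exon = (
        np.random.default_rng(s) for s in streams
    )
    codes = _random_seq(rng_seq, spec.genome_length, spec.gc)
    truth: dict = {"seed": spec.seed, "chrom": spec.chrom}

    planted_sites: dict[str, list[int]] = {}
    for recognition, spacing in spec.site_spacing.items():
        site_codes = np.array([BASES.index(b) for b in recognition])
        positions = list(range(spacing, spec.genome_length - 4, spacing))
        for pos in positions:
            codes[pos : pos + 4] = site_codes
        planted_sites[recognition] = positions
    truth["planted_sites"] = planted_sites

    repeats: dict[str, str] = {}
    planted_repeats: list[dict] = []
    for r in range(spec.n_repeats):
        rep = _random_seq(rng_rep, spec.repeat_length, spec.gc)
        name = f"REP{r + 1}"
        repeats[name] = _to_str(rep)
        for _ in range(spec.repeat_copies):
            start = int(rng_rep.integers(0, spec.genome_length - spec.repeat_length))
            codes[start : start + spec.repeat_length] = rep
            planted_repeats.append({"name": name, "start": start,
                                    "end": start + spec.repeat_length})
    truth["planted_repeats"] = planted_repeats

    planted_dups: list[dict] = []
    for block_len, n_copies in spec.duplications:
        src = int(rng_dup.integers(0, spec.genome_length - block_len))
        block = codes[src : src + block_len].copy()
        for _ in range(n_copies):
            dst = int(rng_dup.integers(0, spec.genome_length - block_len))
            codes[dst : dst + block_len] = block
            planted_dups.append({"src": src, "dst": dst, "length": block_len})
    truth["planted_duplications"] = planted_dups

    # non-overlapping exons spread over the genome, round-robin genes
    exon_rows = []
    if spec.n_exons:
        slot = spec.genome_length // (spec.n_exons + 1)
        for i in range(spec.n_exons):
            start = slot * (i + 1)
            jitter = int(rng_exon.integers(0, max(1, slot - spec.exon_length - 2 * spec.pad)))
            start = min(start + jitter, spec.genome_length - spec.exon_length - spec.pad)
            gene = f"GENE{(i % spec.genes) + 1}"
            exon_rows.append((spec.chrom, start, start + spec.exon_length, gene))
    exons = pd.DataFrame(exon_rows, columns=["chrom", "start", "end", "gene"])
    truth["exons"] = exon_rows

    snp_positions = sorted(
        int(p) for p in rng_snp.choice(spec.genome_length, size=spec.n_snps, replace=False)
    ) if spec.n_snps else []
    snp_rows = []
    for pos in snp_positions:
        ref = BASES[codes[pos]]
        alt = rng_snp.choice([b for b in BASES if b != ref])
        snp_rows.append((spec.chrom, pos, ref, alt))
    snp_table = pd.DataFrame(snp_rows, columns=["chrom", "pos0", "ref", "alt"])
    truth["snps"] = snp_rows

    genome = {spec.chrom: _to_str(codes)}
    return SyntheticReference(
        genome=genome,
        exons=exons,
        snps=SNPTrack((spec.chrom, pos) for pos in snp_positions),
        snp_table=snp_table,
        repeats=repeats,
        truth=truth,
    )


def _genotype_probs(
    genotypes: Sequence[tuple[str, ...] | str], error_matrix: ErrorMatrix
) -> np.ndarray:
    """Per-position observation distribution: hom = P row, het = equal mixture."""
    P = error_matrix.p
    probs = np.empty((len(genotypes), 4))
    for i, gt in enumerate(genotypes):
        alleles = tuple(gt) if not isinstance(gt, str) else tuple(gt)
        rows = [P[BASES.index(al)] for al in alleles]
        probs[i] = np.mean(rows, axis=0)
    return probs


def _multinomial_rows(
    rng: np.random.Generator, depths: np.ndarray, probs: np.ndarray
) -> np.ndarray:
    """Row-wise multinomial draws with per-row depth and probabilities."""
    out = np.zeros((len(depths), 4), dtype=np.int64)
    uniq = np.unique(depths)
    for depth in uniq:
        idx = np.flatnonzero(depths == depth)
        if depth == 0:
            continue
        out[idx] = rng.multinomial(int(depth), probs[idx])
    return out


def simulate_pileup(
    genotypes: Sequence[tuple[str, ...] | str],
    depths: int | Sequence[int],
    error_matrix: ErrorMatrix | None = None,
    seed: int = 0,
    interval: GenomicInterval | None = None,
) -> StrandedPileup:
    """Stranded pileup drawn from a genotype + per-base error model.

    ``genotypes``: per position a 1-allele (hom) or 2-allele (het) tuple or
    string, e.g. "A" or ("A", "G"). ``depths``: per-strand depth, scalar
    or per-position. Counts on each strand are independent multinomials.
    """
    error_matrix = error_matrix or ErrorMatrix.uniform(DEFAULT_ERROR_RATE)
    L = len(genotypes)
    interval = interval or GenomicInterval("chrS", 0, L)
    if len(interval) != L:
        raise ValueError("interval length must match genotype count")
    depths_arr = np.full(L, depths, dtype=np.int64) if np.isscalar(depths) else np.asarray(depths, dtype=np.int64)
    probs = _genotype_probs(genotypes, error_matrix)
    s_fwd, s_rev = np.random.SeedSequence(seed).spawn(2)
    fwd = _multinomial_rows(np.random.default_rng(s_fwd), depths_arr, probs)
    rev = _multinomial_rows(np.random.default_rng(s_rev), depths_arr, probs)
    return StrandedPileup(interval, fwd, rev)


def simulate_matched_pair(
    normal_genotypes: Sequence[tuple[str, ...] | str],
    somatic_spec: Mapping[int, tuple[str, float]],
    depths: int | Sequence[int],
    error_matrix: ErrorMatrix | None = None,
    seed: int = 0,
    loh_spec: Mapping[int, float] | None = None,
    interval: GenomicInterval | None = None,
) -> tuple[StrandedPileup, StrandedPileup, pd.DataFrame]:
    """Matched normal/tumor pileups with planted somatic variants and LOH.

    ``somatic_spec``: position -> (variant base, tumor fraction); tumor
    base-call distribution at such positions is the (1-f)/f mixture of the
    normal genotype's distribution and the variant row. ``loh_spec``:
    position -> tumor fraction of the FIRST allele of the normal het
    genotype (0.5 = balanced). Returns (normal, tumor, truth table).
    """
    error_matrix = error_matrix or ErrorMatrix.uniform(DEFAULT_ERROR_RATE)
    P = error_matrix.p
    L = len(normal_genotypes)
    interval = interval or GenomicInterval("chrS", 0, L)
    depths_arr = np.full(L, depths, dtype=np.int64) if np.isscalar(depths) else np.asarray(depths, dtype=np.int64)
    normal_probs = _genotype_probs(normal_genotypes, error_matrix)
    tumor_probs = normal_probs.copy()
    truth_rows = []
    offset = interval.start
    for pos, (alt, fraction) in somatic_spec.items():
        i = pos - offset
        tumor_probs[i] = (1 - fraction) * normal_probs[i] + fraction * P[BASES.index(alt)]
        truth_rows.append({"pos0": pos, "kind": "somatic", "alt": alt, "fraction": fraction})
    for pos, fraction in (loh_spec or {}).items():
        i = pos - offset
        alleles = tuple(normal_genotypes[i])
        if len(alleles) != 2:
            raise ValueError(f"LOH site {pos} must be heterozygous in the normal")
        x, y = alleles
        tumor_probs[i] = fraction * P[BASES.index(x)] + (1 - fraction) * P[BASES.index(y)]
        truth_rows.append({"pos0": pos, "kind": "loh", "alt": x, "fraction": fraction})
    streams = np.random.SeedSequence(seed).spawn(4)
    rngs = [np.random.default_rng(s) for s in streams]
    normal = StrandedPileup(
        interval,
        _multinomial_rows(rngs[0], depths_arr, normal_probs),
        _multinomial_rows(rngs[1], depths_arr, normal_probs),
    )
    tumor = StrandedPileup(
        interval,
        _multinomial_rows(rngs[2], depths_arr, tumor_probs),
        _multinomial_rows(rngs[3], depths_arr, tumor_probs),
    )
    truth = pd.DataFrame(truth_rows, columns=["pos0", "kind", "alt", "fraction"])
    return normal, tumor, truth


def simulate_barcoded_reads(
    samples: Mapping[str, str],
    n_reads: int,
    per_base_error: float = DEFAULT_ERROR_RATE,
    dual: bool = False,
    seed: int = 0,
) -> list[BarcodedRead]:
    """Barcoded reads with per-base barcode miscalls and known truth.

    ``samples``: barcode base -> sample name (e.g. {"A": "s1", ...}).
    Reads are assigned to samples uniformly; each barcode base is misread
    with probability ``per_base_error``, uniformly into the other three
    bases. In dual mode both mates carry the sample's barcode,
    independently corrupted.
    """
    if not 0.0 <= per_base_error < 1.0:
        raise ValueError("per_base_error must be in [0, 1)")
    barcodes = list(samples)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    true_idx = rng.integers(0, len(barcodes), size=n_reads)

    def corrupt(idx: np.ndarray) -> list[str]:
        bases = [barcodes[i] for i in idx]
        flip = rng.random(n_reads) < per_base_error
        out = []
        for base, f in zip(bases, flip):
            if f:
                alternatives = [b for b in BASES if b != base]
                out.append(alternatives[int(rng.integers(0, 3))])
            else:
                out.append(base)
        return out

    bc1 = corrupt(true_idx)
    bc2 = corrupt(true_idx) if dual else [None] * n_reads
    return [
        BarcodedRead(
            name=f"read{i}",
            barcode=bc1[i],
            barcode2=bc2[i],
            true_sample=samples[barcodes[true_idx[i]]],
        )
        for i in range(n_reads)
    ]
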