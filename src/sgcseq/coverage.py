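"""Fold-coverage analysis and the three-tier concentration adjustment.

Capture yield varies widely between oligos. Measuring the mean per-base
fold-coverage (FC) over each amplicon sorts oligos into performance tiers,
and re-pooling concentrations by tier (10x more for low yield, 10x less
for high yield) narrows the coverage distribution:

=========  ===============  =============
tier       mean amplicon FC concentration
=========  ===============  =============
high       > 1000           5 pM
medium     100 - 1000       50 pM
low        < 100            500 pM
=========  ===============  =============

Boundary values (exactly 100 or 1000) fall in the medium tier. The module
also provides coverage summaries, order-of-magnitude FC distributions,
median-normalized log10 coverage tracks with Pearson correlations across
samples, and mean-FC stratification by amplicon length, arm GC% and flap
size — the covariates that drive capture performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import CaptureOligo
from .pileup import StrandedPileup
from .reference import GenomicInterval

TIER_CONCENTRATION_PM = {"high": 5, "medium": 50, "low": 500}
HIGH_FC = 1000.0
LOW_FC = 100.0


@dataclass(frozen=True)
class ConcentrationTier:
    oligo_id: str
    mean_fc: float
    tier: str
    concentration_pM: int


def amplicon_mean_fc(pileup: StrandedPileup, amplicon: GenomicInterval) -> float:
    """Arithmetic mean of total (fwd+rev) depth over the amplicon bases."""
    sub = pileup.subset(amplicon)
    return float(sub.depth.mean())


def assign_tier(mean_fc: float, oligo_id: str = "") -> ConcentrationTier:
    """Tier and adjusted concentration for one oligo's mean fold-coverage."""
    if mean_fc < 0:
        raise ValueError("mean fold-coverage must be non-negative")
    if mean_fc > HIGH_FC:
        tier = "high"
    elif mean_fc >= LOW_FC:
        tier = "medium"
    else:
        tier = "low"
    return ConcentrationTier(oligo_id, float(mean_fc), tier, TIER_CONCENTRATION_PM[tier])


def adjust_panel(
    oligos: Sequence[CaptureOligo], pileup: StrandedPileup
) -> pd.DataFrame:
    """Tier table for a panel: oligo_id, mean_fc, tier, concentration_pM."""
    rows = []
    for o in oligos:
        fc = amplicon_mean_fc(pileup, o.amplicon)
        tier = assign_tier(fc, o.oligo_id)
        rows.append(
            {
                "oligo_id": tier.oligo_id,
                "mean_fc": tier.mean_fc,
                "tier": tier.tier,
                "concentration_pM": tier.concentration_pM,
            }
        )
    return pd.DataFrame(rows)


def coverage_summary(
    pileups: Sequence[StrandedPileup],
    targets: Sequence[GenomicInterval],
    off_target_bases: int = 0,
) -> dict[str, float]:
    """Assay-level coverage summary over target bases.

    Returns median FC, the percentage of target bases with FC >= 10, the
    percentage above half the median, and the off-target percentage
    (mapped bases outside targets over all mapped bases). ``off_target_bases``
    supplies the outside-target mapped-base count, which pileups restricted
    to targets cannot see.
    """
    if not targets:
        raise ValueError("no targets supplied")
    depths = []
    for target in targets:
        for p in pileups:
            seg = p.interval.intersect(target)
            if seg is not None:
                depths.append(p.subset(seg).depth)
    if not depths:
        raise ValueError("pileups do not overlap any target")
    depth = np.concatenate(depths)
    median = float(np.median(depth))
    on_target_bases = int(depth.sum())
    total = on_target_bases + off_target_bases
    return {
        "median_fc": median,
        "pct_fc_ge_10": 100.0 * float((depth >= 10).mean()),
        "pct_above_half_median": 100.0 * float((depth > median / 2).mean()),
        "pct_off_target": 100.0 * off_target_bases / total if total else 0.0,
    }


def fc_distribution(mean_fcs: Sequence[float], n_decades: int = 5) -> pd.DataFrame:
    """Proportion of entries per order-of-magnitude FC bin.

    Bins: [0, 1), [1, 10), [10, 100), ... with the last bin open-ended.
    """
    fcs = np.asarray(mean_fcs, dtype=float)
    if fcs.size == 0:
        raise ValueError("empty fold-coverage input")
    edges = [0.0] + [10.0**k for k in range(n_decades)] + [np.inf]
    counts, _ = np.histogram(fcs, bins=edges)
    labels = ["<1"] + [
        f"{int(edges[i])}-{int(edges[i + 1]) - 1}" for i in range(1, n_decades)
    ] + [f">={int(edges[n_decades])}"]
    return pd.DataFrame(
        {"bin": labels, "proportion": counts / fcs.size, "count": counts}
    )


def normalize_logfc(
    depth: np.ndarray, zero_floor: float | None = None
) -> np.ndarray:
    """log10 of each position's depth over the sample median depth.

    Zero-depth positions map to a finite floor (default log10(0.5/median))
    so downstream correlations stay computable. Invariant under rescaling
    all depths by a constant.
    """
    depth = np.asarray(depth, dtype=float)
    median = float(np.median(depth))
    if median <= 0:
        raise ValueError("sample median depth must be positive")
    if zero_floor is None:
        zero_floor = float(np.log10(0.5 / median))
    out = np.full(depth.shape, zero_floor, dtype=float)
    nz = depth > 0
    out[nz] = np.log10(depth[nz] / median)
    return out


def pairwise_correlation(tracks: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Pearson correlation matrix between normalized coverage tracks."""
    names = list(tracks)
    if len(names) < 2:
        raise ValueError("need at least two tracks")
    mat = np.vstack([np.asarray(tracks[n], dtype=float) for n in names])
    corr = np.corrcoef(mat)
    return pd.DataFrame(corr, index=names, columns=names)


def _length_bin(length: int) -> str:
    if length < 200:
        return "<200"
    if length <= 600:
        return "200-600"
    if length <= 800:
        return "601-800"
    return ">800"


def _gc_bin(gc_percent: float) -> str:
    return "<75%" if gc_percent < 75.0 else ">=75%"


def _flap_bin(flap: int) -> str:
    if flap == 0:
        return "none"
    return "short" if flap <= 100 else "long"


def performance_covariates(
    oligos: Sequence[CaptureOligo], mean_fcs: Mapping[str, float]
) -> pd.DataFrame:
    """Mean FC stratified by amplicon length, arm GC% and flap size.

    Long-format table: covariate, stratum, n, mean_fc. Strata with no
    oligos are simply absent. GC binning uses < 75% vs >= 75%; flap size
    uses the larger of the two flaps (0 = none, <= 100 short, > 100 long).
    """
    records = []
    for o in oligos:
        if o.oligo_id not in mean_fcs:
            continue
        fc = mean_fcs[o.oligo_id]
        records.append(
            {
                "length": _length_bin(len(o.amplicon)),
                "gc": _gc_bin(o.arm_gc_percent()),
                "flap": _flap_bin(max(o.flap5, o.flap3)),
                "fc": fc,
            }
        )
    if not records:
        raise ValueError("no oligos with fold-coverage measurements")
    df = pd.DataFrame(records)
    out = []
    for covariate in ("length", "gc", "flap"):
        grouped = df.groupby(covariate)["fc"].agg(["size", "mean"])
        for stratum, row in grouped.iterrows():
            out.append(
                {
                    "covariate": covariate,
                    "stratum": stratum,
                    "n": int(row["size"]),
                    "mean_fc": float(row["mean"]),
                }
            )
    return pd.DataFrame(out)
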