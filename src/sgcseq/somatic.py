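"""Somatic mutation detection in matched tumor/normal pairs.

For a fixed position let ``a`` be the most frequent base in the normal and
``b`` the highest-count base other than ``a`` in the tumor. The statistic

    D = n_b(tumor) / N_tumor  -  n_b(normal) / N_normal

is the difference in the fractional representation of the candidate
variant base. At a shared homozygous position |D| is small; at a somatic
hom-to-het change D is a large positive fraction. The standard error is
the two-proportion construction

    SE = sqrt( p_t (1 - p_t) / N_t  +  p_n (1 - p_n) / N_n )

and with sufficient depth D is approximately t-distributed, giving a
1 - alpha confidence interval D +/- t_{1-alpha/2, df} * SE, with
Welch-Satterthwaite degrees of freedom by default (a pooled
``N_t + N_n - 2`` alternative is available). A position is reported when,
independently on BOTH strands, D > 0 with the CI lower bound above the
minimum acceptable change D0, or D < 0 with the CI upper bound below -D0
(double-strand confirmation). Hom-to-het gains are what D detects;
het-to-hom shifts (loss of heterozygosity) are found separately by
isolating normal heterozygous positions and testing the tumor's
allele-count imbalance with the same machinery.

The SE construction, the t degrees of freedom and the default alpha = 0.05
and D0 = 0.10 are this package's reconstruction of the method — the
standard two-proportion choices consistent with its description — and are
all configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .pileup import BASES, StrandedPileup


@dataclass
class SomaticConfig:
    alpha: float = 0.05
    d0: float = 0.10
    min_depth: int = 10                  # per sample per strand
    df_method: str = "welch"             # "welch" or "pooled"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.d0 < 1.0:
            raise ValueError("d0 must be in (0, 1)")
        if self.df_method not in {"welch", "pooled"}:
            raise ValueError("df_method must be 'welch' or 'pooled'")


@dataclass(frozen=True)
class SomaticCall:
    position: int
    a: str                       # most frequent base in normal
    b: str                       # candidate variant base (tumor)
    d: float                     # combined-strand D
    se: float
    ci: tuple[float, float]
    d_fwd: float
    d_rev: float
    tumor_fraction: float        # fraction of tumor reads carrying b
    normal_fraction: float
    passes: bool


def _top_base(counts: np.ndarray) -> np.ndarray:
    return np.argsort(-counts, axis=-1, kind="stable")[..., 0]


def _variant_base(tumor: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Highest-count tumor base excluding ``a``; ties by base order."""
    masked = tumor.astype(float).copy()
    np.put_along_axis(masked, a[..., None], -1.0, axis=-1)
    return np.argsort(-masked, axis=-1, kind="stable")[..., 0]


def somatic_d(
    normal_counts: Sequence[int] | np.ndarray,
    tumor_counts: Sequence[int] | np.ndarray,
) -> tuple[str, str, float]:
    """(a, b, D) for one position's combined counts.

    Raises on zero depth in either sample (no data).
    """
    n = np.asarray(normal_counts, dtype=np.int64)
    t = np.asarray(tumor_counts, dtype=np.int64)
    if n.shape != (4,) or t.shape != (4,):
        raise ValueError("counts must be length-4 vectors")
    if n.sum() == 0 or t.sum() == 0:
        raise ValueError("zero depth in one sample: no data")
    a = int(_top_base(n[None, :])[0])
    b = int(_variant_base(t[None, :], np.array([a]))[0])
    d = t[b] / t.sum() - n[b] / n.sum()
    return BASES[a], BASES[b], float(d)


def _se_and_df(
    p_t: float, n_t: int, p_n: float, n_n: int, df_method: str
) -> tuple[float, float]:
    v_t = p_t * (1.0 - p_t) / n_t
    v_n = p_n * (1.0 - p_n) / n_n
    se = float(np.sqrt(v_t + v_n))
    if df_method == "pooled":
        return se, float(n_t + n_n - 2)
    num = (v_t + v_n) ** 2
    den = v_t**2 / max(n_t - 1, 1) + v_n**2 / max(n_n - 1, 1)
    df = num / den if den > 0 else float(n_t + n_n - 2)
    return se, float(df)


def somatic_ci(
    normal_counts: Sequence[int] | np.ndarray,
    tumor_counts: Sequence[int] | np.ndarray,
    alpha: float = 0.05,
    df_method: str = "welch",
) -> tuple[float, float, float]:
    """(SE, lower, upper) of the t-based 1 - alpha confidence interval for D."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    n = np.asarray(normal_counts, dtype=np.int64)
    t = np.asarray(tumor_counts, dtype=np.int64)
    if n.sum() < 2 or t.sum() < 2:
        raise ValueError("need depth >= 2 in both samples")
    _, b, d = somatic_d(n, t)
    bi = BASES.index(b)
    p_t, p_n = t[bi] / t.sum(), n[bi] / n.sum()
    se, df = _se_and_df(p_t, int(t.sum()), p_n, int(n.sum()), df_method)
    tq = float(stats.t.ppf(1.0 - alpha / 2.0, df)) if se > 0 else 0.0
    return se, d - tq * se, d + tq * se


def _strand_stats(
    normal: np.ndarray,
    tumor: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    config: SomaticConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(D, CI lower, CI upper) arrays for one strand, NaN where depth is short."""
    n_n = normal.sum(axis=1)
    n_t = tumor.sum(axis=1)
    nb_n = np.take_along_axis(normal, b[:, None], axis=1)[:, 0]
    nb_t = np.take_along_axis(tumor, b[:, None], axis=1)[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        p_n = np.where(n_n > 0, nb_n / np.maximum(n_n, 1), np.nan)
        p_t = np.where(n_t > 0, nb_t / np.maximum(n_t, 1), np.nan)
        d = p_t - p_n
        v_n = p_n * (1 - p_n) / np.maximum(n_n, 1)
        v_t = p_t * (1 - p_t) / np.maximum(n_t, 1)
        se = np.sqrt(v_t + v_n)
        if config.df_method == "pooled":
            df = (n_t + n_n - 2).astype(float)
        else:
            den = v_t**2 / np.maximum(n_t - 1, 1) + v_n**2 / np.maximum(n_n - 1, 1)
            df = np.where(den > 0, (v_t + v_n) ** 2 / np.where(den > 0, den, 1.0),
                          (n_t + n_n - 2).astype(float))
        tq = stats.t.ppf(1.0 - config.alpha / 2.0, np.maximum(df, 1.0))
        lo = d - tq * se
        hi = d + tq * se
    short = (n_n < config.min_depth) | (n_t < config.min_depth)
    d = np.where(short, np.nan, d)
    return d, np.where(short, np.nan, lo), np.where(short, np.nan, hi)


def call_somatic(
    normal: StrandedPileup,
    tumor: StrandedPileup,
    mask: np.ndarray | None = None,
    config: SomaticConfig | None = None,
) -> list[SomaticCall]:
    """Double-strand confirmed somatic variant calls over matched pileups.

    A position passes when on BOTH strands independently (D > 0 and CI
    lower > D0) or (D < 0 and CI upper < -D0); repeat-masked positions are
    suppressed. All evaluated candidate positions with a nonzero tumor
    variant base are returned with ``passes`` set accordingly.
    """
    config = config or SomaticConfig()
    if normal.interval != tumor.interval:
        raise ValueError("normal and tumor pileups must cover the same interval")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (len(normal),):
            raise ValueError("mask length must match pileup interval")
    n_tot, t_tot = normal.total, tumor.total
    a = _top_base(n_tot)
    b = _variant_base(t_tot, a)
    nb_t = np.take_along_axis(t_tot, b[:, None], axis=1)[:, 0]
    depth_n, depth_t = n_tot.sum(axis=1), t_tot.sum(axis=1)
    evaluable = (nb_t > 0) & (depth_n > 0) & (depth_t > 0)
    if mask is not None:
        evaluable &= ~mask
    d0 = config.d0
    d_f, lo_f, hi_f = _strand_stats(normal.fwd, tumor.fwd, a, b, config)
    d_r, lo_r, hi_r = _strand_stats(normal.rev, tumor.rev, a, b, config)
    with np.errstate(invalid="ignore"):
        pass_f = ((d_f > 0) & (lo_f > d0)) | ((d_f < 0) & (hi_f < -d0))
        pass_r = ((d_r > 0) & (lo_r > d0)) | ((d_r < 0) & (hi_r < -d0))
    passes = pass_f & pass_r & evaluable
    calls: list[SomaticCall] = []
    for i in np.flatnonzero(evaluable):
        nc, tc = n_tot[i], t_tot[i]
        try:
            se, lo, hi = somatic_ci(nc, tc, config.alpha, config.df_method)
        except ValueError:
            continue
        _, _, d = somatic_d(nc, tc)
        calls.append(
            SomaticCall(
                position=int(normal.interval.start + i),
                a=BASES[a[i]],
                b=BASES[b[i]],
                d=d,
                se=se,
                ci=(lo, hi),
                d_fwd=float(d_f[i]),
                d_rev=float(d_r[i]),
                tumor_fraction=float(tc[b[i]] / depth_t[i]),
                normal_fraction=float(nc[b[i]] / depth_n[i]),
                passes=bool(passes[i]),
            )
        )
    return calls


@dataclass(frozen=True)
class LOHCall:
    position: int
    allele_x: str
    allele_y: str
    tumor_imbalance: float       # tumor fraction of allele x minus 0.5
    se: float
    ci: tuple[float, float]
    passes: bool


def detect_loh(
    normal: StrandedPileup,
    tumor: StrandedPileup,
    het_positions: Sequence[tuple[int, str, str]],
    config: SomaticConfig | None = None,
    margin: float = 0.10,
) -> list[LOHCall]:
    """Loss-of-heterozygosity detection at known normal-het positions.

    ``het_positions``: (position, allele_x, allele_y) triples, typically
    from the SNV caller run on the normal. For each site the tumor
    allele-fraction imbalance d = n_x / (n_x + n_y) - 0.5 is tested with a
    one-sample binomial SE and t-based CI; a site is reported as LOH when
    the CI excludes zero beyond ``margin``. Zero tumor coverage at a site
    yields no call for it.
    """
    config = config or SomaticConfig()
    if normal.interval != tumor.interval:
        raise ValueError("normal and tumor pileups must cover the same interval")
    calls: list[LOHCall] = []
    t_tot = tumor.total
    for pos, ax, ay in het_positions:
        i = pos - normal.interval.start
        if not 0 <= i < len(normal):
            raise ValueError(f"het position {pos} outside pileup interval")
        nx = int(t_tot[i, BASES.index(ax)])
        ny = int(t_tot[i, BASES.index(ay)])
        n = nx + ny
        if n == 0:
            continue
        p = nx / n
        d = p - 0.5
        se = float(np.sqrt(p * (1 - p) / n)) if n > 1 else float("nan")
        if n > 1 and se > 0:
            tq = float(stats.t.ppf(1.0 - config.alpha / 2.0, n - 1))
            lo, hi = d - tq * se, d + tq * se
        else:
            lo, hi = d, d
        passes = bool(n >= config.min_depth and ((lo > margin) or (hi < -margin)))
        calls.append(LOHCall(pos, ax, ay, d, se, (lo, hi), passes))
    return calls
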