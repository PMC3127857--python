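"""Minimal VCF 4.2 output for SNV and somatic calls.

Internally the pipeline reasons in 0-based half-open coordinates and base
count matrices; VCF (1-based) is emitted only at the output boundary for
interoperability.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .snv import SNVCall
from .somatic import SomaticCall

_SNV_HEADER = """\
##fileformat=VCFv4.2
##source=sgcseq
##INFO=<ID=LLRF,Number=1,Type=Float,Description="Forward-strand log likelihood ratio">
##INFO=<ID=LLRR,Number=1,Type=Float,Description="Reverse-strand log likelihood ratio">
##INFO=<ID=MASKED,Number=0,Type=Flag,Description="Position repeat-masked">
##INFO=<ID=AF2,Number=1,Type=Float,Description="Second-allele fraction">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""

_SOMATIC_HEADER = """\
##fileformat=VCFv4.2
##source=sgcseq
##somatic_model=two-proportion D statistic with t-based CI (reconstruction; alpha and D0 configurable)
##INFO=<ID=D,Number=1,Type=Float,Description="Tumor minus normal variant-base fraction">
##INFO=<ID=SE,Number=1,Type=Float,Description="Standard error of D">
##INFO=<ID=CI_LO,Number=1,Type=Float,Description="CI lower bound">
##INFO=<ID=CI_HI,Number=1,Type=Float,Description="CI upper bound">
##INFO=<ID=DF,Number=1,Type=Float,Description="Forward-strand D">
##INFO=<ID=DR,Number=1,Type=Float,Description="Reverse-strand D">
##INFO=<ID=TF,Number=1,Type=Float,Description="Tumor variant fraction">
##INFO=<ID=NF,Number=1,Type=Float,Description="Normal variant fraction">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_snv_vcf(
    calls: Sequence[SNVCall],
    chrom: str,
    reference: Mapping[str, str],
    path,
) -> None:
    seq = reference[chrom]
    with open(path, "w") as fh:
        fh.write(_SNV_HEADER)
        for c in sorted(calls, key=lambda c: c.position):
            ref = seq[c.position]
            alt = c.b2 if c.b1 == ref else c.b1
            info = f"LLRF={c.llr_fwd:.3f};LLRR={c.llr_rev:.3f};AF2={c.second_fraction:.4f}"
            if c.masked:
                info += ";MASKED"
            fh.write(
                f"{chrom}\t{c.position + 1}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n"
            )


def write_somatic_vcf(
    calls: Sequence[SomaticCall],
    chrom: str,
    reference: Mapping[str, str],
    path,
    passing_only: bool = True,
) -> None:
    seq = reference[chrom]
    with open(path, "w") as fh:
        fh.write(_SOMATIC_HEADER)
        for c in sorted(calls, key=lambda c: c.position):
            if passing_only and not c.passes:
                continue
            ref = seq[c.position]
            info = (
                f"D={c.d:.4f};SE={c.se:.4f};CI_LO={c.ci[0]:.4f};CI_HI={c.ci[1]:.4f};"
                f"DF={c.d_fwd:.4f};DR={c.d_rev:.4f};"
                f"TF={c.tumor_fraction:.4f};NF={c.normal_fraction:.4f}"
            )
            flt = "PASS" if c.passes else "lowD"
            fh.write(f"{chrom}\t{c.position + 1}\t.\t{ref}\t{c.b}\t.\t{flt}\t{info}\n")
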