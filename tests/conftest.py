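"""Shared fixtures: small on-disk format examples and an exact Fisher oracle."""
from __future__ import annotations

from fractions import Fraction
from math import comb

import pytest

from rmscan import GenomicInterval, TEInstance


def exact_fisher_tail(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact rational one-sided tail P(X >= a) for the 2x2 table [[a,b],[c,d]].

    X ~ Hypergeometric(N = a+b+c+d, K = a+c, n = a+b), accumulated with an
    integer term recurrence — independent of any floating-point path.
    """
    N, K, n = a + b + c + d, a + c, a + b
    kmax = min(K, n)
    if a > kmax:
        return Fraction(0)
    term = comb(K, a) * comb(N - K, n - a)
    total = term
    for k in range(a, kmax):
        term = term * (K - k) * (n - k) // ((k + 1) * (N - K - n + k + 1))
        total += term
    return Fraction(total, comb(N, n))


def make_te(chrom: str, start: int, end: int, subfamily: str = "AluYa5",
            divergence: float = 1.0, instance_id: str | None = None,
            human_specific: bool | None = True) -> TEInstance:
    return TEInstance(
        GenomicInterval(chrom, start, end),
        subfamily=subfamily,
        family="Alu",
        divergence=divergence,
        instance_id=instance_id or f"{subfamily}:{chrom}:{start}",
        human_specific=human_specific,
    )


RM_OUT = """\
   SW   perc perc perc  query     position in query            matching          repeat           position in repeat
score   div. del. ins.  sequence  begin end      (left)  repeat  class/family  begin  end    (left)   ID

  463   11.5  0.0  0.0  chr1        101     400 (9600) +  AluYa5     SINE/Alu      1  300    (0)      1
  463    1.2  0.0  0.0  chr1       1001    1310 (8690) C  AluYa5     SINE/Alu      1  310    (0)      2
 1200   20.1  0.2  0.0  chr1       2001    2600 (7400) +  L1PA2      LINE/L1       1  600    (0)      3
  500    2.2  0.0  0.0  chr2        501     800 (9200) +  AluYa5     SINE/Alu      1  300    (0)      4
 1100   18.9  0.1  0.0  chr2       3001    3700 (6300) C  L1PA2      LINE/L1       1  700    (0)      5
"""


@pytest.fixture
def rm_out_file(tmp_path):
    path = tmp_path / "annotation.out"
    path.write_text(RM_OUT)
    return path


VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000000>
##INFO=<ID=END,Number=1,Type=Integer,Description="End position">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=SVLEN,Number=.,Type=Integer,Description="SV length">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
chr1\t1000\tdel1\t{ref}\tA\t.\tPASS\t.
chr1\t5000\tins1\tA\t{ins}\t.\tPASS\t.
chr1\t8000\tdel2\tA\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=8350
"""


@pytest.fixture
def vcf_file(tmp_path):
    ref = "A" + "C" * 300  # 301 bp REF, 1 bp ALT -> 300 bp deletion
    ins = "A" + "G" * 80
    path = tmp_path / "calls.vcf"
    path.write_text(VCF.format(ref=ref, ins=ins))
    return path


@pytest.fixture
def bed_file(tmp_path):
    path = tmp_path / "calls.bed"
    path.write_text("chr1\t1000\t1400\nchr2\t50\t120\n")
    return path
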