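"""Nei–Gojobori (1986) pairwise dN/dS with Jukes–Cantor correction.

Site counting enumerates the nine single-nucleotide neighbours of each
codon; a change is synonymous when the encoded amino acid is unchanged.
Changes that would create a stop codon are counted as nonsynonymous, so
S + N = 3 × (number of codons) holds exactly.  Observed differences in
multi-hit codons are averaged over the minimal mutational pathways; pathways
passing through a stop codon are excluded unless no stop-free pathway
exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import log

from .genetic_code import INVERTEBRATE_MITO, GeneticCode, get_genetic_code

NUCLEOTIDES = "ACGT"


@dataclass
class DnDsEstimate:
    S: float  # synonymous sites (averaged over the two sequences)
    N: float  # nonsynonymous sites
    Sd: float  # observed synonymous differences
    Nd: float
    pS: float | None
    pN: float | None
    dS: float | None  # None when p >= 3/4 (JC correction undefined)
    dN: float | None
    omega: float | None  # None when dS is 0 or undefined


def _syn_fraction(codon: str, code: GeneticCode) -> float:
    """Number of synonymous sites in a codon (0..3)."""
    aa = code.forward[codon]
    syn = 0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if code.forward[alt] == aa and aa != "*":
                syn += 1
    return syn / 3.0


def _pathway_counts(a: str, b: str, code: GeneticCode) -> tuple:
    """(syn, nonsyn) differences between two codons, pathway-averaged."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in permutations(diff):
        cur = a
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if code.forward[cur] == code.forward[nxt] and code.forward[cur] != "*":
                sd += 1
            else:
                nd += 1
            if code.forward[nxt] == "*":
                through_stop = True
            cur = nxt
        results.append((through_stop, sd, nd))
    valid = [r for r in results if not r[0]] or results
    sd = sum(r[1] for r in valid) / len(valid)
    nd = sum(r[2] for r in valid) / len(valid)
    return sd, nd


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def ng86_pairwise(
    seq_a: str, seq_b: str, code_id: int = INVERTEBRATE_MITO
) -> DnDsEstimate:
    """NG86 dN, dS and omega for a pair of in-frame sequences.

    Codons containing gaps or N in either sequence are skipped entirely.
    """
    code = get_genetic_code(code_id)
    a = seq_a.upper().replace("U", "T")
    b = seq_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) % 3:
        raise ValueError(f"length {len(a)} not divisible by 3")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if not (set(ca) <= set(NUCLEOTIDES) and set(cb) <= set(NUCLEOTIDES)):
            continue
        if code.forward[ca] == "*" or code.forward[cb] == "*":
            raise ValueError(f"stop codon at codon {i // 3 + 1}")
        s = (_syn_fraction(ca, code) + _syn_fraction(cb, code)) / 2.0
        S += s
        N += 3.0 - s
        sd, nd = _pathway_counts(ca, cb, code)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else None
    pN = Nd / N if N > 0 else None
    dS = _jc_correct(pS) if pS is not None else None
    dN = _jc_correct(pN) if pN is not None else None
    omega = None
    if dS is not None and dN is not None and dS > 0:
        omega = dN / dS
    return DnDsEstimate(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, dS=dS, dN=dN, omega=omega)
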