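"""Base composition, strand skews, and the protein-coding summary.

AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C); both are signed and
undefined (``None``) when the denominator is zero.  N bases are excluded from
all counts and from percentage denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genetic_code import INVERTEBRATE_MITO, get_genetic_code
from .mito_io import GeneFeature, Mitogenome


@dataclass
class CompositionStats:
    a: int
    c: int
    g: int
    t: int
    at_percent: float
    gc_percent: float
    at_skew: float | None
    gc_skew: float | None

    def rounded(self) -> dict:
        """Report-precision view: percentages to 2 dp, skews to 3 dp."""
        rnd = lambda x, k: None if x is None else round(x, k)
        return {
            "AT%": rnd(self.at_percent, 2),
            "GC%": rnd(self.gc_percent, 2),
            "AT-skew": rnd(self.at_skew, 3),
            "GC-skew": rnd(self.gc_skew, 3),
        }


def base_composition(seq: str) -> CompositionStats:
    """Composition and skews of a DNA sequence (N excluded from counts)."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    a, c, g, t = (seq.count(b) for b in "ACGT")
    non_n = a + c + g + t
    if non_n == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return CompositionStats(
        a=a,
        c=c,
        g=g,
        t=t,
        at_percent=100.0 * (a + t) / non_n,
        gc_percent=100.0 * (g + c) / non_n,
        at_skew=(a - t) / (a + t) if a + t else None,
        gc_skew=(g - c) / (g + c) if g + c else None,
    )


@dataclass
class GeneCodonInfo:
    name: str
    length: int
    start_codon: str
    stop_codon: str  # "TAA"/"TAG"/... or incomplete "T"/"TA"
    incomplete_stop: bool
    internal_stop: bool  # in-frame premature stop flagged, not fatal


@dataclass
class CodingSummary:
    genome_id: str
    total_pcg_length: int
    pcg_fraction: float  # percent of genome
    genes: list


def coding_summary(g: Mitogenome, code_id: int = INVERTEBRATE_MITO) -> CodingSummary:
    """Start/stop codon table and protein-coding fraction of a genome.

    An incomplete stop ("T" or "TA") is asserted only when the gene length
    mod 3 is 1 or 2 *and* the next annotated feature begins within 2 nt
    downstream — completion by polyadenylation requires an abutting gene.
    """
    code = get_genetic_code(code_id)
    pcgs = g.pcgs()
    if not pcgs:
        raise ValueError(f"genome {g.id} has no protein-coding features")
    n = len(g)
    total = sum(f.length(n) for f in pcgs)
    genes = []
    for f in pcgs:
        seq = g.feature_sequence(f)
        start_codon = seq[:3]
        rem = len(seq) % 3
        incomplete = rem in (1, 2) and _abutting_downstream(g, f)
        if incomplete:
            stop = seq[-rem:]
        elif rem == 0:
            stop = seq[-3:]
        else:
            stop = seq[-rem:]  # non-multiple length without abutting gene
        frame = seq[: len(seq) - rem] if rem else seq
        internal = any(
            code.is_stop(frame[i : i + 3]) for i in range(3, len(frame) - 3, 3)
        )
        genes.append(
            GeneCodonInfo(
                name=f.name,
                length=len(seq),
                start_codon=start_codon,
                stop_codon=stop,
                incomplete_stop=incomplete,
                internal_stop=internal,
            )
        )
    return CodingSummary(
        genome_id=g.id,
        total_pcg_length=total,
        pcg_fraction=100.0 * total / n,
        genes=genes,
    )


def _abutting_downstream(g: Mitogenome, f: GeneFeature, slack: int = 2) -> bool:
    """True if another annotated feature starts within ``slack`` nt of f's end."""
    n = len(g)
    end = f.end
    for other in g.features:
        if other is f:
            continue
        gap = (other.start - end) % n if g.circular else other.start - end
        if 0 <= gap <= slack:
            return True
    return False
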