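"""Genetic codes for mitochondrial codon analyses.

Thin wrapper around Biopython's NCBI tables exposing the pieces the codon
machinery needs: the sense-codon list in a fixed order, stop and initiator
sets, and literal translation (initiators are *not* forced to methionine, so
e.g. a GTG-started ORF reads Val — the N-terminal motif matchers accept both).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

NUCS = "TCAG"  # NCBI codon-table ordering

#: Default: invertebrate mitochondrial code (NCBI translation table 5).
INVERTEBRATE_MITO = 5


@dataclass(frozen=True)
class GeneticCode:
    code_id: int
    name: str
    forward: dict  # codon -> amino acid, stops mapped to '*' (all 64 codons)
    stop_codons: frozenset
    start_codons: frozenset
    sense_codons: tuple  # fixed NCBI order, stops excluded

    @property
    def n_sense(self) -> int:
        return len(self.sense_codons)

    def codon_index(self) -> dict:
        return {c: i for i, c in enumerate(self.sense_codons)}

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def translate_codon(self, codon: str) -> str:
        return self.forward[codon]

    def translate(self, seq: str) -> str:
        """Translate an in-frame nucleotide sequence; trailing stop dropped."""
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3:
            raise ValueError(f"sequence length {len(seq)} not divisible by 3")
        aas = []
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            aa = self.forward.get(codon)
            if aa is None:
                raise ValueError(f"untranslatable codon {codon!r} at nt {i}")
            aas.append(aa)
        if aas and aas[-1] == "*":
            aas.pop()
        return "".join(aas)


@lru_cache(maxsize=None)
def get_genetic_code(code_id: int = INVERTEBRATE_MITO) -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[code_id]
    forward = {}
    for c in ("".join(t) for t in product(NUCS, repeat=3)):
        forward[c] = table.forward_table.get(c, "*")
    sense = tuple(c for c in forward if forward[c] != "*")
    return GeneticCode(
        code_id=code_id,
        name=table.names[0],
        forward=forward,
        stop_codons=frozenset(table.stop_codons),
        start_codons=frozenset(table.start_codons),
        sense_codons=sense,
    )
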