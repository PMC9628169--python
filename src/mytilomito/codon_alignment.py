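"""Frame-validated codon alignments bound to a genetic code."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import INVERTEBRATE_MITO, get_genetic_code

log = logging.getLogger(__name__)

#: integer index for a codon containing a gap or ambiguity
MISSING = -1


class AlignmentError(ValueError):
    pass


@dataclass
class CodonAlignment:
    """Aligned coding sequences as a matrix of sense-codon indices.

    ``codons[t, j]`` is the index of taxon *t*'s codon in column *j* within
    the genetic code's sense-codon list, or :data:`MISSING` for codons
    containing a gap or N.
    """

    taxa: list
    codons: np.ndarray  # (n_taxa, n_codons) int16
    code_id: int = INVERTEBRATE_MITO

    @property
    def n_taxa(self) -> int:
        return self.codons.shape[0]

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    def sequences(self) -> dict:
        """Back-translation to codon strings ('---' for missing)."""
        code = get_genetic_code(self.code_id)
        out = {}
        for t, taxon in enumerate(self.taxa):
            parts = [
                code.sense_codons[i] if i >= 0 else "---"
                for i in self.codons[t]
            ]
            out[taxon] = "".join(parts)
        return out

    def drop_incomplete_columns(self) -> tuple:
        """Remove columns with a gap/N in any taxon; returns (clean, n_dropped)."""
        keep = (self.codons >= 0).all(axis=0)
        dropped = int((~keep).sum())
        if dropped:
            log.info(
                "dropped %d/%d codon columns containing gaps or ambiguity",
                dropped,
                self.n_codons,
            )
        return (
            CodonAlignment(list(self.taxa), self.codons[:, keep], self.code_id),
            dropped,
        )


def from_strings(
    seqs: dict, code_id: int = INVERTEBRATE_MITO, strip_final_stop: bool = True
) -> CodonAlignment:
    """Build an alignment from taxon -> nucleotide-string mapping."""
    code = get_genetic_code(code_id)
    index = code.codon_index()
    taxa = list(seqs)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
    (length,) = lengths
    if length % 3:
        raise AlignmentError(f"alignment length {length} not divisible by 3")
    ncod = length // 3
    mat = np.full((len(taxa), ncod), MISSING, dtype=np.int16)
    stop_cols = set()
    for t, taxon in enumerate(taxa):
        s = seqs[taxon].upper().replace("U", "T")
        for j in range(ncod):
            codon = s[3 * j : 3 * j + 3]
            if codon in index:
                mat[t, j] = index[codon]
            elif codon in code.stop_codons:
                if j == ncod - 1:
                    stop_cols.add(j)
                else:
                    raise AlignmentError(
                        f"internal stop codon {codon} in taxon {taxon!r} at "
                        f"codon {j + 1}"
                    )
            elif set(codon) <= set("ACGTN-"):
                pass  # gap or ambiguity -> MISSING
            else:
                raise AlignmentError(
                    f"invalid codon {codon!r} in taxon {taxon!r} at codon {j + 1}"
                )
    if stop_cols:
        if not strip_final_stop:
            raise AlignmentError("terminal stop codons present")
        log.info("stripped terminal stop-codon column")
        mat = mat[:, : ncod - 1]
    return CodonAlignment(taxa, mat, code_id)


def load_codon_alignment(path, code_id: int = INVERTEBRATE_MITO) -> CodonAlignment:
    """Read an aligned FASTA of in-frame coding sequences."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: empty FASTA")
    return from_strings({r.id: str(r.seq) for r in records}, code_id)


def write_codon_alignment(aln: CodonAlignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=taxon, description="")
        for taxon, seq in aln.sequences().items()
    ]
    SeqIO.write(records, str(path), "fasta")
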