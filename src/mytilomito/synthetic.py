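"""Synthetic mitogenomes and codon alignments with known ground truth.

The genome generator emulates the features the analysis relies on: a
circular molecule with the mussel gene roster (13 PCGs + 2 rRNAs + tRNAs,
heavy-strand encoded except trnG), AT-rich composition with negative AT-skew
and positive GC-skew, short intergenic spacers, and — optionally — an
unannotated atp8-like ORF planted in one long spacer: a single hydrophobic
block, a PQ motif at the N-terminus, a positively charged C-terminal tail,
and a length inside the family's band.  The alignment simulator evolves
codons along a tree under GY94 with branch- (and optionally site-) specific
omega, using the same generator matrices as the likelihood code.

Every generator is a pure function of its spec; the seed fully determines
the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_alignment import CodonAlignment
from .codon_model import (
    PhyloTree,
    edge_classes,
    gy94_rate_matrix,
    mean_rate,
    parse_tree,
    spectral,
)
from .genetic_code import INVERTEBRATE_MITO, get_genetic_code
from .mito_io import GeneFeature, Mitogenome

#: composition target: AT ~63%, AT-skew ~ -0.23, GC-skew ~ +0.26
DEFAULT_BASE_FREQS = {"A": 0.2426, "C": 0.1369, "G": 0.2331, "T": 0.3874}

#: (name, kind, length, strand) in circular order; atp8 is deliberately absent
DEFAULT_ROSTER = (
    ("cox1", "PCG", 1536, "+"),
    ("cox2", "PCG", 690, "+"),
    ("trnD", "tRNA", 66, "+"),
    ("atp6", "PCG", 678, "+"),
    ("nad4L", "PCG", 270, "+"),
    ("cox3", "PCG", 780, "+"),
    ("trnG", "tRNA", 66, "-"),
    ("nad3", "PCG", 351, "+"),
    ("nad2", "PCG", 978, "+"),
    ("trnH", "tRNA", 66, "+"),
    ("nad4", "PCG", 1320, "+"),
    ("nad5", "PCG", 1665, "+"),
    ("nad6", "PCG", 474, "+"),
    ("cob", "PCG", 1140, "+"),
    ("nad1", "PCG", 903, "+"),
    ("rrnL", "rRNA", 1250, "+"),
    ("rrnS", "rRNA", 850, "+"),
)

_HYDROPHOBIC = "LIVF"
_HYDROPHILIC = "STNQDEGKRHP"
_LITERAL_START_AA = {"ATG": "M", "GTG": "V", "ATA": "M", "ATT": "I", "ATC": "I", "TTG": "L"}


class SyntheticSpecError(ValueError):
    pass


@dataclass
class SyntheticGenomeSpec:
    seed: int = 0
    roster: tuple = DEFAULT_ROSTER
    spacer_len: int = 30  # ordinary inter-gene spacers (below scan minimum)
    atp8_spacer_len: int = 300  # the long spacer carrying the planted ORF
    plant_atp8: bool = True
    atp8_aa: int = 39  # protein length, inside the 37-139 aa band
    atp8_start_codon: str = "ATG"
    atp8_stop_codon: str = "TAG"
    tm_start: int = 6  # 1-based residue where the hydrophobic block begins
    tm_len: int = 23
    pq_motif: bool = True  # plant MPQL/PQ at the N-terminus
    cterm_positive: int = 3  # R/H/K residues planted in the tail
    base_freqs: dict = field(default_factory=lambda: dict(DEFAULT_BASE_FREQS))
    code_id: int = INVERTEBRATE_MITO


def _sense_codon_freqs(code, base_freqs) -> np.ndarray:
    pi = np.array(
        [
            base_freqs[c[0]] * base_freqs[c[1]] * base_freqs[c[2]]
            for c in code.sense_codons
        ]
    )
    return pi / pi.sum()


def _random_dna(rng, n, base_freqs) -> str:
    bases = "ACGT"
    p = np.array([base_freqs[b] for b in bases])
    return "".join(np.array(list(bases))[rng.choice(4, size=n, p=p / p.sum())])


def _random_pcg(rng, length, code, codon_p) -> str:
    if length % 3:
        raise SyntheticSpecError(f"PCG length {length} not a codon multiple")
    n_codons = length // 3 - 2
    body = rng.choice(code.n_sense, size=n_codons, p=codon_p)
    return "ATG" + "".join(code.sense_codons[i] for i in body) + "TAA"


def design_atp8_protein(spec: SyntheticGenomeSpec, rng) -> str:
    """An amino-acid sequence satisfying the planted diagnostics."""
    L = spec.atp8_aa
    tm0, tm1 = spec.tm_start - 1, spec.tm_start - 1 + spec.tm_len  # 0-based half-open
    if tm0 < 4 or tm1 > L - spec.cterm_positive:
        raise SyntheticSpecError("TM block does not fit inside the protein")
    res = list(rng.choice(list(_HYDROPHILIC), size=L))
    res[0] = _LITERAL_START_AA.get(spec.atp8_start_codon, "M")
    if spec.pq_motif:
        res[1:4] = ["P", "Q", "L"]
    res[tm0:tm1] = rng.choice(list(_HYDROPHOBIC), size=spec.tm_len, p=[0.4, 0.3, 0.25, 0.05])
    tail_pos = rng.choice(np.arange(L - 6, L), size=spec.cterm_positive, replace=False)
    for p in tail_pos:
        res[p] = rng.choice(list("RHK"))
    return "".join(res)


def _encode_protein(protein, start_codon, stop_codon, code, rng) -> str:
    by_aa: dict = {}
    for codon in code.sense_codons:
        by_aa.setdefault(code.forward[codon], []).append(codon)
    codons = [start_codon]
    for aa in protein[1:]:
        codons.append(by_aa[aa][rng.integers(len(by_aa[aa]))])
    codons.append(stop_codon)
    return "".join(codons)


def generate_mitogenome(spec: SyntheticGenomeSpec) -> tuple:
    """Build a genome and its truth table.

    Returns ``(Mitogenome, truth)`` where ``truth`` is a dict with a
    ``features`` DataFrame (the annotated roster) and an ``atp8`` dict with
    the exact planted coordinates (or ``None``).  The planted ORF is
    preceded by an in-frame stop so the most upstream in-band initiator of
    its segment is exactly the planted start codon.
    """
    rng = np.random.default_rng(spec.seed)
    code = get_genetic_code(spec.code_id)
    codon_p = _sense_codon_freqs(code, spec.base_freqs)
    atp8_slot = max(
        (i for i, g in enumerate(spec.roster) if g[0] == "atp6"), default=0
    )
    parts = []
    features = []
    atp8_truth = None
    pos = 0
    for i, (name, kind, length, strand) in enumerate(spec.roster):
        if kind == "PCG":
            seq = _random_pcg(rng, length, code, codon_p)
        else:
            seq = _random_dna(rng, length, spec.base_freqs)
        features.append(GeneFeature(name, kind, pos, pos + len(seq), strand))
        parts.append(seq)
        pos += len(seq)
        if i == atp8_slot:
            spacer, truth_rel = _atp8_spacer(spec, rng, code)
            if truth_rel is not None:
                atp8_truth = dict(truth_rel)
                atp8_truth["start"] += pos
                atp8_truth["end"] += pos
            parts.append(spacer)
            pos += len(spacer)
        else:
            parts.append(_random_dna(rng, spec.spacer_len, spec.base_freqs))
            pos += spec.spacer_len
    genome = Mitogenome(
        id=f"synth-{spec.seed}",
        sequence="".join(parts),
        circular=True,
        features=features,
        source="mytilomito synthetic generator",
    )
    truth = {
        "features": pd.DataFrame(
            [
                {
                    "genome_id": genome.id,
                    "name": f.name,
                    "kind": f.kind,
                    "start": f.start,
                    "end": f.end,
                    "strand": f.strand,
                }
                for f in features
            ]
        ),
        "atp8": atp8_truth,
    }
    return genome, truth


def _atp8_spacer(spec, rng, code):
    """The long spacer, optionally containing the planted atp8-like ORF."""
    if not spec.plant_atp8:
        return _random_dna(rng, spec.atp8_spacer_len, spec.base_freqs), None
    protein = design_atp8_protein(spec, rng)
    orf = _encode_protein(protein, spec.atp8_start_codon, spec.atp8_stop_codon, code, rng)
    pad_total = spec.atp8_spacer_len - len(orf) - 3
    if pad_total < 20:
        raise SyntheticSpecError(
            f"atp8_spacer_len {spec.atp8_spacer_len} too short for the ORF"
        )
    left = pad_total // 2
    right = pad_total - left
    spacer = (
        _random_dna(rng, left, spec.base_freqs)
        + "TAA"  # in-frame stop guarding the planted start
        + orf
        + _random_dna(rng, right, spec.base_freqs)
    )
    truth = {
        "start": left + 3,
        "end": left + 3 + len(orf),
        "strand": "+",
        "protein": protein,
        "nt_length": len(orf),
        "start_codon": spec.atp8_start_codon,
        "stop_codon": spec.atp8_stop_codon,
        "tm_block": (spec.tm_start, spec.tm_start + spec.tm_len - 1),
    }
    return spacer, truth


# ---------------------------------------------------------------------------
# codon alignments along a tree


@dataclass
class SimAlignmentSpec:
    newick: str
    n_codons: int = 500
    kappa: float = 2.0
    omega: float = 0.2  # background / single omega
    class_omegas: dict | None = None  # class -> omega (branch models)
    class_by_taxon: dict | None = None  # taxon -> class; clades inherit
    foreground: tuple = ()  # taxa whose branches carry omega2 at positive sites
    pos_fraction: float = 0.0  # fraction of sites under positive selection
    omega2: float = 1.0
    codon_freqs: np.ndarray | None = None  # default: uniform over sense codons
    code_id: int = INVERTEBRATE_MITO
    seed: int = 0


def simulate_codon_alignment(spec: SimAlignmentSpec) -> tuple:
    """Evolve codons along the tree; returns ``(CodonAlignment, truth)``.

    ``truth`` records the tree, the per-edge omega map, and (in branch-site
    mode) the boolean per-site positive-selection indicator.  Transition
    matrices are exact matrix exponentials from the same spectral machinery
    the likelihood uses.
    """
    rng = np.random.default_rng(spec.seed)
    code = get_genetic_code(spec.code_id)
    tree = parse_tree(spec.newick)
    n = code.n_sense
    pi = (
        np.full(n, 1.0 / n)
        if spec.codon_freqs is None
        else np.asarray(spec.codon_freqs, float)
    )
    pi = pi / pi.sum()
    edges = tree.edges()
    if spec.class_omegas:
        classes = edge_classes(tree, spec.class_by_taxon or {})
        omega_edge = {
            v: spec.class_omegas.get(classes[v], spec.omega) for v in edges
        }
    else:
        omega_edge = {v: spec.omega for v in edges}
    fg_edges = set()
    if spec.foreground:
        fg_classes = edge_classes(tree, {t: "fg" for t in spec.foreground})
        fg_edges = {v for v, c in fg_classes.items() if c == "fg"}
    site_positive = np.zeros(spec.n_codons, dtype=bool)
    if spec.pos_fraction > 0:
        site_positive = rng.random(spec.n_codons) < spec.pos_fraction

    def transition(kappa, omega, t, rate_ref=None):
        # site mixtures share one time scale (the background omega's rate),
        # so positively selected sites genuinely evolve faster
        if rate_ref is None:
            Q = gy94_rate_matrix(kappa, omega, pi, spec.code_id)
        else:
            Q = gy94_rate_matrix(
                kappa, omega, pi, spec.code_id, scale=False
            ) / mean_rate(kappa, rate_ref, pi, spec.code_id)
        return spectral(Q, pi).transition(t)

    states = {tree.root: rng.choice(n, size=spec.n_codons, p=pi)}
    for v in tree.postorder[::-1]:  # preorder
        for c in tree.children[v]:
            t = tree.lengths[c]
            base_P = transition(spec.kappa, omega_edge[c], t)
            child = _propagate(states[v], base_P, rng)
            if site_positive.any() and c in fg_edges:
                pos_P = transition(spec.kappa, spec.omega2, t, rate_ref=omega_edge[c])
                child_pos = _propagate(states[v], pos_P, rng)
                child = np.where(site_positive, child_pos, child)
            states[c] = child
    mat = np.stack([states[i] for i in range(tree.n_leaves)]).astype(np.int16)
    aln = CodonAlignment(list(tree.taxa), mat, spec.code_id)
    truth = {
        "tree": tree,
        "omega_by_edge": omega_edge,
        "foreground_edges": fg_edges,
        "site_positive": site_positive,
        "pi": pi,
    }
    return aln, truth


def _propagate(parent_states, P, rng):
    cum = P.cumsum(axis=1)
    r = rng.random(parent_states.shape[0])
    return (cum[parent_states] < r[:, None]).sum(axis=1)
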