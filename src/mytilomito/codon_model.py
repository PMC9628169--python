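"""Goldman–Yang (1994) codon substitution model and tree likelihood.

The generator over sense codons has q_ij = 0 for multi-nucleotide changes
and pi_j, kappa*pi_j, omega*pi_j, omega*kappa*pi_j for synonymous
transversions/transitions and nonsynonymous transversions/transitions; it is
scaled to one expected substitution per codon site, so branch lengths are in
substitutions per codon.  The chain is reversible, so transition matrices
come from an eigendecomposition in the pi-symmetrized basis.

Likelihoods use Felsenstein pruning over the sense-codon states.  The trees
this package targets are small (tens of taxa at most), so partials are kept
unscaled in double precision; underflow raises with the offending site.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import dendropy
import numpy as np

from .codon_alignment import CodonAlignment
from .genetic_code import INVERTEBRATE_MITO, get_genetic_code

_PURINES = frozenset("AG")


class CodonModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# code structure: single-nucleotide codon neighbours


@lru_cache(maxsize=None)
def _neighbour_structure(code_id: int):
    """Index pairs (i, j) of sense codons one nucleotide apart, with
    transition and synonymy flags (both directions included)."""
    code = get_genetic_code(code_id)
    sense = code.sense_codons
    ii, jj, ts, syn = [], [], [], []
    for i, a in enumerate(sense):
        for j, b in enumerate(sense):
            if i == j:
                continue
            diff = [k for k in range(3) if a[k] != b[k]]
            if len(diff) != 1:
                continue
            (k,) = diff
            ii.append(i)
            jj.append(j)
            ts.append((a[k] in _PURINES) == (b[k] in _PURINES))
            syn.append(code.forward[a] == code.forward[b])
    return (
        np.array(ii),
        np.array(jj),
        np.array(ts, dtype=bool),
        np.array(syn, dtype=bool),
    )


def gy94_rate_matrix(
    kappa: float,
    omega: float,
    codon_freqs: np.ndarray,
    code_id: int = INVERTEBRATE_MITO,
    scale: bool = True,
) -> np.ndarray:
    """The GY94 generator Q over sense codons (rows sum to zero).

    With ``scale=True`` the expected substitution rate per codon site,
    sum_i pi_i * (-q_ii), is 1.
    """
    pi = np.asarray(codon_freqs, dtype=float)
    code = get_genetic_code(code_id)
    n = code.n_sense
    if pi.shape != (n,):
        raise CodonModelError(f"codon_freqs must have length {n}")
    if kappa <= 0 or omega < 0:
        raise CodonModelError("kappa must be > 0 and omega >= 0")
    ii, jj, ts, syn = _neighbour_structure(code_id)
    rate = pi[jj] * np.where(ts, kappa, 1.0) * np.where(syn, 1.0, omega)
    Q = np.zeros((n, n))
    Q[ii, jj] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        mu = -(pi * np.diag(Q)).sum()
        if mu > 0:
            Q /= mu
    return Q


def mean_rate(
    kappa: float, omega: float, codon_freqs: np.ndarray,
    code_id: int = INVERTEBRATE_MITO,
) -> float:
    """Expected substitutions per codon site of the *unscaled* generator."""
    Q = gy94_rate_matrix(kappa, omega, codon_freqs, code_id, scale=False)
    return float(-(np.asarray(codon_freqs) * np.diag(Q)).sum())


@dataclass
class SpectralGenerator:
    """Eigendecomposition of a reversible Q in the pi-symmetrized basis."""

    eigenvalues: np.ndarray
    right: np.ndarray  # D^{-1/2} U
    left: np.ndarray  # U^T D^{1/2}
    Q: np.ndarray

    def transition(self, t: float) -> np.ndarray:
        if t < 0:
            raise CodonModelError(f"negative branch length {t}")
        P = (self.right * np.exp(self.eigenvalues * t)) @ self.left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def spectral(Q: np.ndarray, pi: np.ndarray) -> SpectralGenerator:
    d = np.sqrt(np.maximum(pi, 1e-300))
    S = Q * (d[:, None] / d[None, :])
    S = (S + S.T) / 2.0  # enforce exact symmetry
    w, U = np.linalg.eigh(S)
    return SpectralGenerator(
        eigenvalues=w, right=U / d[:, None], left=U.T * d[None, :], Q=Q
    )


# ---------------------------------------------------------------------------
# codon frequencies


def codon_frequencies(
    aln: CodonAlignment, model: str = "F3x4"
) -> np.ndarray:
    """Equilibrium codon frequencies from the alignment.

    ``F3x4``: position-specific nucleotide frequencies; ``F1x4``: pooled
    nucleotide frequencies; ``uniform``: equal over sense codons.  All are
    renormalized over sense codons with a small floor so no sense codon has
    zero frequency.
    """
    code = get_genetic_code(aln.code_id)
    sense = code.sense_codons
    n = len(sense)
    if model == "uniform":
        return np.full(n, 1.0 / n)
    counts = np.zeros((3, 4))
    nuc_index = {b: i for i, b in enumerate("TCAG")}
    flat = aln.codons[aln.codons >= 0]
    for idx in flat:
        codon = sense[idx]
        for pos in range(3):
            counts[pos, nuc_index[codon[pos]]] += 1
    counts += 0.5  # pseudocount keeps frequencies strictly positive
    if model == "F1x4":
        pooled = counts.sum(axis=0)
        pooled /= pooled.sum()
        counts = np.tile(pooled, (3, 1))
    elif model == "F3x4":
        counts /= counts.sum(axis=1, keepdims=True)
    else:
        raise CodonModelError(f"unknown frequency model {model!r}")
    pi = np.array(
        [
            counts[0, nuc_index[c[0]]]
            * counts[1, nuc_index[c[1]]]
            * counts[2, nuc_index[c[2]]]
            for c in sense
        ]
    )
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# trees


@dataclass
class PhyloTree:
    """Array-based rooted view of a (possibly unrooted) tree.

    Node 0..n_leaves-1 are leaves in ``taxa`` order; every non-root node has
    the branch above it, indexed by the node id.  ``postorder`` lists
    internal nodes after their children.
    """

    taxa: list
    parent: np.ndarray  # parent[node] (-1 for root)
    children: list  # children[node] -> list of node ids
    lengths: np.ndarray  # branch length above each node (root entry unused)
    root: int
    newick: str = ""

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    def edges(self) -> list:
        """Node ids that carry a branch (everything but the root)."""
        return [v for v in range(self.n_nodes) if v != self.root]

    @property
    def postorder(self) -> list:
        order = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return order[::-1]

    def leaf_sets(self) -> dict:
        """node -> frozenset of descendant taxon labels."""
        out = {}
        for v in self.postorder:
            if not self.children[v]:
                out[v] = frozenset([self.taxa[v]])
            else:
                s = frozenset()
                for c in self.children[v]:
                    s |= out[c]
                out[v] = s
        return out

    def with_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        return PhyloTree(
            self.taxa, self.parent, self.children, np.asarray(lengths, float),
            self.root, self.newick,
        )

    def to_newick(self) -> str:
        def rec(v):
            if not self.children[v]:
                lab = self.taxa[v]
            else:
                lab = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if v == self.root:
                return lab + ";"
            return f"{lab}:{self.lengths[v]:.8g}"

        return rec(self.root)


def parse_tree(newick: str) -> PhyloTree:
    """Parse a newick string (or path) into a :class:`PhyloTree`."""
    import os

    newick = str(newick)
    if os.path.exists(newick):
        src = open(newick).read()
    else:
        src = newick
    try:
        dt = dendropy.Tree.get(
            data=src, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise CodonModelError(f"could not parse newick tree: {exc}") from exc
    leaves = [lf for lf in dt.leaf_node_iter()]
    taxa = [lf.taxon.label for lf in leaves]
    if len(set(taxa)) != len(taxa):
        raise CodonModelError("duplicate taxon labels in tree")
    node_id = {}
    for i, lf in enumerate(leaves):
        node_id[lf] = i
    next_id = len(leaves)
    for nd in dt.preorder_node_iter():
        if nd not in node_id:
            node_id[nd] = next_id
            next_id += 1
    n = next_id
    parent = np.full(n, -1, dtype=int)
    children: list = [[] for _ in range(n)]
    lengths = np.zeros(n)
    root = node_id[dt.seed_node]
    for nd in dt.preorder_node_iter():
        v = node_id[nd]
        for ch in nd.child_nodes():
            c = node_id[ch]
            parent[c] = v
            children[v].append(c)
            lengths[c] = ch.edge.length if ch.edge.length is not None else 0.1
    return PhyloTree(taxa, parent, children, lengths, root, newick=src)


def edge_classes(
    tree: PhyloTree, class_by_taxon: dict, default: str = "background"
) -> dict:
    """Assign a class label to every branch.

    A branch gets a non-default class when every leaf below it maps to that
    class; terminal branches use their taxon's class directly.  Unmapped
    taxa and mixed clades get ``default``.
    """
    sets = tree.leaf_sets()
    out = {}
    for v in tree.edges():
        labs = {class_by_taxon.get(t, default) for t in sets[v]}
        out[v] = labs.pop() if len(labs) == 1 else default
    return out


# ---------------------------------------------------------------------------
# likelihood


def _leaf_partials(aln_codons: np.ndarray, n_states: int) -> list:
    """Per-leaf (n_patterns, n_states) indicator partials (missing -> ones)."""
    eye = np.eye(n_states)
    out = []
    for row in aln_codons:
        L = np.ones((row.shape[0], n_states))
        known = row >= 0
        L[known] = eye[row[known]]
        out.append(L)
    return out


def compress_patterns(codons: np.ndarray) -> tuple:
    """Unique alignment columns and their multiplicities."""
    cols, inverse, counts = np.unique(
        codons.T, axis=0, return_inverse=True, return_counts=True
    )
    return cols.T, counts.astype(float), inverse


@dataclass
class PruneResult:
    site_likelihoods: np.ndarray  # per-pattern likelihood (unscaled)
    down: dict  # node -> (n_patterns, n_states) subtree partials
    P: dict  # edge node -> transition matrix
    contrib: dict  # node -> down[v] @ P[v].T


def prune(
    tree: PhyloTree,
    leaf_partials: list,
    P_by_edge: dict,
    pi: np.ndarray,
) -> PruneResult:
    down: dict = {}
    contrib: dict = {}
    for v in tree.postorder:
        if not tree.children[v]:
            down[v] = leaf_partials[v]
        else:
            L = None
            for c in tree.children[v]:
                L = contrib[c] if L is None else L * contrib[c]
            down[v] = L
        if v != tree.root:
            contrib[v] = down[v] @ P_by_edge[v].T
    site_l = down[tree.root] @ pi
    return PruneResult(site_likelihoods=site_l, down=down, P=P_by_edge, contrib=contrib)


def outside_partials(tree: PhyloTree, res: PruneResult, pi: np.ndarray) -> dict:
    """G[v]: outside partial indexed by the state at v's parent.

    dL_site/dt_v = sum_{xy} G[v][s, x] (Q P_v)[x, y] down[v][s, y].
    """
    A = {tree.root: np.broadcast_to(pi, res.down[tree.root].shape)}
    G: dict = {}
    for v in tree.postorder[::-1]:  # preorder
        for c in tree.children[v]:
            g = A[v]
            for sib in tree.children[v]:
                if sib is not c:
                    g = g * res.contrib[sib]
            G[c] = g
            A[c] = g @ res.P[c]
    return G


def branch_length_gradient(
    tree: PhyloTree,
    res: PruneResult,
    G: dict,
    Q_by_edge: dict,
) -> dict:
    """dL_site/dt_e for every edge, as per-pattern vectors."""
    out = {}
    for v in tree.edges():
        M = Q_by_edge[v] @ res.P[v]
        out[v] = np.einsum("sx,sx->s", G[v], res.down[v] @ M.T)
    return out


def site_log_likelihoods(
    aln: CodonAlignment,
    tree: PhyloTree,
    kappa: float,
    omega_by_edge: dict,
    codon_freqs: np.ndarray,
) -> np.ndarray:
    """Per-site log-likelihoods under GY94 with one omega per branch."""
    code = get_genetic_code(aln.code_id)
    order = [aln.taxa.index(t) for t in tree.taxa]
    leafs = _leaf_partials(aln.codons[order], code.n_sense)
    specs = {
        w: spectral(gy94_rate_matrix(kappa, w, codon_freqs, aln.code_id), codon_freqs)
        for w in set(omega_by_edge.values())
    }
    P = {v: specs[omega_by_edge[v]].transition(tree.lengths[v]) for v in tree.edges()}
    res = prune(tree, leafs, P, codon_freqs)
    sl = res.site_likelihoods
    if (sl <= 0).any() or not np.isfinite(sl).all():
        bad = int(np.flatnonzero(~(sl > 0))[0])
        raise CodonModelError(f"non-finite site likelihood at site {bad}")
    return np.log(sl)


def log_likelihood(
    aln: CodonAlignment,
    tree: PhyloTree,
    kappa: float,
    omega: float | dict,
    codon_freqs: np.ndarray,
) -> float:
    """Total log-likelihood; ``omega`` is a scalar or an edge -> omega map."""
    if not isinstance(omega, dict):
        omega = {v: float(omega) for v in tree.edges()}
    return float(site_log_likelihoods(aln, tree, kappa, omega, codon_freqs).sum())
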