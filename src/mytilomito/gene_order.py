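"""Linearized mitochondrial gene arrangements and their comparison.

A circular genome's features are rotated so an anchor gene (cox1 by
default) comes first, gene labels are normalized to canonical names, and two
arrangements are compared for identity and signed breakpoint distance
(adjacencies present in one order but not the other, treating an adjacency
and its strand-flipped reversal as the same).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .mito_io import Mitogenome

#: canonical labels of the 13 PCGs and 2 rRNAs
CANONICAL_GENES = (
    "cox1", "cox2", "cox3", "cob", "nad1", "nad2", "nad3", "nad4",
    "nad4L", "nad5", "nad6", "atp6", "atp8", "rrnS", "rrnL",
)

_ALIASES = {
    "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "co1": "cox1", "co2": "cox2", "co3": "cox3",
    "cox1": "cox1", "cox2": "cox2", "cox3": "cox3",
    "cytb": "cob", "cob": "cob", "cytochromeb": "cob",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4L", "nd5": "nad5", "nd6": "nad6",
    "nad1": "nad1", "nad2": "nad2", "nad3": "nad3", "nad4": "nad4",
    "nad4l": "nad4L", "nad5": "nad5", "nad6": "nad6",
    "atp6": "atp6", "atp8": "atp8", "atpase6": "atp6", "atpase8": "atp8",
    "rrns": "rrnS", "rrnl": "rrnL", "12srrna": "rrnS", "16srrna": "rrnL",
    "srrna": "rrnS", "lrrna": "rrnL", "rns": "rrnS", "rnl": "rrnL",
}

_TRNA_RE = re.compile(r"^trn([a-z])(\d*)$", re.IGNORECASE)


class GeneOrderError(ValueError):
    pass


def canonical_label(name: str) -> str:
    key = re.sub(r"[\s_\-]", "", name).lower()
    if key in _ALIASES:
        return _ALIASES[key]
    m = _TRNA_RE.match(key)
    if m:
        return f"trn{m.group(1).upper()}{m.group(2)}"
    return name


@dataclass
class GeneOrder:
    genome_id: str
    tokens: list  # [(canonical label, +1/-1), ...], tokens[0] is the anchor
    anchor: str
    include_trnas: bool

    def labels(self) -> list:
        return [t[0] for t in self.tokens]


def linearize(
    g: Mitogenome, anchor: str = "cox1", include_trnas: bool = False
) -> GeneOrder:
    """Rotate the circular feature order so ``anchor`` is position 1.

    Duplicated tRNAs get numeric suffixes (trnH, trnH2, ...); duplicated
    PCG/rRNA labels are an error.
    """
    feats = [
        f
        for f in sorted(g.features, key=lambda f: (f.start, f.end))
        if f.kind in ("PCG", "rRNA") or (include_trnas and f.kind == "tRNA")
    ]
    labels = []
    seen: dict = {}
    for f in feats:
        lab = canonical_label(f.name)
        count = seen.get(lab, 0)
        seen[lab] = count + 1
        if count and f.kind == "tRNA":
            lab = f"{lab}{count + 1}"
        labels.append(lab)
    dups = [
        lab
        for lab, cnt in seen.items()
        if cnt > 1 and not lab.startswith("trn")
    ]
    if dups:
        raise GeneOrderError(f"{g.id}: duplicated gene labels: {sorted(dups)}")
    tokens = [
        (lab, 1 if f.strand == "+" else -1) for lab, f in zip(labels, feats)
    ]
    anchor_lab = canonical_label(anchor)
    try:
        pos = [t[0] for t in tokens].index(anchor_lab)
    except ValueError:
        raise GeneOrderError(f"{g.id}: anchor gene {anchor!r} not present") from None
    tokens = tokens[pos:] + tokens[:pos]
    return GeneOrder(g.id, tokens, anchor_lab, include_trnas)


def _adjacencies(tokens: list) -> set:
    """Signed circular adjacencies, canonicalized for strand flips."""
    adj = set()
    for (a, sa), (b, sb) in zip(tokens, tokens[1:] + tokens[:1]):
        fwd = ((a, sa), (b, sb))
        rev = ((b, -sb), (a, -sa))
        adj.add(min(fwd, rev))
    return adj


@dataclass
class OrderComparison:
    identical: bool
    shared_prefix: int
    breakpoints: int
    dropped_labels: tuple = ()


def compare_orders(a: GeneOrder, b: GeneOrder) -> OrderComparison:
    """Identity, shared prefix and signed breakpoint distance of two orders.

    When gene sets differ, the comparison runs on the intersection and
    reports the dropped labels.
    """
    if a.include_trnas != b.include_trnas:
        raise GeneOrderError("orders built with different include_trnas settings")
    set_a, set_b = set(a.labels()), set(b.labels())
    common = set_a & set_b
    dropped = tuple(sorted((set_a | set_b) - common))
    ta = [t for t in a.tokens if t[0] in common]
    tb = [t for t in b.tokens if t[0] in common]
    identical = ta == tb and not dropped
    prefix = 0
    for x, y in zip(ta, tb):
        if x != y:
            break
        prefix += 1
    breakpoints = len(_adjacencies(ta) - _adjacencies(tb))
    return OrderComparison(
        identical=identical,
        shared_prefix=prefix,
        breakpoints=breakpoints,
        dropped_labels=dropped,
    )


def orders_table(orders: list):
    """One row per genome: the linearized arrangement as a string."""
    import pandas as pd

    rows = [
        {
            "genome": o.genome_id,
            "anchor": o.anchor,
            "arrangement": " ".join(
                ("-" if s < 0 else "") + lab for lab, s in o.tokens
            ),
        }
        for o in orders
    ]
    return pd.DataFrame(rows)


def pairwise_matrix(orders: list):
    """Pairwise breakpoint-distance matrix as a DataFrame."""
    import pandas as pd

    ids = [o.genome_id for o in orders]
    mat = [
        [compare_orders(x, y).breakpoints for y in orders] for x in orders
    ]
    return pd.DataFrame(mat, index=ids, columns=ids)
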