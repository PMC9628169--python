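"""Read/write annotated mitogenomes and the shared coordinate model.

All coordinates are 0-based half-open internally.  GenBank and GFF3
(1-based inclusive) are converted at the boundary.  Features crossing the
origin of a circular genome are stored with ``wraps_origin=True`` and
``start > end``; their length is computed modulo the genome length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import (
    CompoundLocation,
    SeqFeature,
    SimpleLocation,
)
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

#: GenBank/GFF feature types mapped onto our feature kinds.
_KIND_BY_TYPE = {
    "CDS": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
}


class MitoIOError(ValueError):
    """Raised for malformed genome inputs."""


@dataclass
class GeneFeature:
    """A typed gene feature on a mitogenome.

    ``start``/``end`` are 0-based half-open.  ``start > end`` is only legal
    when ``wraps_origin`` is true (the feature crosses the circular origin).
    """

    name: str
    kind: str  # {PCG, tRNA, rRNA, other}
    start: int
    end: int
    strand: str  # {+, -}
    wraps_origin: bool = False
    incomplete_stop: bool = False

    def __post_init__(self) -> None:
        if self.kind not in {"PCG", "tRNA", "rRNA", "other"}:
            raise MitoIOError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise MitoIOError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.wraps_origin and self.start >= self.end:
            raise MitoIOError(
                f"feature {self.name}: start {self.start} >= end {self.end} "
                "without wraps_origin"
            )

    def length(self, genome_length: int | None = None) -> int:
        if not self.wraps_origin:
            return self.end - self.start
        if genome_length is None:
            raise MitoIOError(
                f"feature {self.name} wraps the origin; genome length required"
            )
        return genome_length - self.start + self.end


@dataclass
class Mitogenome:
    """A circular (or linear) mitochondrial genome with typed features."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    source: str = ""
    lineage: str | None = None  # optional F-type / M-type tag; never inferred

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise MitoIOError(
                f"genome {self.id}: ambiguity codes other than N are not "
                f"supported: {sorted(bad)}"
            )
        n = len(self.sequence)
        for f in self.features:
            if not (0 <= f.start < n) or f.end > n or f.end < 0:
                raise MitoIOError(
                    f"genome {self.id}: feature {f.name} coordinates "
                    f"[{f.start}, {f.end}) outside [0, {n})"
                )
            if f.wraps_origin and not self.circular:
                raise MitoIOError(
                    f"genome {self.id}: feature {f.name} wraps the origin of "
                    "a non-circular genome"
                )
        self.features.sort(key=lambda f: (f.start, f.end))

    def __len__(self) -> int:
        return len(self.sequence)

    def pcgs(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "PCG"]

    def feature_sequence(self, f: GeneFeature) -> str:
        """Extract a feature's sequence on its own strand (wrap-aware)."""
        return extract_region(self, f.start, f.end, f.strand).sequence


@dataclass
class GenomeRegion:
    """An extracted stretch of genome sequence, strand-resolved."""

    genome_id: str
    start: int
    end: int
    strand: str
    sequence: str


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_region(g: Mitogenome, start: int, end: int, strand: str = "+") -> GenomeRegion:
    """Extract [start, end) on the given strand.

    ``end <= start`` on a circular genome wraps through the origin.  Minus
    strand returns the reverse complement.
    """
    n = len(g)
    if not (0 <= start < n):
        raise MitoIOError(f"start {start} outside [0, {n})")
    if end <= start:
        if not g.circular:
            raise MitoIOError(
                f"region [{start}, {end}) wraps the origin of non-circular "
                f"genome {g.id}"
            )
        seq = g.sequence[start:] + g.sequence[:end]
    else:
        if end > n:
            raise MitoIOError(f"end {end} beyond genome length {n}")
        seq = g.sequence[start:end]
    if strand == "-":
        seq = reverse_complement(seq)
    return GenomeRegion(g.id, start, end, strand, seq)


# ---------------------------------------------------------------------------
# GenBank


def read_genbank(path) -> Mitogenome:
    """Read a single-record GenBank flat file into a :class:`Mitogenome`."""
    records = list(SeqIO.parse(str(path), "genbank"))
    if len(records) == 0:
        raise MitoIOError(f"{path}: no GenBank records found")
    if len(records) > 1:
        ids = ", ".join(r.id for r in records)
        raise MitoIOError(f"{path}: expected a single record, found: {ids}")
    rec = records[0]
    circular = rec.annotations.get("topology", "linear") == "circular"
    n = len(rec.seq)
    features: list[GeneFeature] = []
    for ft in rec.features:
        kind = _KIND_BY_TYPE.get(ft.type)
        if kind is None:
            continue
        name = _feature_name(ft)
        try:
            start = int(ft.location.start)
            end = int(ft.location.end)
        except (TypeError, AttributeError) as exc:  # fuzzy/unknown locations
            raise MitoIOError(f"{path}: unparseable location for feature {name}") from exc
        strand = "-" if ft.location.strand == -1 else "+"
        wraps = False
        if isinstance(ft.location, CompoundLocation):
            parts = sorted(ft.location.parts, key=lambda p: int(p.start))
            # join(x..N, 1..y) across the origin of a circular record
            if (
                circular
                and len(parts) == 2
                and int(parts[-1].end) == n
                and int(parts[0].start) == 0
            ):
                start, end, wraps = int(parts[-1].start), int(parts[0].end), True
            else:
                raise MitoIOError(
                    f"{path}: unsupported compound location for feature {name}"
                )
        features.append(GeneFeature(name, kind, start, end, strand, wraps_origin=wraps))
    if not features:
        log.warning("%s: record %s has no gene features", path, rec.id)
    return Mitogenome(
        id=rec.id,
        sequence=str(rec.seq),
        circular=circular,
        features=features,
        source=f"genbank:{path}",
    )


def _feature_name(ft: SeqFeature) -> str:
    for key in ("gene", "product", "locus_tag", "label"):
        if key in ft.qualifiers:
            return str(ft.qualifiers[key][0])
    return ft.type


def write_genbank(g: Mitogenome, path) -> None:
    rec = SeqRecord(Seq(g.sequence), id=g.id, name=g.id[:16], description=g.source)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if g.circular else "linear"
    type_by_kind = {v: k for k, v in _KIND_BY_TYPE.items()}
    for f in g.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps_origin:
            loc = CompoundLocation(
                [
                    SimpleLocation(f.start, len(g), strand),
                    SimpleLocation(0, f.end, strand),
                ]
            )
        else:
            loc = SimpleLocation(f.start, f.end, strand)
        rec.features.append(
            SeqFeature(loc, type=type_by_kind.get(f.kind, "misc_feature"),
                       qualifiers={"gene": [f.name]})
        )
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA + GFF3 / TSV feature tables

_GFF_KIND_BY_TYPE = {
    "CDS": "PCG",
    "gene": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
}


def read_fasta_with_table(fasta, table) -> Mitogenome:
    """Read a genome from FASTA plus a GFF3 or TSV feature table.

    The TSV dialect is the one :func:`write_feature_tsv` emits (0-based
    half-open); GFF3 is 1-based inclusive and converted on read.
    """
    records = list(SeqIO.parse(str(fasta), "fasta"))
    if len(records) != 1:
        raise MitoIOError(f"{fasta}: expected a single FASTA record")
    rec = records[0]
    text = open(table).read()
    if text.startswith("##gff"):
        seq_id, circular, features = _parse_gff3(text, len(rec.seq))
    else:
        seq_id, circular, features = _parse_feature_tsv(text)
    if seq_id is not None and seq_id != rec.id:
        raise MitoIOError(
            f"feature table id {seq_id!r} does not match FASTA header {rec.id!r}"
        )
    n = len(rec.seq)
    for f in features:
        if f.end > n or f.start >= n:
            raise MitoIOError(
                f"feature {f.name} coordinates beyond sequence length {n}"
            )
    if not features:
        log.warning("%s: empty feature table", table)
    return Mitogenome(
        id=rec.id,
        sequence=str(rec.seq),
        circular=circular,
        features=features,
        source=f"fasta:{fasta}",
    )


def _parse_gff3(text: str, n: int):
    seq_id = None
    circular = True
    features = []
    for line in text.splitlines():
        if line.startswith("##sequence-region"):
            seq_id = line.split()[1]
        if line.startswith("#") or not line.strip():
            if "is_circular=false" in line:
                circular = False
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise MitoIOError(f"malformed GFF3 line: {line!r}")
        seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
        seq_id = seq_id or seqid
        kind = _GFF_KIND_BY_TYPE.get(ftype)
        if kind is None:
            continue
        attr = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        name = attr.get("gene", attr.get("Name", attr.get("ID", ftype)))
        wraps = attr.get("wraps_origin", "false") == "true"
        s, e = int(start) - 1, int(end)  # 1-based inclusive -> 0-based half-open
        if wraps:
            # stored as start..end with end < start already absolute
            s, e = int(start) - 1, int(end)
        features.append(
            GeneFeature(
                name,
                kind,
                s,
                e,
                strand,
                wraps_origin=wraps,
                incomplete_stop=attr.get("incomplete_stop", "false") == "true",
            )
        )
    return seq_id, circular, features


def write_gff3(g: Mitogenome, path) -> None:
    type_by_kind = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "other": "misc_feature"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {g.id} 1 {len(g)}\n")
        if not g.circular:
            fh.write("# is_circular=false\n")
        for f in g.features:
            attrs = f"ID={f.name};gene={f.name}"
            if f.wraps_origin:
                attrs += ";wraps_origin=true"
            if f.incomplete_stop:
                attrs += ";incomplete_stop=true"
            fh.write(
                "\t".join(
                    [
                        g.id,
                        "mytilomito",
                        type_by_kind[f.kind],
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def _parse_feature_tsv(text: str):
    seq_id = None
    circular = True
    features = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return seq_id, circular, features
    header = lines[0].rstrip("\n").split("\t")
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        seq_id = row.get("genome_id", seq_id)
        features.append(
            GeneFeature(
                row["name"],
                row["kind"],
                int(row["start"]),
                int(row["end"]),
                row["strand"],
                wraps_origin=row.get("wraps_origin", "False") == "True",
                incomplete_stop=row.get("incomplete_stop", "False") == "True",
            )
        )
    return seq_id, circular, features


def write_feature_tsv(g: Mitogenome, path) -> None:
    cols = "genome_id name kind start end strand wraps_origin incomplete_stop".split()
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for f in g.features:
            fh.write(
                "\t".join(
                    [
                        g.id,
                        f.name,
                        f.kind,
                        str(f.start),
                        str(f.end),
                        f.strand,
                        str(f.wraps_origin),
                        str(f.incomplete_stop),
                    ]
                )
                + "\n"
            )


def write_fasta(g: Mitogenome, path) -> None:
    rec = SeqRecord(Seq(g.sequence), id=g.id, description=g.source)
    SeqIO.write([rec], str(path), "fasta")


def rotate(g: Mitogenome, offset: int) -> Mitogenome:
    """Rotate a circular genome so old position ``offset`` becomes position 0."""
    if not g.circular:
        raise MitoIOError(f"cannot rotate non-circular genome {g.id}")
    n = len(g)
    offset %= n
    seq = g.sequence[offset:] + g.sequence[:offset]
    feats = []
    for f in g.features:
        length = f.length(n)
        s = (f.start - offset) % n
        if s + length <= n:
            feats.append(replace(f, start=s, end=s + length, wraps_origin=False))
        else:
            feats.append(replace(f, start=s, end=s + length - n, wraps_origin=True))
    return Mitogenome(g.id, seq, True, feats, source=g.source, lineage=g.lineage)
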