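"""Sequence and gene-model I/O with IUPAC-aware DNA primitives.

Internal coordinates are 0-based half-open everywhere; user-facing
reports (motif tables, polyadenylation positions) are 1-based inclusive.
Sequences are DNA only: lowercase input is accepted and uppercased, U is
rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "IUPAC_SETS",
    "IUPAC_COMPLEMENT",
    "SequenceRecord",
    "GeneModel",
    "InvalidSequenceError",
    "GeneModelError",
    "validate_dna",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gene_models",
]

#: The 15-letter IUPAC DNA alphabet (ambiguity codes included) mapped to
#: the set of concrete bases each letter stands for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

_VALID_RE = re.compile(r"[^ACGTRYSWKMBDHVN]")
_COMP_TABLE = str.maketrans(IUPAC_COMPLEMENT)


class InvalidSequenceError(ValueError):
    """A sequence contains characters outside the IUPAC DNA alphabet."""


class GeneModelError(ValueError):
    """A gene model violates its structural invariants."""


def validate_dna(seq: str, name: str = "sequence") -> str:
    """Uppercase ``seq`` and verify it is non-empty IUPAC DNA.

    Raises :class:`InvalidSequenceError` naming the offending 1-based
    position on failure.
    """
    if not seq:
        raise InvalidSequenceError(f"{name}: empty sequence")
    seq = seq.upper()
    m = _VALID_RE.search(seq)
    if m:
        raise InvalidSequenceError(
            f"{name}: illegal character {m.group()!r} at position {m.start() + 1}"
        )
    return seq


def revcomp(seq: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, K<->M, B<->V, D<->H, N<->N)."""
    seq = validate_dna(seq)
    return seq.translate(_COMP_TABLE)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (genomic scaffold or cDNA)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", validate_dna(self.seq, name=self.id))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneModel:
    """Scaffold-anchored exon/CDS intervals for a single-isoform gene.

    ``exons`` are 0-based half-open intervals, sorted and pairwise
    disjoint; ``cds`` is a single genomic interval whose endpoints fall
    inside the exon union (the spliced CDS is then contiguous on the
    mature transcript).
    """

    gene_id: str
    seq_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"{self.gene_id}: strand must be '+' or '-'")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not exons:
            raise GeneModelError(f"{self.gene_id}: gene has no exons")
        for s, e in exons:
            if not 0 <= s < e:
                raise GeneModelError(f"{self.gene_id}: bad exon interval [{s}, {e})")
        if list(exons) != sorted(exons):
            exons = tuple(sorted(exons))
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise GeneModelError(f"{self.gene_id}: overlapping exons at {s2}")
        object.__setattr__(self, "exons", exons)
        cs, ce = int(self.cds[0]), int(self.cds[1])
        if not cs < ce:
            raise GeneModelError(f"{self.gene_id}: empty CDS interval")
        if not (self._covers(cs) and self._covers(ce - 1)):
            raise GeneModelError(
                f"{self.gene_id}: CDS endpoints [{cs}, {ce}) fall outside the exon union"
            )
        object.__setattr__(self, "cds", (cs, ce))

    def _covers(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, genomic order."""
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly multi-line, CRLF-tolerant) FASTA file.

    Returns one :class:`SequenceRecord` per header, input order, with
    sequences uppercased. Raises on missing/empty files and on
    non-IUPAC characters (error names the record and position).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records = [
        SequenceRecord(id=r.id, seq=str(r.seq)) for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records in input order, wrapped at ``width`` columns."""
    bio = [_BioRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def _parent_gene(db: gffutils.FeatureDB, feature) -> "gffutils.Feature | None":
    for anc in db.parents(feature):
        if anc.featuretype == "gene":
            return anc
    return None


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene/exon/CDS features from a GFF3 file into gene models.

    GFF3 1-based inclusive coordinates are converted to 0-based
    half-open. Every exon/CDS must descend (directly or via an mRNA)
    from a gene feature; every CDS segment must lie within one exon.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GFF3 file not found: {path}")
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = list(db.features_of_type("gene"))
    by_gene_exons: dict[str, list[tuple[int, int]]] = {g.id: [] for g in genes}
    by_gene_cds: dict[str, list[tuple[int, int]]] = {g.id: [] for g in genes}

    for ftype, store in (("exon", by_gene_exons), ("CDS", by_gene_cds)):
        for f in db.features_of_type(ftype):
            parent = _parent_gene(db, f)
            if parent is None:
                raise GeneModelError(
                    f"{ftype} at {f.seqid}:{f.start}-{f.end} has no parent gene"
                )
            store[parent.id].append((f.start - 1, f.end))

    models = []
    for g in genes:
        exons = sorted(set(by_gene_exons[g.id]))
        cds_parts = sorted(by_gene_cds[g.id])
        if not exons:
            raise GeneModelError(f"gene {g.id} has no exon features")
        if not cds_parts:
            raise GeneModelError(f"gene {g.id} has no CDS features")
        for cs, ce in cds_parts:
            if not any(s <= cs and ce <= e for s, e in exons):
                raise GeneModelError(
                    f"gene {g.id}: CDS segment [{cs}, {ce}) straddles an intron "
                    f"or falls outside the exon union"
                )
        cds = (cds_parts[0][0], cds_parts[-1][1])
        models.append(
            GeneModel(
                gene_id=g.id,
                seq_id=g.seqid,
                strand=g.strand if g.strand in ("+", "-") else "+",
                exons=tuple(exons),
                cds=cds,
            )
        )
    return models


def write_gene_models(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS), bit-stable order.

    CDS segments are emitted per exon overlap with correct phase.
    """
    lines = ["##gff-version 3"]
    for m in models:
        start, end = m.span
        attrs_gene = f"ID={m.gene_id}"
        rna_id = f"{m.gene_id}.t1"
        lines.append(
            "\t".join([m.seq_id, "sodkit", "gene", str(start + 1), str(end),
                       ".", m.strand, ".", attrs_gene])
        )
        lines.append(
            "\t".join([m.seq_id, "sodkit", "mRNA", str(start + 1), str(end),
                       ".", m.strand, ".", f"ID={rna_id};Parent={m.gene_id}"])
        )
        for i, (s, e) in enumerate(m.exons, 1):
            lines.append(
                "\t".join([m.seq_id, "sodkit", "exon", str(s + 1), str(e),
                           ".", m.strand, ".",
                           f"ID={rna_id}.exon{i};Parent={rna_id}"])
            )
        # CDS segments: exon overlaps with the cds interval, with phase
        cs, ce = m.cds
        segments = []
        for s, e in m.exons:
            os_, oe = max(s, cs), min(e, ce)
            if os_ < oe:
                segments.append((os_, oe))
        ordered = segments if m.strand == "+" else segments[::-1]
        covered = 0
        phases = {}
        for s, e in ordered:
            phases[(s, e)] = (3 - covered % 3) % 3
            covered += e - s
        for j, (s, e) in enumerate(segments, 1):
            lines.append(
                "\t".join([m.seq_id, "sodkit", "CDS", str(s + 1), str(e),
                           ".", m.strand, str(phases[(s, e)]),
                           f"ID={rna_id}.cds{j};Parent={rna_id}"])
            )
    Path(path).write_text("\n".join(lines) + "\n")
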