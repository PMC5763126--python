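"""Degenerate-consensus motif scanning of promoter windows.

Compiles IUPAC consensus patterns (ARE, hARE, XRE, ...) and counts
occurrences per orientation in the region upstream of each gene's start
codon, producing a gene x (motif, orientation) count table.

Matching semantics: a subject position satisfies a pattern position iff
the subject base's IUPAC set is a subset of the pattern base's set, so a
masked (N) genome position matches only a pattern N and can never
inflate counts. All overlapping occurrences are reported. Reverse
(3'-5') hits are matches of the reverse-complemented pattern, reported
in forward-window coordinates with strand "-".
"""

from __future__ import annotations

import json
import logging
import re
import tomllib
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import (
    GeneModel,
    IUPAC_SETS,
    InvalidSequenceError,
    SequenceRecord,
    revcomp,
    validate_dna,
)

__all__ = [
    "FORWARD", "REVERSE",
    "DegenerateMotif", "MotifHit",
    "compile_motif", "default_motifs", "load_motifs",
    "scan_sequence", "extract_upstream", "scan_promoters", "build_count_table",
    "hits_to_bed", "hits_to_json",
]

logger = logging.getLogger(__name__)

#: Orientation labels used in count-table columns.
FORWARD = "5'-3'"
REVERSE = "3'-5'"

#: For each IUPAC pattern letter, the subject letters whose base set is a
#: subset of the pattern letter's base set.
_ALLOWED_SUBJECTS: dict[str, str] = {
    p: "".join(c for c, cset in IUPAC_SETS.items() if cset <= pset)
    for p, pset in IUPAC_SETS.items()
}


@dataclass(frozen=True)
class DegenerateMotif:
    """A named IUPAC degenerate consensus pattern."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"motif {self.name!r}: empty pattern")
        for i, c in enumerate(self.pattern.upper()):
            if c not in IUPAC_SETS:
                raise ValueError(
                    f"motif {self.name!r}: non-IUPAC character {c!r} at position {i + 1}"
                )
        object.__setattr__(self, "pattern", self.pattern.upper())

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def position_sets(self) -> tuple[frozenset[str], ...]:
        """Allowed concrete bases at each pattern position."""
        return tuple(IUPAC_SETS[c] for c in self.pattern)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence within a scanned window.

    ``start`` is a 0-based offset in the window; ``matched_seq`` is the
    forward-strand subsequence regardless of hit strand.
    """

    motif_name: str
    gene_id: str
    start: int
    length: int
    strand: str
    matched_seq: str


def compile_motif(name: str, pattern: str) -> DegenerateMotif:
    """Validate and compile an IUPAC consensus into a motif."""
    return DegenerateMotif(name=name, pattern=pattern)


def default_motifs() -> list[DegenerateMotif]:
    """The three promoter elements scanned by default, table order."""
    return [
        compile_motif("ARE", "TGACNNNGC"),
        compile_motif("hARE", "TGACNNN"),
        compile_motif("XRE", "TGCRCNC"),
    ]


def load_motifs(path: str | Path) -> list[DegenerateMotif]:
    """Load a motif set from a TOML (``name = "PATTERN"``, optionally
    under a ``[motifs]`` table) or two-column TSV (name<TAB>pattern) file."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        table = data.get("motifs", data)
        items = [(k, v) for k, v in table.items() if isinstance(v, str)]
    else:
        items = []
        for ln in path.read_text().splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            name, pattern = ln.split("\t")[:2]
            items.append((name, pattern))
    motifs = [compile_motif(n, p) for n, p in items]
    names = [m.name for m in motifs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate motif names in {path}")
    if not motifs:
        raise ValueError(f"no motifs found in {path}")
    return motifs


@lru_cache(maxsize=256)
def _lookahead_regex(pattern: str) -> re.Pattern[str]:
    # Lookahead so overlapping occurrences are all found.
    body = "".join(f"[{_ALLOWED_SUBJECTS[c]}]" for c in pattern)
    return re.compile(f"(?=({body}))")


def scan_sequence(
    window: str,
    motif: DegenerateMotif,
    strands: Iterable[str] = ("+", "-"),
    gene_id: str = "",
) -> list[MotifHit]:
    """All occurrences of ``motif`` in ``window`` on the given strands.

    A window shorter than the pattern yields an empty list; an invalid
    window character raises :class:`InvalidSequenceError`.
    """
    strands = tuple(strands)
    if not strands or any(s not in ("+", "-") for s in strands):
        raise ValueError("strands must be a non-empty subset of {'+', '-'}")
    window = validate_dna(window, name="window")
    n = len(motif)
    hits: list[MotifHit] = []
    for strand in strands:
        pat = motif.pattern if strand == "+" else revcomp(motif.pattern)
        for m in _lookahead_regex(pat).finditer(window):
            start = m.start()
            hits.append(
                MotifHit(
                    motif_name=motif.name,
                    gene_id=gene_id,
                    start=start,
                    length=n,
                    strand=strand,
                    matched_seq=window[start : start + n],
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def extract_upstream(
    genome: SequenceRecord, gene: GeneModel, window_nt: int
) -> str:
    """The ``window_nt`` bases immediately 5' of the start codon, 5'->3'
    relative to the gene.

    For a minus-strand gene this is the reverse complement of the bases
    immediately 3' of the CDS end on the forward genome strand. The
    window is truncated (with a logged warning) at contig boundaries;
    zero available bases yield an empty string.
    """
    if gene.seq_id != genome.id:
        raise ValueError(
            f"gene {gene.gene_id} is on {gene.seq_id!r}, not on scaffold {genome.id!r}"
        )
    if window_nt < 1:
        raise ValueError("window_nt must be >= 1")
    cs, ce = gene.cds
    if gene.strand == "+":
        start = max(0, cs - window_nt)
        window = genome.seq[start:cs]
    else:
        end = min(len(genome.seq), ce + window_nt)
        window = revcomp(genome.seq[ce:end]) if end > ce else ""
    if len(window) < window_nt:
        logger.warning(
            "gene %s: upstream window truncated to %d nt (requested %d)",
            gene.gene_id, len(window), window_nt,
        )
    return window


def scan_promoters(
    genomes: Sequence[SequenceRecord],
    genes: Sequence[GeneModel],
    motifs: Sequence[DegenerateMotif] | None = None,
    window_nt: int = 1000,
) -> list[MotifHit]:
    """Scan every gene's upstream window with every motif, both strands."""
    motifs = list(motifs) if motifs is not None else default_motifs()
    by_id = {g.id: g for g in genomes}
    hits: list[MotifHit] = []
    for gene in genes:
        if gene.seq_id not in by_id:
            raise ValueError(
                f"gene {gene.gene_id}: scaffold {gene.seq_id!r} not among genomes"
            )
        window = extract_upstream(by_id[gene.seq_id], gene, window_nt)
        if not window:
            continue
        for motif in motifs:
            hits.extend(scan_sequence(window, motif, ("+", "-"), gene_id=gene.gene_id))
    return hits


def build_count_table(
    genomes: Sequence[SequenceRecord],
    genes: Sequence[GeneModel],
    motifs: Sequence[DegenerateMotif] | None = None,
    window_nt: int = 1000,
) -> pd.DataFrame:
    """Gene x (motif, orientation) occurrence counts.

    Columns are motif-major with the forward (5'-3') orientation first.
    hARE and ARE are counted independently: an ARE site also contributes
    hARE counts wherever the hARE pattern matches.
    """
    motifs = list(motifs) if motifs is not None else default_motifs()
    hits = scan_promoters(genomes, genes, motifs, window_nt)
    columns = [(m.name, o) for m in motifs for o in (FORWARD, REVERSE)]
    table = pd.DataFrame(
        0,
        index=pd.Index([g.gene_id for g in genes], name="gene"),
        columns=pd.MultiIndex.from_tuples(columns, names=["motif", "orientation"]),
        dtype=int,
    )
    for h in hits:
        ori = FORWARD if h.strand == "+" else REVERSE
        table.loc[h.gene_id, (h.motif_name, ori)] += 1
    return table


def hits_to_bed(hits: Sequence[MotifHit], path: str | Path) -> None:
    """Per-hit BED6 (0-based half-open window coordinates, strand column)."""
    lines = [
        "\t".join(
            [h.gene_id, str(h.start), str(h.start + h.length),
             h.motif_name, "0", h.strand]
        )
        for h in hits
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def hits_to_json(hits: Sequence[MotifHit], path: str | Path) -> None:
    payload = [
        {
            "motif": h.motif_name, "gene": h.gene_id, "start": h.start,
            "length": h.length, "strand": h.strand, "matched_seq": h.matched_seq,
        }
        for h in hits
    ]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
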