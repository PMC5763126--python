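"""Gene-architecture characterisation of annotated loci.

Derives, from a genomic scaffold plus a gene model: ORF and protein
lengths, average-mass molecular weight, 5'/3' UTR lengths, exon/intron
counts with UTR-intron classification, and AATAAA polyadenylation-signal
positions on the mature transcript.

The ORF convention here includes the stop codon, so a clean ORF of
``n`` nt encodes ``n/3 - 1`` amino acids. Models whose spliced CDS does
not translate cleanly are reported with a flag rather than rejected —
published annotations contain such cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.SeqUtils import molecular_weight as _bio_mw

from .core_io import GeneModel, SequenceRecord, revcomp, validate_dna

__all__ = [
    "GeneArchitecture",
    "TranslationError",
    "protein_length_from_orf",
    "translate_orf",
    "molecular_weight",
    "find_polya_signals",
    "summarize_architecture",
]

_TABLE = unambiguous_dna_by_id[1]
_STOPS = frozenset(_TABLE.stop_codons)
_AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")


class TranslationError(ValueError):
    """The ORF violates start/stop/frame expectations."""


@dataclass
class GeneArchitecture:
    """Per-gene summary of coding and non-coding structure."""

    gene_id: str
    orf_nt: int
    protein_aa: int
    mw_kda: float
    utr5_nt: int
    utr3_nt: int
    n_exons: int
    n_introns: int
    utr_introns: list[str] = field(default_factory=list)
    polya_positions: list[int] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def transcript_nt(self) -> int:
        return self.utr5_nt + self.orf_nt + self.utr3_nt


def protein_length_from_orf(orf_nt: int) -> int:
    """Amino-acid count for an ORF that includes its stop codon."""
    if orf_nt % 3 != 0:
        raise ValueError(f"ORF length {orf_nt} nt is not divisible by 3")
    if orf_nt < 6:
        raise ValueError(f"ORF length {orf_nt} nt is shorter than start + stop")
    return orf_nt // 3 - 1


def translate_orf(orf_seq: str) -> str:
    """Translate a complete ORF (ATG ... stop, standard genetic code) to one-letter protein.

    Raises :class:`TranslationError` on a missing start/stop, an
    internal stop (its codon number is reported), a frame violation or
    an ambiguous base inside a codon.
    """
    orf_seq = validate_dna(orf_seq, name="ORF")
    if len(orf_seq) % 3 != 0:
        raise TranslationError(f"ORF length {len(orf_seq)} not divisible by 3")
    if len(orf_seq) < 6:
        raise TranslationError("ORF shorter than start codon + stop codon")
    if any(c not in "ACGT" for c in orf_seq):
        pos = next(i for i, c in enumerate(orf_seq) if c not in "ACGT")
        raise TranslationError(f"ambiguous base {orf_seq[pos]!r} at nt {pos + 1}")
    if not orf_seq.startswith("ATG"):
        raise TranslationError(f"ORF does not begin with ATG (got {orf_seq[:3]})")
    codons = [orf_seq[i : i + 3] for i in range(0, len(orf_seq), 3)]
    if codons[-1] not in _STOPS:
        raise TranslationError(f"ORF does not end with a stop codon (got {codons[-1]})")
    protein = []
    for i, codon in enumerate(codons[:-1], start=1):
        if codon in _STOPS:
            raise TranslationError(f"internal stop codon at codon {i}")
        protein.append(_TABLE.forward_table[codon])
    return "".join(protein)


def molecular_weight(protein: str) -> float:
    """Average-mass molecular weight in Da (residue masses + one water)."""
    if not protein:
        raise ValueError("empty protein sequence")
    protein = protein.upper()
    for i, aa in enumerate(protein):
        if aa not in _AA20:
            raise ValueError(f"non-standard residue {aa!r} at position {i + 1}")
    return float(_bio_mw(protein, seq_type="protein", monoisotopic=False))


def find_polya_signals(
    transcript: str, utr3_start: int, signal: str = "AATAAA"
) -> list[int]:
    """1-based start positions of every (possibly overlapping) ``signal``
    occurrence at or after 1-based position ``utr3_start``, ascending."""
    transcript = validate_dna(transcript, name="transcript")
    if not 1 <= utr3_start <= len(transcript) + 1:
        raise ValueError(f"utr3_start {utr3_start} outside transcript")
    signal = validate_dna(signal, name="signal")
    positions = []
    i = transcript.find(signal, utr3_start - 1)
    while i != -1:
        positions.append(i + 1)
        i = transcript.find(signal, i + 1)
    return positions


def _splice(genome: SequenceRecord, gene: GeneModel) -> tuple[str, list[int]]:
    """Forward-strand mature transcript and per-exon cumulative offsets."""
    parts = [genome.seq[s:e] for s, e in gene.exons]
    offsets = [0]
    for p in parts[:-1]:
        offsets.append(offsets[-1] + len(p))
    return "".join(parts), offsets


def _transcript_coord(gene: GeneModel, offsets: list[int], gpos: int) -> int:
    """Forward-transcript coordinate of genomic base ``gpos`` (must be exonic)."""
    for (s, e), off in zip(gene.exons, offsets):
        if s <= gpos < e:
            return off + (gpos - s)
    raise ValueError(f"genomic position {gpos} is intronic")


def summarize_architecture(
    genome: SequenceRecord,
    gene: GeneModel,
    polya_signal: str = "AATAAA",
    expected_protein_aa: int | None = None,
) -> GeneArchitecture:
    """Splice the gene, locate the CDS on the mature transcript, and
    compute the full architecture summary.

    ``expected_protein_aa``, when given (e.g. from an external
    annotation), is checked against ``orf_nt/3 - 1``; disagreement adds
    a ``length_discrepancy`` flag instead of raising.
    """
    transcript_fwd, offsets = _splice(genome, gene)
    L = len(transcript_fwd)
    cs, ce = gene.cds
    t_start = _transcript_coord(gene, offsets, cs)
    t_end = _transcript_coord(gene, offsets, ce - 1) + 1
    orf_fwd = transcript_fwd[t_start:t_end]
    orf_nt = len(orf_fwd)

    if gene.strand == "+":
        transcript = transcript_fwd
        utr5, utr3 = t_start, L - t_end
        orf_seq = orf_fwd
    else:
        transcript = revcomp(transcript_fwd)
        utr5, utr3 = L - t_end, t_start
        orf_seq = revcomp(orf_fwd)

    flags: list[str] = []
    protein = None
    try:
        protein = translate_orf(orf_seq)
    except TranslationError as exc:
        flags.append(f"translation_error: {exc}")

    if protein is not None:
        protein_aa = len(protein)
        mw_kda = molecular_weight(protein) / 1000.0
    else:
        protein_aa = max(orf_nt // 3 - 1, 0)
        mw_kda = float("nan")

    if expected_protein_aa is not None and expected_protein_aa != orf_nt // 3 - 1:
        flags.append(
            f"length_discrepancy: annotated {expected_protein_aa} aa vs "
            f"{orf_nt // 3 - 1} aa from {orf_nt} nt ORF"
        )

    # Intron classification on the pre-mRNA, relative to the CDS interval.
    labels_genomic = []
    for gs, ge in gene.introns:
        if ge <= cs:
            labels_genomic.append("left")
        elif gs >= ce:
            labels_genomic.append("right")
        else:
            labels_genomic.append("cds")
    if gene.strand == "+":
        ordered = labels_genomic
        left_label, right_label = "5'", "3'"
    else:
        ordered = labels_genomic[::-1]
        left_label, right_label = "3'", "5'"
    utr_introns = [
        (left_label if lab == "left" else right_label)
        for lab in ordered
        if lab != "cds"
    ]

    polya = (
        find_polya_signals(transcript, utr5 + orf_nt + 1, signal=polya_signal)
        if utr3 > 0
        else []
    )

    return GeneArchitecture(
        gene_id=gene.gene_id,
        orf_nt=orf_nt,
        protein_aa=protein_aa,
        mw_kda=mw_kda,
        utr5_nt=utr5,
        utr3_nt=utr3,
        n_exons=len(gene.exons),
        n_introns=len(gene.exons) - 1,
        utr_introns=utr_introns,
        polya_positions=polya,
        flags=flags,
    )


def architecture_table(architectures: Sequence[GeneArchitecture]):
    """One-row-per-gene summary DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene": a.gene_id,
                "orf_nt": a.orf_nt,
                "protein_aa": a.protein_aa,
                "mw_kda": round(a.mw_kda, 2),
                "utr5_nt": a.utr5_nt,
                "utr3_nt": a.utr3_nt,
                "n_exons": a.n_exons,
                "n_introns": a.n_introns,
                "utr_introns": ",".join(a.utr_introns),
                "polya_positions": ",".join(map(str, a.polya_positions)),
                "flags": ";".join(a.flags),
            }
            for a in architectures
        ]
    ).set_index("gene")
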