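"""Synthetic-data generators with a machine-readable ground-truth ledger.

Every input the analysis pipeline consumes can be generated here:
promoter-bearing gene loci with motifs planted at known counts, qPCR Ct
tables with known treatment fold changes, logistic NBT-inhibition
assays with known 50%-inhibition points, Lowry standards, and binomial
survival counts. Each generator is a pure function of (seed, plan) and
emits a truth record alongside the data.

Truth for motif counts is produced by re-scanning the finished sequence
with an independent brute-force matcher, never by assuming the plant
plan succeeded, so the ledger is exact even when planted sites nest
(a full ARE always contains a half-ARE) or random background spells out
an extra site the masking step could not remove.

The default study layout mirrors a 3 priming x 3 challenge factorial on
red flour beetle larvae: genes soda/sodb/sodc plus the infection marker
atta2 and the rp49 reference, three biological replicates measured in
technical duplicate, three independent survival experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    GeneModel,
    IUPAC_SETS,
    SequenceRecord,
    revcomp,
    write_fasta,
    write_gene_models,
)
from .motif_scan import FORWARD, REVERSE, DegenerateMotif, default_motifs

__all__ = [
    "PRIMING_LEVELS",
    "CHALLENGE_LEVELS",
    "ArchitecturePlan",
    "Locus",
    "brute_force_hits",
    "brute_force_counts",
    "generate_locus",
    "generate_qpcr_dataset",
    "generate_activity_dataset",
    "generate_survival_dataset",
    "generate_bundle",
    "default_locus_plans",
    "default_fold_changes",
    "default_survival_probs",
]

PRIMING_LEVELS = ("naive", "PBS", "hkBt1")
CHALLENGE_LEVELS = ("naive", "PBS", "Bt1")

_BASES = "ACGT"
_STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in _STOP_CODONS
)


# ---------------------------------------------------------------------------
# Independent brute-force scanner (the truth oracle)
# ---------------------------------------------------------------------------

def _naive_match_starts(window: str, pattern: str) -> list[int]:
    """Position-by-position subset matching, no regex, no shortcuts."""
    psets = [IUPAC_SETS[c] for c in pattern]
    n = len(pattern)
    starts = []
    for i in range(len(window) - n + 1):
        ok = True
        for j in range(n):
            if not IUPAC_SETS[window[i + j]] <= psets[j]:
                ok = False
                break
        if ok:
            starts.append(i)
    return starts


def brute_force_hits(
    window: str, motif: DegenerateMotif
) -> dict[str, list[int]]:
    """Start offsets of all (overlapping) matches per orientation."""
    return {
        FORWARD: _naive_match_starts(window, motif.pattern),
        REVERSE: _naive_match_starts(window, revcomp(motif.pattern)),
    }


def brute_force_counts(
    window: str, motifs: Sequence[DegenerateMotif]
) -> dict[str, dict[str, int]]:
    return {
        m.name: {o: len(starts) for o, starts in brute_force_hits(window, m).items()}
        for m in motifs
    }


# ---------------------------------------------------------------------------
# Locus generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitecturePlan:
    """Transcript layout: UTR/ORF lengths, intron insertion points
    (transcript position, intron length) and 1-based polyA-signal
    positions on the mature transcript."""

    utr5_nt: int
    orf_nt: int
    utr3_nt: int
    introns: tuple[tuple[int, int], ...] = ()
    polya_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.orf_nt % 3 != 0 or self.orf_nt < 6:
            raise ValueError("orf_nt must be a multiple of 3 and >= 6")
        if self.utr5_nt < 0 or self.utr3_nt < 0:
            raise ValueError("UTR lengths must be non-negative")
        L = self.transcript_nt
        pos = [p for p, _ in self.introns]
        if pos != sorted(pos) or len(set(pos)) != len(pos):
            raise ValueError("intron positions must be strictly increasing")
        for p, ln in self.introns:
            if not 0 < p < L:
                raise ValueError(f"intron position {p} outside transcript (0, {L})")
            if ln < 4:
                raise ValueError("introns must be at least 4 nt")
        utr3_lo = self.utr5_nt + self.orf_nt + 1
        for p in self.polya_positions:
            if not utr3_lo <= p <= L - 5:
                raise ValueError(
                    f"polyA position {p} outside the 3'UTR [{utr3_lo}, {L - 5}]"
                )

    @property
    def transcript_nt(self) -> int:
        return self.utr5_nt + self.orf_nt + self.utr3_nt


@dataclass
class Locus:
    """A generated scaffold + gene model + exact truth record."""

    record: SequenceRecord
    gene: GeneModel
    truth: dict


def _rand_dna(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(list(_BASES), size=n)) if n else []


def _rand_orf(rng: np.random.Generator, orf_nt: int) -> tuple[str, str]:
    """(orf_seq, protein): ATG + random sense codons + random stop."""
    n_inner = orf_nt // 3 - 2
    codons = ["ATG"] + [
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=n_inner)
    ] + [_STOP_CODONS[rng.integers(0, 3)]]
    orf = "".join(codons)
    from .gene_architecture import translate_orf

    return orf, translate_orf(orf)


def _mask_polya(rng: np.random.Generator, chars: list[str], region_start: int,
                keep: set[int], signal: str = "AATAAA") -> None:
    """Destroy accidental polyA signals at/after region_start (0-based),
    leaving starts in ``keep`` untouched."""
    for _ in range(10):
        s = "".join(chars)
        dirty = [
            i for i in range(region_start, len(s) - len(signal) + 1)
            if s[i : i + len(signal)] == signal and i not in keep
        ]
        if not dirty:
            return
        for i in dirty:
            j = i + int(rng.integers(0, len(signal)))
            if any(k <= j < k + len(signal) for k in keep):
                continue
            current = chars[j]
            choices = [b for b in "CG" if b != current] or ["C"]
            chars[j] = choices[int(rng.integers(0, len(choices)))]


def _mask_motifs(
    rng: np.random.Generator,
    window: list[str],
    motifs: Sequence[DegenerateMotif],
    protected: list[tuple[int, int]],
    max_passes: int = 10,
) -> None:
    """Substitute single bases to destroy motif matches that do not
    overlap any protected (planted) interval."""

    def inside_protected(pos: int) -> bool:
        return any(ps <= pos < pe for ps, pe in protected)

    planted_spans = set(protected)

    for _ in range(max_passes):
        s = "".join(window)
        changed = False
        for motif in motifs:
            for pat in (motif.pattern, revcomp(motif.pattern)):
                for i in _naive_match_starts(s, pat):
                    if (i, i + len(pat)) in planted_spans:
                        continue
                    # break the match at a constrained pattern position
                    # that does not sit inside any planted interval
                    js = [
                        j for j, c in enumerate(pat)
                        if len(IUPAC_SETS[c]) < 4 and not inside_protected(i + j)
                    ]
                    if not js:
                        continue
                    j = js[int(rng.integers(0, len(js)))]
                    bad = sorted(set(_BASES) - IUPAC_SETS[pat[j]])
                    window[i + j] = bad[int(rng.integers(0, len(bad)))]
                    changed = True
                s = "".join(window)
        if not changed:
            return


def generate_locus(
    seed: int | np.random.SeedSequence,
    motif_plan: Mapping[str, tuple[int, int]] | None = None,
    architecture_plan: ArchitecturePlan | None = None,
    motifs: Sequence[DegenerateMotif] | None = None,
    gene_id: str = "gene1",
    seq_id: str = "scaffold_1",
    strand: str = "+",
    window_nt: int = 1000,
    pad_nt: int = 60,
) -> Locus:
    """Generate one scaffold carrying one gene with planted promoter
    motifs and a planned transcript architecture.

    ``motif_plan`` maps motif name -> (forward, reverse) planted counts
    within the ``window_nt`` bases upstream of the start codon. The
    truth record's counts come from a brute-force re-scan of the final
    window, so nested occurrences (an ARE plant always carries a
    forward hARE) are included exactly as a scanner will see them.
    """
    rng = np.random.default_rng(seed)
    motifs = list(motifs) if motifs is not None else default_motifs()
    by_name = {m.name: m for m in motifs}
    motif_plan = dict(motif_plan or {})
    for name in motif_plan:
        if name not in by_name:
            raise ValueError(f"motif plan references unknown motif {name!r}")
    plan = architecture_plan or ArchitecturePlan(
        utr5_nt=300, orf_nt=462, utr3_nt=100, introns=((150, 250),),
        polya_positions=(820,),
    )
    planted_total = sum(
        (nf + nr) * len(by_name[name]) for name, (nf, nr) in motif_plan.items()
    )
    if planted_total > window_nt // 2:
        raise ValueError(
            f"motif plan infeasible: {planted_total} planted nt exceed half of "
            f"the {window_nt} nt window"
        )

    # --- mature transcript -------------------------------------------------
    utr5 = _rand_dna(rng, plan.utr5_nt)
    orf, protein = _rand_orf(rng, plan.orf_nt)
    utr3 = _rand_dna(rng, plan.utr3_nt)
    transcript = utr5 + list(orf) + utr3
    utr3_region = plan.utr5_nt + plan.orf_nt
    keep = {p - 1 for p in plan.polya_positions}
    _mask_polya(rng, transcript, utr3_region, keep)
    for p in plan.polya_positions:
        transcript[p - 1 : p + 5] = list("AATAAA")

    # --- insert introns -> genomic gene sequence ---------------------------
    pieces: list[str] = []
    exon_local: list[tuple[int, int]] = []   # genomic intervals within the gene
    tpos_map: list[tuple[int, int, int]] = []  # (t_start, t_end, g_start)
    g = 0
    prev = 0
    boundaries = list(plan.introns) + [(plan.transcript_nt, 0)]
    for pos, ilen in boundaries:
        exon_seq = transcript[prev:pos]
        exon_local.append((g, g + len(exon_seq)))
        tpos_map.append((prev, pos, g))
        pieces.append("".join(exon_seq))
        g += len(exon_seq)
        if ilen:
            pieces.append("".join(_rand_dna(rng, ilen)))
            g += ilen
        prev = pos
    gene_seq = "".join(pieces)

    def genomic_of(tpos: int) -> int:
        for ts, te, gs in tpos_map:
            if ts <= tpos < te:
                return gs + (tpos - ts)
        raise ValueError(f"transcript position {tpos} unmapped")

    cds_local = (
        genomic_of(plan.utr5_nt),
        genomic_of(plan.utr5_nt + plan.orf_nt - 1) + 1,
    )

    # --- assemble scaffold and clean/plant the promoter window -------------
    scaffold = _rand_dna(rng, window_nt) + list(gene_seq) + _rand_dna(rng, pad_nt)
    cds_start = window_nt + cds_local[0]
    win_lo = cds_start - window_nt
    window = scaffold[win_lo:cds_start]

    _mask_motifs(rng, window, motifs, protected=[])

    planted: list[tuple[int, int]] = []
    for name in sorted(motif_plan):
        nf, nr = motif_plan[name]
        motif = by_name[name]
        m = len(motif)
        for orientation, count in (("+", nf), ("-", nr)):
            for _ in range(count):
                for _attempt in range(10_000):
                    start = int(rng.integers(0, window_nt - m + 1))
                    if not any(start < pe and ps < start + m for ps, pe in planted):
                        break
                else:
                    raise ValueError("could not place planted motifs without overlap")
                inst = "".join(
                    sorted(IUPAC_SETS[c])[int(rng.integers(0, len(IUPAC_SETS[c])))]
                    for c in motif.pattern
                )
                if orientation == "-":
                    inst = revcomp(inst)
                window[start : start + m] = list(inst)
                planted.append((start, start + m))

    _mask_motifs(rng, window, motifs, protected=planted)
    scaffold[win_lo:cds_start] = window

    # planted sites and the ORF must have survived masking
    assert "".join(scaffold[cds_start : cds_start + 3]) == "ATG"

    truth_counts = brute_force_counts("".join(window), motifs)

    # polyA truth: re-scan the final 3'UTR of the mature transcript
    final_transcript = "".join(
        "".join(scaffold[window_nt + s : window_nt + e]) for s, e in exon_local
    )
    polya_truth = [
        i + 1
        for i in range(utr3_region, len(final_transcript) - 5)
        if final_transcript[i : i + 6] == "AATAAA"
    ]

    utr_intron_truth = [
        "5'" if pos <= plan.utr5_nt else "3'"
        for pos, _ in plan.introns
        if pos <= plan.utr5_nt or pos >= plan.utr5_nt + plan.orf_nt
    ]

    seq = "".join(scaffold)
    exons_genomic = tuple((window_nt + s, window_nt + e) for s, e in exon_local)
    cds_genomic = (window_nt + cds_local[0], window_nt + cds_local[1])
    if strand == "-":
        L = len(seq)
        seq = revcomp(seq)
        exons_genomic = tuple(sorted((L - e, L - s) for s, e in exons_genomic))
        cds_genomic = (L - cds_genomic[1], L - cds_genomic[0])
        utr_intron_truth = utr_intron_truth[::-1]

    record = SequenceRecord(id=seq_id, seq=seq)
    gene = GeneModel(
        gene_id=gene_id, seq_id=seq_id, strand=strand,
        exons=exons_genomic, cds=cds_genomic,
    )

    from .gene_architecture import molecular_weight

    truth = {
        "motif_counts": truth_counts,
        "architecture": {
            "orf_nt": plan.orf_nt,
            "protein_aa": len(protein),
            "mw_kda": molecular_weight(protein) / 1000.0,
            "utr5_nt": plan.utr5_nt,
            "utr3_nt": plan.utr3_nt,
            "n_exons": len(exons_genomic),
            "n_introns": len(exons_genomic) - 1,
            "utr_introns": utr_intron_truth,
            "polya_positions": polya_truth,
        },
        "window_nt": window_nt,
        "strand": strand,
    }
    return Locus(record=record, gene=gene, truth=truth)


# ---------------------------------------------------------------------------
# qPCR / activity / survival datasets
# ---------------------------------------------------------------------------

def generate_qpcr_dataset(
    seed: int | np.random.SeedSequence,
    fold_changes: Mapping[str, Mapping[tuple[str, str], float]],
    noise_sd: float = 0.2,
    n_bio: int = 3,
    n_tech: int = 2,
    reference_gene: str = "rp49",
    baseline_dct: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Long-format Ct table with planted per-cell fold changes.

    Reference Ct ~ N(20, sd); target Ct = reference Ct + baseline dCt -
    log2(fold) + N(0, sd); technical replicates add N(0, sd/2). With
    noise 0 the Livak chain recovers every fold change exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    genes = sorted(fold_changes)
    for g, cells in fold_changes.items():
        for (p, c), f in cells.items():
            if p not in PRIMING_LEVELS or c not in CHALLENGE_LEVELS:
                raise ValueError(f"unknown treatment cell {(p, c)} for gene {g}")
            if f <= 0:
                raise ValueError(f"fold change must be > 0 ({g}, {p}/{c})")
    baseline = dict(baseline_dct or {})
    for g in genes:
        baseline.setdefault(g, 5.0)

    rows = []
    for priming in PRIMING_LEVELS:
        for challenge in CHALLENGE_LEVELS:
            for rep in range(1, n_bio + 1):
                sample = f"{priming}-{challenge}-r{rep}"
                ref_ct = 20.0 + rng.normal(0.0, noise_sd)
                gene_ct = {reference_gene: ref_ct}
                for g in genes:
                    fold = fold_changes[g].get((priming, challenge), 1.0)
                    gene_ct[g] = (
                        ref_ct + baseline[g] - np.log2(fold)
                        + rng.normal(0.0, noise_sd)
                    )
                for g in [reference_gene] + genes:
                    for tech in range(1, n_tech + 1):
                        rows.append(
                            {
                                "sample_id": sample,
                                "priming": priming,
                                "challenge": challenge,
                                "gene": g,
                                "bio_rep": rep,
                                "tech_rep": tech,
                                "ct": gene_ct[g] + rng.normal(0.0, noise_sd / 2.0),
                            }
                        )
    df = pd.DataFrame(rows)
    truth = {
        g: {
            f"{p}/{c}": float(fold_changes[g].get((p, c), 1.0))
            for p in PRIMING_LEVELS for c in CHALLENGE_LEVELS
        }
        for g in genes
    }
    return df, truth


def generate_activity_dataset(
    seed: int | np.random.SeedSequence,
    true_x50: Mapping[str, float],
    protein_mg_per_ml: Mapping[str, float],
    n_points: int = 7,
    hill: float = 2.0,
    a_blank: float = 0.8,
    noise_sd: float = 0.0,
    lowry_slope: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Logistic inhibition curves + Lowry table with known activities.

    Inhibition follows 100 / (1 + (x50/x)^hill); assay amounts span the
    20-80% inhibition range symmetrically (in log amount) so the
    midpoint sits exactly at x50 when ``n_points`` is odd. Noise is
    additive on absorbance readings.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    rng = np.random.default_rng(seed)
    assay_rows, lowry_rows = [], []
    truth: dict[str, dict] = {}
    span = 4.0 ** (1.0 / hill)  # 20% and 80% inhibition amounts are x50 / span, x50 * span
    for conc in np.linspace(0.0, 2.0, 9):
        lowry_rows.append(
            {
                "kind": "standard", "sample_id": "",
                "conc": float(conc),
                "absorbance": float(lowry_slope * conc + rng.normal(0.0, noise_sd)),
            }
        )
    for sample in sorted(true_x50):
        x50 = float(true_x50[sample])
        if x50 <= 0:
            raise ValueError(f"x50 must be > 0 for sample {sample!r}")
        amounts = np.geomspace(x50 / span, x50 * span, n_points)
        inhib = 100.0 / (1.0 + (x50 / amounts) ** hill)
        for x, pct in zip(amounts, inhib):
            a_sample = a_blank * (1.0 - pct / 100.0) + rng.normal(0.0, noise_sd)
            assay_rows.append(
                {
                    "sample_id": sample, "amount": float(x),
                    "a_blank": a_blank, "a_sample": float(a_sample),
                }
            )
        protein = float(protein_mg_per_ml[sample])
        lowry_rows.append(
            {
                "kind": "sample", "sample_id": sample, "conc": float("nan"),
                "absorbance": float(lowry_slope * protein + rng.normal(0.0, noise_sd)),
            }
        )
        truth[sample] = {
            "x50_ul": x50,
            "units_per_ul": 1.0 / x50,
            "protein_mg_per_ml": protein,
            "specific_activity_u_per_mg": (1.0 / x50) * 1000.0 / protein,
        }
    return pd.DataFrame(assay_rows), pd.DataFrame(lowry_rows), truth


def generate_survival_dataset(
    seed: int | np.random.SeedSequence,
    true_probs: Mapping[tuple[str, str], float],
    n_per_cell: int = 35,
    n_experiments: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Binomial survival counts per treatment cell per experiment."""
    if n_per_cell <= 0:
        raise ValueError("n_per_cell must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for priming in PRIMING_LEVELS:
        for challenge in CHALLENGE_LEVELS:
            p = float(true_probs.get((priming, challenge), 1.0))
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"survival probability {p} outside [0, 1]")
            for exp in range(1, n_experiments + 1):
                alive = int(rng.binomial(n_per_cell, p))
                rows.append(
                    {
                        "priming": priming, "challenge": challenge,
                        "experiment": exp, "alive": alive, "total": n_per_cell,
                    }
                )
    df = pd.DataFrame(rows)
    truth = {
        f"{p}/{c}": float(true_probs.get((p, c), 1.0))
        for p in PRIMING_LEVELS for c in CHALLENGE_LEVELS
    }
    return df, truth


# ---------------------------------------------------------------------------
# Default study layout and full bundles
# ---------------------------------------------------------------------------

def default_locus_plans() -> dict[str, dict]:
    """Three loci mirroring the studied genes' topologies and the
    published promoter-element counts (nested half-sites included)."""
    return {
        "soda": {
            "seq_id": "scaffold_34",
            # the reverse ARE plant also spells a reverse hARE, so plant
            # one fewer reverse hARE than the target table shows
            "motif_plan": {"ARE": (0, 1), "hARE": (6, 2), "XRE": (1, 0)},
            "architecture_plan": ArchitecturePlan(
                utr5_nt=326, orf_nt=462, utr3_nt=100,
                introns=((150, 300),), polya_positions=(879,),
            ),
        },
        "sodb": {
            "seq_id": "scaffold_67",
            "motif_plan": {"ARE": (0, 0), "hARE": (0, 2), "XRE": (0, 0)},
            "architecture_plan": ArchitecturePlan(
                utr5_nt=2290, orf_nt=615, utr3_nt=60,
                introns=((400, 2000), (2450, 150), (2650, 120), (2800, 100)),
                polya_positions=(2910, 2936),
            ),
        },
        "sodc": {
            "seq_id": "scaffold_56",
            "motif_plan": {"ARE": (0, 0), "hARE": (2, 3), "XRE": (0, 0)},
            "architecture_plan": ArchitecturePlan(
                utr5_nt=662, orf_nt=684, utr3_nt=36,
                introns=((300, 250), (900, 180)), polya_positions=(1360,),
            ),
        },
    }


def default_fold_changes() -> dict[str, dict[tuple[str, str], float]]:
    """Planted expression responses shaped like the study's outcome:
    soda up after heat-killed-bacteria priming, sodb up only for
    hkBt1/naive, sodc down in every treated cell, atta2 up after any
    challenge."""
    soda = {("hkBt1", "naive"): 2.6, ("hkBt1", "Bt1"): 2.0}
    sodb = {("hkBt1", "naive"): 2.0}
    sodc = {
        (p, c): 0.4
        for p in PRIMING_LEVELS for c in CHALLENGE_LEVELS
        if (p, c) != ("naive", "naive")
    }
    atta2 = {}
    for p in PRIMING_LEVELS:
        atta2[(p, "PBS")] = 3.0
        atta2[(p, "Bt1")] = 8.0
    return {"soda": soda, "sodb": sodb, "sodc": sodc, "atta2": atta2}


def default_survival_probs() -> dict[tuple[str, str], float]:
    """Priming raises survival of infected larvae; controls survive."""
    probs = {}
    for p in PRIMING_LEVELS:
        probs[(p, "naive")] = 1.0
        probs[(p, "PBS")] = 0.95
    probs[("naive", "Bt1")] = 0.60
    probs[("PBS", "Bt1")] = 0.65
    probs[("hkBt1", "Bt1")] = 0.90
    return probs


def _default_activity_plan() -> tuple[dict[str, float], dict[str, float]]:
    """27 samples (9 cells x 3 experiments) with treatment-dependent
    specific activity: high in primed+infected, low in naive/Bt1."""
    units = {  # U/uL extract per treatment cell
        ("naive", "naive"): 0.10, ("PBS", "naive"): 0.10, ("hkBt1", "naive"): 0.11,
        ("naive", "PBS"): 0.16, ("PBS", "PBS"): 0.09, ("hkBt1", "PBS"): 0.10,
        ("naive", "Bt1"): 0.08, ("PBS", "Bt1"): 0.15, ("hkBt1", "Bt1"): 0.16,
    }
    x50, protein = {}, {}
    for (p, c), u in units.items():
        for exp in range(1, 4):
            sid = f"{p}-{c}-e{exp}"
            x50[sid] = 1.0 / u
            protein[sid] = 1.2
    return x50, protein


def generate_bundle(
    seed: int,
    out_dir: str | Path,
    window_nt: int = 1000,
    noise_sd: float = 0.2,
    n_per_cell: int = 35,
) -> dict:
    """Write a complete synthetic study to ``out_dir`` and return truth.

    Files: genome.fasta, genes.gff3, ct.csv, assay.csv, lowry.csv,
    survival.csv, truth.json. One global seed fans out to per-dataset
    sub-seeds through numpy's SeedSequence spawning, so each dataset is
    independently reproducible and the bundle is byte-stable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(seed).spawn(6)

    plans = sorted(default_locus_plans().items())
    locus_seeds = children[0].spawn(len(plans))
    records, genes, loci_truth = [], [], {}
    for (gene_id, entry), locus_seed in zip(plans, locus_seeds):
        locus = generate_locus(
            locus_seed,
            motif_plan=entry["motif_plan"],
            architecture_plan=entry["architecture_plan"],
            gene_id=gene_id,
            seq_id=entry["seq_id"],
            window_nt=window_nt,
        )
        records.append(locus.record)
        genes.append(locus.gene)
        loci_truth[gene_id] = locus.truth

    write_fasta(records, out / "genome.fasta")
    write_gene_models(genes, out / "genes.gff3")

    ct, expr_truth = generate_qpcr_dataset(
        children[1], default_fold_changes(), noise_sd=noise_sd
    )
    ct.to_csv(out / "ct.csv", index=False, float_format="%.6f")

    x50, protein = _default_activity_plan()
    assay, lowry, activity_truth = generate_activity_dataset(
        children[2], x50, protein, noise_sd=0.0
    )
    assay.to_csv(out / "assay.csv", index=False, float_format="%.6f")
    lowry.to_csv(out / "lowry.csv", index=False, float_format="%.6f")

    survival, survival_truth = generate_survival_dataset(
        children[3], default_survival_probs(), n_per_cell=n_per_cell
    )
    survival.to_csv(out / "survival.csv", index=False)

    truth = {
        "seed": seed,
        "loci": loci_truth,
        "expression_fold_change": expr_truth,
        "activity": activity_truth,
        "survival_probability": survival_truth,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return truth
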