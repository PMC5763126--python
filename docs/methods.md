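# Methods

This note documents the models, conventions and numerical choices
behind sodkit, and what the synthetic-data generators do and do not
emulate.

## Coordinate and sequence conventions

All internal coordinates are 0-based half-open; user-facing reports
(motif tables, polyadenylation positions) are 1-based inclusive, the
convention of molecular-biology prose. Sequences are DNA over the
15-letter IUPAC alphabet; lowercase input is uppercased, `U` is
rejected. Reverse complementation is IUPAC-aware (R↔Y, K↔M, B↔V, D↔H,
S/W/N self-complementary) and is an involution, which the property
suite asserts on random strings.

## Degenerate motif scanning

A consensus pattern is compiled to per-position allowed-base sets. A
subject position satisfies a pattern position iff the subject base's
IUPAC set is a **subset** of the pattern's set; consequently a masked
genome base (`N`) matches only a pattern `N` and can never inflate
counts. Scanning is implemented with an overlapping-match (lookahead)
regular expression; correctness is established against an independent
position-by-position brute-force enumerator, which also produces the
truth ledger of the synthetic generator — the two routes never share
code.

Choices where the underlying convention is genuinely open:

- **Window**: counts are taken in the 1,000 nt immediately 5′ of the
  start codon by default (`window_nt` is a config/CLI knob; 2,000 nt is
  the wider span sometimes analysed for such promoters). Windows are
  truncated with a logged warning at contig edges.
- **Overlaps**: all overlapping occurrences are counted. Any
  deterministic overlap-suppression rule is ill-defined for degenerate
  patterns, and raw occurrence counts are the quantity reported.
- **Nesting**: half-sites inside full sites count for both motifs
  (hARE occurrences embedded in a full ARE are included in the hARE
  column). This independence convention is the only one reproducible
  without access to the original scanning code, and the synthetic
  truth is produced by re-scanning, so it is consistent by
  construction.
- **Orientation**: reverse (3′–5′) hits are matches of the
  reverse-complemented pattern, reported in forward-window coordinates
  with strand `-`; count-table columns are labelled `5'-3'`/`3'-5'`,
  motif-major.
- A metal response element (MRE) has no default pattern; it can be
  added through the motif config, since no consensus is fixed here.

## Gene architecture

The mature transcript is the exon splice; the CDS is a single genomic
interval whose endpoints must lie in exons (multi-exon CDSs are
represented by per-exon CDS segments in GFF3, each contained in one
exon — a segment spanning an intron is rejected as malformed). The ORF
convention **includes the stop codon**, so protein length = ORF nt/3 −
1; this is the convention that makes 615 nt ↔ 204 aa and 501 nt ↔ 166
aa consistent. Annotated loci whose stated protein length disagrees
with this arithmetic are reported with a `length_discrepancy` flag
rather than an error, and a spliced CDS that fails translation
(missing start/stop, internal stop, ambiguous codon) yields a
`translation_error` flag with protein length falling back to the
length formula — published annotations contain both situations.

Introns are classified 5′UTR / CDS / 3′UTR by their position relative
to the CDS on the pre-mRNA, in gene orientation. Molecular weight uses
average (not monoisotopic) residue masses plus one water, matching the
"deduced molecular weight" convention. Only `AATAAA` is searched as a
polyadenylation signal by default (the signal string is configurable,
e.g. to add `ATTAAA`); positions are 1-based on the mature transcript
and overlapping occurrences are all reported.

## Relative qPCR quantification

Technical replicates are averaged arithmetically; a spread above 0.5
cycles raises a QC flag but never drops data. The Livak chain is
computed **per biological replicate**: ΔCt(c, r) = Ct_target − Ct_ref,
ΔΔCt(c, r) = ΔCt(c, r) − ΔCt(calibrator, r), RQ = 2^−ΔΔCt, pairing
replicate r with calibrator replicate r because the replicates are
independent experiments; a pooled-calibrator mode
(`per_replicate=False`) subtracts the calibrator's mean ΔCt instead,
and is also the fallback (with a warning) when a calibrator replicate
is missing. The calibrator cell's per-replicate RQ is exactly 1 by
construction. Summaries are mean ± SE (sd/√n) on the RQ scale, the
scale on which such results are plotted. Perfect doubling (base 2) is
assumed in the RQ formula; measured primer efficiencies (E =
10^(−1/slope) from an OLS fit of Ct on log10 quantity) are quality
control only, with E > 1.9 passing. Efficiency-corrected (Pfaffl)
quantification is out of scope.

## ANOVA, Student–Newman–Keuls, Wilcoxon, survival

One-way ANOVA uses the classical between/within mean-square ratio
(computed directly because SNK needs MSE and its degrees of freedom;
agreement with `scipy.stats.f_oneway` is asserted in tests).

The SNK procedure sorts group means, then tests ranges stepwise from
widest (p = k) to narrowest (p = 2): the range spanning groups i..j is
significant when mean_j − mean_i > q(α, p, ν)·√(MSE/ñ); once a range
is non-significant, every pair nested inside it is declared
non-significant without testing (stepwise closure, asserted as an
invariant). For unbalanced groups ñ is the harmonic mean of the two
group sizes being compared, which makes the k = 2 case algebraically
identical to the pooled-variance t-test via q(α, 2, ν) = √2·t₁₋α/₂,ν.

The studentized-range quantile is computed here from first principles:
the CDF is the double integral of the normal-range probability over
the chi-distributed pooled-SD scale, evaluated with Gauss–Legendre
quadrature (200 nodes over z ∈ [−9, 9] for the inner integral, 120
nodes over a ±14σ scale interval for the outer; ν ≥ 10⁶ switches to
the known-scale form) and inverted with Brent's method to 10⁻⁸. The
independent cross-checks are `scipy.stats.studentized_range` and the
√2·t identity, both matched to well below four significant digits.
Under the global null (k = 3, n = 10) the empirical familywise error
rate at α = 0.05 is ≈ 0.05 over 2,000 simulations.

Pairwise Wilcoxon rank-sum tests are exact (full enumeration) when
both groups have n ≤ 8 and there are no ties, and use the
tie-corrected normal approximation otherwise; a from-scratch
enumeration oracle verifies all n ≤ 6 cases in the tests. Raw p-values
are the headline output, mirroring how multiple pairwise tests are
usually reported in this literature; a Holm-adjusted matrix is always
returned alongside. The unit of observation for survival is the
per-experiment proportion (mean ± SE across independent experiments;
a single experiment yields SE 0 with an `se_undefined` flag), with
Wilcoxon tests run on those proportions; individual-level data can be
passed directly if preferred. Survival-time modelling (Kaplan–Meier,
Cox) is out of scope: survival is scored at a single time point.

## Activity assay

Percent inhibition is 100·(A_blank − A_sample)/A_blank, clamped to
[0, 100] with a flag (negative apparent inhibition is assay noise and
must not propagate as negative activity). The amount at 50% inhibition
is found by piecewise-linear interpolation on (amount, inhibition)
after tie-averaging duplicate amounts; the curve must be
non-decreasing and must bracket 50%, otherwise the offending points
are named in the error. Activity is 1/x₅₀ units per amount-unit;
specific activity divides by Lowry-derived protein (OLS line of
absorbance on concentration, inverted at the sample absorbance,
extrapolation flagged). On logistic curves with five points spanning
20–80% inhibition the interpolated x₅₀ is within 5% of truth (worst
case ≈ 1.5% in the acceptance run); a point sitting exactly on 50%
is recovered exactly.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (seed, plan); one bundle seed
fans out to per-dataset sub-seeds via `numpy.random.SeedSequence`
spawning, so every dataset is independently reproducible and
regeneration is byte-identical.

- **Loci**: uniform-ACGT background; accidental motif matches are
  destroyed by single-base substitution at a constrained pattern
  position (full-window rejection sampling is hopeless for a 7-mer
  half-site expected several times per kb per strand), planted
  instances are protected, and the final window is re-scanned with
  the brute-force matcher — **truth is what the re-scan finds**, never
  what the plan requested, so nested and irreducible accidental sites
  are ledgered exactly. Transcripts are UTR5 + (ATG, random sense
  codons, stop) + UTR3 with polyA signals planted at planned
  positions; introns are random sequence inserted at planned
  transcript offsets (no splice-site dinucleotides — splicing is taken
  from the annotation, not predicted). Minus-strand loci are built
  forward and reverse-complemented with coordinates flipped.
- **Default study**: three loci whose exon/intron topologies, UTR and
  ORF lengths and planted promoter-element counts mirror the
  characterised beetle sod genes (the 2-exon/5′UTR-intron gene with
  its polyA signal at transcript nt 879; a 5-exon gene with a ~2 kb
  5′UTR intron; a 3-exon gene), a 3 × 3 priming (naive/PBS/hkBt1) ×
  challenge (naive/PBS/Bt1) factorial with genes soda, sodb, sodc,
  the infection marker atta2 and reference rp49, 3 biological
  replicates in technical duplicate with Ct noise sd 0.2 cycles,
  27 activity samples (9 cells × 3 experiments) on noiseless logistic
  curves, and binomial survival with 35 larvae per cell per experiment
  (≈ the per-cell share of a 960-larva experiment) — primed larvae
  surviving infection at 0.90 versus 0.60–0.65 for controls.
- **Not emulated**: realistic GC content or codon usage, splice-site
  motifs, read-level RNA-seq, amplification-curve fluorescence, or
  inter-plate qPCR batch effects. Passing recovery tests therefore
  demonstrates correctness of the computational chain under the
  assumed noise model, not robustness to every artefact of real data.

## Pipeline determinism

All reports are sorted, floats are formatted with fixed precision, and
the manifest contains the package version, seed and a SHA-256 over the
config *excluding the output directory*, so the same analysis run
twice — anywhere — produces byte-identical reports and manifests. Stage
failures abort with the stage name and a structured log line records
per-stage row counts.

## Known limitations

- The ΔΔCt recovery property "estimate within 2·SE of the planted fold
  in ≥ 90% of simulations" is not attainable with three biological
  replicates: a ±2·(estimated SE) interval has t₂-type coverage
  (≈ 82% normal-theory, ≈ 85% with RQ's lognormal skew) independent of
  the noise scale. The corresponding test asserts the stated bound and
  documents the shortfall; coverage against the estimator's true
  sampling SE is ≈ 95% and is reported by the acceptance script for
  context.
- SNK controls the familywise error rate only under the complete null;
  this is a known property of the procedure, not of this
  implementation.
- Architecture assumes a single isoform per gene model (n_introns =
  n_exons − 1); alternative transcripts are represented as separate
  gene models.
- The activity module starts from absorbance pairs; raw kinetic traces
  and isoform-resolved activity are out of scope.
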