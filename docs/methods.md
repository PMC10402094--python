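# Methods

This note records the models, conventions and numerical choices behind
isobench, and what its synthetic fixtures do and do not show about real
long-read RNA-seq data.

## Coordinates and formats

All internal genomic intervals are 0-based half-open; GTF I/O (1-based,
fully closed) converts at the boundary, making the conversion an
involution by construction. Strand is mandatory on every exon row:
donor/acceptor identity — and with it the NIC/NNC distinction — is
undefined without it, so un-stranded rows are rejected rather than
guessed. A transcript's exons must share one chromosome; "fusion" is a
statement about spanning multiple reference *genes*, not multiple
chromosomes. Missing abundance cells are read as 0 TPM with a logged
count, consistent with the "estimate > 0 means detected" convention used
by PET; negative values are errors, never clamped.

## Structural classification

The classifier assigns exactly one category per model (the categories
partition the submission) via a cascade:

1. **FSM** — the query's intron chain equals a reference chain on the
   same chromosome and strand. The associated reference transcript is
   the chain-match minimizing |dist_TSS| + |dist_TTS|, ties broken by
   lexicographic transcript id (no tie rule is standard; this one is
   deterministic). End distances are signed in transcription direction.
   **RM** requires both |distances| ≤ the window (default 50 nt, a
   configuration parameter).
2. **ISM** — the chain is a *contiguous, proper* sub-chain of some
   reference chain; association as for FSM.
3. Otherwise the same-strand reference genes overlapped by the query are
   counted first: none → **ANTISENSE** (opposite-strand overlap) or
   **INTERGENIC**; more than one gene with exonic contact → **FUSION**;
   exactly one gene → the site test below. Resolving gene multiplicity
   before the site test keeps every category reachable — a literal
   "any novel site → NNC" step run first would absorb all fusion
   transcripts, since the gene-bridging junction is almost never
   annotated.
4. Within one gene: a query with no exonic contact at all is
   **GENIC_INTRON**; else if every donor and every acceptor site is
   annotated (gene-locally by default; a genome-wide site scope is
   exposed as an option, since site catalogs can be read either way) the
   model is **NIC**, otherwise **NNC**. A query exon fully spanning a
   reference intron sets the intron-retention flag; retention with
   otherwise annotated sites is NIC.

Mono-exon models have no chain. The rules are a minimal consistent
extension, deliberately simplified relative to full SQANTI3 behaviour:
containment in a mono-exon reference transcript → FSM; containment in a
single exon of a multi-exon reference → ISM; partial exon overlap →
GENIC_GENOMIC; fully intronic → GENIC_INTRON. Mono-exon models enter UJC
analysis through a span key (exact span by default, optionally quantized
to a bin width), since a junction-free model has no chain identity; this
is an artifact convention, not a community standard.

## Detection metrics

Each truth transcript gets its single best status — RM beats FSM/ISM —
so TP + PTP + FN = n_truth and the positive detection rate unique(TP +
PTP)/n_truth cannot exceed 1. ISM and genic models are neither TP nor FP;
they depress precision only through the submission-size denominator.
Both the printed false *discovery* rate ((n_submitted − #RM)/n_submitted)
and false *detection* rate (FP/n_submitted) are implemented exactly as
defined by the framework they come from, without reconciling them with
the conventional FDR = FP/(TP+FP). Redundancy's numerator is the raw
FSM + ISM model count, including ISMs of truths that also have an RM.
Simulated-mode sensitivity denominators are the known/novel id sets of
the truth annotation, which is expected to contain only transcripts for
which reads were actually generated. Any ratio with an empty denominator
is NA with a reason code — never silently 0 — because averaging NAs and
averaging zeros answer different questions.

SRTM/SNTM support logic: an end is supported if within the window of a
reference TSS/TTS or inside an orthogonal peak (± window); SNTM
additionally requires short-read coverage of every *novel* junction —
annotated junctions inside a novel model are exempt. With no junction
track supplied, SNTM is NA rather than false.

## Quantification metrics

All logs are natural; the replicate transform is log(TPM + 1).

- **SCC** routes through `scipy.stats.spearmanr` (average-rank ties); a
  zero-variance rank vector gives NA.
- **MRD** restricts to θ > 0 (the relative difference is undefined at
  zero truth); matched zeros are excluded, not counted as perfect.
- **NRMSE** uses the I−1-denominator standard deviation of the truth;
  the constant-mean predictor therefore scores √((I−1)/I) exactly.
- **IM** is the mean of CV²_ig over (transcript, group) entries, CV
  computed from log1p values with the sample (R−1) standard deviation;
  entries whose replicates are all zero are excluded (CV is 0/0 there).
- **ACVC** summarizes the CV-vs-mean-log-abundance relationship by
  equal-count binning (default 50 bins) with a median per bin and
  trapezoidal integration over the observed range. This avoids a curve
  smoother and its tuning; absolute ACVC values are comparable only
  within one binning configuration.
- **C(α)** counts replicate pairs on the same side of α; C(0) = 1 and
  C(α > max) = 1 identically. The scalar CM defaults to α₀ = ln 2, i.e.
  a 1-TPM expressed threshold; the default grid is 0 to just past the
  data maximum in 0.1 steps. ACC depends on the grid span, so the curve
  and grid are always reported with it.
- **RE** bins estimates into M = 100 equal-width bins over [0, max]
  (max landing in the top bin); entropy is over occupied bins, so any
  constant vector — including all-zero — scores exactly 0, and M
  singleton bins score ln M. Because bins scale with the maximum, RE is
  invariant to uniform rescaling. Matrix-level RE is the mean over
  replicate columns, on the raw TPM scale.
- **Mixing**: the expected mixture is w·a + (1−w)·b after rescaling both
  samples to the mean of their totals — TPM is compositional, so the
  combination is only meaningful on a common scale, and this choice is a
  no-op for already-matched totals. The weight is recoverable in closed
  form as the least-squares projection of (mix − b) onto (a − b).
- **K-value**: gene exon structures are cut into disjoint segments at
  every exon boundary before building the binary isoform × segment
  matrix, since "exon e" is otherwise ill-defined under partial overlap.
  K = σ_max/σ_min; σ_min below 1e-10·σ_max (or more isoforms than
  segments) returns +∞ — the gene's isoforms cannot be separated by
  coverage at all.
- **Stratified reporting** bins transcripts by true abundance, parent
  gene isoform count, exon count, spliced length and gene K-value, with
  per-stratum MRD min–max normalized within each feature; strata below
  `min_n` = 3 report NA with a note.

An alternative reading of the irreproducibility formula (summing CV
rather than CV²) exists; the default follows the squared form, and the
replicate grouping interprets G as biological sample groups each carrying
R replicates.

## Synthetic data

The generator emulates the *structure* of a benchmarking study, not its
sequencing physics. Genes are non-overlapping, strand-alternating, with
5–9 exons of 100–300 nt and introns of 0.3–2 kb; isoforms of a gene share
the base chain except for one shifted internal acceptor (+12 nt per
variant), giving distinct chains with mostly shared junctions.
Submissions plant categories by construction: FSM copies with ≤ 25 nt end
jitter (inside the 50-nt RM window), 5′ truncations (ISM), internal exon
skips reconnecting annotated sites (NIC), +6 nt donor shifts to
unannotated sites clear of the end window (NNC), plus antisense and
intergenic models placed where they can overlap nothing on their own
strand. Abundances are log-normal (μ = 3, σ = 1.5 on the log scale),
normalized to 10⁶; replicates multiply by exp(ε), ε ~ N(0, σ²) with
σ = 0.1 by default, and renormalize. Everything is driven by
`numpy.random.default_rng([seed, salt])`, so a (seed, config) pair fixes
every output byte.

What passing these fixtures does **not** show: robustness to alignment
artifacts, truncation-length distributions, abundance-dependent noise
(an option exists but is off by default), non-canonical splice sites,
overlapping genes, or mono-exon-rich loci. The fixtures verify the
*metric arithmetic and the classification logic*, not pipeline quality
on real reads — read-level simulation is explicitly out of scope.

## Problem sizes

Tests and examples run on fixtures of 5–70 genes (up to ~500 transcripts)
with 3 replicates — sizes chosen so that every expected value is
hand-checkable or brute-forceable by an independent oracle while the full
suite executes in seconds. The mixing-weight recovery check uses 501
transcripts at noise σ = 0.05, where the least-squares estimator's
sampling error is comfortably below the ±0.02 assertion band.

## Known limitations

- Mono-exon classification is a simplified convention (above).
- Genic-genomic multi-exon models are effectively absorbed by NIC/NNC;
  only mono-exon models land in GENIC_GENOMIC.
- No genome sequence handling: splice-site canonicality, intra-priming
  and RT-switching artifacts are out of scope.
- ACVC/ACC magnitudes depend on binning/grid configuration by design and
  are not comparable across configurations.
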