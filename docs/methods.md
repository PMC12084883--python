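# Methods

This note documents the models, decision rules, parameters and numerical
choices behind `tailscope`, and what the synthetic-data generators do and do
not emulate.

## isomiR assignment and 3′-end classification

**Reference model.** A mature miRNA is anchored at a 0-based offset inside
its pri-miRNA transcript; the pri sequence downstream of the mature 3′ end
is the genomic context for templated/non-templated calls. Sequences are
stored in DNA space (U→T on ingest) because reads arrive as DNA. Loading
requires ≥ `flank_min` (default 8) downstream bases per mature — tails are
analysed up to that length — and mature length ≥ 16 by default.

**Assignment.** A read is assigned by exact match of an internal motif — the
13-mer at mature positions [2, 15), chosen once and exposed in configuration
because motif-based isomiR profilers do not standardise the coordinates —
at the same 5′-anchored position, with the 5′ prefix matching exactly.
Among motif candidates the Levenshtein distance between the read and mature
3′ suffixes (via edlib) must be ≤ `edit_distance_3p` (default 3); ties break
by smaller distance, then lexicographically smaller miRNA name. Reads with
5′-end variation are left unassigned by default (5′ isomiRs are not
analysed); `five_prime_tolerance=1` optionally tolerates a one-base offset.

**Classification.** Against mature m with genomic flank g:

| read | class |
|---|---|
| = m | canonical |
| proper prefix of m | trimmed (trim_len = len(m) − len(read)) |
| m + e, e = g[:len(e)] in full | ambiguous (templated) |
| m + e, any mismatch to g | nt_tail (whole extension reported) |
| prefix(m, k) + e, k < len(m) | ambiguous (shortened-with-extension) |

The *whole-extension rule*: an extension is genomic only when it matches the
flank at every position; one mismatch makes the entire extension
non-templated. The four-class taxonomy is defined on whole tails, so no
templated-prefix/NT-suffix split is attempted; mixed tails land in `nt_tail`
with the full extension recorded. A flank shorter than the extension can
never match in full and therefore yields `nt_tail`.

**Retention.** Per miRNA, an isomiR is kept when its read count ≥ `min_read`
(9) **or** its within-miRNA frequency ≥ `min_ratio` (0.1). OR is the
default because it matches the cited profiler's semantics of rescuing
high-frequency isoforms of rare miRNAs; AND is available. At low depth this
filter preferentially drops rare distinct NT tails, which shifts
read-weighted class fractions — recovery experiments therefore disable it
(`min_read=1, min_ratio=0`) when the quantity of interest is the
classifier's output rather than the profiler's.

## NT-tail statistics

Class fractions are read-weighted by default (population summaries describe
reads); an isomiR-weighted variant exists behind a flag since descriptive
percentages in the literature are often ambiguous between the two.
NT-nucleotide frequencies pool all positions of all NT tails, weighted by
read count. Tail-composition tables bin tails by length (lengths >
`max_len`, default 3, pool into the last bin) and tabulate every tail
k-mer, with mono(A)/mono(U)/mono(C)/mono(G) at length 1 and contains-A vs
A-free at length ≥ 2. Uridine is carried internally as T and relabelled U
only in outputs.

Between-genotype comparisons of per-sample statistics use the two-sided
Mann–Whitney rank-sum test: exact enumeration when n₁+n₂ ≤ 12 without ties,
otherwise the tie-corrected normal approximation. Descriptive panels use
α = 0.05 without multiplicity correction; the differential stages use BH.
With 3 vs 5 samples the smallest achievable exact two-sided p is
2/C(8,3) = 2/56 ≈ 0.0357, reached only under complete separation — group
sizes, not effect sizes, bound the attainable significance.

## Differential accumulation (NB Wald)

A deliberately minimal reimplementation in the DESeq2 mould, *not* DESeq2:

- **Size factors**: median-of-ratios. Reference = per-feature geometric mean
  across samples; factor_j = exp(median over features of log(K_ij) −
  log-geomean_i), over features positive in all samples. For sparse matrices
  (isomiR counts) a poscounts-style reference (geometric mean over positive
  entries, zeros counting in the denominator) is available and used by the
  pipeline. Factors are defined up to the common reference; only their
  ratios are identified.
- **Dispersion**: per-feature method of moments pooled over the two groups,
  `α = Σ(n_g−1)(v_g − m_g·mean(1/s_j)) / Σ(n_g−1)m_g²`, floored at 1e-8.
  No trend fitting or shrinkage.
- **Group fit**: with α fixed, the NB log-link MLE of each group mean solves
  Σ_j (k_j − μ_j)/(1 + αμ_j) = 0 with μ_j = s_j·e^θ; solved by damped Newton
  iteration (30 steps, step clipped to ±5), vectorised over features. Group
  means are floored at 1e-6 to keep all-zero groups finite; their huge
  standard errors make such features non-significant rather than unstable.
- **Wald test**: z = (θ_test − θ_ref)/√(1/I_ref + 1/I_test) with Fisher
  information I_g = Σ_j μ_j/(1+αμ_j), referred to a **t distribution with
  n₁+n₂−2 df**. With ~5 samples per group the plug-in dispersion makes the
  normal reference anticonservative; the t reference keeps the measured null
  type-I rate at ≈ 0.049 (nominal 0.05) in NB simulations.
- **BH** over features with any nonzero count; all-zero features are
  reported with NaN p-values and excluded from adjustment.
- **Calls**: isomiR mode requires padj < 0.05 and |log2FC| > 1; gene mode
  padj < 0.05 only.

Known divergences from DESeq2 (no dispersion trend/shrinkage, no apeglm
fold-change shrinkage, no Cook's outlier handling) are intentional; validity
is demonstrated on synthetic NB data only.

The mono(A)-vs-canonical analysis pairs, per miRNA quantified with both
forms, the KO-vs-WT log2FC of its mono(A)-tailed isomiR (single NT
adenosine) with that of its canonical isomiR, computed on normalized counts
with a 0.5 pseudocount unless supplied from the differential stage, and
reports the Pearson r with a two-sided p (NA with a warning below 3 usable
miRNAs).

## Poly(A) tail-length comparison

Input is the nanopolish-polya TSV dialect (required columns `readname`,
`contig`, `position`, `polya_length`, `qc_tag`; extra columns ignored).
Only PASS and SUFFCLIP reads are analysed; spike-in/carrier contigs can be
excluded by name prefix. Reads are pooled across replicate animals within a
condition (the per-condition read-support rule implies pooling); transcripts
with < 10 reads in either condition are excluded; each remaining transcript
is tested with the two-sided Mann–Whitney rank-sum; BH across tested
transcripts; a significant change requires |median_KO − median_WT| ≥ 5 nt
**and** padj < 0.05.

The unpaired rank-sum is the default deliberately: a signed-rank test is a
paired procedure and read populations from two animals are not paired. A
per-transcript signed-rank variant over matched replicate medians remains a
fidelity option for comparison with descriptions that name the signed-rank.
Global distributions are read-weighted (medians and quartiles over reads,
not over per-transcript medians), optionally restricted to a gene subset
such as DE up/down sets.

## miRNA:target integration

Predicted pairs are filtered to miRNAs with a quantified mono(A) isomiR and
to differentially accumulated target genes. With ≥ 3 matched sample ids
shared by the miRNA and gene matrices, each pair gets the Pearson r of
normalized expression across those samples, classified negative (r < 0) or
positive, undefined when either vector is constant. Without matched samples
— miRNA and mRNA cohorts are often sequenced from different animals — the
classification falls back to log2FC sign concordance (negative when the
fold changes point in opposite directions) and no r is reported. Both modes
are implemented because neither is canonical for unmatched cohorts; outputs
label which was used (`pearson_r` is NaN in concordance mode).

## Synthetic-data generators

All generators are pure functions of (params, seed); cohorts use one RNG
stream per sample, seeded `seed + sample_index`. A JSON truth manifest
(schema version 1) records parameters and realized draws sufficient to
compute every expected downstream summary without re-reading the files.

**Small-RNA reads.** Per sample: per-miRNA abundance is log-normal
(σ = 1.0); each read is canonical (p = 0.55), trimmed (truncated-geometric
trim length, p = 0.35 per step), templated extension copied from the flank,
pure NT tail (per-position i.i.d. from the genotype emission), or — with
small probability (`p_mixed` = 0.02 of the extension branch) — a mixed
one-genomic-base + NT-suffix tail that exercises the whole-extension rule.
Defaults give ≈ 55% canonical, ≈ 26% trimmed and ≈ 10% NT-tailed reads,
with emission (A, C, G, U) = (0.65, 0.06, 0.04, 0.25) in WT and
(0.45, 0.10, 0.05, 0.40) in KO — an adenylation loss compensated by U and C.
Tail lengths follow {1: 0.6, 2: 0.3, 3: 0.1}. Trim and tail lengths are
bounded at 3 nt so every generated read clears the default edit-distance-3
assignment gate; this makes the manifest's expected class fractions exactly
the mixture weights, with an analytic correction for NT tails that coincide
with the flank by chance (classified ambiguous). Emission-recovery
experiments set `p_mixed = 0`: the recovery target is the emission vector,
and mixed tails by construction blend a uniform-composition genomic base
into the NT-classified pool (≈ −0.01 on the A frequency at the defaults).
Qualities are constant `I`; the pipeline ignores them.

Not emulated: sequencing error, adapters, PCR duplication, 5′ variation,
internal editing, correlated (non-i.i.d.) tail emission, trims/tails beyond
the assignment gate, and real miRNA abundance structure. Passing recovery
tests therefore demonstrates correctness of the decomposition and statistics
under the stated generative model, not robustness to artefacts removed by
upstream trimming/QC in real data.

**Poly(A) tables.** Per transcript and condition, read counts are NB
(mean 200, dispersion 0.1) and tail lengths log-normal with median
exp(4.6) ≈ 100 nt and log-sd 0.18; planted transcripts get the KO median
shifted additively (log-mean log(median + shift)). A `qc_fail_rate`
fraction of rows carries a non-PASS tag; passing rows are PASS (85%) or
SUFFCLIP (15%). The defaults are calibrated so that a planted −10 nt median
shift at the stated read support is reliably detectable under the
≥ 5 nt + padj rule (measured detection ≈ 0.97); real direct-RNA
per-transcript spreads are wider, so detection rates on real data will be
lower at equal coverage.

**Count matrices.** NB counts with log-normal base means (log2 mean 7,
sd 1.5), log-normal library-size factors (log-sd 0.15, recorded in the
truth), planted genes with exact mean ratio 2^log2FC, dispersion supplied
by the caller (0.05 in validation).

**Repressive pairs.** gene = c − a·miRNA + ε with a ∈ [0.5, 2], multiplicative
log-normal sample variation on the miRNA, and ε of SD 0.1 × signal SD —
planted inverse regulation for the sign-classification check.

## Numerical and bookkeeping choices

- Coordinates 0-based half-open throughout; DNA alphabet internally.
- Deterministic ordering everywhere: collapsed reads by (count desc, seq);
  profile records by (miRNA, count desc, seq); transcripts and features
  sorted by id. All stages are invariant to input order.
- Dispersion floor 1e-8, group-mean floor 1e-6 (sparse isomiR counts).
- Empty inputs: empty FASTQ → empty profile with a warning; empty profile →
  `EmptyProfileError`; profile without NT tails → distinct `NoNTTailsError`;
  no transcript passing the poly(A) support filter → empty result with a
  warning; < 3 usable miRNAs/samples for a correlation → NA with a warning.
- The pipeline writes a provenance header (version, config hash, seed) on
  every TSV; reruns with an identical configuration are byte-identical.
  Configuration is a single YAML file with unknown keys rejected; CLI flags
  override it.

## Validation problem sizes

The test suite validates at: exhaustive 3′-variant enumeration (1365 distinct
sequences) for the classifier oracle; 200 random profiles for normalization
invariants; 100 seeded 3-vs-5 cohorts at 10⁵ reads/sample for emission
recovery and rank-sum power; 50×(2000 features, 5v5) null and 100× planted
8-fold NB simulations for differential calibration; 100 seeded poly(A)
datasets (20 transcripts, ~200 reads/side) plus a 200-permutation null for
the tail-length rules; and 100 seeded sets of 20 repressive pairs for the
integration stage. `scripts/acceptance.py` recomputes the same quantities
(some at 50 seeds) in about a minute.

## Known limitations

- The NB stage is not a DESeq2 substitute on real data: no dispersion
  shrinkage means noisier calls at very small n than DESeq2 would give.
- Whole-extension classification deliberately refuses to split mixed tails;
  datasets rich in long templated-prefix tails will show inflated NT-tail
  A/G content relative to a split-based classifier.
- 5′ isomiRs are out of scope; 5′-shifted reads are unassigned by default.
- The integration stage's concordance mode conflates correlation with fold
  change when cohorts are unmatched; it is labelled, not hidden, in output.
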