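# Methods

This note documents the models, conventions and numerical choices behind
`oryzarray`, in the order the pipeline runs.

## Probe design

Coordinates are 1-based inclusive on the mRNA sense strand; probes are
stored in transcript sense (reverse-complementing for synthesis chemistry is
out of scope).

*3' window.* "Within 1,200 nt of the 3' terminus" is interpreted as a
constraint on the probe's **last** base: every candidate's 3' end must lie in
the final `window` nucleotides (equivalently end ≥ L − window + 1). The
rationale is the 3' bias of labeled aRNA: the informative coordinate is
where the probe stops, not where it starts. Transcripts shorter than the
window simply use their full length; transcripts shorter than one probe
(60 nt) yield no candidates.

*Filters.* A candidate passes iff it passes every filter; the recorded
verdict names the first failure in the fixed order N-content, window, GC,
repeat, self-complementarity, but the pass/fail outcome is provably
order-independent (tested on 10,000 random 60-mers). Conventions:

- **GC**: (#G + #C)/60, bounds 0.40 and 0.60 both inclusive.
- **Simple repeats**: the longest run, in nucleotides, that is either a
  homopolymer or a tandem dinucleotide repeat (period 2, two distinct
  letters). Runs of 6 nt or more fail (`max_repeat` = 5). This is the
  standard low-complexity reading of "fewer than 6 simple nucleotide
  repeats"; the threshold is exposed in `DesignParams`.
- **Self-complementarity**: the length of the longest segment whose reverse
  complement also occurs in the probe — equivalently the longest common
  substring of the probe and its reverse complement — computed exactly by
  dynamic programming. This is a hairpin-stem proxy chosen to be
  alignment-style, dependency-free and brute-force-verifiable; full RNA
  folding is deliberately out of scope. Default cutoff 15 nt. A palindromic
  segment (its own reverse complement, e.g. `ACGT`) counts at full length;
  a homopolymer has score 0 because its reverse complement never occurs.
- **N**: allowed in input transcripts, but any candidate window containing
  N is discarded at enumeration time.

*Selection.* Among passing candidates the probe with the smallest distance
to the 3' end wins; ties break by |GC − 0.5|, then by smaller start
coordinate, making selection invariant to input order. Exactly one probe
per gene is retained; keeping alternates is not modeled.

## Specificity classification

BLAST is replaced by an internal seed-and-extend matcher so the
classification is self-contained and exactly testable. Candidate windows are
genome positions sharing at least one exact `seed_len`-mer (default 16) with
the probe, on either strand; each window is scored by ungapped end-to-end
comparison and accepted at ≥ `min_matches` of 60 identical bases (default
47, ≈ 78% identity, in the spirit of conventional cross-hybridization
rules — the original platform's alignment cutoffs are not public, so these
are explicit, configurable conventions). Accepted windows are deduplicated
and windows within 59 nt on the same contig and strand are merged into one
locus, keeping the best-matching position, so a single genomic site is never
counted twice.

Seeding is a heuristic: a window at exactly 47/60 can break every 16-mer, so
rare low-identity hits can be missed. `seed_len=1` degenerates to an exact
all-offsets scan; the test suite bounds the heuristic's miss rate on
synthetic data and verifies the exact mode against an independent
one-hot-correlation scorer.

Hit counts collapse to none (0) / unique (1) / multiple (≥ 2) per genome and
the (japonica, indica) pair maps to groups A–G. The two status pairs with no
place in the seven-group scheme — (none, none) and (none, multiple) — map to
UNASSIGNED rather than inventing membership; in the published scheme indica
multi-hit probes occur only in groups that also hit japonica.

## One-channel intensity pipeline

- **Detection**: flag must be `good` and SNR = foreground/background ≥ 2
  (configurable); zero background with a good flag counts as detected.
- **Normalization**: value = max(foreground − background, 1); each array is
  scaled by (reference median / its detected-spot median) with the reference
  being the median of per-array medians. The equal-median invariant holds to
  1e-9 relative tolerance and is asserted in tests.
- **Replicate QC**: pairwise Pearson r of log2 intensities over spots
  detected in both arrays; pairs with fewer than 3 common spots are reported
  missing.
- **Ratios and p-values**: the original platform used a proprietary
  error-weighted model; here the log2 ratio is the inverse-variance-weighted
  mean of all pairwise log2 differences, which for equal-variance technical
  replicates reduces to mean_A − mean_B (the implemented form), and the
  p-value is a two-sided Welch t-test on the detected log2 intensities
  (≥ 2 detected arrays per side required). Probes detected in only one
  tissue are compared against the intensity floor (log2 = 0): the ratio uses
  the floor for the missing side, and when the detected side covers at least
  half of its arrays the p-value is a one-sample t-test against the floor;
  such present/absent calls carry a `one_sided_detection` flag. Probes with
  a single detected replicate on one side get a ratio but no p-value and are
  never called significant.
- **DE calling**: up iff log2 ratio ≥ 1 and p < 0.05 (fold inclusive, p
  strict), down symmetric; no multiple-testing correction by default (the
  validation design used raw p < 0.05), Benjamini–Hochberg behind a flag.
- **Tissue-specific calling**: no published definition exists, so the
  toolkit uses an explicit detection-based one, labeled as such in outputs:
  significant in the right direction, detected in ≥ ⌈n/2⌉ arrays of the
  expressed tissue and 0 arrays of the other.

## Enrichment reporting

One-sided Fisher exact p-values are standard hypergeometric upper tails;
the DAVID service's modified Fisher (EASE) statistic is intentionally **not**
reimplemented — it depends on hosted, version-specific background sets — so
published enrichment p-values are context only, while the count/percentage
arithmetic of the report format is reproduced exactly. Percentages round
half-up to 2 decimals to match the printed report convention. The bundled
report fixture includes a block whose printed cluster size (438) disagrees
with the accompanying text's count of root-specific genes (463); its
percentages recompute from 438, and the toolkit always computes against the
caller-supplied cluster size.

## qPCR concordance

ΔCt = mean Ct(target) − mean Ct(reference) per tissue over replicates;
ΔΔCt = ΔCt_A − ΔCt_B; log2 fold = −ΔΔCt. Pearson r between paired array and
qPCR log2 ratios uses the t transform with n − 2 df for its p-value. The
bundled 66-gene panel stores log2 values rounded to 2 decimals, so the
recomputed correlation is compared at ±0.01 to absorb rounding relative to
raw instrument values; whether the published figure was computed before or
after rounding is unknowable.

## Synthetic data generator

The generator emulates the validation study design: two genomes derived from
a common ancestor by independent per-base substitution (default 2%), with
per-genome verbatim duplications (10%) planting multi-hit probes and
single-genome deletions (10%, side chosen 50/50 or pinned via
`absent_genome`) planting the asymmetric groups; genes are embedded in
random spacer sequence (200 nt) on one contig per genome. Divergence is
applied before duplication, so paralogs are identical — a documented
simplification that makes dup-derived truth exact at any identity threshold.
Transcripts carry the japonica-version sequence regardless of presence in
the japonica genome, mirroring probes designed from a curated transcript
list.

Arrays follow a log-normal intensity model chosen because the analysis
operates on log2 intensities: per-probe baseline log2 intensity
~ Normal(10, 1.5), a `de_fraction` (default 10%) of probes shifted by
±2 log2 units in the shoot tissue (half up, half down), replicate noise
~ Normal(0, 0.3) on the log2 scale, foreground = 2^signal plus an additive
background ~ Normal(100, 10) truncated at 0, all flags good. Five technical
replicate arrays per tissue is the default, matching the validation design.
All randomness flows through one seeded generator; identical configs produce
byte-identical files (array paths in the sample sheet are relative so runs
are relocatable and comparable).

What the generator does **not** emulate: realistic rice base composition,
spatial artifacts, scanner saturation, flag heterogeneity, and
probe-sequence-dependent hybridization efficiency. Passing tests therefore
demonstrate the correctness of the computations under the stated model, not
the platform's wet-lab performance; published catalog-scale figures
(probe counts, genome coverage counts, DE counts on the deposited raw data)
require the original genome databases and raw intensity files and are
documented as context, not recomputed.

## Problem sizes and tolerances

The test and acceptance workloads use 2,000 probes × 10 arrays for the
end-to-end expression study (recovery ≥ 90%, null type-I 0.05 ± 0.02 —
with ~1,800 null probes the Monte-Carlo standard error of the type-I
proportion is ≈ 0.005), a 50-kb genome × 100 probes for matcher/oracle
equivalence, 10,000 random 60-mers for filter order-independence, and
150–200 genes for genome-truth agreement. Floating-point conventions: the
normalization invariant is asserted at 1e-9 relative tolerance; Welch
p-values on degenerate (zero-variance) inputs are NaN and never significant;
percentage rounding uses decimal half-up, not banker's rounding.

## Known limitations

- The matcher is ungapped; indel-containing cross-hybridization sites are
  not modeled (the published pipeline's aligner settings are unknown).
- One probe per gene; multi-probe genes are collapsed by the caller.
- The error model behind the published per-probe p-values is proprietary
  and unrecoverable; only the threshold semantics (|log2| ≥ 1, p < 0.05)
  are faithful.
- Control-probe categories (hybridization controls, ladders, negatives) are
  annotations only; no sequence rules are modeled for them.
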