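# Methods

This note documents the statistical procedures, the synthetic study the
package generates, the numerical choices, and the limits of what the tests
demonstrate.

## Study design being modelled

The analysis targets a bulk study of cultured endothelial cells under
seven expression arms — control (normal glucose), high glucose (HG),
memory (transient HG followed by normal glucose), each of HG/memory with
sulforaphane (SF), and HG/memory under NRF2 overexpression (OE) — with
three RNA replicates per arm, plus four accessibility arms (control, HG,
memory, memory+SF) with two ATAC replicates per arm. All contrasts are
treatment versus the shared control. "Memory" features are those still
differential after glucose normalisation; "restored" features are baseline
differential features that lose their call under an intervention.

## Differential expression: NB moment/Wald test

The test is a deliberately transparent stand-in for shrinkage-based NB
GLM packages, designed so that every quantity is auditable and so that
planted-truth recovery, not numerical equality with any particular tool,
defines correctness.

- **Normalisation.** Median-of-ratios size factors over features with
  all-positive counts, rescaled to geometric mean 1. If no feature
  qualifies the function raises rather than silently switching reference;
  the caller decides how to proceed.
- **Dispersion.** One pooled α per contrast with Var = μ + αμ². Per
  feature, the pooled within-group variance (n_A + n_B − 2 df) and the
  mean normalised count give the moment statistic (v − ȳ)/ȳ²; the global
  estimate is the **mean** over features of max(0, ·). A quantile of this
  statistic would sit systematically below the target at two or three
  replicates — the per-feature sampling distribution is strongly
  right-skewed (the median of a 4-df variance estimate is ≈ 0.84 of its
  mean), which would shrink the standard error and inflate |z| enough to
  break null calibration. The mean is asymptotically unbiased here, and
  the max(0, ·) truncation adds a slight conservative bias at low counts.
  Monte-Carlo checks at fixed seeds show the null p < 0.05 fraction within
  3 binomial SE of 0.05 under this choice.
- **Effect and test.** log2FC uses a pseudo-count of 0.5 in both group
  means so it stays bounded for zero groups. The Wald SE is the delta-
  method variance of a log2 ratio of NB means, with group means floored at
  the pseudo-count; two-sided normal p; BH over tested features. Features
  with zero counts in every sample are excluded from BH (reported with
  p = padj = 1, log2FC = 0) — an independent-filtering analogue.
- **Calls.** DEG ⇔ padj < 0.05 AND |log2FC| > 0.5, strict inequalities.
  Direction is the sign of log2FC.

Size factors are estimated within the two contrasted groups' samples, so a
contrast's result does not depend on unrelated arms in the same matrix.

## Differential accessibility: exact Poisson test

Replicates are pooled within condition and scaled to tags per 10 million
of the condition's pooled library. The reference rate is floored at 1.0
normalised tag (bounded fold, defined tail); the observed count is ceiled
to the integer support. The gain tail is P(X ≥ ⌈treat⌉ | λ = ref) and the
loss tail swaps the roles; scipy's survival function evaluates the exact
tail (verified against arbitrary-precision summation to 1e-12 relative
error for λ ≤ 1e4). DAR ⇔ fold > 1.5 in one direction with that
direction's tail p < 1e-4. Pooling replicates (rather than a
replicate-aware variant) is an explicit design choice and is logged; the
fold uses the normalised pooled counts with no pseudo-count beyond the
λ floor. The test treats pooled counts as Poisson; biological
overdispersion between replicates is intentionally not modelled, matching
the tag-count test this stands in for.

## Consensus peaks, annotation, enhancers, linkage

- **Consensus**: a first-replicate peak is kept iff it overlaps ≥ 1 bp a
  peak in *every* other replicate; the kept interval is the merged span of
  seed and partners; overlapping spans are merged afterwards so consensus
  sets are non-overlapping.
- **Annotation** assigns one class per region by its midpoint with
  precedence promoter > exon > intron > intergenic; the promoter window is
  the strand-aware TSS−1000..TSS+100. Midpoint (not any-overlap)
  assignment keeps classes a partition, matching pie-chart semantics.
- **DAE**: a DAR overlapping ≥ 1 bp of at least one H3K4me1 peak and at
  least one H3K27ac peak. "Enriched with both marks" is read as peak
  co-overlap, not a signal-intensity threshold.
- **Linkage**: features are assigned to the TAD containing their midpoint
  (half-open); TADs must be non-overlapping. Candidate targets default to
  the *intersection* of the HG and memory DEG sets (configurable to the
  union). A DAE with several targets counts once in the concordance
  summary, concordant if any link is concordant — the denominator is DAEs
  with at least one candidate target.

## Restoration and report semantics

Restored = baseline \ intervention, remaining = baseline ∩ intervention,
computed on call sets against the shared control. By default the
intervention's direction is not examined ("remained differentially
expressed" semantics); a stricter direction-aware variant (the remaining
feature must keep its baseline direction) is available behind a flag.
Every percentage in the report is an integer percent rounded half away
from zero, and the report validator recomputes each one from its own
numerator and denominator, plus the partition identities
(shared + unique = total; restored + remaining = baseline; up + down =
DARs). The report contains configuration, seeds and thresholds but no
wall-clock fields; timestamps go to the log stream, so identical inputs
give byte-identical reports.

## Motif scanning and enrichment

PFM counts → probabilities with pseudocount 0.25 per base; log-odds
against the background (uniform by default); both strands scanned; ZOOPS
hit at ≥ 0.8 × the motif's maximum achievable score (configurable).
Enrichment is the hypergeometric upper tail of target hits given pooled
target+background hits, BH-adjusted across motifs. When no background is
supplied, a seeded dinucleotide shuffle (Altschul–Erickson Eulerian-path
resampling, 3× the target count) preserves base and adjacent-pair
composition — a GC/dinucleotide control that needs no external data. This
scanner is intentionally simple: no de-novo discovery, no CpG-matched
background selection.

Promoter windows are extracted strand-aware and reverse-complemented for
minus-strand genes; enhancer windows are peak-center ± 50 bp. Windows are
clipped to chromosome bounds with a warning.

## Synthetic study generator

The generator is first-class, tested code; its defaults *are* the study
conditions.

- **Genome**: 2 chromosomes × 4 Mb, each tiled back-to-back by 100 TADs
  (40 kb) — sub-megabase domains at a density that leaves roughly one
  shared DEG per TAD, so linkage is sparse rather than saturated. 2,000
  genes (1–6 kb, short 100–300 bp exons) and 2,000 candidate 400 bp
  regions; candidate regions never overlap a promoter window or each
  other, so planted accessibility changes are intrinsically non-promoter.
- **Expression truth**: planted classes shared_up/down (120/80),
  HG-unique (40/20), memory-unique (30/20), |log2FC| = 2; 50 % of each
  class is SF-restored and 75 % OE-restored (the intervention arm's
  planted lfc returns to 0). Baseline means U[100, 1000], NB dispersion
  0.05, per-sample size factors U[0.8, 1.25]. Seven arms × 3 replicates =
  21 samples.
- **Accessibility truth**: classes hg_up (60), hg_down (20), memory_up
  (persistent, 30), sf_restored (90), |lfc| = 1 (fold 2); baseline means
  U[200, 600] per replicate (pooled mean ≥ 400), NB dispersion 0.003 —
  near-Poisson region counts, consistent with the pooled Poisson test's
  assumption and with a stable-region false-call rate below 1e-3 at the
  1.5-fold/1e-4 thresholds. Half of each non-stable class is
  enhancer-flagged and co-marked by both histone marks; 20 unplanted
  regions are chance co-marked and equal numbers singly marked. Replicate
  peak sets jitter each region by ±30 bp and add 5 % non-reproducible
  noise peaks, which consensus removes.
- **Coordinated concordance**: with probability 0.8 an enhancer-flagged
  planted region is drawn from the TAD of a same-direction planted shared
  DEG; otherwise it is placed at random. This wires in the
  enhancer–target concordance that the linkage stage is meant to recover
  without any shared code path.
- **Sequences**: uniform random bases; the configured consensus (default
  bZIP core TGACTCA; IUPAC degeneracies allowed, e.g. TGASTCA) is embedded
  at rate p_target = 0.8 in planted down-gene promoters and enhancer
  centers, random strand, degeneracies resolved at random. The PFM library
  is the planted motif plus four decoy consensi (GC-box, E-box, GATA,
  CCAAT).
- **Determinism**: one `numpy` generator seeded from the config drives
  every stage in a fixed order; a fixed seed gives byte-identical files.

What the generator does **not** emulate: read-level noise, fragment-length
and GC biases, peak-caller artefacts, correlated gene programs,
heterogeneous per-feature dispersions, signal-intensity gradations of
histone marks, or Hi-C contact frequencies (TADs are consumed as
coordinates). Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under the stated model, not
end-to-end fidelity to any particular sequencing dataset.

## Problem sizes and numerical choices

Tests run the full default design (2,000 genes / 2,000 regions / 8 Mb
genome) for recovery checks and a proportionally scaled-down design (400
genes / 300 regions / 2 Mb) for unit tests; the complete suite and the
acceptance script each finish in well under a minute on one CPU. Tie-break
and degenerate-input rules: percentages with zero denominators are NA
(None), all-zero features get p = 1 by convention, a feature whose
midpoint falls outside all TADs is unassigned, unknown chromosomes
annotate as intergenic with a warning, empty replicate peak sets yield an
empty consensus with a warning, and motif enrichment refuses a background
that shares ids with the targets.

## Known limitations

- The DE test uses one pooled dispersion; strongly feature-specific
  overdispersion would mis-calibrate tails (real data would call for a
  per-feature shrinkage estimator).
- The Poisson accessibility test ignores replicate variability by design;
  with more replicates a count-model test would be preferable.
- Midpoint TAD assignment gives a single domain per feature; features
  spanning a boundary are not split.
- The ZOOPS scanner reports hit/no-hit per window set; it does not model
  occurrence counts or positional preference.
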