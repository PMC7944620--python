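# Methods

## Model and procedure

`triadtrack` analyses homoeolog bias within wheat gene triads — sets of
three syntenic genes with a 1:1:1 correspondence across the A, B and D
subgenomes — for histone-modification ChIP (H3K4me3, H3K27me3) and RNA
assays across a panel of tetraploid and hexaploid genotypes.

1. **Quantification.** Gene-level read counts are converted to TPM:
   `TPM_g = 1e6 · (c_g/L_g) / Σ_h (c_h/L_h)` with lengths in kilobases.
   The denominator universe is every gene in the supplied count table,
   so library normalisation precedes triad subsetting. Replicates are
   combined by the arithmetic mean of TPM (configurable to
   single-replicate analysis); TPM columns sum to one million by
   construction.
2. **Bias classification.** Within each triad only the A and B
   homoeologs enter (the D copy is deliberately excluded even in
   hexaploid genotypes, where the question is how the AABB component
   behaves). The pair is normalised to `rel_A = a/(a+b)`,
   `rel_B = 1 − rel_A`, and the triad takes the category of the nearest
   Euclidean anchor among (0.5, 0.5) → A=B, (1, 0) → A>B and
   (0, 1) → A<B. Because rel_A + rel_B = 1, this reduces to thresholds
   at rel_A = 0.25 and 0.75; both the anchor-distance form and the
   boundary form are asserted against each other in the tests. A triad
   is *modified* (or *expressed*, for RNA) when either homoeolog is
   strictly above τ = 0.5 TPM; triads below threshold carry no
   category. Category assignment is scale-invariant; the modified
   filter intentionally is not (absolute τ).
3. **Series tracking.** Per-triad categories over a three-genotype
   series collapse to four transition classes. Domestication
   (WTW → DTW → ETW), Group labels: I `c1=c2=c3`; II `c1≠c2, c2=c3`;
   III `c1≠c2, c2≠c3`; IV `c1=c2, c2≠c3`. Ploidy transition
   (TAA10 → ETW → XX329), Pattern labels: I all equal; II `c1≠c2,
   c1=c3` (reversible, strictly D-genome dependent); III `c1=c2, c2≠c3`
   (appears only on D reintroduction); IV `c1≠c2, c2=c3` (extraction
   change that persists). A triad unmodified in any series genotype is
   `not_tracked` and excluded from denominators.
4. **Statistics.** Subgenome asymmetry among biased triads uses the
   exact two-sided binomial test at p₀ = 0.5 (minimum-likelihood
   two-sided rule). Between-category and concordance comparisons use
   the pooled two-proportion chi-square with Yates continuity
   correction (capped at the observed difference, matching the standard
   corrected test). Modification-level comparisons use Wilcoxon
   rank-sum with an exact enumeration path (dynamic programme over the
   rank-sum distribution) for combined n ≤ 16 without ties, otherwise a
   normal approximation with tie and continuity corrections. GO
   enrichment is upper-tail hypergeometric with Benjamini–Hochberg FDR
   over all tested terms, significant at q < 0.05.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| τ (modified threshold) | 0.5 | TPM | strict `>`; applied per homoeolog |
| tie order at rel_A ∈ {0.25, 0.75} | A=B first | — | conservative toward the dominant balanced class |
| replicate aggregation | mean | — | per-replicate mode available |
| α (tests) | 0.05 | — | two-sided throughout |
| q threshold (enrichment) | 0.05 | — | BH-adjusted |

## The synthetic-data generator

The generator is first-class, tested code: it emits the exact file
contracts the readers consume (count TSVs, triad table, BED gene
coordinates, zone partition) plus the planted truth. Its defaults are
the emulated study conditions and are not tuned per run:

- 17,753 triads at full scale (the reference triad count); genes on a
  synthetic genome of 7 chromosome groups × 3 subgenomes, 100 Mb each,
  partitioned into R1/R2a/C/R2b/R3 at 15/30/10/30/15% of length.
- Per-marker modified-triad fractions 0.814 (H3K4me3), 0.505
  (H3K27me3), 0.90 (RNA); a triad is modified in every genotype of a
  run or in none, which keeps per-line and union denominators equal
  and recoverable.
- First-genotype category proportions (A=B, A>B, A<B):
  (0.894, 0.068, 0.038) for H3K4me3, (0.849, 0.088, 0.063) for
  H3K27me3, (0.805, 0.117, 0.078) for RNA — the A>B share exceeds A<B,
  reproducing A-subgenome dominance.
- Transition-class frequencies per series and marker (e.g. Group I
  0.883 / 0.709, Pattern I 0.961 / 0.767 for H3K4me3 / H3K27me3).
  Planted counts use largest-remainder rounding of n·π, so truth
  frequencies are exact and frequency-recovery tests are deterministic.
- Signal: a triad's combined A+B TPM is 2μ·exp(σZ − σ²/2) with
  μ = 50 TPM, σ = 1, Z truncated at −2.5; biased triads draw the
  favoured homoeolog's rel uniformly in [0.80, 0.95], balanced triads
  in [0.45, 0.55]; unmodified homoeologs draw uniformly in
  [0.01, 0.2] TPM. Modified triads are floored at 20 TPM combined so
  planted categories remain recoverable at finite sequencing depth.
  Mean signal is scaled by compartment (distal:interstitial:proximal
  3:2:1 for H3K4me3, 2:1.5:1 for H3K27me3) to reproduce the distal
  enrichment gradient.
- Counts: expected count ∝ planted TPM × gene length, scaled to a
  library of 10⁶ reads per 1,000 triads (floored at 10⁶); replicate
  noise is negative-binomial with per-marker dispersion φ
  (var = m + m²/φ): φ = 200 (H3K4me3), 12 (H3K27me3), 40 (RNA). These
  defaults were fixed once by Monte-Carlo so that replicate TPM Pearson
  correlations under the default signal spread emulate the observed
  replicate concordance of the two markers (≈0.99 and ≈0.91);
  `noiseless=True` emits rounded expectations instead.
- RNA transition labels copy the H3K4me3 label with probability 0.5
  (triads modified in both assays), planting the
  modification–expression concordance that the concordance module is
  designed to detect; H3K27me3 is left uncoupled.
- All randomness flows from one `numpy` Generator seeded by the config;
  identical configs give byte-identical output files.

What the generator does **not** emulate: read-level artefacts
(mappability, GC bias, input-control background), between-genotype
library-depth imbalance, spatial autocorrelation of chromatin domains
beyond the three-compartment gradient, partial modification (a triad
modified in some genotypes only), and D-homoeolog bias structure (the D
copy gets balanced signal in hexaploids, since A/B classification
ignores it). Passing tests therefore demonstrate correctness of the
pipeline's arithmetic, rules and statistics under a faithful
statistical skeleton of the data — not robustness to alignment- or
protocol-level artefacts in real ChIP-seq.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open internally; GFF3 is shifted on
  read. Gene position for zone lookup is the midpoint
  `floor((start+end)/2)`.
- Ties at rel_A exactly 0.25/0.75 go to A=B (then A>B); distances are
  rounded at 1e-12 before argmin so float noise cannot flip a tie.
- Both homoeologs zero → relative signal undefined → unmodified.
- Zero-variance replicate columns: Pearson r reported missing with a
  warning. Degenerate pooled proportions (0 or 1): p = 1 with a
  warning. Zero biased triads: the binomial test refuses rather than
  fabricating a p-value.
- Ploidy-series triples with all three categories distinct match none
  of the four verbal class definitions; they are labelled III and
  flagged `double_change` so they can be counted separately.
- The concordance null-calibration check runs the proportion test
  without the Yates correction: the corrected statistic is
  intentionally conservative, so calibration is a property of the
  uncorrected chi-square. The correction remains the default for
  substantive comparisons.
- The exact binomial test is discrete: at n = 200 its achievable size
  at nominal α = 0.05 is ≈ 0.040, which is what the calibration
  measurement reports.

## Scale of the shipped analyses

The acceptance run uses the full 17,753-triad scale for both series
(seconds on one CPU). Property suites use 800–10,000 triads: noiseless
recovery at 10,000, calibration with 10⁴ null draws and 300 independent
concordance tables, dispersion-degradation on an 800-triad grid. These
sizes were chosen as the smallest that make the stochastic assertions
stable.

## Known limitations

- "Statistically equal" is operationalised purely as nearest-anchor
  assignment; no secondary significance test (e.g. replicate-agreement
  requirement) is layered on the category call.
- Only the A/B two-homoeolog scheme is implemented, not the
  seven-category ternary classification used elsewhere for full A/B/D
  triads.
- TPM uses annotated gene-body length, not exon-union length; with
  precomputed gene-level counts the distinction is unresolvable here.
- Between-sample normalisation beyond TPM (TMM, quantile) is out of
  scope, as is peak calling, alignment and BAM handling.
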