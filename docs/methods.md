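# Methods

## Model

Each local splice event has two isoforms. For sample *n*, the isoform-1 read
count I_n out of the total T_n = I₁ + I₂ covering the event is modeled as
beta-binomial:

    p_n ~ Beta(ω ψ, ω (1 − ψ)),    I_n | T_n ~ Binomial(T_n, p_n)

where ψ ∈ (0, 1) is the expected percent spliced in (PSI) and ω = α + β is the
beta concentration. The binomial layer accounts for measurement noise at the
observed depth, so low-coverage samples are automatically down-weighted; the
beta layer absorbs biological PSI variation between samples. Samples with
T_n = 0 contribute a log density of 0 (the empty trial is certain) and are
excluded from the count of informative samples.

All beta-binomial densities and tail probabilities are evaluated in log space
through log-gamma functions; tails are summed exactly over the discrete
support with `logsumexp`, so scores remain finite at any count.

### Differential test

The one-group model fits (ψ_A, ω_A) to the pooled samples; the two-group model
fits (Ψ₁, Ψ₂, ω_G) with the concentration shared between groups. The reported
statistic is

    LR = ℓ_two-group − ℓ_one-group,

the improvement in total log likelihood, non-negative at the optimum because
the models are nested. No χ² calibration or multiple-testing correction is
applied: the intended operating mode is ranking by LR with a fixed threshold
(default 8). Events are scored only when each group has at least two covered
samples; otherwise they are flagged `insufficient`.

### Outlier score

For each event the isoform with mean PSI < 0.5 across the covered reference
samples is labeled *minor* (ties, exactly 0.5, resolve to isoform 1; the
orientation is decided on the reference only and applied unchanged to test
samples). A beta distribution constrained to be strictly decreasing on [0, 1]
— α_R ∈ (1/β_M, 1], β_R ∈ (1, β_M] — is fitted to the minor-isoform counts.
When the reference contains no minor reads at all, the likelihood has no
interior optimum and the closed form α_R = 1, β_R = min(β_M, Σ T_n) is used.

A test sample with minor count I_s of T_s is scored by the upper tail of its
minor count under the fitted beta-binomial:

    score = −log₁₀ P(X ≥ I_s),    X ~ BetaBinomial(T_s, α_R, β_R).

**Log base.** The score is defined in base 10, so the default cutoff of 10
corresponds to a tail probability of 10⁻¹⁰ and the score reads as the number
of zeros in a p-value-like quantity. The test is one-sided by construction:
the strictly decreasing reference beta makes a *deficit* of the minor isoform
undetectable, deliberately. A score of 0 means the minor count is 0. When two
reference panels are available, per-sample scores are combined by the
element-wise minimum, which is conservative: a missing score in either run
propagates as missing.

## Parameters

| Parameter | Meaning | Default | Notes |
|---|---|---|---|
| ω_M | upper bound on the beta concentration, ω ∈ (2, ω_M + 2) | 200 | lower bound 2 keeps the beta unimodal-or-flat rather than U-shaped |
| β_M | upper bound on β_R (and 1/β_M the lower bound on α_R) | 80 | caps how sharply the reference can concentrate at 0 |
| LR threshold | differential operating point | 8 | used for flagging only; results are ranked |
| score threshold | outlier operating point | 10 | tail 10⁻¹⁰ in base 10 |
| min_depth | depth below which PSI is treated as missing (baselines) | 10 | 0 disables masking |

## Optimization

Fits run in unconstrained coordinates via logistic maps (ω = ω_M/(1+eᵃ) + 2,
Ψ = 1/(1+eᵇ); analogous maps for α_R, β_R) using Nelder–Mead with a BFGS
fallback on failure, a function tolerance of 1e-8 and at most 500 iterations.
Starts are placed at the method-of-moments PSI (lightly smoothed to avoid the
boundary) with the concentration at mid-range, plus two concentration
offsets. The two-group fit additionally starts from the one-group optimum
with Ψ₁ = Ψ₂, which guarantees LR ≥ 0 up to solver tolerance because
Nelder–Mead never returns a point worse than its best start. Mapped
parameters are clipped microscopically inside their open intervals so
boundary-seeking data (e.g. all samples at PSI = 1) yield finite likelihoods;
fitted ψ̂ then reports a value inside (0, 1) arbitrarily close to the
boundary. Per-event fit failures are flagged in `fit_status`, never fatal.

## Comparator statistics

Welch's two-sample t-test on PSI uses the unequal-variance statistic with
Welch–Satterthwaite degrees of freedom. When both within-group variances are
zero the statistic is undefined; the implementation returns p = 1 if the
means agree and p = 0 otherwise, flagged `degenerate`, so benchmark sweeps
complete. MAD and IQR scores floor their denominators at 0.01. Quartiles use
linear interpolation between order statistics (recorded here because other
quantile conventions change IQR scores; the formula itself does not fix one).
The MAD score is signed; the benchmark utility can rank on the absolute
value.

## Protein-effect prediction

Transcripts are read from a GTF (gene/transcript/exon/CDS/stop_codon) with
the coding span taken as CDS plus stop codon; genome sequence from FASTA.
A transcript matches an event isoform when every junction of that isoform
coincides with one of the transcript's intron boundary pairs; the retained
isoform of an IR event instead requires the intron interval to be fully
exonic. Edits rebuild the exon chain as the complement of the edited intron
set within the transcript span, so exon removal (ES), intron retention and
mutually-exclusive substitution fall out of one rule, and the inverse edit
restores the original chain exactly.

Translation starts at the annotated start codon and proceeds through the
(possibly edited) transcript to the first stop; absence of a stop marks a
stop-loss candidate. "Alignment" of the two proteins is longest-common-prefix
/ longest-common-suffix trimming — exact here because the two proteins are
identical outside one contiguous edit by construction — with the suffix
bounded so it never overlaps the prefix, and a terminal `*` kept with the
altered region when the divergence runs to a sequence end. Classification
precedence: NonCoding (the edit leaves the coding-span exon content
unchanged, e.g. a UTR-only event) → Silent (identical proteins) →
FrameDisruption (coding-length change not a multiple of 3) → StopLoss →
Truncation (in-frame edit introducing an early stop) → Insertion/Deletion by
the sign of the length change. Two consequences of this taxonomy are worth
noting: an in-frame equal-length replacement is reported as Insertion (there
is no Substitution category), and a clean Deletion has an empty altered run,
which the literal novelty rule (altered sequence found in no annotated
protein of the gene) classifies as Known. Selenocysteine readthrough and
non-standard codes are unsupported; affected transcripts yield Unknown.

Novelty is a substring search of the altered peptide (stop mark stripped)
against the annotated protein sequences of the gene. One pair per event is
selected by: known transcript pair first, then longest altered run, then
longest starting-isoform protein, with a lexicographic transcript-id
tie-break. Reference proteins and Known alternative proteins go to the
known-isoform FASTA; Novel alternatives to the novel-isoform FASTA.

## Synthetic data

`simulate_counts` draws exactly the generative model above (depth Poisson by
default, zero-depth samples permitted to exercise missing-data paths), so
tests of calibration and power measure the estimator, not model mismatch.
What it does **not** emulate: overdispersed or correlated depths, shared
splicing factors across events, mapping artifacts, or annotation errors —
passing calibration here shows the statistics are implemented correctly, not
that real RNA-seq data meet the model's assumptions.

`make_toy_annotation` builds a < 100 kb genome whose genes (alternating
strands) realize every supported (event type, effect) combination, with
segment-specific codons so altered runs trim unambiguously, intron-like
boundaries (GT..AG), a 5′ UTR free of ATG and a 3′ UTR containing stops in
all three frames so frameshifts terminate. The expected proteins are computed
inside the generator by direct string assembly of the constructed exon
chains — independent of the annotation/editing/translation pipeline — which
makes the fixture an end-to-end oracle. The ES deletion/frameshift entries
use 102- and 103-nt cassettes, the canonical frame-arithmetic pair. The
catalog contains no Silent entry: under the NonCoding-first precedence a
protein-identical event is only constructible outside the CDS; Silent is
exercised directly at the classifier level.

## Evaluation sizes

The shipped evaluation uses problem sizes chosen to give stable Monte-Carlo
estimates at desk scale: 200 events for power at LR > 8, 2000 events for
null calibration (binomial s.e. ≈ 0.2% at a 1% bound), 100 replicates for
PSI recovery, 2000 event-samples for outlier calibration, and ≥ 100 random
small instances per fit family for optimizer-vs-grid agreement (grids
200×200 for the diff fits, 300×300 for the constrained reference fit,
tolerance 0.1 nats).

## Known limitations

- Only two-group comparison and one-vs-reference outlier designs; no
  continuous covariates.
- Event types beyond the five supported (alternate first/last exons, complex
  events) are out of scope, as is event detection itself (counts come from an
  upstream detector).
- The LR is used as a ranking statistic; its null distribution is not
  calibrated against χ² and thresholds are operating points, not p-values.
- Events matched by transcripts of multiple genes are annotated per gene of
  record (`gene_id` on the event); cross-gene peptide collisions are not
  resolved.
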