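# Methods

## Model

The genome is partitioned into fixed-width bins (default 200 bp; the trailing
partial bin of each chromosome is retained so lengths are conserved exactly).
The observation at bin *t* is a binary vector x_t over M marks. A K-state
hidden Markov model generates the data: a hidden chain z_t with initial
distribution π and transition matrix A, and per-state independent Bernoulli
emissions,

    P(x_t | z_t = k) = ∏_m E[k,m]^{x_tm} (1 − E[k,m])^{1 − x_tm}.

Chromosomes are independent sequences, each restarted from π. Concatenated
multi-condition fitting pools all conditions' chromosomes as sequences
sharing one parameter set; each condition is then segmented separately with
those shared parameters, which is what makes per-bin cross-tabulation of the
two segmentations meaningful.

Assumptions worth stating: marks are conditionally independent given the
state (the usual trade-off that makes K×M emission tables interpretable);
state duration is geometric (no explicit duration modeling); strand is
ignored throughout.

## Fitting

Baum–Welch EM with per-position scaling in the forward/backward recursions
(the per-bin log-emission maximum is factored out first), so sequences of
millions of bins cannot underflow. Defaults: `max_iter=200`; convergence when
the relative log-likelihood improvement falls below `tol=1e-3`; emissions
clamped to [1e-6, 1 − 1e-6] at every M-step to keep the likelihood finite on
degenerate data. The log-likelihood trace is recorded per iteration and is
non-decreasing up to 1e-8 relative tolerance; a decrease is recorded as a fit
warning.

Initialization (`information`, the default) blends the K most frequent
observation row patterns with the column means plus small seeded jitter;
`random` draws emissions uniform(0.2, 0.8). Both are deterministic given the
seed. EM converges to local optima, so fits are reproducible only given
(data, K, seed, init) — state labels are arbitrary and all cross-model
comparisons go through emission matching or correlation, never label
identity.

Segmentation default is the per-bin posterior mode, ties broken toward the
lower state index; Viterbi is available where a single coherent path is
wanted. Subset evaluation re-segments with hidden marks marginalized out of
the emission product (their Bernoulli factor sums to one), so the same
parameters are evaluated on less evidence — no refit involved.

## Binarization

Counts are assigned to bins by read 5′ position. A mark is called present
when the Poisson upper tail P(X ≥ observed | λ) is ≤ `p_threshold` (default
1e-4, ties call 1). Without a control, λ is the mark's genome-wide mean;
with a control, the control count is scaled by total-depth ratio with a
pseudocount of 1 and floored at the genome-wide mean so empty control bins
cannot generate calls. Observed 0 is never called. These defaults follow the
common practice for this test; all are exposed in `BinarizeParams`.

Note the operating characteristics this test implies: with background rate
λ_bg and signal rate λ_bg·e, the smallest callable count x* is set by the
*estimated* background (which the genome-wide mean inflates when many bins
carry signal), and recovery of true signal bins is P(Poisson(λ_bg·e) ≥ x*).
Recovery above 95% therefore needs roughly x* ≲ λ_signal − 1.6·√λ_signal;
at λ_bg ≈ 1 that means enrichment of ~20–30×, not ~10×. The tests verify
empirical recovery against this closed form rather than assuming a rate.

## Comparison statistics

With B[w,m] the number of bins in state w (condition 1) and m (condition 2):
JI_s = B_ss/(B_s· + B_·s − B_ss), O_s = B_ss/B_s·, FC_s = log2(B_·s/B_s·);
genome-wide overlap = trace(B)/ΣB. Computed on bin counts: on a uniform grid
these equal base-pair ratios up to at most one trailing partial bin per
chromosome (noted in output metadata). States absent from both conditions
get NaN (flagged, never silently dropped); a state absent from condition 1
only gets O = NaN and FC = +inf as an explicit sentinel.

Chromatin-type classification uses strict inequalities: a state takes a type
iff that type's overlap fraction is > 0.66 **and** every other type is
< 0.20; otherwise `mixed:<top>+<second>`. Exactly 0.66 or 0.20 therefore
classifies as mixed. Since 0.66 > 0.5, two types can never both clear the
majority bar (asserted).

Per-state signal aggregation gives each state region the bp-weighted mean of
overlapping signal intervals; regions without signal are dropped with a
logged count. Box-plot summaries exclude outliers by Tukey fences at
1.5×IQR.

TE-gene grouping: wild-type TPM > 0 (strict, raw values) excludes a gene;
remaining genes with mutant TPM < 0.1 are "no expression"; the rest are
quartiled by ascending mutant TPM with ties broken by gene id, the remainder
(pool size mod 4) going to the earlier quartiles; "expressed" = q3 ∪ q4.

## Synthetic data

The generator emulates the study conditions at desk scale, with all
randomness flowing from one seed through named substreams (model, tracks,
counts, perturbation, annotation, expression):

- Genome: 3 chromosomes × 1 Mb at 200 bp (15,000 bins). Small enough for
  seconds-scale fits, large enough that empirical transition/emission
  frequencies concentrate.
- Model: K=8 states typed H,H,H,F,F,E,E,I; M=12 marks. The
  blockwise-distinct design gives every state at least one near-diagnostic
  mark (emission 0.85–0.95 in-state, 0.02–0.15 out), echoing the sparse
  block structure of real emission tables. Self-transition 0.9 (mean run
  2 kb).
- Perturbation: contiguous blocks of heterochromatin-state (H) bins are
  reassigned to a designated facultative state in condition 2 (fraction 0.5
  by default), mirroring regional heterochromatin-to-facultative conversion;
  blocks rather than independent bins keep the second condition realistic
  for HMM refitting. The generator returns the exact expected confusion
  matrix implied by its edits, computed by bookkeeping, and the pipeline's
  cross-tabulation must reproduce it bin-for-bin.
- Annotation/expression: TE genes are placed by Poisson sampling at 1 per
  10 kb of H-state extent versus 0.1 per 10 kb of euchromatin (a ~10×
  density contrast, ≥5× asserted on sufficiently large instances); genes go
  to euchromatin. Expression is zero-inflated (80% zeros for unperturbed TE
  genes); TE genes whose ground-truth state changed become log-normally
  expressed in the mutant; a 5% wild-type-expressed subset exercises the
  exclusion rule.

What the generator does **not** emulate: read-level sequence, mappability
and GC structure, correlated mark noise, replicate variability, or realistic
TE family structure. Passing tests demonstrate correctness of the
algorithms and statistics under the model's own assumptions — they do not
certify performance on real ChIP-seq data, where binarization quality and
mark correlations dominate.

## Problem sizes and numerical choices

The standard recovery instance is K=2, M=3, 20,000 bins, blockwise
emissions, self-transition 0.9: median per-entry emission error over five
seeded re-fits is ~0.002 (well under the 0.05 design target) and ~99% of
bins are correctly assigned after Hungarian matching of emission rows.
Enumeration oracles run at ≤6 bins and K≤3, where exhaustive path sums are
exact; agreement is required to 1e-10. Model files store parameters in
`%.10g` text and are byte-reproducible for a given seed; probabilities are
renormalized on load to absorb text round-off.

Degenerate inputs: a single unique observation row yields a warned fit, not
a crash; K exceeding the number of distinct rows warns; all-zero marks
binarize to all-zero calls with a warning; empty masks and mismatched mark
sets raise.

## Known limitations

- EM finds local optima; the state-number diagnostic is bookkeeping over
  emission correlations, not an automatic model-selection criterion — the
  choice of K on real data involves judgment about biological
  interpretability that is deliberately not automated.
- Subset evaluation marginalizes marks from the full model rather than
  re-learning on the reduced mark set; both workflows are possible (refit
  via `fit_model` on masked tracks), and they answer slightly different
  questions.
- The comparison statistics assume both segmentations share one state
  universe (a concatenated model); comparing independently learned models
  requires a state-matching step first.
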