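# Methods

`chipsim` simulates a ChIP-seq experiment from first principles: a
statistical-mechanics model of transcription-factor (TF) occupancy feeds an
explicit, fragment-resolved simulation of the experimental protocol
(extraction, PCR, sequencing), and a set of evaluation tools quantifies
what can and cannot be inferred from the resulting read counts.

## Occupancy model

Each of *n* genomic loci carries one binding site with mismatch energy
ε ≥ 0 (kBT units, kBT = 1 everywhere; the consensus sequence has ε = 0).
A locus is a two-state system — bound (weight `exp(-(ε - μ))`) or unbound
(weight `exp(-ε_u)`) — so the occupancy probability is the logistic

    p_b = 1 / (1 + exp(ε - ε_u - μ)).

`μ` is the TF chemical potential (log-concentration; default 3) and
`ε_u = 1.59` fixes the consensus-site occupancy at 0.99 under the default
potential. Genome-wide energies follow a truncated power law with density
`f(ε) ∝ (E_max - ε)^(-α)` on `[0, E_max]` (defaults α = 0.5, E_max = 10),
which puts most loci at weak sites; sampling uses the exact inverse CDF
`ε = E_max (1 - (1-u)^{1/(1-α)})`. Mean and variance have closed forms
(`E_max/(2-α)`; `E_max² [(1-α)/(3-α) - ((1-α)/(2-α))²]`) that the tests
cross-check by quadrature.

Variants:

- **Cooperative binding** — a four-state partition function over TFs A and
  B with interaction energy Δ (Δ < 0 cooperative, 0 independent, > 0
  competitive; Δ = +∞ handled as a strict-competition limit). The ChIP of
  A sees the two states containing A.
- **Indirect binding** — a fraction of loci is occupied according to B's
  energy and chemical potential; A's energy is irrelevant there by
  construction.
- **False positives** — loci with no target-TF site whose energies come
  from a derived power law with mean `f·m` and the true-positive law's
  variance, via `r = v/(f²m²) + 1`, `α_fp = 3 + 2/(r-2)`,
  `E_max_fp = f·m·(2 - α_fp)`. The printed reference pair (0.76, 6.78)
  follows from (α=0.5, E_max=6, f=1.367); `f` can also be solved by Brent
  root-finding on the quadrature mean-occupancy ratio
  (`solve_fp_scaling`), e.g. f ≈ 2.302 for ratio 10. Deriving the
  truncation from `α_fp` rather than `α_tp` is deliberate: it is the only
  reading that reproduces the reference pair and preserves the variance
  (checked to 1e-6 by quadrature).
- **Chromatin accessibility** — occupancy is scaled by the sigmoid
  `p_acc = 1/(1 + exp(-β d))` in the per-base DNase read density *d*. It
  applies to the ChIP sample only; the input sample's occupancy is already
  phenomenological (below). The model assumes closed chromatin is never
  bound, so it underestimates occupancy for pioneer TFs.

The input (control) sample uses 10% of the ChIP cell count and a constant
background energy `ε_bg` (default 1) at every locus with μ = 0 — a
phenomenological stand-in for nonspecific binding of the whole TF
complement.

## Protocol simulation

All stages track fragments exactly, per locus:

1. **Binding**: bound-fragment count `F_b ~ Binomial(C, p_b)` over `C`
   cells (default 1e5).
2. **Extraction**: `F_e ~ Binomial(F_b, p_e)`; `p_e` aggregates lysis,
   cross-linking, pull-down and size selection (two thinnings compose into
   one with the product probability — a tested invariant). Default law:
   truncated normal on [0,1], mean 0.5, sd 0.05; a CV parameterisation and
   a power-law alternative are available. The two samples share per-locus
   `p_e` and PCR efficiency. Totals are equalised before PCR by binomial
   down-sampling of the richer sample (factor `D`).
3. **PCR**: each extracted fragment grows through `n_cy` cycles (default
   15) of a Galton–Watson process — every copy duplicates with probability
   `p_a` per cycle, `A = (1+p_a)^{n_cy}` (default A = 1000 ⇒ p_a ≈ 0.58).
   The copy-number distribution is computed exactly by per-cycle binomial
   convolution with tail truncation below 1e-16 per entry (< 1e-12 total
   mass; closed-form moments reproduced to 1e-6 relative). Distributions
   are cached on a 0.01 grid of `p_a` by default; exact off-grid
   computation is a flag.
4. **Sequencing**: `r = c·n` reads (depth c = 100) are drawn from the
   pooled amplified fragments as a multivariate hypergeometric sample via
   the sequential conditional scheme (exchangeable in locus order — tested,
   not assumed). Within a locus, reads are allocated to parent fragments
   the same way, implemented as a uniform distinct-fragment draw mapped to
   parents. A parent contributes at most one unique read; the remainder
   are PCR duplicates, so `u_i + d_i = r_i` exactly. Amplified pools
   exceed numpy's hypergeometric-parameter cap (1e9), so large draws use
   an exact windowed inverse-CDF sampler on a ±12σ window of the log-pmf.

The per-locus output is the unique-read ratio ChIP/input ("read-count
ratio", the peak-intensity analogue). Loci with zero unique input reads
get an undefined (NaN) ratio, are excluded from downstream metrics, and
are counted in the result object; at default parameters they are
vanishingly rare.

Reproducibility: one root seed; every stage and sample draws from a child
generator derived from the seed plus a stable string tag (crc32), so runs
are bit-identical and stages independently replayable.

## Read synthesis

Given intervals with summits, unique ChIP fragment starts are Gaussian
around `summit - d/2` (fragment length d = 200, jitter sd j = 50); control
starts are uniform on the interval. Each unique start is repeated once per
sampled PCR copy, so duplicates share coordinates by construction and are
flagged in read names (a truth TSV maps read → locus/fragment/duplicate).
Coordinates are 0-based half-open; draws are rounded (floored for the
uniform case) and clamped to keep fragments on the contig. Plus-strand
reads are the first `l` bases of the fragment; minus-strand reads are the
reverse complement of the final `l` bases (the convention adopted for the
ambiguous boundary case). Single-end mode picks a strand fairly per
fragment from a dedicated stream; paired mode emits both. Base qualities
are a single configurable character, default `K` (Phred-33 Q = 42, the
maximum ordinarily produced by Illumina pipelines). No base-call errors,
adapters, or mappability effects are modelled.

## Motif toolkit

Energy matrices are additive 4×L mismatch models, column-shifted so each
column minimum is 0. `nearest_energy_sequence` finds the sequence closest
to a target energy by cached exhaustive enumeration for L ≤ 12 (ties
resolve to the lower energy, deterministically) and greedy coordinate
refinement with restarts beyond that. PWMs use the log2-odds form with
background pseudocounts, `W_ij = log2((N_ij + b_i)/(b_i(N+1)))`. Motif
distortion is the per-position K-L divergence between pseudocounted
probability columns in bits; since directionality is a convention, the
symmetrised form `½[D(P‖Q) + D(Q‖P)]` is the default with one-directional
variants behind a flag. Indirect-binding backgrounds come from a
first-order Markov (dinucleotide) model; the packaged AT-rich model is a
synthetic fixture, not fitted to a real genome. The reference
motif-recovery workflow plants the nearest-energy site at each locus
(replacing the drawn energy with the achieved one), simulates, ranks loci
by ratio, and builds the PWM from the top 10%; comparisons are always
against a baseline PWM from a heterogeneity-free run at the same seed, so
assay-to-assay motif differences cannot masquerade as protocol effects.

## Evaluation metrics

- **Fidelity**: among uniformly sampled within-bin locus pairs whose
  ratios differ by at least the margin (default 10%), the fraction where
  the higher-ratio locus has strictly lower energy. Pairs failing the
  margin are excluded (the conditional reading of "if … then"); energy
  ties count as failures. Percentile bins are computed on defined ratios
  with stable tie-breaking.
- **ROC/auROC**: threshold sweep of ratios against site labels
  (scikit-learn), with TPR at a requested FPR by linear interpolation;
  auROC equals the normalised Mann–Whitney U statistic (exact test
  oracle).
- **Specificity ratio** `r_e`: mean occupancy×extraction at true-positive
  loci over the same at false-positive loci; reduces to the
  mean-occupancy ratio for equal efficiencies.

## Posterior inference of binding energies

The likelihood of a ratio given an energy has no closed form, so it is
estimated by simulation: a bank of Gaussian KDEs of the ratio
distribution, one per grid energy (grid = one draw of the energy law),
linearly interpolated between flanking grid energies for queries off the
grid. (The interpolation is oriented so a query at a grid point returns
that KDE's value exactly.) Posteriors are sampled by Metropolis–Hastings
with truncated-normal proposals on the law's support, sd proportional to
the current state (relative sd floors at 1e-3 near zero so the chain can
leave the origin). Within the chain, the likelihood profile is precomputed
at every grid energy and interpolated — mathematically identical to
evaluating the flanking KDEs per step, but O(1). After each replicate the
retained samples (every t-th after burn-in) become the next prior via a
Gaussian KDE with reflection at the support bounds. Uncertainty is the
97.5–2.5 percentile width of the retained samples.

Full-scale settings (burn-in 10 000, thinning 100, 10 000 retained,
relative sd 0.02 — about one million steps per update) are hours-scale
when combined with a 1000×1000 bank. The scaled profile used by the tests
(grid 100, 100 replicates, burn-in 1000, thinning 10, 1000 retained) uses
a 10%-relative proposal instead: a flat-likelihood diagnostic shows the 2%
walk cannot traverse the support within 11 000 steps, while the Hastings
correction makes the stationary distribution independent of the proposal
width. An asymmetric forward/backward proposal pair (0.02/0.2) remains
available as options. Scaled calibration: 95% credible intervals cover
true energies in ≥ 85% of 40 trials after three replicates, mean width
falls monotonically over replicates 1→5, and high-affinity (2 kBT) sites
stay markedly more uncertain than 5 kBT sites — the number-of-replicates
story the inference machinery exists to tell.

## Synthetic fixtures

`fixtures` generates i.i.d. random genomes at a requested GC content,
non-overlapping interval sets with planted nearest-energy sites at their
summits (truth table included), and long-tailed lognormal density tracks
emulating windowed DNase read counts (counts per 150 bp window divided by
150). These exercise every pipeline path without downloads; they do not
reproduce real-genome composition beyond what a dinucleotide background
can, so passing tests demonstrate correctness of the machinery, not
biological realism of any particular genome.

## Problem sizes and known limitations

Tests and the reproduction script run at the reference scales (n = 1000
loci, C = 1e5 cells, depth 100, 10-seed averages) except posterior
inference, which uses the scaled bank/chain profile above; those sizes are
the package's chosen balance of statistical stability against runtime.

Deterministic analysis of the occupancy model places bounds on some
simulated summaries: with defaults, Pearson correlation of occupancy vs
energy is −0.96 for direct loci and −0.86 for cooperative loci (Δ = −6),
and the occupancy-overlap auROC at mean-occupancy ratio 10 is 0.955; the
simulated protocol adds only ~10–15% CV of ratio noise at default cell
counts and depth, so simulated correlations and auROC land essentially at
these deterministic values. Published ChIP-seq simulators report weaker
values for nominally similar settings, consistent with additional noise
sources not part of this model; the qualitative orderings (which factors
matter, and in which direction) are robust to that difference. Other
limitations: exponential-phase PCR only (no saturation or polymerase
errors), error-free sequencing and perfect de-duplication, one binding
site per locus, and no nucleosome/pioneer-TF chromatin dynamics.
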