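# Methods

## Count model

Cleavage read counts at putative off-target sites are modeled as a
zero-inflated negative binomial: a point mass at zero with weight π
(capturing technical zeros — active sites missed by the assay — alongside
genuinely inactive sites) mixed with a negative binomial NB(μ, θ) for the
reads of active sites.  The NB variance μ + μ²/θ makes θ the
overdispersion control; the mixture's moments are

- mean = (1 − π) μ
- variance = (1 − π) μ (1 + μ/θ + π μ)
- CV = √variance / mean (reported as +∞ when the mean is 0).

Log pmfs are evaluated through log-gamma; the k = 0 branch uses a
log-sum-exp of [log π, log(1 − π) + log NB(0)] for stability.  Counts in
the data are normalized reals; the likelihood rounds them to the nearest
integer once at evaluation time.  After the network's activations,
parameters are clamped to π ∈ [1e−6, 1 − 1e−6], μ, θ ∈ [1e−6, 1e6] to keep
the loss finite.  Sampling uses the gamma–Poisson mixture representation.
Reduced heads (zero-inflated Poisson, plain NB, Poisson) share the same
machinery and serve as ablation baselines; in the common (π, μ, θ)
parameterization the Poisson-family heads use the large-dispersion limit
θ = 10⁶, under which NB and Poisson pmfs agree to ~1e−4 per value.

## Inputs

**Interface encoding (6×23).**  One-hot rows in the fixed channel order
A, T, G, C are OR-merged across the sgRNA and target sequences; this order
is the one consistent with the standard printed examples (T→T = 0100,
{G,C} = 0011).  Two extra rows restore mismatch direction: row 4 is set
when the sgRNA base's channel index is below the target's, row 5
otherwise, so G→C is 0011-10 and C→G is 0011-01 and swapping the two
sequences exactly flips the direction bits.  N (e.g. from an NGG search
pattern) contributes an all-zero one-hot, no direction bit, and is not
counted as a mismatch — no base identity is fabricated.  U is normalized
to T.  Only equal-length 23-nt pairs are supported; bulges are rejected
(the encoding has no insertion channel).  Column 0 is the 5′ end of the
written sequence; positions 21–23 are treated as PAM-proximal in
stratified summaries.

**Physical descriptors (4×23).**  For each site position a 147-bp window
(73-bp flank each side, N-padded at contig edges, reverse-complemented for
minus-strand sites) yields four scores, in fixed row order:

1. *Sequence complexity* by block decomposition: the window is cut into
   non-overlapping blocks (default size 12, remainder dropped) and the
   score is Σ complexity(block) + log₂(multiplicity) over distinct blocks.
   Per-block complexities come from a pluggable k-mer table; without a
   table a Shannon-entropy fallback (bits/symbol × block length, N as a
   fifth symbol) is used so nothing external is required.
2. *GC content*: (#G + #C)/147, N in the denominator only.
3. *Nucleosome occupancy* and 4. *nucleosome affinity*: either looked up
   at the window center in a per-base track file (chrom, pos, occupancy,
   affinity, tab-separated), or computed by a deterministic
   sequence-derived surrogate — the 10-bp phase coherence of AA/TT/TA
   dinucleotides (amplitude of the period-10 Fourier component of the
   dinucleotide indicator, normalized by the dinucleotide count) for
   affinity, and a logistic transform of it for occupancy.  The surrogate
   reflects the classic 10-bp periodicity signal of nucleosome-favoring
   sequences; it is a stand-in for a trained nucleosome model, chosen so
   that the whole pipeline is reproducible from sequence alone.  The
   provider identity is recorded in model metadata.

The descriptor value for position j is computed on the window centered at
j (not averaged over windows covering j).  Each descriptor row is min–max
normalized with statistics fitted once on the training set, persisted with
the model, and clipped to [0, 1] at inference; a degenerate row
(max = min) normalizes to 0 with a warning.

## Network and training

Default sizes: sequence branch Conv(6→128, width 1) + BatchNorm + ReLU,
Conv(128→32, width 3, same padding) + BatchNorm + ReLU, MaxPool(2, 2)
(23 → 11 positions), bi-LSTM with 128 hidden units per direction whose two
final states are concatenated, then a 128-unit projection; descriptor
branch Conv(4→32, width 3) + BatchNorm + ReLU, flattened, 128-unit
projection; the concatenated 256-d encoding passes a 64-unit joint layer
into one scalar head per parameter (sigmoid → π, exponential → μ, θ).
Unstated details fixed here: same padding, concatenated final LSTM states
(not mean pooling), batch-norm between convolution and ReLU, fan-in-scaled
normal initialization from the run seed, forget-gate bias 1.

Defaults for training follow the full-scale protocol: Adam at learning
rate 1e−5, batch size 128, 70/20/10 train/validation/test split
(floor-based sizes, remainder to train), early stopping after 50 epochs
without validation improvement, at most 500 epochs, best-validation
weights restored.  The optimization objective is the mean per-sample NLL
(equivalent to the summed NLL up to a constant factor; it keeps the
learning rate meaningful across batch sizes).

The network stack is implemented on a small reverse-mode autodiff engine
over float64 numpy arrays written for this package (tensor ops, 1-D
convolution, max pooling, LSTM recurrences, batch norm, log-gamma);
gradients are verified against central finite differences in the test
suite.  Everything is CPU-bound and deterministic given the seed.

**Scaled-down preset.**  Tests, examples and the acceptance script use a
`compact` preset with the same topology (16/8 conv kernels, 16 LSTM units
per direction, 32/32/16 dense units) trained with learning rate 1e−3 for
tens of epochs.  These sizes were chosen so a full
simulate–train–evaluate cycle runs in minutes on one CPU; the 1e−5 rate is
matched to the full architecture and corpus and barely moves the compact
network in that budget.  The default configuration remains the full-scale
one.

## Uncertainty outputs

Quantiles on the discrete support use right-continuous inversion
ucb = min{k : CDF(k) ≥ level}, making interval coverage conservative
(never silently below nominal).  Off-target credible intervals fix the
lower bound at zero activity and report the upper bound (95% default) —
in guide design only the upper tail of an off-target posterior matters.
Counts are converted to activity frequencies by the stored scale constant
(the post-normalization maximum, 10 000 in the training pipeline).  Site
orderings by UCB break ties by mean, then input order.

**Calibration.**  The diagnostic plots observed against nominal one-sided
coverage; the identity line indicates calibration.  Two estimators are
provided.  `method="quantile"` counts observations at or below their
posterior's level-quantile; on a discrete support with a large zero mass
this is necessarily conservative — with π = 0.6, every level below 0.6
"covers" ≈ 60% of draws — so it cannot trace the identity line even for a
perfect model.  `method="pit"` (default) uses the randomized probability
integral transform u = F(y − 1) + v · pmf(y), v ~ U(0, 1), which is
exactly uniform when the observations come from the forecast
distributions; this is the appropriate form of the observed-vs-expected
diagnostic for count forecasts and is what the self-consistency tests
assert (max deviation ≤ 0.03 at n = 5 000).  The grid defaults to
0.05, 0.10, …, 0.95.

## Aggregate specificity

For a guide with M off-target sites, each site's posterior is sampled
n_samp times (default 1 000) independently, and sample s of the score is
log(Σᵢ offᵢ[s] / max(on[s], 1)).  The sum excludes the on-target; the
denominator floor of 1 count guards against zero on-target draws (rare,
since on-target π ≈ 0) and is configurable.  Natural log; switching log
base rescales all scores monotonically and cannot change guide rankings.
Off-target discovery is delegated to an external genome-search tool whose
tab-separated output (pattern, target, chrom, 0-based position, strand,
mismatch count) is parsed with duplicate loci dropped (first kept);
default mismatch cap N = 5.

## Synthetic data

The generator plants guide sites into a uniform random genome:
per guide one 0-mismatch on-target plus off-targets with m ~ U{1..6}
mutated positions at non-overlapping loci (random strand; minus-strand
sites are planted as reverse complements).  Ground truth per site:
μ = μ_on · decay^m · 2^(2(GC − 0.5)) and π = logistic(logit(π₀) + b·m),
with defaults μ_on = 2000 (on the capped 10 000-count scale),
decay = 0.4, θ = 0.7, π₀ = 0.05, b = 0.7 — values chosen to reproduce the
qualitative structure of genome-wide assay data: a ~40% zero fraction,
orders-of-magnitude decay of the mean over 1–6 mismatches, strong
overdispersion, and context (GC) signal that only the descriptor branch
can exploit.  Counts are single ZINB draws from the truth; the truth is
written to a sidecar table, and a dropout operation can zero positive
counts with a given probability to emulate additional technical zeros.

What the generator does *not* emulate: read-level artifacts (PCR
duplicates, mapping noise), realistic genome composition (repeats,
isochores), chromatin that deviates from the dinucleotide surrogate, and
any mismatch-position or mismatch-identity preference — the planted mean
depends only on the mismatch *count*.  Passing recovery tests therefore
demonstrate that the estimator and architecture can extract the planted
mismatch/GC structure from ~20 000 sparse, overdispersed counts; they do
not certify performance on real assay data.

## Normalization of read counts

Two linear steps: per-guide totals are equalized to the mean per-guide
total (any positive constant would do — it cancels in the next step), then
all counts are scaled so the global maximum is 10 000.  Both factors are
stored and invert the transform to 1e−9 relative error.  Guides with zero
total are left unscaled in step 1.

## Numerical and interface conventions

Coordinates are 0-based half-open everywhere internally (a flag accepts
1-based input).  All tables are tab-separated with headers.  Checkpoints
are single npz archives holding weights, config snapshot, descriptor
normalization statistics, count scale and provenance metadata, guarded by
a format tag.  Every stochastic routine takes an explicit seed; repeated
runs are byte-identical.

## Known limitations

- On-target activity prediction is out of scope: the model is built
  around the sparse many-off-target regime and its LCB-at-zero interval
  convention is meaningless for on-targets.
- The nucleosome surrogate is a sequence-only approximation; with real
  data a precomputed per-base track should be supplied.
- The compact preset trades capacity for CPU speed; the full-size
  architecture is untested here at corpus scale.
- The discrete-quantile calibration curve is conservative by design; use
  the PIT curve to judge calibration.
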