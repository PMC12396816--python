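# Methods

## Model

Each site `i` of a parent sequence carries an independent exponential
mutation clock with rate `λᵢ` determined by its nucleotide context; over a
branch of length `t`, the site mutates with probability
`pᵢ = 1 − exp(−t·λᵢ)`. A mutated site draws its new base from the
conditional substitution probability (CSP) row, a categorical distribution
over the three non-parent bases. Mutations on a branch are treated as
simultaneous, so all contexts are read from the parent sequence and the
order of events never enters the likelihood. Only `t·λᵢ` is identified
within a pair; `t` is therefore a fixed per-pair offset (the normalized
mutation count, i.e. substitutions per informative site) so that `λ` is
learned on a scale common to all pairs.

### Convolutional architecture

The parent is tokenized into overlapping centered 3-mers (64 unambiguous
3-mers plus one ambiguity token covering `N`-containing windows and the
two boundary positions). Tokens index a trainable `65×E` embedding; a
width-`K` convolution (`F` filters, bias, symmetric zero padding so output
length equals input length) runs over the embeddings; a rectifier and
(training-only, inverted) dropout follow; an affine `F→1` head gives the
log rate and an affine `F→5` head gives CSP logits over (A,C,G,T,
ambiguity). The ambiguity column and the parent-base column are set to
−∞ before the softmax, so each CSP row is a distribution over the three
non-parent bases. Because each 3-mer extends one base beyond the kernel
window, the effective context is `K+2` bases: kernel 11 is an effective
13-mer model.

Wirings: `joined` shares one embedding+convolution trunk between both
heads; `hybrid` shares only the embedding with one convolution per head;
`independent` gives the rate head its own full stack and the CSP head two
full stacks whose convolution outputs are summed element-wise before the
nonlinearity. The 65-token vocabulary, 5-wide CSP head, and the assignment
of the third stack to the CSP sub-model are the unique simple decomposition
we found that reproduces all three published parameter counts
(2057 joined large, 4539 independent medium, 5931 independent large);
the closed-form count is checked against exhaustive weight enumeration in
tests. Rectifier choice and dropout placement (after the nonlinearity,
before the heads) are conventional and parameter-free, so counts are
unaffected.

Rates are positive by construction (`λ = exp` of the head output), which
makes the branch-length offset act additively in log space.

### Baselines

The 5-mer table baseline assigns one log rate and one 5-wide CSP logit
row to each of the 1024 unambiguous 5-mers plus an ambiguity token
(6150 scalars in our parameterization; published 5-mer baselines print
other totals whose composition is not derivable, so we document our own).
The per-site×5-mer variant multiplies the 5-mer rate by a per-position
factor `sᵢ` over a fixed site range, with a squared-magnitude penalty
(coefficient 1e-4) on `log sᵢ` to suppress artifacts at rarely observed
positions; the penalty form is our choice, selected as the mildest
standard regularizer.

## Training

Loss per pair = Bernoulli negative log-likelihood of the mutation
indicators under `pᵢ = 1 − exp(−t·λᵢ)` at unmasked sites, plus
`0.01 ×` the categorical cross-entropy of the child base at mutated
unmasked sites (the weight roughly evens the two contributions and is
configurable). Losses are summed within a pair and averaged over the
pairs of a minibatch. The censored-Bernoulli link is our reading of the
waiting-time model with offsets; it reduces to a Poisson race when
`t·λ` is small.

Optimizer: Adam (lr 1e-3 default, β = 0.9/0.999), 100 epochs by default,
implemented in NumPy with hand-written analytic gradients (verified
against numerical differentiation to 1e-4 relative in tests). No
deep-learning framework is used: the models are ≤ ~6k parameters, and a
NumPy implementation keeps training single-CPU, dependency-light, and
bit-reproducible under a fixed seed. Pairs with zero observed
substitutions are excluded from training (offset 0 gives identically zero
gradient) but kept for evaluation. With `joint_branch_opt`, each gradient
epoch is followed by per-pair branch-length re-optimization (alternation
once per epoch; the schedule is otherwise unconstrained). Loss sums per
pair are averaged over pairs, not sites; this affects only the effective
learning rate.

Branch-length optimization maximizes the placement likelihood per pair by
bounded 1-D search on `[0, 5]` (well beyond any per-site scale) to
absolute tolerance 1e-8; with uniform rates it matches the closed form
`t* = −ln(1 − m/L)/λ`.

## Data handling

- PCP tables are TSV/CSV with `parent`, `child`, optional `sample_id`,
  `family_id`, `branch_length`, `loss_mask` columns; masks serialize as
  0/1 strings so round trips are bit-exact. Gapped sequences are rejected
  at load time (insertions/deletions make site positions ambiguous).
- Sites where parent or child is `N` are never informative; the loss mask
  can only shrink from there.
- The normalized mutation count divides substitutions by *informative*
  sites (masked sites leave both numerator and denominator), and the
  <10-mutation edge filter counts informative substitutions only: both
  choices keep the quantities per-informative-site and are applied
  consistently.
- Fourfold-degenerate masking classifies each complete parent codon
  (frame offset 0 by default — sequences are aligned to the V-gene start)
  against the standard genetic code; third positions of the eight fourfold
  codon families (CT,GT,TC,CC,AC,GC,CG,GG prefixes) stay unmasked, all
  other sites, codons containing `N`, and trailing partial codons are
  masked. The operation is idempotent.
- Tree extraction takes one PCP per edge with the parent at the rootward
  node, dropping the edge incident to the naive (germline outgroup) node;
  coordinates are 0-based throughout, and stated inclusive windows
  (e.g. evaluation positions 80–319) include both endpoints.

## Evaluation

Scores pool all informative window sites across pairs using
`p = 1 − exp(−t*·λ)` with per-pair likelihood-optimized `t*`, making
scores comparable across pairs (probabilities, not raw rates, are ranked —
the same quantity the fit assessment uses). AUROC is computed as the
Mann–Whitney statistic (ties ½), identical to all-pairs counting. AUPRC
is average precision without interpolation, with deterministic tie-breaks
by (pair, site). R-precision is micro-averaged: total hits over total R
across pairs with R ≥ 1. Substitution accuracy takes the CSP argmax with
alphabetical tie-break. The binned fit uses 20 equal-width bins in
log₁₀(probability) spanning the pooled score range; the overlap statistic
is `Σ min(Oᵦ, Eᵦ) / (½ ΣOᵦ + ½ ΣEᵦ)`. Mean per-site log-likelihood is the
Bernoulli placement log-likelihood averaged over window sites.

## Synthetic data

The generator realizes exactly the assumed process: per-site exponential
clocks with rates from a k-mer truth table (contexts read from the
parent), categorical base choice from the truth CSP rows, branch lengths
drawn per pair. Defaults: uniform random parents of length 300, 100 pairs,
branch lengths log-uniform on [0.005, 0.1] — spanning normalized mutation
counts of roughly 1–30 substitutions per 300-base pair, bracketing the
few-mutations-per-edge regime of real clonal-family data. Offsets are then
recomputed as normalized mutation counts, mimicking the real pipeline.
Boundary or `N` contexts fall back to the geometric-mean rate and a
uniform CSP (a neutral, documented choice). In-frame mode emits parents
starting with ATG and free of in-frame stop codons, for synonymous-masking
fixtures. Random truth tables use log-normal rates (σ = 1, about a
50-fold hot/cold spread, comparable to published 5-mer mutability tables)
and Dirichlet(1,1,1) CSP rows.

The generator does **not** emulate selection, indels, shared ancestry
between pairs, sequencing error, or the 5' coverage gradient of real
repertoires, so green tests establish correctness of the inference
machinery under the model's own assumptions — not real-data performance,
which requires the published repertoire datasets and is out of scope here.

### Parameter-recovery experiment

A kernel-1 model (context = one 3-mer) with embedding 16 and 64 filters is
trained for 100 epochs (lr 0.01) on 250 pairs × 200 sites = 50,000 sites
simulated from a seeded random 3-mer truth at fixed branch length 0.4.
The design is a power calculation, fixed before measurement: recovering
64 CSP rows to mean total-variation distance < 0.05 needs ≥ ~200
mutations per 3-mer context (the sampling-noise floor of a 3-category
estimate with n observations is ≈ 1.2/√n), hence the informative branch
length and ~14,000 total mutations; the width (64 filters) removes the
rank bottleneck a narrow trunk imposes on 64 independent CSP rows; the
learning rate 0.01 converges the small table-like model within the fixed
100-epoch budget. Rates are compared by Spearman rank correlation (the
overall scale is not identified). The truth model evaluated on its own
simulation (300 pairs × 400 sites, default branch-length law) checks
calibration: histogram overlap > 0.95.

## Numerical choices

- `p = 1 − exp(−x)` is computed as `-expm1(-x)`; `log p` as
  `log(-expm1(-x))` and `log(1−p)` as `−x`, preserving precision for
  small `t·λ`.
- A mutated site whose CSP assigns zero mass to the observed base yields
  an explicitly infinite cross-entropy (never clipped); training aborts
  with a diagnostic on non-finite loss.
- CSP argmax ties break alphabetically; ranking ties break by (pair,
  site) index; AUROC handles score ties as ½ via average ranks.
- Model files are versioned JSON containing the configuration and named
  flat weight arrays; load∘save preserves predictions bit-exactly.

## Limitations

- Real-data benchmarks (held-out repertoire AUROC/AUPRC tables) require
  the published processed datasets and full-scale training; they are not
  reproduced here.
- The per-site×5-mer baseline's published parameter total is not
  derivable from its description; our reimplementation documents its own
  count.
- Training is single-CPU full-precision NumPy; it is deliberately sized
  for models of a few thousand parameters, not for large architectures.
- AUROC pools sites globally rather than averaging per pair; with very
  heterogeneous pairs the two differ.
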