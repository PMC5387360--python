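# Methods

This note documents the models, the synthetic study conditions, the
numerical choices and the known limitations of `scmethyl`.

## Model

### Inputs

A target CpG site is the C of a CG dinucleotide, addressed 1-based on the
forward strand; profiles from both strands are assumed pre-collapsed to
forward-strand C positions. Two inputs are built per site:

- **Sequence window**: L_win (odd, default 1001) bases centred on the C,
  one-hot encoded with channel order A, T, G, C. Unknown bases (N, IUPAC
  codes, overhang past a chromosome end) become all-zero rows, which
  contribute nothing to convolutional activations; windows are never
  dropped for being near an edge.
- **Neighbour context** per cell: the K (default 25) nearest observed CpG
  sites on each side contribute their binary state and their distance,
  clipped at `max_dist` and divided by it. Layout: left neighbours
  farthest→nearest, then right neighbours nearest→farthest, each as a
  (state, distance) pair — 4K values. Missing neighbours are padded with
  state 0.5 (uninformative) and relative distance 1.0 (maximally far).
  The target site itself is excluded from its own context. `max_dist` is
  the largest neighbour distance collected on the training profiles,
  computed once and stored with the model; the alternative reading
  (largest consecutive-CpG gap genome-wide) differs only through the
  clipping constant.

### Architecture

The DNA module applies F motif-scanning filters of length L as a valid
(unpadded) convolution with ReLU, then non-overlapping max pooling with
step P (trailing `width mod P` positions are dropped), optionally further
conv–pool pairs, then one fully connected ReLU layer. Biases are included
(zero-initialised); there is no reverse-complement tying. The CpG module
embeds each cell's 4K-vector through one ReLU layer (E units, default 256)
and scans the embedded cells with a bidirectional GRU (hidden size H,
default 256; independent forward/backward parameters; zero initial
states); the two final hidden states are concatenated (2H outputs,
independent of the number of cells). Cells are scanned in sorted-cell-id
order; a biGRU with untied parameters is not literally order-invariant,
and no order symmetrisation is applied. The joint module applies two
512-unit ReLU layers to the concatenated [DNA; CpG] features and one
sigmoid output per cell.

### Training

The objective is the masked negative log-likelihood summed over observed
site–cell pairs plus λ₂ times the sum of squared weights (biases
excluded; an unsquared-norm variant is available via `l2_squared=False`).
Probabilities are clipped to [1e−7, 1−1e−7] before the logs. Optimisation
is Adam at batch size 128, global learning rate decayed multiplicatively
per epoch, Glorot-uniform initialisation, inverted dropout after each
pooling and fully connected layer (training mode only), and early
stopping when total validation loss fails to improve for
`early_stop_patience_epochs` (default 10) epochs, restoring the
best-epoch parameters. Protocol: the DNA and CpG modules are pre-trained
independently, each with its own per-cell sigmoid head; the joint model
is assembled from the pre-trained bodies (heads discarded), those
parameters frozen, and only the joint layers trained. All randomness
flows from one integer seed; identical seeds give bitwise-identical
parameter files (written via numpy pickle, not zip containers, precisely
so the bytes are reproducible).

When the chromosome split supplies no validation chromosomes (tiny
simulated genomes), the validation set is carved as the last `val_frac`
(default 15%) of each training chromosome **by position**. The blocking
matters: a random-site validation set shares local windows with training
sites, cannot detect chromosome-specific overfitting, and in our
experiments made both early stopping and model selection actively
misleading.

For small conv-net training runs, `train_with_restarts` trains from
several seeded initialisations and keeps the model with the best
validation AUC — initialisation luck is the dominant variance source at
desk scale, and validation AUC (on the positionally blocked set) tracks
held-out AUC well.

## Evaluation

Metrics (AUC by midrank statistic, accuracy, F1, MCC) are computed over
the pooled observed site–cell pairs of the evaluation set; a per-cell
breakdown is also available. Probabilities are thresholded at 0.5, with
exactly 0.5 mapping to unmethylated. Metrics undefined on one-class truth
are reported as missing, never imputed. Context stratification treats BED
intervals as 0-based half-open and asks whether the CpG *dinucleotide*
(1-based positions pos and pos+1) overlaps an interval — this is the only
convention under which a site at position 100 is inside both (99,100) and
(100,200) but outside (0,99), which is the behaviour we contract.
Coverage strata are inclusive-left/exclusive-right with a right-inclusive
last bin.

## Motif interpretation

Seqlets are window substrings at positions where a filter's activation
exceeds half its global maximum (strictly; at threshold 1.0 the argmax
positions are kept). PWMs use a pseudocount of 1 per nucleotide per
column and are written in MEME minimal format (ACGT column order).
Filter activity is a centre-weighted mean of activations with a
triangular kernel: with 1-based position i and centre c = (W+1)/2, raw
weight 1 − |i−c|/c, normalised to sum to one — the centre has maximal
weight, edge weights stay positive, and uniform activations are a fixed
point. Influence is the Pearson correlation of activity with predicted
methylation per cell, averaged over cells. Interpretation runs on
held-out (test-chromosome) sequences by default.

## Mutation effects

The effect of substituting base d at window position i is the analytic
gradient of the cell-mean prediction at the wild-type input times
(1 − s_nid), so wild-type entries are exactly zero; per-position scores
take the maximum absolute value over bases, and dataset profiles average
over sites. No re-normalisation of the one-hot rows is applied for the
hypothetical substitution. Positions hitting the central CpG dinucleotide
are flagged, since mutating them destroys the site whose state is
predicted. An exhaustive single-substitution re-prediction oracle bounds
the first-order error in tests (0.05 absolute on near-linear models).

## Mean/variance network

Targets per site and window scale s ∈ {1000, …, 5000} bp: each cell's
mean state over its observed sites in the window (the site itself
included), the across-cell mean, and the population (divide-by-T)
variance. Cells with no observation in a window are excluded with the
divisor reduced; at least two included cells are required, otherwise the
(site, scale) target is missing and skipped by the summed-MSE objective.
The network copies the trained DNA module, replaces the head with 2·|S|
sigmoid units (multi-task over scales), freezes the first-layer
convolutional filters, and fine-tunes the rest. The variance head uses a
plain sigmoid even though v ≤ 0.25; no output rescaling is applied.

## Synthetic study conditions

The generator emulates what the models exploit: background sequence with
C/G frequencies tuned so the CpG dinucleotide density hits a target
(default 0.02); planted PWM instances at recorded positions; a per-site
methylation propensity sigmoid(base + motif score · weight + σ·z) where z
is a unit-variance Ornstein–Uhlenbeck field over CpG positions
(exponential kernel — simulated exactly and sequentially at the irregular
positions) mixed from a shared and a per-cell component
(√ρ·z_shared + √(1−ρ)·z_cell, so ρ is the cross-cell logit correlation);
Bernoulli states; and independent per-cell observation masks at coverage
fractions in the single-cell bisulfite range. Motif match scores are PWM
log-odds rescaled to [0,1] and thresholded at 0.8, so only near-consensus
matches within `motif_radius` of a site contribute. The planted default
motif (consensus TGACGTCA) carries a central CG — every instance contains
a target CpG — and balanced G+C content, so near-matches are rare in the
A/T-rich background that density tuning produces.

Three named fixtures define the experiments (all deterministic from one
seed):

- **motif** (sequence-driven): 2 × 50 kb chromosomes, 5 cells, coverage
  0.3, motif effect +5 logits within 100 bp of an instance over a −2.5
  base (background ≈ 8% methylated, motif-adjacent ≈ 92%), weak spatial
  field (σ 0.5). Used for DNA-module recovery: desk-scale training
  reaches held-out AUC ≥ 0.75 and first-layer seqlet PWMs match the
  planted PWM at r > 0.8.
- **neighbor** (correlation-driven): 2 × 50 kb, 8 cells, coverage 0.3, no
  motifs, strong short-range field (σ 3, length scale 500 bp), cross-cell
  mixing 0.85. Used to show the CpG module beats both window averaging
  (which weights a 3001 bp window uniformly) and cross-cell averaging
  (which ignores within-cell context).
- **variance** (window-scale sequence signal): 2 × 100 kb, 8 cells,
  coverage 0.5, motif effect +3.5 logits within 400 bp, base −2.5,
  moderate field (σ 1), low cross-cell mixing 0.3. Regional methylation
  mean and cell-to-cell variance both respond to motif coverage here.
  This fixture is deliberately larger and more densely observed than the
  others: mean/variance targets live at 1–5 kb scale, so a 50 kb
  chromosome offers only ~50 independent regression examples, too few to
  identify a window-scale regression at all. Chromosome length and
  coverage were sized for identifiability of this experiment (the site-
  scale fixtures are unchanged); desk-scale window lengths and the number
  of independent windows still bound what is achievable, and the
  mean-prediction correlations reached here are far below what the same
  architecture attains on real genomes with thousands of kilobases of
  training sequence.

What the generator does **not** emulate: read-level bisulfite conversion
noise, strand asymmetry, non-CpG contexts, CpG islands and other
non-stationary sequence composition, annotation-dependent methylation
domains, and realistic motif grammars. Passing the recovery tests
demonstrates that the implementation can extract planted signal of the
modelled kinds — not that it reproduces published performance on real
data.

## Desk-scale configurations

`scmethyl.presets` pins the small configurations used by the tests and
the acceptance script: DNA module with one conv–pool pair (32 filters of
length 11, pool 47, 32 FC units, dropout 0.25), 201 bp windows for
site-level prediction and 1001 bp for the variance network, K = 10
neighbours, λ₂ = 0.03, learning rate 3e−3 with 0.995 decay, up to 300
epochs with patience 40, and 3 restarts. The published-scale defaults
(1001 bp, 128/256 filters, 256-unit GRU, learning rate 1e−4, batch 128)
remain the dataclass defaults. The wide pooling step deserves a note: at
~1000 training sites, fine-grained pooling leaves enough positional
freedom for the fully connected layer to memorise chromosome-specific
patterns, and a near-position-invariant representation is what makes
cross-chromosome generalisation possible at this scale.

## Numerical choices

- Float64 throughout; gradients exact up to roundoff (verified against
  central differences at 1e−4 relative tolerance).
- Probability clipping at 1e−7 for the NLL; clip gradient passes through
  inside the bounds.
- Max-pool ties break toward the first maximal position (argmax).
- Binarization of read counts: methylated iff strictly more methylated
  than unmethylated reads; ties are unmethylated.
- AUC uses the midrank tie convention.
- Early stopping monitors total validation loss (NLL + L2) for the
  site-level models; the variance network fine-tunes under a fixed epoch
  budget when no validation set is supplied.

## Limitations

- The biGRU output depends on cell order (fixed sorted order is used);
  order-invariance claims hold only approximately.
- The variance head's sigmoid range [0,1] exceeds the attainable v range
  [0,0.25]; calibration of v̂ is therefore poor even when ranking is
  informative.
- Desk-scale models are far smaller than the published-scale defaults;
  the acceptance quantities characterise this implementation on
  synthetic fixtures, not published performance on real single-cell
  data.
- The random-forest baseline uses fixed sensible hyper-parameters
  (100 trees) rather than a per-cell search.
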