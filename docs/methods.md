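# Methods

`peptox` implements a sequence-only peptide/protein toxicity classifier
family: two complementary per-sequence encoders feed a fused feature
vector into an information-bottleneck classification head, and five
architecture variants modify individual stages of that stack.  This note
records the model, the numerical choices, and what the synthetic-data
experiments do and do not demonstrate.

## Model overview

Every input is an amino-acid sequence over the 20 standard one-letter
codes with a binary toxic/nontoxic label.  Two encoders run in parallel:

1. **Evolutionary encoder.** The sequence is truncated/padded to a fixed
   1002 positions and each position is replaced by its BLOSUM62
   substitution-score row (20 columns, alphabetical order), giving a
   1002 x 20 grid.  A 2D convolution whose kernel spans the full residue
   axis extracts local inter-residue correlation; a stacked bidirectional
   GRU then captures long- and short-range order effects.  The
   concatenation of the final hidden states (2 layers x 2 directions x
   hidden 512) is the 2048-dimensional evolutionary feature.
2. **Graphical/statistical (FEGS) encoder.** Described below; emits a
   578-dimensional vector (158 curve eigenvalues + 20 amino-acid +
   400 dipeptide frequencies) from the *unpadded* sequence.

The two vectors are concatenated (2626 dims by default) and compressed
by a bottleneck head: a linear map to a latent `z` (width 128 by
default) followed by a fully connected sigmoid classifier that sees only
`z`.  The variational variant makes the latent stochastic.

### The five variants

| id | change |
|----|--------|
| `baseline` | CNN + BiGRU + FEGS + deterministic bottleneck |
| `design1`  | scaled dot-product self-attention over the BiGRU's per-position outputs, masked mean-pooled and projected back to 2048 |
| `design2`  | BiGRU replaced by a transformer encoder: sinusoidal positional encoding, 6 layers, 8 heads with per-head key/value width 64 (d = 512), inner feed-forward width 2048, each sublayer wrapped as LayerNorm(x + Sublayer(x)) |
| `design3`  | channel attention: sigmoid gates on CNN channels (masked spatial mean -> MLP -> sigmoid -> broadcast product) and a gated weighted sum of the four BiGRU state vectors, reducing the evolutionary feature to 512 |
| `design4`  | the modified graphical coordinate rule in the FEGS encoder; since that rule is the only one this package ships, `design4` is structurally the baseline composition and the id is kept for completeness |
| `design5`  | variational information bottleneck: an extra MLP on the concatenated vector, then `(mu, log sigma^2)` heads, reparameterized sampling during training, `z = mu` at inference, KL(N(mu, sigma^2) || N(0, I)) added to the loss with weight beta |

Interpretive choices the source material leaves open, fixed here and
flagged as interpretations: the "four hidden layers" of the BiGRU are
read as 2 stacked layers x 2 directions = four final state vectors of
width 512 (consistent with both the 2048 concatenation and the 512
reduction); the transformer and self-attention variants pool
per-position outputs by masked mean and project to the baseline width so
the fusion contract is variant-independent; the extra MLP of `design5`
sits before the bottleneck on the concatenated vector.

## The graphical encoder in detail

For each physicochemical property scale (one numeric value per amino
acid):

1. **zeta series.** Sort the 20 amino acids ascending by value (ties
   broken alphabetically, so features are reproducible), take cumulative
   sums of the sorted values, and affinely rescale the cumulative series
   so its minimum maps to 1 and its maximum to 20.  For non-negative
   scales the series is non-decreasing with endpoints exactly 1 and 20;
   for scales with negative entries the cumulative series may be
   non-monotone and only the min->1/max->20 mapping is guaranteed.  A
   constant cumulative series (all-zero scale) degenerates to the evenly
   spaced series 1..20.
2. **Cone coordinates.** Each property owns a right circular cone (apex
   at the origin, axis +z, default height 1 and base radius 1).  An
   amino acid with zeta value z sits on the lateral surface at axial
   fraction t = z/20 and azimuth 2*pi*z/20:
   `(r t cos(2 pi z / 20), r t sin(2 pi z / 20), h t)`.
   This spiral parametrization satisfies the cone surface equation
   x^2 + y^2 = (r z_axis / h)^2 exactly and spreads the 20 residues over
   both height and angle, so distinct zeta values never collide.
3. **Pair coordinates.** The coordinate of an ordered pair (a, b) is the
   midpoint of the two single-residue coordinates.
4. **Curve.** The sequence's curve starts at the origin; step i adds the
   residue's cone coordinate plus the pair coordinate of the adjacent
   pair (s_{i-1}, s_i) weighted by the *prefix pair frequency* f_i — the
   count of that pair among the i-1 adjacent pairs of the first i
   residues divided by i-1 (f_1 = 0).  A sequence of N residues yields
   N + 1 points including the origin.
5. **Distance matrix and eigenvalue.** M is the (N+1) x (N+1) matrix of
   Euclidean distances between curve points (symmetric, non-negative,
   zero diagonal).  Its largest eigenvalue — the Perron root of this
   non-negative symmetric matrix — is the property's scalar feature.

The cone geometry, midpoint pair rule and curve-step rule are this
package's documented parametrization of the construction; they honor all
stated constraints (cumulative 1–20 scaling, one cone per property,
prefix pair frequency, N+1 curve points, hollow symmetric distance
matrix, leading eigenvalue) and are isolated in three small functions so
an alternative rule can be swapped in.

The statistical block is the 20 amino-acid frequencies followed by the
400 dipeptide frequencies, each block normalized by its own observation
count (a length-1 sequence has an all-zero dipeptide block).  The
578 = 158 + 20 + 400 split matches the printed feature dimension.

**Property table.** The packaged table
(`peptox/data/aaindex1_synthetic_158.tsv`) is a *synthetic* AAindex1
stand-in: 158 deterministic pseudo-scales with realistic spread and
sign variety.  It fixes the feature dimension and exercises every code
path (including negative scales), but carries no biochemical meaning;
substitute a real AAindex1-derived TSV via `PropertyTable.from_tsv` for
scientific use.

## Numerical choices

- **Eigensolver.** Dense symmetric (`eigvalsh`) up to 512 curve points,
  Lanczos (`scipy.sparse.linalg.eigsh`) beyond; the two agree to 1e-6
  relative on test matrices.  Asymmetry beyond 1e-8 is a data error.
- **Padding.** Truncation keeps the N-terminal prefix; padding is
  appended C-terminally.  Padding rows of the BLOSUM grid are all-zero
  (no real BLOSUM62 row is), and padded positions freeze the GRU hidden
  state, are excluded from attention softmaxes (additive -1e9 mask) and
  from mean pooling.
- **Nonstandard residues.** Default policy drops anything outside the
  20-letter alphabet; the alternative `map` policy substitutes
  B->D, Z->E, U->C, J->L, O->K and drops the rest.
- **Loss.** Binary cross-entropy with probabilities smoothly squeezed
  into [1e-7, 1 - 1e-7]; KL weight beta defaults to 1e-3 (the
  deterministic head forces beta = 0).  One latent draw per example per
  training step; posterior mean at inference.
- **Optimizer.** AdamW (decoupled weight decay), one integer seed
  driving weight initialization, minibatch shuffling and latent
  sampling; training is bit-reproducible given the seed.
- **Metrics.** Accuracy, sensitivity, specificity, F1 and Matthews
  correlation from the confusion counts; a vanishing denominator
  reports 0 with a warning so cross-validation aggregation never
  aborts.  McNemar's test uses the exact two-sided binomial p-value
  when the discordant count b + c < 25 and the continuity-corrected
  chi-square otherwise; the uncorrected statistic (b-c)^2/(b+c) is
  available by flag.  Length-interval error rates use half-open bins,
  by default deciles of the evaluated length distribution.

## Synthetic data: what it shows

The generator draws sequences of uniform random residues with lengths
uniform in a range (default 20–50) and plants a short motif (default
`KWKWK`) at a random position in a `motif_rate` fraction of positives.
Negatives can contain the motif only by chance, so the signal strength
is known and tunable.  This emulates the *shape* of the real task —
labeled FASTA in, probability out, class-balanced training — but none of
its biology: real toxins share evolutionary families, length/composition
biases and motif redundancy that random sequences lack.  Passing the
recovery experiments therefore shows that the pipeline can extract a
planted sequence signal end to end, not that it reaches any particular
accuracy on real toxin benchmarks (which require the external datasets
and full-scale training).

Experiment sizes were chosen to keep a full run on one CPU core in the
minutes range: recovery trains on 400 sequences (200 per class) and
evaluates on 100 held-out sequences, with a reduced encoder
(56-position window, 16 CNN filters, hidden 16) whose dimension
arithmetic is identical to the full-size configuration.  Full-size
(1002/512/2048) forward passes are exercised for the dimension
contracts; training at that width is out of scope here.  Epoch-budget
defaults (500 protein / 150 peptide) are retained as configuration
defaults for full-scale use.

## Known limitations

- The packaged property table is synthetic; eigenvalue features on it
  are structurally correct but biologically meaningless.
- No redundancy filtering, no transfer learning from pretrained protein
  weights, no hyperparameter search — all out of scope.
- The neural stack runs on a small numpy autodiff core written for this
  package; it is exact (gradient-checked against central differences)
  but not optimized for GPU or large-batch throughput.
- `design4` is an alias of the baseline composition because only the
  modified graphical coordinate rule ships.
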