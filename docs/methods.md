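# Methods

## Model

`coevspec` models a paired protease–substrate alignment as draws from a
q-state Potts distribution P(A) ∝ exp(Σ_{i<j} e_ij(A_i, A_j) + Σ_i
h_i(A_i)) over the L = L_NIa + L_Sub concatenated columns, with the gap
treated as a full 21st state. Parameters are inferred by the mean-field
approximation: couplings are the negated inverse of the
connected-correlation matrix C_ij(A,B) = f_ij(A,B) − f_i(A) f_j(B)
restricted to q−1 states per position, and fields follow from the
mean-field consistency relation h_i(A) = ln(f_i(A)/f_i(gap)) − Σ_j Σ_B
e_ij(A,B) f_j(B). Mean-field inversion is a weak-coupling
approximation: absolute parameter values are biased at strong coupling
(couplings shrink with the pseudocount), but pair rankings, score
differences and mutation signs — the quantities the tool reports — are
stable, which is what the synthetic recovery checks measure.

Specificity is the canonical-minus-scrambled energy difference. Two
Potts models are fit on the same rows: the canonical model on
organism-matched pairs and a null model on rows whose substrate block
was re-partnered by a uniform random permutation. For a candidate pair,

    H = − Σ_{i ∈ protease block} Σ_{j ∈ substrate block} e_ij(A_i, A_j)
        − Σ_{i=1..L} h_i(A_i)

is evaluated under both parameter sets and H_spec = H_can − H_scram.
Only inter-block couplings enter H even though the joint fit also
produces intra-block couplings; fields run over all positions. The
scrambled subtraction cancels everything two unrelated family members
share (composition, conservation), leaving the pairing-specific signal.

## Key parameter choices

| parameter | default | meaning |
|---|---|---|
| `pseudocount` | 0.5 | relative weight λ of the uniform frequency prior (f = λ/q + (1−λ)·counts); the customary mfDCA default. λ > 0 also guarantees an invertible C. |
| `identity_threshold` | 0.8 | rows sharing ≥ 80% identical columns (gap counts as a matchable state, all columns of the concatenated row) split one unit of weight; M_eff is the weight sum. |
| gauge | gap | every coupling row/column and field entry involving the gap is zero, so gap padding contributes nothing and a bare 7-mer motif in a 20-column block scores through its motif columns only. |
| `n_scrambles` | 1 | number of pooled substrate permutations in the null alignment; pooling more permutations lowers the variance of the null at the cost of n× more rows in the second fit. |
| `masked` | True | zero all parameters touching substrate columns outside the P6–P1′ window, in *both* Hamiltonians (applying the mask to only one would make the subtraction compare different energy surfaces). |
| clip range | [−180, −80] | applied to masked H_spec before comparison with fluorescence readouts, which cannot be negative; values outside the range saturate. |
| DeltaCon `seed, g, ε` | 42, 20, 0.01 | node-group count and propagation strength of the approximate fast-belief-propagation affinities; with g ≥ n the computation is exact (one-hot identity groups). |

Scrambling does not forbid fixed points: with M rows the expected
number of rows keeping their partner is 1, negligible against
alignment size, and the unconditioned uniform permutation is simpler
to reason about and to test.

Positions are 1-based inclusive everywhere user-facing; substrate
positions may also be addressed as P6…P1′ through the motif window
(window columns map to P6, P5, P4, P3, P2, P1, P1′ in order).

## Numerical choices

- C is inverted densely (one (L·(q−1))² solve); singular C (λ = 0 with
  low diversity) raises an error advising a pseudocount.
- Couplings are exactly symmetrized (e_ij(A,B) = e_ji(B,A)) after
  inversion; diagonal blocks are zero.
- Direct information uses the standard two-site construction: for each
  pair, auxiliary single-site factors are fixed-point iterated
  (tolerance 1e−6, max 500 iterations, error on non-convergence) until
  the two-site marginals match f_i and f_j; DI is the KL divergence of
  that distribution from the factorized product. DI is clamped at 0
  against rounding.
- Mutation scans are incremental — only terms touching the mutated
  position are re-evaluated — and agree with full rescoring to 1e−8;
  scans propose residues only, never the gap.
- ROC curves keep every distinct threshold (no intermediate dropping);
  AUC is trapezoidal; the Youden-optimal threshold maximizes TPR − FPR
  with ties broken toward the lower FPR (the more conservative
  classifier). Raw H_spec grids are sign-inverted internally so larger
  = positive class; sign-inverted or cognate-normalized grids are used
  as-is.
- Pearson p-values use the exact t transform (n − 2 df), two- or
  one-tailed.
- DeltaCon edge weights must be non-negative; the preparation helper
  clips, sign-inverts and min–max rescales H_spec grids to [0, 1]. The
  published pipeline states only that edge weights were "normalized";
  min–max is this package's documented choice (exposed, with "none" as
  the alternative), so graph similarities against external readouts
  are comparable only under the same normalization. Affinities are
  computed by a dense linear solve of (I + ε²D − εA) S = B and clamped
  at 0 before the square root.
- Cognate normalization divides each row by its diagonal entry and
  errors on a zero diagonal, naming the protease.

## Synthetic ground truth

The generator emulates the statistical structure the inference
assumes: a Potts model over a protease block and a substrate block
whose inter-block couplings encode specificity classes. Residue states
are assigned round-robin to n_classes classes; remainder states (and
the gap) are classless and carry no couplings, so the classes cover
equally many states — otherwise the larger class is entropically
favored and dominates the sampled mixture. Each planted (protease,
substrate) contact carries a table with +coupling_scale for same-class
state pairs and −coupling_scale across classes; the planted protease
positions are additionally chained to each other with the same table
so that every sampled row adopts one coherent class, making "matched
pair" well defined at the row level. Defaults: L_NIa = 25, L_Sub = 7,
q = 8, 3 classes, 6 planted contacts, coupling scale 1.5, field scale
0.1 — sized so that a 5,000-row sample supports full recovery in
seconds while leaving visible class overlap.

Sampling runs one independent Gibbs chain per row (heat-bath updates,
one sweep = all L positions) for burn_in + thin sweeps and takes the
final state, so rows are exactly independent; the mean-energy trace is
monitored and a drifting tail logs a convergence warning. The L = 2
exactness test checks the sampler against the enumerable Boltzmann
distribution.

What the generator does **not** emulate: phylogenetic correlation
between rows (real homolog sets are tree-structured, which inflates
apparent covariation and is exactly what identity reweighting
mitigates), gaps with insertion/deletion structure, biased amino-acid
composition, and the 21-letter alphabet at realistic depth (tests use
reduced q for speed; all code paths are q-generic). Passing the
synthetic recovery criteria therefore shows the inference machinery is
correct on data satisfying its own assumptions — not that real-data
scores are calibrated. Absolute H_spec values on real alignments also
depend on the reweighting threshold, pseudocount and gauge, for which
the published study reports no values; rankings and mutation-effect
signs are the robust outputs.

## Recovery metrics

`recovery_report` quantifies three things against the planted truth:
(a) precision of the top-k inter-block direct-information pairs at k =
number of planted contacts; (b) AUC of −H_spec as a classifier of
class-matched vs mismatched protease/substrate row combinations (100
rows, all 10,000 combinations); (c) the fraction of class-switching
single-site substrate substitutions whose ΔH_spec sign matches the
planted direction, where the planted direction is defined by the
mutated position's coupled protease partner (mutating toward the
partner's class lowers the true energy). Row-majority class labels are
used for (b); for (c) the partner position's own state defines the
truth, since majority labels are only ~90% coherent with individual
positions.

## Known limitations

- Mean-field inversion materializes the full (L, L, q, q) coupling
  array: a 245+20-column, q = 21 model takes ~250 MB and a ~5,400²
  dense inversion (minutes, single CPU); memory, not time, is the
  practical ceiling for longer concatenations.
- Unaligned query mapping is profile-free (exact training-row match,
  motif-window placement, or global alignment to the block consensus);
  distant homologs with long insertions should be aligned externally
  and supplied pre-aligned.
- The scrambled null is a single (or pooled) permutation draw, not an
  analytic null; with very small alignments the null fit itself is
  noisy and H_spec inherits that variance.
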