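# coevspec

Coevolutionary scoring of protease–substrate specificity for potyviral
NIa proteases.

NIa proteases of the *Potyviridae* family recognize a short (~7 residue,
P6–P1′) cleavable sequence, and protease and substrate have coevolved:
organism-matched pairs carry covariation signals that random
protease–substrate combinations lack. `coevspec` turns that signal into
a quantitative specificity score. It is aimed at protein engineers who
want to rank natural protease–substrate pairs, predict the effect of
single-site substrate mutations, and design orthogonal (mutually
non-crossreactive) protease sets — and at computational biologists who
want a self-contained, fully testable implementation of the underlying
inference.

## The model

From a paired alignment (a protease block of length L<sub>NIa</sub>
concatenated to a substrate block of length L<sub>Sub</sub>, rows
matched by organism), mean-field direct coupling analysis (mfDCA)
infers a 21-state Potts model: couplings *e<sub>ij</sub>(A, B)* and
local fields *h<sub>i</sub>(A)* obtained by inverting the
connected-correlation matrix of reweighted, pseudocount-regularized
amino-acid frequencies. The energy of a candidate pair is

```
H = − Σ_{i ∈ protease} Σ_{j ∈ substrate} e_ij(A_i, A_j) − Σ_i h_i(A_i)
```

with the coupling sum restricted to inter-molecular position pairs.
Two models are fit: one on the canonical (organism-matched) rows,
one on rows whose substrates were randomly re-partnered. The
specificity score is

```
H_spec = H_canonical − H_scrambled
```

— the scrambled term removes family-likeness shared by arbitrary
homolog combinations, so what remains is the interaction-specific
signal. More negative H_spec means stronger predicted specificity.
*Masked* H_spec zeroes every parameter touching substrate positions
outside the P6–P1′ window, for experiments that probe the bare motif.

On top of the score the package provides single-site mutation scans
(ΔH_spec, negative = predicted improvement), per-coupling
decompositions of score differences, protease × substrate
orthogonality matrices with the standard transforms (clipping to
[−180, −80], sign inversion, cognate/diagonal normalization), ROC
analysis with Youden's J threshold selection, and DeltaCon
bipartite-graph similarity (fast-belief-propagation affinities,
Matusita distance, similarity = 1/(1+d)).

A synthetic module generates paired alignments from a *known* Potts
ground truth with planted inter-block contacts and specificity
classes, so every stage — reweighting, frequency counting, coupling
inversion, DI ranking, H_spec separation, mutation signs — is testable
end to end without any download.

## Worked example

```python
from coevspec import GroundTruthSpec, SpecificityScorer, make_ensemble, recovery_report

spec = GroundTruthSpec()          # 25+7 columns, q=8, 3 specificity classes
ens = make_ensemble(spec, n_rows=1500, burn_in=150, seed=11)
scorer = SpecificityScorer(scramble_seed=12).fit(ens.alignment)

prot = ens.alignment.protease_block.sequences[0]
sub = ens.alignment.substrate_block.sequences[0]
score = scorer.score_pair(prot, sub, masked=False)
print(f"H_can = {score.h_can:.2f}, H_scram = {score.h_scram:.2f}, "
      f"H_spec = {score.h_spec:.2f}")

effects = scorer.mutation_scan(prot, sub, targets=[2], masked=False)
best = min(effects, key=lambda e: e.delta_h)
print(f"substrate position 2: best {best.from_state}->{best.to_state} "
      f"dH = {best.delta_h:.2f}")

print(recovery_report(ens, scorer, rng_seed=13))
```

prints

```
H_can = -5.12, H_scram = 3.89, H_spec = -9.00
substrate position 2: best D->C dH = -2.46
{'di_precision': 1.0, 'matched_auc': 0.9012711218749034,
 'delta_h_sign_agreement': 0.9833333333333333, 'n_planted': 6,
 'n_eval_rows': 100, 'n_mutation_trials': 60}
```

The true partner scores well below zero (H_spec = −9.00: the canonical
model finds the pair far more plausible than the scrambled null does);
the most favorable substitution at substrate position 2 is predicted
to improve cleavage (ΔH < 0). The recovery report shows the fit
recovered the planted structure: all 6 planted inter-block contacts
top the direct-information ranking, H_spec separates class-matched
from mismatched combinations with AUC 0.90, and 98% of class-switching
mutations get the planted ΔH sign.

The same pipeline is scriptable from a shell — `coevspec simulate`,
`train`, `score`, `scan`, `matrix`, `roc`, `deltacon`, `recover`
(see `coevspec --help`); real alignments enter through `coevspec pair`
/ `train` as aligned FASTA or Stockholm blocks.

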