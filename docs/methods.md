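# Methods

## Problem and model

`dmccda` scores unobserved circRNA–disease pairs from three information
sources: verified associations (a sparse binary bipartite matrix `A`),
circRNA sequences, and the placement of diseases on the Disease Ontology
DAG. The modelling assumption is guilt-by-association: similar circRNAs
tend to partner with similar diseases. The method first *propagates* the
two side similarities through `A`, then *denoises* the result under a
low-rank prior with box constraints, once in each space, and blends the
two recovered score matrices.

The completion step solves, per spliced block `M`,

```
min_X  ‖X‖* + (α/2)‖X − M‖²_F    s.t.  0 ≤ X ≤ 1
```

The fidelity term runs over *all* entries — the block is treated as a
noisy observation to be denoised, not as a partially observed matrix with
a mask. The nuclear norm is the convex surrogate for rank; the box
constraint keeps scores interpretable as association strengths in [0, 1].
The objective is strictly convex (α > 0), so the minimizer is unique —
which is also what lets the test suite compare the ADMM solution against
an independent projected-subgradient solver.

### ADMM solver

Splitting `X = W` with multiplier `Y` and penalty `β` gives three exact
updates per iteration:

1. `W ← clip((αM + Y + βM1)/(α + β), 0, 1)` — the stationary point of the
   quadratic part, projected onto the box;
2. `M1 ← svt(W − Y/β, 1/β)` — singular-value soft-thresholding, the
   proximal map of the nuclear norm;
3. `Y ← Y + β(M1 − W)`.

Initialization: `M1₀ = W₀ = M`, `Y₀ = 0`. The final score matrix is read
from `W`, the box-feasible iterate, so bounds hold exactly rather than up
to the primal residual.

**Stopping rule.** Iteration stops when *both* the relative Frobenius
change of `M1` and the relative primal residual `‖M1 − W‖_F/‖M1‖_F` fall
below `tol`, or at `max_iter`. Requiring both is slightly stronger than a
change-only rule and guarantees that at termination the two iterates
agree to the tolerance, so it does not matter which one is reported. With
the defaults (`α = 1`, `β = 10`, `tol = 1e−6`) random blocks of the sizes
used in the tests converge in roughly 100–150 iterations; the larger
structured pipeline blocks may use the full `max_iter = 300` cap, at
which point the residuals are ~1e−6–1e−5 and scores have long stabilized
at score precision.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha_admm` | 1.0 | fidelity weight of the completion objective (unitless) |
| `beta_admm` | 10.0 | ADMM penalty; SVT threshold is `1/beta_admm` |
| `tol` | 1e−6 | relative stopping tolerance (both residuals) |
| `max_iter` | 300 | iteration cap per block |
| `alpha_mix` | 0.7 | weight of the circRNA-space scores in the blend |
| `w_e` | 0.5 | semantic decay per is_a hop |
| `beta_prime` | 1.0 | original GIP bandwidth |

`alpha_mix = 0.7` favours the circRNA space, the setting that performs
best in the source analyses; `w_e = 0.5` is the standard decay of
Wang-style DAG similarity; `beta_prime = 1` is the GIP convention. The
ADMM pair (1, 10) follows the bounded-nuclear-norm literature the model
builds on; the solver is insensitive to `beta_admm` within an order of
magnitude since it only affects the path, not the unique optimum.

## Design choices that were genuinely open

* **Normalization denominators.** The column/row rescaling of `Ac = CC·A`
  and `Ad = A·DD` uses the *Euclidean norm* of the original `A`'s
  column/row (the network-consistency-projection convention), with
  0/0 defined as 0 so that a new node's slice stays exactly zero until
  similarity fills it in.
* **Block orientation.** Blocks are horizontal splices with the
  association part last (`[K | assoc]`); only the round-trip property of
  extraction matters, and it is tested.
* **Scores from `W` vs `M1`.** Both agree to within the primal residual
  at convergence; `W` is used because it is box-feasible by construction.
* **Semantic recursion.** The max-over-children recursion is evaluated
  bottom-up over the ancestor closure; with a uniform `w_e` it collapses
  to `w_e^(shortest upward hop count)`, and multi-parent terms take the
  union of all is_a paths as their closure.
* **Evaluation pooling.** LOOCV pools every held-out positive's score
  (from its own masked refit) against the candidate scores of the
  full-data model; five-fold CV does the same per repeat with
  unstratified uniform fold shuffles drawn from per-repeat substreams of
  one master seed. Per-fold candidate rescoring is available behind a
  flag. GIP kernels are always recomputed from the masked matrix.
* **AUC ties.** The ROC sweep uses trapezoidal integration over all
  distinct thresholds, equivalent to the Mann–Whitney statistic with ties
  counted one half, so rankings with duplicated scores evaluate
  permutation-stably.
* **Edit distance.** Unit costs for insertion, deletion and substitution;
  sequences are uppercased with U→T before comparison so DNA- and
  RNA-alphabet FASTA files agree. Distances are computed by edlib's
  global (Needleman–Wunsch) aligner.

## The synthetic benchmark

`simulate_instance` plants the structure the model assumes. Each circRNA
and disease gets a dominant latent cluster (of `rank` clusters) and a
non-negative factor vector concentrated on it; the truth matrix is the
min–max-rescaled factor product; the top `density` fraction of entries
become the known positives (exact counts, deterministic fold
arithmetic); `CC`/`DD` are cosine similarities of the factors with
symmetric Gaussian jitter (scale `noise`), clipped to [0, 1] with unit
diagonal restored. Sequence families reuse the circRNA clusters (one
random prototype per cluster, i.i.d. substitutions at `mut_rate`), and
the random ontology places same-cluster diseases as sibling leaves of a
rooted tree.

Default conditions: `nc = 60`, `nd = 20`, `rank = 3`, `density = 0.05`
(60 positives, the few-percent density regime of curated circRNA–disease
data), `seq_len = 200`, `mut_rate = 0.05`, `noise = 0.05`. These sizes
keep a full repeated-CV sweep in seconds while leaving the recovery
problem non-trivial (jitter, hard thresholding, sparse positives).

What passing on this generator shows — and does not show. Because the
similarities derive from the same latent factors as the associations, the
generator certifies that the pipeline *recovers planted signal through
the intended mechanism* and that each component contributes (the two
ablations score measurably lower). It does not certify performance on
real curated data, where similarity quality is uneven, the DAG is deep
and unbalanced, sequence lengths vary by orders of magnitude, and the
association process is not low-rank plus noise.

## Numerical notes and degenerate inputs

* An all-zero association matrix has no defined GIP bandwidth and is
  rejected; single empty profiles are fine (kernel 1 against another
  empty profile, `exp(−β‖p‖²)` against profile `p`).
* Exact score ties in rankings and written tables break on the
  lexicographic (circRNA, disease) ID order, so outputs are
  deterministic.
* The pipeline contains no randomness: repeated runs are bit-identical,
  and permuting the input axes permutes the scores (to SVD floating-point
  reproducibility, ~1e−9).
* Scores in the completion-backed modes lie in [0, 1] by construction.
  The multiplication-only ablation has no box step and its blended scores
  can exceed 1; AUC-based evaluation is unaffected since it is invariant
  to monotone score transforms.
* `svt_shrink` rejects non-finite input; ADMM raises with the recent
  iteration trace if a residual ever becomes non-finite.

## Known limitations

* Masked (partially observed) completion is out of scope — the model
  denoises fully observed blocks.
* Only two similarity sources per axis are fused; no learning of fusion
  weights beyond the single `alpha_mix` scan.
* LOOCV refits once per positive and is quadratic-ish in the positive
  count; at desk scale this is seconds, but large curated datasets would
  want the k-fold protocol instead.
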