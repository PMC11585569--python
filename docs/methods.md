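# Methods

## Model and assumptions

Metabolite dynamics `dM/dt = S·v(M, p)` are linearized at a stable steady
state. Two independent Gaussian noise sources act on the system: `ω`
directly on metabolite concentrations (covariance `D₁`, diagonal) and `τ`
on reaction parameters (covariance `D₂`, diagonal). Propagating parameter
noise through the rate sensitivities `K = ∂v/∂p` (diagonal, one parameter
per reaction) and the stoichiometry gives the total forcing covariance

    D = S (K D₂ Kᵀ) Sᵀ + D₁,

which is symmetric PSD by construction and generally non-diagonal: species
sharing a reaction receive correlated forcing with sign
`sign(S_ir · S_jr)` per shared reaction `r`. Conflicting signs from
several shared reactions are represented explicitly as *indeterminate*
and resolved by a random ±1 per sampled matrix, never silently. For
condensed multi-step interactions (superpathways over unmeasured
intermediates), the sign is `(−1)^(k+1)` with `k` the number of same-side
(type-2) steps.

The stationary covariance obeys `J C + C Jᵀ = −2D`. The forward solve
uses the Bartels–Stewart algorithm (`scipy.linalg.solve_continuous_lyapunov`);
the result is explicitly symmetrized and the identity residual is checked
against `1e−8 · max(1, max|D|)`, warning with a condition estimate of the
Kronecker operator when violated. Jacobians with spectral abscissa above
`−1e−9` are rejected as unstable.

## The regression-loss statistic

Restricted to the Jacobian zero-pattern, the Lyapunov identity becomes
`A q = b` with one equation per upper-triangle position `(i ≤ j)` in
row-major order (a fixed, documented ordering shared by `A` and `b`), one
column per free Jacobian entry in row-major order, and
`b = −2 vech(D)`. The coefficient of unknown `J[k,l]` in equation `(i,j)`
is `[k=i]·C[l,j] + [k=j]·C[l,i]`.

For each candidate interaction `(i,j)`, the two condition systems are
stacked block-diagonally with the two `J_ij` columns merged (the
"shared-entry" constraint), and the score is the least-squares residual
minimized over sampled right-hand sides. Numerically the per-element
residual is computed as `‖b_c − Q Qᵀ b_c‖` with `Q` an orthonormal basis
(SVD) of the merged column space — identical to minimum-norm least squares
at any rank, stable under rank deficiency, and computable for all 1000
samples with one matrix product per element. The public `element_loss`
uses LAPACK `gelsd` directly; a test asserts both routes agree to 1e−10.

Sample streams are prefix-stable: sample `s` draws from a generator keyed
by `(seed, s)`, so increasing the sample count never changes earlier
draws and the min over samples is monotone. All elements score the same
sample stream, making comparisons across elements paired. `R*` is min–max
normalized to [0, 1] over the evaluated support — by default the
off-diagonal pattern positions (interactions); diagonal entries can be
included by flag. If all losses agree to machine precision the matrix is
reported as all zeros and flagged degenerate, rather than stretching
rounding noise across [0, 1].

### Identifiability

A structural precondition surfaced during development: the per-condition
system `A` must have full column rank, i.e. the Jacobian pattern must not
carry more free entries than upper-triangle equations within any connected
block. Otherwise every constrained system is exactly consistent, all
losses are zero, and the statistic is uninformative. The synthetic
generator enforces this by construction (resampling until the vectorized
system at a generic covariance has full column rank); users supplying
their own interaction networks inherit the check implicitly through the
degenerate-result flag. Sparse, superpathway-like patterns — the intended
input — satisfy it comfortably.

## Sampling strategies

* **diagonal** — `D` diagonal with i.i.d. uniform [0, 1] entries; the
  classical independent-fluctuation assumption.
* **topological** — every structurally allowed entry gets an i.i.d.
  uniform [0, 1] magnitude times its structural sign (random ± for
  indeterminate entries, one draw per matrix). Whether the published
  protocol scales a single shared magnitude or per-entry magnitudes is
  ambiguous; per-entry magnitudes are used here (both were evaluated; the
  qualitative comparisons are unchanged).
* **integrative** — as topological, but each off-diagonal magnitude is
  uniform on [0, bound(i,j)] where the bound is the enzyme-activity
  variance mapped to that interaction; diagonals sample [0, diag_scale]
  (default 1; per-metabolite overrides via the bounds diagonal). A missing
  bound on a structurally nonzero entry is an error naming the entry.

Uniform (not Gaussian) magnitudes are the maximum-entropy choice on the
stated bounded ranges. Samplers take an explicit generator; there is no
global random state.

## Enzyme activities from expression

GPR rules (identifiers, case-insensitive `and`/`or`, parentheses, no
negation) are evaluated with AND → max of children and OR → sum of
children. Per condition, activities use the unbiased (n−1) sample
variance; conditions need at least two samples. The bound for a
multi-step interaction is the **maximum** variance over its superpathway's
reactions — the bound must admit the largest constituent fluctuation; the
aggregation rule is a package choice as no canonical one exists.

## Synthetic benchmark

`generate_network(n, m, density)` builds random mass-action networks:
`m` core reactions with 1–2 substrates and 1–2 products (disjoint,
`density` = probability of the bimolecular choice), unit stoichiometry,
log-normal rate constants, plus one balancing first-order outflow and one
constant inflow per species so that a random concentration vector in
[0.5, 2] is an *exact* steady state. Networks are redrawn (bounded
retries) until Hurwitz-stable and identifiable. The second condition
scales selected rate constants by a factor (default 5×) with both
Jacobians evaluated at the reference state, so changed entries scale by
exactly the factor and the ground-truth changed set is the support of
`|J_h − J_d|`.

Perturbed fluctuation pairs follow the benchmark recipe: shared base `D`
with uniform [0, 1] diagonal; `N` off-diagonal positions each receiving a
magnitude uniform on [0, Md] (mirrored; the unsigned magnitude added to
both incident diagonals); then independent symmetric Gaussian noise of
standard deviation `ε_D · Md` per condition. The recipe does not fix the
off-diagonal sign, so a random ± per position is drawn (consistent with
the random-sign convention for indeterminate structure). Noise is not
clipped and the result is not projected to PSD — the covariance
generation is a linear solve and the evaluation counts non-PSD draws
instead. Mixed-magnitude settings are expressed as component groups
`(count, magnitude, in_topology)`; the topological structure given to the
inference covers only groups flagged `in_topology` (the "structure known
for large fluctuations only" protocol), while integrative bounds cover
all groups.

The default benchmark model is a 10-metabolite, 9-core-reaction network
at density 0.15 with 3 reactions changed 5-fold — the scale of a mid-size
central-carbon pathway model with the sparsity typical of
superpathway-condensed networks. This yields ≈ 24 free Jacobian entries
against 55 equations per condition (strongly overdetermined), 14
evaluated interactions and ≈ 5–6 strongly changed ones, enough for
threshold and top-5 metrics to be meaningful.

## Evaluation protocol

Per repeat: draw a perturbed `(D_h, D_d)`, forward-solve `(C_h, C_d)`,
run each strategy on the same per-element projection bases, min–max
normalize both `R*` and the true `DJ` over the same off-diagonal support
(entries where an interaction vanished entirely are assigned the largest
finite value and flagged), then score. Precision (PPV) and recall (TPR)
threshold both normalized matrices at 0.3–0.9; undefined ratios (empty
denominators) are excluded from averages and the exclusion count is
reported. Top-k precision is the overlap of the k largest entries, ties
broken by lowest linear index. Default protocol: 200 repeats × 1000
samples per setting; the full battery runs in a few minutes on one CPU.

What passing benchmarks do and do not show: the generator emulates the
*statistical structure* of condition-specific fluctuation data — sparse
stable Jacobians differing in a known entry set, structured symmetric
fluctuations with controlled off-diagonal count/magnitude/noise. It does
not emulate finite-sample covariance estimation error (covariances are
exact Lyapunov solutions), Michaelis–Menten saturation, allosteric
regulation absent from network databases, or measurement error in
expression data; conclusions about real data carry those caveats.

### Observed behaviour of the strategy comparison

On this synthetic family, structure-aware sampling consistently matches
or improves *precision* and top-k accuracy over the diagonal assumption,
with the largest gains for strong off-diagonal fluctuations, and the
diagonal assumption is indistinguishable (precision gap ≲ 0.1) when
off-diagonal fluctuations are small — both expected patterns. A recall
*reduction* under structured sampling and a systematic integrative-over-
topological precision gain did not reproduce robustly here: the
differences sit within Monte-Carlo error of zero at 200 repeats. An
oracle analysis (scoring elements with the residual of the true `b`)
ranks changed interactions perfectly even at the highest noise setting,
so the information is present in the data; the limiting factor is the
min-over-samples statistic itself, whose contrast shrinks as the sampled
cone's dimension grows. Two acceptance tests encode the stricter
directional claims and are left failing rather than weakened.

## Numerical choices and limitations

* Dense linear algebra throughout; intended scale is tens of metabolites.
* Stability margin `−1e−9`; Lyapunov residual tolerance
  `1e−8 · max(1, max|D|)`; PSD assertions at `−1e−10`; degenerate
  normalization threshold `1e−12` relative.
* One enzyme parameter per reaction (diagonal `K`); correlated parameter
  fluctuations (non-diagonal `D₂`) are out of scope.
* Actual Jacobian values `q` are not reported — only the loss proxy; no
  significance calibration of `R*` entries is attempted.
* CSV/TSV formats: labelled square CSVs (comma, '.' decimal, UTF-8,
  `repr`-precision floats for exact round trips); reaction networks as
  `(reaction_id, species_id, stoich_coeff, is_dependency)` edge lists;
  interaction networks as
  `(source, target, n_type2_steps, reaction_ids, sign_override)` rows.
  Species order follows first appearance; all matrices carry label
  headers.
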