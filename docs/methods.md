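# Methods

## Model and conventions

The package works with stimulus-driven pairwise maximum-entropy (Ising)
models of binned spike rasters:

    P(σ | s) = exp( h(s)·σ + σᵀ J σ ) / Z(s),     h(s) = C(s) β,

σ ∈ {0,1}^N per time bin, C(s) an L×R stimulus design matrix, β an R×N
weight matrix, and J an N×N coupling matrix. Conventions are fixed once and
enforced everywhere:

* **Spin coding is {0,1}.** The {−1,+1} convention is refused, never
  silently converted: the factor 2 in the exact conditional
  P(σ_i = 1 | σ_{j≠i}; s) = logistic(h_i(s) + 2 Σ_{j≠i} σ_j J_ji) is only
  correct for symmetric J with zero diagonal in {0,1} coding, and every fit
  and sampler in the package relies on it.
* **J is stored exactly symmetric with zero diagonal.** A nonzero diagonal
  handed to the constructor is absorbed into a per-neuron field offset
  (σ_i² = σ_i) with a logged warning.
* **Everything is carried in log space**; ratios of partition values are
  computed as exp(log Za − log Zb).
* **Per-bin quantities are computed once per unique covariate row** and
  broadcast back to bins. Trial-structured protocols have at most
  bins-per-trial unique rows (500 for the reference protocol), which is
  what makes exact 20-neuron enumeration a desk-scale reference: ~10⁶
  pattern energies are reused across all 500 rows instead of all 20,000
  bins.
* **Pattern keys** are little-endian bit-packed integers (neuron 0 = least
  significant bit) up to N = 64, packed byte strings beyond; tables are
  canonically ordered by key so serialized tables are portable.

## The missing-mass approximation

Z(s) = X(s) + Y(s), where X(s) sums the unnormalized weights of the unique
patterns observed in training data (computed exactly: per-pattern quadratic
energies once, one matrix product per unique stimulus row) and Y(s) is
recovered from the missing mass M(s) = Y(s)/Z(s) via Z = X/(1−M). The
implementation uses the X/(1−M) form rather than X·(1 + M/(1−M)) — the
algebra is identical, the operations fewer.

* **Good–Turing**: M_GT = n_singletons/L, the classical count estimator of
  the probability of everything not yet seen. It is a single constant: it
  corrects the bias of X(s) but cannot track stimulus modulation.
* **Conditional-logistic**: the joint pattern probability is factorized as
  a chain P(σ_1|σ_2…σ_N; s)·P(σ_2|σ_3…σ_N; s)…P(σ_N|s) with neurons ordered
  by descending mean firing rate (ties broken by original index), so the
  lowest-rate neuron — whose spikes carry the least information about its
  dependence on others — gets the stimulus-only conditional. Each
  conditional is fitted as its own logistic regression on
  [C(s), {2σ_j : j later in the ordering}]. Ising models are not
  projective: these fitted weights do not equal the joint model's β and J,
  and are not meant to. What matters is that the chain product is a
  *normalized* distribution, so M_CL(s) = 1 − Σ_observed P_chain(σ|s) is a
  proper missing-mass estimate per bin. Tiny negative values from floating
  point are clipped to zero (counted and logged); M ≥ 1 is treated as an
  error — it signals a broken chain fit and refusing to invert is safer
  than clipping.

The conditional-logistic path costs O(U·N·N_pat) plus the O(L·R·N) chain
fits, with U ≤ L unique stimulus rows. Operation counts (not wall-clock
times) are accumulated in a global counter; the test suite verifies linear
growth in L and N_pat against exponential-in-N growth of enumeration.

## Fitting

All regressions are ridge-penalized logistic IRLS (Newton with step
halving), deterministic given inputs. Defaults: ridge 1e-4 (guarantees
finite weights under separation), gradient-norm tolerance 1e-8, 100
iteration cap. A step below machine precision terminates the iteration:
at large L the attainable gradient floor is set by the conditioning of the
normal equations, not by the tolerance. No intercept is added silently —
the caller's basis must span a constant (the B-spline basis does, by
partition of unity).

The joint model is fitted by pseudo-likelihood: neuron i's spikes are
regressed on [C(s), {2σ_j}_{j≠i}], so the neighbor coefficients estimate
J_ji directly; the two per-pair estimates are symmetrized by averaging and
the diagonal forced to zero. Averaging (rather than a jointly constrained
fit) is the package's documented choice. A neuron that never spikes or
never stays silent makes its regression degenerate and is reported by
index as an error.

## Baselines

* **Importance sampling**: per unique stimulus row, n patterns are drawn
  from an independent-Bernoulli proposal (per-neuron stimulus-only
  logistic fits; the model's own stimulus weights by default), and the
  weight ratios w(σ)/q(σ|s) are averaged in the linear domain with
  log-sum-exp shift stabilization. The per-bin `mc_se` is the standard
  error of the mean ratio. Fresh draws per unique row, broadcast to bins;
  seeded and reproducible.
* **Naive mean field**: damped fixed point m_i = logistic(h_i + [2J m]_i)
  from m = logistic(h); log Z is the factorized variational lower bound.
* **TAP**: adds the Onsager reaction term (second-order Plefka) to the
  fields and to the free energy, in the {0,1} convention
  (correction ½(1−2m_i)Σ_j K²_ij m_j(1−m_j) with K = 2J). TAP is *not* a
  bound: on weakly coupled sparse populations its leading (third-order)
  error is positive and it can slightly exceed exact Z, which the test
  suite documents.
* **Bethe**: loopy belief propagation on the fully connected pairwise
  graph, messages parametrized by log odds, parallel schedule, damping 0.5,
  convergence when the largest message change falls below 1e-8 (500
  iteration cap); log Z from the Bethe free energy of the fixed-point
  beliefs. Non-converged bins are flagged and returned.
* **Low-rate expansion**: log Z ≈ Σ_i log(1+e^{h_i}) +
  Σ_{i<j} p_i p_j (e^{2J_ij} − 1) with p = logistic(h) — the leading
  correction in the firing probability. All four baselines are exact at
  J = 0.

## Synthetic data

The reference protocol mirrors a repeated-trial experiment: 2500 ms trials
at 5 ms bins (500 bins/trial), 4th-order B-splines on 100 ms knots
(clamped, partition of unity, 28 basis functions), per-neuron weights drawn
uniformly in [−6, −2] and shifted by a scalar offset (root-bisection under
J = 0) so each neuron's mean firing probability matches the 5 Hz target; J
is uniform on [−J_max, J_max], symmetrized, zero diagonal. Zernike
polynomials (first 10, Noll ordering and normalization) are provided for
place-field-style drive on the unit disc.

Rasters are drawn by single-site Gibbs sampling: 20 burn-in + 10 recorded
sweeps per bin, warm-started from the previous bin (consecutive bins share
similar fields, so warm starts mix fast), first bin from independent draws
at logistic(h). Trials are independent chains and are sampled in parallel.
The sweep schedule is validated at small N: the empirical pattern
distribution at fixed stimulus is within total-variation 0.01 of the
enumerated distribution for a 4-neuron coupled model.

Because couplings shift realized rates (and strong positive coupling can
run away), `simulate_protocol` re-balances the per-neuron field offsets
self-consistently — simulate, compare empirical to target rates, nudge by
the damped logit difference — so the *data* has the protocol's rates, as a
real recording would.

**Staging a target missing mass.** With rates held, the Good–Turing
missing mass of a 100 s, 20-neuron recording is nearly flat in J_max
(≈1.1% across the stable coupling range) and collapses at stronger
coupling, where attractor states repeat patterns. It is, however, smooth
and monotone in the firing rate (≈1% at 5 Hz to ≈10% at 20 Hz), which is
also how large missing masses arise in real recordings. The calibration
helper therefore keeps the protocol's J_max and bisects a scalar rate
multiplier until the simulated M_GT hits the requested value (±10%
relative in the validation experiments). The validation experiments are
therefore indexed by their achieved missing mass, with firing rate the
staging variable.

**What the synthetic experiments do and do not show.** They exercise the
full pipeline — sampling noise, fitting error, stimulus modulation — under
a correctly specified model with smooth trial-locked drive. They do not
probe model misspecification (real populations are not exactly pairwise,
nor stationary), refractoriness or spike-history structure, electrode
artifacts, or non-trial-locked stimuli. Accuracy on real data with
comparable sparseness is plausible but not demonstrated by these tests.

## Numerical and design choices

* Enumeration cap N = 24 (blocked 2^14-pattern enumeration, chunked unique
  rows); above it, `exact_partition` refuses and names the approximations.
* Quantile convention for ratio summaries: linear interpolation of order
  statistics (numpy default, type 7). Error is summarized by the 0.005 and
  0.995 quantiles of Ẑ(s)/Z_ref(s); this ratio equals the common
  mis-scaling factor of all pattern probabilities at that stimulus.
* Train/test: fits and the pattern table always come from the training
  split; Z series can be evaluated on held-out covariates (`train_frac`);
  the default uses all data, matching the validation experiments.
* NMF/TAP fixed points: damped iteration (0.5) from m = logistic(h),
  tolerance 1e-8, cap 500; per-row convergence flags are carried on the
  returned series.
* Validation problem sizes: 20-neuron, 40-trial (100 s) experiments with
  exact enumeration over ≤500 unique rows for the headline checks;
  10-neuron, 300-trial replicates for coupling recovery; smaller
  populations for enumeration oracles. These sizes keep every oracle exact
  while exercising realistic pattern counts (hundreds to thousands).

## Known limitations

* The chain missing mass inherits logistic-regression error; it is
  accurate because unobserved patterns are individually improbable and
  errors average out, not because the chain equals the joint model.
* Good–Turing assumes exchangeable draws; strong bin-to-bin dependence
  (sticky attractor states) biases it downward, which is also why heavily
  coupled regimes are staged by rate rather than coupling strength.
* TAP and Bethe values are standard literature forms in the {0,1}
  convention; they are compared qualitatively, and TAP in particular is
  not a lower bound.
* Exact enumeration beyond N = 24 is refused rather than attempted.
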