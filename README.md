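# isingz

Fast, accurate approximation of the **stimulus-dependent partition function**
of pairwise maximum-entropy (Ising) models of binned population spike trains.

## The problem

A stimulus-driven Ising model assigns each binary spike pattern
σ ∈ {0,1}<sup>N</sup> the probability

```
P(σ | s) = exp( h(s)·σ + σᵀ J σ ) / Z(s),        h(s) = C(s) β
```

with per-bin stimulus fields h(s) built from a covariate matrix C(s) (e.g.
B-splines in trial time, or Zernike polynomials of position on a disc) and a
symmetric coupling matrix J (zero diagonal, {0,1} spin coding). The
normalizer Z(s) sums 2<sup>N</sup> terms and — because it depends on the
stimulus — must be recomputed for every unique stimulus value in the
recording. Naive evaluation is O(L·2<sup>N</sup>) and becomes infeasible
beyond ~20 neurons.

## The method

Spiking populations are sparse, so almost all of Z(s) is carried by the few
patterns that actually occur in the training data. Split

```
Z(s) = X(s) + Y(s)
```

into the exactly computed sum X(s) over observed patterns and the remainder
Y(s) over unobserved ones. Writing the **missing mass**
M(s) = Y(s)/Z(s) — the total model probability of never-observed patterns —
gives the inversion

```
Z(s) = X(s) / (1 − M(s)).
```

Two estimates of M are provided:

* **Good–Turing**: M_GT = (#patterns observed exactly once)/L, a constant
  that removes the bias of X(s) but not its stimulus-driven variance;
* **conditional-logistic**: factorize the joint pattern probability into a
  chain of N conditionals ordered by firing rate, fit each with a logistic
  regression on the stimulus and the later-ordered neurons, and set
  M_CL(s) = 1 − Σ<sub>observed</sub> P_chain(σ|s). The chain is normalized
  by construction, so this tracks the stimulus modulation of the missing
  mass bin by bin.

The whole pipeline costs roughly O(L·N·N_pat) where N_pat ≪ 2<sup>N</sup> is
the number of unique observed patterns. For comparison the package also
implements exact enumeration (N ≤ 24, deduplicated over unique stimulus
rows), Monte Carlo importance sampling with an independent-neuron proposal,
and four deterministic baselines (naive mean field, TAP, Bethe via loopy
belief propagation, and a low-firing-rate expansion), plus pseudo-likelihood
fitting of the joint model and a seeded Gibbs simulator for ground-truth
validation experiments.

## Worked example

```python
import isingz as iz

report = iz.run_experiment({
    "protocol": {"n_neurons": 12, "n_trials": 40, "j_max": 0.25, "seed": 42},
    "methods": ["exact", "x_only", "gt", "cl"],
})

print(f"Good-Turing missing mass: {report['missing_mass']['m_gt']:.4f}")
print(f"mean conditional-logistic missing mass: {report['missing_mass']['m_cl_mean']:.4f}")
print(f"unique training patterns: {report['n_patterns_train']}")
for method in ("x_only", "gt", "cl"):
    s = report["methods"][method]["summary"]
    print(f"{method:>7}: mean={s['mean']:.4f}  99% band=({s['q005']:.4f}, {s['q995']:.4f})")
```

prints

```
Good-Turing missing mass: 0.0025
mean conditional-logistic missing mass: 0.0022
unique training patterns: 143
 x_only: mean=0.9978  99% band=(0.9939, 0.9995)
     gt: mean=1.0003  99% band=(0.9963, 1.0020)
     cl: mean=1.0000  99% band=(1.0000, 1.0000)
```

This simulates a 12-neuron population for 100 s (2500 ms trials, 5 ms bins,
B-spline drive, ~5 Hz mean rates), fits the model by pseudo-likelihood, and
summarizes the ratio Ẑ(s)/Z_exact(s) per method. The uncorrected sum X(s)
underestimates Z by the missing mass (mean 0.9978 ≈ 1 − M); the Good–Turing
constant removes that bias but leaves stimulus-driven variance; the
conditional-logistic correction removes both, normalizing every pattern
probability to within a few parts in 10⁵ here.

The same pipeline is scriptable from a shell:

```
isingz simulate --neurons 20 --trials 40 --seed 1 --out data.npz
isingz fit --data data.npz --out fit.json --chain chain.json
isingz partition --data data.npz --model fit.json --method cl --chain chain.json --out z_cl.tsv
isingz partition --data data.npz --model fit.json --method exact --out z_exact.tsv
isingz evaluate --num z_cl.tsv --den z_exact.tsv
```

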