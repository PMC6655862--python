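# chancap

Information-theoretic analysis of single-cell signaling data: **mutual
information**, **channel capacity**, and **pairwise probabilities of correct
discrimination** for systems with a discrete input (stimulus level) and a
continuous, possibly high-dimensional output (e.g., a single-cell response
trajectory).

## Who it is for

Computational biologists quantifying how reliably a signaling pathway
transmits information about stimulus identity or dose — for example, how many
ligand concentrations a pathway can resolve from single-cell readouts, and
which concentration pairs gain discriminability from response *dynamics*
(time-series) over single time points.

## The method

Given data {(xᵢ, y_l^i)} with m stimulus levels and nᵢ cells per level, the
estimators work entirely through the conditional *input* distribution
P(xᵢ | Y = y) — an m-class classification problem fitted by multinomial
logistic regression,

    log P(xᵢ|Y=y) / P(x_m|Y=y) = αᵢ + βᵢᵀ y ,

never through the d-dimensional output densities P(y | xᵢ):

* **MI** under an input distribution P(X):
  `MI ≈ Σᵢ P(xᵢ) (1/nᵢ) Σ_l log₂[ P̂(xᵢ|y_l^i) / P(xᵢ) ]`.
* **Capacity** `C* = max_{P(X)} MI` by Blahut–Arimoto-style alternate
  maximization: the per-level expected log-posteriors
  `Dᵢ = (1/nᵢ) Σ_l log₂ Q(xᵢ|y_l^i)` drive the closed-form input update
  `P(xᵢ) ∝ exp(Dᵢ)`, and the posterior is recalibrated to each new prior by a
  closed-form intercept shift — one regression fit total.
* **PCD** for a level pair at equal priors: the average over held-out cells of
  `max{P̂(xᵢ|y), P̂(xⱼ|y)}` (Bayes-rule assignment accuracy, 0.5 = fully
  overlapping, 1 = disjoint), estimated over repeated train/test splits.

See `docs/methods.md` for assumptions, parameters, and numerical choices.

## Worked example

Simulate the benchmark dose–response channel — log-normal output with
saturating log-mean μ(x) = 10·x/(1+x), unit log-variance, eleven doses in
[0, 100] — and estimate everything from the sample (the log-normal family is
analyzed in log-output coordinates, where the linear-logit posterior is
exact):

```python
import numpy as np
import chancap as cc

spec = cc.scenario1_spec()
sample = cc.simulate_channel(spec, n_per_level=1000, seed=1, log_output=True)

mi = cc.estimate_mi(sample, prior="uniform")
cap = cc.estimate_capacity(sample)
print(f"MI (uniform prior): {mi.mi_bits:.3f} bits")
print(f"Capacity C*:        {cap.capacity_bits:.3f} bits "
      f"({cap.iterations} iterations, converged={cap.converged})")
print("P*(X):", np.round(cap.optimal_input.probs, 3))

pair = cc.estimate_pcd_pair(sample, "0.0", "100.0", seed=1)
print(f"PCD(dose 0, dose 100): {pair['mean']:.3f} +/- {pair['sd']:.3f}")
```

prints

```
MI (uniform prior): 1.594 bits
Capacity C*:        1.754 bits (126 iterations, converged=True)
P*(X): [0.235 0.    0.    0.    0.089 0.183 0.186 0.063 0.    0.    0.243]
PCD(dose 0, dose 100): 1.000 +/- 0.000
```

So under a uniform dose distribution the channel transmits ≈1.59 bits; the
capacity-achieving input concentrates on ~5 well-separated doses and reaches
≈1.75 bits (the density-based ground truth for this channel, computed by
`cc.oracle_mi(spec)` / `cc.oracle_capacity(spec)`, is 1.594 / 1.737 bits);
and the extreme doses are discriminated essentially without error.  2^1.75 ≈
3.4: the pathway resolves between three and four dose levels.

The same estimators run from the shell on any response table in the
one-row-per-cell layout (first column the stimulus label, remaining numeric
columns the response dimensions):

```
chancap simulate --preset scenario1 --n 1000 --seed 1 --out-dir run/
chancap capacity run/simulated.csv --out-dir run/
chancap pcd run/simulated.csv --boot-repeats 50 --out-dir run/
```

For time-resolved data, `time_point_view` / `time_window_view` restrict a
multi-column sample to one time stamp or to all stamps up to a time, which is
how snapshot vs trajectory information is compared.

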