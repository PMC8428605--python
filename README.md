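# mixtwice

Empirical-Bayes large-scale hypothesis testing that estimates **two** mixing
distributions — one over latent effects, one over latent variances — and
reports a local false discovery rate (lfdr) and a local false sign rate
(lfsr) for every testing unit.

It is aimed at high-dimensional, small-sample two-group comparisons such as
peptide-array antibody profiling (10⁵–10⁶ probes, ~10 subjects per group),
where standard FDR pipelines acting on p-values are underpowered and where
the gap between estimated and true standard errors is too large to ignore.

## Model

Each unit *i* contributes an estimated effect *x_i* and squared standard
error *s_i²* with shared, design-based degrees of freedom ν:

- x_i | θ_i, σ_i² ~ N(θ_i, σ_i²),  ν s_i²/σ_i² ~ χ²_ν
- θ_i ~ g, discrete on a regular grid a₋K..a_K, **unimodal** at the null a₀
- σ_i² ~ h, discrete on a regular positive grid b₁..b_L, unconstrained

(g, h) maximize l(g,h) = Σ_i log Σ_{k,l} g_k h_l p(x_i|a_k,b_l) p(s_i²|b_l)
over the product of simplices with the unimodality ordering constraints
(EM warm start + SLSQP, feasibility restored exactly at return). Per unit,

- lfdr_i = P(θ_i = a₀ | x_i, s_i²)   (posterior mass on the null),
- lfsr_i = min{P(θ_i ≤ a₀ | ·), P(θ_i ≥ a₀ | ·)}   (sign-robust analogue),

and the discovery list at level c is {i : lfdr_i ≤ c} (or lfsr). The null
proportion estimate π₀̂ is ĝ at the mode. See `docs/methods.md` for
assumptions, defaults, solver details and limitations.

## Worked example

```python
import mixtwice as mt

# a synthetic sparse-signal study: 1000 units, 10 samples/group,
# pi0 = 0.9, effects from a scale-mixture of normals, sigma^2 = 1
spec = mt.make_scenario("near_normal", pi0=0.9, m=1000, n_per_group=10)
study = mt.simulate_dataset(spec, seed=7)      # .stats holds (x, s2, df=18)

fit = mt.fit_mixtwice(study.stats)             # K=15, L=10 defaults
post = mt.posterior_effects(fit, study.stats)
dl = mt.discovery_list(post, 0.10, "lfdr")

print("pi0_hat", round(mt.estimate_pi0(fit), 4))
print("discoveries", dl.size, "estimated fdr", round(dl.fdr_estimate, 4))
print("true fdp", mt.empirical_fdp(dl, study.theta))
```

prints

```
pi0_hat 0.7798
discoveries 22 estimated fdr 0.01
true fdp 0.0
```

Read: the fitted effect distribution puts 78% of its mass exactly at 0
(an under-estimate of the true 90% — at n = 10 the null atom is only
partially identified); 22 units clear the 10% lfdr threshold, their mean
lfdr (~0.01) estimates the false-discovery rate within the list, and
because the ground truth is known here the realized false discovery
proportion can be checked — 0 of the 22 are true nulls.

The same pipeline runs from the shell on delimited tables:

```sh
mixtwice fit --input stats.tsv --s2-col s2 --df 22 --fdr 0.1 \
             --output results.tsv --mixing-output mixing.tsv
mixtwice summarize --matrix intensities.tsv --labels labels.tsv \
             --reference control --double-log --output stats.tsv
mixtwice permute  --matrix intensities.tsv --labels labels.tsv \
             --n-perm 100 --seed 1 --output perm.tsv
mixtwice benchmark --scenario near_normal --reps 50 --seed 1 \
             --output oc.tsv --aggregate-output oc_agg.tsv
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch — simulates a sparse-signal study,
fits the two mixing distributions, extracts lfdr/lfsr and the 10% discovery
list, and runs a seeded operating-characteristic benchmark (π₀ recovery and
empirical FDR by π₀ stratum) — logging progress to stderr and writing the
JSON summary to `--out`.
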