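# psybayes

Bayesian models and posterior-comparison tools for the data that
psychological experiments actually produce: reaction times, success rates,
sequential task responses, colors and plain numeric samples.  The package
is aimed at researchers and students who want modern Bayesian workflows —
custom likelihoods, hierarchical pooling, ROPE/HDI-based conclusions,
convergence diagnostics — without writing probabilistic programs.

## What it contains

| Model / tool | Likelihood | Group comparison currency |
| --- | --- | --- |
| `fit_ttest` | scaled/shifted Student-t `y ~ t_nu(mu, sigma)` | `mu` draws |
| `fit_reaction_time` | hierarchical exGaussian `t ~ N(mu_i, sigma_i) + Exp(lambda_i)` | `E = mu_mu + 1/mu_lambda` |
| `fit_success_rate` | hierarchical Bernoulli-Beta, `p_i ~ Beta(p*tau, (1-p)*tau)` | group `p` draws |
| `fit_linear` | hierarchical `y = alpha_i + beta_i x + eps` | `mu_alpha` / `mu_beta` / `mu_sigma` |
| `fit_color` | truncated normals (R,G,B,S,V) + von Mises hue | per-component means |
| `bayesian_bootstrap` | Dirichlet-weighted statistic draws | statistic draws |

Fits are compared draw-wise: `P(a > b) = #{a_i > b_i}/n` over aligned
posterior draws, optionally with a ROPE (region of practical equivalence)
inside which draws count as equal, plus the 95% HDI of the difference.
Multi-group comparisons add per-group probabilities of being largest or
smallest.  Convergence is reported through split R-hat, effective sample
size and Monte Carlo standard errors.  Seeded generators
(`generate_flanker`, `generate_adaptation`, `generate_stroop`,
`generate_afterimages`) emulate four classic experiment structures with
recorded ground truth, so every workflow runs end-to-end out of the box.

See `docs/methods.md` for model details, priors, sampler design and
limitations.

## Worked example: flanker reaction times

Compare reaction times of a control and a test group on synthetic flanker
data with a known 50 ms slowing:

```python
import psybayes as pb

rt, _ = pb.generate_flanker(group_shift=0.05, seed=77)   # 22 subjects x 80 trials per group
fits = []
for i, group in enumerate(("control", "test")):
    sub = rt.frame[(rt.frame.group == group) & (rt.frame.correct == 1)]
    fits.append(pb.fit_reaction_time(
        sub[["subject", "rt", "correct"]],
        settings=pb.SamplerSettings(chains=2, warmup=600, iter=600, seed=78 + i),
    ))

result = pb.compare_means(fits, rope=pb.RopeInterval(-0.01, 0.01))
pair = result.pair(0, 1)
print(f"P(control faster) = {pair.p_smaller:.3f}")
print(f"P(practically equal) = {pair.p_equal:.3f}")
print(f"95% HDI of difference: [{pair.hdi.lower:.3f}, {pair.hdi.upper:.3f}] s")
```

which prints

```
P(control faster) = 1.000
P(practically equal) = 0.000
95% HDI of difference: [-0.111, -0.046] s
```

The whole 95% HDI of the group-mean difference is negative and outside the
±10 ms ROPE, so the control group is credibly faster, by roughly 50-110 ms
— the generator's true shift was 50 ms.  `pb.summarize_fit(fits[0])`
prints the per-parameter table (mean, se_mean, sd, quantiles, n_eff,
Rhat); R-hat near 1 and adequate n_eff should be confirmed before reading
any comparison.

The same analysis runs from the shell:

```sh
psybayes simulate flanker --seed 77 --out-dir data
psybayes fit reaction-time --input data/flanker_rt.csv --group control \
    --filter-correct --out-prefix fits/control --chains 2 --warmup 600 --iter 600
psybayes fit reaction-time --input data/flanker_rt.csv --group test \
    --filter-correct --out-prefix fits/test --chains 2 --warmup 600 --iter 600
psybayes compare fits/control.yaml fits/test.yaml --rope -0.01,0.01 --out cmp.csv
psybayes plot difference fits/control.yaml fits/test.yaml --out diff.png
```

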