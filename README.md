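# zigcusum

Statistical process monitoring for **zero-inflated, autocorrelated count
series** — infectious-disease counts, defect counts, area-level crime
counts: data with far more zeros than a Poisson law allows and with serial
carryover from one period to the next.

The package implements

* the **ZIG-marginal INAR(1) process with a random thinning coefficient**:
  X_t = a_t ∘ X_{t−1} + ε_t, where the thinning coefficient a_t equals α
  with probability 1 − β and 0 with probability β, and the stationary
  marginal is the zero-inflated geometric ZIG(p, θ) —
  P(X=0) = p + (1−p)/(1+θ), P(X=j) = (1−p)θ^j/(1+θ)^{j+1};
  mean μ = (1−p)θ, variance σ² = (1−p)θ[(1+p)θ+1], lag-1 autocorrelation
  ρ = α(1−β);
* an **upper CUSUM chart** C_t = max(0, X_t − k + C_{t−1}) (signal when
  C_t > h) and the **Shewhart chart** (signal when X_t > UCL) for this
  process;
* **exact ARL and SDRL** via the bivariate Markov chain on the finite
  control region: sparse solves of (I−Q)u⁽¹⁾ = 1 and (I−Q)u⁽²⁾ = 2Qu⁽¹⁾;
* **chart design**: k = ⌈μ₀⌉ and an integer search for the h whose
  in-control ARL is closest to a target (370 by convention);
* **shift analysis**: out-of-control ARL profiles under mean shifts
  μ₁ = μ₀ + δσ₀ (carried by θ or by p) and correlation shifts (α or β);
* **estimation** from observed series by conditional least squares and
  conditional maximum likelihood, with AIC/BIC;
* a **seeded simulator** of process paths and of chart run lengths, used
  as the independent Monte-Carlo oracle for the exact solves.

## Worked example

```python
import zigcusum as z

params = z.ZIGParams(theta=1.0, p=0.1, alpha=0.5, beta=0.5)
z.process_moments(params)
# ProcessMoments(mean=0.9, variance=1.89, acf1=0.25)

summary = z.cusum_arl_sdrl(params, z.ChartDesign(h=9, k=2, c0=0))
round(summary.arl, 2), round(summary.sdrl, 2)
# (340.55, 339.0)  -> a false alarm roughly every 340 in-control months

# design a chart for a fitted process and profile it against mean shifts
fitted = z.ZIGParams(theta=2.0495, p=0.185, alpha=0.547, beta=0.5188)
z.recommend_k(fitted)                      # 2   (mu0 = 1.67)
z.find_h(fitted, k=2)                      # (34, 363.44...)
prof = z.arl_profile(z.ZIGParams(1, 0.1, 0.5, 0.5), z.ChartDesign(22, 1),
                     [z.ShiftSpec("mean_theta", d) for d in (0, 0.5, 1, 1.5, 6)])
prof[["delta", "arl", "dev_percent"]].round(2)
#    delta     arl  dev_percent
# 0    0.0  348.22         0.00
# 1    0.5   38.62       -88.91
# 2    1.0   19.31       -94.46
# 3    1.5   12.94       -96.29
# 4    6.0    3.44       -99.01
```

A mean shift of half an in-control standard deviation cuts the average run
length from 348 months to 39 — the chart reacts about nine times faster to
a real change than it false-alarms.

The same operations are available from the shell:

```sh
zigcusum arl --theta 1 --p 0.1 --alpha 0.5 --beta 0.5 --h 9 --k 2
# {"chart": "cusum", "h": 9, "k": 2, "c0": 0, "arl": 340.55, "sdrl": 339.0, ...}
zigcusum simulate --theta 2 --p 0.2 --alpha 0.5 --beta 0.5 -n 500 --seed 7 -o series.csv
zigcusum fit series.csv --method cml
zigcusum monitor series.csv --h 31 --k 2
```

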