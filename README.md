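# prepost

Design and simulation of two-arm pre-post randomized clinical trials in which
the endpoint is measured at several **pre-treatment (baseline)** visits and
several **post-treatment (follow-up)** visits. The package answers two design
questions:

1. **How many subjects per group** does an ANCOVA analysis need when there are
   *S* baselines and *T* follow-ups?
2. **Given a fixed visit budget** *M = S + T*, how should the visits be split
   between baselines and follow-ups to minimize that sample size?

It is aimed at trial statisticians planning repeated-measures pre-post designs
(e.g. chorea scores in Huntington disease trials, depression inventories),
and at methodologists who want to check how far the continuous-outcome theory
carries over to binary endpoints by simulation.

## The model

Each subject contributes the vector (X₁,…,X_S, Y₁,…,Y_T), multivariate normal
with an exchangeable-block covariance: corr(Xₛ, Xₛ′) = ρ_X,
corr(Yₜ, Yₜ′) = ρ_Y, corr(Xₛ, Yₜ) = ρ_XY, and variances σ²_X, σ²_Y.
The analysis is ANCOVA on the subject-level means — regress Ȳ on the
treatment indicator with the centered X̄ as covariate. The treatment-effect
estimator δ̂ then has

    var(δ̂) ≈ (1/n₀ + 1/n₁) σ²_Y [ (1+(T−1)ρ_Y)/T − ρ²_XY S / (1+(S−1)ρ_X) ]

and the per-group sample size at two-sided level α and power 1−β is

    n(S,T) = ⌈ 2 (z_{1−α/2} + z_{1−β})² σ²_Y / δ² × [bracket above] ⌉ .

For a fixed budget M the bracket, viewed as a function of S with T = M − S,
has a unique interior minimum whenever M ≥ √((1−ρ_Y)/((1−ρ_X)ρ²_XY)) + 1;
`prepost` evaluates the closed-form optimum, rounds it by comparing the
objective at the two neighbouring integers, and verifies against exhaustive
search. Arbitrary (non-exchangeable) covariance matrices are supported
through the block-mean formula.

For **binary endpoints** no closed form exists, so the package generates
correlated 0/1 data through a Gaussian copula (latent normal correlation
matrix R, margins dichotomized at p, with the treated-arm follow-up
probability p′ = p·e^{β₁}/(1−p+p·e^{β₁})) and estimates power by Monte
Carlo: logistic regression for a single follow-up, GEE logistic regression
with a robust sandwich variance for several, plus empirical calibration of
the Z test so small-sample Type-I error is held exactly at α.

## Worked example

A depression trial ("Beat the Blues") gives the estimates σ̂²_Y = 116.8,
ρ̂_XY = 0.52, ρ̂_X = ρ̂_Y = 0.77 and a treatment effect δ̂ = 5.4 points.
How large must each group be with 2 baselines and 4 follow-ups?

```bash
$ prepost samplesize --s 2 --t 4 --sigma2-y 116.8 --delta 5.4
S=2, T=4: n per group = 33 (unrounded 32.82, bracket 0.5220)
```

A single pre-post design needs 46 per group, so the (2, 4) design saves
28.3% of the subjects. With a budget of M = 5 visits:

```bash
$ prepost optimal-s --m 5 --rho-x 0.77 --rho-y 0.77 --rho-xy 0.52
S_opt = 2 (real-valued 1.84, M threshold 2.92, f(floor)=0.5571, f(ceil)=0.5411, method=closed_form)
```

i.e. two baselines and three follow-ups beat a single baseline with four
follow-ups (n = 35 vs 36 per group). The same library calls are available in
Python:

```python
from prepost import (BEAT_THE_BLUES, AllocationSpec, DesignInputs,
                     sample_size_per_group, s_opt_integer)

sample_size_per_group(BEAT_THE_BLUES, AllocationSpec(2, 4),
                      DesignInputs(delta=5.4)).n   # -> 33
s_opt_integer(5, BEAT_THE_BLUES).s_int             # -> 2
```

Monte-Carlo presets reproduce the simulation studies, e.g.
`prepost simulate --table t3 --reps 5000 --out t3.csv` (ANCOVA power grid) or
`prepost simulate --table fig2 --n 100 --out fig2.csv` (calibrated GEE power
across every split of a 10-visit budget).

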