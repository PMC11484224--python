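# drgsd — two-stage group-sequential designs with delayed responses

`drgsd` is a planning and evaluation toolkit for two-arm, two-stage
group-sequential clinical trials with a normally distributed endpoint whose
outcome is observed only after a time lag. At the interim analysis a
fraction `I1` of the maximum per-arm sample size `n_max` has observed
outcomes, while a further fraction `IΔt` of patients is already recruited
but still "in the pipeline". The toolkit is aimed at trial statisticians
who want to compare designs that formally use the pipeline data against a
standard design that ignores it.

## Designs and model

Three one-sided designs (level `α`, target power `1 − β`) are supported,
all built on error-spending functions (Pocock-like or
O'Brien–Fleming-like) evaluated at the interim information fraction:

* **GSD** — standard error-spending design: stop at interim for efficacy
  (`Z1 ≥ u1`) or futility (`Z1 ≤ l1`); otherwise test the inverse-normal
  combination `Z1+2 ≥ d2` at the final analysis.
* **DR-GSD** — delayed-response design: crossing `(l1, u1)` stops
  *recruitment* only; the efficacy decision is then taken on the enlarged
  statistic `Z̃1` (interim plus pipeline data) against `d1`, which is chosen
  to balance, under the null, promising stops that end in non-rejection
  against futility stops that end in rejection.
* **RR-GSD** — repeated-rejection variant: an interim rejection requires
  both `Z1 ≥ u1` and the confirmation `Z̃1 ≥ d1` with `d1 = Φ⁻¹(1 − α)`
  fixed; a low crossing is always futility.

The statistic vector `(Z1, Z̃1, Z1+2)` follows the canonical multivariate
normal law with `corr(Za, Zb) = √(Ia/Ib)` and drift
`(δ/σ)·√(I_k·n_max/2)`, which is how all boundaries and operating
characteristics are computed analytically. The lower boundary is
**nonbinding** throughout: `u1` and `d2` are derived as if the trial always
continues below `u1`, so ignoring a futility signal never inflates the
type-I error. Expected sample size always counts pipeline patients,
whether or not their data inform a decision.

## Worked example

A phase III schizophrenia trial (effect `δ = 1.6`, `σ = 7.5`) needs 345
patients per group in a fixed design for 80% power at one-sided
`α = 0.025`. An interim after 200 observed outcomes with 208 patients in
the pipeline gives `I1 = 0.29` and `IΔt = 0.3`. With Pocock-like α- and
β-spending:

```sh
$ drgsd example
design     l1    u1    d1    d2  p_futility  p_reject_interim  power  expected_n_total
 fixed    NaN   NaN   NaN 1.960         NaN               NaN  0.800           690.000
   GSD  0.259 2.322   NaN 2.119       0.106             0.208  0.722           601.286
DR_GSD  0.259 2.322 1.584 2.119       0.089             0.224  0.739           601.286
RR_GSD -0.164 1.815 1.960 2.043       0.098             0.329  0.737           569.222
```

Reading the table: GSD and DR-GSD share the continuation region
`(0.259, 2.322)` and final critical value 2.119, hence also the expected
total sample size 601.3 (of a 690 maximum). The DR-GSD turns some interim
stops into rejections via its decision value `d1 = 1.584`, lifting power
from 0.722 to 0.739 at no sample-size cost. The RR-GSD's more liberal
upper boundary (1.815) makes an interim rejection much more likely (0.329
vs 0.208) and lowers the expected sample size to 569.2, at comparable
power (0.737). All probabilities are at the assumed effect `δ = 1.6`.

Other entry points: `drgsd boundaries` (one design's boundary set, JSON),
`drgsd performance --delta …` (operating characteristics at chosen
effects), `drgsd grid` (the packaged 2-family × 9-fraction-pair × 3-design
comparison grid), and `drgsd simulate` (Monte-Carlo power and expected
sample size, canonical or patient-level mode). Every command accepts a
flat YAML/JSON config file and echoes its resolved configuration.

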