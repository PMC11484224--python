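# Methods

## Model

Two arms of up to `n_max` patients each, outcomes
`X_C ~ N(0, σ²)`, `X_I ~ N(δ, σ²)` with common unknown `σ`, one-sided test
of `δ ≤ 0` at level `α`. Three standardized statistics are tracked: the
interim statistic `Z1` on the first `n1 = I1·n_max` patients per arm, the
decision statistic `Z̃1` on `ñ1 = (I1 + IΔt)·n_max` per arm (interim plus
pipeline), and the inverse-normal combination
`Z1+2 = w1·Z1 + w2·Z2` with pre-fixed weights `w1 = √(n1/n_max)`,
`w2 = √(1 − n1/n_max)`, where `Z2` is computed on the `n_max − n1`
post-interim patients. With these weights `(Z1, Z̃1, Z1+2)` follows the
canonical multivariate normal law: unit variances,
`corr(Za, Zb) = √(Ia/Ib)` for information fractions `Ia ≤ Ib ∈
{I1, I1+IΔt, 1}`, and mean `(δ/σ)·√(I_k·n_max/2)` at effect `δ`. The
correlation structure is Markov: `corr(Z1, Z1+2) =
corr(Z1, Z̃1)·corr(Z̃1, Z1+2)`.

All analytic computations use this known-variance normal model; the
pooled-SD (t-type) refinement appears only in the patient-level simulator,
where it is exercised against the normal-theory boundaries.

## Boundary determination

Error spending at the interim fraction `t = I1` uses either the
Pocock-like form `f(t) = level·ln(1 + (e−1)·t)` or the
O'Brien–Fleming-like form `f(t) = 2·(1 − Φ(Φ⁻¹(1 − level/2)/√t))`, for
both `α` and `β`. Writing `α1 = f_α(I1)`, `β1 = f_β(I1)`:

* **GSD**: `u1 = Φ⁻¹(1 − α1)`; `d2` solves
  `P₀(Z1 < u1, Z1+2 ≥ d2) = α − α1` (continuation assumed below `u1`, i.e.
  the futility boundary is nonbinding); `l1` solves
  `P_δ̃(Z1 ≤ l1) = β1`; the design alternative `δ̃` solves total power
  `= 1 − β` at the fixed `n_max`.
* **DR-GSD**: same `{l1, u1, d2, δ̃}`; `d1` is the unique root of the null
  balance `P₀(Z1 ≥ u1, Z̃1 < d1) = P₀(Z1 ≤ l1, Z̃1 ≥ d1)`, which makes the
  decision analysis spend exactly `α1` when the lower boundary is
  respected and less when it is ignored — type-I control is preserved
  either way.
* **RR-GSD**: `d1 = Φ⁻¹(1 − α)` fixed; `u1` solves
  `P₀(Z1 ≥ u1, Z̃1 ≥ d1) = α1`; `d2` as above (with the RR `u1`); the
  interim type-II spend covers both futility routes,
  `P_δ̃(Z1 ≤ l1) + P_δ̃(Z1 ≥ u1, Z̃1 < d1) = β1`, and `δ̃` again solves
  total power `= 1 − β`.

Solving order for RR-GSD is `u1`, then `d2`, then the `(l1, δ̃)` fixed
point — valid because `u1` and `d2` do not depend on `δ̃`.

**Design-alternative calibration.** `δ̃` is the effect at which the β-spend
is anchored. It is calibrated *per design* so that the design's own
type-II spending partition sums to `β` at the planned `n_max` (the
standard β-spending convention). For GSD and RR-GSD this coincides with
global power `= 1 − β` at `δ̃`; for DR-GSD — whose rejection event strictly
contains the GSD's — the global power at `δ̃` slightly exceeds `1 − β`.
Because the RR-GSD spends `β1` over two routes, its `δ̃` differs from the
GSD/DR-GSD value.

## Operating characteristics

Interim outcome probabilities per design (all evaluated under the
canonical model at drift `δ`):

| design | P(futility) | P(reject at interim) |
|---|---|---|
| GSD | `P(Z1 ≤ l1)` | `P(Z1 ≥ u1)` |
| DR-GSD | `P(Z1 ∉ (l1,u1), Z̃1 < d1)` | `P(Z1 ∉ (l1,u1), Z̃1 ≥ d1)` |
| RR-GSD | `P(Z1 ≤ l1) + P(Z1 ≥ u1, Z̃1 < d1)` | `P(Z1 ≥ u1, Z̃1 ≥ d1)` |

For the DR-GSD, "futility" means recruitment stop followed by
non-rejection, whichever boundary was crossed; it is not a classical
futility statement. All designs continue with probability
`P(l1 < Z1 < u1)`, so the three outcomes partition the sample space.
Global power adds `P(Z1 ∈ (l1,u1), Z1+2 ≥ d2)` to the interim rejection
probability. Expected total sample size is
`E[N] = 2·(ñ1 + P(continue)·(n_max − ñ1))`: pipeline patients are always
randomized, and a continued trial recruits to the planned maximum — hence
GSD and DR-GSD, sharing `(l1, u1)`, share `E[N]` exactly. Conditional
power is `P(Z1+2 ≥ d2, Z1 ∈ (l1,u1)) / P(Z1 ∈ (l1,u1))` and is identical
for GSD and DR-GSD by construction.

Negative effects are allowed in evaluation grids (to study futility
stopping); the "power" reported there is the rejection probability under
harm.

## Numerics

* Rectangle probabilities of the (tri)variate normal are computed by a
  deterministic composite Gauss–Legendre reduction (conditioning on the
  first coordinate; unit-length panels, 24 nodes each, intervals truncated
  at ±9 where the normal mass is ~1e−19). Absolute accuracy is well below
  the 1e−7 policy and repeated calls are bit-for-bit identical, which a
  randomized quasi-Monte-Carlo integrator would not give.
* Root finding uses Brent's method bracketed on `[−10, 10]` (z-scale) with
  tolerance 1e−8; all realistic boundaries lie well inside. The `δ̃` search
  runs on the standardized final-analysis drift in `(0, 10]`.
* Information fractions are taken as exact reals as given (e.g. `I1 =
  0.29`, not `200/690`); patient counts are real-valued internally and
  rounded to whole patients only for reporting and in the patient-level
  simulator. Probes during `δ̃` calibration that push `l1` above `u1`
  contribute zero continuation probability.
* Degenerate inputs raise typed errors: pipeline fraction 0 for the
  delayed designs (the `d1` balance becomes indeterminate), spending
  increments that leave nothing for a stage, an empty continuation region,
  conditional power when the continuation probability underflows.

## Simulation

`canonical` mode draws `(Z1, Z̃1, Z1+2)` directly from the canonical law
(Cholesky factor of the correlation matrix plus drift) and applies each
design's decision logic; `patient_level` mode synthesizes outcomes for
every randomized patient and computes pooled-SD statistics from raw data.
One seed per run; replications consume `SeedSequence.spawn` substreams, so
any fixed configuration and seed reproduces bit-for-bit. A flag disables
futility stopping to probe the nonbinding worst case for type-I error.
Default experiment size is 10,000 trials per replication and 100
replications, matching the standard protocol for estimating the sampling
variability of power and expected sample size; tests use smaller sizes
(10⁵–10⁶ total draws) chosen to keep Monte-Carlo standard errors far below
the tolerances they assert.

The patient-level generator emulates an idealized parallel-group trial:
normal outcomes, common known-design `σ`, exact 1:1 allocation, no
dropout, no covariates, no recruitment calendar. Passing tests therefore
validate the probability model and decision logic, not robustness to
non-normality, unequal variances or operational drift. Calendar-time
quantities (expected duration, recruitment-rate scenarios) are out of
scope throughout.

## Known limitations

* Two stages only; no K-stage generalization, unequal allocation, or
  binary/survival endpoints.
* Binding-futility variants are not implemented (nonbinding is the
  regulatory-preferred convention and the only one exposed).
* The O'Brien–Fleming-like spending form is the standard Lan–DeMets one;
  alternative one-sided OBF approximations would shift boundaries slightly.
* Comparison-grid point probabilities depend on the `δ̃` calibration
  convention; the worked example is the package's quantitative anchor, and
  grid outputs are validated for internal consistency (partitioning,
  monotonicity, GSD/DR-GSD equalities) rather than against external point
  values.
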