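# Methods

## The model

Lifetimes are drawn from an m-component **mixed exponential distribution**
(MED) with weights π = (π₁,…,π_m), Σπ_k = 1, and rates λ = (λ₁,…,λ_m):

    f(x; θ) = Σ_k π_k λ_k e^(−λ_k x),    s(x; θ) = Σ_k π_k e^(−λ_k x).

Data arise from a **Type-II progressively censored** life test: n units go
on test, and at the i-th observed failure R_i surviving units are withdrawn
at random; the test ends at the N-th failure (R₁+…+R_N+N = n). Each unit
belongs to one mixture component, but membership is latent. The package's
subject is the case where membership is *partially* known: for unit i and
component k an analyst supplies a **plausibility** pl_{i,k} ∈ [0,1] — the
singleton (contour) value of a Dempster–Shafer mass function over the label
frame — with pl ≡ 1 meaning total ignorance and a 0/1 row meaning a certain
label.

## The evidential likelihood and the E2M iteration

Censoring intervals [t_i, ∞) and soft labels are both encoded as contour
functions; assuming cognitive independence of lifetime and label evidence,
the **evidential likelihood** is the expectation of the data's joint
contour under the model. For the progressively censored MED it factorizes
as

    L(θ; pl) = Π_i [ Σ_k π_k pl_{i,k} λ_k e^(−λ_k t_i) ]
             · Π_i Π_{j≤R_i} [ Σ_k π_k pl_{ij,k} e^(−λ_k t_i) ],

where the censored factor uses the *censoring epoch time* t_i, not the
unobservable lifetime. With pl ≡ 1 this reduces to the classical
face-value likelihood Π_i f(t_i)·s(t_i)^{R_i} (the scheme-dependent
multiplicative constant is dropped throughout; it does not involve θ).
With certain labels and no censoring it reduces to the complete-data
likelihood.

The maximizer (the **MELE**) is found by an EM-like alternation (**E2M**)
whose E-step conditions the model posterior by the contour — a normalized
product, i.e. Dempster's combination of a Bayesian mass with an arbitrary
mass — giving closed-form responsibilities

    a_ik ∝ π_k λ_k e^(−λ_k t_i) pl_{i,k}          (observed units),
    e_ijk ∝ π_k e^(−λ_k t_i) pl_{ij,k}            (censored units),

and conditional means ξ_ik = t_i + 1/λ_k for censored lifetimes (exact by
memorylessness; verified against quadrature in the tests). The M-step is
the Lagrangian closed form

    A_k = Σ_i a_ik + Σ_{ij} e_ijk,   C_k = Σ_{ij} ξ_ik e_ijk,
    π_k ← A_k / Σ_l A_l,             λ_k ← A_k / (C_k + Σ_i t_i a_ik).

The evidential log-likelihood is provably nondecreasing along this path;
the implementation asserts it every iteration and aborts on any decrease
beyond 1e-8 relative (which would indicate a bug, not a model property).
With the vacuous matrix the iteration is *identical*, step for step, to
classical EM for progressively censored MEDs — tested against an
independently coded EM at 1e-12.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `epsilon` | 1e-10 | convergence: squared step in π **and** in λ must both fall below it. Note it is absolute in λ (units 1/time²), so convergence declarations are not scale-free. |
| `max_iter` | 5000 | iteration cap; label-blind fits on heavily censored data can legitimately need ~10⁴ iterations (the likelihood is extremely flat near degenerate modes). |
| `restarts` | 100 | random restarts with best-evidential-log-likelihood selection; exponential-mixture likelihoods are multimodal and spiky. |
| `init` | `random` | π₁⁽⁰⁾ = \|0.5+Z\|, λ⁽⁰⁾ = (\|0.2+Z\|, \|0.8+Z\|), Z ~ N(0, 0.1 variance); also `fixed` = ((0.5,0.5),(1,0.5)) and `quantile` (reciprocal data quantiles — the only strategy whose scale adapts to the data). |

Restarts that collapse onto a degenerate spike (any λ_k > 1e8 or π_k <
1e-10) are discarded and counted rather than clamped; such spikes are a
well-known pathology of exponential-mixture likelihoods and carry no
scientific content. A fit fails only if *no* restart converges.
Components of a finished fit are reported in descending-rate order, which
resolves label switching (mixture components are exchangeable).

## Soft-label generator (simulation studies)

The corruption model draws, per unit, an error probability q_i from a Beta
distribution moment-matched to mean ρ and standard deviation σ (feasible
iff σ² < ρ(1−ρ)); with probability q_i the unit's label is replaced by a
uniform draw over all m labels. The plausibility row is then

    pl_{i,k} = q_i/m + 1 − q_i   at the conditioning label,
    pl_{i,k} = q_i/m             elsewhere.

The conditioning label is by default the *reported* (possibly corrupted)
label — the only quantity an analyst without oracle access could use; a
`condition_on="true"` flag implements the alternative reading. Censored
units receive soft labels by the identical mechanism in simulation; on
real data, where censored units usually have no elicited labels, a matrix
covering only observed units is accepted and censored rows default to
vacuous.

Study defaults mirror the reference simulation conditions: truth
π = (0.3, 0.7), λ = (0.6, 0.1), ρ = σ = 0.2, schemes
`scheme-1` (all removals at the last failure), `scheme-2` (all at the
first), `scheme-3` (one per failure, remainder at the end), replicates
s = 100 (50 in the shipped regression study, for runtime), per-replicate
fits from the fixed init (0.5, 0.5), (1, 0.5). MELE and MLE within a
replicate consume bit-identical data and corruption draws (common random
numbers); estimates are aligned to truth by descending rate before
accumulating bias and MSE. Nonconverged or collapsed replicates are
dropped and counted, not imputed.

## What the simulator does and does not emulate

`simulate_progressive` replays the physical experiment — generate n labeled
lifetimes, repeatedly observe the minimum among survivors and remove R_i of
the rest uniformly at random — rather than using the uniform-spacings
transform, because the study design needs the *true* hidden lifetimes and
labels of removed units. Lifetime generation and removal use independent
substreams split from the master seed, so observed failures are invariant
to the removal pattern under common random numbers. The generator draws
exact exponentials with independent censoring; it does not emulate
covariate-dependent rates, dependent removal decisions, time-varying
hazards, or measurement error in the recorded times, so passing tests
demonstrate correctness of the estimator under the model's own assumptions,
not robustness to their violation.

## Numerical choices

- All likelihoods go through log-sum-exp over components; plausibility
  zeros become −∞ summands and are handled exactly.
- E-step rows are normalized after factoring out the per-row maximum of
  the component log-densities, so λ·t up to hundreds cannot underflow.
- A unit whose plausibility row is all zero (no plausible label) raises a
  degenerate-observation error naming the unit rather than producing NaNs.
- Lifetime ties (probability zero, possible in floating point) are broken
  by generation index.
- Mass-function arithmetic (a testing/pedagogy core — the estimator itself
  consumes only contours) uses bitmask subsets, a 1e-9 tolerance on total
  mass, and prunes post-combination masses below 1e-12.

## Worked-example caveat

The package ships the classical 30-observation aircraft air-conditioning
failure-time dataset with a 30×2 soft-label matrix produced by an
evidential clustering of the same times (consumed as data, not
recomputed). On this input the best-of-100-restarts fits reproducibly
give, in descending-rate order,

    MELE: π̂₁ = 0.8538, λ̂₁ = 0.0279, λ̂₂ = 0.0050   (evidential ll −154.66)
    MLE:  π̂₁ = 0.3492, λ̂₁ = 0.0642, λ̂₂ = 0.0120   (observed ll −151.18)

both confirmed as global optima by an independent multi-start Nelder–Mead
maximization of the respective objectives. Earlier published point
estimates for this example differ; they are not stationary points of
either objective on this input (for the uncensored case, any EM iterate
must satisfy Σ_k π̂_k/λ̂_k = the sample mean, 59.6 here, which those values
violate), so agreement with them should not be expected.

## Known limitations

- Exponential components only; other lifetime families are an extension
  point, not implemented.
- No standard errors or observed information for the estimates.
- The `epsilon` stopping rule is absolute in λ; rescale data (the model is
  exactly scale-equivariant) or tighten `epsilon` for very small rates.
- The general Dempster-combination core is exponential in frame size and
  intended for small frames (≤ ~10 labels); the estimation path never uses
  it.
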