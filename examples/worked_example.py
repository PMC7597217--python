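"""Fit the two-component mixed exponential to the air-conditioning data.

Runs the evidential-EM fit twice on the 30 packaged failure times: once
with the shipped soft-label plausibility matrix (MELE) and once with the
vacuous all-ones matrix, which is exactly classical EM (MLE).  Components
are reported in descending-rate order, so pi1/lam1 describe the short-lived
sub-population and lam2 the long-lived one.
"""

from evidmix import E2MConfig, LikelihoodContext, fit_e2m, load_aircon_sample

for label, with_pl in [("MELE (soft labels)", True), ("MLE (no labels)", False)]:
    sample, plmat = load_aircon_sample(with_plausibility=with_pl)
    ctx = LikelihoodContext(sample, plmat, m=2)
    fit = fit_e2m(ctx, E2MConfig(init="random", restarts=100, epsilon=1e-10, seed=7))
    th = fit.theta_hat
    print(f"{label}:")
    print(f"  pi  = ({th.pi[0]:.4f}, {th.pi[1]:.4f})")
    print(f"  lam = ({th.lam[0]:.4f}, {th.lam[1]:.4f})  [1/hour]")
    print(f"  evidential loglik = {fit.loglik:.4f}  ({fit.n_iter} iterations)")

print(
    "\nThe soft labels concentrate most units in the faster-failing component,\n"
    "pulling its weight up relative to the label-blind fit."
)
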