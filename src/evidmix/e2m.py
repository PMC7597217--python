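"""Evidential EM (E2M) estimation of the mixed exponential model.

The estimator maximizes the evidential likelihood — the expectation of the
data's label/censoring contour function under the model — by alternating
closed-form E- and M-steps.  With the vacuous plausibility matrix the
iteration is exactly the classical EM algorithm for progressively censored
mixed exponential data, and the fixed point is the ordinary MLE; with
informative plausibilities the fixed point is the maximal evidential
likelihood estimate (MELE).

E-step responsibilities, at current parameters (pi, lam):

    a_ik    = pi_k lam_k e^{-lam_k t_i} pl_{i,k}  / (sum over components)
    e_ijk   = pi_k e^{-lam_k t_i} pl_{ij,k}       / (sum over components)
    xi_ik   = t_i + 1/lam_k        (mean residual life of component k at t_i)

M-step (from the Lagrangian of the expected complete-data log-likelihood
under the sum-to-one constraint on pi):

    A_k = sum_i a_ik + sum_{ij} e_ijk,   C_k = sum_{ij} xi_ik e_ijk
    pi_k  <- A_k / sum_l A_l
    lam_k <- A_k / (C_k + sum_i t_i a_ik)

The evidential log-likelihood is guaranteed nondecreasing along the
iteration; the fit aborts with a diagnostic if a decrease beyond numerical
tolerance is ever observed.  Exponential-mixture likelihoods are multimodal,
so the fitter supports random restarts with best-likelihood selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from .likelihood import LikelihoodContext, evidential_loglik
from .med import MEDParams, component_truncated_mean

__all__ = [
    "EStepQuantities",
    "E2MConfig",
    "E2MFit",
    "RestartSummary",
    "MonotonicityError",
    "ComponentCollapseError",
    "NonconvergenceError",
    "e_step",
    "q_function",
    "m_step",
    "e2m_path",
    "fit_e2m",
    "init_strategy",
]

#: a restart is discarded as degenerate when a rate explodes or a weight vanishes
COLLAPSE_LAM_MAX = 1e8
COLLAPSE_PI_MIN = 1e-10
#: relative tolerance on the monotone-likelihood guarantee of the iteration
MONOTONE_RTOL = 1e-8

INIT_TAGS = ("random", "fixed", "quantile")


class MonotonicityError(RuntimeError):
    """The evidential log-likelihood decreased — indicates an implementation bug."""


class ComponentCollapseError(RuntimeError):
    def __init__(self, k: int, msg: str = ""):
        self.component = k
        super().__init__(msg or f"mixture component {k} collapsed (empty or degenerate)")


class NonconvergenceError(RuntimeError):
    def __init__(self, traces):
        self.traces = traces
        super().__init__("no restart of the E2M algorithm converged")


@dataclass
class EStepQuantities:
    """Posterior responsibilities and truncated means at the current theta.

    ``a`` is N x m over observed units; ``e`` is a list of R_i x m blocks,
    one per censoring epoch; ``xi`` is N x m with xi_ik = t_i + 1/lam_k.
    Rows of a and e each sum to one.
    """

    a: np.ndarray
    e: List[np.ndarray]
    xi: np.ndarray


@dataclass
class E2MConfig:
    """Fitting controls for the E2M loop.

    ``epsilon`` bounds the squared parameter step in BOTH the weight and the
    rate vectors at convergence; ``restarts`` > 1 reruns the loop from fresh
    initializations and keeps the best evidential log-likelihood.
    """

    init: Union[MEDParams, str] = "random"
    epsilon: float = 1e-10
    max_iter: int = 5000
    restarts: int = 100
    seed: Optional[int] = None

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_iter < 1 or self.restarts < 1:
            raise ValueError("max_iter and restarts must be >= 1")
        if isinstance(self.init, str) and self.init not in INIT_TAGS:
            raise ValueError(f"unknown init strategy {self.init!r}; expected {INIT_TAGS}")


@dataclass
class RestartSummary:
    theta: Optional[MEDParams]
    loglik: float
    n_iter: int
    converged: bool
    collapsed: bool


@dataclass
class E2MFit:
    """Result of an E2M fit: best estimate, trace, and restart table."""

    theta_hat: MEDParams
    loglik: float
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    restart_results: List[RestartSummary] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "theta_hat": self.theta_hat.as_dict(),
            "loglik": self.loglik,
            "loglik_trace": np.asarray(self.loglik_trace).tolist(),
            "n_iter": self.n_iter,
            "converged": self.converged,
            "restarts": [
                {
                    "theta": r.theta.as_dict() if r.theta is not None else None,
                    "loglik": r.loglik,
                    "n_iter": r.n_iter,
                    "converged": r.converged,
                    "collapsed": r.collapsed,
                }
                for r in self.restart_results
            ],
        }


# ----------------------------------------------------------------------
# E- and M-steps
# ----------------------------------------------------------------------

def _normalize_rows(raw: np.ndarray, what: str) -> np.ndarray:
    denom = raw.sum(axis=1, keepdims=True)
    if np.any(denom <= 0) or not np.all(np.isfinite(denom)):
        bad = int(np.argmin((denom > 0) & np.isfinite(denom)))
        raise ValueError(f"degenerate observation: {what} unit {bad} has zero posterior mass")
    return raw / denom


def e_step(ctx: LikelihoodContext, theta: MEDParams) -> EStepQuantities:
    """Closed-form E-step: responsibilities a, e and truncated means xi."""
    t = ctx.sample.t
    # observed units: a_ik proportional to pi_k f_k(t_i) pl_ik
    log_f = np.log(theta.lam) - np.outer(t, theta.lam)  # component log-densities
    raw_a = theta.pi * np.exp(log_f - log_f.max(axis=1, keepdims=True)) * ctx.pl_obs
    a = _normalize_rows(raw_a, "observed")
    # censored units at epoch i: e_ijk proportional to pi_k s_k(t_i) pl_ijk
    e: List[np.ndarray] = []
    for i, pl_rows in enumerate(ctx.pl_cens):
        if pl_rows.shape[0] == 0:
            e.append(np.zeros((0, theta.m)))
            continue
        log_s = -theta.lam * t[i]
        raw_e = theta.pi * np.exp(log_s - log_s.max()) * pl_rows
        e.append(_normalize_rows(raw_e, f"epoch-{i} censored"))
    xi = component_truncated_mean(t[:, None], theta.lam[None, :])
    return EStepQuantities(a=a, e=e, xi=xi)


def q_function(ctx: LikelihoodContext, theta: MEDParams, est: EStepQuantities) -> float:
    """Expected complete-data log-likelihood at theta under the E-step posterior."""
    t = ctx.sample.t
    logpi = np.log(theta.pi)
    loglam = np.log(theta.lam)
    q = float(np.sum(est.a * (logpi + loglam - np.outer(t, theta.lam))))
    for i, e_rows in enumerate(est.e):
        if e_rows.shape[0] == 0:
            continue
        q += float(np.sum(e_rows * (logpi + loglam) - theta.lam * est.xi[i] * e_rows))
    return q


def m_step(est: EStepQuantities, ctx: LikelihoodContext) -> MEDParams:
    """Closed-form maximizer of the Q function under sum(pi) = 1."""
    t = ctx.sample.t
    A = est.a.sum(axis=0)
    C = np.zeros_like(A)
    for i, e_rows in enumerate(est.e):
        if e_rows.shape[0] == 0:
            continue
        A = A + e_rows.sum(axis=0)
        C = C + (est.xi[i] * e_rows).sum(axis=0)
    if np.any(A <= 0):
        raise ComponentCollapseError(int(np.argmin(A > 0)))
    pi = A / A.sum()
    lam = A / (C + (t[:, None] * est.a).sum(axis=0))
    return MEDParams(pi, lam)


# ----------------------------------------------------------------------
# initialization
# ----------------------------------------------------------------------

def init_strategy(
    tag: str,
    rng: np.random.Generator | int | None = None,
    times: Optional[np.ndarray] = None,
    m: int = 2,
) -> MEDParams:
    """Produce initial parameters for the E2M loop.

    * ``fixed`` — pi = (0.5, 0.5), lam = (1, 0.5); m = 2 only.
    * ``random`` — a random-restart recipe for m = 2: pi_1 = |0.5 + Z_1|,
      lam = (|0.2 + Z_2|, |0.8 + Z_3|) with Z ~ Normal(0, variance 0.1);
      draws with pi_1 outside (0, 1) or a zero rate are rejected and redrawn.
    * ``quantile`` — rates from reciprocal spread-out quantiles of the data,
      equal weights; works for any m >= 1.
    """
    rng = np.random.default_rng(rng)
    if tag == "fixed":
        if m != 2:
            raise ValueError("fixed init is defined for m = 2")
        return MEDParams(np.array([0.5, 0.5]), np.array([1.0, 0.5]))
    if tag == "random":
        if m != 2:
            raise ValueError("random init recipe is defined for m = 2")
        sd = np.sqrt(0.1)
        for _ in range(1000):
            pi1 = abs(0.5 + rng.normal(0.0, sd))
            lam1 = abs(0.2 + rng.normal(0.0, sd))
            lam2 = abs(0.8 + rng.normal(0.0, sd))
            if 0.0 < pi1 < 1.0 and lam1 > 0.0 and lam2 > 0.0:
                return MEDParams(np.array([pi1, 1.0 - pi1]), np.array([lam1, lam2]))
        raise RuntimeError("could not draw a valid random initialization")
    if tag == "quantile":
        if times is None or len(times) == 0:
            raise ValueError("quantile init needs data")
        qs = np.quantile(times, np.linspace(0.25, 0.9, m))
        qs = np.maximum(qs, np.max(times) * 1e-6)
        return MEDParams(np.full(m, 1.0 / m), 1.0 / qs[::-1])
    raise ValueError(f"unknown init strategy {tag!r}")


# ----------------------------------------------------------------------
# main loop
# ----------------------------------------------------------------------

def e2m_path(
    ctx: LikelihoodContext, theta0: MEDParams, epsilon: float = 1e-10, max_iter: int = 5000
) -> tuple:
    """A single E2M run from theta0 (no restarts, no collapse filtering).

    Returns ``(theta, loglik_trace, n_iter, converged)``; useful for studying
    the iteration itself.  Raises :class:`MonotonicityError` if the trace
    ever decreases beyond numerical tolerance."""
    theta = theta0
    trace = [evidential_loglik(ctx, theta)]
    converged = False
    for it in range(1, max_iter + 1):
        est = e_step(ctx, theta)
        theta_new = m_step(est, ctx)
        ll = evidential_loglik(ctx, theta_new)
        prev = trace[-1]
        if ll < prev - MONOTONE_RTOL * max(1.0, abs(prev)):
            raise MonotonicityError(
                f"evidential log-likelihood decreased at iteration {it}: "
                f"{prev:.10g} -> {ll:.10g}"
            )
        trace.append(ll)
        d_pi = float(np.sum((theta_new.pi - theta.pi) ** 2))
        d_lam = float(np.sum((theta_new.lam - theta.lam) ** 2))
        theta = theta_new
        if d_pi <= epsilon and d_lam <= epsilon:
            converged = True
            break
    return theta, np.array(trace), len(trace) - 1, converged


def _collapsed(theta: MEDParams) -> bool:
    return bool(np.any(theta.lam > COLLAPSE_LAM_MAX) or np.any(theta.pi < COLLAPSE_PI_MIN))


def fit_e2m(ctx: LikelihoodContext, config: Optional[E2MConfig] = None) -> E2MFit:
    """Fit the mixed exponential model by evidential EM with restarts.

    Each restart runs the E/M alternation from its own initialization until
    the squared steps in both the weight and the rate vector fall below
    ``config.epsilon`` (or ``max_iter``).  Restarts that collapse onto a
    degenerate spike (a rate above 1e8 or a weight below 1e-10) are
    discarded and counted.  The returned fit is the restart with the highest
    evidential log-likelihood, components ordered by descending rate.
    """
    config = config or E2MConfig()
    rng = np.random.default_rng(config.seed)
    n_restarts = config.restarts if isinstance(config.init, str) else 1

    summaries: List[RestartSummary] = []
    best = None  # (loglik, theta, trace, n_iter, converged)
    for r in range(n_restarts):
        if isinstance(config.init, str):
            theta0 = init_strategy(config.init, rng, ctx.sample.t, ctx.m)
        else:
            theta0 = config.init
        try:
            theta, trace, n_iter, converged = e2m_path(
                ctx, theta0, config.epsilon, config.max_iter
            )
        except (ComponentCollapseError, ValueError):
            summaries.append(RestartSummary(None, -np.inf, 0, False, True))
            continue
        if _collapsed(theta):
            summaries.append(RestartSummary(theta, -np.inf, n_iter, converged, True))
            continue
        ll = trace[-1]
        summaries.append(RestartSummary(theta, float(ll), n_iter, converged, False))
        if converged and (best is None or ll > best[0]):
            best = (float(ll), theta, trace, n_iter, converged)
    if best is None:
        raise NonconvergenceError(summaries)
    ll, theta, trace, n_iter, converged = best
    return E2MFit(
        theta_hat=theta.sorted_by_rate(),
        loglik=ll,
        loglik_trace=trace,
        n_iter=n_iter,
        converged=converged,
        restart_results=summaries,
    )
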