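"""Likelihoods for mixed exponential data under progressive censoring.

Three log-likelihoods, all via a shared log-sum-exp kernel over components:

* complete-data — hidden labels and censored lifetimes known (simulation);
* observed-data ("face-value") — sum_i [log f(t_i) + R_i log s(t_i)],
  the classical likelihood for progressively censored data with the
  scheme-dependent multiplicative constant dropped (it does not involve
  the parameters);
* evidential — the expectation of the data's contour function under the
  model; each observed unit contributes
  log sum_k pi_k pl_{i,k} lam_k e^{-lam_k t_i} and each unit censored at
  epoch i contributes log sum_k pi_k pl_{ij,k} e^{-lam_k t_i}.  Note the
  censored factor uses the censoring time t_i, not the unobservable
  lifetime.

With the vacuous (all-ones) plausibility matrix the evidential likelihood
coincides with the observed-data one; with certain labels and no censoring
it coincides with the complete-data likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .censoring import ProgressiveSample
from .labels import PlausibilityMatrix, vacuous_plausibility
from .med import MEDParams, med_logpdf, med_logsurvival

__all__ = [
    "LikelihoodContext",
    "complete_loglik",
    "observed_loglik",
    "evidential_loglik",
]


@dataclass
class LikelihoodContext:
    """A censored sample paired with label plausibilities.

    When the supplied matrix covers only the observed units, censored units
    default to vacuous (all-ones) rows — the real-data case where no labels
    were elicited for removed units.
    """

    sample: ProgressiveSample
    plmat: Optional[PlausibilityMatrix] = None
    m: int = 2

    # filled in __post_init__: pl_obs (N x m), pl_cens list of (R_i x m)
    def __post_init__(self):
        N = self.sample.N
        R = self.sample.scheme.R
        n_cens = int(R.sum())
        if self.plmat is None:
            self.plmat = vacuous_plausibility(self.sample, self.m)
        if self.plmat.m != self.m:
            raise ValueError("plausibility matrix has wrong number of components")
        if self.plmat.n_units == N + n_cens:
            obs, cens = self.plmat.split(N)
        elif self.plmat.n_units == N:
            obs = self.plmat.pl
            cens = np.ones((n_cens, self.m))
        else:
            raise ValueError(
                f"plausibility matrix has {self.plmat.n_units} rows; "
                f"expected {N} (observed only) or {N + n_cens} (with censored)"
            )
        self.pl_obs = obs
        # group censored rows by removal epoch
        self.pl_cens = []
        start = 0
        for Ri in R:
            self.pl_cens.append(cens[start : start + Ri])
            start += Ri


def complete_loglik(w: ProgressiveSample, theta: MEDParams) -> float:
    """Log-likelihood of the fully revealed experiment (labels and z known)."""
    if w.labels_obs is None or w.z is None or w.labels_cens is None:
        raise ValueError("complete-data likelihood needs labels and hidden lifetimes")
    logpi = np.log(theta.pi)
    loglam = np.log(theta.lam)
    lab = np.asarray(w.labels_obs, dtype=int)
    total = float(np.sum(logpi[lab] + loglam[lab] - theta.lam[lab] * w.t))
    for zi, labi in zip(w.z, w.labels_cens):
        if len(zi):
            labi = np.asarray(labi, dtype=int)
            total += float(np.sum(logpi[labi] + loglam[labi] - theta.lam[labi] * zi))
    return total


def observed_loglik(sample: ProgressiveSample, theta: MEDParams) -> float:
    """Face-value log-likelihood sum_i [log f(t_i) + R_i log s(t_i)]."""
    lf = med_logpdf(sample.t, theta)
    ls = med_logsurvival(sample.t, theta)
    return float(np.sum(lf + sample.scheme.R * ls))


def evidential_loglik(ctx: LikelihoodContext, theta: MEDParams) -> float:
    """Evidential log-likelihood of a censored sample with soft labels."""
    t = ctx.sample.t
    logpi = np.log(theta.pi)
    loglam = np.log(theta.lam)
    # observed units: log sum_k pi_k pl_ik lam_k exp(-lam_k t_i)
    with np.errstate(divide="ignore"):
        log_pl_obs = np.log(ctx.pl_obs)
    terms = logpi + loglam - np.outer(t, theta.lam) + log_pl_obs
    obs_contrib = logsumexp(terms, axis=1)
    if not np.all(np.isfinite(obs_contrib)):
        bad = int(np.argmin(np.isfinite(obs_contrib)))
        raise ValueError(f"degenerate observation: unit {bad} has zero total plausibility")
    total = float(obs_contrib.sum())
    # censored units at epoch i: log sum_k pi_k pl_ijk exp(-lam_k t_i)
    for i, pl_rows in enumerate(ctx.pl_cens):
        if pl_rows.shape[0] == 0:
            continue
        with np.errstate(divide="ignore"):
            log_pl = np.log(pl_rows)
        terms = logpi - theta.lam * t[i] + log_pl
        contrib = logsumexp(terms, axis=1)
        if not np.all(np.isfinite(contrib)):
            raise ValueError(
                f"degenerate observation: a unit censored at epoch {i} has zero total plausibility"
            )
        total += float(contrib.sum())
    return total
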