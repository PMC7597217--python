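"""The m-component mixed exponential distribution (MED).

Density, survival, cdf, component-wise terms, labeled sampling, and the
truncated-mean closed form consumed by the E-step of the evidential EM
algorithm.  Parameters are the mixture weights ``pi`` (summing to one) and
the component rates ``lam`` (units 1/time):

    f(x) = sum_k pi_k lam_k exp(-lam_k x),      x >= 0
    s(x) = sum_k pi_k exp(-lam_k x)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "MEDParams",
    "med_pdf",
    "med_logpdf",
    "med_cdf",
    "med_survival",
    "med_logsurvival",
    "med_mean",
    "component_truncated_mean",
    "sample_med_with_labels",
]


@dataclass(frozen=True)
class MEDParams:
    """Parameters theta = (pi, lam) of an m-component mixed exponential.

    ``pi`` are mixture weights in (0, 1) summing to one; ``lam`` are strictly
    positive rates, one per component.
    """

    pi: np.ndarray
    lam: np.ndarray

    def __post_init__(self):
        pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        if pi.shape != lam.shape or pi.ndim != 1:
            raise ValueError("pi and lam must be 1-d vectors of equal length")
        if pi.size < 1:
            raise ValueError("at least one component required")
        if abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError(f"mixture weights sum to {pi.sum()}, not 1")
        if np.any(pi <= 0.0) or np.any(pi >= 1.0 + 1e-12):
            if pi.size > 1 or not np.isclose(pi[0], 1.0):
                raise ValueError("each weight must lie in (0, 1)")
        if np.any(lam <= 0.0):
            raise ValueError("rates must be strictly positive")
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "lam", lam)

    @property
    def m(self) -> int:
        return self.pi.size

    def sorted_by_rate(self) -> "MEDParams":
        """Components reordered by descending rate (label-switching fix)."""
        order = np.argsort(-self.lam, kind="stable")
        return MEDParams(self.pi[order], self.lam[order])

    def as_dict(self) -> dict:
        return {"pi": self.pi.tolist(), "lam": self.lam.tolist()}


def _check_nonneg(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("times must be nonnegative")
    return x


def med_logpdf(x, theta: MEDParams) -> np.ndarray:
    """log f(x) via log-sum-exp over components (stable for large lam*x)."""
    x = _check_nonneg(x)
    # shape (..., m)
    terms = (
        np.log(theta.pi)
        + np.log(theta.lam)
        - np.multiply.outer(x, theta.lam)
    )
    return logsumexp(terms, axis=-1)


def med_pdf(x, theta: MEDParams) -> np.ndarray:
    """Mixture density f(x) = sum_k pi_k lam_k exp(-lam_k x)."""
    return np.exp(med_logpdf(x, theta))


def med_logsurvival(x, theta: MEDParams) -> np.ndarray:
    """log s(x), s(x) = sum_k pi_k exp(-lam_k x)."""
    x = _check_nonneg(x)
    terms = np.log(theta.pi) - np.multiply.outer(x, theta.lam)
    return logsumexp(terms, axis=-1)


def med_survival(x, theta: MEDParams) -> np.ndarray:
    return np.exp(med_logsurvival(x, theta))


def med_cdf(x, theta: MEDParams) -> np.ndarray:
    return 1.0 - med_survival(x, theta)


def med_mean(theta: MEDParams) -> float:
    """E[X] = sum_k pi_k / lam_k."""
    return float(np.sum(theta.pi / theta.lam))


def component_truncated_mean(t, lam_k) -> np.ndarray | float:
    """E[Z | Z >= t] for an Exponential(lam_k) lifetime: t + 1/lam_k.

    This is the closed form of the E-step integral
    int_t^inf z f_k(z) / s_k(t) dz, exact by the memorylessness of the
    exponential distribution.
    """
    t = _check_nonneg(t)
    lam_k = np.asarray(lam_k, dtype=float)
    if np.any(lam_k <= 0):
        raise ValueError("rate must be strictly positive")
    out = t + 1.0 / lam_k
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def sample_med_with_labels(
    n: int, theta: MEDParams, rng: np.random.Generator | int | None = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw n lifetimes with their true component labels.

    Labels are multinomial on ``pi``; lifetime i is Exponential(lam[label_i]).
    Returns ``(lifetimes, labels)`` with labels in 0..m-1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    labels = rng.choice(theta.m, size=n, p=theta.pi)
    lifetimes = rng.exponential(scale=1.0 / theta.lam[labels])
    return lifetimes, labels
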