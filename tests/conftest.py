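import numpy as np
import pytest

from evidmix import (
    E2MConfig,
    LikelihoodContext,
    MEDParams,
    Scheme,
    expand_scheme,
    load_aircon_sample,
    simulate_progressive,
)

# true parameters of the simulation studies: pi = (0.3, 0.7), lam = (0.6, 0.1)
STUDY_THETA = MEDParams(np.array([0.3, 0.7]), np.array([0.6, 0.1]))


@pytest.fixture(scope="session")
def study_theta():
    return STUDY_THETA


@pytest.fixture(scope="session")
def aircon():
    """(sample, plausibility matrix) for the 30 air-conditioning failures."""
    return load_aircon_sample(with_plausibility=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_censored_sample():
    scheme = expand_scheme("scheme-1", n=40, N=12)
    return simulate_progressive(STUDY_THETA, scheme, np.random.default_rng(99))


def random_theta(rng, m=2, lam_scale=1.0):
    """A random valid parameter vector, rates well separated from zero."""
    pi = rng.dirichlet(np.full(m, 2.0))
    pi = np.clip(pi, 0.02, None)
    pi = pi / pi.sum()
    lam = rng.uniform(0.05, 2.0, size=m) * lam_scale
    return MEDParams(pi, lam)


def classical_em_progressive(sample, theta0, max_iter=500, epsilon=1e-10):
    """Independently coded classical EM for the progressively censored
    mixed exponential model (no label information).

    Written directly from the face-value likelihood's standard EM updates,
    without reference to the package's E2M code: observed responsibilities
    use component densities, censored ones component survivals at the
    censoring time, censored lifetimes are imputed by t_i + 1/lam_k.
    Returns the list of parameter iterates (including theta0).
    """
    t = sample.t
    R = sample.scheme.R
    pi = theta0.pi.copy()
    lam = theta0.lam.copy()
    iterates = [(pi.copy(), lam.copy())]
    for _ in range(max_iter):
        f = pi * lam * np.exp(-np.outer(t, lam))  # N x m component terms
        a = f / f.sum(axis=1, keepdims=True)
        s = pi * np.exp(-np.outer(t, lam))
        e = s / s.sum(axis=1, keepdims=True)  # shared by all R_i units at epoch i
        xi = t[:, None] + 1.0 / lam[None, :]
        A = a.sum(axis=0) + (R[:, None] * e).sum(axis=0)
        C = (R[:, None] * xi * e).sum(axis=0)
        new_pi = A / A.sum()
        new_lam = A / (C + (t[:, None] * a).sum(axis=0))
        d_pi = np.sum((new_pi - pi) ** 2)
        d_lam = np.sum((new_lam - lam) ** 2)
        pi, lam = new_pi, new_lam
        iterates.append((pi.copy(), lam.copy()))
        if d_pi <= epsilon and d_lam <= epsilon:
            break
    return iterates
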