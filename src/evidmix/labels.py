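"""Plausibility matrices over component labels.

A plausibility matrix gives, per unit and per mixture component, the
plausibility that the unit belongs to that component.  Rows cover the
observed units first (in failure order) and then, when the sample is
censored and labels exist for the removed units, the censored units grouped
by removal epoch.  Special cases: the vacuous matrix (all ones — no label
information, recovering classical EM/MLE), the certain matrix (0/1
indicators of known labels), a file-supplied matrix, and the beta
label-corruption model used in simulation studies.

The corruption model draws, for unit i, an error probability q_i from a
Beta distribution with given mean rho and standard deviation sigma; with
probability q_i the reported label is replaced by a uniform draw over all m
labels.  The plausibility row is then built from the reported label b*:

    pl_{i,k} = q_i/m + 1 - q_i   if k = b*_i,
    pl_{i,k} = q_i/m             otherwise.

By default b* is the reported (possibly corrupted) label — the only version
an analyst without access to the truth could compute; conditioning on the
true label is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .censoring import ProgressiveSample

__all__ = [
    "PlausibilityMatrix",
    "CorruptionModel",
    "vacuous_plausibility",
    "certain_plausibility",
    "beta_from_mean_sd",
    "corrupt_and_contour",
    "read_plausibility_csv",
    "write_plausibility_csv",
]


@dataclass(frozen=True)
class PlausibilityMatrix:
    """Per-unit, per-component label plausibilities in [0, 1].

    ``pl`` has one row per unit (observed units first, then censored units
    in epoch order) and one column per mixture component.  Every row must
    have at least one positive entry.
    """

    pl: np.ndarray

    def __post_init__(self):
        pl = np.asarray(self.pl, dtype=float)
        if pl.ndim != 2:
            raise ValueError("plausibility matrix must be 2-d")
        if np.any(pl < 0) or np.any(pl > 1 + 1e-12):
            raise ValueError("plausibility entries must lie in [0, 1]")
        if np.any(pl.max(axis=1) <= 0):
            bad = int(np.argmax(pl.max(axis=1) <= 0))
            raise ValueError(f"row {bad} is all zero: unit has no plausible label")
        object.__setattr__(self, "pl", np.minimum(pl, 1.0))

    @property
    def n_units(self) -> int:
        return self.pl.shape[0]

    @property
    def m(self) -> int:
        return self.pl.shape[1]

    def split(self, N: int) -> Tuple[np.ndarray, np.ndarray]:
        """Rows for observed units (first N) and for censored units (rest)."""
        return self.pl[:N], self.pl[N:]


def vacuous_plausibility(sample: ProgressiveSample, m: int) -> PlausibilityMatrix:
    """All-ones matrix: total ignorance about every unit's label.

    Feeding this to the estimator reproduces the classical EM algorithm for
    progressively censored mixtures.
    """
    n_cens = int(np.sum(sample.scheme.R))
    return PlausibilityMatrix(np.ones((sample.N + n_cens, m)))


def certain_plausibility(labels: np.ndarray, m: int) -> PlausibilityMatrix:
    """0/1 indicator matrix for exactly known labels (0-based)."""
    labels = np.asarray(labels, dtype=int)
    if np.any(labels < 0) or np.any(labels >= m):
        raise ValueError("labels must lie in 0..m-1")
    pl = np.zeros((labels.size, m))
    pl[np.arange(labels.size), labels] = 1.0
    return PlausibilityMatrix(pl)


def beta_from_mean_sd(rho: float, sigma: float) -> Tuple[float, float]:
    """Moment-invert a Beta distribution from mean rho and sd sigma.

    Returns (alpha, beta).  Requires sigma^2 < rho (1 - rho).
    """
    if not (0.0 < rho < 1.0):
        raise ValueError("rho must lie in (0, 1)")
    var = sigma * sigma
    if var >= rho * (1.0 - rho):
        raise ValueError(
            f"infeasible: sigma^2 = {var:.4g} must be < rho(1-rho) = {rho * (1 - rho):.4g}"
        )
    nu = rho * (1.0 - rho) / var - 1.0
    return rho * nu, (1.0 - rho) * nu


@dataclass(frozen=True)
class CorruptionModel:
    """Beta label-corruption model with mean error rate rho and sd sigma."""

    rho: float
    sigma: float
    m: int

    def __post_init__(self):
        beta_from_mean_sd(self.rho, self.sigma)  # feasibility check
        if self.m < 1:
            raise ValueError("m must be >= 1")

    def beta_params(self) -> Tuple[float, float]:
        return beta_from_mean_sd(self.rho, self.sigma)


def corrupt_and_contour(
    true_labels: np.ndarray,
    model: CorruptionModel,
    rng: np.random.Generator | int | None = None,
    condition_on: str = "reported",
) -> Tuple[np.ndarray, PlausibilityMatrix, np.ndarray]:
    """Corrupt labels and build the matching plausibility matrix.

    Per unit i: draw q_i ~ Beta(mean rho, sd sigma); with probability q_i
    replace the label by a uniform draw over all m labels; the plausibility
    row has one entry q_i/m + 1 - q_i at the conditioning label and q_i/m
    elsewhere.  ``condition_on`` selects the conditioning label: "reported"
    (default) or "true".

    Returns ``(reported_labels, matrix, q)``; q is stored so a corrupted
    dataset is exactly reproducible from (seed, rho, sigma).
    """
    if condition_on not in ("reported", "true"):
        raise ValueError("condition_on must be 'reported' or 'true'")
    rng = np.random.default_rng(rng)
    true_labels = np.asarray(true_labels, dtype=int)
    m = model.m
    if np.any(true_labels < 0) or np.any(true_labels >= m):
        raise ValueError("labels must lie in 0..m-1")
    alpha, beta = model.beta_params()
    n = true_labels.size
    q = rng.beta(alpha, beta, size=n)
    corrupt = rng.random(n) < q
    uniform_draw = rng.integers(0, m, size=n)
    reported = np.where(corrupt, uniform_draw, true_labels)

    cond = reported if condition_on == "reported" else true_labels
    pl = np.tile((q / m)[:, None], (1, m))
    pl[np.arange(n), cond] = q / m + 1.0 - q
    return reported, PlausibilityMatrix(pl), q


def read_plausibility_csv(path) -> PlausibilityMatrix:
    """Read a plausibility matrix from CSV.

    Accepts either ``id,pl_1,...,pl_m`` (id column dropped) or bare numeric
    columns; one row per unit in sample order.
    """
    df = pd.read_csv(path)
    cols = [c for c in df.columns if str(c).lower() not in ("id", "unit")]
    mat = df[cols].to_numpy(dtype=float)
    return PlausibilityMatrix(mat)


def write_plausibility_csv(matrix: PlausibilityMatrix, path) -> None:
    df = pd.DataFrame(
        matrix.pl, columns=[f"pl_{k + 1}" for k in range(matrix.m)]
    )
    df.insert(0, "id", np.arange(1, matrix.n_units + 1))
    df.to_csv(path, index=False, float_format="%.6f")
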