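"""Type-II progressive censoring: scheme validation and simulation.

A life test places ``n`` units on test; at the time of the i-th observed
failure, ``R_i`` of the surviving units are withdrawn at random, and the
test ends at the ``N``-th failure.  The scheme must satisfy
``R_1 + ... + R_N + N = n``.

Simulation is by explicit experiment replay — generate ``n`` labeled
lifetimes, repeatedly record the minimum surviving lifetime as the next
observed failure and remove ``R_i`` survivors uniformly at random — so the
hidden lifetimes and true labels of removed units are retained for use by
the label-corruption model and the Monte Carlo study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .med import MEDParams, sample_med_with_labels

__all__ = [
    "Scheme",
    "ProgressiveSample",
    "expand_scheme",
    "simulate_progressive",
    "sample_to_frame",
]

NAMED_SCHEMES = ("scheme-1", "scheme-2", "scheme-3")


@dataclass(frozen=True)
class Scheme:
    """A Type-II progressive censoring plan R = (R_1, ..., R_N) for n units."""

    n: int
    R: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.R, dtype=int)
        if R.ndim != 1 or R.size < 1:
            raise ValueError("R must be a nonempty vector")
        if np.any(R < 0):
            raise ValueError("removal counts must be nonnegative")
        if R.sum() + R.size != self.n:
            raise ValueError(
                f"scheme infeasible: sum(R) + N = {R.sum() + R.size} != n = {self.n}"
            )
        object.__setattr__(self, "R", R)

    @property
    def N(self) -> int:
        return int(self.R.size)

    @classmethod
    def complete(cls, n: int) -> "Scheme":
        """No censoring: N = n, all R_i = 0."""
        return cls(n, np.zeros(n, dtype=int))

    def to_csv_row(self) -> str:
        return ",".join([str(self.n), str(self.N)] + [str(r) for r in self.R])

    @classmethod
    def from_csv_row(cls, row: str) -> "Scheme":
        parts = [int(p) for p in row.strip().split(",")]
        n, N, R = parts[0], parts[1], parts[2:]
        if len(R) != N:
            raise ValueError("scheme row length does not match N")
        return cls(n, np.array(R))


def expand_scheme(tag: str, n: int, N: int) -> Scheme:
    """Expand a named censoring plan into an explicit scheme.

    * ``scheme-1`` — all removals at the final failure: R = (0,...,0, n-N).
    * ``scheme-2`` — all removals at the first failure: R = (n-N, 0,...,0).
    * ``scheme-3`` — one removal per failure, the rest at the end:
      R = (1,...,1, n-2N+1); requires n >= 2N - 1.
    """
    if N < 1 or N > n:
        raise ValueError("need 1 <= N <= n")
    R = np.zeros(N, dtype=int)
    if tag == "scheme-1":
        R[-1] = n - N
    elif tag == "scheme-2":
        R[0] = n - N
    elif tag == "scheme-3":
        if n < 2 * N - 1:
            raise ValueError(f"scheme-3 infeasible: n = {n} < 2N - 1 = {2 * N - 1}")
        R[:] = 1
        R[-1] = n - 2 * N + 1
    else:
        raise ValueError(f"unknown scheme tag {tag!r}; expected one of {NAMED_SCHEMES}")
    return Scheme(n, R)


@dataclass
class ProgressiveSample:
    """A progressively censored sample, optionally with the hidden truth.

    ``t`` holds the ordered observed failure times.  In simulation the
    hidden lifetimes ``z`` of removed units (grouped by removal epoch, group
    i of size R_i) and the true labels of both observed and removed units
    are retained; on real data they are ``None``.
    """

    scheme: Scheme
    t: np.ndarray
    labels_obs: Optional[np.ndarray] = None
    z: Optional[List[np.ndarray]] = None
    labels_cens: Optional[List[np.ndarray]] = None

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        if t.size != self.scheme.N:
            raise ValueError("number of observed failures must equal N")
        if np.any(np.diff(t) < 0):
            raise ValueError("observed failure times must be nondecreasing")
        self.t = t
        if self.z is not None:
            if len(self.z) != self.scheme.N:
                raise ValueError("z must have one group per failure epoch")
            for i, (zi, Ri) in enumerate(zip(self.z, self.scheme.R)):
                zi = np.asarray(zi, dtype=float)
                if zi.size != Ri:
                    raise ValueError(f"epoch {i}: expected {Ri} hidden lifetimes")
                if np.any(zi < t[i]):
                    raise ValueError(f"epoch {i}: hidden lifetime below its censoring time")
                self.z[i] = zi

    @property
    def n(self) -> int:
        return self.scheme.n

    @property
    def N(self) -> int:
        return self.scheme.N

    @property
    def has_truth(self) -> bool:
        return self.labels_obs is not None

    def all_true_labels(self) -> np.ndarray:
        """Labels of observed units followed by censored units in epoch order."""
        if self.labels_obs is None:
            raise ValueError("sample carries no true labels")
        cens = (
            np.concatenate(self.labels_cens)
            if self.labels_cens and any(len(g) for g in self.labels_cens)
            else np.array([], dtype=int)
        )
        return np.concatenate([self.labels_obs, cens]).astype(int)


def simulate_progressive(
    theta: MEDParams,
    scheme: Scheme,
    rng: np.random.Generator | int | None = None,
) -> ProgressiveSample:
    """Simulate a progressively censored MED life test, keeping the truth.

    Lifetime generation and survivor removal use independent substreams
    split from the master seed, so the observed failure values are invariant
    to the removal pattern under common random numbers.
    """
    master = np.random.default_rng(rng)
    rng_life, rng_removal = master.spawn(2)
    lifetimes, labels = sample_med_with_labels(scheme.n, theta, rng_life)

    alive = list(range(scheme.n))  # generation indices; ties broken by index
    t_obs = np.empty(scheme.N)
    labels_obs = np.empty(scheme.N, dtype=int)
    z_groups: List[np.ndarray] = []
    lab_groups: List[np.ndarray] = []
    for i in range(scheme.N):
        # next failure among survivors (min lifetime, index-stable)
        fail_pos = min(range(len(alive)), key=lambda p: (lifetimes[alive[p]], alive[p]))
        fail_idx = alive.pop(fail_pos)
        t_obs[i] = lifetimes[fail_idx]
        labels_obs[i] = labels[fail_idx]
        Ri = int(scheme.R[i])
        if Ri > 0:
            removed_pos = rng_removal.choice(len(alive), size=Ri, replace=False)
            removed = sorted((alive[p] for p in removed_pos))
            alive = [u for u in alive if u not in set(removed)]
            z_groups.append(lifetimes[removed].copy())
            lab_groups.append(labels[removed].copy())
        else:
            z_groups.append(np.array([]))
            lab_groups.append(np.array([], dtype=int))
    return ProgressiveSample(scheme, t_obs, labels_obs, z_groups, lab_groups)


def sample_to_frame(sample: ProgressiveSample) -> pd.DataFrame:
    """Tabulate a sample: columns time, status (1=observed), epoch, true_label."""
    rows = []
    for i, t in enumerate(sample.t):
        lab = int(sample.labels_obs[i]) + 1 if sample.labels_obs is not None else None
        rows.append({"time": t, "status": 1, "epoch": i + 1, "true_label": lab})
    if sample.z is not None:
        for i, group in enumerate(sample.z):
            for j, zval in enumerate(group):
                lab = (
                    int(sample.labels_cens[i][j]) + 1
                    if sample.labels_cens is not None
                    else None
                )
                # the recorded time of a censored unit is its censoring epoch time
                rows.append(
                    {"time": sample.t[i], "status": 0, "epoch": i + 1, "true_label": lab}
                )
    return pd.DataFrame(rows)
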