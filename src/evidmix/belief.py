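"""Minimal Dempster–Shafer core over a finite frame of discernment.

This module provides the belief-function machinery that underlies the
evidential likelihood: mass functions (basic belief assignments) on a finite
frame, belief/plausibility evaluation, contour extraction, Dempster's rule of
combination, and the probability-by-contour conditioning used by the E2M
algorithm's E-step.

Subsets of the frame are represented as bitmasks over the ordered element
list.  Full power-set combination is a pedagogical/testing facility; the
estimation path consumes contour functions only, since the evidential
likelihood depends on a mass function only through its contour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Hashable, Iterable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "Frame",
    "MassFunction",
    "ContourFunction",
    "IncombinableError",
    "belief_and_plausibility",
    "contour",
    "dempster_combine",
    "condition_probability_by_contour",
]

#: absolute tolerance on the total mass of a BBA
MASS_SUM_TOL = 1e-9
#: masses below this after combination are pruned and the rest renormalized
MASS_PRUNE_TOL = 1e-12


class IncombinableError(ValueError):
    """Raised when two mass functions are in total conflict (k = 1)."""


@dataclass(frozen=True)
class Frame:
    """Ordered finite frame of discernment Omega = {omega_1, ..., omega_c}."""

    elements: Tuple[Hashable, ...]

    def __init__(self, elements: Iterable[Hashable]):
        elems = tuple(elements)
        if len(elems) == 0:
            raise ValueError("frame must be nonempty")
        if len(set(elems)) != len(elems):
            raise ValueError("frame elements must be distinct")
        object.__setattr__(self, "elements", elems)

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def full_mask(self) -> int:
        return (1 << len(self.elements)) - 1

    def subset_to_mask(self, subset: Iterable[Hashable]) -> int:
        """Encode a subset of the frame as a bitmask; raises if not a subset."""
        mask = 0
        index = {e: i for i, e in enumerate(self.elements)}
        for x in subset:
            if x not in index:
                raise ValueError(f"{x!r} is not an element of the frame")
            mask |= 1 << index[x]
        return mask

    def mask_to_subset(self, mask: int) -> frozenset:
        return frozenset(
            e for i, e in enumerate(self.elements) if mask & (1 << i)
        )


@dataclass(frozen=True)
class MassFunction:
    """A basic belief assignment m : 2^Omega -> [0, 1] with sum(m) = 1.

    Focal sets are stored as bitmasks over the ordered frame.  Focal sets
    must be nonempty and distinct and their masses must lie in (0, 1] and
    sum to one within ``MASS_SUM_TOL``.
    """

    frame: Frame
    focal: Tuple[Tuple[int, float], ...]  # (bitmask, mass)

    def __post_init__(self):
        seen = set()
        total = 0.0
        for mask, mass in self.focal:
            if mask == 0:
                raise ValueError("focal sets must be nonempty")
            if mask > self.frame.full_mask:
                raise ValueError("focal set not contained in the frame")
            if mask in seen:
                raise ValueError("focal sets must be distinct")
            if not (0.0 < mass <= 1.0 + MASS_SUM_TOL):
                raise ValueError(f"mass {mass} outside (0, 1]")
            seen.add(mask)
            total += mass
        if abs(total - 1.0) > MASS_SUM_TOL:
            raise ValueError(f"masses sum to {total}, not 1")

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------
    @classmethod
    def from_subsets(
        cls, frame: Frame, assignment: Dict[frozenset, float] | Sequence[Tuple[Iterable, float]]
    ) -> "MassFunction":
        items = assignment.items() if isinstance(assignment, dict) else assignment
        focal = tuple((frame.subset_to_mask(A), float(m)) for A, m in items)
        return cls(frame, focal)

    @classmethod
    def vacuous(cls, frame: Frame) -> "MassFunction":
        """Total ignorance: all mass on the whole frame."""
        return cls(frame, ((frame.full_mask, 1.0),))

    @classmethod
    def categorical(cls, frame: Frame, subset: Iterable[Hashable]) -> "MassFunction":
        """Certainty that the truth lies in ``subset``."""
        return cls(frame, ((frame.subset_to_mask(subset), 1.0),))

    @classmethod
    def bayesian(cls, frame: Frame, probs: Sequence[float]) -> "MassFunction":
        """All focal sets singletons; a probability distribution on the frame."""
        if len(probs) != len(frame):
            raise ValueError("probability vector length must match the frame")
        focal = tuple(
            (1 << i, float(p)) for i, p in enumerate(probs) if p > 0.0
        )
        return cls(frame, focal)

    # ------------------------------------------------------------------
    def mass_of(self, subset: Iterable[Hashable]) -> float:
        mask = self.frame.subset_to_mask(subset)
        for m, v in self.focal:
            if m == mask:
                return v
        return 0.0


@dataclass(frozen=True)
class ContourFunction:
    """The contour pl(omega) = Pl({omega}), one value in [0, 1] per element.

    The vacuous mass function yields the all-ones contour; a Bayesian mass
    yields its own probability vector.
    """

    frame: Frame
    pl: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.pl, dtype=float)
        if arr.shape != (len(self.frame),):
            raise ValueError("contour length must match the frame")
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise ValueError("contour values must lie in [0, 1]")
        object.__setattr__(self, "pl", np.clip(arr, 0.0, 1.0))

    def to_json_dict(self) -> Dict[str, float]:
        return {str(e): float(v) for e, v in zip(self.frame.elements, self.pl)}


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------

def belief_and_plausibility(m: MassFunction, A: Iterable[Hashable]) -> Tuple[float, float]:
    """Return (Bel(A), Pl(A)).

    Bel(A) sums the masses of nonempty focal sets contained in A; Pl(A) sums
    the masses of focal sets intersecting A.  Always 0 <= Bel <= Pl <= 1.
    """
    mask = m.frame.subset_to_mask(A)
    bel = sum(v for b, v in m.focal if b & ~mask == 0)
    pl = sum(v for b, v in m.focal if b & mask != 0)
    return min(bel, 1.0), min(pl, 1.0)


def contour(m: MassFunction) -> ContourFunction:
    """Extract the contour function pl(omega) = Pl({omega})."""
    c = len(m.frame)
    pl = np.zeros(c)
    for mask, v in m.focal:
        for i in range(c):
            if mask & (1 << i):
                pl[i] += v
    return ContourFunction(m.frame, np.minimum(pl, 1.0))


def dempster_combine(m1: MassFunction, m2: MassFunction) -> MassFunction:
    """Dempster's rule of combination with conflict renormalization.

    Raises :class:`IncombinableError` when the conflict k equals 1 (the two
    sources are totally contradictory).  Combining with the vacuous mass is
    the identity.
    """
    if m1.frame != m2.frame:
        raise ValueError("mass functions must share a frame")
    combined: Dict[int, float] = {}
    conflict = 0.0
    for b1, v1 in m1.focal:
        for b2, v2 in m2.focal:
            inter = b1 & b2
            w = v1 * v2
            if inter == 0:
                conflict += w
            else:
                combined[inter] = combined.get(inter, 0.0) + w
    if conflict >= 1.0 - 1e-15 or not combined:
        raise IncombinableError(
            f"total conflict (k = {conflict:.6g}); masses cannot be combined"
        )
    norm = 1.0 - conflict
    focal = {b: v / norm for b, v in combined.items() if v / norm > MASS_PRUNE_TOL}
    total = sum(focal.values())
    focal = tuple((b, v / total) for b, v in sorted(focal.items()))
    return MassFunction(m1.frame, focal)


def condition_probability_by_contour(
    p: ContourFunction, pl: ContourFunction
) -> ContourFunction:
    """Condition a probability distribution by a contour function.

    Computes (p (+) pl)(omega) = p(omega) pl(omega) / (1 - k) where
    1 - k = sum_omega p(omega) pl(omega) is the expectation of pl under p.
    This equals Dempster combination of the Bayesian mass with any mass
    whose contour is ``pl``, and reduces to ordinary conditioning when
    ``pl`` is the indicator of a subset.
    """
    if p.frame != pl.frame:
        raise ValueError("contours must share a frame")
    prob = np.asarray(p.pl, float)
    if abs(prob.sum() - 1.0) > 1e-9:
        raise ValueError("first argument must be a probability distribution")
    prod = prob * np.asarray(pl.pl, float)
    norm = prod.sum()
    if norm <= 0.0:
        raise IncombinableError("total conflict: E_p[pl] = 0")
    return ContourFunction(p.frame, prod / norm)
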