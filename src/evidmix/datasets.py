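"""Packaged example datasets.

``aircon30`` is a classical reliability benchmark: 30 successive failure
times of an aircraft air-conditioning system, commonly fitted with a
two-component mixed exponential model.  The companion 30 x 2 plausibility
matrix carries soft sub-population labels for the same 30 units, produced
by an evidential clustering of the failure times; it is consumed as shipped
data, not recomputed here.  The dataset is complete (no censoring): the
scheme is N = n = 30 with all removals zero.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .censoring import ProgressiveSample, Scheme
from .labels import PlausibilityMatrix, read_plausibility_csv

__all__ = ["FIXTURES", "load_fixture", "load_aircon_sample"]

FIXTURES = ("aircon30", "aircon30+labels")


def _data_path(name: str):
    return resources.files("evidmix.data").joinpath(name)


def load_fixture(name: str) -> Tuple[np.ndarray, Optional[PlausibilityMatrix]]:
    """Return (failure_times, plausibility_matrix_or_None) for a fixture."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
    with resources.as_file(_data_path("aircon30.csv")) as p:
        times = pd.read_csv(p)["time"].to_numpy(dtype=float)
    plmat = None
    if name == "aircon30+labels":
        with resources.as_file(_data_path("aircon30_plausibility.csv")) as p:
            plmat = read_plausibility_csv(p)
        if plmat.n_units != times.size:
            raise ValueError("plausibility matrix does not match the failure data")
    return times, plmat


def load_aircon_sample(with_plausibility: bool = True):
    """The air-conditioning data as a ready-to-fit (sample, plmat) pair."""
    name = "aircon30+labels" if with_plausibility else "aircon30"
    times, plmat = load_fixture(name)
    sample = ProgressiveSample(Scheme.complete(times.size), np.sort(times))
    return sample, plmat
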