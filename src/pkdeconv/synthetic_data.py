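"""Synthetic validation data: a realistic extended-release absorption profile
pushed through the TMDD model, with configurable sampling and noise.

The test input mimics the absorption of an injectable microsphere depot
formulation: a fast initial burst (freely available surface drug) plus two
delayed peaks (diffusion- and erosion-controlled release). It is the sum of

* two Erlang-shaped peaks  u_i(t) = a_i ktr_i^{n_i} t^{n_i - 1}
  e^{-ktr_i t} / (n_i - 1)!   (the impulse response of a chain of n_i
  transit compartments, carrying total mass a_i), and
* a bi-exponential burst    u_3(t) = r_1 e^{-k_1 t} + r_2 e^{-k_2 t}.

Datasets are the model-predicted concentrations at a sampling schedule,
optionally corrupted with proportional noise y = f (1 + sigma eps), eps
standard Student-t (default, 4 df) or Gaussian.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from math import factorial
from typing import Optional

import numpy as np

from .inference import Dataset, NoiseModel
from .pk_model import PKParameters, simulate_dynamic

__all__ = [
    "TestInputParams",
    "SamplingSchedule",
    "test_input",
    "erlang_peak",
    "burst",
    "total_input_mass",
    "make_schedule",
    "generate_dataset",
    "write_dataset",
    "MINUTES_PER_HOUR",
    "MINUTES_PER_WEEK",
    "SHORT_T_END_MIN",
    "LONG_T_END_MIN",
]

MINUTES_PER_HOUR = 60.0
MINUTES_PER_WEEK = 7.0 * 24.0 * 60.0
SHORT_T_END_MIN = 48.0 * MINUTES_PER_HOUR       # 2,880 min
LONG_T_END_MIN = 12.0 * MINUTES_PER_WEEK        # 120,960 min

#: sparse short-timescale schedule in hours: a reconstruction of a typical
#: 12-point clinical sampling design over the first 48 h
SPARSE_SHORT_HOURS = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0,
                      36.0, 48.0)


@dataclass(frozen=True)
class TestInputParams:
    """Parameters of the synthetic absorption profile (all per kg bodyweight).

    n1, n2 : Erlang shape integers (number of transit compartments)
    a1, a2 : peak masses, pmol/kg
    ktr1, ktr2 : transit rate constants, 1/min
    r1, r2 : burst coefficients, pmol min^-1 kg^-1
    k1, k2 : burst decay rates, 1/min
    """

    __test__ = False  # not a pytest item despite the Test* name

    n1: int = 10
    a1: float = 2700.0
    ktr1: float = 1.5e-4
    n2: int = 4
    a2: float = 800.0
    ktr2: float = 1.8e-4
    r1: float = 0.12
    r2: float = 0.02
    k1: float = 7.64e-3
    k2: float = 4.76e-4

    def __post_init__(self) -> None:
        for name in ("n1", "n2"):
            val = getattr(self, name)
            if not (isinstance(val, (int, np.integer)) and val >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {val!r}")
        for name in ("a1", "a2", "ktr1", "ktr2", "r1", "r2", "k1", "k2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SamplingSchedule:
    """Observation times in minutes with their provenance labels."""

    label: str       # 'dense' or 'sparse'
    timescale: str   # 'short' or 'long'
    times: tuple     # minutes, strictly increasing, > 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("schedule times must be positive and increasing")

    @property
    def times_min(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)


def erlang_peak(t, a: float, ktr: float, n: int) -> np.ndarray:
    """a * ktr^n t^{n-1} e^{-ktr t} / (n-1)!  — integrates to a over [0, inf)."""
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError(f"Erlang shape must be an integer >= 1, got {n!r}")
    t = np.asarray(t, dtype=float)
    return a * ktr ** n * t ** (n - 1) * np.exp(-ktr * t) / factorial(n - 1)


def burst(t, p: TestInputParams) -> np.ndarray:
    """Bi-exponential initial burst u_3(t)."""
    t = np.asarray(t, dtype=float)
    return p.r1 * np.exp(-p.k1 * t) + p.r2 * np.exp(-p.k2 * t)


def test_input(t, p: Optional[TestInputParams] = None,
               include_burst: bool = True) -> np.ndarray:
    """The synthetic absorption rate u(t) = u1 + u2 (+ u3), pmol min^-1 kg^-1.

    ``include_burst=False`` gives the slow (long-timescale) component only.
    """
    p = p or TestInputParams()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    u = (erlang_peak(t, p.a1, p.ktr1, p.n1)
         + erlang_peak(t, p.a2, p.ktr2, p.n2))
    if include_burst:
        u = u + burst(t, p)
    return u


def total_input_mass(p: Optional[TestInputParams] = None) -> float:
    """Analytic total absorbed mass: a1 + a2 + r1/k1 + r2/k2 (pmol/kg)."""
    p = p or TestInputParams()
    return p.a1 + p.a2 + p.r1 / p.k1 + p.r2 / p.k2


def make_schedule(timescale: str, label: str) -> SamplingSchedule:
    """Build a sampling schedule.

    dense : 100 equally spaced points t_k = k T/100, k = 1..100 (t = 0 is
        excluded because proportional error is degenerate at C = 0).
    sparse short : 12 clinical-style timepoints within 0-48 h.
    sparse long : the 48 h point plus weekly samples, weeks 1-12.
    """
    if timescale not in ("short", "long"):
        raise ValueError("timescale must be 'short' or 'long'")
    t_end = SHORT_T_END_MIN if timescale == "short" else LONG_T_END_MIN
    if label == "dense":
        times = tuple(np.arange(1, 101) * t_end / 100.0)
    elif label == "sparse":
        if timescale == "short":
            times = tuple(np.asarray(SPARSE_SHORT_HOURS) * MINUTES_PER_HOUR)
        else:
            times = (SHORT_T_END_MIN,) + tuple(
                np.arange(1, 13) * MINUTES_PER_WEEK
            )
    else:
        raise ValueError("schedule label must be 'dense' or 'sparse'")
    return SamplingSchedule(label=label, timescale=timescale, times=times)


def generate_dataset(
    input_params: Optional[TestInputParams],
    schedule: SamplingSchedule,
    params: Optional[PKParameters] = None,
    noise: Optional[NoiseModel] = None,
    seed: Optional[int] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
):
    """Generate a synthetic dataset by simulating the TMDD system.

    Concentrations are the exact model output at the schedule times; if a
    noise model is given, each observation is multiplied by (1 + sigma eps)
    with iid standardized errors, and any non-positive draw is redrawn (the
    number of redraws is recorded in the returned info dict).

    Returns
    -------
    (dataset, info) : the :class:`~pkdeconv.inference.Dataset` plus a
        truth/provenance sidecar dict (input parameters, schedule, seed,
        noise settings, redraw count).
    """
    input_params = input_params or TestInputParams()
    params = params or PKParameters()
    times = schedule.times_min
    clean = simulate_dynamic(lambda t: test_input(t, input_params), params,
                             times, rtol=rtol, atol=atol, check_input=False)
    rng = np.random.default_rng(seed)
    redraws = 0
    if noise is None:
        conc = clean.copy()
    else:
        conc = np.empty_like(clean)
        for i, f in enumerate(clean):
            while True:
                if noise.family == "student_t":
                    eps = rng.standard_t(noise.df)
                else:
                    eps = rng.standard_normal()
                y = f * (1.0 + noise.sigma * eps)
                if y > 0:
                    conc[i] = y
                    break
                redraws += 1
    dataset = Dataset(times=times, conc=conc, timescale=schedule.timescale)
    info = {
        "input_params": input_params.to_dict(),
        "pk_params": params.to_dict(),
        "schedule": {"label": schedule.label, "timescale": schedule.timescale,
                     "times_min": times.tolist()},
        "noise": None if noise is None else {
            "family": noise.family, "sigma": noise.sigma, "df": noise.df},
        "seed": seed,
        "n_redraws": redraws,
    }
    return dataset, info


def write_dataset(dataset: Dataset, info: dict, csv_path, sidecar_path) -> None:
    """Write the dataset CSV and its truth/provenance JSON sidecar."""
    dataset.to_csv(csv_path)
    with open(sidecar_path, "w") as fh:
        json.dump(info, fh, indent=2)
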