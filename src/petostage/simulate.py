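"""Stochastic simulation of the multistage process: a brute-force oracle.

Each of C independent stem cells undergoes ``n_divisions`` divisions; at
every division each not-yet-acquired driver arises with probability u.
A cell initiates cancer once it carries all M drivers, subject to
immune policing: each acquired driver independently escapes detection
with probability 1-e_d, and a fully transformed cell escapes with
probability 1-e_c.  The empirical cohort incidence must agree with the
analytic risk equation, which it approximates to O(u) (per-division
Bernoulli versus the continuous exponential waiting time).

Per-driver acquisition is simulated by geometric waiting times, the
exact distribution of the first successful Bernoulli(u) division, so
simulation cost is independent of ``n_divisions``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import MultistageParams

__all__ = ["SimScenario", "SimResult", "simulate_cohort", "generate_scenarios"]

_MAX_CELLS = 10**6  # desk-scale guard
_CHUNK_DRAWS = 20_000_000  # cap on replicate*C*M draws held at once


@dataclass(frozen=True)
class SimScenario:
    """One simulation setting: parameters, divisions, seed, replicates."""

    params: MultistageParams
    n_divisions: int
    seed: int = 0
    replicates: int = 1000

    def __post_init__(self) -> None:
        if self.n_divisions < 0:
            raise ValueError(f"n_divisions must be >= 0, got {self.n_divisions}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if self.params.C > _MAX_CELLS:
            raise ValueError(
                f"C={self.params.C} exceeds the desk-scale limit {_MAX_CELLS}"
            )
        if self.params.u > 1e-2:
            raise ValueError(
                f"u={self.params.u} outside the per-division Bernoulli "
                "regime (u <= 1e-2)"
            )


@dataclass(frozen=True)
class SimResult:
    """Empirical incidence: fraction of replicate cohorts with cancer."""

    estimate: float
    se: float
    n_cancer: int
    replicates: int


def simulate_cohort(scenario: SimScenario) -> SimResult:
    """Simulate replicate cohorts; return the empirical lifetime risk.

    The standard error uses an Agresti–Coull-style adjusted proportion
    (successes+2)/(replicates+4) so that all-negative or all-positive
    runs still yield a usable uncertainty band.
    """
    p = scenario.params
    C = int(round(p.C))
    M = int(round(p.M))
    n = scenario.n_divisions
    R = scenario.replicates
    rng = np.random.default_rng(scenario.seed)

    n_cancer = 0
    if p.u == 0.0 or n == 0 or p.e_c >= 1.0:
        pass  # no cell can transform (or none survives policing)
    else:
        chunk = max(1, _CHUNK_DRAWS // max(C * M, 1))
        done = 0
        while done < R:
            r = min(chunk, R - done)
            # geometric waiting time = division index of first success
            waits = rng.geometric(p.u, size=(r, C, M))
            acquired = waits <= n
            if p.e_d > 0.0:
                acquired &= rng.random(size=(r, C, M)) < (1.0 - p.e_d)
            transformed = acquired.all(axis=2)
            if p.e_c > 0.0:
                transformed &= rng.random(size=(r, C)) < (1.0 - p.e_c)
            n_cancer += int(transformed.any(axis=1).sum())
            done += r

    estimate = n_cancer / R
    p_adj = (n_cancer + 2) / (R + 4)
    se = float(np.sqrt(p_adj * (1.0 - p_adj) / R))
    return SimResult(estimate=estimate, se=se, n_cancer=n_cancer, replicates=R)


_DEFAULT_RANGES: dict = {
    "C": (200, 3000),
    "u": (2e-4, 2e-3),
    "M": (1, 4),
    "n_divisions": (50, 400),
    "e_c": (0.0, 0.0),
    "e_d": (0.0, 0.0),
}


def generate_scenarios(
    seed: int,
    n: int,
    ranges: dict | None = None,
    replicates: int = 1200,
) -> list[SimScenario]:
    """Seeded random scenario generator for property tests.

    C and u are sampled log-uniformly (both span orders of magnitude),
    M uniformly over its integer range, policing efficiencies uniformly.
    Deterministic under a fixed seed.  Bounds are clipped to the
    desk-scale simulation limits (C <= 1e6, u <= 1e-2).
    """
    r = dict(_DEFAULT_RANGES, **(ranges or {}))
    if r["C"][1] > _MAX_CELLS:
        raise ValueError(f"C upper bound exceeds desk-scale limit {_MAX_CELLS}")
    if r["u"][1] > 1e-2:
        raise ValueError("u upper bound exceeds the simulable regime 1e-2")
    rng = np.random.default_rng(seed)
    out: list[SimScenario] = []
    for i in range(n):
        C = float(np.round(np.exp(rng.uniform(*np.log(r["C"])))))
        u = float(np.exp(rng.uniform(*np.log(r["u"]))))
        M = int(rng.integers(r["M"][0], r["M"][1] + 1))
        n_div = int(rng.integers(r["n_divisions"][0], r["n_divisions"][1] + 1))
        e_c = float(rng.uniform(*r["e_c"]))
        e_d = float(rng.uniform(*r["e_d"]))
        params = MultistageParams(
            C=C, k=float(n_div), u=u, M=M, t=1.0, e_c=e_c, e_d=e_d
        )
        out.append(
            SimScenario(
                params=params,
                n_divisions=n_div,
                seed=int(rng.integers(0, 2**31 - 1)),
                replicates=replicates,
            )
        )
    return out
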