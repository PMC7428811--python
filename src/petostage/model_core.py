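"""Multistage carcinogenesis risk equations with immune-policing extensions.

The multistage (Armitage–Doll-type) model treats cancer initiation as the
accumulation of ``M`` driver mutations in any one of ``C`` at-risk stem
cells, each dividing ``k`` times per year with a driver-mutation
probability ``u`` per division.  The per-cell, per-driver probability by
age ``t`` is ``x = 1 - exp(-u*k*t)``; the lifetime risk is

    p = 1 - {1 - (1-e_c) * [(1-e_d) * x]**M}**C

where ``e_c`` is the immune system's efficiency at detecting a fully
transformed cancer cell and ``e_d`` its efficiency at detecting a cell
carrying any single driver mutation.  With ``e_c = e_d = 0`` this is the
basic multistage risk; each policing term recovers its own special case.

All probabilities are evaluated in log space (``log1p``/``expm1``) so that
whale-scale cell counts (``C ~ 1e12``) with per-cell risks of ``1e-14`` or
smaller neither underflow nor lose precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "MultistageParams",
    "per_driver_prob",
    "lifetime_risk_exact",
    "lifetime_risk_approx",
    "per_cell_target",
]


@dataclass(frozen=True)
class MultistageParams:
    """Full parameter set consumed by the risk equations.

    Parameters
    ----------
    C : float
        Number of at-risk stem cells (>= 1).  May be non-integer after
        body-mass scaling (e.g. the hypothetical mouse colon carries
        2e8 * 0.02/60 = 66,666.67 cells).
    k : float
        Stem-cell division rate, divisions per year (>= 0).
    u : float
        Driver-mutation probability per cell division (0 <= u <= 1).
    M : float
        Number of driver mutations required for malignancy (>= 1).
        Integer in the forward model; real-valued solutions arise from
        the added-drivers solver.
    t : float
        Age / exposure time in years (>= 0).
    e_c : float, optional
        Immune detection efficiency against cancer cells, in [0, 1].
    e_d : float, optional
        Immune detection efficiency against each driver mutation,
        in [0, 1].
    """

    C: float
    k: float
    u: float
    M: float
    t: float
    e_c: float = 0.0
    e_d: float = 0.0

    def __post_init__(self) -> None:
        if not self.C >= 1:
            raise ValueError(f"C must be >= 1, got {self.C}")
        if not self.k >= 0:
            raise ValueError(f"k must be >= 0, got {self.k}")
        if not 0.0 <= self.u <= 1.0:
            raise ValueError(f"u must be in [0, 1], got {self.u}")
        if not self.M >= 1:
            raise ValueError(f"M must be >= 1, got {self.M}")
        if not self.t >= 0:
            raise ValueError(f"t must be >= 0, got {self.t}")
        if not 0.0 <= self.e_c <= 1.0:
            raise ValueError(f"e_c must be in [0, 1], got {self.e_c}")
        if not 0.0 <= self.e_d <= 1.0:
            raise ValueError(f"e_d must be in [0, 1], got {self.e_d}")

    def with_(self, **changes) -> "MultistageParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)


def per_driver_prob(u: float, k: float, t: float) -> float:
    """Probability that one cell acquires a given driver mutation by age t.

    ``x = 1 - exp(-u*k*t)``: the cell undergoes ``k*t`` divisions, each an
    independent chance ``u`` of the driver arising, in the continuous
    (exponential) limit.  Monotone nondecreasing in each argument.
    """
    if u < 0 or k < 0 or t < 0:
        raise ValueError(f"u, k, t must be nonnegative, got ({u}, {k}, {t})")
    return -math.expm1(-u * k * t)


def _log_per_cell_risk(p: MultistageParams) -> float:
    """log of q_cell = (1-e_c) * [(1-e_d) * x]**M; -inf when zero."""
    x = per_driver_prob(p.u, p.k, p.t)
    x_eff = (1.0 - p.e_d) * x
    if x_eff <= 0.0 or p.e_c >= 1.0:
        return -math.inf
    return math.log1p(-p.e_c) + p.M * math.log(x_eff)


def lifetime_risk_exact(params: MultistageParams) -> float:
    """Exact lifetime cancer risk p = 1 - {1 - (1-e_c)[(1-e_d)x]^M}^C.

    Reduces to the basic multistage risk when ``e_c = e_d = 0``, and to
    each single-policing form when the other efficiency is zero.
    Evaluated as ``-expm1(C * log1p(-q_cell))`` so that huge ``C`` and
    tiny per-cell risks remain accurate.
    """
    log_q = _log_per_cell_risk(params)
    if log_q == -math.inf:
        return 0.0
    q = math.exp(log_q)
    if q >= 1.0:
        return 1.0
    return -math.expm1(params.C * math.log1p(-q))


def lifetime_risk_approx(params: MultistageParams) -> float:
    """Small-p approximation p ≈ C*(1-e_c)*[(1-e_d)*u*k*t]^M.

    Accurate when the exact risk is small (relative error < 1% whenever
    the exact p < 0.005 and u*k*t < 0.05); may exceed 1 outside that
    regime and is then meaningless as a probability.
    """
    p = params
    return p.C * (1.0 - p.e_c) * ((1.0 - p.e_d) * p.u * p.k * p.t) ** p.M


def per_cell_target(p_target: float, C: float) -> float:
    """Per-cell cancer probability q such that 1 - (1-q)^C = p_target.

    ``q = 1 - (1-p_target)**(1/C)``, computed as
    ``-expm1(log1p(-p_target)/C)`` to survive C up to 1e12 and beyond.
    """
    if not 0.0 < p_target < 1.0:
        raise ValueError(f"p_target must be in (0, 1), got {p_target}")
    if not C >= 1:
        raise ValueError(f"C must be >= 1, got {C}")
    return -math.expm1(math.log1p(-p_target) / C)
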