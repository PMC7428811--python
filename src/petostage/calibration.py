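"""Hypothetical-mouse baseline calibration.

Each tissue's baseline is built by (1) scaling the human stem-cell count
down to mouse body mass, (2) scaling the division rate by the chosen MR
exponent, then (3) picking the integer driver count M >= 2 and solving
the somatic mutation rate u so that the mouse's lifetime risk is exactly
the 1% target.  M is chosen to keep u as close as possible to 1e-5 per
division on a log scale, because plausible somatic rates span orders of
magnitude; ties (never triggered on the study inputs) break toward the
smaller M.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .allometry import SpeciesSpec, TissueSpec, scale_cell_count, scale_division_rate
from .model_core import MultistageParams, lifetime_risk_exact, per_cell_target

__all__ = [
    "CalibrationResult",
    "InfeasibleTargetError",
    "solve_u_for_risk",
    "solve_u_for_risk_bracketed",
    "calibrate_baseline",
]

logger = logging.getLogger(__name__)


class InfeasibleTargetError(ValueError):
    """The requested risk target cannot be reached with any u in [0, 1]."""


@dataclass(frozen=True)
class CalibrationResult:
    """Baseline (M, u) pair at the calibrated 1% mouse risk.

    ``achieved_risk`` is re-evaluated through the exact risk equation,
    not assumed; ``params`` carries the full mouse-scale parameter set.
    """

    tissue: str
    M: int
    u: float
    achieved_risk: float
    beta: float
    params: MultistageParams


def solve_u_for_risk(C: float, k: float, t: float, M: float, p_target: float) -> float:
    """Mutation rate u giving lifetime risk exactly ``p_target``.

    Closed-form inversion of the exact risk equation:
    ``u = -log(1 - q**(1/M)) / (k*t)`` with ``q`` the per-cell target
    ``1 - (1-p_target)**(1/C)``.
    """
    if not (C >= 1 and k > 0 and t > 0):
        raise ValueError(f"need C >= 1, k > 0, t > 0; got ({C}, {k}, {t})")
    if not M >= 1:
        raise ValueError(f"M must be >= 1, got {M}")
    q = per_cell_target(p_target, C)
    x = math.exp(math.log(q) / M)
    if x >= 1.0:
        raise InfeasibleTargetError(
            f"per-driver probability {x} >= 1: target risk {p_target} "
            f"unreachable with C={C}, M={M}"
        )
    return -math.log1p(-x) / (k * t)


def solve_u_for_risk_bracketed(
    C: float, k: float, t: float, M: float, p_target: float
) -> float:
    """Independent check of :func:`solve_u_for_risk` by bracketed
    root-finding in log10(u) over [-15, -2]."""

    def f(log10_u: float) -> float:
        p = lifetime_risk_exact(MultistageParams(C=C, k=k, u=10**log10_u, M=M, t=t))
        return p - p_target

    return 10 ** brentq(f, -15.0, -2.0, xtol=1e-13, rtol=8.9e-16)


def calibrate_baseline(
    tissue: TissueSpec,
    baseline_species: SpeciesSpec,
    beta: float = 0.0,
    p_target: float = 0.01,
    u_anchor: float = 1e-5,
    reference: SpeciesSpec | None = None,
    M_max: int = 10,
) -> CalibrationResult:
    """Calibrate the (M, u) baseline for one tissue and MR exponent.

    Evaluates the closed-form u for each integer M in [2, M_max] and
    selects the M whose u minimises ``|log10(u / u_anchor)|``.
    """
    from .allometry import HUMAN

    reference = HUMAN if reference is None else reference
    C = scale_cell_count(tissue, baseline_species, reference)
    k = scale_division_rate(tissue, baseline_species, reference, beta)
    t = baseline_species.lifespan

    best: tuple[float, int, float] | None = None
    for M in range(2, M_max + 1):
        u = solve_u_for_risk(C, k, t, M, p_target)
        dist = abs(math.log10(u / u_anchor))
        logger.info(
            "calibrate %s beta=%g: M=%d -> u=%.4e (|log10 u/anchor|=%.3f)",
            tissue.name, beta, M, u, dist,
        )
        if best is None or dist < best[0] - 1e-12:
            best = (dist, M, u)
    assert best is not None
    _, M_sel, u_sel = best
    params = MultistageParams(C=C, k=k, u=u_sel, M=M_sel, t=t)
    achieved = lifetime_risk_exact(params)
    logger.info(
        "calibrate %s beta=%g: selected M=%d, u=%.4e, achieved risk=%.6g",
        tissue.name, beta, M_sel, u_sel, achieved,
    )
    return CalibrationResult(
        tissue=tissue.name, M=M_sel, u=u_sel, achieved_risk=achieved,
        beta=beta, params=params,
    )
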