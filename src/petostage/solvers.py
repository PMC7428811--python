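"""Inverse solvers for the evolutionary hypotheses.

Starting from a mouse-calibrated baseline, each solver asks what single
parameter change would hold a larger, longer-lived species' lifetime
risk at the 1% target:

* ``mutation_rate`` — fold-reduction in the somatic mutation rate u;
* ``added_drivers`` — extra driver mutations ΔM (extra layers of genetic
  suppression), real-valued;
* ``policing_cancer`` — maximum escape probability 1-e_c of a fully
  transformed cancer cell from immune surveillance;
* ``policing_driver`` — maximum per-driver escape probability 1-e_d.

All solvers invert the exact risk equation in closed form and verify the
solution by plugging it back in; ``achieved_risk`` is always recomputed.
Species no riskier than the baseline get sentinel solutions (fold 1,
ΔM 0, escape 1) flagged ``no_change_needed`` rather than errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .allometry import SpeciesSpec, TissueSpec, scale_cell_count, scale_division_rate
from .calibration import CalibrationResult, solve_u_for_risk
from .model_core import (
    MultistageParams,
    lifetime_risk_exact,
    per_cell_target,
    per_driver_prob,
)

__all__ = [
    "HypothesisSolution",
    "unmitigated_risk",
    "solve_mutation_fold",
    "solve_added_drivers",
    "solve_policing_cancer",
    "solve_policing_driver",
    "solve_all",
]

HYPOTHESES = ("mutation_rate", "added_drivers", "policing_cancer", "policing_driver")


@dataclass(frozen=True)
class HypothesisSolution:
    """One hypothesis' required parameter change for one scenario.

    ``value`` is the quantity the study tabulates: a fold-reduction of u
    (>= 1), added drivers ΔM (>= 0), or an escape probability (<= 1).
    ``achieved_risk`` is the risk re-evaluated at the solved parameters.
    """

    hypothesis: str
    tissue: str
    species: str
    beta: float
    value: float
    achieved_risk: float
    unmitigated_risk: float
    no_change_needed: bool = False


def _species_scale(
    baseline: CalibrationResult,
    tissue: TissueSpec,
    species: SpeciesSpec,
    reference: SpeciesSpec,
    beta: float,
) -> MultistageParams:
    """Mouse-baseline (u, M) carried to the target species' (C, k, t)."""
    return MultistageParams(
        C=scale_cell_count(tissue, species, reference),
        k=scale_division_rate(tissue, species, reference, beta),
        u=baseline.u,
        M=baseline.M,
        t=species.lifespan,
    )


def unmitigated_risk(
    baseline: CalibrationResult,
    tissue: TissueSpec,
    species: SpeciesSpec,
    reference: SpeciesSpec,
    beta: float,
) -> float:
    """Lifetime risk at target-species scale with no evolved change."""
    return lifetime_risk_exact(_species_scale(baseline, tissue, species, reference, beta))


def solve_mutation_fold(
    baseline: CalibrationResult,
    tissue: TissueSpec,
    species: SpeciesSpec,
    reference: SpeciesSpec,
    beta: float,
    p_target: float = 0.01,
) -> HypothesisSolution:
    """Fold-reduction of u restoring the target risk: u_mouse / u_required."""
    sp = _species_scale(baseline, tissue, species, reference, beta)
    unmit = lifetime_risk_exact(sp)
    if unmit < p_target:
        return HypothesisSolution(
            "mutation_rate", tissue.name, species.name, beta,
            value=1.0, achieved_risk=unmit, unmitigated_risk=unmit,
            no_change_needed=True,
        )
    u_req = solve_u_for_risk(sp.C, sp.k, sp.t, sp.M, p_target)
    achieved = lifetime_risk_exact(sp.with_(u=u_req))
    return HypothesisSolution(
        "mutation_rate", tissue.name, species.name, beta,
        value=baseline.u / u_req, achieved_risk=achieved, unmitigated_risk=unmit,
    )


def solve_added_drivers(
    baseline: CalibrationResult,
    tissue: TissueSpec,
    species: SpeciesSpec,
    reference: SpeciesSpec,
    beta: float,
    p_target: float = 0.01,
) -> HypothesisSolution:
    """Extra driver mutations ΔM = ln(q)/ln(x) - M_baseline.

    ``q`` is the per-cell target risk, ``x`` the per-driver probability
    at the baseline mutation rate and target-species k·t.  ΔM is
    real-valued: one recessive tumor suppressor gene contributes two
    drivers, a protooncogene one.
    """
    sp = _species_scale(baseline, tissue, species, reference, beta)
    unmit = lifetime_risk_exact(sp)
    if unmit < p_target:
        return HypothesisSolution(
            "added_drivers", tissue.name, species.name, beta,
            value=0.0, achieved_risk=unmit, unmitigated_risk=unmit,
            no_change_needed=True,
        )
    x = per_driver_prob(sp.u, sp.k, sp.t)
    if x >= 1.0:
        raise ValueError("per-driver probability is 1: no finite M suffices")
    q = per_cell_target(p_target, sp.C)
    M_req = math.log(q) / math.log(x)
    achieved = lifetime_risk_exact(sp.with_(M=M_req))
    return HypothesisSolution(
        "added_drivers", tissue.name, species.name, beta,
        value=M_req - baseline.M, achieved_risk=achieved, unmitigated_risk=unmit,
    )


def solve_policing_cancer(
    baseline: CalibrationResult,
    tissue: TissueSpec,
    species: SpeciesSpec,
    reference: SpeciesSpec,
    beta: float,
    p_target: float = 0.01,
) -> HypothesisSolution:
    """Escape probability 1-e_c = q / x^M for cancer-cell surveillance.

    The baseline (mouse) immune system is assumed to detect nothing
    (escape 1); the value is the largest escape probability consistent
    with the target risk at species scale.
    """
    sp = _species_scale(baseline, tissue, species, reference, beta)
    unmit = lifetime_risk_exact(sp)
    if unmit < p_target:
        return HypothesisSolution(
            "policing_cancer", tissue.name, species.name, beta,
            value=1.0, achieved_risk=unmit, unmitigated_risk=unmit,
            no_change_needed=True,
        )
    x = per_driver_prob(sp.u, sp.k, sp.t)
    q = per_cell_target(p_target, sp.C)
    # log-space: x^M underflows at whale scale
    escape = math.exp(math.log(q) - sp.M * math.log(x))
    escape = min(escape, 1.0)
    achieved = lifetime_risk_exact(sp.with_(e_c=1.0 - escape))
    return HypothesisSolution(
        "policing_cancer", tissue.name, species.name, beta,
        value=escape, achieved_risk=achieved, unmitigated_risk=unmit,
    )


def solve_policing_driver(
    baseline: CalibrationResult,
    tissue: TissueSpec,
    species: SpeciesSpec,
    reference: SpeciesSpec,
    beta: float,
    p_target: float = 0.01,
) -> HypothesisSolution:
    """Per-driver escape probability 1-e_d = q^(1/M) / x."""
    sp = _species_scale(baseline, tissue, species, reference, beta)
    unmit = lifetime_risk_exact(sp)
    if unmit < p_target:
        return HypothesisSolution(
            "policing_driver", tissue.name, species.name, beta,
            value=1.0, achieved_risk=unmit, unmitigated_risk=unmit,
            no_change_needed=True,
        )
    x = per_driver_prob(sp.u, sp.k, sp.t)
    q = per_cell_target(p_target, sp.C)
    escape = min(math.exp(math.log(q) / sp.M - math.log(x)), 1.0)
    achieved = lifetime_risk_exact(sp.with_(e_d=1.0 - escape))
    return HypothesisSolution(
        "policing_driver", tissue.name, species.name, beta,
        value=escape, achieved_risk=achieved, unmitigated_risk=unmit,
    )


def solve_all(
    baseline: CalibrationResult,
    tissue: TissueSpec,
    species: SpeciesSpec,
    reference: SpeciesSpec,
    beta: float,
    p_target: float = 0.01,
) -> dict[str, HypothesisSolution]:
    """All four hypothesis solutions for one tissue/species/scaling."""
    solvers = {
        "mutation_rate": solve_mutation_fold,
        "added_drivers": solve_added_drivers,
        "policing_cancer": solve_policing_cancer,
        "policing_driver": solve_policing_driver,
    }
    return {
        name: fn(baseline, tissue, species, reference, beta, p_target)
        for name, fn in solvers.items()
    }
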