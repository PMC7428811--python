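"""Allometric scaling rules mapping reference-species tissue parameters
across body sizes.

Whole-body basal metabolic rate scales with body mass roughly as W^0.7
(Kleiber's law); per unit mass this is a cellular metabolic rate of
W^-0.3.  The metabolic-rate (MR) hypothesis posits that the somatic
mutation accumulation rate u*k declines in proportion, which we model by
scaling the division rate k by a mass-ratio power ``beta`` (0 for no MR
effect, -0.15 intermediate, -0.3 full).  Tissue stem-cell counts scale in
proportion to body mass.  The human is the reference species: its
measured stem-cell counts and division rates anchor all scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "SpeciesSpec",
    "TissueSpec",
    "ScalingConfig",
    "cellular_metabolic_rate",
    "scale_cell_count",
    "scale_division_rate",
    "intraspecific_risk_exponent",
    "implied_exponent",
    "lifespan_from_size",
    "MOUSE",
    "HUMAN",
    "BLUE_WHALE",
    "COLORECTAL",
    "HEPATOCELLULAR",
    "ESOPHAGEAL",
]


@dataclass(frozen=True)
class SpeciesSpec:
    """A species' body mass (kg) and lifespan (years)."""

    name: str
    weight: float
    lifespan: float

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValueError(f"weight must be > 0, got {self.weight}")
        if not self.lifespan > 0:
            raise ValueError(f"lifespan must be > 0, got {self.lifespan}")


@dataclass(frozen=True)
class TissueSpec:
    """A cancer type's stem-cell compartment in the reference species.

    ``C_ref`` is the stem-cell count and ``k_ref`` the division rate
    (divisions/year), both as measured in the reference species (human).
    """

    name: str
    C_ref: float
    k_ref: float

    def __post_init__(self) -> None:
        if not self.C_ref >= 1:
            raise ValueError(f"C_ref must be >= 1, got {self.C_ref}")
        if not self.k_ref > 0:
            raise ValueError(f"k_ref must be > 0, got {self.k_ref}")


# Study species: house mouse, human, blue whale.
MOUSE = SpeciesSpec("mouse", weight=0.02, lifespan=2.0)
HUMAN = SpeciesSpec("human", weight=60.0, lifespan=80.0)
BLUE_WHALE = SpeciesSpec("blue_whale", weight=150_000.0, lifespan=90.0)

# Human tissue stem-cell compartments (Tomasetti & Vogelstein estimates).
COLORECTAL = TissueSpec("colorectal", C_ref=2e8, k_ref=73.0)
HEPATOCELLULAR = TissueSpec("hepatocellular", C_ref=3.01e8, k_ref=0.9125)
ESOPHAGEAL = TissueSpec("esophageal", C_ref=6.6528e6, k_ref=33.2)


@dataclass(frozen=True)
class ScalingConfig:
    """How division rate and lifespan change with size.

    ``beta`` is the MR exponent applied to k through the body-mass ratio
    (any beta <= 0; the study uses 0, -0.15 and -0.3).  Because tissue
    cell number is proportional to body mass, writing the scaling in
    terms of mass ratios or cell-count ratios is equivalent up to a
    constant absorbed in the reference rate.  ``lifespan_exponent`` is
    the exponent of the comparative lifespan/size relation T = T'*C^0.3.
    """

    beta: float = 0.0
    lifespan_exponent: float = 0.3
    reference_species: SpeciesSpec = field(default=HUMAN)

    def __post_init__(self) -> None:
        if not self.beta <= 0:
            raise ValueError(f"beta must be <= 0, got {self.beta}")


def cellular_metabolic_rate(W: float) -> float:
    """Relative cellular metabolic rate R = W^-0.3 at body mass W (kg)."""
    if not W > 0:
        raise ValueError(f"W must be > 0, got {W}")
    return W**-0.3


def scale_cell_count(
    tissue: TissueSpec, species: SpeciesSpec, reference: SpeciesSpec = HUMAN
) -> float:
    """Stem-cell count in ``species``: C_ref times the body-mass ratio."""
    return tissue.C_ref * (species.weight / reference.weight)


def scale_division_rate(
    tissue: TissueSpec,
    species: SpeciesSpec,
    reference: SpeciesSpec = HUMAN,
    beta: float = 0.0,
) -> float:
    """Division rate in ``species``: k_ref * (W/W_ref)^beta.

    beta = 0 leaves the measured rate unchanged; beta = -0.3 applies the
    full cellular metabolic-rate scaling (smaller animals divide faster).
    """
    if beta > 0:
        raise ValueError(f"beta must be <= 0, got {beta}")
    return tissue.k_ref * (species.weight / reference.weight) ** beta


def intraspecific_risk_exponent(M: float, beta: float = -0.3) -> float:
    """Exponent of C in the within-species risk p ∝ C^(1 + beta*M).

    Under MR scaling u*k ∝ C^beta at fixed lifespan, the small-p risk is
    C * (u'k'T)^M * C^(beta*M), so risk scales as C^(1+beta*M): rising
    with size for M = 2 (exponent 0.4 at beta = -0.3), nearly flat for
    M = 3 (0.1), and falling for M >= 4 (-0.2 at M = 4).
    """
    if not M >= 1:
        raise ValueError(f"M must be >= 1, got {M}")
    return 1.0 + beta * M


def implied_exponent(rate_ratio: float, W_small: float, W_large: float) -> float:
    """MR exponent implied by a small/large-species mutation-rate ratio.

    Solves rate_ratio = (W_large/W_small)^(-exponent): e.g. the observed
    3-fold mouse/human somatic mutation-rate ratio over masses
    0.02/60 kg gives -0.137, i.e. about -0.14.
    """
    if not rate_ratio > 0:
        raise ValueError(f"rate_ratio must be > 0, got {rate_ratio}")
    if not (W_small > 0 and W_large > 0):
        raise ValueError("masses must be > 0")
    if W_small == W_large:
        raise ValueError("masses must be distinct")
    return -math.log(rate_ratio) / math.log(W_large / W_small)


def lifespan_from_size(T_prime: float, C: float, exponent: float = 0.3) -> float:
    """Comparative lifespan/size relation T = T' * C^exponent.

    Composed with the full MR scaling u*k ∝ C^-0.3, the product u*k*T is
    size-independent, so the small-p risk grows linearly with C.
    """
    if not T_prime > 0:
        raise ValueError(f"T_prime must be > 0, got {T_prime}")
    if not C >= 1:
        raise ValueError(f"C must be >= 1, got {C}")
    return T_prime * C**exponent
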