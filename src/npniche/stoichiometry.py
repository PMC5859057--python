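"""Plot-level nutrient mass ratios and limitation classification.

Tissue N:P, N:K and K:P mass ratios (mg/mg) are used as proxies for the
relative availability of nitrogen, phosphorus and potassium to the plant
community.  Biomass production is classed as N-limited below N:P = 13.5,
P-limited above N:P = 16 and co-limited in between; potassium limitation
is indicated jointly by N:K > 2.1 and K:P < 3.4.  The analysis gradient
coordinate is log10(N:P).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

NP_LOWER = 13.5
NP_UPPER = 16.0
NK_THRESHOLD = 2.1
KP_THRESHOLD = 3.4


class NPClass(enum.Enum):
    N_LIMITED = "N_LIMITED"
    CO_LIMITED = "CO_LIMITED"
    P_LIMITED = "P_LIMITED"


@dataclass(frozen=True)
class NutrientRatios:
    """Mass ratios of one plot; ``np = nk * kp`` holds algebraically."""

    np: float
    nk: float
    kp: float
    log_np: float


def nutrient_ratios(plant_n: float, plant_p: float, plant_k: float) -> NutrientRatios:
    """Compute N:P, N:K, K:P and log10(N:P) from tissue concentrations (mg/g)."""
    if plant_n <= 0 or plant_p <= 0 or plant_k <= 0:
        raise ValueError(
            f"tissue concentrations must be positive, got "
            f"N={plant_n}, P={plant_p}, K={plant_k}"
        )
    np_ratio = plant_n / plant_p
    return NutrientRatios(
        np=np_ratio,
        nk=plant_n / plant_k,
        kp=plant_k / plant_p,
        log_np=float(np.log10(np_ratio)),
    )


def classify_np(np_ratio: float, lower: float = NP_LOWER, upper: float = NP_UPPER) -> NPClass:
    """Class the N:P ratio as N-, P- or co-limited.

    Boundary values exactly equal to a threshold fall in the co-limited
    class (the outer classes use strict inequalities).
    """
    if np_ratio <= 0:
        raise ValueError(f"N:P ratio must be positive, got {np_ratio}")
    if not lower < upper:
        raise ValueError(f"need lower < upper, got {lower} >= {upper}")
    if np_ratio < lower:
        return NPClass.N_LIMITED
    if np_ratio > upper:
        return NPClass.P_LIMITED
    return NPClass.CO_LIMITED


def classify_k(
    nk: float,
    kp: float,
    nk_threshold: float = NK_THRESHOLD,
    kp_threshold: float = KP_THRESHOLD,
) -> bool:
    """True iff potassium limits biomass production: N:K > 2.1 and K:P < 3.4."""
    if nk <= 0 or kp <= 0:
        raise ValueError(f"ratios must be positive, got nk={nk}, kp={kp}")
    return nk > nk_threshold and kp < kp_threshold


def log_np_gradient(np_ratios: np.ndarray) -> np.ndarray:
    """log10 gradient coordinate for an array of positive N:P ratios."""
    arr = np.asarray(np_ratios, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("all N:P ratios must be positive")
    return np.log10(arr)
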