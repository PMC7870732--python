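"""Lean body mass (LBM) estimators.

Three routes to LBM:

* ``lbm_james`` — the sex-specific James predictive equation from weight
  and height (the formula built into most PET/CT consoles):
  male  LBM = 1.10 W - 120 (W/H)^2,
  female LBM = 1.07 W - 148 (W/H)^2, W in kg, H in cm.
* ``lbm_lc`` — the limited-coverage CT route: whole-body fat mass is
  predicted from the limited-coverage fat volume by a linear model
  FM_WB = alpha + beta * FV_LC (FV_LC in LITRES), then LBM = W - FM_WB.
  The default coefficients (alpha = 2.892 kg, beta = 1.3337 kg/L) are the
  published development-cohort fit.
* ``lbm_wholebody_reference`` — the reference standard, W minus the fat
  mass measured on whole-body CT.

``fit_fat_model`` refits the FV_LC -> FM_WB line on a user cohort by
ordinary least squares.

Note on units: the linear model is only dimensionally consistent with
FV_LC in litres (beta is kg/L); volumetry results in mL must be divided
by 1000 (``FatVolumetryResult.fat_volume_l`` does this).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import DomainError, FitError

_JAMES_COEFFS = {"male": (1.10, 120.0), "female": (1.07, 148.0)}


@dataclass(frozen=True)
class Subject:
    sex: str  # "male" | "female"
    weight_kg: float
    height_cm: float

    def __post_init__(self) -> None:
        if self.sex not in _JAMES_COEFFS:
            raise DomainError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.weight_kg <= 0:
            raise DomainError(f"weight must be positive, got {self.weight_kg}")
        if self.height_cm <= 0:
            raise DomainError(f"height must be positive, got {self.height_cm}")


@dataclass(frozen=True)
class LinearFatModel:
    """FM_WB (kg) = alpha_kg + beta_kg_per_l * FV_LC (L)."""

    alpha_kg: float = 2.892
    beta_kg_per_l: float = 1.3337
    r: Optional[float] = None
    n: Optional[int] = None
    provenance: str = "development-cohort coefficients"

    def predict_fm_wb(self, fv_lc_l: float) -> float:
        if fv_lc_l < 0:
            raise DomainError(f"fat volume must be non-negative, got {fv_lc_l}")
        return self.alpha_kg + self.beta_kg_per_l * fv_lc_l


#: the published development-cohort coefficients
DEFAULT_FAT_MODEL = LinearFatModel()


@dataclass(frozen=True)
class LBMEstimate:
    method: str  # james_pe | limited_coverage | whole_body_reference
    lbm_kg: float
    inputs: dict = field(default_factory=dict)
    flagged: bool = False  # True when the value is outside (0, weight]


def lbm_james(s: Subject) -> LBMEstimate:
    """James predictive equation.

    A non-positive or above-weight result (possible in extreme body habitus,
    where this equation is known to misbehave) is returned flagged rather
    than clamped.
    """
    a, b = _JAMES_COEFFS[s.sex]
    lbm = a * s.weight_kg - b * (s.weight_kg / s.height_cm) ** 2
    flagged = not (0 < lbm <= s.weight_kg)
    if flagged:
        warnings.warn(
            f"James equation gave implausible LBM {lbm:.2f} kg for "
            f"W={s.weight_kg} kg, H={s.height_cm} cm",
            stacklevel=2,
        )
    return LBMEstimate(
        method="james_pe",
        lbm_kg=lbm,
        inputs={"sex": s.sex, "weight_kg": s.weight_kg, "height_cm": s.height_cm},
        flagged=flagged,
    )


def lbm_lc(
    weight_kg: float,
    fv_lc_l: float,
    model: LinearFatModel = DEFAULT_FAT_MODEL,
) -> LBMEstimate:
    """LBM from limited-coverage fat volume: W - (alpha + beta * FV_LC)."""
    if weight_kg <= 0:
        raise DomainError(f"weight must be positive, got {weight_kg}")
    fm_wb = model.predict_fm_wb(fv_lc_l)
    lbm = weight_kg - fm_wb
    flagged = lbm <= 0
    if flagged:
        warnings.warn(
            f"limited-coverage model gave non-positive LBM {lbm:.2f} kg "
            f"(W={weight_kg}, predicted FM_WB={fm_wb:.2f})",
            stacklevel=2,
        )
    return LBMEstimate(
        method="limited_coverage",
        lbm_kg=lbm,
        inputs={
            "weight_kg": weight_kg,
            "fv_lc_l": fv_lc_l,
            "predicted_fm_wb_kg": fm_wb,
            "alpha_kg": model.alpha_kg,
            "beta_kg_per_l": model.beta_kg_per_l,
        },
        flagged=flagged,
    )


def lbm_wholebody_reference(weight_kg: float, fm_wb_kg: float) -> LBMEstimate:
    """Reference standard: LBM = W - FM_WB, fat mass measured on whole-body CT."""
    if weight_kg <= 0:
        raise DomainError(f"weight must be positive, got {weight_kg}")
    if not 0 <= fm_wb_kg < weight_kg:
        raise DomainError(
            f"fat mass must lie in [0, weight), got FM={fm_wb_kg} for W={weight_kg}"
        )
    return LBMEstimate(
        method="whole_body_reference",
        lbm_kg=weight_kg - fm_wb_kg,
        inputs={"weight_kg": weight_kg, "fm_wb_kg": fm_wb_kg},
    )


def fit_fat_model(
    pairs: Sequence[tuple[float, float]] | np.ndarray,
) -> LinearFatModel:
    """Ordinary least squares of FM_WB (kg) on FV_LC (L).

    Returns the fitted intercept/slope together with the Pearson r of the
    fit and the sample size; the fitted line passes through the sample
    means to numerical precision.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise FitError("pairs must be an (n, 2) array of (fv_lc_l, fm_wb_kg)")
    if arr.shape[0] < 3:
        raise FitError(f"need at least 3 pairs, got {arr.shape[0]}")
    fv, fm = arr[:, 0], arr[:, 1]
    if np.ptp(fv) == 0:
        raise FitError("FV_LC values are all equal; regression is degenerate")
    res = stats.linregress(fv, fm)
    return LinearFatModel(
        alpha_kg=float(res.intercept),
        beta_kg_per_l=float(res.slope),
        r=float(res.rvalue),
        n=int(arr.shape[0]),
        provenance="user fit",
    )
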