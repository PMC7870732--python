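"""Synthetic inputs with known ground truth.

Three generators make every other module testable without any image
download:

* ``make_ct_phantom`` — a nested-ellipsoid CT phantom (fat shell over a
  lean core in air) whose fat volume is known both analytically
  (4/3 pi (abc_outer - abc_inner)) and exactly by voxel count.
* ``make_pet_phantom`` — a uniform-background PET volume with a spherical
  lesion and a designated liver region.
* ``make_cohort`` — a body-composition cohort with a linear
  FV_LC -> FM_WB relationship plus Gaussian noise.
* ``make_percist_cohort`` — paired-timepoint lesion SUL_peak values under
  two LBM algorithms whose between-timepoint LBM changes follow a
  categorical mixture of the three clinically observed mechanisms
  (LBM loss, LBM gain, weight gain with fat-mass loss).

All generators are deterministic for a fixed seed and spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .ct_io import ImageVolume
from .exceptions import SpecError
from .percist import classify_change, rescale_sul_peak

# --- helpers ----------------------------------------------------------------


def _truncnorm(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


# --- CT phantom -------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Nested-ellipsoid body phantom.

    Semi-axes are in mm along the (slice, row, col) axes.  Tissue HU are
    means with truncated-Gaussian noise; the fat noise is truncated to the
    adipose window [-190, -30] so intensity noise never moves a fat voxel
    out of the segmentation window (geometry error and intensity error stay
    separable in tests).
    """

    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    outer_semi_axes_mm: tuple[float, float, float] = (200.0, 100.0, 80.0)
    inner_semi_axes_mm: tuple[float, float, float] = (180.0, 80.0, 60.0)
    margin_mm: float = 8.0
    #: sub-voxel displacement of the ellipsoid center, mm; averaging the
    #: discretization error over several offsets removes the lattice-alignment
    #: artefacts a perfectly centred ellipsoid exhibits at even spacings
    center_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    fat_hu: tuple[float, float] = (-100.0, 20.0)  # mean, sd
    lean_hu: tuple[float, float] = (40.0, 10.0)
    air_hu: tuple[float, float] = (-1000.0, 0.0)
    couch: bool = False  # detached fat-density slab under the body
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(i < o for i, o in zip(self.inner_semi_axes_mm, self.outer_semi_axes_mm)):
            raise SpecError("inner ellipsoid must be strictly inside the outer one")
        if any(s <= 0 for s in self.spacing_mm):
            raise SpecError("spacing must be positive")

    @property
    def analytic_fat_volume_ml(self) -> float:
        ao, bo, co = self.outer_semi_axes_mm
        ai, bi, ci = self.inner_semi_axes_mm
        return 4.0 / 3.0 * np.pi * (ao * bo * co - ai * bi * ci) / 1000.0


@dataclass(frozen=True)
class PhantomTruth:
    analytic_fat_volume_ml: float
    voxel_fat_count: int
    voxel_fat_volume_ml: float
    fat_mask: np.ndarray
    body_mask: np.ndarray


def make_ct_phantom(spec: PhantomSpec) -> tuple[ImageVolume, PhantomTruth]:
    """Build the phantom; voxel membership is center-in-shape."""
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    semi = np.asarray(spec.outer_semi_axes_mm, dtype=float)
    extent = semi + spec.margin_mm
    shape = tuple(int(np.ceil(2 * e / s)) + 1 for e, s in zip(extent, spacing))
    if spec.couch:
        shape = (shape[0], shape[1] + int(np.ceil(30.0 / spacing[1])), shape[2])

    center = (np.asarray(shape) - 1) / 2.0 * spacing + np.asarray(spec.center_offset_mm)
    zc = (np.arange(shape[0]) * spacing[0] - center[0])[:, None, None]
    yc = (np.arange(shape[1]) * spacing[1] - center[1])[None, :, None]
    xc = (np.arange(shape[2]) * spacing[2] - center[2])[None, None, :]

    def _inside(axes):
        a, b, c = axes
        return (zc / a) ** 2 + (yc / b) ** 2 + (xc / c) ** 2 <= 1.0

    outer = _inside(spec.outer_semi_axes_mm)
    inner = _inside(spec.inner_semi_axes_mm)
    if outer[0].any() or outer[-1].any():
        raise SpecError("outer ellipsoid touches the grid boundary; enlarge the margin")
    shell = outer & ~inner

    vox = np.empty(shape, dtype=float)
    vox[...] = _truncnorm(rng, *spec.air_hu, -1024.0, -900.0, shape) if spec.air_hu[1] else spec.air_hu[0]
    vox[shell] = _truncnorm(rng, *spec.fat_hu, -190.0, -30.0, int(shell.sum()))
    vox[inner] = _truncnorm(rng, *spec.lean_hu, 0.0, 100.0, int(inner.sum()))

    body = outer.copy()
    if spec.couch:
        # detached fat-density slab, separated from the body by >= 2 air rows
        y0 = shape[1] - int(np.ceil(20.0 / spacing[1]))
        vox[:, y0:, :] = -120.0
        body_gap = outer[:, y0 - 2 :, :].any()
        if body_gap:
            raise SpecError("couch slab overlaps the body; enlarge the margin")

    voxel_ml = float(np.prod(spacing)) / 1000.0
    truth = PhantomTruth(
        analytic_fat_volume_ml=spec.analytic_fat_volume_ml,
        voxel_fat_count=int(shell.sum()),
        voxel_fat_volume_ml=int(shell.sum()) * voxel_ml,
        fat_mask=shell,
        body_mask=body,
    )
    return ImageVolume(vox, tuple(spacing), modality="CT"), truth


# --- PET phantom ------------------------------------------------------------


@dataclass(frozen=True)
class PETPhantomSpec:
    shape: tuple[int, int, int] = (40, 60, 60)
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    background_sul: float = 1.0
    lesion_center_mm: tuple[float, float, float] = (60.0, 60.0, 60.0)
    lesion_diameter_mm: float = 30.0
    lesion_sul: float = 8.0
    liver_center_mm: tuple[float, float, float] = (60.0, 120.0, 120.0)
    liver_diameter_mm: float = 40.0
    liver_sul_mean: float = 2.0
    liver_sul_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_sul <= self.background_sul:
            raise SpecError("lesion SUL must exceed background SUL")
        d = np.linalg.norm(np.subtract(self.lesion_center_mm, self.liver_center_mm))
        if d < (self.lesion_diameter_mm + self.liver_diameter_mm) / 2.0:
            raise SpecError("lesion and liver regions overlap")


@dataclass(frozen=True)
class PETPhantomTruth:
    lesion_mask: np.ndarray
    liver_mask: np.ndarray
    lesion_sul: float
    liver_sul_mean: float
    liver_sul_sd: float


def make_pet_phantom(spec: PETPhantomSpec) -> tuple[ImageVolume, PETPhantomTruth]:
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    coords = [np.arange(n) * s for n, s in zip(spec.shape, spacing)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")

    def _sphere(center, diameter):
        cz, cy, cx = center
        return (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= (diameter / 2.0) ** 2

    lesion = _sphere(spec.lesion_center_mm, spec.lesion_diameter_mm)
    liver = _sphere(spec.liver_center_mm, spec.liver_diameter_mm)
    if not lesion.any():
        raise SpecError("lesion sphere contains no voxel centers")

    vox = np.full(spec.shape, float(spec.background_sul))
    vox[lesion] = spec.lesion_sul
    if spec.liver_sul_sd > 0:
        vox[liver] = rng.normal(spec.liver_sul_mean, spec.liver_sul_sd, int(liver.sum()))
    else:
        vox[liver] = spec.liver_sul_mean

    truth = PETPhantomTruth(
        lesion_mask=lesion,
        liver_mask=liver,
        lesion_sul=spec.lesion_sul,
        liver_sul_mean=spec.liver_sul_mean,
        liver_sul_sd=spec.liver_sul_sd,
    )
    return ImageVolume(vox, tuple(spacing), modality="PET"), truth


# --- regression cohort ------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Body-composition cohort emulating a PET/CT referral population.

    Defaults reproduce the development-cohort conditions: n = 199 with a
    93/199 female fraction; sex-specific weight/height distributions
    (men 63.5 +/- 15.1 kg, 166.6 +/- 6.7 cm; women 56.2 +/- 9.2 kg,
    156.3 +/- 5.9 cm); limited-coverage fat volume lognormal with mean
    11.084 L; FM_WB = alpha + beta * FV_LC + N(0, noise_sd).  The noise SD
    of 1.9 kg together with the FV spread gives a sample Pearson r near
    0.977.
    """

    n: int = 199
    female_fraction: float = 93.0 / 199.0
    male_weight: tuple[float, float] = (63.5, 15.1)  # mean, sd (kg)
    female_weight: tuple[float, float] = (56.2, 9.2)
    male_height: tuple[float, float] = (166.6, 6.7)  # mean, sd (cm)
    female_height: tuple[float, float] = (156.3, 5.9)
    fv_lc_mean_l: float = 11.084
    fv_lc_sigma_log: float = 0.55
    alpha_kg: float = 2.892
    beta_kg_per_l: float = 1.3337
    noise_sd_kg: float = 1.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise SpecError("cohort needs n >= 3")
        if self.noise_sd_kg < 0:
            raise SpecError("noise_sd must be non-negative")
        if not 0 <= self.female_fraction <= 1:
            raise SpecError("female_fraction must be in [0, 1]")


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Columns: sex, weight_kg, height_cm, fv_lc_l, fm_wb_kg, lbm_wb_kg.

    FM_WB is constrained to (0, W) by resampling the offending rows."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    female = rng.random(n) < spec.female_fraction
    w_mean = np.where(female, spec.female_weight[0], spec.male_weight[0])
    w_sd = np.where(female, spec.female_weight[1], spec.male_weight[1])
    h_mean = np.where(female, spec.female_height[0], spec.male_height[0])
    h_sd = np.where(female, spec.female_height[1], spec.male_height[1])
    weight = np.clip(rng.normal(w_mean, w_sd), 30.0, None)
    height = np.clip(rng.normal(h_mean, h_sd), 120.0, None)

    sigma = spec.fv_lc_sigma_log
    mu_log = np.log(spec.fv_lc_mean_l) - sigma**2 / 2.0

    fv = np.exp(rng.normal(mu_log, sigma, n))
    fm = spec.alpha_kg + spec.beta_kg_per_l * fv + rng.normal(0.0, spec.noise_sd_kg, n)
    bad = (fm <= 0) | (fm >= weight)
    for _ in range(1000):
        if not bad.any():
            break
        k = int(bad.sum())
        fv[bad] = np.exp(rng.normal(mu_log, sigma, k))
        fm[bad] = spec.alpha_kg + spec.beta_kg_per_l * fv[bad] + rng.normal(0.0, spec.noise_sd_kg, k)
        bad = (fm <= 0) | (fm >= weight)
    else:
        raise SpecError("could not satisfy 0 < FM_WB < W after bounded resampling")

    return pd.DataFrame(
        {
            "sex": np.where(female, "female", "male"),
            "weight_kg": weight,
            "height_cm": height,
            "fv_lc_l": fv,
            "fm_wb_kg": fm,
            "lbm_wb_kg": weight - fm,
        }
    )


# --- paired-timepoint PERCIST cohort ----------------------------------------

#: percent LBM change (mean, sd) per mechanism, for the PE and LC algorithms:
#: lbm_loss - LBM falls after treatment (PE overestimates the loss);
#: lbm_gain - LBM rises (PE overestimates the gain);
#: divergent - weight (hence PE LBM) rises while CT fat-derived LBM falls.
LBM_CHANGE_MECHANISMS = {
    "lbm_loss": {"pe": (-7.2, 2.2), "lc": (-2.8, 1.8)},
    "lbm_gain": {"pe": (5.7, 1.5), "lc": (1.8, 1.7)},
    "divergent": {"pe": (1.8, 1.0), "lc": (-4.8, 1.9)},
}


@dataclass(frozen=True)
class PercistCohortSpec:
    """Paired-timepoint lesion cohort under two LBM algorithms.

    Baseline SUL_peak is lognormal with a floor of 4.0 g/mL: measurable
    target lesions must exceed about 1.5 x liver mean + 2 SD (~3.6 for a
    typical 2.0 +/- 0.3 liver), and the floor also keeps the 0.8 SUL
    minimal-absolute-change gate from ever masking a >= 30% change, so any
    simulated discordance is purely threshold-driven.  The true percent
    change mixes a response arm (-39.78 +/- 18.52 %) and a progression arm
    (+34.03 +/- 19.18 %).  LBM changes follow the mechanism mixture in
    ``LBM_CHANGE_MECHANISMS`` (draws truncated at +/- 3 SD);
    ``lbm_change_scale = 0`` freezes LBM between timepoints.
    """

    n: int = 241
    baseline_sul_median: float = 6.0
    baseline_sul_sigma_log: float = 0.35
    baseline_sul_floor: float = 4.0
    p_decrease: float = 0.6
    decrease_pct: tuple[float, float] = (-39.78, 18.52)  # mean, sd (%)
    increase_pct: tuple[float, float] = (34.03, 19.18)
    lbm_pe_baseline: tuple[float, float] = (47.01, 8.38)  # mean, sd (kg)
    lc_to_pe_ratio: tuple[float, float] = (42.26 / 47.01, 0.03)
    mechanism_weights: tuple[float, float, float] = (16 / 27, 5 / 27, 6 / 27)
    lbm_change_scale: float = 1.0
    threshold_pct: float = 30.0
    min_abs_change: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SpecError("cohort needs n >= 1")
        if self.baseline_sul_floor <= 0:
            raise SpecError("baseline SUL floor must be positive")
        if abs(sum(self.mechanism_weights) - 1.0) > 1e-9:
            raise SpecError("mechanism weights must sum to 1")
        if self.lbm_change_scale < 0:
            raise SpecError("lbm_change_scale must be non-negative")


def reachable_discordance_band(spec: PercistCohortSpec) -> tuple[float, float]:
    """Bounds (lo, hi) on |PE percent change| outside which PE/LC
    discordance is algebraically impossible under the spec's truncated
    LBM-change draws.

    The LC change is (1 + p/100) * f - 1 with ratio factor
    f = (1 + dLC) / (1 + dPE); discordance requires the LC change to sit on
    the other side of the threshold, so |p| must lie between
    threshold / f_max and threshold / f_min (in 1+p/100 terms).
    """
    s = spec.lbm_change_scale
    fs = []
    for mech in LBM_CHANGE_MECHANISMS.values():
        for sign_pe in (-3, 3):
            for sign_lc in (-3, 3):
                d_pe = s * (mech["pe"][0] + sign_pe * mech["pe"][1]) / 100.0
                d_lc = s * (mech["lc"][0] + sign_lc * mech["lc"][1]) / 100.0
                fs.append((1 + d_lc) / (1 + d_pe))
    f_min, f_max = min(fs), max(fs)
    t = 1.0 + spec.threshold_pct / 100.0  # works symmetrically on the 1+p scale
    lo = 100.0 * (t / f_max - 1.0)
    hi = 100.0 * (t / f_min - 1.0)
    return min(lo, hi), max(lo, hi)


def make_percist_cohort(spec: PercistCohortSpec) -> pd.DataFrame:
    """One row per patient: SUL_peak at both timepoints under both LBM
    algorithms, the LBM values used, the mechanism, and the two response
    classes."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    base_pe = spec.baseline_sul_median * np.exp(
        rng.normal(0.0, spec.baseline_sul_sigma_log, n)
    )
    base_pe = np.maximum(base_pe, spec.baseline_sul_floor)

    decrease = rng.random(n) < spec.p_decrease
    pct = np.where(
        decrease,
        _truncnorm(rng, *spec.decrease_pct, -95.0, 200.0, n),
        _truncnorm(rng, *spec.increase_pct, -95.0, 200.0, n),
    )
    fu_pe = base_pe * (1.0 + pct / 100.0)

    lbm_pe_base = _truncnorm(rng, *spec.lbm_pe_baseline, 30.0, 75.0, n)
    ratio0 = _truncnorm(rng, *spec.lc_to_pe_ratio, 0.80, 1.00, n)
    lbm_lc_base = lbm_pe_base * ratio0

    names = list(LBM_CHANGE_MECHANISMS)
    mech_idx = rng.choice(len(names), size=n, p=spec.mechanism_weights)
    d_pe = np.empty(n)
    d_lc = np.empty(n)
    for i, name in enumerate(names):
        sel = mech_idx == i
        k = int(sel.sum())
        if not k:
            continue
        m_pe, s_pe = LBM_CHANGE_MECHANISMS[name]["pe"]
        m_lc, s_lc = LBM_CHANGE_MECHANISMS[name]["lc"]
        d_pe[sel] = _truncnorm(rng, m_pe, s_pe, m_pe - 3 * s_pe, m_pe + 3 * s_pe, k)
        d_lc[sel] = _truncnorm(rng, m_lc, s_lc, m_lc - 3 * s_lc, m_lc + 3 * s_lc, k)
    d_pe *= spec.lbm_change_scale / 100.0
    d_lc *= spec.lbm_change_scale / 100.0

    lbm_pe_fu = lbm_pe_base * (1.0 + d_pe)
    lbm_lc_fu = lbm_lc_base * (1.0 + d_lc)

    base_lc = np.array(
        [rescale_sul_peak(s, p, l) for s, p, l in zip(base_pe, lbm_pe_base, lbm_lc_base)]
    )
    fu_lc = np.array(
        [rescale_sul_peak(s, p, l) for s, p, l in zip(fu_pe, lbm_pe_fu, lbm_lc_fu)]
    )

    rows = []
    for i in range(n):
        res_pe = classify_change(
            base_pe[i], fu_pe[i], spec.threshold_pct, spec.min_abs_change, "PE"
        )
        res_lc = classify_change(
            base_lc[i], fu_lc[i], spec.threshold_pct, spec.min_abs_change, "LC"
        )
        rows.append(
            {
                "patient_id": f"P{i:04d}",
                "mechanism": names[mech_idx[i]],
                "baseline_sul_pe": base_pe[i],
                "followup_sul_pe": fu_pe[i],
                "pct_change_pe": res_pe.percent_change,
                "baseline_sul_lc": base_lc[i],
                "followup_sul_lc": fu_lc[i],
                "pct_change_lc": res_lc.percent_change,
                "lbm_pe_base": lbm_pe_base[i],
                "lbm_pe_fu": lbm_pe_fu[i],
                "lbm_lc_base": lbm_lc_base[i],
                "lbm_lc_fu": lbm_lc_fu[i],
                "class_pe": res_pe.response.name,
                "class_lc": res_lc.response.name,
            }
        )
    return pd.DataFrame(rows)
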