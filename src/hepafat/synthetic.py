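"""Synthetic cohorts, phantoms and slice predictions.

The simulators reproduce the statistical structure the analysis assumes so
every downstream stage is testable without patient data:

* ``simulate_cohort`` draws a latent true non-contrast liver attenuation per
  subject from a two-component (steatotic / non-steatotic) Gaussian mixture,
  produces the paired post-contrast value by inverting the phase's
  registered correction model, and places phase-specific Gaussian residual
  noise on the non-contrast side of each pair — the response variable of
  the correction regression.
* ``simulate_phantom`` builds an ellipsoid liver/spleen phantom on a 3D HU
  grid with optional axial cropping, emulating scans with partial organ
  coverage.
* ``simulate_slice_predictions`` emulates a slice-level phase classifier
  with a configurable per-slice accuracy, for exercising the scan-level
  vote.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .attenuation import LIVER_LABEL, SPLEEN_LABEL, PhantomVolume
from .correction import (
    DERIVATION_RMSE_HU,
    POST_CONTRAST_PHASES,
    PUBLISHED_MODELS,
    CorrectionModel,
    correct,
    invert,
)
from .phase_id import PHASES, SlicePrediction

__all__ = [
    "CohortSimConfig",
    "PhantomConfig",
    "Ellipsoid",
    "ConfidenceParams",
    "paired_from_model",
    "simulate_cohort",
    "simulate_phantom",
    "simulate_slice_predictions",
]

# Latent non-contrast draws are kept this many HU inside the invertible
# interval (alpha, alpha+beta) of every requested phase model.
_DOMAIN_MARGIN_HU = 5.0
_MAX_RESAMPLE_ROUNDS = 1000

# Per-phase spleen means follow a single worked multi-phase example
# (non-contrast 38.2, arterial 86.0, venous 99.3, delayed 73.1 HU);
# no population spleen distributions are available.
_DEFAULT_SPLEEN_MEANS = {
    "non-contrast": 38.2,
    "arterial": 86.0,
    "venous": 99.3,
    "delayed": 73.1,
}


class CohortSimConfig(BaseModel):
    """Study conditions for the simulated cohort.

    Defaults mirror the derivation setting: 7.6% moderate-to-severe
    steatosis prevalence, class means 28.8 (steatotic) vs 57.9 HU
    (non-steatotic) on non-contrast scans, and residual noise per
    post-contrast phase equal to each correction equation's derivation
    RMSE (4.7 / 7.4 / 4.9 HU).
    """

    n_subjects: int = Field(gt=0)
    prevalence_moderate: float = Field(default=0.076, ge=0.0, le=1.0)
    mean_L_normal: float = 57.9
    sd_L_normal: float = Field(default=6.0, gt=0.0)
    mean_L_steatotic: float = 28.8
    sd_L_steatotic: float = Field(default=6.0, gt=0.0)
    spleen_mean_by_phase: dict = Field(default_factory=lambda: dict(_DEFAULT_SPLEEN_MEANS))
    spleen_sd: float = Field(default=6.0, gt=0.0)
    residual_sd_by_phase: dict = Field(default_factory=lambda: dict(DERIVATION_RMSE_HU))
    phases: tuple = tuple(PHASES)
    seed: int = 0

    @model_validator(mode="after")
    def _check_phases(self) -> "CohortSimConfig":
        unknown = set(self.phases) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phases {sorted(unknown)}; valid: {PHASES}")
        for phase in self.phases:
            if phase == "non-contrast":
                continue
            if phase not in self.residual_sd_by_phase:
                raise ValueError(f"phase {phase!r} has no residual SD configured")
            if self.residual_sd_by_phase[phase] < 0:
                raise ValueError(f"residual SD for {phase!r} must be >= 0")
            if phase not in self.spleen_mean_by_phase:
                raise ValueError(f"phase {phase!r} has no spleen mean configured")
        return self


def _latent_bounds(
    phases: Sequence[str], models: Mapping[str, CorrectionModel]
) -> tuple[float, float]:
    lo = _DOMAIN_MARGIN_HU
    hi = np.inf
    for phase in phases:
        if phase == "non-contrast":
            continue
        hi = min(hi, models[phase].saturation - _DOMAIN_MARGIN_HU)
    if hi <= lo:
        raise ValueError("invertible latent interval is empty for the requested phases")
    return lo, hi


def _draw_truncated_mixture(
    rng: np.random.Generator, config: CohortSimConfig, lo: float, hi: float
) -> np.ndarray:
    """Mixture draw with out-of-domain values resampled (bounded rounds)."""
    n = config.n_subjects
    steatotic = rng.random(n) < config.prevalence_moderate
    latent = np.where(
        steatotic,
        rng.normal(config.mean_L_steatotic, config.sd_L_steatotic, n),
        rng.normal(config.mean_L_normal, config.sd_L_normal, n),
    )
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        bad = (latent <= lo) | (latent >= hi)
        if not bad.any():
            return latent, steatotic
        k = int(bad.sum())
        redraw = np.where(
            steatotic[bad],
            rng.normal(config.mean_L_steatotic, config.sd_L_steatotic, k),
            rng.normal(config.mean_L_normal, config.sd_L_normal, k),
        )
        latent[bad] = redraw
    raise RuntimeError(
        f"could not draw latent attenuation inside ({lo:.1f}, {hi:.1f}) HU "
        f"after {_MAX_RESAMPLE_ROUNDS} resampling rounds; check means/SDs"
    )


def simulate_cohort(
    config: CohortSimConfig,
    models: Mapping[str, CorrectionModel] = PUBLISHED_MODELS,
) -> pd.DataFrame:
    """Simulate per-subject, per-phase attenuation records.

    Output is a long table with one row per subject per requested phase:

    - ``liver_hu``: latent non-contrast value on non-contrast rows, the
      post-contrast value L' (exact model inverse of the latent) on
      post-contrast rows;
    - ``nc_observed_hu``: the phase's observed non-contrast pairing,
      ``correct(L') + N(0, sigma_phase)`` (NaN on non-contrast rows, where
      ``liver_hu`` is already the non-contrast measurement);
    - ``latent_liver_nc_hu`` and ``steatosis_truth`` (latent < 40 HU) carry
      the ground truth.
    """
    for phase in config.phases:
        if phase != "non-contrast" and phase not in models:
            raise KeyError(f"no correction model registered for phase {phase!r}")
    rng = np.random.default_rng(config.seed)
    lo, hi = _latent_bounds(config.phases, models)
    latent, component = _draw_truncated_mixture(rng, config, lo, hi)
    truth = latent < 40.0

    rows = []
    for phase in config.phases:
        spleen = rng.normal(config.spleen_mean_by_phase[phase], config.spleen_sd, config.n_subjects)
        if phase == "non-contrast":
            liver = latent
            nc_observed = np.full(config.n_subjects, np.nan)
        else:
            model = models[phase]
            liver = invert(latent, model)
            noise = rng.normal(0.0, config.residual_sd_by_phase[phase], config.n_subjects)
            nc_observed = correct(liver, model) + noise
        for i in range(config.n_subjects):
            rows.append(
                {
                    "subject_id": f"S{i:05d}",
                    "phase": phase,
                    "liver_hu": liver[i],
                    "spleen_hu": spleen[i],
                    "nc_observed_hu": nc_observed[i],
                    "latent_liver_nc_hu": latent[i],
                    "steatosis_truth": bool(truth[i]),
                    "mixture_component": "steatotic" if component[i] else "normal",
                }
            )
    return pd.DataFrame(rows)


def paired_from_model(
    model: CorrectionModel,
    n: int,
    noise_sd: float,
    rng: np.random.Generator,
    latent_lo: float = 10.0,
    latent_hi: float = 70.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate paired (post-contrast, non-contrast) HU from a model.

    Latent non-contrast values are uniform on ``(latent_lo, latent_hi)``
    (which must sit inside the model's invertible interval); the
    post-contrast value is the exact model inverse and Gaussian noise of
    SD ``noise_sd`` lands on the non-contrast side — the regression's
    response variable.  This is the simulate-and-refit protocol used to
    check coefficient recovery.
    """
    if not (model.alpha < latent_lo < latent_hi < model.saturation):
        raise ValueError(
            f"latent range ({latent_lo}, {latent_hi}) must lie inside "
            f"({model.alpha}, {model.saturation})"
        )
    latent = rng.uniform(latent_lo, latent_hi, n)
    l_post = invert(latent, model)
    l_nc = latent + rng.normal(0.0, noise_sd, n)
    return l_post, l_nc


class Ellipsoid(BaseModel):
    """Axis-aligned ellipsoid in voxel units."""

    center: tuple
    semiaxes: tuple

    @model_validator(mode="after")
    def _check(self) -> "Ellipsoid":
        if len(self.center) != 3 or len(self.semiaxes) != 3:
            raise ValueError("center and semiaxes must have three components")
        if any(a <= 0 for a in self.semiaxes):
            raise ValueError("semiaxes must be positive")
        return self


class PhantomConfig(BaseModel):
    """Geometry and intensity parameters of the two-organ phantom."""

    grid_shape: tuple = (48, 48, 32)
    voxel_spacing: tuple = (1.5, 1.5, 2.5)
    liver_ellipsoid: Ellipsoid = Ellipsoid(center=(16.0, 24.0, 15.0), semiaxes=(11.0, 14.0, 10.0))
    spleen_ellipsoid: Ellipsoid = Ellipsoid(center=(38.0, 24.0, 15.0), semiaxes=(6.0, 8.0, 7.0))
    liver_hu: float = 55.7
    spleen_hu: float = 38.2
    texture_sd: float = Field(default=8.0, ge=0.0)
    background_hu: float = -1000.0
    crop_fraction: float = Field(default=0.0, ge=0.0, lt=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_geometry(self) -> "PhantomConfig":
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be three positive mm values")
        for name, ell in (("liver", self.liver_ellipsoid), ("spleen", self.spleen_ellipsoid)):
            for c, a, n in zip(ell.center, ell.semiaxes, self.grid_shape):
                if c - a < 0 or c + a > n - 1:
                    raise ValueError(f"{name} ellipsoid exceeds grid before cropping")
        return self


def _ellipsoid_mask(shape: tuple, ell: Ellipsoid) -> np.ndarray:
    grids = np.ogrid[[slice(0, int(n)) for n in shape]]
    acc = np.zeros(tuple(int(n) for n in shape), dtype=float)
    for g, c, a in zip(grids, ell.center, ell.semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def simulate_phantom(config: PhantomConfig) -> PhantomVolume:
    """Build the phantom volume: organs over air, optional axial crop.

    Cropping removes ``floor(crop_fraction * nz)`` slices from the top
    (high-z) end of both image and mask, emulating a field of view that
    truncates the organs.
    """
    shape = tuple(int(n) for n in config.grid_shape)
    liver = _ellipsoid_mask(shape, config.liver_ellipsoid)
    spleen = _ellipsoid_mask(shape, config.spleen_ellipsoid)
    if (liver & spleen).any():
        raise ValueError("liver and spleen ellipsoids overlap")

    rng = np.random.default_rng(config.seed)
    image = np.full(shape, config.background_hu, dtype=float)
    mask = np.zeros(shape, dtype=np.int16)
    for organ_mask, hu, label in (
        (liver, config.liver_hu, LIVER_LABEL),
        (spleen, config.spleen_hu, SPLEEN_LABEL),
    ):
        n = int(organ_mask.sum())
        values = np.full(n, hu) if config.texture_sd == 0 else rng.normal(hu, config.texture_sd, n)
        image[organ_mask] = values
        mask[organ_mask] = label

    n_crop = int(np.floor(config.crop_fraction * shape[2]))
    if n_crop:
        image = image[:, :, : shape[2] - n_crop]
        mask = mask[:, :, : shape[2] - n_crop]
    return PhantomVolume(image=image, mask=mask, spacing=config.voxel_spacing)


class ConfidenceParams(BaseModel):
    """Beta-distribution parameters for slice confidences.

    Correctly labeled slices draw from Beta(correct_a, correct_b)
    (default mean 0.8); mislabeled slices from Beta(incorrect_a,
    incorrect_b) (default mean 0.5).
    """

    correct_a: float = Field(default=8.0, gt=0)
    correct_b: float = Field(default=2.0, gt=0)
    incorrect_a: float = Field(default=4.0, gt=0)
    incorrect_b: float = Field(default=4.0, gt=0)


def simulate_slice_predictions(
    true_phase: str,
    n_slices: int,
    accuracy: float,
    confidence_params: Optional[ConfidenceParams] = None,
    seed: int = 0,
) -> list[SlicePrediction]:
    """Emulate a slice-level phase classifier of given per-slice accuracy.

    Each slice keeps the true label with probability ``accuracy`` and
    otherwise receives a uniformly chosen wrong phase.
    """
    if true_phase not in PHASES:
        raise ValueError(f"true_phase must be one of {PHASES}")
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    params = confidence_params or ConfidenceParams()
    rng = np.random.default_rng(seed)
    others = [p for p in PHASES if p != true_phase]
    preds = []
    for idx in range(n_slices):
        if rng.random() < accuracy:
            label = true_phase
            conf = rng.beta(params.correct_a, params.correct_b)
        else:
            label = others[rng.integers(len(others))]
            conf = rng.beta(params.incorrect_a, params.incorrect_b)
        preds.append(SlicePrediction(slice_index=idx, label=label, confidence=float(conf)))
    return preds
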