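"""End-to-end orchestration: simulate -> extract -> vote -> correct -> FF -> evaluate.

Each stage writes CSV/JSON artifacts into the run directory and is recorded
in a manifest with SHA-256 checksums, so identical config+seed runs are
byte-reproducible.  A single global seed is fanned out to per-stage child
seeds through ``numpy.random.SeedSequence([seed, stage_index])``, keeping
stage-level reproducibility without seed reuse.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .attenuation import LIVER_LABEL, SPLEEN_LABEL, masked_mean, save_phantom
from .correction import PUBLISHED_MODELS, correct, load_models
from .evaluation import roc_auc, threshold_sweep
from .fat_fraction import FF_INTERCEPT, FF_SLOPE
from .phase_id import PHASES, vote_phase
from .synthetic import (
    CohortSimConfig,
    PhantomConfig,
    simulate_cohort,
    simulate_phantom,
    simulate_slice_predictions,
)

__all__ = ["RunConfig", "StageError", "run", "KNOWN_STAGES"]

logger = logging.getLogger(__name__)

KNOWN_STAGES = (
    "simulate-cohort",
    "simulate-phantom",
    "extract",
    "phase-vote",
    "correct",
    "ff",
    "evaluate",
)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


class RunConfig(BaseModel):
    """Configuration of a full synthetic run."""

    out_dir: Path
    seed: int = 0
    stages: tuple = KNOWN_STAGES
    n_subjects: int = Field(default=1000, gt=0)
    cohort_overrides: dict = Field(default_factory=dict)
    phantom_overrides: dict = Field(default_factory=dict)
    threshold_grid_hu: tuple = tuple(range(40, 105, 5))
    model_registry_path: Optional[Path] = None
    n_vote_slices: int = 18
    vote_accuracy: float = 0.9

    def validate_stages(self) -> None:
        unknown = set(self.stages) - set(KNOWN_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; valid: {KNOWN_STAGES}")


def _child_seed(seed: int, stage_index: int) -> int:
    return int(np.random.SeedSequence([seed, stage_index]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run(config: RunConfig) -> dict:
    """Execute the configured stages in order; return the run manifest.

    A stage failure aborts the run: partial outputs are retained and a
    ``FAILED`` marker file names the failing stage.
    """
    config.validate_stages()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    models = (
        load_models(config.model_registry_path)
        if config.model_registry_path
        else dict(PUBLISHED_MODELS)
    )

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "artifacts": {},
    }
    cohort: Optional[pd.DataFrame] = None

    try:
        for idx, stage in enumerate(config.stages):
            seed = _child_seed(config.seed, idx)
            logger.info("[%s] starting (child seed %d)", stage, seed)
            produced: list[Path] = []

            if stage == "simulate-cohort":
                sim_cfg = CohortSimConfig(
                    n_subjects=config.n_subjects, seed=seed, **config.cohort_overrides
                )
                cohort = simulate_cohort(sim_cfg, models)
                path = out / "cohort.csv"
                _write_csv(cohort, path)
                produced.append(path)

            elif stage == "simulate-phantom":
                ph_cfg = PhantomConfig(seed=seed, **config.phantom_overrides)
                phantom = simulate_phantom(ph_cfg)
                img, msk, sidecar = (
                    out / "phantom_image.nii",
                    out / "phantom_mask.nii",
                    out / "phantom_labels.json",
                )
                save_phantom(phantom, img, msk, sidecar)
                produced += [img, msk, sidecar]
                manifest["phantom"] = {
                    "liver": masked_mean(phantom, LIVER_LABEL).__dict__,
                    "spleen": masked_mean(phantom, SPLEEN_LABEL).__dict__,
                }

            elif stage == "extract":
                ph_cfg = PhantomConfig(seed=_child_seed(config.seed, idx - 1),
                                       **config.phantom_overrides)
                phantom = simulate_phantom(ph_cfg)
                rows = []
                for organ, label in (("liver", LIVER_LABEL), ("spleen", SPLEEN_LABEL)):
                    mm = masked_mean(phantom, label)
                    rows.append({"organ": organ, "mean_hu": mm.mean_hu, "n_voxels": mm.n_voxels})
                path = out / "phantom_attenuation.csv"
                _write_csv(pd.DataFrame(rows), path)
                produced.append(path)

            elif stage == "phase-vote":
                rows = []
                for k, phase in enumerate(PHASES):
                    preds = simulate_slice_predictions(
                        phase,
                        config.n_vote_slices,
                        config.vote_accuracy,
                        seed=seed + k,
                    )
                    vote = vote_phase(preds)
                    rows.append(
                        {
                            "true_phase": phase,
                            "voted_phase": vote.label,
                            "tied": vote.tied,
                            **{f"weight_{p}": w for p, w in vote.weights.items()},
                        }
                    )
                path = out / "phase_votes.csv"
                _write_csv(pd.DataFrame(rows), path)
                produced.append(path)

            elif stage == "correct":
                if cohort is None:
                    raise RuntimeError("'correct' requires the simulate-cohort stage")
                corrected = np.where(
                    cohort["phase"] == "non-contrast",
                    cohort["liver_hu"],
                    [
                        correct(l, models[p]) if p != "non-contrast" else l
                        for l, p in zip(cohort["liver_hu"], cohort["phase"])
                    ],
                )
                cohort = cohort.assign(corrected_liver_hu=corrected)
                path = out / "cohort_corrected.csv"
                _write_csv(cohort, path)
                produced.append(path)

            elif stage == "ff":
                if cohort is None or "corrected_liver_hu" not in cohort:
                    raise RuntimeError("'ff' requires the correct stage")
                cohort = cohort.assign(
                    ff_percent=FF_SLOPE * cohort["corrected_liver_hu"] + FF_INTERCEPT
                )
                path = out / "cohort_ff.csv"
                _write_csv(cohort, path)
                produced.append(path)

            elif stage == "evaluate":
                if cohort is None or "corrected_liver_hu" not in cohort:
                    raise RuntimeError("'evaluate' requires the correct stage")
                rows = []
                for phase in sorted(set(cohort["phase"]) - {"non-contrast"}):
                    sub = cohort[cohort["phase"] == phase]
                    truth = sub["steatosis_truth"].to_numpy()
                    scores = sub["corrected_liver_hu"].to_numpy()
                    # lower attenuation = fattier liver: negate for ROC
                    roc = roc_auc(-scores, truth)
                    sweep = threshold_sweep(
                        scores, truth, config.threshold_grid_hu, "less_than"
                    )
                    for row in sweep.rows:
                        rows.append(
                            {
                                "phase": phase,
                                "threshold_hu": row.threshold,
                                **row.metrics.rounded(),
                                "optimal": row is sweep.optimal,
                                "auroc": roc.auroc,
                            }
                        )
                path = out / "evaluation.csv"
                _write_csv(pd.DataFrame(rows), path)
                produced.append(path)

            manifest["stages"].append({"name": stage, "child_seed": seed})
            for p in produced:
                manifest["artifacts"][p.name] = _sha256(p)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage!r} failed: {exc}\n")
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
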