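"""End-to-end pipeline driver over the synthetic cohort.

``run_pipeline`` executes the enabled stages in dependency order on a
self-generated synthetic cohort, writing every artifact (signature, metric
tables, stat maps, mediation summary) with a provenance sidecar carrying the
config hash and seed.  The trained signature is cached by config hash so
that re-running with only downstream stages toggled reuses it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .datasets import BetaImageSet
from .interpret import bootstrap_weight_map, haufe_transform
from .mediation import multilevel_mediation
from .regional import parcel_prediction
from .signature import (
    CVScheme,
    compute_metrics,
    crossvalidate,
    forced_choice_from_values,
    train_signature,
)
from .space import default_space
from .specificity import cross_classify, octant_ssdo, spatial_correlation
from .synth import (
    CohortConfig,
    default_ground_truth,
    generate_conditioned_pair,
    generate_cohort,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "train", "evaluate", "interpret", "regional",
              "specificity", "mediate")


@dataclass
class PipelineConfig:
    """Everything a deterministic pipeline run needs."""

    outdir: str = "fearsig_run"
    seed: int = 0
    dims: tuple[int, int, int] = (24, 24, 18)
    n_subjects: int = 20
    trials_per_subject: int = 60
    rating_levels: int = 5
    drop_top_level_subjects: int = 0
    n_folds: int = 10
    n_repeats: int = 2
    n_boot: int = 500
    n_perm: int = 500
    fdr_level: float = 0.05
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["dims"] = list(d["dims"])
        d["stages"] = list(d["stages"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["dims"] = tuple(d["dims"])
        d["stages"] = tuple(d["stages"])
        return cls(**d)

    def config_hash(self, *fields: str) -> str:
        d = json.loads(self.to_json())
        if fields:
            d = {k: d[k] for k in fields}
        return hashlib.sha1(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:12]


#: config fields that determine the trained signature (cache key)
_SIGNATURE_FIELDS = (
    "seed", "dims", "n_subjects", "trials_per_subject", "rating_levels",
    "drop_top_level_subjects",
)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages; returns the artifact directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    full_hash = config.config_hash()
    sig_hash = config.config_hash(*_SIGNATURE_FIELDS)
    timings: dict[str, float] = {}

    def sidecar(extra=None):
        meta = {"config_hash": full_hash, "seed": config.seed}
        if extra:
            meta.update(extra)
        return meta

    space = default_space(config.dims)
    truth = default_ground_truth(space, seed=config.seed)
    scheme = CVScheme(n_folds=config.n_folds, n_repeats=config.n_repeats,
                      seed=config.seed)

    trial_set = cond_set = events = None
    if "simulate" in config.stages:
        t0 = time.perf_counter()
        cfg = CohortConfig(
            n_subjects=config.n_subjects,
            trials_per_subject=config.trials_per_subject,
            rating_levels=config.rating_levels,
            drop_top_level_subjects=config.drop_top_level_subjects,
            seed=config.seed,
        )
        trial_set, cond_set, events = generate_cohort(space, truth, cfg)
        nio.save_mask(out / "mask.nii.gz", space)
        nio.save_atlas(out / "atlas.nii.gz", space)
        nio.save_events(out / "events.tsv", events)
        nio.save_map(out / "ground_truth_encoding.nii.gz",
                     truth.encoding_pattern, space, sidecar())
        timings["simulate"] = time.perf_counter() - t0

    def need_cohort():
        if cond_set is None:
            raise RuntimeError(
                "cohort not available: enable the 'simulate' stage first"
            )

    model = None
    sig_stem = out / "signature"
    if "train" in config.stages:
        t0 = time.perf_counter()
        need_cohort()
        cached = sig_stem.with_suffix(".json")
        if cached.exists():
            meta = json.loads(cached.read_text())
            if meta.get("config", {}).get("cache_hash") == sig_hash:
                model = nio.load_model(sig_stem, space)
                logger.info("train: reusing cached signature (%s)", sig_hash)
        if model is None:
            model = train_signature(cond_set)
            model.config["cache_hash"] = sig_hash
            nio.save_model(sig_stem, model, space)
        timings["train"] = time.perf_counter() - t0

    pairs = None
    if "evaluate" in config.stages:
        t0 = time.perf_counter()
        need_cohort()
        pairs = crossvalidate(cond_set, scheme)
        metrics = compute_metrics(pairs)
        values = pairs.predicted
        fc = forced_choice_from_values(values, cond_set.ratings,
                                       cond_set.subject_ids, ("high", "low"))
        table = pd.DataFrame([{**metrics.to_dict(),
                               "fc_high_low_accuracy": fc.accuracy,
                               "fc_high_low_d": fc.cohens_d}])
        table.to_csv(out / "metrics.tsv", sep="\t", index=False)
        (out / "metrics.json").write_text(json.dumps(
            sidecar({"metrics": metrics.to_dict()}), indent=2))
        timings["evaluate"] = time.perf_counter() - t0

    if "interpret" in config.stages and model is not None:
        t0 = time.perf_counter()
        need_cohort()
        boot = bootstrap_weight_map(cond_set, n_boot=config.n_boot,
                                    seed=config.seed)
        thr = boot.thresholded(config.fdr_level)
        nio.save_map(out / "bootstrap_z.nii.gz", boot.statistic, space,
                     sidecar({"n_boot": config.n_boot}))
        nio.save_map(out / "bootstrap_z_thresholded.nii.gz", thr.statistic,
                     space, sidecar({"fdr_level": config.fdr_level}))
        pattern = haufe_transform(cond_set.data, model.weights)
        nio.save_map(out / "activation_pattern.nii.gz", pattern.values, space,
                     sidecar())
        timings["interpret"] = time.perf_counter() - t0

    if "regional" in config.stages:
        t0 = time.perf_counter()
        need_cohort()
        table = parcel_prediction(cond_set, space, scheme)
        table.to_csv(out / "parcel_predictions.tsv", sep="\t", index=False)
        timings["regional"] = time.perf_counter() - t0

    if "specificity" in config.stages and model is not None:
        t0 = time.perf_counter()
        pair_set = generate_conditioned_pair(
            space, truth, n_subjects=config.n_subjects, delta=3.0,
            seed=config.seed + 1,
        )
        fc, p_perm = cross_classify(model, pair_set, n_perm=config.n_perm,
                                    seed=config.seed)
        r_spatial, p_spatial = spatial_correlation(
            model.weights, truth.threat_pattern, n_perm=config.n_perm,
            seed=config.seed,
        )
        octants = octant_ssdo(model.weights, truth.threat_pattern)
        pd.DataFrame({
            "octant": np.arange(1, 9),
            "label": octants.labels,
            "ssdo": octants.ssdo,
            "n_voxels": octants.counts,
        }).to_csv(out / "octant_ssdo.tsv", sep="\t", index=False)
        (out / "specificity.json").write_text(json.dumps(sidecar({
            "cs_accuracy": fc.accuracy, "cs_p_perm": p_perm,
            "spatial_r": r_spatial, "spatial_p": p_spatial,
        }), indent=2))
        timings["specificity"] = time.perf_counter() - t0

    if "mediate" in config.stages and model is not None and trial_set is not None:
        t0 = time.perf_counter()
        # trial-wise expressions of the fear signature mediate a general
        # latent (here: noisy rating readout) -> rating association
        rng = np.random.default_rng(config.seed + 2)
        cv_trial = crossvalidate(trial_set, scheme)
        x = cv_trial.predicted + rng.normal(0, 0.5, trial_set.n_obs)
        triplets = pd.DataFrame({
            "subject": trial_set.subject_ids,
            "x": x,
            "m": cv_trial.predicted,
            "y": trial_set.ratings,
        })
        result = multilevel_mediation(triplets, n_boot=config.n_boot,
                                      seed=config.seed)
        (out / "mediation.json").write_text(json.dumps(sidecar({
            "estimates": result.estimates,
            "ci": {k: list(v) for k, v in result.ci.items()},
            "p": result.p,
            "cohens_d_ab": result.cohens_d_ab,
        }), indent=2))
        timings["mediate"] = time.perf_counter() - t0

    (out / "provenance.json").write_text(json.dumps({
        "config": json.loads(config.to_json()),
        "config_hash": full_hash,
        "signature_hash": sig_hash,
        "space_fingerprint": space.fingerprint(),
        "stage_timings_s": timings,
    }, indent=2))
    logger.info("pipeline finished: %s", {k: round(v, 2) for k, v in
                                          timings.items()})
    return out
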