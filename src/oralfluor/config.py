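"""Pipeline configuration and end-to-end orchestration.

One YAML (or JSON) file configures every stage.  All randomness flows from a
single root ``seed``: the simulation seed and the pixel-subsample seed are
derived from it with a seed sequence, and the resolved values are emitted
explicitly in the config dump and the run manifest, so every artifact on
disk is reproducible from (config, seed) alone.

Coordinate convention throughout: (row, col), 0-based, row-major.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .errors import ConfigurationError
from .evaluate import CohortItem, CVReport, lopocv, report, velscope_baseline
from .features import build_feature_stacks, total_intensity
from .preprocess import PreprocessConfig, preprocess
from .simulate import SimulationConfig, assign_labels, simulate_patient

logger = logging.getLogger(__name__)

POOL_CHOICES = ("absolute", "relative", "both")
K_CHOICES = (3, 4, 5)


@dataclass(frozen=True)
class ClassifierConfig:
    pool: str = "absolute"
    top_k: int = 4
    C: float = 1.0
    pixel_cap: Optional[int] = 2000
    calibration: str = "platt"

    def validate(self) -> None:
        if self.pool not in POOL_CHOICES:
            raise ConfigurationError(f"pool must be one of {POOL_CHOICES}")
        if self.top_k not in (1,) + K_CHOICES:
            raise ConfigurationError(f"top_k must be 1 or one of {K_CHOICES}")
        if self.C <= 0:
            raise ConfigurationError("C must be positive")
        if self.pixel_cap is not None and self.pixel_cap < 1:
            raise ConfigurationError("pixel_cap must be >= 1 or null")
        if self.calibration != "platt":
            raise ConfigurationError("calibration must be 'platt'")


@dataclass(frozen=True)
class EvaluationConfig:
    max_fpr: float = 0.30
    run_baseline: bool = True
    overlays: bool = True
    full_grid: bool = False  # run all 3 pools x k in {3,4,5}

    def validate(self) -> None:
        if not 0.0 <= self.max_fpr <= 1.0:
            raise ConfigurationError("max_fpr must lie in [0, 1]")


@dataclass(frozen=True)
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = 0

    def validate(self) -> None:
        self.simulation.validate()
        self.preprocess.validate()
        self.classifier.validate()
        self.evaluation.validate()


def derive_seeds(root_seed: int) -> dict[str, int]:
    """Expand the root seed into named per-stage seeds (all < 2**31)."""
    state = np.random.SeedSequence(int(root_seed)).generate_state(2)
    return {
        "simulation": int(state[0] % 2**31),
        "subsample": int(state[1] % 2**31),
    }


def _build_section(cls, data: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) in section {section!r}: {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        coerced[f.name] = v
    try:
        return cls(**coerced)
    except TypeError as exc:
        raise ConfigurationError(f"invalid section {section!r}: {exc}") from exc


def config_from_dict(data: Optional[dict]) -> PipelineConfig:
    data = dict(data or {})
    known = {"simulation", "preprocess", "classifier", "evaluation", "seed"}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s): {sorted(unknown)}")
    seed = int(data.get("seed", 0))
    sim_section = dict(data.get("simulation") or {})
    # All randomness flows from the root seed; the simulation seed is derived.
    sim_section.pop("seed", None)
    sim_section["seed"] = derive_seeds(seed)["simulation"]
    # YAML dicts of band fractions arrive as lists.
    if "class_band_fractions" in sim_section:
        sim_section["class_band_fractions"] = {
            g: tuple(v) for g, v in sim_section["class_band_fractions"].items()
        }
    cfg = PipelineConfig(
        simulation=_build_section(SimulationConfig, sim_section, "simulation"),
        preprocess=_build_section(PreprocessConfig, dict(data.get("preprocess") or {}), "preprocess"),
        classifier=_build_section(ClassifierConfig, dict(data.get("classifier") or {}), "classifier"),
        evaluation=_build_section(EvaluationConfig, dict(data.get("evaluation") or {}), "evaluation"),
        seed=seed,
    )
    cfg.validate()
    return cfg


def load_config(path) -> PipelineConfig:
    """Parse and validate a YAML/JSON pipeline config; unknown keys are
    rejected and every default is resolved."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
    if data is not None and not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    return config_from_dict(data)


def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_to_dict(cfg: PipelineConfig) -> dict:
    """Fully-resolved plain-dict form; every defaulted field is explicit."""
    return _plain(cfg)


def dump_config(cfg: PipelineConfig, path=None) -> str:
    text = yaml.safe_dump(config_to_dict(cfg), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    ).hexdigest()[:16]


def build_cohort_items(cfg: PipelineConfig, manual_masks: Optional[dict] = None) -> list[CohortItem]:
    """Simulate, preprocess and featurize the cohort one patient at a time.

    Only the per-patient feature stacks are retained; the raw decay cubes are
    released as soon as each patient is processed.
    """
    cfg.validate()
    manual_masks = manual_masks or {}
    items: list[CohortItem] = []
    for i, grade in enumerate(assign_labels(cfg.simulation)):
        sample = simulate_patient(cfg.simulation, i, grade)
        manual = manual_masks.get(sample.patient_id)
        (lcube, lmask), (hcube, hmask) = preprocess(sample, cfg.preprocess, manual_lesion=manual)
        lesion_stack, healthy_stack = build_feature_stacks(lcube, lmask, hcube, hmask)
        items.append(
            CohortItem(
                patient_id=sample.patient_id,
                lesion_stack=lesion_stack,
                histopathology=sample.histopathology,
                site=sample.site,
                total_intensity=total_intensity(lcube, lesion_stack.mask),
            )
        )
    return items


def run_pipeline(cfg: PipelineConfig, out_dir) -> list[CVReport]:
    """simulate -> preprocess -> features -> cross-validate (+ baseline) -> report."""
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(cfg.seed)
    logger.info("pipeline seeds: %s (config hash %s)", seeds, config_hash(cfg))

    items = build_cohort_items(cfg)

    if cfg.evaluation.full_grid:
        runs = [(pool, k) for pool in POOL_CHOICES for k in K_CHOICES]
    else:
        runs = [(cfg.classifier.pool, cfg.classifier.top_k)]
    cvs = [
        lopocv(
            items, pool=pool, k=k, C=cfg.classifier.C,
            pixel_cap=cfg.classifier.pixel_cap, max_fpr=cfg.evaluation.max_fpr,
            seed=seeds["subsample"], keep_maps=cfg.evaluation.overlays,
        )
        for pool, k in runs
    ]
    if cfg.evaluation.run_baseline:
        cvs.append(
            velscope_baseline(
                items, C=cfg.classifier.C, pixel_cap=cfg.classifier.pixel_cap,
                max_fpr=cfg.evaluation.max_fpr, seed=seeds["subsample"],
                keep_maps=cfg.evaluation.overlays,
            )
        )
    report(cvs, out_dir, overlays=cfg.evaluation.overlays)
    manifest = {
        "package_version": __version__,
        "config": config_to_dict(cfg),
        "config_hash": config_hash(cfg),
        "derived_seeds": seeds,
        "n_patients": len(items),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return cvs
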