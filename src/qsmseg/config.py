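"""Run configuration: YAML loading, defaults, and the ``demo_tiny`` profile.

``default_config`` mirrors the full-scale study setup (5 folds, batch 32,
Adam at 1e-4, patience 20, crop 96/128, loss weights 0.6/0.3/0.1). ``demo_tiny`` is a reduced profile sized
for a single CPU: smaller grids and cohorts, base_filters 8, crop 64, two
folds, a higher learning rate suited to the small model, and short patience.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from .network import NetworkConfig
from .phantom import (DomainSpec, PhantomSpec, source_domain_spec,
                      source_phantom_spec, target_domain_spec,
                      target_phantom_spec)
from .preprocess import AugmentRanges
from .training import LossWeights, PreprocessConfig, TrainConfig

__all__ = ["RunConfig", "default_config", "demo_tiny_config", "load_config",
           "save_config"]


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int
    n_test: int
    n_folds: int
    seed: int = 0


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to run simulate -> pretrain -> train -> evaluate."""

    name: str
    seed: int
    target_phantom: PhantomSpec
    source_phantom: PhantomSpec
    target_cohort: CohortConfig
    source_cohort: CohortConfig
    network: NetworkConfig          # n_classes is set per domain at build time
    training: TrainConfig
    normalize_range: tuple[float, float] | None
    augment: AugmentRanges
    threshold: float = 0.5
    top_k: int = 2
    work_dir: str = "runs"

    def preprocess_for(self, domain: DomainSpec) -> PreprocessConfig:
        class_ids = (1, 2) if domain.n_foreground_classes == 2 else (1, 2, 3)
        return PreprocessConfig(crop_size=domain.crop_size, class_ids=class_ids,
                                normalize_range=self.normalize_range,
                                augment=self.augment)

    def network_for(self, domain: DomainSpec) -> NetworkConfig:
        return replace(self.network, n_classes=domain.n_foreground_classes)


def default_config(seed: int = 0) -> RunConfig:
    """Full-scale configuration (5 folds, 75 + 100 subjects, crop 96/128)."""
    return RunConfig(
        name="default",
        seed=seed,
        target_phantom=target_phantom_spec(seed=seed),
        source_phantom=source_phantom_spec(seed=seed + 1),
        target_cohort=CohortConfig(n_subjects=75, n_test=15, n_folds=5, seed=seed),
        source_cohort=CohortConfig(n_subjects=100, n_test=20, n_folds=5, seed=seed),
        network=NetworkConfig(in_channels=3, n_classes=3, base_filters=32, depth=4),
        training=TrainConfig(batch_size=32, initial_lr=1e-4, patience=20,
                             max_epochs=300, seed=seed),
        normalize_range=(-0.3, 0.5),
        augment=AugmentRanges(),
    )


def demo_tiny_config(seed: int = 0, work_dir: str = "runs/demo_tiny") -> RunConfig:
    """Reduced profile for CPU-scale end-to-end runs and the test suite."""
    target_dom = target_domain_spec(matrix_rows=72, matrix_cols=72, n_slices=14,
                                    voxel_size=(0.83, 0.83, 1.6), crop_size=64)
    source_dom = source_domain_spec(matrix_rows=72, matrix_cols=72, n_slices=12,
                                    voxel_size=(0.83, 0.83, 2.0), crop_size=64)
    return RunConfig(
        name="demo_tiny",
        seed=seed,
        target_phantom=target_phantom_spec(domain=target_dom, seed=seed),
        source_phantom=source_phantom_spec(domain=source_dom, seed=seed + 1),
        target_cohort=CohortConfig(n_subjects=20, n_test=4, n_folds=2, seed=seed),
        source_cohort=CohortConfig(n_subjects=8, n_test=2, n_folds=2, seed=seed),
        network=NetworkConfig(in_channels=3, n_classes=3, base_filters=8, depth=4),
        # batch and learning rate are scaled to the small cohort: batch 8
        # keeps ~15 optimizer steps per epoch, and the 8-filter model takes
        # the larger 1e-2 step size without instability
        training=TrainConfig(batch_size=8, initial_lr=1e-2, patience=5,
                             max_epochs=25, seed=seed),
        normalize_range=(-0.3, 0.5),
        augment=AugmentRanges(),
        work_dir=work_dir,
    )


_PROFILES = {"default": default_config, "demo_tiny": demo_tiny_config}


# ----------------------------------------------------------------- YAML I/O
def _to_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d["target_phantom"]["domain"] = asdict(cfg.target_phantom.domain)
    d["source_phantom"]["domain"] = asdict(cfg.source_phantom.domain)
    return d


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))
    return path


def _phantom_from_dict(d: dict) -> PhantomSpec:
    from .phantom import NucleusSpec

    dom = DomainSpec(**{**d["domain"],
                        "voxel_size": tuple(d["domain"]["voxel_size"])})

    def nucleus(n):
        return NucleusSpec(**{**n,
                              "center_offset": tuple(n["center_offset"]),
                              "semiaxis_ratios": tuple(n["semiaxis_ratios"])})

    return PhantomSpec(domain=dom,
                       nuclei=tuple(nucleus(n) for n in d["nuclei"]),
                       distractors=tuple(nucleus(n) for n in d.get("distractors", ())),
                       background_mean=d["background_mean"],
                       noise_sd=d["noise_sd"],
                       background_field_amplitude=d["background_field_amplitude"],
                       jitter_sd=d["jitter_sd"], seed=d["seed"])


def load_config(path_or_profile: str | Path, seed: int | None = None) -> RunConfig:
    """Load a YAML run configuration, or a named profile (``default``,
    ``demo_tiny``)."""
    if str(path_or_profile) in _PROFILES:
        return _PROFILES[str(path_or_profile)](seed=seed if seed is not None else 0)
    d = yaml.safe_load(Path(path_or_profile).read_text())
    try:
        cfg = RunConfig(
            name=d["name"],
            seed=d["seed"],
            target_phantom=_phantom_from_dict(d["target_phantom"]),
            source_phantom=_phantom_from_dict(d["source_phantom"]),
            target_cohort=CohortConfig(**d["target_cohort"]),
            source_cohort=CohortConfig(**d["source_cohort"]),
            network=NetworkConfig(**d["network"]),
            training=TrainConfig(
                **{**d["training"],
                   "loss_weights": LossWeights(**d["training"]["loss_weights"])}),
            normalize_range=tuple(d["normalize_range"]) if d.get("normalize_range") else None,
            augment=AugmentRanges(shift=d["augment"]["shift"],
                                  rotation=d["augment"]["rotation"],
                                  shear=tuple(d["augment"]["shear"])),
            threshold=d.get("threshold", 0.5),
            top_k=d.get("top_k", 2),
            work_dir=d.get("work_dir", "runs"),
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"invalid run configuration {path_or_profile}: {exc}") from exc
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    return cfg
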