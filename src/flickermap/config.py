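"""Run configuration: one dataclass per pipeline stage, loadable from YAML/JSON.

Every parameter has a documented default; unknown keys are rejected so a
typo in a config file fails loudly instead of silently running defaults.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessingParams",
    "ClusteringParams",
    "LocalizationParams",
    "TrackingParams",
    "FretParams",
    "SpatialParams",
    "RunConfig",
    "load_config",
    "dump_config",
]


@dataclass
class PreprocessingParams:
    """Ratio movie + temporal filtering + variance normalization.

    baseline_frames: frames used for the per-pixel F0 and noise estimate.
    butterworth_cutoff: high-pass corner frequency in Hz (removes drift
    and bleaching); butterworth_order: filter order; the filter is applied
    forward-backward (zero phase) so event times are not shifted.
    """

    baseline_frames: int = 100
    butterworth_cutoff: float = 0.1
    butterworth_order: int = 2

    def validate(self) -> None:
        if self.baseline_frames < 2:
            raise ConfigError("preprocessing.baseline_frames must be >= 2")
        if self.butterworth_cutoff <= 0:
            raise ConfigError("preprocessing.butterworth_cutoff must be > 0")
        if self.butterworth_order < 1:
            raise ConfigError("preprocessing.butterworth_order must be >= 1")


@dataclass
class ClusteringParams:
    """Thresholding + density-peak clustering of supra-threshold voxels.

    spatial_sigma (px) smooths each normalized frame before thresholding
    at z_threshold (the normalized movie is unit variance by construction).
    The density of each supra-threshold voxel counts neighbours inside an
    ellipsoid of radii (radius_t frames, radius_y px, radius_x px); voxels
    with density > rho_min and normalized distance-to-denser > delta_min
    become cluster centers; clusters smaller than min_cluster_size voxels
    are discarded.
    """

    spatial_sigma: float = 1.0
    z_threshold: float = 3.0
    radius_t: float = 3.0
    radius_y: float = 2.0
    radius_x: float = 2.0
    rho_min: float = 8.0
    delta_min: float = 2.0
    min_cluster_size: int = 4

    def validate(self) -> None:
        for name in ("spatial_sigma", "z_threshold", "radius_t", "radius_y", "radius_x"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"clustering.{name} must be > 0")
        if self.min_cluster_size < 1:
            raise ConfigError("clustering.min_cluster_size must be >= 1")


@dataclass
class LocalizationParams:
    """Subpixel 2D-Gaussian localization of each event."""

    fit_window: int = 5  # half-width in px of the fit window

    def validate(self) -> None:
        if self.fit_window < 1:
            raise ConfigError("localization.fit_window must be >= 1")


@dataclass
class TrackingParams:
    """Per-frame DoG spot detection + nearest-neighbor linking + MSD fit.

    threshold = None means auto: threshold_nsigma times the robust noise
    sigma (1.4826 * MAD) of the difference-of-Gaussians image.
    """

    sigma_small: float = 1.0
    sigma_large: float = 3.0
    threshold: float | None = None
    threshold_nsigma: float = 5.0
    min_pixels: int = 3
    max_link_dist: float = 3.0
    max_lag: int = 20
    fit_lags: int = 10

    def validate(self) -> None:
        if not self.sigma_small < self.sigma_large:
            raise ConfigError("tracking.sigma_small must be < sigma_large")
        if self.threshold is not None and self.threshold <= 0:
            raise ConfigError("tracking.threshold must be > 0 (or null for auto)")
        if self.threshold_nsigma <= 0:
            raise ConfigError("tracking.threshold_nsigma must be > 0")
        if self.min_pixels < 1:
            raise ConfigError("tracking.min_pixels must be >= 1")
        if self.max_link_dist <= 0:
            raise ConfigError("tracking.max_link_dist must be > 0")
        if self.fit_lags < 2:
            raise ConfigError("tracking.fit_lags must be >= 2")
        if self.max_lag < self.fit_lags:
            raise ConfigError("tracking.max_lag must be >= fit_lags")


@dataclass
class FretParams:
    """FRET index/efficiency/force maps and force-region segmentation.

    alpha: fraction of donor-labeled sensors with an acceptor; gamma:
    donor/acceptor quantum-yield correction. Both are experimentally
    determined per sensor batch; the defaults (1, 1) are uncalibrated
    placeholders and a warning is logged whenever they are used.
    """

    alpha: float = 1.0
    gamma: float = 1.0
    donor_background: float = 0.0
    acceptor_background: float = 0.0
    intensity_floor: float | None = None  # None: 5x background noise sigma
    blur_sigma: float = 2.0
    threshold_fraction: float = 0.75
    registration_offset: tuple[float, float] = (0.0, 0.0)  # (dx, dy) px

    def validate(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ConfigError("fret.alpha must be in (0, 1]")
        if self.gamma <= 0:
            raise ConfigError("fret.gamma must be > 0")
        if self.donor_background < 0 or self.acceptor_background < 0:
            raise ConfigError("fret backgrounds must be >= 0")
        if self.blur_sigma <= 0:
            raise ConfigError("fret.blur_sigma must be > 0")
        if not (0 < self.threshold_fraction < 1):
            raise ConfigError("fret.threshold_fraction must be in (0, 1)")


@dataclass
class SpatialParams:
    """Distance-to-force-region analysis and square-geometry statistics."""

    n_null: int = 1000
    corner_fraction: float = 0.25

    def validate(self) -> None:
        if self.n_null < 1:
            raise ConfigError("spatial.n_null must be >= 1")
        if not (0 < self.corner_fraction < 0.5):
            raise ConfigError("spatial.corner_fraction must be in (0, 0.5)")


_GROUPS = {
    "preprocessing": PreprocessingParams,
    "clustering": ClusteringParams,
    "localization": LocalizationParams,
    "tracking": TrackingParams,
    "fret": FretParams,
    "spatial": SpatialParams,
}


@dataclass
class RunConfig:
    """Full run configuration: one group per pipeline stage plus a seed."""

    preprocessing: PreprocessingParams = field(default_factory=PreprocessingParams)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    localization: LocalizationParams = field(default_factory=LocalizationParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    fret: FretParams = field(default_factory=FretParams)
    spatial: SpatialParams = field(default_factory=SpatialParams)
    seed: int = 0

    def validate(self) -> None:
        for name in _GROUPS:
            getattr(self, name).validate()

    @classmethod
    def from_dict(cls, raw: dict | None) -> "RunConfig":
        raw = dict(raw or {})
        kwargs = {}
        for name, group_cls in _GROUPS.items():
            sub = raw.pop(name, {}) or {}
            if not isinstance(sub, dict):
                raise ConfigError(f"config group '{name}' must be a mapping")
            known = {f.name for f in fields(group_cls)}
            unknown = set(sub) - known
            if unknown:
                raise ConfigError(
                    f"unknown key(s) in config group '{name}': {sorted(unknown)}"
                )
            if "registration_offset" in sub and sub["registration_offset"] is not None:
                sub = {**sub, "registration_offset": tuple(sub["registration_offset"])}
            kwargs[name] = group_cls(**sub)
        seed = raw.pop("seed", 0)
        if not isinstance(seed, int):
            raise ConfigError("seed must be an integer")
        if raw:
            raise ConfigError(f"unknown top-level config key(s): {sorted(raw)}")
        cfg = cls(seed=seed, **kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        out = {name: dataclasses.asdict(getattr(self, name)) for name in _GROUPS}
        # tuples do not round-trip through YAML; store as list
        out["fret"]["registration_offset"] = list(out["fret"]["registration_offset"])
        out["seed"] = self.seed
        return out


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML (or JSON) run configuration; ``None`` yields all defaults.

    Absent groups/keys take their documented defaults; unknown keys raise
    :class:`~flickermap.errors.ConfigError` naming the key. The effective
    configuration is logged at INFO level.
    """
    if path is None:
        cfg = RunConfig.from_dict({})
    else:
        path = Path(path)
        if not path.exists():
            raise IOError(f"config file not found: {path}")
        text = path.read_text()
        raw = yaml.safe_load(text) if text.strip() else {}
        if raw is not None and not isinstance(raw, dict):
            raise ConfigError(f"{path}: config root must be a mapping")
        cfg = RunConfig.from_dict(raw)
    logger.info("effective configuration: %s", json.dumps(cfg.to_dict()))
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the effective configuration back to YAML (round-trip stable)."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
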