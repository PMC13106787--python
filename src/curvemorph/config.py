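"""Generator and pipeline configuration.

Only a handful of generator defaults are anchored to published measurements of
the 48 hpf wild-type ventricle: the OC apical-area distribution (mean 142 µm²,
SD 43 µm²), the typical regional cell counts (~50–60 OC, ~25–30 IC) and the
0.3 µm imaging slice/pixel pitch.  Everything else (IC distributions,
apicobasal lengths, elongation, membrane fraction triplets, noise levels,
tube geometry) is a documented free choice — see docs/methods.md.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["GeneratorConfig", "ExperimentSpec", "PipelineConfig", "config_hash"]


def _triplet(basal: float, lateral: float, apical: float) -> tuple[float, ...]:
    return (basal, lateral, apical)


@dataclass
class GeneratorConfig:
    """Everything needed to synthesize one seeded ventricle.

    Membrane fraction triplets are ``(basal, lateral, apical)`` and must sum
    to 1; they set what share of a cell's total cortical signal sits on each
    membrane domain.
    """

    stage: str = "48"
    seed: int = 0
    genotype: str = "WT"

    # tube geometry (µm / rad)
    bend_radius: float = 100.0
    tube_radius: float = 50.0
    bend_angle: float = 2.5
    cell_diameter_typical: float = 13.0

    # regional cell counts
    n_oc: int = 55
    n_ic: int = 27
    n_neither: int = 18

    # apical-area distributions (µm²); OC numbers follow the 48 hpf wild-type
    # reference dataset (mean 142, SD 43)
    oc_area_mean: float = 142.0
    oc_area_sd: float = 43.0
    ic_area_mean: float = 85.0
    ic_area_sd: float = 25.0

    # elongation ratio = circumferential extent / longitudinal extent
    oc_elongation: float = 1.8
    ic_elongation: float = 1.1

    # apicobasal length distributions (µm): squamous OC vs cuboidal IC
    oc_height_mean: float = 4.5
    oc_height_sd: float = 0.7
    ic_height_mean: float = 7.5
    ic_height_sd: float = 1.0
    neither_area_mean: float = 110.0
    neither_area_sd: float = 30.0
    neither_height_mean: float = 6.0
    neither_height_sd: float = 0.8

    # membrane fraction triplets (basal, lateral, apical) per region/channel
    oc_factin_fractions: tuple = _triplet(0.50, 0.30, 0.20)
    ic_factin_fractions: tuple = _triplet(0.25, 0.45, 0.30)
    oc_pmyosin_fractions: tuple = _triplet(0.45, 0.33, 0.22)
    ic_pmyosin_fractions: tuple = _triplet(0.28, 0.42, 0.30)

    # intensity model (arbitrary units)
    intensity_scale: float = 150.0
    intensity_jitter: float = 0.10  # lognormal sigma of the per-cell scale
    noise_sd: float = 3.0
    background: float = 7.5  # 5% of the intensity scale
    membrane_value: float = 200.0
    pixel_size: float = 0.3  # µm/px, matching the 0.3 µm slice pitch

    # tessellation plumbing
    gap: float = 0.6  # µm left between neighbouring cells
    margin: float = 2.0  # µm inset of placements from region boundaries
    donor_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.stage not in {"36", "37", "48"}:
            raise ValueError(f"unsupported stage {self.stage!r}")
        for name in ("n_oc", "n_ic"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_neither < 0:
            raise ValueError("n_neither must be >= 0")
        for name in (
            "oc_area_sd", "ic_area_sd", "neither_area_sd",
            "oc_height_sd", "ic_height_sd", "neither_height_sd",
            "noise_sd", "intensity_jitter",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if not 0.0 <= self.donor_fraction <= 1.0:
            raise ValueError("donor_fraction must be in [0, 1]")
        for name in (
            "oc_factin_fractions", "ic_factin_fractions",
            "oc_pmyosin_fractions", "ic_pmyosin_fractions",
        ):
            trip = tuple(float(v) for v in getattr(self, name))
            if len(trip) != 3 or any(v < 0 for v in trip):
                raise ValueError(f"{name} must be three non-negative values")
            if abs(sum(trip) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {sum(trip)!r})")
            object.__setattr__(self, name, trip)

    def fractions(self, region: str, channel: str) -> tuple[float, float, float]:
        key = "oc" if region == "OC" else "ic"
        chan = "factin" if channel == "F-actin" else "pmyosin"
        return getattr(self, f"{key}_{chan}_fractions")

    def replace(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)

    @classmethod
    def for_stage(cls, stage: str, **kw) -> "GeneratorConfig":
        """Stage presets: 36–37 hpf hearts are smaller and less divergent."""
        if stage == "48":
            return cls(stage="48", **kw)
        base = dict(
            stage=stage,
            bend_radius=85.0,
            tube_radius=42.5,
            bend_angle=2.3,
            cell_diameter_typical=11.0,
            oc_area_mean=85.0,
            oc_area_sd=22.0,
            ic_area_mean=70.0,
            ic_area_sd=18.0,
            oc_elongation=1.3,
            ic_elongation=1.1,
            oc_height_mean=6.0,
            oc_height_sd=0.8,
            ic_height_mean=6.5,
            ic_height_sd=0.8,
            n_oc=45,
            n_ic=22,
            n_neither=14,
        )
        base.update(kw)
        return cls(**base)

    @classmethod
    def mutant(cls, genotype: str, **kw) -> "GeneratorConfig":
        """Presets emulating the 48 hpf mutant phenotypes.

        ``tbx5a``: OC planar expansion fails (mean apical area 108 µm²,
        matching the published mutant group mean) and cells stay cuboidal with
        reduced basal actomyosin enrichment.  ``myh6`` (no atrial
        contraction): similar OC failure with slightly smaller cells.
        """
        presets = {
            "tbx5a": dict(
                genotype="tbx5a",
                oc_area_mean=108.0,
                oc_area_sd=40.0,
                oc_elongation=1.3,
                oc_height_mean=7.0,
                oc_factin_fractions=_triplet(0.32, 0.42, 0.26),
                oc_pmyosin_fractions=_triplet(0.38, 0.38, 0.24),
            ),
            "myh6": dict(
                genotype="myh6",
                oc_area_mean=105.0,
                oc_area_sd=35.0,
                oc_elongation=1.3,
                oc_height_mean=6.5,
                ic_area_mean=85.0,
                oc_factin_fractions=_triplet(0.30, 0.44, 0.26),
                oc_pmyosin_fractions=_triplet(0.33, 0.42, 0.25),
            ),
        }
        if genotype not in presets:
            raise ValueError(f"no preset for genotype {genotype!r}")
        base = presets[genotype]
        base.update(kw)
        return cls(**base)


@dataclass
class ExperimentSpec:
    """An experimental arm compared against the run's control hearts."""

    genotype: str = "tbx5a"
    n_embryos: int = 2
    overrides: dict = field(default_factory=dict)

    def generator(self, base: GeneratorConfig) -> GeneratorConfig:
        cfg = GeneratorConfig.mutant(self.genotype)
        merged = {**asdict(base), **{k: v for k, v in asdict(cfg).items()
                                     if getattr(cfg, k) != getattr(GeneratorConfig(), k)}}
        merged.update(self.overrides)
        merged["genotype"] = self.genotype
        return GeneratorConfig(**merged)


@dataclass
class PipelineConfig:
    """Top-level configuration for the generate→…→stats pipeline."""

    seed: int = 0
    stage: str = "48"
    n_embryos: int = 2
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    experiment: ExperimentSpec | None = field(default_factory=ExperimentSpec)

    # intensity-profiling options (µm)
    band_width: float = 1.0
    corner_exclusion: float = 1.0
    subtract_background: bool = True

    # statistics options
    stats_level: str = "cell"  # cell | embryo (both are written)
    outlier_k: float = 1.5
    metrics: tuple = ("apical_area", "apicobasal_length", "volume", "circularity")
    # optional reference scale per metric: {metric: (mean_ref, sd_ref)};
    # when absent the control group's own mean/SD serve as the reference
    reference_stats: dict = field(default_factory=dict)

    write_images: bool = False
    make_plots: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_embryos <= 0:
            raise ValueError("n_embryos must be > 0")
        if self.band_width <= 0 or self.corner_exclusion < 0:
            raise ValueError("band parameters out of range")
        if self.stats_level not in {"cell", "embryo"}:
            raise ValueError("stats_level must be 'cell' or 'embryo'")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "generator" in data and isinstance(data["generator"], dict):
            data["generator"] = GeneratorConfig(**data["generator"])
        if "experiment" in data:
            exp = data["experiment"]
            data["experiment"] = ExperimentSpec(**exp) if isinstance(exp, dict) else exp
        if "metrics" in data:
            data["metrics"] = tuple(data["metrics"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=True)


def _plain(obj):
    """Recursively coerce to YAML/JSON-safe builtins."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def config_hash(cfg) -> str:
    """Stable sha256 of a (dataclass) configuration."""
    if hasattr(cfg, "__dataclass_fields__"):
        cfg = asdict(cfg)
    payload = json.dumps(_plain(cfg), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()
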