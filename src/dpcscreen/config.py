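"""Run configuration: serializable parameters for a reproducible run.

A run re-executed from its saved config and seed reproduces all
deterministic outputs bit-identically.  Output artifacts written by the
CLI carry the config hash and seed in a provenance sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

SCHEMA_VERSION = "1"


@dataclass
class GeneratorConfig:
    baseline_activated_fraction: float = 0.05
    max_activated_fraction: float = 0.9
    half_effect_dose: float = 2.5
    hill_coefficient: float = 1.5
    onset_time_h: float = 6.0
    base_doubling_time: float = 24.0
    peak_dose: float = 10.0
    peak_rate_multiplier: float = 1.6
    high_dose_suppression: float = 0.5
    carrying_capacity: float = 500.0
    canvas: tuple[int, int] = (512, 512)
    render_scale: float = 1.0
    n_initial: float = 100.0
    model_dose: float = 10.0


@dataclass
class SegmentationConfig:
    channel: str = "dpc"
    min_area: int = 60
    smoothing_scale: float = 2.0


@dataclass
class ClassifierConfig:
    backend: str = "mlp"
    epochs: int = 120
    input_size: int = 96
    n_per_class: int = 200
    train_fraction: float = 0.8


@dataclass
class QcConfig:
    z_prime_min: float = 0.5
    cv_max: float | None = None
    control_level: float = 0.95
    model_tail: float = 0.05
    r_squared_threshold: float = 0.3


@dataclass
class ScreenConfig:
    n_compounds: int = 96
    inhibitor_fraction: float = 0.1
    toxic_fraction: float = 0.05
    primary_conc_um: float = 10.0
    confirmation_concs_um: tuple[float, ...] = (20.0, 10.0, 5.0, 1.0)
    canvas: tuple[int, int] = (128, 128)
    render_scale: float = 0.267
    n_initial: float = 45.0
    n_control: int = 12
    n_model: int = 12


@dataclass
class RunConfig:
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    qc: QcConfig = field(default_factory=QcConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    schema_version: str = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def build(dc, d):
            if d is None:
                return dc()
            names = {f.name: f for f in dataclasses.fields(dc)}
            kwargs = {}
            for k, v in d.items():
                if k in names:
                    if isinstance(v, list):
                        v = tuple(v)
                    kwargs[k] = v
            return dc(**kwargs)

        version = str(data.get("schema_version", SCHEMA_VERSION))
        if version.split(".")[0] != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version!r}")
        return cls(
            seed=int(data.get("seed", 0)),
            generator=build(GeneratorConfig, data.get("generator")),
            segmentation=build(SegmentationConfig, data.get("segmentation")),
            classifier=build(ClassifierConfig, data.get("classifier")),
            qc=build(QcConfig, data.get("qc")),
            screen=build(ScreenConfig, data.get("screen")),
            schema_version=version,
        )


def write_provenance(out_dir: str | Path, config: RunConfig, extra: dict | None = None) -> Path:
    """Write the provenance sidecar (config hash + seed) for a run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "schema_version": config.schema_version,
    }
    if extra:
        payload.update(extra)
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(payload, indent=2))
    return path
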