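"""Run configuration: one YAML-serialisable object for the whole pipeline.

A :class:`RunConfig` captures everything a run depends on — simulation
design (or ingest paths), extraction options, screening and model
settings, and the seed — and round-trips losslessly through YAML. Every
analysis artifact embeds the configuration digest so outputs can be tied
back to the exact settings that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import GroupPhenotype, SimulationDesign

__all__ = ["RunConfig"]


def _design_to_dict(design: SimulationDesign) -> dict:
    out = dataclasses.asdict(design)
    out["age_range"] = list(design.age_range)
    out["phenotypes"] = {
        label: {
            "ou_theta": p.ou_theta,
            "ou_sigma_ap": p.ou_sigma_ap,
            "ou_sigma_ml": p.ou_sigma_ml,
            "osc_amp": p.osc_amp,
            "osc_freq_band": list(p.osc_freq_band),
            "jerk_rate": p.jerk_rate,
            "jerk_amp": p.jerk_amp,
        }
        for label, p in design.phenotypes.items()
    }
    return out


def _design_from_dict(raw: dict) -> SimulationDesign:
    raw = dict(raw)
    if "age_range" in raw:
        raw["age_range"] = tuple(raw["age_range"])
    if "phenotypes" in raw:
        raw["phenotypes"] = {
            label: GroupPhenotype(label=label, **{
                **params,
                "osc_freq_band": tuple(params["osc_freq_band"]),
            })
            for label, params in raw["phenotypes"].items()
        }
    return SimulationDesign(**raw)


@dataclass
class RunConfig:
    """All settings for one end-to-end run."""

    #: 'simulate' generates the cohort; 'ingest' reads trials from disk.
    mode: str = "simulate"
    input_path: str | None = None
    metadata_path: str | None = None
    out_dir: str = "copsway_run"
    seed: int = 0
    design: SimulationDesign = field(default_factory=SimulationDesign)
    fs_override: float | None = None
    lowpass_hz: float | None = None
    freq_component_form: str = "prieto"
    screening_quantile: float = 0.975
    screen: str = "univariate"
    alpha: float = 0.05
    reference_group: str = "dystonia"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError("mode must be 'simulate' or 'ingest'")
        if self.mode == "ingest" and not self.input_path:
            raise ValueError("ingest mode requires input_path")
        if not 0.5 < self.screening_quantile < 1:
            raise ValueError("screening_quantile must lie in (0.5, 1)")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["design"] = _design_to_dict(self.design)
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "design" in raw and not isinstance(raw["design"],
                                              SimulationDesign):
            raw["design"] = _design_from_dict(raw["design"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        """Short stable hash of the scientific configuration.

        Filesystem locations (out_dir, input/metadata paths) are excluded:
        two runs with the same settings written to different directories
        produce the same digest and the same numbers.
        """
        raw = self.to_dict()
        for key in ("out_dir", "input_path", "metadata_path"):
            raw.pop(key, None)
        canonical = json.dumps(raw, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
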