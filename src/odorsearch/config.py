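"""Run configuration: YAML/JSON round-trip, hashing, packaged fixtures."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

from .arena import ArenaConfig
from .infotaxis import InfotaxisConfig
from .plume import DOSE_LEVELS, DoseLevel, PlumeParams
from .reactive import ReactiveConfig, config_for_strategy

__all__ = ["RunConfig", "load_config", "table1_counts"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: arena, plume, dose table,
    per-strategy reactive parameters and infotaxis parameters."""

    arena: ArenaConfig = field(default_factory=ArenaConfig)
    plume: PlumeParams = field(default_factory=PlumeParams)
    doses: dict[str, DoseLevel] = field(
        default_factory=lambda: dict(DOSE_LEVELS))
    reactive: dict[str, ReactiveConfig] = field(
        default_factory=lambda: {s: config_for_strategy(s)
                                 for s in ("sp", "za", "ze")})
    infotaxis: InfotaxisConfig = field(default_factory=InfotaxisConfig)

    # -------------------------------------------------------------- encode
    def to_dict(self) -> dict:
        def listify(d: dict) -> dict:
            return {k: (list(v) if isinstance(v, tuple)
                        else listify(v) if isinstance(v, dict) else v)
                    for k, v in d.items()}

        return {
            "arena": listify(dataclasses.asdict(self.arena)),
            "plume": listify(dataclasses.asdict(self.plume)),
            "doses": {k: dataclasses.asdict(v) for k, v in self.doses.items()},
            "reactive": {k: dataclasses.asdict(v)
                         for k, v in self.reactive.items()},
            "infotaxis": listify(dataclasses.asdict(self.infotaxis)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        if "arena" in d:
            arena = dict(d["arena"])
            for key in ("start", "source"):
                if key in arena:
                    arena[key] = tuple(arena[key])
            kwargs["arena"] = ArenaConfig(**arena)
        if "plume" in d:
            plume = dict(d["plume"])
            if "source_pos" in plume:
                plume["source_pos"] = tuple(plume["source_pos"])
            kwargs["plume"] = PlumeParams(**plume)
        if "doses" in d:
            kwargs["doses"] = {k: DoseLevel(**v) for k, v in d["doses"].items()}
        if "reactive" in d:
            kwargs["reactive"] = {k: ReactiveConfig(**v)
                                  for k, v in d["reactive"].items()}
        if "infotaxis" in d:
            it = dict(d["infotaxis"])
            if "model_plume" in it:
                mp = dict(it["model_plume"])
                if "source_pos" in mp:
                    mp["source_pos"] = tuple(mp["source_pos"])
                it["model_plume"] = PlumeParams(**mp)
            kwargs["infotaxis"] = InfotaxisConfig(**it)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        """Stable hash of the resolved configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path=None) -> RunConfig:
    """Load a YAML/JSON config file; None gives the defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.from_dict(data or {})


def table1_counts() -> pd.DataFrame:
    """Packaged success/total trial counts of the robotic assay (tidy form:
    strategy, dose, successes, totals)."""
    with resources.files("odorsearch.data").joinpath(
            "table1_success_counts.csv").open() as fh:
        return pd.read_csv(fh)
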