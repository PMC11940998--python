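"""YAML/JSON run configuration: one document that pins every stage.

A run config round-trips losslessly through its file representation and is
validated before any computation starts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .plsda import PLSConfig
from .preprocess import PreprocessConfig
from .protocol import ProtocolConfig
from .synth import PeakSpec, SyntheticConfig, WavenumberAxis, default_peak_library

__all__ = ["RunConfig", "load_run_config"]


@dataclass(frozen=True)
class RunConfig:
    preprocess: PreprocessConfig = PreprocessConfig()
    pls: PLSConfig = PLSConfig()
    protocol: ProtocolConfig = ProtocolConfig()
    synth: SyntheticConfig | None = None
    paths: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "preprocess": asdict(self.preprocess),
            "pls": asdict(self.pls),
            "protocol": asdict(self.protocol),
            "paths": dict(self.paths),
        }
        if self.synth is not None:
            sd = asdict(self.synth)
            sd["classes"] = [list(c) for c in self.synth.classes]
            sd["peaks"] = [asdict(p) for p in self.synth.peaks]
            sd["baseline_coeffs"] = list(self.synth.baseline_coeffs)
            d["synth"] = sd
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _synth_from_dict(d: dict) -> SyntheticConfig:
    kwargs = dict(d)
    if "axis" in kwargs:
        kwargs["axis"] = WavenumberAxis(**kwargs["axis"])
    if "peaks" in kwargs:
        kwargs["peaks"] = [PeakSpec(**p) for p in kwargs["peaks"]]
    else:
        kwargs["peaks"] = default_peak_library()
    if "classes" in kwargs:
        kwargs["classes"] = tuple((str(c[0]), int(c[1]), int(c[2])) for c in kwargs["classes"])
    if "baseline_coeffs" in kwargs:
        kwargs["baseline_coeffs"] = tuple(float(c) for c in kwargs["baseline_coeffs"])
    return SyntheticConfig(**kwargs)


def _from_dict(doc: dict) -> RunConfig:
    known = {"preprocess", "pls", "protocol", "synth", "paths", "seed"}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    pp = doc.get("preprocess", {})
    if "crop" in pp:
        pp = dict(pp, crop=tuple(pp["crop"]))
    cfg = RunConfig(
        preprocess=PreprocessConfig(**pp),
        pls=PLSConfig(**doc.get("pls", {})),
        protocol=ProtocolConfig(**doc.get("protocol", {})),
        synth=_synth_from_dict(doc["synth"]) if "synth" in doc else None,
        paths={k: str(v) for k, v in doc.get("paths", {}).items()},
    )
    if cfg.synth is not None:
        cfg.synth.validate()
    return cfg


def load_run_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML (or JSON) run configuration file."""
    path = Path(path)
    if not path.exists():
        raise ValueError(f"config file not found: {path}")
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    try:
        return _from_dict(doc)
    except TypeError as err:
        raise ValueError(f"invalid config in {path}: {err}") from err
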