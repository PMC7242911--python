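"""Serializable assay reports shared by every fitting pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any

ASSAY_KINDS = (
    "mst_binding",
    "dose_response",
    "stopflow",
    "quench",
    "accumulation",
    "tissue",
    "stats",
)


@dataclasses.dataclass
class AssayReport:
    """Record of one fit or quantification: parameters, flags, provenance.

    ``parameters`` maps a name to a dict with keys ``value``, ``se`` and
    ``units`` (``se`` may be None for quantities without an uncertainty).
    ``provenance`` carries input paths, the config hash, the seed and the
    package version so a report can be regenerated from itself.
    """

    assay: str
    parameters: dict[str, dict[str, Any]] = dataclasses.field(default_factory=dict)
    flags: list[str] = dataclasses.field(default_factory=list)
    provenance: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.assay not in ASSAY_KINDS:
            raise ValueError(
                f"unknown assay kind {self.assay!r}; expected one of {ASSAY_KINDS}"
            )

    def add_parameter(
        self, name: str, value: float, se: float | None = None, units: str = ""
    ) -> None:
        self.parameters[name] = {
            "value": None if value is None else float(value),
            "se": None if se is None else float(se),
            "units": units,
        }

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AssayReport":
        return cls(
            assay=d["assay"],
            parameters=d.get("parameters", {}),
            flags=list(d.get("flags", [])),
            provenance=d.get("provenance", {}),
        )

    @classmethod
    def from_json(cls, text: str) -> "AssayReport":
        return cls.from_dict(json.loads(text))

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json() + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "AssayReport":
        return cls.from_json(Path(path).read_text())


def make_provenance(
    inputs: list[str] | None = None,
    config: dict[str, Any] | None = None,
    seed: int | None = None,
) -> dict[str, Any]:
    """Provenance block: inputs, deterministic config hash, seed, version."""
    from aquakin import __version__

    cfg_json = json.dumps(config or {}, sort_keys=True)
    return {
        "inputs": inputs or [],
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "config": config or {},
        "seed": seed,
        "software_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
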