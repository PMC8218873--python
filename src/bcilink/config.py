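"""One structured document holding every stage's parameters.

Defaults are the deployed system's constants: 20 kS/s x 12-bit ADC with a
24-bit sync word per 50 us frame, the 500 uV single-sample mitigation
threshold, 1 s severely-errored-second windows, 300 s analysis segments,
and the 6x6 / 120 s Grid Task.  Unknown keys in a config file are rejected
rather than ignored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .decoder import GridTaskConfig
from .link import ImpairmentConfig, LinkSpec
from .mitigation import MitigationConfig

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class SignalDefaults:
    n_channels: int = 96
    duration_s: float = 60.0
    native_rate: float = 60_000.0
    seed: int = 0


@dataclass(frozen=True)
class QCDefaults:
    ses_window_s: float = 1.0
    segment_s: float = 300.0
    welch_window_s: float = 4.0


@dataclass(frozen=True)
class RunConfig:
    signal: SignalDefaults = field(default_factory=SignalDefaults)
    link: LinkSpec = field(default_factory=LinkSpec)
    impairment: ImpairmentConfig = field(default_factory=ImpairmentConfig)
    mitigation: MitigationConfig = field(default_factory=MitigationConfig)
    qc: QCDefaults = field(default_factory=QCDefaults)
    task: GridTaskConfig = field(default_factory=GridTaskConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        blob = json.dumps(self.to_dict(), indent=2, sort_keys=True, default=str)
        if path is not None:
            Path(path).write_text(blob)
        return blob

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        sections = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(doc) - set(sections)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        for name, sec in doc.items():
            typ = {
                "signal": SignalDefaults,
                "link": LinkSpec,
                "impairment": ImpairmentConfig,
                "mitigation": MitigationConfig,
                "qc": QCDefaults,
                "task": GridTaskConfig,
            }[name]
            valid = {f.name for f in dataclasses.fields(typ)}
            bad = set(sec) - valid
            if bad:
                raise ValueError(f"unknown keys in config section {name!r}: {sorted(bad)}")
            if name == "impairment" and sec.get("gilbert_elliott") is not None:
                from .link import GilbertElliott

                sec = dict(sec)
                sec["gilbert_elliott"] = GilbertElliott(**sec["gilbert_elliott"])
            kwargs[name] = typ(**sec)
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
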