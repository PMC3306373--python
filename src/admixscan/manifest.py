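"""Run manifests: a reproducibility record written next to every stage output."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field

import yaml

from . import __version__


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config_dict: dict) -> str:
    canonical = yaml.safe_dump(config_dict, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


@dataclass
class RunManifest:
    stage: str
    seed: int | None
    config_hash: str | None
    package_version: str = __version__
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: dict = field(default_factory=dict)
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S%z"))

    def add_input(self, path) -> None:
        self.inputs[str(path)] = sha256_file(path)

    def add_output(self, path) -> None:
        self.outputs[str(path)] = sha256_file(path)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
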