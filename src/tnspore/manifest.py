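"""Run manifests: enough metadata to check that a run is reproducible."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


@dataclass
class RunManifest:
    tool: str
    version: str
    seed: int | None = None
    config_hash: str = ""
    inputs: dict[str, str] = field(default_factory=dict)     # path -> sha256
    outputs: dict[str, str] = field(default_factory=dict)    # path -> sha256
    record_counts: dict[str, int] = field(default_factory=dict)
    wall_time_s: float = 0.0
    _t0: float = field(default_factory=time.monotonic, repr=False)

    def add_input(self, path) -> None:
        self.inputs[Path(path).name] = sha256_file(path)

    def add_output(self, path) -> None:
        self.outputs[Path(path).name] = sha256_file(path)

    def count(self, stage: str, n: int) -> None:
        self.record_counts[stage] = int(n)

    def write(self, path) -> None:
        self.wall_time_s = round(time.monotonic() - self._t0, 3)
        payload = {k: v for k, v in self.__dict__.items() if not k.startswith("_")}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
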