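"""Run manifests: reproducibility metadata written next to every output.

Inter-laboratory SAR comparisons are notoriously variable, so every CLI
run records exactly what produced its outputs: the config snapshot, the
package version, all seeds, timestamps, per-stage runtimes and a checksum
inventory of the files written.  The manifest is written last, after all
outputs exist.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    command: str
    seed: int
    config: dict = field(default_factory=dict)
    version: str = ""
    started: str = ""
    finished: str = ""
    stage_runtimes_s: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)   # relative path -> sha256

    def __post_init__(self):
        if not self.version:
            from . import __version__
            self.version = __version__
        if not self.started:
            self.started = time.strftime("%Y-%m-%dT%H:%M:%S")
        self._t0 = time.monotonic()
        self._stage_start = self._t0

    def stage_done(self, name: str) -> None:
        now = time.monotonic()
        self.stage_runtimes_s[name] = round(now - self._stage_start, 3)
        self._stage_start = now

    def add_output(self, outdir, path) -> None:
        rel = str(Path(path).relative_to(outdir))
        self.outputs[rel] = sha256_file(path)

    def write(self, outdir) -> Path:
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        payload = {k: v for k, v in self.__dict__.items()
                   if not k.startswith("_")}
        path = Path(outdir) / "manifest.json"
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
        return path

    @staticmethod
    def verify(outdir) -> bool:
        """Check that every listed output is present with matching checksum."""
        outdir = Path(outdir)
        with open(outdir / "manifest.json") as fh:
            payload = json.load(fh)
        for rel, digest in payload["outputs"].items():
            p = outdir / rel
            if not p.exists() or sha256_file(p) != digest:
                return False
        return True
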