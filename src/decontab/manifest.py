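"""Run provenance: a machine-readable manifest for every CLI run."""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__


def file_digest(path: str | Path) -> str:
    """sha256 hex digest of a file's bytes."""
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class StageTally:
    stage: str
    taxa_in: int
    taxa_out: int


@dataclass
class RunManifest:
    """What ran, on what, with which resolved parameters.

    Stage tallies must satisfy conservation: within a stage,
    ``taxa_in - taxa_out`` is the number of removals, and consecutive stages
    chain (``taxa_out`` of one equals ``taxa_in`` of the next).
    """

    command: str = ""
    params: dict = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)
    seed: int | None = None
    version: str = __version__
    started: str = ""
    finished: str = ""
    stage_tallies: list[StageTally] = field(default_factory=list)

    @classmethod
    def start(cls, params: dict, seed: int | None = None) -> "RunManifest":
        return cls(
            command=" ".join(sys.argv),
            params=params,
            seed=seed,
            started=datetime.now(timezone.utc).isoformat(),
        )

    def add_input(self, path: str | Path) -> None:
        self.input_digests[str(path)] = file_digest(path)

    def add_stage(self, stage: str, taxa_in: int, taxa_out: int) -> None:
        self.stage_tallies.append(StageTally(stage, taxa_in, taxa_out))

    def validate(self) -> None:
        for tally in self.stage_tallies:
            if tally.taxa_out > tally.taxa_in:
                raise ValueError(f"stage {tally.stage!r} created taxa")
        for prev, nxt in zip(self.stage_tallies, self.stage_tallies[1:]):
            if prev.taxa_out != nxt.taxa_in:
                raise ValueError(
                    f"stage chain broken: {prev.stage!r} out={prev.taxa_out} "
                    f"!= {nxt.stage!r} in={nxt.taxa_in}"
                )

    def finish(self) -> None:
        self.finished = datetime.now(timezone.utc).isoformat()
        self.validate()

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "params": self.params,
            "input_digests": self.input_digests,
            "seed": self.seed,
            "version": self.version,
            "started": self.started,
            "finished": self.finished,
            "stage_tallies": [
                {"stage": t.stage, "taxa_in": t.taxa_in, "taxa_out": t.taxa_out}
                for t in self.stage_tallies
            ],
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.to_dict(), handle, indent=2)

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path, encoding="utf-8") as handle:
            doc = json.load(handle)
        manifest = cls(
            command=doc["command"],
            params=doc["params"],
            input_digests=doc["input_digests"],
            seed=doc["seed"],
            version=doc["version"],
            started=doc["started"],
            finished=doc["finished"],
        )
        for t in doc["stage_tallies"]:
            manifest.add_stage(t["stage"], t["taxa_in"], t["taxa_out"])
        return manifest
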