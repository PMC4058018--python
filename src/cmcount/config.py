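"""Run configuration: TOML parsing, validation and provenance hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .imaging import CountConfig


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration.

    Sections of the TOML file map onto fields: ``[paths]`` (slide_dir,
    manifest, out_dir), ``[imaging]`` (every :class:`CountConfig` cut-off)
    and ``[run]`` (seed, log_level).  Unknown keys are rejected rather than
    silently ignored.
    """

    slide_dir: str | None = None
    manifest: str | None = None
    out_dir: str = "cmcount_out"
    imaging: CountConfig = field(default_factory=CountConfig)
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        """Stable digest of the full configuration for provenance records."""
        payload = {
            "slide_dir": self.slide_dir,
            "manifest": self.manifest,
            "out_dir": self.out_dir,
            "imaging": dataclasses.asdict(self.imaging),
            "seed": self.seed,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


_PATH_KEYS = {"slide_dir", "manifest", "out_dir"}
_RUN_KEYS = {"seed", "log_level"}
_IMAGING_KEYS = {f.name for f in dataclasses.fields(CountConfig)}


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)

    unknown_sections = set(raw) - {"paths", "imaging", "run"}
    if unknown_sections:
        raise ConfigError(f"unknown config sections: {sorted(unknown_sections)}")

    paths = raw.get("paths", {})
    if bad := set(paths) - _PATH_KEYS:
        raise ConfigError(f"unknown [paths] keys: {sorted(bad)}")
    imaging_raw = raw.get("imaging", {})
    if bad := set(imaging_raw) - _IMAGING_KEYS:
        raise ConfigError(f"unknown [imaging] keys: {sorted(bad)}")
    run = raw.get("run", {})
    if bad := set(run) - _RUN_KEYS:
        raise ConfigError(f"unknown [run] keys: {sorted(bad)}")

    try:
        imaging = CountConfig(**imaging_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [imaging] settings: {exc}") from exc
    return RunConfig(
        slide_dir=paths.get("slide_dir"),
        manifest=paths.get("manifest"),
        out_dir=paths.get("out_dir", "cmcount_out"),
        imaging=imaging,
        seed=int(run.get("seed", 0)),
        log_level=str(run.get("log_level", "INFO")),
    )
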