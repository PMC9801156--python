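"""Run configuration: a small, versioned YAML schema shared by all CLI
commands.  Every field has a documented default and unknown keys are
rejected by name, so a typo cannot silently fall back to a default."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .acvo import AcvoConfig
from .synthetic import SyntheticConfig
from .training import AnfisTemplate

CONFIG_VERSION = 1


class ConfigError(ValueError):
    """A configuration file failed to parse or validate."""


@dataclass(frozen=True)
class RunConfig:
    """Top-level run settings.

    ``seed`` governs the generator, the data split and the optimizer of a
    run; ``verbosity`` 0 silences informational logging.
    """

    seed: int = 0
    verbosity: int = 1
    acvo: AcvoConfig = field(default_factory=AcvoConfig)
    anfis: AnfisTemplate = field(default_factory=lambda: AnfisTemplate(n_inputs=7))
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)


_SECTIONS = {
    "acvo": AcvoConfig,
    "anfis": AnfisTemplate,
    "synthetic": SyntheticConfig,
}
_SCALARS = {"seed", "version", "verbosity"}


def _build_section(cls, payload: dict, section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(payload) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section {section!r}: {', '.join(sorted(unknown))}"
        )
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in payload.items()
    }
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {section!r}: {exc}") from exc


def load_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Parse a YAML run config; ``seed`` (e.g. from the command line)
    overrides the file's value."""
    payload: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        payload = raw
    unknown = set(payload) - _SCALARS - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown key(s): {', '.join(sorted(unknown))}")
    version = payload.get("version", CONFIG_VERSION)
    if version != CONFIG_VERSION:
        raise ConfigError(f"unsupported config version {version}")
    kwargs: dict = {}
    for name, cls in _SECTIONS.items():
        if name in payload:
            if not isinstance(payload[name], dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            kwargs[name] = _build_section(cls, payload[name], name)
    if "verbosity" in payload:
        kwargs["verbosity"] = int(payload["verbosity"])
    kwargs["seed"] = int(seed if seed is not None else payload.get("seed", 0))
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the full run configuration (for log headers)."""
    canonical = yaml.safe_dump(_plain(asdict(config)), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items() if k != "planted"}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
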