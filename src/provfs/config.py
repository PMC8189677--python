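"""Configuration: virtual-dynamic-file (VDF) rules, cache sizes, store settings.

The config file is YAML. A minimal example::

    vdf_rules:
      - name: fastq_to_fasta
        source_pattern: "*.fastq"
        extension: ".fasta"
        command: "seqkit fq2fa {source}"
        output_channel: stdout
    cache:
      block_size: 131072
      memory_limit: 268435456
    store:
      flush_threshold: 10000

``command`` templates must contain the ``{source}`` placeholder; rules with
``output_channel: file`` must also contain ``{output}``.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field

import yaml

DEFAULT_BLOCK_SIZE = 128 * 1024
DEFAULT_MEMORY_LIMIT = 256 * 1024 * 1024
DEFAULT_FLUSH_THRESHOLD = 10_000

SOURCE_PLACEHOLDER = "{source}"
OUTPUT_PLACEHOLDER = "{output}"


class ConfigError(ValueError):
    """Raised for malformed or inconsistent configuration."""


@dataclass(frozen=True)
class VDFSpec:
    """One virtual-dynamic-file rule.

    A real file whose basename matches ``source_pattern`` gains a virtual
    sibling named ``<source name><extension>`` whose content is the output of
    ``command_template`` run over the source.
    """

    name: str
    source_pattern: str
    extension: str
    command_template: str
    output_channel: str = "stdout"  # "stdout" | "file"

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("VDF rule must have a non-empty name")
        if not self.extension or not self.extension.startswith("."):
            raise ConfigError(
                f"rule {self.name!r}: extension must be non-empty and begin with '.'"
            )
        if SOURCE_PLACEHOLDER not in self.command_template:
            raise ConfigError(
                f"rule {self.name!r}: command template lacks {SOURCE_PLACEHOLDER}"
            )
        if self.output_channel not in ("stdout", "file"):
            raise ConfigError(
                f"rule {self.name!r}: output_channel must be 'stdout' or 'file'"
            )
        if self.output_channel == "file" and OUTPUT_PLACEHOLDER not in self.command_template:
            raise ConfigError(
                f"rule {self.name!r}: output_channel=file requires {OUTPUT_PLACEHOLDER} "
                "in the command template"
            )

    def matches_source(self, basename: str) -> bool:
        return fnmatch.fnmatchcase(basename, self.source_pattern)

    def virtual_name(self, source_basename: str) -> str:
        """Virtual entry name for a matching source (full name + extension)."""
        return source_basename + self.extension

    def command_for(self, source_path: str, output_path: str | None = None) -> str:
        cmd = self.command_template.replace(SOURCE_PLACEHOLDER, _shquote(source_path))
        if self.output_channel == "file":
            if output_path is None:
                raise ValueError("file-channel rule needs an output path")
            cmd = cmd.replace(OUTPUT_PLACEHOLDER, _shquote(output_path))
        return cmd


def _shquote(s: str) -> str:
    import shlex

    return shlex.quote(s)


@dataclass
class CacheConfig:
    block_size: int = DEFAULT_BLOCK_SIZE
    memory_limit: int = DEFAULT_MEMORY_LIMIT
    disk_tier: str | None = None  # default: temp dir per mount session

    def __post_init__(self) -> None:
        if self.block_size <= 0 or self.memory_limit <= 0:
            raise ConfigError("cache block_size and memory_limit must be positive")


@dataclass
class StoreConfig:
    database: str | None = None  # default: in-memory / per-session file
    flush_threshold: int = DEFAULT_FLUSH_THRESHOLD

    def __post_init__(self) -> None:
        if self.flush_threshold <= 0:
            raise ConfigError("store flush_threshold must be positive")


@dataclass
class LogConfig:
    level: str = "INFO"
    destination: str | None = None  # None -> stderr


@dataclass
class Config:
    vdf_rules: list[VDFSpec] = field(default_factory=list)
    cache: CacheConfig = field(default_factory=CacheConfig)
    store: StoreConfig = field(default_factory=StoreConfig)
    log: LogConfig = field(default_factory=LogConfig)

    def __post_init__(self) -> None:
        names = [r.name for r in self.vdf_rules]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ConfigError(f"duplicate VDF rule names: {sorted(dupes)}")
        _check_rule_collisions(self.vdf_rules)

    def to_snapshot(self) -> dict:
        """JSON-serializable snapshot stored with each mount session."""
        return {
            "vdf_rules": [
                {
                    "name": r.name,
                    "source_pattern": r.source_pattern,
                    "extension": r.extension,
                    "command": r.command_template,
                    "output_channel": r.output_channel,
                }
                for r in self.vdf_rules
            ],
            "cache": {
                "block_size": self.cache.block_size,
                "memory_limit": self.cache.memory_limit,
            },
            "store": {"flush_threshold": self.store.flush_threshold},
        }


def _check_rule_collisions(rules: list[VDFSpec]) -> None:
    """Two rules may not produce the same virtual name from one source.

    Detected structurally: identical extensions with overlapping patterns are
    only a collision if some name can match both patterns; we approximate with
    a direct cross-test of each rule's pattern against the other's (cheap and
    catches the practical cases: equal patterns, '*' wildcards).
    """
    for i, a in enumerate(rules):
        for b in rules[i + 1 :]:
            if a.extension != b.extension:
                continue
            probe_a = a.source_pattern.replace("*", "x").replace("?", "x")
            probe_b = b.source_pattern.replace("*", "x").replace("?", "x")
            if (
                a.matches_source(probe_b)
                and b.matches_source(probe_b)
                or a.matches_source(probe_a)
                and b.matches_source(probe_a)
            ):
                raise ConfigError(
                    f"rules {a.name!r} and {b.name!r} produce the same virtual "
                    f"name for sources matching both patterns"
                )


def parse_config(text: str) -> Config:
    """Parse YAML configuration text into a validated :class:`Config`.

    Omitted cache/store sections receive defaults. Raises
    :class:`ConfigError` naming the offending rule for invalid rules,
    duplicate names, or colliding virtual names.
    """
    try:
        raw = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:  # pragma: no cover - message path
        raise ConfigError(f"invalid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("top-level config must be a mapping")

    rules = []
    for item in raw.get("vdf_rules", []) or []:
        if not isinstance(item, dict):
            raise ConfigError("each vdf_rules entry must be a mapping")
        try:
            rules.append(
                VDFSpec(
                    name=str(item.get("name", "")),
                    source_pattern=str(item.get("source_pattern", "*")),
                    extension=str(item.get("extension", "")),
                    command_template=str(item.get("command", item.get("command_template", ""))),
                    output_channel=str(item.get("output_channel", "stdout")),
                )
            )
        except ConfigError:
            raise
        except Exception as exc:
            raise ConfigError(f"invalid rule {item!r}: {exc}") from exc

    cache_raw = raw.get("cache", {}) or {}
    store_raw = raw.get("store", {}) or {}
    log_raw = raw.get("log", {}) or {}
    return Config(
        vdf_rules=rules,
        cache=CacheConfig(
            block_size=int(cache_raw.get("block_size", DEFAULT_BLOCK_SIZE)),
            memory_limit=int(cache_raw.get("memory_limit", DEFAULT_MEMORY_LIMIT)),
            disk_tier=cache_raw.get("disk_tier"),
        ),
        store=StoreConfig(
            database=store_raw.get("database"),
            flush_threshold=int(store_raw.get("flush_threshold", DEFAULT_FLUSH_THRESHOLD)),
        ),
        log=LogConfig(
            level=str(log_raw.get("level", "INFO")),
            destination=log_raw.get("destination"),
        ),
    )


def load_config(path: str) -> Config:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_config(fh.read())
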