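"""YAML run configuration.

Key spellings follow the pipeline's documented config contract
(``Search_strategy`` with its capital S included); lookup falls back to
case-insensitive matching so hand-edited files are forgiving. Unknown
keys warn rather than fail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


KNOWN_KEYS = {
    "search_strategy",
    "genome_fasta",
    "species_ncbi_feature_table",
    "trimmed_dir",
    "alignment_dir",
    "output_dir",
    "min_rpm",
    "max_difference",
    "max_mismatch_rate",
    "length_min",
    "length_max",
    "max_hits",
    "flank",
    "seed",
    "top_n_abundance",
    "include_antisense",
    "header_map",
}


@dataclass
class PipelineConfig:
    """Validated run description with defaults applied."""

    search_strategy: str = "host"
    genome_fasta: Path | None = None
    species_ncbi_feature_table: Path | None = None
    trimmed_dir: Path | None = None
    alignment_dir: Path | None = None
    output_dir: Path = Path(".")
    min_rpm: float = 10.0
    max_difference: int = 4
    max_mismatch_rate: float = 0.05
    length_min: int = 16
    length_max: int = 40
    max_hits: int = 50
    flank: int = 0
    seed: int = 0
    top_n_abundance: int = 5
    include_antisense: bool = False
    header_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_rpm < 0:
            raise ConfigError(f"min_rpm must be >= 0, got {self.min_rpm}")
        if not (1 <= self.length_min <= self.length_max):
            raise ConfigError(
                f"length range [{self.length_min}, {self.length_max}] is not sane"
            )
        if self.flank < 0:
            raise ConfigError(f"flank must be >= 0, got {self.flank}")
        if self.search_strategy == "host":
            if self.genome_fasta is None:
                raise ConfigError("missing required key: genome_fasta")
            if self.species_ncbi_feature_table is None:
                raise ConfigError("missing required key: species_NCBI_feature_table")

    @property
    def length_range(self) -> tuple[int, int]:
        return (self.length_min, self.length_max)

    def to_dict(self) -> dict[str, Any]:
        """Canonical (documented-spelling) dict form; round-trip stable."""
        return {
            "Search_strategy": self.search_strategy,
            "genome_fasta": str(self.genome_fasta) if self.genome_fasta else None,
            "species_NCBI_feature_table": (
                str(self.species_ncbi_feature_table)
                if self.species_ncbi_feature_table
                else None
            ),
            "trimmed_dir": str(self.trimmed_dir) if self.trimmed_dir else None,
            "alignment_dir": str(self.alignment_dir) if self.alignment_dir else None,
            "output_dir": str(self.output_dir),
            "min_rpm": self.min_rpm,
            "max_difference": self.max_difference,
            "max_mismatch_rate": self.max_mismatch_rate,
            "length_min": self.length_min,
            "length_max": self.length_max,
            "max_hits": self.max_hits,
            "flank": self.flank,
            "seed": self.seed,
            "top_n_abundance": self.top_n_abundance,
            "include_antisense": self.include_antisense,
            "header_map": dict(self.header_map),
        }


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML config file, applying documented defaults."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_mapping(data)


def config_from_mapping(data: Mapping[str, Any]) -> PipelineConfig:
    norm: dict[str, Any] = {}
    for key, value in data.items():
        lkey = str(key).lower()
        if lkey not in KNOWN_KEYS:
            logger.warning("unknown config key %r ignored", key)
            continue
        norm[lkey] = value

    def _path(key: str) -> Path | None:
        return Path(norm[key]) if norm.get(key) is not None else None

    kwargs: dict[str, Any] = {}
    if "search_strategy" in norm:
        kwargs["search_strategy"] = str(norm["search_strategy"])
    for key in ("genome_fasta", "species_ncbi_feature_table", "trimmed_dir", "alignment_dir"):
        if key in norm:
            kwargs[key] = _path(key)
    if "output_dir" in norm and norm["output_dir"] is not None:
        kwargs["output_dir"] = Path(norm["output_dir"])
    for key, caster in (
        ("min_rpm", float),
        ("max_difference", int),
        ("max_mismatch_rate", float),
        ("length_min", int),
        ("length_max", int),
        ("max_hits", int),
        ("flank", int),
        ("seed", int),
        ("top_n_abundance", int),
        ("include_antisense", bool),
    ):
        if key in norm and norm[key] is not None:
            kwargs[key] = caster(norm[key])
    if "header_map" in norm and norm[key := "header_map"] is not None:
        kwargs["header_map"] = {str(k): str(v) for k, v in norm[key].items()}
    return PipelineConfig(**kwargs)


def dump_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return path
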