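"""Pipeline configuration.

Every numeric threshold used anywhere in the pipeline lives in
:class:`PipelineConfig`, so the analysis constants have a single greppable
source of truth.  Config files are flat ``key: value`` YAML; unset keys take
the defaults, unknown keys are an error.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for malformed or out-of-range configuration."""


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds of the sedaDNA analysis pipeline.

    Attributes
    ----------
    min_read_length : int
        Minimum merged-read length kept after filtering (bp).
    dust_threshold : float
        Reads with a DUST low-complexity score strictly above this are removed.
    lca_min_score : float
        Minimum similarity-search bitscore for a hit to enter LCA assignment.
    lca_max_evalue : float
        Maximum e-value for LCA assignment.
    lca_min_identity : float
        Minimum percent identity for LCA assignment.
    lca_top_percent : float
        Hits within this percentage of the best bitscore are kept (inclusive).
    lca_min_support : float
        Taxa assigned fewer than this percentage of all assigned reads are
        folded into their parent.
    lca_min_cover : float
        Minimum percent of the query covered by the alignment.
    var_min_qual : float
        Minimum Phred site quality for a variant call.
    var_cov_fraction : float
        Variant sites require depth of at least this fraction of mean coverage.
    rare_allele_floor : float
        Alleles below this proportion are dropped as noise (strict ``<``).
    damage_score_threshold : float
        Post-mortem-damage score at or above which a read counts as damaged.
    dmg_var_min_qual : float
        Relaxed site-quality threshold for damage-restricted variant recall.
    dmg_var_min_cov : int
        Relaxed depth threshold for damage-restricted variant recall.
    window_span : int
        Maximum span (bp, inclusive of both ends) of a linked-variant window.
    hap_min_reads : int
        Minimum spanning reads supporting an allele combination.
    hap_min_fraction : float
        Minimum fraction of spanning reads supporting an allele combination.
    n_dedup_replicates : int
        Number of independent random-deduplication replicates.
    profile_length_cap : int
        Hard cap on damage-profile length (bp).
    max_mismatch_rate : float
        Internal mapper: reads above this mismatch rate are left unmapped.
    rng_seed : int
        Master seed; every stochastic stage derives a labelled substream.
    """

    min_read_length: int = 35
    dust_threshold: float = 1.0
    lca_min_score: float = 35.0
    lca_max_evalue: float = 1.0e-5
    lca_min_identity: float = 95.0
    lca_top_percent: float = 10.0
    lca_min_support: float = 0.01
    lca_min_cover: float = 95.0
    var_min_qual: float = 30.0
    var_cov_fraction: float = 0.5
    rare_allele_floor: float = 0.1
    damage_score_threshold: float = 3.0
    dmg_var_min_qual: float = 3.0
    dmg_var_min_cov: int = 3
    window_span: int = 35
    hap_min_reads: int = 3
    hap_min_fraction: float = 0.15
    n_dedup_replicates: int = 5
    profile_length_cap: int = 160
    max_mismatch_rate: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "min_read_length", "dust_threshold", "lca_min_score",
            "lca_max_evalue", "lca_min_identity", "lca_top_percent",
            "lca_min_support", "lca_min_cover", "var_min_qual",
            "rare_allele_floor", "damage_score_threshold", "dmg_var_min_qual",
            "dmg_var_min_cov", "window_span", "hap_min_reads",
            "n_dedup_replicates", "profile_length_cap",
        ]
        for key in positive:
            v = getattr(self, key)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ConfigError(f"{key} must be strictly positive, got {v!r}")
        for key in ("var_cov_fraction", "hap_min_fraction", "max_mismatch_rate"):
            v = getattr(self, key)
            if not (isinstance(v, (int, float)) and 0 < v <= 1):
                raise ConfigError(f"{key} must be in (0, 1], got {v!r}")
        if self.window_span < 2:
            raise ConfigError(
                f"window_span must be >= 2, got {self.window_span!r}")
        if not isinstance(self.rng_seed, int):
            raise ConfigError(f"rng_seed must be an integer, got {self.rng_seed!r}")

    def replace(self, **kwargs) -> "PipelineConfig":
        """Return a copy with the given fields overridden (re-validated)."""
        return dataclasses.replace(self, **kwargs)


_FIELDS = {f.name: f for f in dataclasses.fields(PipelineConfig)}


def load_config(path: str | Path) -> PipelineConfig:
    """Load a flat ``key: value`` config file, applying defaults.

    Unknown keys raise :class:`ConfigError`; out-of-range values raise with
    the offending key named.  An empty file yields all defaults.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a flat key: value mapping")
    unknown = sorted(set(raw) - set(_FIELDS))
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    coerced = {}
    for key, value in raw.items():
        target = _FIELDS[key].type
        if target == "int" and not isinstance(value, int):
            raise ConfigError(f"{key} must be an integer, got {value!r}")
        coerced[key] = value
    return PipelineConfig(**coerced)
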