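"""Run configuration: one YAML file, one global seed, lossless round-trips.

Every stochastic stage derives its seed from ``global_seed`` through the
documented per-stage hash (see :func:`endofactor._utils.derive_seed`), so a
run is reproducible from the config file alone.  Unknown keys are rejected
by name rather than ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._utils import ConfigError, derive_seed
from .ibp import IBPConfig
from .lda import LDAConfig
from .prevalidation import PrevalidationConfig
from .synthetic import SyntheticConfig

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]

_SECTIONS = {
    "synthetic": SyntheticConfig,
    "ibp": IBPConfig,
    "lda": LDAConfig,
}


@dataclass(frozen=True)
class RunConfig:
    synthetic: SyntheticConfig = field(
        default_factory=lambda: SyntheticConfig(n_subjects=300))
    ibp: IBPConfig = field(default_factory=lambda: IBPConfig(
        n_sweeps=150, burn_in=75, burnin_schedule="continuation", n_restarts=3))
    lda: LDAConfig = field(default_factory=lambda: LDAConfig(
        k=3, n_sweeps=300, burn_in=150))
    m: int = 10
    refit_ibp_per_fold: bool = False
    svm_c: float = 1.0
    remove_sites: bool = False
    global_seed: int = 0
    output_dir: str = "endofactor_out"

    def with_seed(self, global_seed: int) -> "RunConfig":
        """Propagate one global seed into every stage config."""
        return dataclasses.replace(
            self,
            global_seed=global_seed,
            synthetic=dataclasses.replace(
                self.synthetic, seed=derive_seed(global_seed, "synthetic")),
            ibp=dataclasses.replace(
                self.ibp, seed=derive_seed(global_seed, "ibp")),
            lda=dataclasses.replace(
                self.lda, seed=derive_seed(global_seed, "lda")),
        )

    def prevalidation_config(self) -> PrevalidationConfig:
        return PrevalidationConfig(
            m=self.m,
            seed=derive_seed(self.global_seed, "prevalidation"),
            ibp_config=self.ibp,
            lda_config=self.lda,
            refit_ibp_per_fold=self.refit_ibp_per_fold,
        )


def _build_section(cls, data: dict, section: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(
            f"unknown key '{sorted(unknown)[0]}' in section '{section}'")
    kwargs = dict(data)
    if "alpha_prior" in kwargs and kwargs["alpha_prior"] is not None:
        kwargs["alpha_prior"] = tuple(kwargs["alpha_prior"])
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config; unknown keys raise naming the offending key."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config file {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")

    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_fields
    if unknown:
        raise ConfigError(f"unknown key '{sorted(unknown)[0]}' at top level")

    kwargs: dict = {}
    for section, cls in _SECTIONS.items():
        if section in raw:
            data = raw[section]
            if not isinstance(data, dict):
                raise ConfigError(f"section '{section}' must be a mapping")
            kwargs[section] = _build_section(cls, data, section)
    for key in top_fields - set(_SECTIONS):
        if key in raw:
            kwargs[key] = raw[key]
    cfg = RunConfig(**kwargs)
    return cfg.with_seed(cfg.global_seed)


def _as_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_as_plain(v) for v in obj]
    return obj


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_as_plain(config), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    """Short stable digest of a config, for provenance headers."""
    blob = yaml.safe_dump(_as_plain(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
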