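"""Pipeline configuration: a strict, round-trippable YAML schema.

The experiment's fixed constants (grid times, stimulus sizes, contrast
ranges) live in the library defaults; the config file holds only the
knobs a rerun might change — experiment kind, cohort size, seeds, output
location.  Unknown keys are rejected so that typos cannot silently fall
back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]

EXPERIMENT_KINDS = ("fmri-main", "fmri-control", "psycho")


@dataclass
class PipelineConfig:
    experiment: str = "fmri-main"
    seed: int = 0
    out_dir: str = "results/pipeline"
    n_subjects: int = 13
    hrf_fit_starts: int = 5
    psychometric_method: str = "ml"
    make_figures: bool = True
    verbosity: int = 1
    #: sha256 of the source file when loaded from disk (provenance).
    source_hash: "str | None" = field(default=None, compare=False)

    def __post_init__(self):
        if self.experiment not in EXPERIMENT_KINDS:
            raise ValueError(
                f"experiment: expected one of {EXPERIMENT_KINDS}, "
                f"got {self.experiment!r}"
            )
        if self.psychometric_method not in ("ml", "ls"):
            raise ValueError(
                f"psychometric_method: expected 'ml' or 'ls', "
                f"got {self.psychometric_method!r}"
            )
        if self.n_subjects < 2:
            raise ValueError("n_subjects: need at least 2")
        if self.seed < 0:
            raise ValueError("seed: must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("source_hash")
        return d

    def config_hash(self) -> str:
        """Digest of the effective settings (not the file formatting)."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config.

    Missing keys take the documented defaults; unknown keys are rejected
    by name.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)} - {"source_hash"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}; "
                         f"known keys are {sorted(known)}")
    cfg = PipelineConfig(**raw)
    cfg.source_hash = hashlib.sha256(text.encode()).hexdigest()[:16]
    return cfg


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
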